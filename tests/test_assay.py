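"""Reporter normalization and cytotoxicity gating."""

import numpy as np
import pandas as pd
import pytest

import pparqsar as p


def raw_table(treated_ratio=None, sc_ratios=(1.0, 1.0, 1.0)):
    """One biological replicate: SC wells plus one treated well per ratio."""
    rows = []
    for t, r in enumerate(sc_ratios):
        rows.append({"group": "SC", "concentration": 0.0, "bio_rep": 1,
                     "tech_rep": t + 1, "FLuc": r * 100.0, "RLuc": 100.0})
    for t, r in enumerate(treated_ratio or []):
        rows.append({"group": "treated", "concentration": 10.0, "bio_rep": 1,
                     "tech_rep": t + 1, "FLuc": r * 100.0, "RLuc": 100.0})
    return pd.DataFrame(rows)


class TestNormalizeReporter:
    def test_treated_identical_to_sc_gives_unity(self):
        drs = p.normalize_reporter(raw_table(treated_ratio=(1.0, 1.0)))
        assert np.allclose(drs.records["response"], 1.0)

    def test_doubled_fluc_gives_fold_two(self):
        drs = p.normalize_reporter(raw_table(treated_ratio=(2.0,)))
        treated = drs.records[drs.records["concentration"] > 0]
        assert treated["response"].iloc[0] == pytest.approx(2.0)

    def test_hand_computed_sc_mean(self):
        # SC ratios (1.0, 1.2, 0.8) average to 1.0; treated ratio 1.5 -> 1.5
        drs = p.normalize_reporter(
            raw_table(treated_ratio=(1.5,), sc_ratios=(1.0, 1.2, 0.8))
        )
        treated = drs.records[drs.records["concentration"] > 0]
        assert treated["response"].iloc[0] == pytest.approx(1.5)

    def test_sc_wells_average_to_one_per_replicate(self):
        raw = pd.concat(
            [raw_table(sc_ratios=(0.9, 1.1, 1.3)),
             raw_table(sc_ratios=(2.0, 2.2)).assign(bio_rep=2)],
            ignore_index=True,
        )
        drs = p.normalize_reporter(raw)
        per_rep = drs.records.groupby("bio_rep")["response"].mean()
        assert np.allclose(per_rep, 1.0)

    def test_idempotence_on_already_normalized_data(self):
        """With SC ratio 1, normalizing again changes nothing."""
        drs = p.normalize_reporter(raw_table(treated_ratio=(1.7, 2.3)))
        again = drs.records.assign(
            group=np.where(drs.records["concentration"] == 0, "SC", "treated"),
            FLuc=drs.records["response"], RLuc=1.0,
        )
        drs2 = p.normalize_reporter(again)
        assert np.allclose(drs.records["response"], drs2.records["response"])

    def test_error_conditions(self):
        bad = raw_table(treated_ratio=(1.0,))
        with pytest.raises(ValueError, match="RLuc"):
            p.normalize_reporter(bad.assign(RLuc=0.0))
        with pytest.raises(ValueError, match="solvent-control"):
            p.normalize_reporter(bad[bad["group"] != "SC"])


class TestHighestNoncytotoxic:
    def prof(self, viab, conc=(10.0, 50.0, 100.0)):
        return p.ViabilityProfile("X", np.array(conc), np.array(viab, dtype=float))

    def test_absolute_threshold_rule(self):
        # 79 < 80 marks 100 µM cytotoxic
        assert p.highest_noncytotoxic(self.prof((98, 95, 79))) == 50.0

    def test_drop_rule_despite_absolute_pass(self):
        # 92 -> 81 drops 11 >= 10 points, so 100 µM cytotoxic although 81 >= 80
        assert p.highest_noncytotoxic(self.prof((100, 92, 81))) == 50.0

    def test_fully_viable_returns_top_dose(self):
        assert p.highest_noncytotoxic(self.prof((100, 100, 100))) == 100.0

    def test_lowest_dose_cytotoxic_returns_none(self):
        assert p.highest_noncytotoxic(self.prof((75, 90, 95))) is None

    def test_prefix_rule_ignores_recovery_at_higher_dose(self):
        # once 50 µM is cytotoxic, apparent recovery at 100 µM does not count
        assert p.highest_noncytotoxic(self.prof((95, 70, 99))) == 10.0

    def test_monotone_in_absolute_threshold(self):
        prof = self.prof((95, 88, 83))
        cuts = [p.highest_noncytotoxic(prof, abs_threshold=t)
                for t in (70, 80, 85, 90, 96)]
        vals = [(-np.inf if c is None else c) for c in cuts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_relative_drop_rule_switch(self):
        # 95 -> 86 is 9 points (passes) but 9.5% relative (fails at 9% threshold)
        prof = self.prof((95, 86, 86))
        assert p.highest_noncytotoxic(prof, drop_threshold=10) == 100.0
        assert p.highest_noncytotoxic(
            prof, drop_threshold=9, drop_rule="relative"
        ) == 10.0


class TestTruncation:
    def make_drs(self, concs):
        rows = [{"concentration": c, "bio_rep": 1, "tech_rep": 1, "response": 1.0}
                for c in concs]
        return p.DoseResponseSet("X", pd.DataFrame(rows))

    def test_rows_above_cutoff_dropped(self):
        drs = self.make_drs([0.1, 1, 10, 50, 100])
        prof = p.ViabilityProfile("X", np.array([10.0, 50.0, 100.0]),
                                  np.array([98.0, 95.0, 79.0]))
        out = p.truncate_to_noncytotoxic(drs, prof)
        assert list(out.records["concentration"]) == [0.1, 1, 10, 50]
        assert out.meta["cytotoxicity_cutoff"] == 50.0

    def test_identity_when_cutoff_is_top_dose(self):
        drs = self.make_drs([1, 10, 50])
        prof = p.ViabilityProfile("X", np.array([50.0]), np.array([99.0]))
        out = p.truncate_to_noncytotoxic(drs, prof)
        pd.testing.assert_frame_equal(out.records, drs.records)

    def test_all_cytotoxic_returns_empty_with_warning(self):
        drs = self.make_drs([1, 10])
        prof = p.ViabilityProfile("X", np.array([1.0, 10.0]),
                                  np.array([60.0, 50.0]))
        with pytest.warns(UserWarning, match="cytotoxic"):
            out = p.truncate_to_noncytotoxic(drs, prof)
        assert out.records.empty

    def test_truncation_never_adds_records(self):
        drs = self.make_drs([1, 10, 50])
        prof = p.ViabilityProfile("X", np.array([1.0, 10.0, 50.0]),
                                  np.array([100.0, 85.0, 84.0]))
        out = p.truncate_to_noncytotoxic(drs, prof)
        assert len(out.records) <= len(drs.records)

    def test_compound_mismatch_rejected(self):
        drs = self.make_drs([1, 10])
        prof = p.ViabilityProfile("Y", np.array([10.0]), np.array([99.0]))
        with pytest.raises(ValueError, match="mismatch"):
            p.truncate_to_noncytotoxic(drs, prof)
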