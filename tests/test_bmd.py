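"""Bayesian BMD engine: candidate fits, averaging, invariants."""

import numpy as np
import pytest

import pparqsar as p
from pparqsar.bmd import CandidateFit, _weighted_quantile

DRAWS, WARMUP = 2000, 1000  # reduced sampling for unit tests


def test_candidate_grid_enumerates_16_models():
    grid = p.candidate_grid()
    assert len(grid) == 16
    assert len({fam for fam, _ in grid}) == 8
    assert len({noise for _, noise in grid}) == 2


class TestBmdFromParams:
    def test_constructed_exponential_returns_ten(self):
        b = p.scale_for_bmd("exponential", 10.0, 30.0, 1.0, bmr=1.5)
        cand = p.ModelCandidate("exponential", "normal", a=1.0, c=30.0, b=b, d=1.0)
        assert p.bmd_from_params(cand, bmr=1.5) == pytest.approx(10.0, rel=1e-8)

    def test_hill_root_matches_grid_oracle(self):
        cand = p.ModelCandidate("hill", "normal", a=1.0, c=25.0, b=8.0, d=2.0)
        grid = np.linspace(1e-6, 100.0, 1_000_000)
        m = cand.median(grid)
        oracle = grid[np.argmax(m >= 1.5)]
        assert p.bmd_from_params(cand, 1.5) == pytest.approx(oracle, rel=1e-4)

    def test_unreached_plateau(self):
        cand = p.ModelCandidate("hill", "normal", a=1.0, c=1.2, b=8.0, d=2.0)
        assert np.isinf(p.bmd_from_params(cand, 1.5))


class TestFitCandidate:
    def test_self_family_noise_free_recovery(self):
        spec = p.CurveSpec(family="hill", true_bmd=10.0, steepness=1.2,
                           noise_scale=0.0)
        drs = p.simulate_dose_response(spec, seed=0)
        fit = p.fit_candidate(drs, "hill", "normal", draws=DRAWS, warmup=WARMUP,
                              seed=3)
        assert fit.ok
        assert np.median(fit.bmd_draws) == pytest.approx(10.0, rel=0.01)

    def test_seeded_determinism(self):
        spec = p.CurveSpec(family="exponential", noise_model="lognormal",
                           noise_scale=0.15)
        drs = p.simulate_dose_response(spec, seed=5)
        f1 = p.fit_candidate(drs, "hill", "lognormal", draws=DRAWS,
                             warmup=WARMUP, seed=9)
        f2 = p.fit_candidate(drs, "hill", "lognormal", draws=DRAWS,
                             warmup=WARMUP, seed=9)
        assert np.array_equal(f1.draws, f2.draws)
        assert np.array_equal(f1.bmd_draws, f2.bmd_draws)

    def test_retained_draw_count(self):
        spec = p.CurveSpec(family="hill", noise_scale=0.1)
        drs = p.simulate_dose_response(spec, seed=1)
        fit = p.fit_candidate(drs, "exponential", "normal", draws=DRAWS,
                              warmup=WARMUP, seed=0)
        assert fit.draws.shape == (DRAWS - WARMUP, 5)

    def test_lognormal_noise_rejects_nonpositive_responses(self):
        spec = p.CurveSpec(family="hill", noise_model="normal", noise_scale=2.0,
                           background=0.1, max_effect=0.5)
        drs = p.simulate_dose_response(spec, seed=2)
        assert (drs.records["response"] <= 0).any()
        fit = p.fit_candidate(drs, "hill", "lognormal", draws=DRAWS,
                              warmup=WARMUP, seed=0)
        assert not fit.ok and fit.log_marginal == -np.inf


class TestModelAverage:
    @staticmethod
    def fake_fit(family, noise, bmd_draws, log_ml):
        return CandidateFit(family, noise, draws=None,
                            bmd_draws=np.asarray(bmd_draws, dtype=float),
                            log_marginal=log_ml, map_theta=None)

    def test_single_candidate_mixture_is_identity(self):
        draws = np.random.default_rng(0).lognormal(2.3, 0.3, 2000)
        fits = [self.fake_fit("hill", "normal", draws, -10.0),
                self.fake_fit("logit", "normal", np.full(2000, 99.0), -np.inf)]
        res = p.model_average(fits, "X")
        assert res.weights["hill/normal"] == pytest.approx(1.0)
        assert res.bmd == pytest.approx(float(np.median(draws)), rel=1e-6)
        lo, hi = np.quantile(draws, [0.05, 0.95])
        assert res.bmdl == pytest.approx(lo, rel=0.01)
        assert res.bmdu == pytest.approx(hi, rel=0.01)

    def test_equal_weight_symmetric_mixture_median(self):
        # pools symmetric around 1 and around 3 -> averaged median is 2
        a = 1.0 + np.linspace(-0.5, 0.5, 101)
        b = 3.0 + np.linspace(-0.5, 0.5, 101)
        fits = [self.fake_fit("hill", "normal", a, -5.0),
                self.fake_fit("logit", "normal", b, -5.0)]
        res = p.model_average(fits, "X")
        assert res.bmd == pytest.approx(2.0, abs=1e-9)
        assert res.weights["hill/normal"] == pytest.approx(0.5)

    def test_weights_normalize(self):
        rng = np.random.default_rng(1)
        fits = [self.fake_fit(f, n, rng.lognormal(2, 0.5, 100), -50.0 - i)
                for i, (f, n) in enumerate(p.candidate_grid())]
        res = p.model_average(fits, "X")
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert len(res.weights) == 16

    def test_all_failed_flags_result(self):
        fits = [self.fake_fit("hill", "normal", None, -np.inf)]
        fits[0].ok = False
        res = p.model_average(fits, "X")
        assert res.failed and res.bmd is None

    def test_weighted_quantile_midpoint_convention(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.ones(4)
        assert _weighted_quantile(v, w, 0.5)[0] == pytest.approx(2.5)


@pytest.fixture(scope="module")
def noisy_fit():
    spec = p.CurveSpec(family="exponential", true_bmd=10.0,
                       noise_model="lognormal", noise_scale=0.15)
    drs = p.simulate_dose_response(spec, seed=4)
    return p.estimate_bmd(drs, draws=DRAWS, warmup=WARMUP, seed=4)


class TestEstimateBmd:
    def test_interval_orders_and_uncertainty_ratio(self, noisy_fit):
        res = noisy_fit
        assert res.trend_ok and not res.failed
        assert res.bmdl <= res.bmd <= res.bmdu
        assert res.uncertainty_ratio >= 1.0
        assert len(res.weights) == 16
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_trend_returns_gated_empty_result(self):
        rng = np.random.default_rng(0)
        spec = p.CurveSpec(family="hill", noise_scale=0.0)
        drs = p.simulate_dose_response(spec, seed=0)
        drs.records["response"] = 1.0 + rng.normal(0, 0.05, len(drs.records))
        res = p.estimate_bmd(drs, draws=DRAWS, warmup=WARMUP, seed=0)
        assert res.trend_ok is False
        assert res.bmd is None and res.bmdl is None and res.bmdu is None

    def test_scale_equivariance_on_noise_free_fit(self):
        """Multiplying concentrations by 10 multiplies the BMD by 10."""
        base = p.CurveSpec(family="hill", true_bmd=5.0, noise_scale=0.0)
        scaled = p.CurveSpec(
            family="hill", true_bmd=50.0, noise_scale=0.0,
            concentrations=tuple(10 * c for c in base.concentrations),
        )
        f1 = p.fit_candidate(p.simulate_dose_response(base, 0), "hill", "normal",
                             draws=DRAWS, warmup=WARMUP, seed=1)
        f2 = p.fit_candidate(p.simulate_dose_response(scaled, 0), "hill", "normal",
                             draws=DRAWS, warmup=WARMUP, seed=1)
        assert np.median(f2.bmd_draws) == pytest.approx(
            10 * np.median(f1.bmd_draws), rel=0.05
        )
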