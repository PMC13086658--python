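"""Reporter-assay preprocessing: normalization and cytotoxicity gating.

Raw dual-luciferase readings (firefly FLuc, *Renilla* RLuc per well) are
turned into fold-induction values relative to the solvent control (SC), and
dose-response curves are truncated at the highest non-cytotoxic concentration
determined from an MTT viability profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseSet",
    "ViabilityProfile",
    "normalize_reporter",
    "highest_noncytotoxic",
    "truncate_to_noncytotoxic",
]

#: canonical long-format columns of a dose-response table
DRS_COLUMNS = ["concentration", "bio_rep", "tech_rep", "response"]


@dataclass
class DoseResponseSet:
    """Per-compound fold-induction records.

    ``records`` is a long DataFrame with one row per well:
    concentration (µM; 0 is reserved for solvent-control wells), bio_rep,
    tech_rep, response (fold-induction relative to SC).
    """

    compound_id: str
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in DRS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dose-response records missing columns {missing}")
        if (self.records["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        """Sorted unique treated concentrations (> 0), µM."""
        c = self.records.loc[self.records["concentration"] > 0, "concentration"]
        return np.sort(c.unique())

    def replicate_means(self) -> pd.DataFrame:
        """Mean response per (concentration, bio_rep), collapsing tech reps."""
        return (
            self.records.groupby(["concentration", "bio_rep"], as_index=False)[
                "response"
            ]
            .mean()
            .sort_values(["concentration", "bio_rep"], ignore_index=True)
        )

    def to_csv(self, path) -> None:
        df = self.records.copy()
        df.insert(0, "compound_id", self.compound_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, compound_id: str | None = None) -> "DoseResponseSet":
        df = pd.read_csv(path)
        if compound_id is not None:
            df = df[df["compound_id"] == compound_id]
        ids = df["compound_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                f"expected a single compound in {path}, found {list(ids)}"
            )
        return cls(str(ids[0]), df[DRS_COLUMNS].reset_index(drop=True))


@dataclass
class ViabilityProfile:
    """MTT viability (% of untreated solvent control) per concentration."""

    compound_id: str
    concentrations: np.ndarray  # ascending, µM
    viability: np.ndarray  # mean % of SC

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must align")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly ascending")
        if np.any(self.viability < 0):
            raise ValueError("viability must be >= 0")


def normalize_reporter(raw: pd.DataFrame, compound_id: str | None = None) -> DoseResponseSet:
    """Normalize raw luciferase readings to fold-induction over solvent control.

    Each well's FLuc/RLuc ratio is divided by the mean solvent-control ratio of
    the same biological replicate (each plate carries its own SC wells), so SC
    wells average to 1.0 per replicate.

    Parameters
    ----------
    raw : DataFrame with columns group ("SC" for solvent-control wells,
        anything else for treated), concentration (µM, ignored for SC rows),
        bio_rep, tech_rep, FLuc, RLuc, and optionally compound_id.
    """
    required = {"group", "concentration", "bio_rep", "tech_rep", "FLuc", "RLuc"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw reporter table missing columns {sorted(missing)}")
    if compound_id is None:
        compound_id = (
            str(raw["compound_id"].iloc[0]) if "compound_id" in raw else "unknown"
        )
    if (raw["RLuc"] <= 0).any():
        raise ValueError("RLuc must be positive in every well")
    df = raw.copy()
    df["ratio"] = df["FLuc"] / df["RLuc"]

    sc = df[df["group"] == "SC"]
    if sc.empty:
        raise ValueError("no solvent-control (group='SC') wells found")
    sc_mean = sc.groupby("bio_rep")["ratio"].mean()
    missing_reps = set(df["bio_rep"].unique()) - set(sc_mean.index)
    if missing_reps:
        raise ValueError(f"biological replicates without SC wells: {sorted(missing_reps)}")

    df["response"] = df["ratio"] / df["bio_rep"].map(sc_mean)
    df.loc[df["group"] == "SC", "concentration"] = 0.0
    n_sc = int((df["group"] == "SC").sum())
    out = df[DRS_COLUMNS].sort_values(
        ["concentration", "bio_rep", "tech_rep"], ignore_index=True
    )
    meta = {
        "top_concentration": float(df["concentration"].max()),
        "n_solvent_controls": n_sc,
    }
    return DoseResponseSet(compound_id, out, meta)


def highest_noncytotoxic(
    profile: ViabilityProfile,
    abs_threshold: float = 80.0,
    drop_threshold: float = 10.0,
    drop_rule: str = "points",
) -> float | None:
    """Highest tested concentration below the onset of cytotoxicity.

    A concentration is cytotoxic when its viability is below ``abs_threshold``
    % of the untreated control, or when it falls at least ``drop_threshold``
    below the viability at the next smaller tested concentration (in absolute
    percentage points by default; ``drop_rule="relative"`` interprets the
    threshold as percent of the preceding value).  Once any concentration is
    cytotoxic all higher ones are treated as cytotoxic, so the result is the
    largest tested concentration with no cytotoxic concentration at or below
    it; ``None`` if the lowest tested concentration is already cytotoxic.
    """
    conc, viab = profile.concentrations, profile.viability
    if conc.size == 0:
        raise ValueError("viability profile is empty")
    if drop_rule not in ("points", "relative"):
        raise ValueError("drop_rule must be 'points' or 'relative'")
    cutoff: float | None = None
    prev = None
    for c, v in zip(conc, viab):
        if v < abs_threshold:
            break
        if prev is not None:
            drop = prev - v
            if drop_rule == "relative":
                drop = 100.0 * drop / prev if prev > 0 else np.inf
            if drop >= drop_threshold:
                break
        cutoff = float(c)
        prev = v
    return cutoff


def truncate_to_noncytotoxic(
    drs: DoseResponseSet,
    profile: ViabilityProfile,
    abs_threshold: float = 80.0,
    drop_threshold: float = 10.0,
) -> DoseResponseSet:
    """Drop all records above the highest non-cytotoxic concentration."""
    if drs.compound_id != profile.compound_id:
        raise ValueError(
            f"compound mismatch: {drs.compound_id!r} vs {profile.compound_id!r}"
        )
    cutoff = highest_noncytotoxic(profile, abs_threshold, drop_threshold)
    if cutoff is None:
        warnings.warn(
            f"{drs.compound_id}: lowest tested concentration is already "
            "cytotoxic; no usable dose range",
            stacklevel=2,
        )
        kept = drs.records.iloc[0:0]
    else:
        kept = drs.records[drs.records["concentration"] <= cutoff]
    meta = dict(drs.meta, cytotoxicity_cutoff=cutoff)
    return DoseResponseSet(drs.compound_id, kept.reset_index(drop=True), meta)
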