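"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the analysis end to end with no external data:
sigmoidal fold-induction curves (any of the eight dose-response families,
normal or log-normal replicate noise), descriptor matrices with a planted
sparse linear signal on log-BMD, and homologous PFAS-like SMILES series for
the featurization and screening stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import DoseResponseSet
from .descriptors import DescriptorMatrix
from .families import FAMILY_NAMES, median_response, scale_for_bmd

__all__ = [
    "CurveSpec",
    "PlantedMatrixSpec",
    "simulate_dose_response",
    "simulate_descriptor_matrix",
    "make_pfas_like_series",
    "DEFAULT_CONCENTRATIONS",
]

#: 7 half-log-spaced concentrations from 0.1 µM, the assay's default grid
DEFAULT_CONCENTRATIONS = tuple(np.round(10.0 ** (0.5 * np.arange(7) - 1.0), 4))


@dataclass
class CurveSpec:
    """Generating parameters of one synthetic concentration-response curve.

    The curve passes exactly through (true_bmd, bmr * background) in the
    median; noise is additive for ``noise_model="normal"`` and multiplicative
    (normal on the log response) for ``"lognormal"``.
    """

    compound_id: str = "synthetic"
    family: str = "hill"
    background: float = 1.0
    true_bmd: float = 10.0
    max_effect: float = 30.0  # plateau fold-induction (absolute, not x background)
    steepness: float = 1.0
    bmr: float = 1.5
    noise_model: str = "normal"
    noise_scale: float = 0.0
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    replicates: tuple = (3, 3)  # (biological, technical)

    def __post_init__(self):
        if self.family not in FAMILY_NAMES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILY_NAMES}")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError("noise_model must be 'normal' or 'lognormal'")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and strictly ascending")
        if not self.true_bmd > 0:
            raise ValueError("true_bmd must be positive")
        if not self.background > 0:
            raise ValueError("background must be positive")
        if min(self.replicates) < 1:
            raise ValueError("replicate counts must be >= 1")

    @property
    def fold_plateau(self) -> float:
        """Plateau as a fold-change over background (the c parameter)."""
        return self.max_effect / self.background


def simulate_dose_response(spec: CurveSpec, seed: int) -> DoseResponseSet:
    """Draw one response per (concentration, bio_rep, tech_rep) well.

    Within-run determinism: the same spec and seed reproduce the output
    exactly.  Replicate noise is i.i.d. across wells (no plate effects).
    """
    rng = np.random.default_rng(seed)
    b = scale_for_bmd(
        spec.family, spec.true_bmd, spec.fold_plateau, spec.steepness, bmr=spec.bmr
    )
    conc = np.asarray(spec.concentrations, dtype=float)
    n_bio, n_tech = spec.replicates
    cc, bb, tt = np.meshgrid(
        conc, np.arange(1, n_bio + 1), np.arange(1, n_tech + 1), indexing="ij"
    )
    median = median_response(
        spec.family, cc.ravel(), spec.background, spec.fold_plateau, b, spec.steepness
    )
    if spec.noise_model == "normal":
        resp = median + rng.normal(0.0, spec.noise_scale, size=median.size)
    else:
        resp = median * np.exp(rng.normal(0.0, spec.noise_scale, size=median.size))
    records = pd.DataFrame(
        {
            "concentration": cc.ravel(),
            "bio_rep": bb.ravel(),
            "tech_rep": tt.ravel(),
            "response": resp,
        }
    ).sort_values(["concentration", "bio_rep", "tech_rep"], ignore_index=True)
    meta = {
        "true_bmd": spec.true_bmd,
        "family": spec.family,
        "scale_b": b,
        "top_concentration": float(conc.max()),
    }
    return DoseResponseSet(spec.compound_id, records, meta)


@dataclass
class PlantedMatrixSpec:
    """Descriptor matrix with a sparse linear signal planted on log-BMD.

    Mirrors the shape of a cleaned modelling matrix (default: 141 mixed
    binary/continuous features over 34 compounds).  Columns
    ``0..n_binary-1`` are Bernoulli 0/1; the rest are standard normal.
    ``correlation_block`` entries (i, j, r) overwrite continuous column j to
    correlate with column i at Pearson r.
    """

    n_compounds: int = 34
    n_features: int = 141
    n_binary: int = 20
    planted_mask: tuple = (5, 40)
    coefficients: tuple = (2.0, -1.0)
    intercept: float = 3.0  # baseline log-BMD, exp(3) ~ 20 µM
    noise_sd: float = 0.05
    binary_p: float = 0.3
    correlation_block: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if len(self.planted_mask) != len(self.coefficients):
            raise ValueError("planted_mask and coefficients must align")
        if any(not 0 <= j < self.n_features for j in self.planted_mask):
            raise ValueError("planted_mask indices out of range")
        if not 0 <= self.n_binary <= self.n_features:
            raise ValueError("n_binary out of range")


def simulate_descriptor_matrix(
    spec: PlantedMatrixSpec,
) -> tuple[DescriptorMatrix, pd.Series]:
    """Generate (X, y) with y = intercept + X[:, planted] @ coef + noise.

    y is on the log-BMD scale (natural log of µM).  The returned matrix is in
    the "cleaned" state: finite everywhere, binary columns 0/1.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_features
    x = rng.standard_normal((n, p))
    for j in range(spec.n_binary):
        x[:, j] = (rng.random(n) < spec.binary_p).astype(float)
    for i, j, r in spec.correlation_block:
        if not abs(r) < 1.0:
            raise ValueError(f"requested correlation |r|={abs(r)} is singular")
        if j < spec.n_binary or i < spec.n_binary:
            raise ValueError("correlation_block applies to continuous columns only")
        zi = (x[:, i] - x[:, i].mean()) / x[:, i].std()
        x[:, j] = r * zi + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    y = (
        spec.intercept
        + x[:, list(spec.planted_mask)] @ np.asarray(spec.coefficients, dtype=float)
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    ids = pd.Index([f"CPD{i:03d}" for i in range(n)], name="compound_id")
    cols = [f"syn:x{j:03d}" for j in range(p)]
    values = pd.DataFrame(x, index=ids, columns=cols)
    kind = pd.Series(
        ["binary" if j < spec.n_binary else "continuous" for j in range(p)],
        index=cols,
    )
    matrix = DescriptorMatrix(values, kind, state="cleaned")
    return matrix, pd.Series(y, index=ids, name="log_bmd")


_SUBGROUPS = ("PFCA", "PFSA", "PFECA", "PFESA", "FTS")


def make_pfas_like_series(
    subgroup: str, chain_lengths: list[int]
) -> list[tuple[str, str]]:
    """Template SMILES for a homologous series of PFAS-like congeners.

    ``chain_lengths`` counts carbons (for FTS, the fluorinated carbons of an
    n:2 fluorotelomer).  Carboxylic series terminate in C(=O)O, sulfonic in
    S(=O)(=O)O; the ether subgroups carry one C-O-C ether oxygen.
    """
    if subgroup not in _SUBGROUPS:
        raise ValueError(f"unsupported subgroup {subgroup!r}; one of {_SUBGROUPS}")
    out = []
    for n in chain_lengths:
        if n < 2:
            raise ValueError("chain length must be >= 2")
        cf2 = "C(F)(F)"
        if subgroup == "PFCA":
            smi = "OC(=O)" + cf2 * (n - 2) + "C(F)(F)F"
        elif subgroup == "PFSA":
            smi = "OS(=O)(=O)" + cf2 * (n - 1) + "C(F)(F)F"
        elif subgroup == "PFECA":
            smi = "OC(=O)" + cf2 * (n - 2) + "OC(F)(F)F"
        elif subgroup == "PFESA":
            smi = "OS(=O)(=O)" + cf2 * (n - 1) + "OC(F)(F)F"
        else:  # FTS, n:2 fluorotelomer sulfonic acid
            smi = "OS(=O)(=O)CC" + cf2 * (n - 1) + "C(F)(F)F"
        out.append((f"{subgroup}-C{n}", smi))
    return out
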