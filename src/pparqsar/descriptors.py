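"""Descriptor computation and the cleaning cascade.

Four blocks are computed per compound from its SMILES (salt form as tested,
no desalting):

- ``maccs:``    166 MACCS substructure keys (binary)
- ``ecfp:``     hashed circular fingerprint, radius 3, 2048 bits (binary)
- ``autocorr:`` 2D autocorrelation descriptors (continuous; see ``autocorr``)
- ``phys:``     the RDKit physicochemical descriptor set, incl. TPSA (continuous)

Cleaning follows a fixed cascade: columns containing any non-finite value are
dropped, then a low-variance filter, then greedy pruning of correlated pairs
(|Pearson r| > 0.9 drops the later column).  Continuous columns are
z-scored against the training rows; binary columns pass through unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .autocorr import autocorrelation_descriptors

__all__ = [
    "DescriptorMatrix",
    "featurize",
    "clean",
    "standardize",
]

log = logging.getLogger(__name__)

N_MACCS = 166  # keys 1..166; RDKit's bit 0 is unused padding


@dataclass
class DescriptorMatrix:
    """Compounds x features with provenance and preprocessing state.

    ``values`` is indexed by compound id with block-prefixed feature columns;
    ``feature_kind`` maps each column to "binary" or "continuous"; ``state``
    tracks the cascade (raw -> cleaned -> standardized); ``scaler`` holds the
    per-feature training (mean, sd) once standardized.
    """

    values: pd.DataFrame
    feature_kind: pd.Series
    state: str = "raw"
    scaler: pd.DataFrame | None = None
    removal_manifest: list = field(default_factory=list)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, features: list[str]) -> "DescriptorMatrix":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        scaler = self.scaler.loc[features] if self.scaler is not None else None
        return replace(
            self,
            values=self.values[features].copy(),
            feature_kind=self.feature_kind[features],
            scaler=scaler,
        )

    def transform(self, new_values: pd.DataFrame) -> pd.DataFrame:
        """Project new raw-scale rows with the stored training scaler."""
        if self.scaler is None:
            raise ValueError("matrix has no scaler; call standardize() first")
        cols = self.feature_names
        missing = [c for c in cols if c not in new_values.columns]
        if missing:
            raise KeyError(f"new rows missing features: {missing}")
        x = new_values[cols].astype(float)
        return (x - self.scaler["mean"]) / self.scaler["sd"]

    def to_csv(self, path, sidecar_path=None) -> None:
        self.values.rename_axis("compound_id").to_csv(path)
        if sidecar_path is not None:
            side = {
                "state": self.state,
                "feature_kind": self.feature_kind.to_dict(),
                "scaler": None
                if self.scaler is None
                else self.scaler.to_dict(orient="index"),
                "removal_manifest": [list(t) for t in self.removal_manifest],
            }
            with open(sidecar_path, "w") as fh:
                json.dump(side, fh, indent=1)


def _feature_row(mol: Chem.Mol, n_ecfp_bits: int) -> dict[str, float]:
    row: dict[str, float] = {}
    maccs = MACCSkeys.GenMACCSKeys(mol)
    for k in range(1, N_MACCS + 1):
        row[f"maccs:f{k}"] = float(maccs.GetBit(k))
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=n_ecfp_bits)
    ecfp = gen.GetFingerprint(mol)
    on = set(ecfp.GetOnBits())
    for k in range(n_ecfp_bits):
        row[f"ecfp:b{k:04d}"] = float(k in on)
    for name, val in autocorrelation_descriptors(mol).items():
        row[f"autocorr:{name}"] = val
    for name, val in Descriptors.CalcMolDescriptors(mol).items():
        try:
            row[f"phys:{name}"] = float(val)
        except (TypeError, ValueError):
            row[f"phys:{name}"] = np.nan
    return row


def featurize(
    compounds: list[tuple[str, str]], n_ecfp_bits: int = 2048
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Compute the raw descriptor matrix for (id, SMILES) pairs.

    Unparseable SMILES are excluded and reported in the returned failure list
    (id, reason); featurization is deterministic for identical SMILES.
    """
    rows, ids, failures = [], [], []
    for cid, smiles in compounds:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            log.warning("unparseable SMILES for %s: %r", cid, smiles)
            failures.append((cid, "unparseable SMILES"))
            continue
        rows.append(_feature_row(mol, n_ecfp_bits))
        ids.append(cid)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"))
    kind = pd.Series(
        [
            "binary" if c.startswith(("maccs:", "ecfp:")) else "continuous"
            for c in values.columns
        ],
        index=values.columns,
    )
    return DescriptorMatrix(values, kind, state="raw"), failures


def clean(
    matrix: DescriptorMatrix,
    var_threshold: float = 1e-8,
    dominant_freq: float = 0.95,
    corr_threshold: float = 0.9,
) -> DescriptorMatrix:
    """Apply the cleaning cascade: non-finite, low-variance, correlation.

    Low variance means variance below ``var_threshold`` or a single value
    covering at least ``dominant_freq`` of the rows.  Correlation pruning is
    greedy in column order: a column is dropped when it exceeds
    ``corr_threshold`` in |Pearson r| against any earlier surviving column,
    so the output has no surviving pair above the threshold and a fixed input
    order yields a fixed output.
    """
    df = matrix.values
    if len(df) < 2:
        raise ValueError("cleaning needs at least 2 rows")
    manifest: list[tuple[str, str]] = []

    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=0)
    for c in df.columns[~finite]:
        manifest.append((c, "non-finite"))
    df = df.loc[:, finite]

    x = df.to_numpy(dtype=float)
    var = x.var(axis=0)
    modal = np.array([pd.Series(col).value_counts().iloc[0] / len(col) for col in x.T])
    low = (var < var_threshold) | (modal >= dominant_freq)
    for c in df.columns[low]:
        manifest.append((c, "low-variance"))
    df = df.loc[:, ~low]

    x = df.to_numpy(dtype=float)
    if df.shape[1] > 1:
        r = np.corrcoef(x, rowvar=False)
        keep: list[int] = []
        for j in range(df.shape[1]):
            if any(abs(r[i, j]) > corr_threshold for i in keep):
                manifest.append((df.columns[j], "correlated"))
            else:
                keep.append(j)
        df = df.iloc[:, keep]

    if df.shape[1] == 0:
        raise ValueError("cleaning removed every feature")
    return DescriptorMatrix(
        df.copy(),
        matrix.feature_kind[df.columns],
        state="cleaned",
        removal_manifest=matrix.removal_manifest + manifest,
    )


def standardize(
    matrix: DescriptorMatrix, training_rows: list[str] | None = None
) -> DescriptorMatrix:
    """Z-score continuous columns against the training rows.

    Binary columns keep their 0/1 coding (identity scaler).  The scaler is
    stored so screening compounds can be projected into the same space.
    """
    df = matrix.values
    train = df if training_rows is None else df.loc[training_rows]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    is_binary = matrix.feature_kind == "binary"
    mean[is_binary] = 0.0
    sd[is_binary] = 1.0
    if (sd[~is_binary] <= 0).any():
        bad = list(sd.index[(~is_binary) & (sd <= 0)])
        raise ValueError(f"zero-variance columns reached standardization: {bad}")
    scaler = pd.DataFrame({"mean": mean, "sd": sd})
    out = (df - mean) / sd
    return DescriptorMatrix(
        out,
        matrix.feature_kind.copy(),
        state="standardized",
        scaler=scaler,
        removal_manifest=list(matrix.removal_manifest),
    )
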