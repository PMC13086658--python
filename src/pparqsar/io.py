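"""CSV dialects shared by the pipeline stages and the CLI."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .assay import DRS_COLUMNS, DoseResponseSet, ViabilityProfile
from .bmd import BmdResult
from .descriptors import DescriptorMatrix

__all__ = [
    "read_compounds",
    "read_dose_response_long",
    "read_viability",
    "read_design_matrix",
    "write_bmd_results",
]


def read_compounds(path) -> list[tuple[str, str]]:
    """(id, SMILES) pairs from a CSV with header, or a plain SMILES file.

    CSV columns are matched case-insensitively (id/compound_id/name,
    smiles).  A plain file holds one SMILES per line, optionally preceded by a
    tab-separated id.
    """
    with open(path) as fh:
        first = fh.readline()
    if "," in first and "smiles" in first.lower():
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        smiles_col = cols["smiles"]
        id_col = next(
            (cols[k] for k in ("id", "compound_id", "dtxsid", "name") if k in cols),
            None,
        )
        ids = (
            df[id_col].astype(str)
            if id_col
            else pd.Series([f"CPD{i:05d}" for i in range(len(df))])
        )
        return list(zip(ids, df[smiles_col].astype(str)))
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                out.append((parts[0], parts[1]))
            else:
                out.append((f"CPD{i:05d}", parts[0]))
    return out


def read_dose_response_long(path) -> dict[str, DoseResponseSet]:
    """Per-compound dose-response sets from a normalized long CSV."""
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("compound_id"):
        out[str(cid)] = DoseResponseSet(
            str(cid), grp[DRS_COLUMNS].reset_index(drop=True)
        )
    return out


def read_viability(path) -> dict[str, ViabilityProfile]:
    """Viability profiles from a (compound_id, concentration, viability) CSV."""
    df = pd.read_csv(path).sort_values(["compound_id", "concentration"])
    out = {}
    for cid, grp in df.groupby("compound_id"):
        out[str(cid)] = ViabilityProfile(
            str(cid),
            grp["concentration"].to_numpy(dtype=float),
            grp["viability"].to_numpy(dtype=float),
        )
    return out


def read_design_matrix(path, sidecar_path=None) -> DescriptorMatrix:
    """Design matrix CSV (block-prefixed headers) back into a DescriptorMatrix."""
    df = pd.read_csv(path, index_col="compound_id")
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            side = json.load(fh)
        kind = pd.Series(side["feature_kind"])[df.columns]
        scaler = (
            None
            if side.get("scaler") is None
            else pd.DataFrame.from_dict(side["scaler"], orient="index").loc[df.columns]
        )
        return DescriptorMatrix(
            df, kind, state=side.get("state", "cleaned"), scaler=scaler,
            removal_manifest=[tuple(t) for t in side.get("removal_manifest", [])],
        )
    is_binary = df.apply(lambda c: set(np.unique(c)) <= {0.0, 1.0})
    kind = pd.Series(np.where(is_binary, "binary", "continuous"), index=df.columns)
    return DescriptorMatrix(df, kind, state="cleaned")


def write_bmd_results(results: list[BmdResult], csv_path, json_path=None) -> None:
    """Per-compound results CSV plus an optional JSON with weights/diagnostics."""
    rows = []
    for r in results:
        rows.append(
            {
                "compound_id": r.compound_id,
                "bmr": r.bmr,
                "trend_ok": r.trend_ok,
                "bmd": r.bmd,
                "bmdl": r.bmdl,
                "bmdu": r.bmdu,
                "bmdu_bmdl_ratio": r.uncertainty_ratio,
                "n_eff_min": min(
                    (d["ess_min"] for d in r.diagnostics.values()
                     if isinstance(d, dict) and np.isfinite(d.get("ess_min", np.nan))),
                    default=None,
                ),
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {
            r.compound_id: {
                "weights": r.weights,
                "trend_ok": r.trend_ok,
                "failed": r.failed,
                "diagnostics": {
                    k: v for k, v in r.diagnostics.items() if isinstance(v, dict)
                },
            }
            for r in results
        }
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)
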