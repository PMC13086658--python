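"""Batch screening of SMILES lists with a trained QSAR model.

Every input compound is featurized, projected with the model's stored scaler,
predicted, and assessed against the composite applicability domain.
Processing is batched so memory stays bounded in the batch size; results are
identical to all-at-once processing and every input id appears exactly once
in the output (as a prediction or a failure record).

Because hashed circular fingerprints can collide (two substructures setting
the same bit), records whose prediction is pulled toward low BMD by a set
fingerprint bit carry a ``collision_check`` flag prompting substructure
verification — the flag marks candidates for manual review, it does not
automate the check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import featurize
from .domain import AdVerdict, assess
from .qsar import QsarModel

__all__ = ["ScreeningRecord", "screen", "top_k", "records_to_frame"]

log = logging.getLogger(__name__)


@dataclass
class ScreeningRecord:
    id: str
    smiles: str
    predicted_bmd: float | None  # µM
    verdict: AdVerdict | None
    collision_check: bool = False
    failure_reason: str | None = None

    @property
    def in_domain(self) -> bool:
        return bool(self.verdict is not None and self.verdict.in_domain)


def _screen_batch(batch, model: QsarModel, n_ecfp_bits: int) -> list[ScreeningRecord]:
    matrix, failures = featurize(batch, n_ecfp_bits=n_ecfp_bits)
    failed = dict(failures)
    smiles_of = dict(batch)
    ecfp_idx = [i for i, f in enumerate(model.feature_names) if f.startswith("ecfp:")]
    out = []
    for cid, smi in batch:
        if cid in failed:
            out.append(ScreeningRecord(cid, smi, None, None,
                                       failure_reason=failed[cid]))
            continue
        raw = matrix.values.loc[cid, model.feature_names].astype(float)
        z = (raw - model.scaler["mean"]) / model.scaler["sd"]
        verdict = assess(z.to_numpy(), model, compound_id=cid)
        if not np.all(np.isfinite(z.to_numpy())):
            out.append(ScreeningRecord(cid, smiles_of[cid], None, verdict,
                                       failure_reason="non-finite descriptor value"))
            continue
        pred = float(np.exp(model.intercept + z.to_numpy() @ model.coefficients))
        collide = any(
            raw.iloc[i] > 0 and model.coefficients[i] < 0 for i in ecfp_idx
        )
        out.append(ScreeningRecord(cid, smiles_of[cid], pred, verdict,
                                   collision_check=collide))
    return out


def screen(
    compounds: list[tuple[str, str]],
    model: QsarModel,
    batch_size: int = 500,
    n_ecfp_bits: int = 2048,
) -> tuple[list[ScreeningRecord], dict]:
    """Apply a trained model to (id, SMILES) pairs; returns records + summary.

    The summary counts successes and in-domain records and reports the median
    predicted BMD among in-domain compounds.  Unparseable SMILES become
    failure records; the pipeline continues.
    """
    if model.scaler is None:
        raise ValueError("model carries no descriptor scaler; cannot screen")
    records: list[ScreeningRecord] = []
    for start in range(0, len(compounds), batch_size):
        records.extend(
            _screen_batch(compounds[start : start + batch_size], model, n_ecfp_bits)
        )
    in_domain = [r.predicted_bmd for r in records if r.in_domain
                 and r.predicted_bmd is not None]
    summary = {
        "n_total": len(records),
        "n_predicted": sum(r.predicted_bmd is not None for r in records),
        "n_failed": sum(r.failure_reason is not None for r in records),
        "n_in_domain": len(in_domain),
        "n_out_of_domain": sum(
            r.predicted_bmd is not None and not r.in_domain for r in records
        ),
        "median_in_domain_bmd": float(np.median(in_domain)) if in_domain else None,
    }
    return records, summary


def top_k(records: list[ScreeningRecord], k: int) -> pd.DataFrame:
    """The k in-domain records with the lowest predicted BMD.

    Out-of-domain and failed records are excluded; ties break by id so the
    ranking is deterministic.
    """
    ranked = sorted(
        (r for r in records if r.in_domain and r.predicted_bmd is not None),
        key=lambda r: (r.predicted_bmd, r.id),
    )
    return records_to_frame(ranked[:k])


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        v = r.verdict
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "predicted_bmd": r.predicted_bmd,
                "in_bbox": None if v is None else v.in_bbox,
                "leverage": None if v is None else v.h,
                "h_star": None if v is None else v.h_star,
                "in_domain": r.in_domain,
                "collision_check": r.collision_check,
                "failure_reason": r.failure_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "smiles", "predicted_bmd", "in_bbox", "leverage",
                 "h_star", "in_domain", "collision_check", "failure_reason"],
    )
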