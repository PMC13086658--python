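"""Composite applicability domain: bounding box AND leverage.

Both criteria are evaluated on the model's selected standardized descriptors
only (never the full initial matrix).  The bounding box accepts a compound
when every feature lies within the training [min, max] inclusive; the
leverage criterion accepts when h = x (XᵀX)⁻¹ xᵀ does not exceed the critical
value h* = 3(p+1)/n.  A compound is in-domain only when both pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qsar import QsarModel

__all__ = ["AdVerdict", "bounding_box", "leverage", "critical_leverage", "assess"]


@dataclass
class AdVerdict:
    """Audit-friendly per-compound domain decision."""

    compound_id: str
    in_bbox: bool
    h: float
    h_star: float
    in_leverage: bool
    in_domain: bool
    reason: str = ""

    def __post_init__(self):
        assert self.in_domain == (self.in_bbox and self.in_leverage)


def bounding_box(x_row, X_train) -> bool:
    """True iff every feature value lies in the training range, inclusive."""
    x = np.asarray(x_row, dtype=float)
    xt = np.asarray(X_train.values if hasattr(X_train, "values") else X_train,
                    dtype=float)
    if x.size != xt.shape[1]:
        raise ValueError(f"feature mismatch: row has {x.size}, train has {xt.shape[1]}")
    return bool(np.all(x >= xt.min(axis=0)) and np.all(x <= xt.max(axis=0)))


def leverage(x_row, X_train, allow_singular: bool = True) -> float:
    """h = xᵀ (XᵀX)⁻¹ x on the training design (no intercept column).

    For a full-rank design the training-row leverages sum to p (the trace of
    the hat matrix).  A singular XᵀX falls back to the pseudo-inverse with a
    warning unless ``allow_singular`` is False.
    """
    x = np.asarray(x_row, dtype=float)
    xt = np.asarray(X_train.values if hasattr(X_train, "values") else X_train,
                    dtype=float)
    if x.size != xt.shape[1]:
        raise ValueError(f"feature mismatch: row has {x.size}, train has {xt.shape[1]}")
    gram = xt.T @ xt
    try:
        v = np.linalg.solve(gram, x)
    except np.linalg.LinAlgError:
        if not allow_singular:
            raise
        warnings.warn("singular XᵀX; using pseudo-inverse for leverage",
                      stacklevel=2)
        v = np.linalg.pinv(gram) @ x
    return float(x @ v)


def critical_leverage(p: int, n: int) -> float:
    """h* = 3(p + 1)/n for p descriptors and n training compounds."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (p + 1) / n


def assess(x_row, model: QsarModel, compound_id: str = "unknown") -> AdVerdict:
    """Composite verdict for one standardized, projected descriptor row.

    A non-finite descriptor value is automatically out-of-domain with a
    reason code.
    """
    if isinstance(x_row, pd.Series):
        x = x_row[model.feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(x_row, dtype=float)
    h_star = critical_leverage(len(model.feature_names), len(model.X_train))
    if not np.all(np.isfinite(x)):
        return AdVerdict(compound_id, False, np.nan, h_star, False, False,
                         reason="non-finite descriptor value")
    in_bbox = bounding_box(x, model.X_train)
    h = leverage(x, model.X_train)
    in_lev = h <= h_star
    reasons = []
    if not in_bbox:
        reasons.append("outside bounding box")
    if not in_lev:
        reasons.append("leverage above critical")
    return AdVerdict(compound_id, in_bbox, h, h_star, in_lev,
                     in_bbox and in_lev, reason="; ".join(reasons))
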