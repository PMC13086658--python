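"""Linear QSAR on log-BMD with µM-scale evaluation and y-randomization.

The model is ordinary least squares on the natural log of the observed BMD
over the selected standardized descriptors; predictions are back-transformed
with exp so they are strictly positive, and every performance metric (R²,
MAE, RMSE) is computed on the original µM scale.  R² is 1 - SS_res/SS_tot and
may be negative (a y-randomized model typically is, by a wide margin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .descriptors import DescriptorMatrix

__all__ = ["QsarModel", "FitMetrics", "fit", "predict", "evaluate_cv", "y_randomize"]


@dataclass
class FitMetrics:
    """Goodness-of-fit on the µM scale; rmse >= mae always."""

    r2: float
    mae: float
    rmse: float
    context: str = "training"


def _metrics(obs: np.ndarray, pred: np.ndarray, context: str) -> FitMetrics:
    resid = obs - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return FitMetrics(
        r2=r2,
        mae=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        context=context,
    )


@dataclass
class QsarModel:
    """Fitted linear BMD model plus everything needed for AD and screening."""

    feature_names: list[str]
    coefficients: np.ndarray  # per standardized feature, log-µM units
    intercept: float  # log-µM
    scaler: pd.DataFrame | None  # per-feature (mean, sd) on the raw scale
    X_train: pd.DataFrame  # standardized training design snapshot
    y_train: np.ndarray  # observed BMD, µM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient count must equal feature count")

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)

    def to_json(self, path) -> None:
        doc = {
            "feature_names": self.feature_names,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": self.intercept,
            "scaler": None
            if self.scaler is None
            else self.scaler.to_dict(orient="index"),
            "X_train": self.X_train.rename_axis("compound_id")
            .reset_index()
            .to_dict(orient="list"),
            "y_train": list(map(float, self.y_train)),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "QsarModel":
        with open(path) as fh:
            doc = json.load(fh)
        xt = pd.DataFrame(doc["X_train"]).set_index("compound_id")
        scaler = (
            None
            if doc["scaler"] is None
            else pd.DataFrame.from_dict(doc["scaler"], orient="index")
        )
        return cls(
            feature_names=doc["feature_names"],
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            intercept=float(doc["intercept"]),
            scaler=scaler,
            X_train=xt[doc["feature_names"]],
            y_train=np.asarray(doc["y_train"], dtype=float),
            metadata=doc.get("metadata", {}),
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.values
    return pd.DataFrame(X)


def fit(X_selected, y_bmd_um, metadata: dict | None = None,
        ridge: float = 0.0) -> QsarModel:
    """Least squares on log(y) over the selected standardized features.

    ``X_selected`` may be a standardized DescriptorMatrix (its scaler is
    carried into the model for screening-time projection) or a plain
    DataFrame/array of already-standardized values.  ``ridge`` adds an L2
    penalty on the slopes (not the intercept); the default 0 keeps the
    plain, interpretable least-squares fit.
    """
    scaler = X_selected.scaler if isinstance(X_selected, DescriptorMatrix) else None
    xdf = _as_frame(X_selected)
    y = np.asarray(y_bmd_um.values if hasattr(y_bmd_um, "values") else y_bmd_um,
                   dtype=float)
    if np.any(y <= 0):
        raise ValueError("BMD values must be positive")
    n, p = xdf.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} compounds, got {n}")
    a = np.column_stack([np.ones(n), xdf.to_numpy(dtype=float)])
    if ridge > 0:
        pen = np.sqrt(ridge) * np.eye(p + 1)
        pen[0, 0] = 0.0  # intercept unpenalized
        beta, *_ = np.linalg.lstsq(
            np.vstack([a, pen]), np.concatenate([np.log(y), np.zeros(p + 1)]),
            rcond=None,
        )
    else:
        if np.linalg.matrix_rank(a) < a.shape[1]:
            raise ValueError("rank-deficient design matrix")
        beta, *_ = np.linalg.lstsq(a, np.log(y), rcond=None)
    return QsarModel(
        feature_names=list(xdf.columns),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        scaler=scaler,
        X_train=xdf.copy(),
        y_train=y,
        metadata=metadata or {},
    )


def predict(model: QsarModel, X_new) -> np.ndarray:
    """Back-transformed BMD predictions, µM (strictly positive)."""
    xdf = _as_frame(X_new)
    missing = [f for f in model.feature_names if f not in xdf.columns]
    if missing:
        raise KeyError(f"prediction rows missing features: {missing}")
    x = xdf[model.feature_names].to_numpy(dtype=float)
    return np.exp(model.intercept + x @ model.coefficients)


def evaluate_cv(
    X, y, folds: int = 5, seed: int = 0
) -> tuple[FitMetrics, pd.DataFrame]:
    """K-fold CV: each compound predicted once by a model not trained on it.

    Returns µM-scale metrics and the per-compound (observed, predicted, fold)
    table.  The fold split uses the documented seed and is distinct from the
    GA's internally re-randomized splits.
    """
    xdf = _as_frame(X)
    y = np.asarray(y.values if hasattr(y, "values") else y, dtype=float)
    if len(y) < folds:
        raise ValueError("need at least `folds` rows")
    xmat = xdf.to_numpy(dtype=float)
    logy = np.log(y)
    pred = np.empty_like(y)
    fold_of = np.empty(len(y), dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(xmat)):
        if tr.size < 2:
            raise ValueError("fold with fewer than 2 training rows")
        a = np.column_stack([np.ones(tr.size), xmat[tr]])
        beta, *_ = np.linalg.lstsq(a, logy[tr], rcond=None)
        pred[te] = np.exp(np.column_stack([np.ones(te.size), xmat[te]]) @ beta)
        fold_of[te] = f
    table = pd.DataFrame(
        {"observed": y, "predicted": pred, "fold": fold_of}, index=xdf.index
    )
    return _metrics(y, pred, "cv"), table


def y_randomize(
    X, y, repeats: int = 20, seed: int = 0, folds: int = 5,
    permutations: list[np.ndarray] | None = None,
) -> tuple[FitMetrics, list[FitMetrics]]:
    """Chance-correlation baseline: permute y, refit, evaluate; average.

    Each repeat shuffles the response (preserving its multiset), re-fits and
    re-evaluates with the same CV protocol.  Returns mean metrics and the
    per-repeat list.  ``permutations`` overrides the random shuffles with an
    explicit list of index vectors (one per repeat).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y.values if hasattr(y, "values") else y, dtype=float)
    per = []
    for r in range(repeats):
        perm = (rng.permutation(len(y)) if permutations is None
                else np.asarray(permutations[r]))
        m, _ = evaluate_cv(X, y[perm], folds=folds, seed=seed + r)
        per.append(FitMetrics(m.r2, m.mae, m.rmse, context="y_randomization"))
    mean = FitMetrics(
        r2=float(np.mean([m.r2 for m in per])),
        mae=float(np.mean([m.mae for m in per])),
        rmse=float(np.mean([m.rmse for m in per])),
        context="y_randomization",
    )
    return mean, per
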