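"""N/O glycosylation-type classification from oxonium features.

A binary logistic regression (two classes reduce the multinomial model to
binomial) on the 9 normalized oxonium intensity ratios. The fit carries a tiny
L2 penalty (strength 1e-4) so that perfectly separable training data — common
with well-behaved synthetic spectra — still yields a finite, deterministic
solution; away from separation this is maximum likelihood for all practical
purposes. Per-feature Wald p-values are computed from the penalized Fisher
information. Besides the hard N/O call, every prediction reports the model
probability of the assigned class, which flags spectra in the gray zone
between the two glycosylation types.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .oxonium import FEATURE_IONS, OxoniumFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticModel",
    "ClassifierReport",
    "train",
    "predict",
    "cross_validate",
    "feature_significance",
    "save_model",
    "load_model",
]

#: L2 penalty strength stabilizing the fit under (quasi-)separation.
RIDGE_ALPHA = 1e-4

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic model over the 9 oxonium ratios; positive class is O."""

    weights: Mapping[int, float]
    intercept: float
    feature_order: tuple[int, ...] = FEATURE_IONS
    positive_class: str = "O"
    training_meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.feature_order) or len(self.weights) != 9:
            raise ValueError("model must carry exactly one weight per feature ion")

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.weights[k] for k in self.feature_order], dtype=float)

    def decision(self, features: OxoniumFeatures) -> float:
        return float(self.coef_vector @ features.vector(self.feature_order) + self.intercept)

    def prob_o(self, features: OxoniumFeatures) -> float:
        return float(1.0 / (1.0 + np.exp(-self.decision(features))))


@dataclass
class ClassifierReport:
    """Pooled accuracy and per-class true rates, plus feature Wald p-values."""

    overall_accuracy: float
    true_n_rate: float
    true_o_rate: float
    per_feature_p_values: Mapping[int, float]
    confusion: Mapping[str, int]
    meta: Mapping[str, object] = field(default_factory=dict)


def _design(features: Sequence[OxoniumFeatures], order: tuple[int, ...]) -> np.ndarray:
    X = np.vstack([f.vector(order) for f in features])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _check_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray(labels)
    classes = set(y.tolist())
    if not classes <= {"N", "O"}:
        raise ValueError(f"labels must be 'N' or 'O', got {classes}")
    if len(classes) < 2:
        raise ValueError("training requires examples of both classes")
    for c in ("N", "O"):
        if int((y == c).sum()) < 2:
            raise ValueError(f"need at least 2 examples of class {c}")
    return y


def _fit_raw(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, float]:
    # sklearn's objective is sum(loss) + ||w||^2 / (2C); C = 1/alpha gives an
    # L2 strength of RIDGE_ALPHA on the weights (intercept unpenalized).
    clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="lbfgs", tol=1e-8, max_iter=500)
    clf.fit(X, y01)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def train(
    features: Sequence[OxoniumFeatures],
    labels: Sequence[str],
    seed: int = 0,
    feature_order: tuple[int, ...] = FEATURE_IONS,
) -> LogisticModel:
    """Fit the N/O logistic classifier.

    Deterministic for a fixed input order (the lbfgs solve involves no
    randomness; ``seed`` is recorded in the training metadata for provenance
    and for seeding downstream cross-validation).
    """
    y = _check_labels(labels)
    X = _design(features, feature_order)
    y01 = (y == "O").astype(int)
    coef, intercept = _fit_raw(X, y01)
    margins = X @ coef + intercept
    if np.all((margins > 0) == (y01 == 1)) and np.min(np.abs(margins)) > 10:
        logger.warning("training data appear separable; ridge-stabilized fit returned")
    meta = {
        "n_N": int((y == "N").sum()),
        "n_O": int((y == "O").sum()),
        "seed": int(seed),
        "ridge_alpha": RIDGE_ALPHA,
    }
    return LogisticModel(
        weights={k: float(w) for k, w in zip(feature_order, coef)},
        intercept=intercept,
        feature_order=tuple(feature_order),
        training_meta=meta,
    )


def predict(model: LogisticModel, features: OxoniumFeatures) -> tuple[str, float]:
    """(label, probability of that label). p(O) >= 0.5 is called O (ties to O)."""
    p_o = model.prob_o(features)
    if p_o >= 0.5:
        return "O", p_o
    return "N", 1.0 - p_o


def cross_validate(
    features: Sequence[OxoniumFeatures],
    labels: Sequence[str],
    k_folds: int = 10,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified k-fold cross-validation; pooled out-of-fold accuracy and
    per-class true rates. Fold assignment is reproducible from ``seed``.
    Feature p-values in the report come from a fit on the full dataset."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = _check_labels(labels)
    X = _design(features, FEATURE_IONS)
    y01 = (y == "O").astype(int)
    if min(int(y01.sum()), int((1 - y01).sum())) < k_folds:
        raise ValueError("each class must have at least k_folds members for stratification")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y01)
    for train_idx, test_idx in skf.split(X, y01):
        coef, intercept = _fit_raw(X[train_idx], y01[train_idx])
        pred[test_idx] = (X[test_idx] @ coef + intercept >= 0).astype(int)
    tn = int(((pred == 0) & (y01 == 0)).sum())  # correctly called N
    to = int(((pred == 1) & (y01 == 1)).sum())  # correctly called O
    fn = int((y01 == 0).sum()) - tn
    fo = int((y01 == 1).sum()) - to
    model = train(features, labels, seed=seed)
    return ClassifierReport(
        overall_accuracy=(tn + to) / len(y01),
        true_n_rate=tn / max(tn + fn, 1),
        true_o_rate=to / max(to + fo, 1),
        per_feature_p_values=feature_significance(model, features, labels),
        confusion={"N_as_N": tn, "N_as_O": fn, "O_as_O": to, "O_as_N": fo},
        meta={"k_folds": k_folds, "seed": seed, "scheme": "stratified"},
    )


def feature_significance(
    model: LogisticModel,
    features: Sequence[OxoniumFeatures],
    labels: Sequence[str],
) -> dict[int, float]:
    """Wald p-values per coefficient from the penalized observed information.

    The information matrix is X'WX (+ the ridge term on the weight block);
    a singular matrix yields NaN p-values with a warning.
    """
    y = np.asarray(labels)
    X = _design(features, model.feature_order)
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    beta = np.append(model.coef_vector, model.intercept)
    p = 1.0 / (1.0 + np.exp(-(Xa @ beta)))
    W = p * (1.0 - p)
    H = (Xa * W[:, None]).T @ Xa
    H[np.arange(9), np.arange(9)] += RIDGE_ALPHA
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; feature p-values unavailable")
        return {k: float("nan") for k in model.feature_order}
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * _stats.norm.sf(np.abs(z))
    return {k: float(pv) for k, pv in zip(model.feature_order, pvals[:9])}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: LogisticModel, path: str) -> None:
    """JSON serialization preserving weights at full double precision."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "positive_class": model.positive_class,
        "feature_order": list(model.feature_order),
        "weights": {str(k): model.weights[k] for k in model.feature_order},
        "intercept": model.intercept,
        "training_meta": dict(model.training_meta),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path: str) -> LogisticModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"model file {path!r} is not valid JSON: {exc}") from exc
    for key in ("schema_version", "feature_order", "weights", "intercept"):
        if key not in payload:
            raise ValueError(f"model file {path!r} missing field {key!r}")
    if payload["schema_version"] != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {payload['schema_version']}")
    order = tuple(int(k) for k in payload["feature_order"])
    try:
        weights = {k: float(payload["weights"][str(k)]) for k in order}
    except KeyError as exc:
        raise ValueError(f"model file {path!r} missing weight for ion {exc}") from exc
    return LogisticModel(
        weights=weights,
        intercept=float(payload["intercept"]),
        feature_order=order,
        positive_class=payload.get("positive_class", "O"),
        training_meta=payload.get("training_meta", {}),
    )
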