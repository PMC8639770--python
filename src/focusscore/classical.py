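"""Logistic-regression focus classifier over the (MD, ED, WPD) features.

This is the classical baseline against which the residual-network classifier
is compared: three hand-crafted features per focus candidate, standardized,
then a maximum-likelihood logistic fit (with a tiny ridge, lambda = 1e-6, to
keep the optimum finite on separable data).  Positive prediction at
probability >= 0.5, matching the network branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["LogisticModel", "fit_logistic", "predict_proba", "RIDGE_LAMBDA"]

#: Ridge penalty on the standardized coefficients; small enough to be
#: negligible at any realistic sample size, large enough to bound the
#: optimum under complete separation.
RIDGE_LAMBDA = 1e-6

FEATURE_NAMES = ("MD", "ED", "WPD")


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic model: sigmoid(intercept + coef . z) on standardized
    features z = (x - mean) / sd."""

    coef: np.ndarray            # shape (3,), on standardized scale
    intercept: float
    feature_means: np.ndarray   # shape (3,)
    feature_sds: np.ndarray     # shape (3,), all > 0
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coef.shape != (3,) or self.feature_means.shape != (3,) \
                or self.feature_sds.shape != (3,):
            raise ValueError("expected 3 features (MD, ED, WPD)")
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("non-finite coefficients")
        if not np.all(self.feature_sds > 0):
            raise ValueError("feature sds must be positive")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        z = (X - self.feature_means) / self.feature_sds
        return z @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive) for each row of X = (MD, ED, WPD); values in (0, 1)."""
        s = self.decision_function(X)
        # numerically stable sigmoid, clipped away from exact 0/1
        with np.errstate(over="ignore"):
            p = np.where(s >= 0, 1.0 / (1.0 + np.exp(-s)),
                         np.exp(np.clip(s, -700, 0)) / (1.0 + np.exp(np.clip(s, -700, 0))))
        return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "feature_names": list(FEATURE_NAMES),
            "training_meta": self.training_meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(coef=np.asarray(d["coef"], dtype=float),
                   intercept=float(d["intercept"]),
                   feature_means=np.asarray(d["feature_means"], dtype=float),
                   feature_sds=np.asarray(d["feature_sds"], dtype=float),
                   training_meta=d.get("training_meta", {}))


def fit_logistic(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> LogisticModel:
    """Maximum-likelihood logistic fit on standardized (MD, ED, WPD).

    ``features`` is (n, 3); ``labels`` binary.  Deterministic given inputs
    (the solver is deterministic; ``seed`` is recorded in the metadata).
    Requires both classes present with >= 2 samples each.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("features must be (n, 3): MD, ED, WPD")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; need both 0 and 1")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)   # constant feature -> zero coefficient
    Z = (X - means) / sds

    # sklearn minimizes 0.5*||w||^2 + C * sum(loss); dividing by C shows the
    # per-problem ridge is lambda = 1/(2C).
    C = 1.0 / (2.0 * RIDGE_LAMBDA)
    lr = LogisticRegression(C=C, solver="lbfgs", tol=1e-12, max_iter=20000,
                            random_state=seed)
    lr.fit(Z, y)
    meta = {"seed": int(seed), "n": int(len(y)),
            "class_counts": {int(c): int(k) for c, k in zip(classes, counts)}}
    return LogisticModel(coef=lr.coef_[0].astype(float),
                         intercept=float(lr.intercept_[0]),
                         feature_means=means, feature_sds=sds,
                         training_meta=meta)


def predict_proba(model: LogisticModel, features: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`LogisticModel.predict_proba`."""
    return model.predict_proba(features)
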