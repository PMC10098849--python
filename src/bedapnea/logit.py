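"""Binomial logistic regression fit by maximum likelihood, from scratch.

The apnea/normal decision per breath frame is a two-class problem:
P(Y=1 | x) = exp(w.x) / (1 + exp(w.x)) with the intercept folded into w
as the last component of the augmented feature vector (x, 1).  The
weights maximize the log-likelihood

    l(w) = sum_i [ y_i (w.x_i) - ln(1 + exp(w.x_i)) ]

via Newton's method (default) or gradient ascent, both with step
halving so the likelihood trace is non-decreasing, and a tiny ridge on
the Hessian to keep near-separable problems finite.  Features are
centered and scaled internally; weights are reported on both scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "LogitModel",
    "TrainReport",
    "predict_proba",
    "log_likelihood",
    "fit_mle",
    "classify",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass
class LogitModel:
    """Fitted weights (intercept appended), feature scaling and cut-off.

    ``weights`` act on the scaled features; ``raw_weights`` is the
    equivalent vector on the original feature scale.  A frame is called
    apnea (class 1) when P(Y=1|x) >= ``threshold``.
    """

    weights: np.ndarray
    feature_names: tuple[str, ...]
    threshold: float = 0.5
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    impute: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.feature_names) + 1:
            raise ValueError("need one weight per feature plus an intercept")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        m = len(self.feature_names)
        if self.center is None:
            self.center = np.zeros(m)
        if self.scale is None:
            self.scale = np.ones(m)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)

    @property
    def raw_weights(self) -> np.ndarray:
        """Weights on the original (unscaled) feature axes, intercept last."""
        slopes = self.weights[:-1] / self.scale
        intercept = self.weights[-1] - float(np.dot(slopes, self.center))
        return np.append(slopes, intercept)

    def _scale_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape[-1]}"
            )
        if self.impute is not None:
            x = np.where(np.isfinite(x), x, self.impute)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature value")
        return (x - self.center) / self.scale


@dataclass
class TrainReport:
    n_samples: int
    iterations: int
    loglik_trace: list[float]
    converged: bool
    method: str
    warnings: list[str] = field(default_factory=list)


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def predict_proba(model: LogitModel, x: np.ndarray) -> float | np.ndarray:
    """P(Y=1 | x) via the overflow-safe logistic function."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xs = model._scale_x(np.atleast_2d(x))
    z = _augment(xs) @ model.weights
    p = expit(z)
    return float(p[0]) if single else p


def log_likelihood(weights: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """l(w) = sum_i [ y_i (w.x_i) - ln(1 + exp(w.x_i)) ], log-sum-exp safe.

    ``X`` must already carry the intercept column.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    z = np.asarray(X, dtype=float) @ np.asarray(weights, dtype=float)
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def fit_mle(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    method: str = "newton",
    tol: float = 1e-8,
    max_iter: int = 100,
    threshold: float = 0.5,
    ridge: float = 1e-8,
) -> tuple[LogitModel, TrainReport]:
    """Maximum-likelihood fit of the binomial logistic model.

    Features are centered and scaled internally (population SD; constant
    columns get scale 1).  Newton iterations solve the Hessian system
    with a small ridge added on near-singularity; gradient ascent uses
    backtracking line search.  Convergence is declared when the max
    absolute weight update falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, m = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{i+1}" for i in range(m))
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    if n < m + 1:
        raise ValueError("need at least m+1 samples")

    defined = np.all(np.isfinite(X), axis=1)
    warnings: list[str] = []
    if not np.all(defined):
        warnings.append(f"excluded {int((~defined).sum())} frames with undefined features")
    Xd, yd = X[defined], y[defined]
    impute = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)

    center = Xd.mean(axis=0)
    scale = Xd.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = _augment((Xd - center) / scale)

    w = np.zeros(m + 1)
    trace = [log_likelihood(w, Xs, yd)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(Xs @ w)
        grad = Xs.T @ (yd - p)
        if method == "newton":
            wgt = p * (1 - p)
            H = (Xs * wgt[:, None]).T @ Xs
            H.flat[:: m + 2] += ridge
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                H.flat[:: m + 2] += 1e-6
                step = np.linalg.solve(H, grad)
        elif method == "gradient":
            step = grad / max(n, 1)
        else:
            raise ValueError(f"method must be 'newton' or 'gradient', got {method!r}")

        # step halving keeps the likelihood trace non-decreasing
        alpha = 1.0
        base = trace[-1]
        for _ in range(60):
            cand = w + alpha * step
            ll = log_likelihood(cand, Xs, yd)
            if ll >= base:
                break
            alpha *= 0.5
        else:
            cand, ll = w, base
        delta = float(np.max(np.abs(cand - w)))
        w = cand
        trace.append(ll)
        if delta < tol:
            converged = True
            break
    if not converged and method == "gradient" and len(trace) >= 2 and trace[-1] - trace[-2] < 1e-12:
        converged = True

    if np.max(np.abs(w)) > 1e4:
        warnings.append("weights very large: data may be perfectly separable (ridge kept the solution finite)")

    model = LogitModel(
        weights=w,
        feature_names=tuple(feature_names),
        threshold=threshold,
        center=center,
        scale=scale,
        impute=impute,
    )
    report = TrainReport(
        n_samples=int(defined.sum()),
        iterations=it,
        loglik_trace=trace,
        converged=converged,
        method=method,
        warnings=warnings,
    )
    return model, report


def classify(model: LogitModel, x: np.ndarray) -> int | np.ndarray:
    """1 iff P(Y=1|x) >= threshold (ties resolve to apnea), else 0."""
    p = predict_proba(model, x)
    if isinstance(p, float):
        return int(p >= model.threshold)
    return (p >= model.threshold).astype(int)


def evaluate(
    model: LogitModel,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict:
    """Accuracy report in the per-group apnea-count layout.

    Per group and overall: actual apnea frames, identified (true
    positive) count, missed count and percentage accuracy
    (identified/actual), plus frame-level accuracy, sensitivity and
    specificity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = np.asarray(classify(model, X)).ravel()
    groups = np.asarray(groups) if groups is not None else np.zeros(y.size, dtype=int)

    def _stats(yy, pp):
        actual = int(np.sum(yy == 1))
        identified = int(np.sum((yy == 1) & (pp == 1)))
        tn = int(np.sum((yy == 0) & (pp == 0)))
        n_neg = int(np.sum(yy == 0))
        return {
            "n_frames": int(yy.size),
            "actual_apnea": actual,
            "identified_apnea": identified,
            "missed": actual - identified,
            "pct_accuracy": 100.0 * identified / actual if actual else float("nan"),
            "frame_accuracy": float(np.mean(yy == pp)),
            "sensitivity": identified / actual if actual else float("nan"),
            "specificity": tn / n_neg if n_neg else float("nan"),
        }

    report = {"groups": {}, "overall": _stats(y, pred)}
    for g in np.unique(groups):
        sel = groups == g
        report["groups"][str(g)] = _stats(y[sel], pred[sel])
    return report


# ---------------------------------------------------------------------------
# model file I/O


def save_model(model: LogitModel, path: str | Path) -> None:
    payload = {
        "feature_names": list(model.feature_names),
        "weights": model.weights.tolist(),
        "raw_weights": model.raw_weights.tolist(),
        "threshold": model.threshold,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "impute": None if model.impute is None else model.impute.tolist(),
        "provenance": "bedapnea logistic MLE",
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> LogitModel:
    payload = json.loads(Path(path).read_text())
    return LogitModel(
        weights=np.asarray(payload["weights"], dtype=float),
        feature_names=tuple(payload["feature_names"]),
        threshold=float(payload["threshold"]),
        center=np.asarray(payload["center"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        impute=None if payload.get("impute") is None else np.asarray(payload["impute"], dtype=float),
    )
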