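"""Symptom-score prediction from regional network features.

A linear model predicts a clinical total (SANS or SAPS) from regional
measures under leave-one-out cross-validation. Features are ranked by
their univariate F statistic, F = r^2 (n-2) / (1 - r^2), the top K are
selected, and K is swept to its best value. Significance comes from
permuting the scores and re-running the whole selection + CV pipeline.

Two selection modes are provided. ``in-fold`` (default) ranks and selects
features on each training fold only, so the held-out subject never
influences standardization or selection. ``global`` selects once on the
full sample before cross-validation — simpler, but optimistically biased;
results may differ between modes on real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasMap


@dataclass(frozen=True)
class PredictionModelSpec:
    measure: str = "F_Se"
    k: int | None = None  # None -> sweep 1..n_features
    selection: str = "in-fold"  # "in-fold" | "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in ("in-fold", "global"):
            raise ValueError("selection must be 'in-fold' or 'global'")


@dataclass
class PredictionResult:
    predicted: np.ndarray
    accuracy_r: float
    k: int
    weights: np.ndarray  # final-model per-region weights (0 for unselected)
    selected: np.ndarray  # indices selected in the final full-sample model
    permutation_p: float | None = None
    system_weights: dict[str, float] = field(default_factory=dict)


def f_rank(features: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rank feature columns by univariate F against y (descending, stable).

    Returns ``(order, f_values)``. Zero-variance features get F = 0 and
    fall to the end of the ranking with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need n >= 3")
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance feature(s) ranked last")
    yc = y - y.mean()
    y_sd = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X - X.mean(axis=0)).T @ yc / (n * sd * y_sd)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    f = r**2 * (n - 2) / (1 - r**2)
    f[dead] = 0.0
    order = np.argsort(-f, kind="stable")
    return order, f


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _loo_predictions(X: np.ndarray, y: np.ndarray, k: int, selection: str) -> np.ndarray:
    """Out-of-fold predictions for every subject.

    Training-fold feature/target moments are obtained by subtracting the
    held-out subject from precomputed full-sample sums, so per-fold
    ranking and standardization cost O(p) instead of O(np).
    """
    n, p = X.shape
    sx_all = X.sum(axis=0)
    sxx_all = (X**2).sum(axis=0)
    sy_all = y.sum()
    syy_all = (y**2).sum()
    sxy_all = X.T @ y
    if selection == "global":
        order, _ = f_rank(X, y)
        sel_global = order[:k]
    predicted = np.empty(n)
    m = n - 1
    for i in range(n):
        sx = sx_all - X[i]
        sxx = sxx_all - X[i] ** 2
        sy = sy_all - y[i]
        syy = syy_all - y[i] ** 2
        sxy = sxy_all - X[i] * y[i]
        if selection == "in-fold":
            # F is monotone in r^2, so ranking by r^2 matches the F ranking
            num = m * sxy - sx * sy
            den = (m * sxx - sx**2) * (m * syy - sy**2)
            r2 = np.where(den > 0, num**2 / np.where(den > 0, den, 1.0), 0.0)
            sel = np.argsort(-r2, kind="stable")[:k]
        else:
            sel = sel_global
        mu = sx[sel] / m
        sd = np.sqrt(np.maximum(sxx[sel] / m - mu**2, 0.0))
        sd[sd == 0] = 1.0
        Xtr = (np.delete(X[:, sel], i, axis=0) - mu) / sd
        ytr = np.delete(y, i)
        A = np.column_stack([np.ones(m), Xtr])
        AtA = A.T @ A
        Aty = A.T @ ytr
        try:
            beta = np.linalg.solve(AtA, Aty)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        xte = (X[i, sel] - mu) / sd
        predicted[i] = beta[0] + xte @ beta[1:]
    return predicted


def loo_cv_predict(
    features: np.ndarray, y: np.ndarray, spec: PredictionModelSpec
) -> PredictionResult:
    """Leave-one-out cross-validated linear prediction with top-K features.

    Per fold the features are standardized on the training subjects; in
    ``in-fold`` mode ranking and selection also use only the training
    fold. Accuracy is the Pearson r between real and predicted scores.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    k = spec.k if spec.k is not None else p
    if not 1 <= k <= p:
        raise ValueError(f"K={k} outside 1..{p}")
    if n < 3:
        raise ValueError("need n >= 3")
    predicted = _loo_predictions(X, y, k, spec.selection)
    if np.std(predicted) == 0 or np.std(y) == 0:
        acc = 0.0
    else:
        acc = float(np.corrcoef(y, predicted)[0, 1])
    # final model: refit on all subjects at this K for interpretable weights
    final_order, _ = f_rank(X, y)
    sel = final_order[:k]
    Xs, _ = _standardize(X[:, sel], X[:, sel])
    beta = _ols_fit(Xs, y)
    weights = np.zeros(p)
    weights[sel] = beta[1:]
    return PredictionResult(
        predicted=predicted, accuracy_r=acc, k=k, weights=weights, selected=sel
    )


def select_best_k(
    features: np.ndarray,
    y: np.ndarray,
    spec: PredictionModelSpec,
    k_grid: np.ndarray | None = None,
) -> PredictionResult:
    """Sweep K and return the result at the best-accuracy K (smallest on ties)."""
    p = np.asarray(features).shape[1]
    if k_grid is None:
        k_grid = np.arange(1, p + 1)
    best: PredictionResult | None = None
    for k in k_grid:
        res = loo_cv_predict(
            features, y,
            PredictionModelSpec(spec.measure, int(k), spec.selection, spec.seed),
        )
        if best is None or res.accuracy_r > best.accuracy_r:
            best = res
    assert best is not None
    return best


def permutation_pvalue(
    features: np.ndarray,
    y: np.ndarray,
    spec: PredictionModelSpec,
    observed_r: float,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    sweep_k: bool = False,
) -> float:
    """Permutation p-value for a prediction accuracy.

    Each permutation shuffles the scores and re-runs the full selection +
    LOO-CV pipeline (including the K sweep when ``sweep_k``); the add-one
    convention keeps p strictly positive.
    """
    rng = np.random.default_rng(rng if rng is not None else spec.seed)
    y = np.asarray(y, dtype=float)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if sweep_k:
            res = select_best_k(features, yp, spec)
        else:
            res = loo_cv_predict(features, yp, spec)
        if res.accuracy_r >= observed_r:
            count += 1
    return (1 + count) / (1 + n_perm)


def system_weights(
    weights: np.ndarray, atlas: AtlasMap, region_ids: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Signed per-system sums of final-model regional weights."""
    weights = np.asarray(weights, dtype=float)
    ids = region_ids or atlas.region_ids
    if weights.shape[0] != len(ids):
        raise ValueError("weights length must match region ids")
    labels = np.asarray([atlas.system_of(r) for r in ids])
    return {
        s: float(weights[labels == s].sum()) for s in atlas.system_names
    }
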