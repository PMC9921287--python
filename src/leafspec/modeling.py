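"""Outlier screening, calibration/test splitting and NIPALS PLSR.

The modelling chain mirrors standard chemometrics practice for spectra with
many collinear bands and few samples:

1. Hotelling's T^2 on principal-component scores flags spectral outliers
   against an F-distribution threshold at a chosen confidence level.
2. The remaining samples are split randomly ~80/20 into calibration and test
   sets; a Welch t-test per nutrient confirms the two sets have statistically
   indistinguishable means (the split is redrawn otherwise).
3. A single-response NIPALS partial least squares regression is fitted on
   the calibration set, and the number of latent variables is chosen at the
   minimum PRESS of a leave-one-out cross-validation, with centring refitted
   inside every fold so nothing leaks from the held-out sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .metrics import r_squared, rmse

__all__ = [
    "PLSModel",
    "CVResult",
    "SplitResult",
    "hotelling_screen",
    "split_calibration_test",
    "fit_plsr",
    "predict",
    "loo_cv",
    "DEFAULT_MAX_LV",
]

#: default cap on candidate latent variables
DEFAULT_MAX_LV = 15


# ---------------------------------------------------------------------------
# Hotelling T^2 spectral outlier screen

def hotelling_screen(
    X: np.ndarray,
    alpha: float = 0.05,
    n_pc: int | None = 5,
    ids: list[str] | None = None,
) -> tuple[list, list, np.ndarray]:
    """Flag spectral outliers by Hotelling's T^2 on PCA scores.

    T^2 for sample i sums its squared scores on the first ``n_pc``
    principal components, each normalised by that component's variance; the
    cut-off is ``n_pc (n-1)/(n - n_pc) * F(1-alpha; n_pc, n-n_pc)``.
    Screening runs once — survivors are not re-screened.  With
    ``n_pc=None`` the component count is min(5, components covering 95% of
    variance).

    Returns ``(kept, removed, t2)`` where kept/removed are sample ids (or
    row indices when ``ids`` is None).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    nonzero = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if nonzero == 0:
        raise ValueError("zero variance: all samples identical")
    if n_pc is None:
        var = s**2
        frac = np.cumsum(var) / var.sum()
        n_pc = min(5, int(np.searchsorted(frac, 0.95) + 1))
    if n_pc >= n:
        raise ValueError("n_pc must be smaller than the number of samples")
    if n_pc > nonzero:
        raise ValueError(f"only {nonzero} non-degenerate components available")

    # score_k = U[:,k] * s_k, component variance s_k^2/(n-1):
    # squared normalised score = (n-1) * U[:,k]^2
    t2 = (n - 1) * np.sum(U[:, :n_pc] ** 2, axis=1)
    threshold = (
        n_pc * (n - 1) / (n - n_pc) * stats.f.ppf(1 - alpha, n_pc, n - n_pc)
    )
    labels = list(range(n)) if ids is None else list(ids)
    removed = [labels[i] for i in np.flatnonzero(t2 > threshold)]
    kept = [labels[i] for i in np.flatnonzero(t2 <= threshold)]
    return kept, removed, t2


# ---------------------------------------------------------------------------
# calibration / test split with mean-equality check

@dataclass
class SplitResult:
    """An accepted calibration/test split and its per-nutrient t-test record."""

    calibration_ids: list
    test_ids: list
    p_values: dict[str, float]
    seed: int
    n_redraws: int


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def split_calibration_test(
    ids: list,
    y_table,
    fraction: float = 0.8,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> SplitResult:
    """Random ~80/20 split, redrawn until every nutrient passes a Welch t-test.

    ``y_table`` is a NutrientTable or DataFrame indexed by sample id.  The
    calibration size is round(fraction * n).  If any nutrient's
    calibration/test means differ at the given alpha the split is redrawn
    with an incremented seed, up to ``max_redraws`` times.
    """
    data = getattr(y_table, "data", y_table)
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_cal = int(round(fraction * n))
    if not 0 < n_cal < n:
        raise ValueError("fraction leaves an empty calibration or test set")

    best: SplitResult | None = None
    best_min_p = -1.0
    for attempt in range(max_redraws + 1):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        cal_ids = [ids[i] for i in sorted(perm[:n_cal])]
        test_ids = [ids[i] for i in sorted(perm[n_cal:])]
        p_values = {
            str(col): _welch_p(
                data.loc[cal_ids, col].to_numpy(dtype=float),
                data.loc[test_ids, col].to_numpy(dtype=float),
            )
            for col in data.columns
        }
        result = SplitResult(cal_ids, test_ids, p_values, seed + attempt, attempt)
        min_p = min(p_values.values()) if p_values else 1.0
        if min_p > alpha:
            return result
        if min_p > best_min_p:
            best, best_min_p = result, min_p
    raise RuntimeError(
        f"no acceptable split in {max_redraws} redraws; best attempt "
        f"(seed {best.seed}) had min p = {best_min_p:.4f}"
    )


# ---------------------------------------------------------------------------
# NIPALS PLSR (single response)

@dataclass
class PLSModel:
    """Fitted PLS regression for one response.

    Predictions through the stored regression coefficients equal the
    component-by-component deflation form to numerical precision.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (n_lv, bands)
    x_loadings: np.ndarray    # (n_lv, bands)
    y_loadings: np.ndarray    # (n_lv,)
    scores: np.ndarray        # (n, n_lv) training scores
    coef: np.ndarray          # (bands,)
    intercept: float
    n_lv: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "n_lv": self.n_lv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_lv=int(d["n_lv"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int):
    """Core NIPALS loop on centred data.

    Returns (W, P, q, T, attained) — deflation stops early if the residual
    rank is exhausted, with ``attained`` the number of components extracted.
    """
    n, p = X.shape
    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd, yd = X.copy(), y.copy()
    cov0 = np.linalg.norm(X.T @ y)
    if cov0 == 0:
        return W, P, q, T, 0
    for a in range(n_lv):
        w = Xd.T @ yd
        norm_w = np.linalg.norm(w)
        if norm_w <= 1e-12 * cov0:
            return W, P, q, T, a
        w /= norm_w
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-24:
            return W, P, q, T, a
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        W[a], P[a], q[a], T[:, a] = w, p_a, q_a, t
        Xd -= np.outer(t, p_a)
        yd = yd - q_a * t
    return W, P, q, T, n_lv


def _coef_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # b = W (P' W)^-1 q with column-major W, P; rows are stored here, so
    # P' W = P_rows @ W_rows' — a small upper-triangular system
    A = P @ W.T  # (a, a)
    return W.T @ np.linalg.solve(A, q)


def fit_plsr(X_cal: np.ndarray, y_cal: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a single-response NIPALS PLS regression with ``n_lv`` components.

    X columns are centred but not variance-scaled (standard for spectra;
    scatter is handled by the preprocessing transforms).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per y value")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if np.all(y == y[0]):
        raise ValueError("constant response: PLSR undefined")
    n = X.shape[0]
    if n_lv > n - 1:
        raise ValueError(f"n_lv={n_lv} exceeds n-1={n - 1}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T, attained = _nipals(X - x_mean, y - y_mean, n_lv)
    if attained < n_lv:
        raise ValueError(
            f"n_lv={n_lv} exceeds the rank of centred X; "
            f"attainable maximum is {attained}"
        )
    coef = _coef_from_factors(W, P, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        intercept=intercept,
        n_lv=n_lv,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict: yhat = (X - x_mean) . b + y_mean."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"band count mismatch: X has {X.shape[1]} bands, "
            f"model expects {model.x_mean.size}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def predict_deflation(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Prediction via successive deflation — algebraically equal to `predict`."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - model.x_mean
    yhat = np.full(X.shape[0], model.y_mean)
    for a in range(model.n_lv):
        t = Xc @ model.weights[a]
        yhat += model.y_loadings[a] * t
        Xc = Xc - np.outer(t, model.x_loadings[a])
    return yhat


# ---------------------------------------------------------------------------
# leave-one-out cross-validation with PRESS-based LV selection

@dataclass
class CVResult:
    """Per-LV PRESS from leave-one-out CV and the selected model's metrics."""

    press: np.ndarray             # (max_lv,) PRESS at 1..max_lv components
    selected_lv: int              # argmin PRESS (smallest LV on ties)
    rmse_c: float                 # calibration fit at selected LV
    r2_c: float
    rmse_cv: float                # from held-out predictions at selected LV
    r2_cv: float
    cv_predictions: np.ndarray = field(repr=False, default=None)  # (n, max_lv)

    @property
    def max_lv(self) -> int:
        return len(self.press)


def loo_cv(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    max_lv: int = DEFAULT_MAX_LV,
    transform_factory=None,
) -> CVResult:
    """Leave-one-out CV over 1..max_lv latent variables.

    Every fold refits the model — including the centring — on the n-1
    remaining samples and predicts the held-out one at every candidate LV
    count.  PRESS(a) is the sum of squared held-out residuals; the selected
    LV minimises PRESS (smallest count on ties).  If a fold's residual rank
    is exhausted below ``max_lv``, its prediction is held constant for the
    remaining counts (extra components cannot change an exact fit).

    ``transform_factory(X_train, y_train) -> callable`` optionally refits a
    preprocessing transform inside every fold and on the full set; this is
    essential for response-supervised transforms like OSC, whose weights
    estimated on all samples would otherwise leak the held-out response
    into the cross-validation and inflate R^2_CV.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out CV")
    max_lv = int(min(max_lv, n - 2))
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if np.all(y == y[0]):
        raise ValueError("constant response: PLSR undefined")

    cv_pred = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        rows = idx != i
        X_tr, y_tr = X[rows], y[rows]
        x_held = X[i]
        if transform_factory is not None:
            transform = transform_factory(X_tr, y_tr)
            X_tr = transform(X_tr)
            x_held = transform(x_held[None, :])[0]
        x_mean = X_tr.mean(axis=0)
        y_mean = y_tr.mean()
        try:
            W, P, q, _, attained = _nipals(X_tr - x_mean, y_tr - y_mean, max_lv)
        except ValueError as exc:
            raise ValueError(f"fold {i} (held-out sample {i}): {exc}") from exc
        # deflation-form prediction of the held-out sample at each LV count
        xc = x_held - x_mean
        yhat = y_mean
        for a in range(max_lv):
            if a < attained:
                t = xc @ W[a]
                yhat = yhat + q[a] * t
                xc = xc - t * P[a]
            cv_pred[i, a] = yhat

    residuals = cv_pred - y[:, None]
    press = np.sum(residuals**2, axis=0)
    selected = int(np.argmin(press)) + 1  # first index on ties via argmin

    X_full = X
    if transform_factory is not None:
        X_full = transform_factory(X, y)(X)
    model = fit_plsr(X_full, y, selected)
    fitted = predict(model, X_full)
    yhat_cv = cv_pred[:, selected - 1]
    return CVResult(
        press=press,
        selected_lv=selected,
        rmse_c=rmse(y, fitted),
        r2_c=r_squared(y, fitted),
        rmse_cv=rmse(y, yhat_cv),
        r2_cv=r_squared(y, yhat_cv),
        cv_predictions=cv_pred,
    )
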