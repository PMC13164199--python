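"""NIPALS PLS1 regression, cross-validated latent-variable selection,
VIP scores, calibration metrics and PCA scores.

The PLS1 decomposition is authored here (it is the quantitative core of the
pipeline): X and y are centered (X optionally autoscaled), weights/loadings
are extracted by NIPALS deflation, and the regression vector is mapped back
to original units.  Derivative NIR spectra are modeled with centered-only
columns (their relative magnitudes are meaningful), whereas GC-IMS marker
matrices are autoscaled because peak volumes span decades; both modes are a
switch.

Metric conventions
------------------
R2    1 - SS_res / SS_tot
RMSE  root mean squared prediction error, response units
RPD   sd(y_true; ddof=1) / RMSE ("residual prediction deviation";
      values above 3 are conventionally read as excellent calibrations)

Cross-validated R2 (Rcv2 / Q2) is computed from *pooled* out-of-fold
predictions, which is stable for small folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass
class ModelMetrics:
    r2: float
    rmse: float
    rpd: float
    context: str = "test"


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 decomposition.

    W are X-weights (unit-norm columns), P X-loadings, q per-component
    y-loadings, T training scores. coef_/intercept_ give predictions in
    original units; they are exactly equivalent to score projection.
    """

    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    coef_: np.ndarray
    intercept_: float
    scale_x: bool = False

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1 : maps centered/scaled X to scores, T = Xc R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Score projection of (new) observations."""
        Xc = (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean) / self.x_scale
        return Xc @ self.rotation

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef_ + self.intercept_

    def coefficients_for(self, n_lv: int) -> tuple:
        """(coef, intercept) in original units using only the first n_lv components."""
        if not 1 <= n_lv <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}]")
        W, P, q = self.W[:, :n_lv], self.P[:, :n_lv], self.q[:n_lv]
        b = W @ np.linalg.solve(P.T @ W, q)
        coef = b / self.x_scale
        return coef, float(self.y_mean - self.x_mean @ coef)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int, scale_x: bool = False) -> PLSModel:
    """Fit a PLS1 model by NIPALS deflation.

    Deterministic (PLS1 needs no random initialization). Raises on a
    zero-variance response or an out-of-bounds component count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y have different numbers of observations")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv={n_lv} outside [1, {max_lv}] for a {n}x{p} problem")

    x_mean = X.mean(axis=0)
    if scale_x:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())

    E = (X - x_mean) / x_scale
    f = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    actual = 0
    for a in range(n_lv):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            break  # residual X carries no covariance with y; stop early
        w /= norm
        t = E @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p_load = E.T @ t / tt
        q_a = (f @ t) / tt
        E -= np.outer(t, p_load)
        f = f - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
        actual += 1
    if actual == 0:
        raise ValueError("no predictive component could be extracted (degenerate X'y)")
    W, P, q, T = W[:, :actual], P[:, :actual], q[:actual], T[:, :actual]

    b = W @ np.linalg.solve(P.T @ W, q)
    coef = b / x_scale
    intercept = float(y_mean - x_mean @ coef)
    return PLSModel(actual, x_mean, x_scale, y_mean, W, P, q, T, coef, intercept, scale_x)


def compute_metrics(y_true, y_pred, context: str = "test") -> ModelMetrics:
    """R2, RMSE and RPD for one evaluation set."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance; R2 and RPD are undefined")
    resid = y_true - y_pred
    r2 = 1.0 - float(resid @ resid) / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    if rmse == 0:
        raise ValueError("perfect prediction: RPD is undefined (division by zero RMSE)")
    rpd = float(np.std(y_true, ddof=1)) / rmse
    return ModelMetrics(r2=r2, rmse=rmse, rpd=rpd, context=context)


def _cv_folds(n: int, k: int, seed: int, stratify=None):
    idx = np.arange(n)
    if stratify is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(idx, np.asarray(stratify)))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(idx))


def cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid,
    folds,
    scale_x: bool = False,
) -> dict:
    """Pooled out-of-fold predictions for every component count in lv_grid.

    One NIPALS fit per fold at the largest requested count; smaller models
    are read off the same decomposition (NIPALS components are nested).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    lv_grid = sorted(set(int(a) for a in lv_grid))
    preds = {a: np.full(y.size, np.nan) for a in lv_grid}
    for train_idx, test_idx in folds:
        if train_idx.size < 2 or test_idx.size < 1:
            raise ValueError("cross-validation fold with fewer than 2 training samples")
        cap = min(train_idx.size - 1, X.shape[1])
        fit_lv = min(max(lv_grid), cap)
        model = fit_pls1(X[train_idx], y[train_idx], fit_lv, scale_x=scale_x)
        for a in lv_grid:
            coef, intercept = model.coefficients_for(min(a, model.n_lv))
            preds[a][test_idx] = X[test_idx] @ coef + intercept
    return preds


def cross_validate_lv(
    X: np.ndarray,
    y: np.ndarray,
    lv_grid=range(1, 11),
    k: int = 5,
    seed: int = 0,
    stratify=None,
    scale_x: bool = False,
):
    """Select the latent-variable count by k-fold cross-validated R2.

    Folds are stratified by the supplied labels (storage class) when given.
    Rcv2 comes from pooled out-of-fold predictions; the best count maximizes
    Rcv2 with ties broken toward fewer components. Returns
    (best_lv, {lv: ModelMetrics}).
    """
    y = np.asarray(y, dtype=float).ravel()
    folds = _cv_folds(y.size, k, seed, stratify)
    preds = cv_predictions(X, y, lv_grid, folds, scale_x=scale_x)
    per_lv = {a: compute_metrics(y, preds[a], context="cv") for a in preds}
    best_lv, best_r2 = None, -np.inf
    for a in sorted(per_lv):
        if per_lv[a].r2 > best_r2 + 1e-12:
            best_lv, best_r2 = a, per_lv[a].r2
    return best_lv, per_lv


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a ) with unit-norm
    weight columns; SSY_a = q_a^2 * t_a't_a is the y-variance captured by
    component a. Mean squared VIP equals 1 by construction.
    """
    ssy = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    p = model.W.shape[0]
    return np.sqrt(p * (model.W**2 @ ssy) / total)


def pca_scores(X: np.ndarray, n_components: int):
    """Column-mean-centered PCA scores and explained-variance ratios."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components={n_components} outside [1, {min(n - 1, p)}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
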