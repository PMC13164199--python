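"""Two-class OPLS-DA for volatile-marker screening.

Orthogonal PLS discriminant analysis splits the predictor variation into a
single class-predictive component and a small number of class-orthogonal
components (Trygg-Wold orthogonal signal correction inside the PLS loop).
Markers are screened by VIP computed from the predictive component only,
with the conventional VIP > 1 cut and a VIP > 2 highlight for the strongest
discriminators.

With the study's contrasts (one physical sample per class, three injection
replicates) cross-validation folds are stratified at replicate level; when
each class contains several distinct samples, folds keep all replicates of
one sample together to avoid replicate leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .pls import fit_pls1


@dataclass
class OPLSDAModel:
    classes: tuple
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w_pred: np.ndarray        # unit-norm predictive weights (filtered X space)
    p_pred: np.ndarray
    t_pred: np.ndarray
    q_pred: float
    W_orth: np.ndarray        # (p, n_orth)
    P_orth: np.ndarray
    T_orth: np.ndarray
    n_orth: int
    r2x: float
    r2y: float
    q2: float
    accuracy: float
    scale_x: bool = True

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean) / self.x_scale
        for a in range(self.n_orth):
            t = Xc @ self.W_orth[:, a]
            Xc = Xc - np.outer(t, self.P_orth[:, a])
        return Xc

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score; the fitted class coding is centered, so the
        decision cutoff is 0."""
        t = self._prepare(X) @ self.w_pred
        return t * self.q_pred

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels at the midpoint cutoff."""
        d = self.decision_values(X) + self.y_mean
        return np.where(d >= 0.5, self.classes[1], self.classes[0])


def _encode(labels) -> tuple:
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA supports exactly two classes, got {len(classes)}")
    y = (labels == classes[1]).astype(float)
    return classes, y


def _osc_fit(E: np.ndarray, f: np.ndarray, n_orth: int):
    """One predictive + n_orth orthogonal components on centered data."""
    p = E.shape[1]
    W_orth = np.zeros((p, n_orth))
    P_orth = np.zeros((p, n_orth))
    T_orth = np.zeros((E.shape[0], n_orth))
    for a in range(n_orth):
        w = E.T @ f
        w /= np.linalg.norm(w)
        t = E @ w
        p_load = E.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            W_orth = W_orth[:, :a]
            P_orth = P_orth[:, :a]
            T_orth = T_orth[:, :a]
            n_orth = a
            break
        w_o /= norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_orth[:, a], P_orth[:, a], T_orth[:, a] = w_o, p_o, t_o
    w = E.T @ f
    w /= np.linalg.norm(w)
    t = E @ w
    p_load = E.T @ t / (t @ t)
    q = (f @ t) / (t @ t)
    return w, p_load, t, q, W_orth, P_orth, T_orth, n_orth


def _folds_for(labels, groups, k: int, seed: int):
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    if groups is not None:
        groups = np.asarray(groups)
        per_class_groups = min(
            len(np.unique(groups[labels == c])) for c in np.unique(labels)
        )
        if per_class_groups > 1:
            # leave whole samples out, one unique-group fold set per seed
            rng = np.random.default_rng(seed)
            uniq = np.unique(groups)
            order = rng.permutation(uniq)
            n_splits = min(k, per_class_groups)
            buckets = [order[i::n_splits] for i in range(n_splits)]
            return [
                (idx[~np.isin(groups, b)], idx[np.isin(groups, b)]) for b in buckets
            ]
    counts = pd.Series(labels).value_counts().min()
    n_splits = max(2, min(k, int(counts)))
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(splitter.split(idx, labels))


def _cv_q2_accuracy(X, y, labels, n_orth, folds, scale_x):
    press, preds = 0.0, np.full(y.size, np.nan)
    for tr, te in folds:
        x_mean = X[tr].mean(axis=0)
        if scale_x:
            x_scale = X[tr].std(axis=0, ddof=1)
            x_scale[x_scale == 0] = 1.0
        else:
            x_scale = np.ones(X.shape[1])
        E = (X[tr] - x_mean) / x_scale
        f = y[tr] - y[tr].mean()
        if np.ptp(f) == 0:
            raise ValueError("a CV fold lost one class entirely")
        w, p_load, t, q, W_o, P_o, _, k_o = _osc_fit(E, f, n_orth)
        Ete = (X[te] - x_mean) / x_scale
        for a in range(k_o):
            t_o = Ete @ W_o[:, a]
            Ete = Ete - np.outer(t_o, P_o[:, a])
        yhat = (Ete @ w) * q + y[tr].mean()
        preds[te] = yhat
        press += float(np.sum((y[te] - yhat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss
    accuracy = float(np.mean((preds >= 0.5) == (y == 1.0)))
    return q2, accuracy


def fit_oplsda(
    X,
    class_labels,
    n_orth: int | None = None,
    k_folds: int = 3,
    seed: int = 0,
    scale_x: bool = True,
    groups=None,
    max_orth: int = 3,
) -> OPLSDAModel:
    """Fit a two-class OPLS-DA model.

    n_orth=None selects the orthogonal-component count automatically:
    starting from 0, a component is added while cross-validated Q2 improves
    by more than 0.01, capped at max_orth. Q2 and CV accuracy use pooled
    out-of-fold predictions. Deterministic given seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes, y = _encode(class_labels)
    for c in (0.0, 1.0):
        if np.sum(y == c) < 2:
            raise ValueError("each class needs at least 2 observations")
    folds = _folds_for(np.asarray(class_labels), groups, k_folds, seed)

    if n_orth is None:
        q2_prev, accuracy = _cv_q2_accuracy(X, y, class_labels, 0, folds, scale_x)
        chosen, q2_best, acc_best = 0, q2_prev, accuracy
        cap = min(max_orth, X.shape[0] - 2, X.shape[1] - 1)
        for k_o in range(1, cap + 1):
            q2_k, acc_k = _cv_q2_accuracy(X, y, class_labels, k_o, folds, scale_x)
            if q2_k > q2_best + 0.01:
                chosen, q2_best, acc_best = k_o, q2_k, acc_k
            else:
                break
        n_orth, q2, accuracy = chosen, q2_best, acc_best
    else:
        q2, accuracy = _cv_q2_accuracy(X, y, class_labels, n_orth, folds, scale_x)

    x_mean = X.mean(axis=0)
    if scale_x:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(X.shape[1])
    E0 = (X - x_mean) / x_scale
    f = y - y.mean()
    w, p_load, t, q_pred, W_o, P_o, T_o, n_orth = _osc_fit(E0.copy(), f, n_orth)

    ssx = float(np.sum(E0**2))
    explained = float(t @ t * (p_load @ p_load))
    for a in range(n_orth):
        explained += float(T_o[:, a] @ T_o[:, a] * (P_o[:, a] @ P_o[:, a]))
    r2x = min(1.0, explained / ssx)
    ssy = float(f @ f)
    r2y = float(q_pred**2 * (t @ t)) / ssy

    return OPLSDAModel(
        classes, x_mean, x_scale, float(y.mean()), w, p_load, t, float(q_pred),
        W_o, P_o, T_o, n_orth, r2x, r2y, q2, accuracy, scale_x,
    )


def oplsda_vip(model: OPLSDAModel) -> np.ndarray:
    """VIP from the predictive component only.

    With a single predictive component and unit-norm weights this reduces to
    VIP_j = sqrt(p) * |w_j|, which preserves sum(VIP^2) = p.
    """
    w = model.w_pred
    p = w.size
    return np.sqrt(p) * np.abs(w)


def screen_markers(
    peak_matrix: pd.DataFrame,
    groups,
    threshold: float = 1.0,
    highlight: float = 2.0,
    seed: int = 0,
    sample_groups=None,
    n_orth: int | None = None,
) -> pd.DataFrame:
    """Screen discriminating compounds between two groups by OPLS-DA VIP.

    peak_matrix: observations x compounds (normalized, deduplicated).
    Returns compounds with VIP > threshold ordered by descending VIP, with a
    vip_gt2 highlight flag; an empty frame (with a warning) when nothing
    passes.
    """
    import warnings

    model = fit_oplsda(
        peak_matrix.to_numpy(dtype=float),
        np.asarray(groups),
        n_orth=n_orth,
        seed=seed,
        groups=sample_groups,
    )
    scores = oplsda_vip(model)
    table = pd.DataFrame(
        {"compound": peak_matrix.columns, "vip": scores}
    ).sort_values("vip", ascending=False, ignore_index=True)
    selected = table[table["vip"] > threshold].reset_index(drop=True)
    selected["vip_gt2"] = selected["vip"] > highlight
    if selected.empty:
        warnings.warn("no compound exceeded the VIP threshold", stacklevel=2)
    selected.attrs["model"] = model
    return selected
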