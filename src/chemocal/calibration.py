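"""NIRS-side modeling: classification screen, PLSR calibration of the
composite indices across preprocessing methods, regression-coefficient
regions, and permutation-test validation.

Protocol mirror: spectra are stratified by storage class and split 80/20 at
spectrum level; the classification screen uses stratified 10-fold CV; PLSR
selects the latent-variable count (grid 1-10) by 5-fold cross-validated R2
on the training partition, refits on all training rows and reports test-set
R2p / RMSEp / RPDp per preprocessing method. Each final model is validated
by a 200-iteration response-permutation test whose Q2-vs-correlation
regression intercept must stay below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    recall_score,
)
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_predict,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import SpectraSet
from .pls import (
    PLSModel,
    _cv_folds,
    compute_metrics,
    cross_validate_lv,
    cv_predictions,
    fit_pls1,
)
from .preprocess import PreprocessSpec, apply_pipeline


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    labels: np.ndarray
    ratio: float
    seed: int
    mode: str = "spectrum"

    def __post_init__(self) -> None:
        n = self.labels.size
        joined = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if not np.array_equal(joined, np.arange(n)):
            raise ValueError("split is not an exhaustive disjoint partition")


def make_split(
    spectra: SpectraSet,
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "spectrum",
) -> SplitPlan:
    """Stratified train/test split of spectra by storage class (sample label).

    spectrum mode assigns individual spectra (the study's protocol, so
    spectra of one physical sample can land on both sides); sample-grouped
    mode would keep whole samples together but is infeasible when every
    class is a single sample, and raises in that case.
    """
    labels = spectra.meta["sample"].to_numpy()
    if mode == "sample":
        counts = pd.Series(labels).groupby(labels).nunique()
        raise ValueError(
            "sample-grouped splitting is infeasible for this design: each "
            "storage class is one physical sample, so a class cannot appear "
            "in both partitions"
        )
    if mode != "spectrum":
        raise ValueError(f"unknown split mode {mode!r}")
    idx = np.arange(labels.size)
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, random_state=seed, stratify=labels
    )
    return SplitPlan(np.sort(train_idx), np.sort(test_idx), labels, ratio, seed, mode)


# ---------------------------------------------------------------------------
# classification screen (standard algorithms; an exploratory stage)
# ---------------------------------------------------------------------------


def _default_classifiers(seed: int) -> dict:
    return {
        "SVM": SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RF": RandomForestClassifier(n_estimators=200, random_state=seed),
    }


def classify_screen(
    spectra: SpectraSet,
    preprocess_specs,
    split: SplitPlan,
    algorithms: dict | None = None,
    cv_k: int = 10,
    seed: int = 0,
    range_name: str = "",
):
    """Storage-class classification over preprocessing x algorithm combinations.

    For each preprocessing spec (fitted on training rows only) and each
    algorithm: stratified cv_k-fold CV metrics on the training partition,
    then held-out test metrics and a confusion matrix. Weighted F1/recall
    use class-frequency weights. Returns (report frame, {key: confusion}).
    """
    if algorithms is None:
        algorithms = _default_classifiers(seed)
    y = split.labels
    y_train, y_test = y[split.train_idx], y[split.test_idx]
    rows, confusions = [], {}
    for spec in preprocess_specs:
        train_set, state = apply_pipeline(spectra.subset(split.train_idx), spec)
        test_set, _ = apply_pipeline(spectra.subset(split.test_idx), spec, state)
        X_train, X_test = train_set.absorbance, test_set.absorbance
        cv = StratifiedKFold(n_splits=cv_k, shuffle=True, random_state=seed)
        for name, proto in algorithms.items():
            from sklearn.base import clone

            est = clone(proto)
            cv_pred = cross_val_predict(est, X_train, y_train, cv=cv)
            est = clone(proto).fit(X_train, y_train)
            test_pred = est.predict(X_test)
            rows.append(
                {
                    "range": range_name,
                    "method": spec.method,
                    "algorithm": name,
                    "cv_accuracy": accuracy_score(y_train, cv_pred),
                    "cv_f1_weighted": f1_score(y_train, cv_pred, average="weighted"),
                    "cv_recall_weighted": recall_score(
                        y_train, cv_pred, average="weighted"
                    ),
                    "test_accuracy": accuracy_score(y_test, test_pred),
                    "test_f1_weighted": f1_score(y_test, test_pred, average="weighted"),
                    "test_recall_weighted": recall_score(
                        y_test, test_pred, average="weighted"
                    ),
                }
            )
            confusions[(range_name, spec.method, name)] = confusion_matrix(
                y_test, test_pred, labels=sorted(np.unique(y))
            )
    return pd.DataFrame(rows), confusions


# ---------------------------------------------------------------------------
# PLSR calibration of a composite index
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Per-method fitted artifacts kept alongside the metrics table."""

    spec: PreprocessSpec
    state: dict
    model: PLSModel
    n_lv: int
    X_train: np.ndarray
    y_train: np.ndarray
    train_labels: np.ndarray


def calibrate_index(
    spectra: SpectraSet,
    index_values: pd.Series,
    preprocess_specs,
    split: SplitPlan,
    lv_grid=range(1, 11),
    cv_k: int = 5,
    seed: int = 0,
    scale_x: bool = False,
    kind: str = "deterioration",
    range_name: str = "",
):
    """PLSR calibration of one composite index over all preprocessing methods.

    Every spectrum carries its sample's index value as response. Per method:
    preprocessing fitted on the training partition, LV count selected by
    cv_k-fold CV (stratified by sample) maximizing Rcv2, refit on all
    training rows, evaluated on the test partition. The best method per
    block maximizes Rp2 with RPDp as tie-break.

    Returns (report DataFrame with Table-5-shaped columns, {method: CalibrationResult}).
    """
    y_all = index_values.loc[spectra.meta["sample"]].to_numpy(dtype=float)
    if np.ptp(y_all) == 0:
        raise ValueError("index values are constant; calibration response degenerate")
    rows, results = [], {}
    for spec in preprocess_specs:
        train_set, state = apply_pipeline(spectra.subset(split.train_idx), spec)
        test_set, _ = apply_pipeline(spectra.subset(split.test_idx), spec, state)
        X_train, X_test = train_set.absorbance, test_set.absorbance
        y_train, y_test = y_all[split.train_idx], y_all[split.test_idx]
        strat = split.labels[split.train_idx]
        best_lv, per_lv = cross_validate_lv(
            X_train, y_train, lv_grid=lv_grid, k=cv_k, seed=seed,
            stratify=strat, scale_x=scale_x,
        )
        model = fit_pls1(X_train, y_train, best_lv, scale_x=scale_x)
        test_metrics = compute_metrics(y_test, model.predict(X_test), context="test")
        cv_metrics = per_lv[best_lv]
        rows.append(
            {
                "kind": kind,
                "range": range_name,
                "method": spec.method,
                "n_lv": best_lv,
                "Rcv2": cv_metrics.r2,
                "RMSEcv": cv_metrics.rmse,
                "RPDcv": cv_metrics.rpd,
                "Rp2": test_metrics.r2,
                "RMSEp": test_metrics.rmse,
                "RPDp": test_metrics.rpd,
            }
        )
        results[spec.method] = CalibrationResult(
            spec, state, model, best_lv, X_train, y_train, strat
        )
    report = pd.DataFrame(rows)
    best = report.sort_values(["Rp2", "RPDp"], ascending=False).index[0]
    report["best"] = False
    report.loc[best, "best"] = True
    return report, results


def coefficient_profile(
    model: PLSModel,
    wavelengths: np.ndarray,
    percentile: float = 90.0,
) -> pd.DataFrame:
    """Contiguous high-|coefficient| wavelength regions of a calibration model.

    Regions are maximal runs of wavelengths whose |regression coefficient|
    exceeds the given percentile of the profile, reported with nm bounds and
    ranked by their peak coefficient magnitude.
    """
    profile = np.abs(model.coef_)
    if np.ptp(profile) == 0:
        return pd.DataFrame(columns=["start_nm", "end_nm", "peak_nm", "peak_abs_coef"])
    threshold = np.percentile(profile, percentile)
    above = profile >= threshold if percentile == 0 else profile > threshold
    rows = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            rows.append((start, i - 1))
            start = None
    if start is not None:
        rows.append((start, above.size - 1))
    out = []
    for lo, hi in rows:
        seg = profile[lo : hi + 1]
        peak = lo + int(np.argmax(seg))
        out.append(
            {
                "start_nm": float(wavelengths[lo]),
                "end_nm": float(wavelengths[hi]),
                "peak_nm": float(wavelengths[peak]),
                "peak_abs_coef": float(profile[peak]),
            }
        )
    frame = pd.DataFrame(out).sort_values("peak_abs_coef", ascending=False, ignore_index=True)
    return frame


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationReport:
    n_iter: int
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    corr_abs: np.ndarray
    original_r2: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float
    passed: bool
    threshold: float = 0.05


def _line_intercept(corr: np.ndarray, metric: np.ndarray) -> float:
    slope, intercept = np.polyfit(corr, metric, 1)
    return float(intercept)


def permutation_test(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_lv: int,
    n_iter: int = 200,
    cv_k: int = 5,
    seed: int = 0,
    scale_x: bool = False,
    stratify=None,
    threshold: float = 0.05,
) -> PermutationReport:
    """Response-permutation validation of a fixed PLSR configuration.

    The preprocessing and LV count are frozen before permuting. Each
    iteration shuffles y, refits at the same LV count, and records training
    R2, pooled cv_k-fold cross-validated Q2, and |corr(y_perm, y)|. Straight
    lines of R2 and Q2 against the correlation (including the unpermuted
    model at correlation 1) give the reported intercepts at correlation 0;
    the model passes when the Q2 intercept is below the threshold.
    """
    import warnings

    if n_iter < 20:
        warnings.warn("fewer than 20 permutations: intercept estimate is unstable", stacklevel=2)
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    y = np.asarray(y_train, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    folds = _cv_folds(y.size, cv_k, seed, stratify)

    def _q2(y_vec: np.ndarray) -> float:
        preds = cv_predictions(X, y_vec, [n_lv], folds, scale_x=scale_x)[n_lv]
        resid = y_vec - preds
        return 1.0 - float(resid @ resid) / float(np.sum((y_vec - y_vec.mean()) ** 2))

    def _r2_train(y_vec: np.ndarray) -> float:
        model = fit_pls1(X, y_vec, min(n_lv, y_vec.size - 1), scale_x=scale_x)
        resid = y_vec - model.predict(X)
        return 1.0 - float(resid @ resid) / float(np.sum((y_vec - y_vec.mean()) ** 2))

    original_r2 = _r2_train(y)
    original_q2 = _q2(y)

    sd_y = y.std()
    r2_perm = np.empty(n_iter)
    q2_perm = np.empty(n_iter)
    corr_abs = np.empty(n_iter)
    for i in range(n_iter):
        y_p = rng.permutation(y)
        corr_abs[i] = abs(float(np.corrcoef(y_p, y)[0, 1])) if sd_y > 0 else 0.0
        r2_perm[i] = _r2_train(y_p)
        q2_perm[i] = _q2(y_p)

    corr_all = np.concatenate([corr_abs, [1.0]])
    r2_intercept = _line_intercept(corr_all, np.concatenate([r2_perm, [original_r2]]))
    q2_intercept = _line_intercept(corr_all, np.concatenate([q2_perm, [original_q2]]))
    return PermutationReport(
        n_iter, r2_perm, q2_perm, corr_abs, original_r2, original_q2,
        r2_intercept, q2_intercept, bool(q2_intercept < threshold), threshold,
    )
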