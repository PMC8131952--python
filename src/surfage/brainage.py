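"""PCA-feature brain-age prediction, overfitting-bias, and delta-age estimation.

Age is predicted from the top principal components of the thickness features
with ordinary least squares, under repeated k-fold cross-validation. The
in-sample counterpart (adjusted R^2 of age on the first k PCs fit to the full
sample) minus the cross-validated r^2 quantifies overfitting bias. Delta age
comes in two forms: delta1 = predicted - chronological age, and delta2 =
delta1 with chronological age regressed out (the orthogonalized residual),
which by OLS construction has exactly zero mean and zero correlation with
age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionResult",
    "DeltaEstimates",
    "pca_scores",
    "cv_predict_age",
    "prediction_metrics",
    "adjusted_r2",
    "fit_linear_age_model",
    "delta1",
    "delta2",
    "delta_condition_correlations",
]


@dataclass
class PredictionResult:
    """Cross-validated prediction metrics per number of components k.

    ``metrics`` has one row per k with columns rmse, mae, corr, cv_r2,
    adj_r2, overfit_bias (each averaged over repetitions).
    ``predicted`` holds pooled cross-validated predictions, shape
    (repetitions, n_k, n_subjects).
    """

    condition: str
    ks: np.ndarray
    metrics: pd.DataFrame
    folds: int
    repetitions: int
    seed: int
    predicted: np.ndarray
    subject_ids: np.ndarray | None = None

    def mean_predicted(self, k: int) -> np.ndarray:
        """Per-subject prediction at k, averaged over repetitions."""
        ik = int(np.where(self.ks == k)[0][0])
        return self.predicted[:, ik, :].mean(axis=0)

    @property
    def best_k(self) -> int:
        """k minimizing cross-validated RMSE."""
        return int(self.metrics["rmse"].idxmin())


@dataclass
class DeltaEstimates:
    """Per-subject delta-age estimates for one condition at a given k."""

    delta1: np.ndarray
    delta2: np.ndarray
    condition: str = ""
    k: int = 0
    subject_ids: np.ndarray | None = None


def pca_scores(
    features: np.ndarray, k: int, fit_rows: np.ndarray | None = None
) -> np.ndarray:
    """Top-k principal component scores, fit on a subject subset.

    Centering and axes come from ``fit_rows`` (all rows when None) and are
    applied to every row, so held-out subjects are projected onto axes they
    did not influence. Component sign is fixed by making each component's
    largest-magnitude loading positive.
    """
    X = np.asarray(features, dtype=np.float64)
    rows = np.arange(X.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    n_fit = rows.size
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > min(n_fit - 1, X.shape[1]):
        raise ValueError(
            f"k={k} exceeds the rank bound min(n_fit-1, units)="
            f"{min(n_fit - 1, X.shape[1])}"
        )
    if k == 0:
        return np.empty((X.shape[0], 0))
    center = X[rows].mean(axis=0)
    _, _, vt = np.linalg.svd(X[rows] - center, full_matrices=False)
    comps = vt[:k]
    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    return (X - center) @ comps.T


def fit_linear_age_model(
    scores: np.ndarray, ages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of age on (intercept, scores): returns (coef, fitted, residuals)."""
    n = ages.size
    X = np.column_stack([np.ones(n), scores])
    coef, *_ = np.linalg.lstsq(X, ages, rcond=None)
    fitted = X @ coef
    return coef, fitted, ages - fitted


def prediction_metrics(predicted: np.ndarray, ages: np.ndarray) -> dict:
    """RMSE, MAE (years) and Pearson correlation of predicted vs true age.

    Correlation is NaN (flagged undefined) for constant predictions.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if predicted.shape != ages.shape:
        raise ValueError("predicted and ages must have equal length")
    err = predicted - ages
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(predicted) == 0 or np.ptp(ages) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(predicted, ages)[0, 1])
    return {"rmse": rmse, "mae": mae, "corr": corr}


def adjusted_r2(features_k: np.ndarray, ages: np.ndarray) -> float:
    """In-sample adjusted R^2 of age on (intercept, k features).

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1); k = 0 (intercept only)
    returns 0 by convention.
    """
    X = np.asarray(features_k, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if k == 0:
        return 0.0
    if n <= k + 1:
        raise ValueError("need n > k + 1 subjects")
    _, fitted, resid = fit_linear_age_model(X, ages)
    ss_res = float((resid**2).sum())
    ss_tot = float(((ages - ages.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _fold_indices(
    n: int, folds: int, rng: np.random.Generator, subject_ids: np.ndarray | None
) -> list[np.ndarray]:
    """Seeded fold partition, stable under subject reordering.

    The permutation is drawn over the canonical (sorted-id) subject order, so
    permuting the rows of the input (with their ids) yields the same folds.
    """
    if subject_ids is not None:
        canonical = np.argsort(np.asarray(subject_ids), kind="stable")
    else:
        canonical = np.arange(n)
    perm = canonical[rng.permutation(n)]
    return [np.sort(f) for f in np.array_split(perm, folds)]


def cv_predict_age(
    features: np.ndarray,
    ages: np.ndarray,
    ks,
    folds: int = 10,
    repetitions: int = 5,
    seed: int = 0,
    pca_policy: str = "global",
    subject_ids: np.ndarray | None = None,
    condition: str = "",
) -> PredictionResult:
    """Repeated k-fold cross-validated age prediction from PCA features.

    For each repetition, subjects are partitioned into ``folds`` seeded folds;
    within each fold an OLS model with intercept on the first k PC scores is
    fit on the training subjects and the held-out subjects are predicted.
    Metrics are computed on the pooled predictions of each repetition and
    averaged.

    ``pca_policy`` controls where the PC basis comes from: ``'global'``
    (default) fits PCA once on all subjects, so cross-validation measures
    the regression's generalization for a fixed feature basis — the setting
    in which overfitting bias grows monotonically with k; ``'within_fold'``
    refits PCA on each training set, which also guards against the (weak)
    basis-estimation leakage but makes the feature set fold-dependent, so
    the bias statistic no longer isolates regression overfitting.

    The in-sample column adj_r2 uses a whole-sample PCA at each k;
    overfit_bias = adj_r2 - cv_r2 where cv_r2 is the squared correlation of
    the pooled cross-validated predictions with age.
    """
    X = np.asarray(features, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    n = ages.size
    if np.isscalar(ks):
        ks = [int(ks)]
    ks = np.array(sorted(int(k) for k in ks))
    if folds < 2 or n < folds:
        raise ValueError("need folds >= 2 and n >= folds")
    if pca_policy not in ("within_fold", "global"):
        raise ValueError("pca_policy must be 'within_fold' or 'global'")
    kmax = int(ks.max())
    min_train = n - int(np.ceil(n / folds))
    if kmax > min(min_train - 1, X.shape[1]):
        raise ValueError(f"k={kmax} exceeds the training-fold rank bound")

    predicted = np.empty((repetitions, ks.size, n))
    rows = []
    for rep in range(repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        fold_sets = _fold_indices(n, folds, rng, subject_ids)
        if pca_policy == "global":
            scores_all = pca_scores(X, kmax)
        for test in fold_sets:
            train = np.setdiff1d(np.arange(n), test)
            if pca_policy == "within_fold":
                scores = pca_scores(X, kmax, fit_rows=train)
            else:
                scores = scores_all
            for ik, k in enumerate(ks):
                coef, _, _ = fit_linear_age_model(scores[train, :k], ages[train])
                Xt = np.column_stack([np.ones(test.size), scores[test, :k]])
                predicted[rep, ik, test] = Xt @ coef
        for ik, k in enumerate(ks):
            m = prediction_metrics(predicted[rep, ik], ages)
            rows.append({"rep": rep, "k": int(k), **m})

    per_rep = pd.DataFrame(rows)
    metrics = per_rep.groupby("k")[["rmse", "mae", "corr"]].mean()
    metrics["cv_r2"] = per_rep.assign(r2=per_rep["corr"] ** 2).groupby("k")["r2"].mean()
    global_scores = pca_scores(X, kmax)
    metrics["adj_r2"] = [
        adjusted_r2(global_scores[:, :k], ages) for k in metrics.index
    ]
    metrics["overfit_bias"] = metrics["adj_r2"] - metrics["cv_r2"]
    return PredictionResult(
        condition=condition,
        ks=ks,
        metrics=metrics,
        folds=folds,
        repetitions=repetitions,
        seed=seed,
        predicted=predicted,
        subject_ids=subject_ids,
    )


def delta1(predicted: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """delta1 = predicted age minus chronological age, per subject."""
    predicted = np.asarray(predicted, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if predicted.shape != ages.shape:
        raise ValueError("predicted and ages must have equal length")
    return predicted - ages


def delta2(d1: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """delta1 orthogonalized against chronological age (OLS with intercept).

    The result has zero mean and zero correlation with age to machine
    precision.
    """
    d1 = np.asarray(d1, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if d1.shape != ages.shape:
        raise ValueError("delta1 and ages must have equal length")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; orthogonalization is undefined")
    X = np.column_stack([np.ones(ages.size), ages])
    coef, *_ = np.linalg.lstsq(X, d1, rcond=None)
    return d1 - X @ coef


def delta_condition_correlations(deltas: dict) -> pd.DataFrame:
    """Pearson correlation matrix of per-subject delta vectors across conditions."""
    names = list(deltas)
    lengths = {np.asarray(v).size for v in deltas.values()}
    if len(lengths) != 1:
        raise ValueError("all conditions must share the subject set")
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = stats.pearsonr(deltas[a], deltas[names[j]]).statistic
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)
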