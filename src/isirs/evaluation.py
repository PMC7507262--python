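"""Cross-validated assessment, d-grid tuning, and feature-redundancy scores.

The evaluation protocol follows the pharmacogenomics convention: samples
(cell lines treated by one drug) are split into 10 roughly equal folds; for
each fold the whole pipeline — standardization, screening, selection, OLS —
is trained on the other nine folds only, and the held-out fold is predicted
with the training fold's standardization parameters.  Out-of-fold predictions
are averaged over repeats and summarised by the Pearson correlation (PCC)
with the observed response and by the mean squared error (MSE).  The target
model size d is tuned by grid search over {2, 4, ..., 50}, taking the d with
the largest cross-validated PCC (smallest d on ties).

Redundancy among a selected feature set is summarised by the mean redundancy
score (MRS): the mean over unordered feature pairs of either the absolute
Pearson correlation or the plug-in mutual information of equal-width-binned
columns (nats).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.metrics import mutual_info_score

from .datatypes import (
    CVReport,
    FeatureMatrix,
    ResponseVector,
    ValidationError,
    check_aligned,
)
from .selection import SelectionConfig, fit_ols, isirs_select, predict, sirs_select, stf_select
from .screening import compute_pcc_scores, rank_features

METHODS = ("isirs", "stf", "sirs", "pcc_screen")


def pcc(pred: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation between predictions and observed values."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValidationError("pcc requires two equal-length vectors")
    if pred.size < 3:
        raise ValidationError("pcc requires at least 3 samples")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        raise ValidationError("pcc undefined for a constant vector")
    return float(stats.pearsonr(pred, true).statistic)


def mse(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean squared error."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValidationError("mse requires equal-length vectors")
    return float(np.mean((pred - true) ** 2))


def skewness(values: np.ndarray) -> float:
    """Sample skewness m3 / m2^(3/2) with population (1/n) moments."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("skewness requires at least 3 values")
    if np.ptp(v) == 0:
        raise ValidationError("skewness undefined for a constant vector")
    return float(stats.skew(v, bias=True))


def _fold_labels(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into near-equal folds (sizes differ by <= 1)."""
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        labels[chunk] = f
    return labels


def _select_on_training(
    Xtr_std: FeatureMatrix,
    Ytr: ResponseVector,
    method: str,
    d: int,
    cfg: SelectionConfig,
) -> tuple[int, ...]:
    if method == "isirs":
        return isirs_select(Xtr_std, Ytr, d, cfg).final_set
    if method == "stf":
        return stf_select(Xtr_std, Ytr, d)
    if method == "sirs":
        return sirs_select(Xtr_std, Ytr, d, cfg)
    if method == "pcc_screen":
        return tuple(int(i) for i in rank_features(compute_pcc_scores(Xtr_std, Ytr), d))
    raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")


def cross_validate(
    X: FeatureMatrix,
    Y: ResponseVector,
    method: str,
    d: int,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    config: SelectionConfig | None = None,
) -> CVReport:
    """Repeated k-fold cross-validation of a screen-select-fit pipeline.

    Everything that can leak — the standardization center/scale, the
    screening scores, the selected set, the OLS coefficients — is computed on
    the training folds only.  Columns that happen to be constant within a
    training fold (possible for sparse binary mutation features) are dropped
    for that fold and noted in the report.  Held-out predictions are averaged
    across repeats before computing PCC and MSE.
    """
    check_aligned(X, Y)
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    n = X.n
    if n < 2 * folds:
        raise ValidationError(f"need n >= 2*folds (n={n}, folds={folds})")
    rng = np.random.default_rng(seed)
    preds = np.zeros((repeats, n))
    assignments = np.zeros((repeats, n), dtype=int)
    selected: list[list[tuple[int, ...]]] = []
    notes: list[str] = []

    for r in range(repeats):
        labels = _fold_labels(n, folds, rng)
        assignments[r] = labels
        sel_r: list[tuple[int, ...]] = []
        for f in range(folds):
            test_idx = np.flatnonzero(labels == f)
            train_idx = np.flatnonzero(labels != f)
            Xtr = X.select_samples(train_idx)
            Ytr = Y.select_samples(train_idx)

            # training-fold standardization, applied as-is to the test fold
            tr_vals = Xtr.values
            sd = np.sqrt(np.mean((tr_vals - tr_vals.mean(axis=0)) ** 2, axis=0))
            keep = np.flatnonzero(sd > 1e-12)
            if keep.size < X.p:
                notes.append(
                    f"repeat {r} fold {f}: dropped {X.p - keep.size} "
                    "constant-in-training columns"
                )
            if keep.size < d:
                raise ValidationError(
                    f"fewer than d={d} usable features in repeat {r} fold {f}"
                )
            center, scale = tr_vals[:, keep].mean(axis=0), sd[keep]
            Xtr_std = FeatureMatrix(
                (tr_vals[:, keep] - center) / scale,
                feature_ids=[X.feature_ids[i] for i in keep],
                sample_ids=list(Xtr.sample_ids),
                omics_type=[X.omics_type[i] for i in keep] if X.omics_type else None,
                standardized=True,
            )
            cfg = SelectionConfig(seed=int(rng.integers(2**31))) if config is None else config
            local = _select_on_training(Xtr_std, Ytr, method, d, cfg)
            sel_r.append(tuple(sorted(int(keep[j]) for j in local)))

            if not local:
                # nothing survived selection on this fold: intercept-only model
                notes.append(f"repeat {r} fold {f}: empty selection, predicting the mean")
                preds[r, test_idx] = Ytr.values.mean()
                continue
            model = fit_ols(Xtr_std, Ytr, list(local))
            Xte = X.select_samples(test_idx)
            Xte_std = FeatureMatrix(
                (Xte.values[:, keep] - center) / scale,
                feature_ids=[X.feature_ids[i] for i in keep],
                sample_ids=list(Xte.sample_ids),
                standardized=True,
            )
            preds[r, test_idx] = predict(model, Xte_std).values
        selected.append(sel_r)

    avg = preds.mean(axis=0)
    return CVReport(
        method=method,
        d=d,
        folds=folds,
        repeats=repeats,
        per_sample_prediction=avg,
        pcc=pcc(avg, Y.values),
        mse=mse(avg, Y.values),
        fold_assignments=assignments,
        seed=seed,
        selected_per_fold=selected,
        notes=notes,
    )


def select_d(
    X: FeatureMatrix,
    Y: ResponseVector,
    method: str = "isirs",
    grid: list[int] | None = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    config: SelectionConfig | None = None,
) -> tuple[int, list[dict]]:
    """Grid-search the model size d by cross-validated PCC.

    Default grid {2, 4, ..., 50}.  Returns ``(best_d, table)`` where the table
    has one row per grid point with its PCC and MSE; ties in PCC go to the
    smallest d (parsimony).
    """
    grid = list(range(2, 51, 2)) if grid is None else sorted(set(int(g) for g in grid))
    if not grid:
        raise ValidationError("empty d grid")
    if max(grid) >= X.n:
        raise ValidationError(f"max grid point {max(grid)} must be < n={X.n}")
    table = []
    for d in grid:
        rep = cross_validate(X, Y, method, d, folds=folds, repeats=repeats,
                             seed=seed, config=config)
        table.append({"d": d, "pcc": rep.pcc, "mse": rep.mse})
    best = max(table, key=lambda row: (row["pcc"], -row["d"]))
    return int(best["d"]), table


def mean_redundancy_pcc(X: FeatureMatrix) -> float:
    """Mean absolute Pearson correlation over unordered feature pairs."""
    if X.p < 2:
        raise ValidationError("redundancy requires at least 2 features")
    sd = X.values.std(axis=0)
    if np.any(sd == 0):
        bad = [X.feature_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant features have undefined correlation: {bad}")
    corr = np.corrcoef(X.values, rowvar=False)
    iu = np.triu_indices(X.p, k=1)
    return float(np.abs(corr[iu]).mean())


def pairwise_mi(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Plug-in mutual information (nats) from an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    return float(mutual_info_score(None, None, contingency=joint))


def mean_redundancy_mi(X: FeatureMatrix, bins: int = 10) -> float:
    """Mean pairwise mutual information over unordered feature pairs.

    Each column is discretized into ``bins`` equal-width bins over its own
    range; MI is the plug-in estimate from the joint histogram, in nats.  The
    plug-in estimator carries a small positive bias for independent columns.
    """
    if X.p < 2:
        raise ValidationError("redundancy requires at least 2 features")
    total = 0.0
    npairs = 0
    for i, j in combinations(range(X.p), 2):
        total += pairwise_mi(X.values[:, i], X.values[:, j], bins=bins)
        npairs += 1
    return total / npairs
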