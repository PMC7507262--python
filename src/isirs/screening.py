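"""Marginal feature screening.

The workhorse is the rank-based marginal utility statistic omega_k used by
sure independent ranking and screening (SIRS).  For a standardized feature
X_k and response Y observed on n samples,

    omega_hat_k = (1/n) sum_j { (1/n) sum_i X_ik * I(Y_i < Y_j) }^2 ,

a double sum over the strict rank indicator I(Y_i < Y_j).  The statistic is a
sample version of E{Omega_k(Y)^2} with Omega(y) = E{x P(Y < y | x)}: it is
large when the conditional distribution of Y shifts with X_k, depends on Y
only through its ranks (hence is robust to outliers and monotone response
transformations), and under the standardization convention is bounded in
[0, 1] by Cauchy-Schwarz.  Tied responses contribute zero to the indicator,
so heavily tied Y attenuates omega_hat.

An absolute-Pearson-correlation score is provided as the classical screening
baseline.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    FeatureMatrix,
    ResponseVector,
    ScreeningScores,
    ValidationError,
    check_aligned,
)

#: columns whose 1/n mean-square deviation falls below this are "constant"
_CONST_TOL = 1e-12


def standardization_params(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column center and scale under the 1/n (population) convention.

    Returns ``(center, scale)`` with ``scale = sqrt(mean((x - center)^2))``.
    Raises :class:`ValidationError` on any constant column.
    """
    center = values.mean(axis=0)
    scale = np.sqrt(np.mean((values - center) ** 2, axis=0))
    if np.any(scale <= _CONST_TOL):
        bad = np.flatnonzero(scale <= _CONST_TOL)
        raise ValidationError(f"constant columns at indices {bad.tolist()[:20]}")
    return center, scale


def standardize_features(X: FeatureMatrix) -> FeatureMatrix:
    """Scale every column to mean 0 and mean-square 1 (1/n convention).

    Returns a new matrix; the input is left untouched.  Constant columns are
    rejected with an error naming the offending features (a zero scale is
    undefined; callers that prefer to drop such columns must do so upstream).
    """
    if X.n < 2:
        raise ValidationError("standardization requires at least 2 samples")
    try:
        center, scale = standardization_params(X.values)
    except ValidationError:
        bad_scale = np.sqrt(np.mean((X.values - X.values.mean(axis=0)) ** 2, axis=0))
        names = [X.feature_ids[i] for i in np.flatnonzero(bad_scale <= _CONST_TOL)]
        raise ValidationError(
            f"cannot standardize constant features: {names[:20]}"
        ) from None
    return FeatureMatrix(
        values=(X.values - center) / scale,
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
        omics_type=list(X.omics_type) if X.omics_type else None,
        standardized=True,
    )


def _require_standardized(X: FeatureMatrix) -> None:
    if not X.standardized:
        raise ValidationError("feature matrix must be standardized first")


def _ranks_from_omega(omega: np.ndarray) -> np.ndarray:
    # stable argsort on -omega: ties resolved by ascending feature index
    order = np.argsort(-omega, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, omega.shape[0] + 1)
    return rank


def compute_omega(X: FeatureMatrix, Y: ResponseVector) -> ScreeningScores:
    """SIRS marginal utility omega_hat_k for every feature.

    Vectorized evaluation of the double sum: with the indicator matrix
    ``M[i, j] = I(Y_i < Y_j)``, the inner sums are the columns of
    ``(1/n) X^T M`` and omega_hat is the row-wise mean of their squares.
    The i = j diagonal is included (it contributes zero under the strict
    inequality), and a constant Y yields omega_hat = 0 for every feature.
    """
    _require_standardized(X)
    check_aligned(X, Y)
    if X.n < 2:
        raise ValidationError("omega requires at least 2 samples")
    n = X.n
    y = Y.values
    indicator = (y[:, None] < y[None, :]).astype(float)  # I(Y_i < Y_j)
    inner = (X.values.T @ indicator) / n  # (p, n): inner[k, j]
    omega = np.einsum("kj,kj->k", inner, inner) / n
    return ScreeningScores(omega=omega, rank=_ranks_from_omega(omega), method="sirs")


def compute_pcc_scores(X: FeatureMatrix, Y: ResponseVector) -> ScreeningScores:
    """Absolute Pearson correlation of each feature with Y (baseline screen).

    The absolute value is taken deliberately: screening cares about the
    strength of the marginal association, not its sign.
    """
    _require_standardized(X)
    check_aligned(X, Y)
    yc = Y.values - Y.values.mean()
    sy = np.sqrt(np.mean(yc**2))
    if sy <= _CONST_TOL:
        raise ValidationError("response is constant; Pearson correlation undefined")
    # columns have mean 0, mean-square 1, so corr_k = (1/n) sum_i X_ik * y~_i
    corr = (X.values.T @ (yc / sy)) / X.n
    omega = np.abs(corr)
    return ScreeningScores(omega=omega, rank=_ranks_from_omega(omega), method="pcc")


def rank_features(scores: ScreeningScores, top_k: int) -> np.ndarray:
    """Indices of the ``top_k`` features by descending score.

    Ties are broken by ascending feature index, so the result is deterministic
    across platforms.
    """
    p = scores.omega.shape[0]
    if not 1 <= top_k <= p:
        raise ValidationError(f"top_k must be in [1, {p}], got {top_k}")
    return scores.order[:top_k].copy()
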