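"""Core in-memory containers shared across the package.

The containers are thin, validated wrappers around numpy arrays.  A
:class:`FeatureMatrix` holds a samples x features block of numeric predictors
(gene expression, mutation status, copy-number status, ...); a
:class:`ResponseVector` holds the per-sample scalar drug response (activity
area) or a residual pseudo-response during iterative selection.  Results of
screening, selection, model fitting, cross-validation and redundancy scoring
each get a small dataclass of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_OMICS = ("expression", "mutation", "copy_number")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class NumericalError(RuntimeError):
    """Raised when a computation fails for numerical reasons (rank deficiency...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class FeatureMatrix:
    """n x p numeric predictor matrix with feature/sample metadata.

    Parameters
    ----------
    values
        Array of shape ``(n, p)``; must be finite (impute or reject missing
        values at the I/O boundary, never here).
    feature_ids, sample_ids
        Unique names for the p columns and n rows.
    omics_type
        Optional per-feature label in ``{expression, mutation, copy_number}``.
    standardized
        True once every column has mean 0 and mean-square 1 under the 1/n
        convention (see :func:`isirs.screening.standardize_features`).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    omics_type: list[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        n, p = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != p:
            raise ValidationError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if self.omics_type is not None:
            if len(self.omics_type) != p:
                raise ValidationError("omics_type length must equal number of features")
            bad_types = sorted(set(self.omics_type) - set(VALID_OMICS))
            if bad_types:
                raise ValidationError(f"unknown omics types: {bad_types}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def select_features(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Column subset (0-based indices), preserving metadata and order given."""
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            omics_type=[self.omics_type[i] for i in idx] if self.omics_type else None,
            standardized=self.standardized,
        )

    def select_samples(self, indices: Sequence[int]) -> "FeatureMatrix":
        """Row subset.  Standardization does not survive subsetting."""
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[idx, :],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            omics_type=list(self.omics_type) if self.omics_type else None,
            standardized=False,
        )


@dataclass
class ResponseVector:
    """Per-sample drug response (or residual pseudo-response)."""

    values: np.ndarray
    sample_ids: list[str]
    label: str = "response"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids length must equal number of values")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            i = int(np.argwhere(~np.isfinite(self.values))[0][0])
            raise ValidationError(f"non-finite response for sample {self.sample_ids[i]!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def select_samples(self, indices: Sequence[int]) -> "ResponseVector":
        idx = list(indices)
        return ResponseVector(self.values[idx], [self.sample_ids[i] for i in idx], self.label)


def check_aligned(X: FeatureMatrix, Y: ResponseVector) -> None:
    if X.sample_ids != Y.sample_ids:
        raise ValidationError(
            "feature matrix and response are not aligned: sample ids differ "
            f"(first mismatch at position "
            f"{next((i for i, (a, b) in enumerate(zip(X.sample_ids, Y.sample_ids)) if a != b), min(X.n, Y.n))})"
        )


@dataclass
class ScreeningScores:
    """Per-feature marginal utility scores and the induced ranking.

    ``omega[k]`` is the screening score of feature k; ``rank[k]`` is its
    1-based rank (1 = largest score, ties broken by ascending feature index).
    """

    omega: np.ndarray
    rank: np.ndarray
    method: str  # {"sirs", "pcc"}

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.rank = np.asarray(self.rank, dtype=int)

    @property
    def order(self) -> np.ndarray:
        """Feature indices sorted by descending omega (stable in index)."""
        return np.argsort(self.rank, kind="stable")


@dataclass
class LassoFit:
    """Solution of the L1-penalized least-squares problem.

    Minimizes sum_i (Y_i - b0 - sum_k b_k X_ik)^2 + lam * sum_k |b_k| with an
    unpenalized intercept.  ``coefficients`` maps feature index -> nonzero
    coefficient; zeroed features are absent.
    """

    intercept: float
    coefficients: dict[int, float]
    lam: float
    objective: float

    @property
    def retained(self) -> list[int]:
        """Indices with nonzero coefficients, ascending."""
        return sorted(self.coefficients)


@dataclass
class IterationRecord:
    """One screen-then-select pass of the iterative procedure."""

    screened: tuple[int, ...]  # A_s, freshly screened candidates
    retained: tuple[int, ...]  # M_s, lasso-retained working set
    residual_norm: float


@dataclass
class SelectionTrace:
    """Full record of an iterative selection run."""

    d: int
    k1: int
    iterations: list[IterationRecord]
    final_set: tuple[int, ...]
    stop_reason: str  # {"reached_d", "size_unchanged", "max_iter"}
    events: list[str] = field(default_factory=list)


@dataclass
class OLSModel:
    """Ordinary-least-squares fit with per-coefficient t-tests.

    All per-feature maps are keyed by the original feature index.  When the
    residual variance is exactly zero the t-tests are undefined:
    ``tests_defined`` is False and std errors / t / p are NaN, while the
    coefficients remain valid.
    """

    features: tuple[int, ...]
    intercept: float
    coefficients: dict[int, float]
    std_errors: dict[int, float]
    t_stats: dict[int, float]
    p_values: dict[int, float]
    significant_at_001: frozenset[int]
    residuals: np.ndarray
    r_squared: float
    tests_defined: bool = True
    alpha: float = 0.01
    # standardization parameters of the training data, needed to transform
    # new samples before prediction (None when fit on raw data)
    train_center: np.ndarray | None = None
    train_scale: np.ndarray | None = None


@dataclass
class CVReport:
    """Cross-validated out-of-fold predictions and their summary metrics."""

    method: str
    d: int
    folds: int
    repeats: int
    per_sample_prediction: np.ndarray
    pcc: float
    mse: float
    fold_assignments: np.ndarray  # (repeats, n) fold label per sample
    seed: int
    selected_per_fold: list[list[tuple[int, ...]]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class RedundancyReport:
    """Mean pairwise association among a set of selected features."""

    mrs_pcc: float
    mrs_mi: float
    n_features: int
    bins: int


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    active_set: tuple[int, ...]
    beta: dict[int, float]
    sigma: float
    hidden: tuple[int, ...] = ()
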