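"""Feature selection: the ISIRS iteration, lasso refinement, and final OLS.

ISIRS interleaves marginal screening with joint selection so that features
whose marginal association with the response is weak — but which matter
jointly with others — can still be recruited:

1. screen the full feature set by the SIRS utility omega_hat and keep the top
   K1 = floor(2d/3) as A1 (K1 < d on purpose, so the procedure cannot stop at
   the first pass);
2. run a lasso on A1 against the response; the nonzero coefficients form the
   working set M1;
3. refit M1 by unpenalized linear regression and take the residuals as a new
   pseudo-response;
4. re-screen the remaining features {1..p} \\ M1 on those residuals, keeping
   the top d - |M1| as A2, and lasso the union A2 ∪ M1 against the ORIGINAL
   response to get M2 (residuals steer the screening only, never the fit);
5. repeat until |M_s| = d, the working-set size stops changing, or an
   iteration cap is hit.

The final model is an ordinary-least-squares fit on the selected features,
with a two-sided t-test per coefficient (equivalently a nested-model test of
dropping that feature), significant at alpha = 0.01 by default.

Baselines: STF ("simple top features", the top-d features by omega_hat with
no iteration) and a single-pass SIRS variant (one screen, one lasso refit,
padded back to d by omega_hat rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .datatypes import (
    FeatureMatrix,
    IterationRecord,
    LassoFit,
    NumericalError,
    OLSModel,
    ResponseVector,
    SelectionTrace,
    ValidationError,
    check_aligned,
)
from .screening import compute_omega, rank_features, standardize_features


@dataclass
class SelectionConfig:
    """Tunables of the iterative selection.

    lambda_policy
        ``{"cv": k}`` picks the lasso penalty by k-fold cross-validation on
        the training data over a 100-point log-spaced path from the smallest
        all-zero penalty down to 1e-3 of it (the default, k=5);
        ``{"fixed": lam}`` uses the given penalty on the package's own scale
        (the raw sum-of-squares objective, see :func:`run_lasso`).
    k1
        Size of the initial screened set; defaults to floor(2d/3).
    max_iterations
        Hard safety cap on screen/select passes.
    seed
        Seeds the internal CV splits of the lasso penalty search.
    """

    lambda_policy: dict | None = None
    k1: int | None = None
    max_iterations: int = 50
    seed: int = 0


def _lasso_objective(
    y: np.ndarray, Xc: np.ndarray, intercept: float, beta: np.ndarray, lam: float
) -> float:
    resid = y - intercept - Xc @ beta
    return float(resid @ resid + lam * np.abs(beta).sum())


def run_lasso(
    X: FeatureMatrix,
    Y: ResponseVector,
    lambda_policy: dict | None = None,
    candidates: np.ndarray | list[int] | None = None,
    seed: int = 0,
) -> LassoFit:
    """L1-penalized least squares on a candidate feature set.

    Minimizes ``sum_i (Y_i - b0 - sum_k b_k X_ik)^2 + lam * sum_k |b_k|``
    with an unpenalized intercept.  The penalty lam lives on this raw
    objective's scale; it maps onto scikit-learn's per-sample parametrisation
    as ``alpha = lam / (2n)``.  ``candidates`` (0-based column indices,
    default all) keys the returned coefficient map; features shrunk exactly
    to zero are dropped from it.
    """
    check_aligned(X, Y)
    if X.n < 3:
        raise ValidationError("lasso requires at least 3 samples")
    cand = np.arange(X.p) if candidates is None else np.asarray(list(candidates), dtype=int)
    if cand.size == 0:
        raise ValidationError("empty candidate set")
    policy = {"cv": 5} if lambda_policy is None else dict(lambda_policy)
    Xc = X.values[:, cand]
    y = Y.values
    n = X.n

    if "fixed" in policy:
        lam = float(policy["fixed"])
        if lam < 0:
            raise ValidationError(f"lambda must be nonnegative, got {lam}")
        if lam == 0.0:
            # plain least squares; coordinate descent is ill-posed at alpha=0
            A = np.column_stack([np.ones(n), Xc])
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            intercept, beta = float(sol[0]), sol[1:]
        else:
            est = Lasso(alpha=lam / (2 * n), fit_intercept=True, max_iter=100_000, tol=1e-10)
            est.fit(Xc, y)
            intercept, beta = float(est.intercept_), est.coef_.copy()
    elif "cv" in policy:
        k = int(policy["cv"])
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        est = LassoCV(
            alphas=100, eps=1e-3, cv=splitter, fit_intercept=True,
            max_iter=100_000, tol=1e-8,
        )
        est.fit(Xc, y)
        intercept, beta = float(est.intercept_), est.coef_.copy()
        lam = float(est.alpha_ * 2 * n)
    else:
        raise ValidationError(f"unknown lambda policy {policy!r}")

    coef = {int(cand[j]): float(beta[j]) for j in np.flatnonzero(beta != 0.0)}
    return LassoFit(
        intercept=intercept,
        coefficients=coef,
        lam=lam,
        objective=_lasso_objective(y, Xc, intercept, beta, lam),
    )


def _collinear_features(A: np.ndarray, features: list[int]) -> list[int]:
    # QR with column pivoting: columns whose R diagonal collapses are the
    # dependent ones (first column of A is the intercept, excluded from blame)
    _, r, piv = sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    dependent = [piv[i] for i in range(len(diag)) if diag[i] <= tol]
    dependent += list(piv[len(diag):])
    return sorted(features[j - 1] for j in dependent if j >= 1)


def fit_ols(
    X: FeatureMatrix,
    Y: ResponseVector,
    features: np.ndarray | list[int] | None = None,
    alpha: float = 0.01,
) -> OLSModel:
    """OLS with intercept on a feature subset, plus per-coefficient t-tests.

    The two-sided test of H0: beta_j = 0 uses n - q - 1 residual degrees of
    freedom (q selected features); it is the nested-model comparison of the
    fit with and without feature j.  ``significant_at_001`` collects the
    features with p < alpha.  A rank-deficient design is an error naming the
    collinear features; an exactly-interpolating fit returns coefficients
    with the tests flagged undefined.
    """
    check_aligned(X, Y)
    feats = list(range(X.p)) if features is None else [int(f) for f in features]
    if len(feats) == 0:
        raise ValidationError("cannot fit OLS on an empty feature set")
    q = len(feats)
    if q >= X.n - 1:
        raise ValidationError(f"need |features| < n - 1 (got q={q}, n={X.n})")
    Xs = X.values[:, feats]
    A = sm.add_constant(Xs, has_constant="add")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        bad = _collinear_features(A, feats)
        raise NumericalError(f"rank-deficient design; collinear features: {bad}")
    res = sm.OLS(Y.values, A).fit()
    coefs = dict(zip(feats, (float(c) for c in res.params[1:])))
    tests_defined = bool(res.ssr > 1e-12 * max(1.0, float(Y.values @ Y.values)))
    if tests_defined:
        ses = dict(zip(feats, (float(s) for s in res.bse[1:])))
        ts = dict(zip(feats, (float(t) for t in res.tvalues[1:])))
        ps = dict(zip(feats, (float(p) for p in res.pvalues[1:])))
        sig = frozenset(f for f in feats if ps[f] < alpha)
    else:
        nan = float("nan")
        ses = {f: nan for f in feats}
        ts = {f: nan for f in feats}
        ps = {f: nan for f in feats}
        sig = frozenset()
    return OLSModel(
        features=tuple(feats),
        intercept=float(res.params[0]),
        coefficients=coefs,
        std_errors=ses,
        t_stats=ts,
        p_values=ps,
        significant_at_001=sig,
        residuals=np.asarray(res.resid, dtype=float),
        r_squared=float(res.rsquared),
        tests_defined=tests_defined,
        alpha=alpha,
    )


def predict(model: OLSModel, X_new: FeatureMatrix) -> ResponseVector:
    """yhat = intercept + sum_k beta_k * x_k for each row of ``X_new``.

    ``X_new`` must already be on the model's feature scale, i.e. transformed
    with the TRAINING standardization parameters (see
    :func:`isirs.evaluation.cross_validate` for the leakage-free recipe).
    """
    if model.features and max(model.features) >= X_new.p:
        raise ValidationError(
            f"model uses feature index {max(model.features)} but X_new has only "
            f"{X_new.p} columns"
        )
    beta = np.array([model.coefficients[f] for f in model.features])
    yhat = model.intercept + X_new.values[:, list(model.features)] @ beta
    return ResponseVector(yhat, list(X_new.sample_ids), label="prediction")


def _ols_residuals(X: FeatureMatrix, Y: ResponseVector, feats: list[int]) -> np.ndarray:
    model = fit_ols(X, Y, feats)
    return model.residuals


def isirs_select(
    X: FeatureMatrix,
    Y: ResponseVector,
    d: int,
    config: SelectionConfig | None = None,
) -> SelectionTrace:
    """Iterative SIRS selection of at most ``d`` features (see module docs).

    The stopping rule compares working-set SIZES between consecutive passes
    (|M_s| = d or |M_s| = |M_{s-1}|), exactly as stated for the procedure; the
    membership may in principle still churn at constant size, which the rule
    ignores.  A hard cap (config.max_iterations) guards pathological cases.
    An empty lasso selection is recorded in ``events``: screening then falls
    back to the centered response, and two empty passes in a row stop the run.
    """
    cfg = config or SelectionConfig()
    if d < 2:
        raise ValidationError(f"d must be >= 2, got {d}")
    if d > X.p:
        raise ValidationError(f"d={d} exceeds the number of features p={X.p}")
    if not X.standardized:
        X = standardize_features(X)
    check_aligned(X, Y)
    k1 = cfg.k1 if cfg.k1 is not None else (2 * d) // 3
    k1 = max(1, min(k1, X.p))

    events: list[str] = []
    iterations: list[IterationRecord] = []
    all_idx = np.arange(X.p)

    scores = compute_omega(X, Y)
    screened = rank_features(scores, k1)
    fit = run_lasso(X, Y, cfg.lambda_policy, candidates=screened, seed=cfg.seed)
    current: list[int] = fit.retained

    stop_reason = "max_iter"
    prev_size: int | None = None
    prev_empty = False
    for _ in range(cfg.max_iterations):
        # residuals of the unpenalized refit on the current working set
        if current:
            resid = _ols_residuals(X, Y, current)
            prev_empty = False
        else:
            events.append("lasso retained no features; residuals fall back to centered Y")
            resid = Y.values - Y.values.mean()
            if prev_empty:
                stop_reason = "size_unchanged"
                iterations.append(
                    IterationRecord(tuple(screened), tuple(current), float(np.linalg.norm(resid)))
                )
                break
            prev_empty = True
        iterations.append(
            IterationRecord(tuple(screened), tuple(current), float(np.linalg.norm(resid)))
        )
        if len(current) == d:
            stop_reason = "reached_d"
            break
        if prev_size is not None and len(current) == prev_size:
            stop_reason = "size_unchanged"
            break
        prev_size = len(current)

        # screen the residuals among features outside the working set
        remaining = np.setdiff1d(all_idx, current, assume_unique=False)
        if remaining.size == 0:
            stop_reason = "reached_d"
            break
        r_resp = ResponseVector(resid, list(Y.sample_ids), label="residual")
        r_scores = compute_omega(X.select_features(remaining), r_resp)
        k_s = min(d - len(current), remaining.size)
        screened = remaining[rank_features(r_scores, k_s)]
        pool = np.concatenate([screened, np.asarray(current, dtype=int)])
        fit = run_lasso(X, Y, cfg.lambda_policy, candidates=pool, seed=cfg.seed)
        current = fit.retained

    return SelectionTrace(
        d=d,
        k1=k1,
        iterations=iterations,
        final_set=tuple(sorted(current)),
        stop_reason=stop_reason,
        events=events,
    )


def stf_select(X: FeatureMatrix, Y: ResponseVector, d: int) -> tuple[int, ...]:
    """Simple top features: the d largest omega_hat, no iteration."""
    if d > X.p:
        raise ValidationError(f"d={d} exceeds the number of features p={X.p}")
    if not X.standardized:
        X = standardize_features(X)
    return tuple(int(i) for i in rank_features(compute_omega(X, Y), d))


def sirs_select(
    X: FeatureMatrix,
    Y: ResponseVector,
    d: int,
    config: SelectionConfig | None = None,
    screen_size: int | None = None,
) -> tuple[int, ...]:
    """Single-pass SIRS comparator: one screen, one lasso refit.

    Screens the top ``screen_size`` features by omega_hat (default d), keeps
    the lasso-retained subset, and pads back up to d with the best-ranked
    screened features that the lasso dropped.  The result is always a subset
    of the screened set.  This is a deliberately non-iterative stand-in; the
    original residual-of-features iteration is out of scope.
    """
    cfg = config or SelectionConfig()
    if d > X.p:
        raise ValidationError(f"d={d} exceeds the number of features p={X.p}")
    if not X.standardized:
        X = standardize_features(X)
    k = min(screen_size if screen_size is not None else d, X.p)
    screened = rank_features(compute_omega(X, Y), k)
    fit = run_lasso(X, Y, cfg.lambda_policy, candidates=screened, seed=cfg.seed)
    kept = [i for i in screened if i in fit.coefficients]  # omega order
    padded = kept + [i for i in screened if i not in fit.coefficients]
    return tuple(sorted(int(i) for i in padded[:d]))
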