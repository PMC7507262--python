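"""Synthetic data generators for the statistical scenarios the method targets.

Three generators:

``generate_linear``
    sparse linear signal, Y = sum_{k in active} beta_k X_k + eps, with an iid
    or equicorrelated Gaussian design — the textbook sure-screening setting.

``generate_hidden_predictor``
    the adversarial scenario iterative screening exists for: feature X4 is
    built to be exactly uncorrelated with Y marginally while being jointly
    essential.  With latent iid Z_1..Z_p ~ N(0,1),

        X_j = Z_j                                   (j != 4)
        X_4 = sqrt(rho) (Z_1+Z_2+Z_3)/sqrt(3) + sqrt(1-rho) Z_4
        Y   = beta (X_1+X_2+X_3) - beta sqrt(3 rho) X_4 + eps ,

    so cov(X_4, Y) = beta sqrt(3 rho) - beta sqrt(3 rho) = 0 by the
    coefficient choice, yet conditional on X_1..X_3 the response still loads
    on X_4: a marginal screen cannot see X_4, a screen of the residuals after
    regressing out X_1..X_3 can.

``generate_multiomics_like``
    a feature block mimicking an integrated cancer-cell-line profile at
    reduced scale: continuous Gaussian expression columns, binary mutation
    columns at a given prevalence, and copy-number columns on the integer
    scale {-2..2}.  No gene-gene correlation structure is emulated.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FeatureMatrix, ResponseVector, TruthRecord, ValidationError


@dataclass
class SimulationScenario:
    """Parameters of a sparse-linear-signal simulation.

    rho is the equicorrelation of the Gaussian design (0 = iid); sigma the
    noise standard deviation; beta maps 0-based active feature index ->
    coefficient.
    """

    n: int = 200
    p: int = 1000
    active_set: tuple[int, ...] = (0, 1, 2, 3, 4)
    beta: dict[int, float] = field(default_factory=lambda: {k: 1.0 for k in range(5)})
    rho: float = 0.0
    sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2 or self.p < 1:
            raise ValidationError("need n >= 2 and p >= 1")
        if not 0 <= self.rho < 1:
            raise ValidationError(f"rho must be in [0, 1), got {self.rho}")
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")
        if not set(self.active_set) <= set(range(self.p)):
            raise ValidationError("active_set must be a subset of {0..p-1}")
        if set(self.beta) != set(self.active_set):
            raise ValidationError("beta keys must equal the active set")


def _ids(prefix: str, count: int) -> list[str]:
    width = max(4, len(str(count)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, count + 1)]


def generate_linear(
    scenario: SimulationScenario,
) -> tuple[FeatureMatrix, ResponseVector, TruthRecord]:
    """Sparse linear signal on a Gaussian design (see module docs)."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n, p, rho = scenario.n, scenario.p, scenario.rho
    Z = rng.standard_normal((n, p))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * Z
    else:
        X = Z
    y = np.zeros(n)
    for k, b in scenario.beta.items():
        y += b * X[:, k]
    y += scenario.sigma * rng.standard_normal(n)
    samples = _ids("S", n)
    fm = FeatureMatrix(X, _ids("F", p), samples)
    rv = ResponseVector(y, samples, label="simulated_response")
    truth = TruthRecord(
        active_set=tuple(sorted(scenario.active_set)),
        beta=dict(scenario.beta),
        sigma=scenario.sigma,
    )
    return fm, rv, truth


def generate_hidden_predictor(
    n: int,
    p: int,
    beta: float = 2.0,
    rho: float = 0.5,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, ResponseVector, TruthRecord]:
    """Marginally-invisible-but-jointly-essential predictor scenario.

    Feature index 3 (0-based; the fourth feature) has cov(X_4, Y) = 0 exactly
    under the model while carrying coefficient -beta*sqrt(3*rho).  Requires
    p >= 4 and 0 < rho < 1.
    """
    if not 0 < rho < 1:
        raise ValidationError(f"rho must be in (0, 1), got {rho}")
    if p < 4:
        raise ValidationError("hidden-predictor scenario needs p >= 4")
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    X = Z.copy()
    X[:, 3] = np.sqrt(rho) * Z[:, :3].sum(axis=1) / np.sqrt(3) + np.sqrt(1 - rho) * Z[:, 3]
    hidden_coef = -beta * np.sqrt(3 * rho)
    y = beta * X[:, :3].sum(axis=1) + hidden_coef * X[:, 3]
    y += sigma * rng.standard_normal(n)
    samples = _ids("S", n)
    fm = FeatureMatrix(X, _ids("F", p), samples)
    rv = ResponseVector(y, samples, label="simulated_response")
    truth = TruthRecord(
        active_set=(0, 1, 2, 3),
        beta={0: beta, 1: beta, 2: beta, 3: hidden_coef},
        sigma=sigma,
        hidden=(3,),
    )
    return fm, rv, truth


def generate_multiomics_like(
    n: int,
    p_expr: int,
    p_mut: int,
    p_cna: int,
    mutation_prevalence: float = 0.2,
    seed: int = 0,
) -> FeatureMatrix:
    """Integrated expression / mutation / copy-number feature block.

    Expression columns are standard normal; mutation columns are Bernoulli at
    the given prevalence; copy-number columns take integer values in {-2..2}
    (peaked at 0).  Any column that comes out constant is redrawn up to 10
    times, so the output always standardizes cleanly.
    """
    if min(p_expr, p_mut, p_cna) < 1:
        raise ValidationError("all omics block sizes must be positive")
    if not 0 < mutation_prevalence < 1:
        raise ValidationError("mutation_prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def _nonconstant(draw) -> np.ndarray:
        for _ in range(10):
            col = draw()
            if np.ptp(col) > 0:
                return col
        raise ValidationError(
            "could not generate a non-constant column in 10 attempts; "
            "prevalence too extreme for this n"
        )

    expr = rng.standard_normal((n, p_expr))
    mut = np.column_stack([
        _nonconstant(lambda: rng.binomial(1, mutation_prevalence, size=n).astype(float))
        for _ in range(p_mut)
    ])
    cna_probs = np.array([0.05, 0.15, 0.6, 0.15, 0.05])
    cna_levels = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    cna = np.column_stack([
        _nonconstant(lambda: cna_levels[rng.choice(5, size=n, p=cna_probs)])
        for _ in range(p_cna)
    ])
    values = np.column_stack([expr, mut, cna])
    ids = _ids("EXPR_", p_expr) + _ids("MUT_", p_mut) + _ids("CNA_", p_cna)
    omics = (
        ["expression"] * p_expr + ["mutation"] * p_mut + ["copy_number"] * p_cna
    )
    return FeatureMatrix(values, ids, _ids("S", n), omics_type=omics)
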