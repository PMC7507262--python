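"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive each quantity from its definition
(double loops, closed forms, normal equations) rather than calling the
package's vectorized implementations, so the tests cross-check two
independent routes to the same number.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from isirs import FeatureMatrix, ResponseVector


def naive_omega(Xv: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Brute-force O(n^2 p) evaluation of the omega_hat double sum."""
    n, p = Xv.shape
    omega = np.zeros(p)
    for k in range(p):
        total = 0.0
        for j in range(n):
            inner = 0.0
            for i in range(n):
                if y[i] < y[j]:
                    inner += Xv[i, k]
            total += (inner / n) ** 2
        omega[k] = total / n
    return omega


def ols_oracle(Xv: np.ndarray, y: np.ndarray) -> dict:
    """Textbook normal-equations OLS with t-tests (intercept included)."""
    n, q = Xv.shape
    A = np.column_stack([np.ones(n), Xv])
    AtA_inv = np.linalg.inv(A.T @ A)
    beta = AtA_inv @ A.T @ y
    resid = y - A @ beta
    dof = n - q - 1
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 * np.diag(AtA_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return {"beta": beta, "se": se, "t": t, "p": p, "resid": resid}


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, gamma) = sign(z) * max(|z| - gamma, 0)."""
    return float(np.sign(z) * max(abs(z) - gamma, 0.0))


def mi_oracle(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Direct sum p(a,b) log(p(a,b)/(p(a)p(b))) over the 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pj = joint / joint.sum()
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    total = 0.0
    for a in range(bins):
        for b in range(bins):
            if pj[a, b] > 0:
                total += pj[a, b] * np.log(pj[a, b] / (px[a] * py[b]))
    return total


def standardize_cols(Xv: np.ndarray) -> np.ndarray:
    """1/n-convention column standardization, independent of the package."""
    c = Xv - Xv.mean(axis=0)
    return c / np.sqrt((c**2).mean(axis=0))


def make_xy(Xv: np.ndarray, y: np.ndarray, standardized: bool = True):
    """Wrap raw arrays into aligned FeatureMatrix / ResponseVector."""
    n, p = np.asarray(Xv).shape
    samples = [f"s{i}" for i in range(n)]
    X = FeatureMatrix(Xv, [f"f{k}" for k in range(p)], samples, standardized=standardized)
    Y = ResponseVector(np.asarray(y, dtype=float), samples)
    return X, Y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
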