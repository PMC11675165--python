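"""Conditional-independence tests for mixed binary/continuous questionnaire
data, plus the Bonferroni family-wise decision rule.

Three test families are provided:

``micg_test``
    Asymptotic chi-square test on the mutual information between two
    continuous variables under a conditional-Gaussian model, stratifying on
    the discrete part of the conditioning set.  Within a stratum of size
    ``N_g`` with partial correlation ``r_g`` of x and y given the continuous
    conditioners, the statistic contribution is ``-N_g * ln(1 - r_g^2)``;
    the total is chi-square with one degree of freedom per stratum.
``gcm_test``
    The generalized covariance measure: regress x and y on z, form the
    products of the two residual series, and refer the normalized mean of
    the products to a standard normal.  Valid with flexible (e.g. boosted
    tree) regressions as long as both fits are consistent enough.
``kci_test``
    Kernel conditional-independence test with Gaussian kernels: the trace
    statistic of the two centered, z-regressed-out kernel matrices, with a
    moment-matched gamma null (no permutations, so results are
    deterministic given the bandwidths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import CiStatement

__all__ = [
    "CiTestResult",
    "micg_test",
    "gcm_test",
    "kci_test",
    "bonferroni_decide",
    "results_to_frame",
]


class DegenerateInputError(ValueError):
    """Data degenerate for the requested test (zero variance, r = 1, ...)."""


@dataclass(frozen=True)
class CiTestResult:
    """Outcome of one conditional-independence test."""

    method: str  # "MIcg" | "GCM" | "KCI"
    statement: CiStatement
    statistic: float
    p_value: float
    n: int
    df: int | None = None  # present iff method == "MIcg"
    alpha: float | None = None
    rejected: bool | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if (self.method == "MIcg") != (self.df is not None):
            raise ValueError("df must be present exactly for MIcg results")


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name not in table.columns:
        raise KeyError(f"variable {name!r} not in table")
    return table[name].to_numpy(dtype=float)


def _is_discrete(col: np.ndarray, max_levels: int = 5) -> bool:
    vals = np.unique(col)
    return len(vals) <= max_levels and np.allclose(vals, np.round(vals))


def _split_z(table: pd.DataFrame, z: Iterable[str],
             discrete: Iterable[str] | None) -> tuple[list[str], list[str]]:
    z = sorted(z)
    if discrete is not None:
        disc = [v for v in z if v in set(discrete)]
    else:
        disc = [v for v in z if _is_discrete(_column(table, v))]
    cont = [v for v in z if v not in disc]
    return disc, cont


def _residuals_linear(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def micg_test(
    table: pd.DataFrame,
    statement: CiStatement,
    discrete: Iterable[str] | None = None,
) -> CiTestResult:
    """Conditional-Gaussian mutual-information chi-square test of x _||_ y | z.

    The conditioning set may mix binary/discrete and continuous variables;
    ``discrete`` forces the classification (default: a variable is discrete
    when it takes at most 5 integer levels).  Requires at least
    ``|continuous z| + 3`` rows in every discrete stratum.
    """
    x = _column(table, statement.x)
    y = _column(table, statement.y)
    disc, cont = _split_z(table, statement.z, discrete)
    n = len(table)

    if disc:
        groups = list(table.groupby(disc, sort=True).indices.values())
    else:
        groups = [np.arange(n)]

    min_rows = len(cont) + 3
    statistic = 0.0
    df = 0
    for idx in groups:
        idx = np.asarray(idx)
        if len(idx) == 0:
            warnings.warn("empty stratum dropped; df reduced", stacklevel=2)
            continue
        if len(idx) < min_rows:
            raise DegenerateInputError(
                f"stratum with {len(idx)} rows < required {min_rows} "
                f"(|continuous z| + 3)"
            )
        zc = np.column_stack([_column(table, v)[idx] for v in cont]) if cont \
            else np.empty((len(idx), 0))
        rx = _residuals_linear(x[idx], zc)
        ry = _residuals_linear(y[idx], zc)
        sx, sy = rx.std(), ry.std()
        if sx <= 0 or sy <= 0:
            raise DegenerateInputError("zero residual variance in a stratum")
        r = float(np.dot(rx, ry) / (len(idx) * sx * sy))
        if abs(r) >= 1.0 - 1e-12:
            raise DegenerateInputError(
                "perfect partial correlation (infinite statistic)")
        statistic += -len(idx) * np.log1p(-r * r)
        df += 1
    if df == 0:
        raise DegenerateInputError("no usable strata")
    p = float(stats.chi2.sf(statistic, df))
    return CiTestResult("MIcg", statement, float(statistic), p, n, df=df)


# -- generalized covariance measure -------------------------------------


def _fit_residuals(y: np.ndarray, Z: np.ndarray, learner: str, seed: int) -> np.ndarray:
    """Out-of-sample-free residuals of y ~ Z under the named learner."""
    if Z.size == 0:
        return y - y.mean()
    if learner == "linear":
        return _residuals_linear(y, Z)
    if learner == "boosted":
        from sklearn.ensemble import GradientBoostingRegressor

        model = GradientBoostingRegressor(
            n_estimators=300, max_depth=2, learning_rate=0.1,
            random_state=seed,
        )
        model.fit(Z, y)
        return y - model.predict(Z)
    raise ValueError(f"unknown learner {learner!r}")


def gcm_test(
    table: pd.DataFrame,
    statement: CiStatement,
    regressor: str = "boosted",
    seed: int = 0,
) -> CiTestResult:
    """Generalized covariance measure test of x _||_ y | z.

    Fits x ~ z and y ~ z with the requested learner ("boosted" — gradient
    boosted trees with 300 trees, depth 2, learning rate 0.1 — or "linear"),
    then refers T = sqrt(n) * mean(R) / sd(R) of the residual products
    R_i = eps_i * xi_i to a standard normal (two-sided).  With an empty
    conditioning set this reduces to a test of zero covariance.
    """
    x = _column(table, statement.x)
    y = _column(table, statement.y)
    n = len(table)
    # the boosted learner needs data to fit; closed-form least squares only
    # needs a full-rank design, which admits tiny worked examples
    min_n = 20 if regressor == "boosted" else len(statement.z) + 3
    if n < min_n:
        raise DegenerateInputError(f"GCM with {regressor!r} requires n >= {min_n}")
    Z = np.column_stack([_column(table, v) for v in sorted(statement.z)]) \
        if statement.z else np.empty((n, 0))
    rx = _fit_residuals(x, Z, regressor, seed)
    ry = _fit_residuals(y, Z, regressor, seed)
    R = rx * ry
    sd = R.std()  # population-style (ddof=0)
    if sd <= 0:
        raise DegenerateInputError("constant residual products")
    T = float(np.sqrt(n) * R.mean() / sd)
    p = float(2.0 * stats.norm.sf(abs(T)))
    return CiTestResult("GCM", statement, T, p, n)


# -- kernel conditional independence ------------------------------------


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    if np.any(sd <= 0):
        raise DegenerateInputError("constant column; kernel bandwidth undefined")
    return (M - M.mean(axis=0)) / sd


def _gaussian_kernel(M: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    sq = np.sum(M * M, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.maximum(d2, 0.0, out=d2)
    if bandwidth is None:
        off = d2[np.triu_indices_from(d2, k=1)]
        med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
        bandwidth = float(np.sqrt(med))
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        raise DegenerateInputError("non-finite kernel bandwidth")
    return np.exp(-d2 / (2.0 * bandwidth**2))


def kci_test(
    table: pd.DataFrame,
    statement: CiStatement,
    bandwidth: float | None = None,
    ridge: float = 1e-3,
    seed: int = 0,
) -> CiTestResult:
    """Kernel conditional-independence test of x _||_ y | z.

    Gaussian kernels with median-heuristic bandwidths on standardized
    inputs; the conditioning set is regressed out of the centered kernel
    matrices by kernel ridge regression (penalty ``ridge``), and the trace
    statistic is referred to a gamma null matched on its first two moments.
    Deterministic given the bandwidths; ``seed`` is accepted for interface
    uniformity.
    """
    n = len(table)
    if n < 20:
        raise DegenerateInputError("KCI requires n >= 20")
    x = _standardize(_column(table, statement.x)[:, None])
    y = _standardize(_column(table, statement.y)[:, None])
    H = np.eye(n) - np.full((n, n), 1.0 / n)

    if statement.z:
        Z = _standardize(
            np.column_stack([_column(table, v) for v in sorted(statement.z)]))
        # augment x with z so that the x-kernel carries the conditioning
        Kx = H @ _gaussian_kernel(np.column_stack([x, Z / 2.0]), bandwidth) @ H
        Ky = H @ _gaussian_kernel(y, bandwidth) @ H
        Kz = _gaussian_kernel(Z, bandwidth)
        Rz = ridge * np.linalg.inv(H @ Kz @ H + ridge * np.eye(n))
        Kx = Rz @ Kx @ Rz
        Ky = Rz @ Ky @ Rz
    else:
        Kx = H @ _gaussian_kernel(x, bandwidth) @ H
        Ky = H @ _gaussian_kernel(y, bandwidth) @ H

    statistic = float(np.sum(Kx * Ky))  # = trace(Kx @ Ky), both symmetric
    mean = float(np.trace(Kx) * np.trace(Ky)) / n
    var = 2.0 * float(np.sum(Kx * Kx)) * float(np.sum(Ky * Ky)) / n**2
    if mean <= 0 or var <= 0:
        raise DegenerateInputError("degenerate kernel matrices")
    shape = mean**2 / var
    scale = var / mean
    p = float(stats.gamma.sf(statistic, a=shape, scale=scale))
    return CiTestResult("KCI", statement, statistic, p, n)


def bonferroni_decide(
    results: Sequence[CiTestResult],
    family_size: int,
    family_alpha: float = 0.05,
) -> list[CiTestResult]:
    """Set each result's decision at the Bonferroni-corrected level.

    The per-test level is ``family_alpha / family_size`` (0.01 for a family
    of five at family level 0.05).
    """
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    if family_size <= 0:
        raise ValueError("family_size must be positive")
    level = family_alpha / family_size
    return [
        replace(r, alpha=level, rejected=bool(r.p_value < level)) for r in results
    ]


def results_to_frame(results: Sequence[CiTestResult]) -> pd.DataFrame:
    """Tidy table of CI test results (one row per statement x method)."""
    rows = []
    for r in results:
        rows.append({
            "x": r.statement.x,
            "y": r.statement.y,
            "z": ",".join(sorted(r.statement.z)),
            "method": r.method,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "n": r.n,
            "alpha": r.alpha,
            "rejected": r.rejected,
        })
    return pd.DataFrame(rows)
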