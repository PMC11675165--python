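"""Average-causal-effect estimators for the ASE model's two target effects.

The metacognition -> fatigue effect (``th3``) and the fatigue x
self-efficacy interaction effect on depression (``th10``) are estimated by
three routes sharing one result type:

``ace_regression``
    Ordinary least squares of the outcome on the treatment plus a valid
    adjustment set; the treatment coefficient identifies the ACE under the
    backdoor criterion.
``ace_propensity``
    Generalized propensity score for a continuous treatment: a Gaussian
    linear model of the treatment given the covariates yields stabilized
    inverse-density weights (truncated at the 1st/99th weight percentiles),
    followed by weighted least squares of the outcome on the treatment with
    heteroscedasticity-robust standard errors.
``ace_dml``
    Double/debiased machine learning in the partially linear model:
    cross-fitted nuisance regressions of treatment and outcome on the
    covariates, then the Neyman-orthogonal residual-on-residual estimate.

Every estimator reports a one-sided p-value in the negative direction —
both theory-driven hypotheses predict negative effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

from .graph import Dag, is_valid_adjustment_set

__all__ = [
    "EffectEstimate",
    "EstimationError",
    "ace_regression",
    "ace_propensity",
    "ace_dml",
    "interaction_ace",
    "estimates_to_frame",
]


class EstimationError(ValueError):
    """Estimation impossible on the given data (rank deficiency, n too small)."""


@dataclass(frozen=True)
class EffectEstimate:
    """One average-causal-effect estimate with its inference."""

    method: str  # "regression" | "propensity" | "dml"
    target: str  # e.g. "theta3", "theta10"
    theta_hat: float
    ci_low: float
    ci_high: float
    t_value: float
    p_one_sided: float
    adjustment_set: frozenset[str]
    n: int
    alpha: float | None = None

    def __post_init__(self):
        if not self.ci_low <= self.theta_hat <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")
        if not 0.0 <= self.p_one_sided <= 1.0:
            raise ValueError("p_one_sided outside [0, 1]")

    @property
    def rejected(self) -> bool | None:
        """One-sided test decision at ``alpha`` (negative direction)."""
        if self.alpha is None:
            return None
        return bool(self.p_one_sided < self.alpha)


def _design(table: pd.DataFrame, cols: Iterable[str]) -> np.ndarray:
    cols = list(cols)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"variable(s) {missing} not in table")
    return table[cols].to_numpy(dtype=float)


def _check_vas(dag: Dag | None, treatment: str, outcome: str,
               z: frozenset[str]) -> None:
    import warnings

    if dag is None:
        warnings.warn(
            "no DAG supplied; adjustment-set validity not checked",
            stacklevel=3,
        )
        return
    if not is_valid_adjustment_set(dag, {treatment}, outcome, z):
        raise EstimationError(
            f"{sorted(z)} is not a valid adjustment set for "
            f"({treatment} -> {outcome}) in the supplied DAG"
        )


def ace_regression(
    table: pd.DataFrame,
    treatment: str,
    outcome: str,
    z: Iterable[str] = (),
    dag: Dag | None = None,
    target: str | None = None,
    alpha: float | None = None,
) -> EffectEstimate:
    """Covariate-adjustment OLS estimate of the ACE of treatment on outcome.

    Regresses the outcome on the treatment and the adjustment set ``z``
    (with intercept); the treatment coefficient is the estimate, with its
    95% two-sided CI and the lower-tail one-sided p-value of the
    t-statistic (the hypothesized effect direction is negative).
    """
    z = frozenset(z)
    _check_vas(dag, treatment, outcome, z)
    n = len(table)
    if n <= len(z) + 2:
        raise EstimationError(f"n = {n} too small for |z| = {len(z)} covariates")
    X = sm.add_constant(_design(table, [treatment, *sorted(z)]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("collinear design (rank deficient)")
    fit = sm.OLS(_design(table, [outcome]).ravel(), X).fit()
    theta = float(fit.params[1])
    t_val = float(fit.tvalues[1])
    ci = fit.conf_int(alpha=0.05)
    p_one = float(stats.t.cdf(t_val, df=fit.df_resid))
    return EffectEstimate(
        method="regression",
        target=target or f"ace({treatment}->{outcome})",
        theta_hat=theta,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        t_value=t_val,
        p_one_sided=p_one,
        adjustment_set=z,
        n=n,
        alpha=alpha,
    )


def ace_propensity(
    table: pd.DataFrame,
    treatment: str,
    outcome: str,
    z: Iterable[str] = (),
    dag: Dag | None = None,
    target: str | None = None,
    alpha: float | None = None,
    truncate: tuple[float, float] | None = None,
) -> EffectEstimate:
    """Generalized-propensity-score estimate for a continuous treatment.

    A Gaussian linear model of the treatment given ``z`` provides the
    conditional density; stabilized weights ``f(t) / f(t | z)`` (marginal
    over conditional) enter a weighted least squares of the outcome on the
    treatment alone.  Standard errors are heteroscedasticity-robust (HC0).
    ``truncate`` optionally clips the weights at the given percentiles;
    it is off by default because with a continuous treatment the largest
    weights sit on the extreme-residual observations that carry the
    deconfounding information, and clipping them biases the slope (see the
    methods note).  With empty ``z`` the weights are exactly 1 and the
    estimate coincides with unadjusted OLS.
    """
    z = frozenset(z)
    _check_vas(dag, treatment, outcome, z)
    n = len(table)
    if n <= len(z) + 2:
        raise EstimationError(f"n = {n} too small for |z| = {len(z)} covariates")
    t = _design(table, [treatment]).ravel()
    y = _design(table, [outcome]).ravel()

    # conditional density f(t | z): Gaussian linear model
    Xz = sm.add_constant(_design(table, sorted(z))) if z else np.ones((n, 1))
    if np.linalg.matrix_rank(Xz) < Xz.shape[1]:
        raise EstimationError("collinear covariates in propensity model")
    ps_fit = sm.OLS(t, Xz).fit()
    sd_cond = float(np.sqrt(np.mean(ps_fit.resid**2)))
    if sd_cond <= 0:
        raise EstimationError("degenerate conditional treatment density")
    f_cond = stats.norm.pdf(t, loc=ps_fit.fittedvalues, scale=sd_cond)

    # marginal density f(t): Gaussian fit
    f_marg = stats.norm.pdf(t, loc=t.mean(), scale=t.std())
    if np.any(f_cond <= 0) or np.any(f_marg <= 0):
        raise EstimationError("non-positive estimated densities")

    w = f_marg / f_cond
    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        w = np.clip(w, lo, hi)

    Xt = sm.add_constant(t)
    fit = sm.WLS(y, Xt, weights=w).fit(cov_type="HC0")
    theta = float(fit.params[1])
    t_val = float(fit.tvalues[1])
    df = n - 2
    half = float(stats.t.ppf(0.975, df) * fit.bse[1])
    p_one = float(stats.t.cdf(t_val, df=df))
    return EffectEstimate(
        method="propensity",
        target=target or f"ace({treatment}->{outcome})",
        theta_hat=theta,
        ci_low=theta - half,
        ci_high=theta + half,
        t_value=t_val,
        p_one_sided=p_one,
        adjustment_set=z,
        n=n,
        alpha=alpha,
    )


def _cross_fit_predict(
    X: np.ndarray, y: np.ndarray, folds: int, learner: str, seed: int
) -> np.ndarray:
    """Out-of-fold predictions of y from X."""
    n = len(y)
    preds = np.empty(n)
    if X.size == 0:
        # no covariates: nuisance is the fold-complement mean
        for _, (tr, te) in enumerate(
            KFold(folds, shuffle=True, random_state=seed).split(np.arange(n))
        ):
            preds[te] = y[tr].mean()
        return preds
    for k, (tr, te) in enumerate(
        KFold(folds, shuffle=True, random_state=seed).split(X)
    ):
        if learner == "linear":
            beta, *_ = np.linalg.lstsq(
                np.column_stack([np.ones(len(tr)), X[tr]]), y[tr], rcond=None)
            preds[te] = np.column_stack([np.ones(len(te)), X[te]]) @ beta
        elif learner == "boosted":
            from sklearn.ensemble import GradientBoostingRegressor

            model = GradientBoostingRegressor(
                n_estimators=300, max_depth=2, learning_rate=0.1,
                random_state=seed + k,
            )
            model.fit(X[tr], y[tr])
            preds[te] = model.predict(X[te])
        else:
            raise ValueError(f"unknown learner {learner!r}")
    return preds


def ace_dml(
    table: pd.DataFrame,
    treatment: str,
    outcome: str,
    z: Iterable[str] = (),
    folds: int = 5,
    seed: int = 0,
    learner: str = "boosted",
    dag: Dag | None = None,
    target: str | None = None,
    alpha: float | None = None,
) -> EffectEstimate:
    """Double/debiased machine learning in the partially linear model.

    Nuisances m(z) = E[treatment | z] and l(z) = E[outcome | z] are fit
    out-of-fold (K-fold cross-fitting); the estimate is the
    residual-on-residual slope and its standard error comes from the
    empirical variance of the Neyman-orthogonal score.  Deterministic given
    ``seed``.
    """
    z = frozenset(z)
    _check_vas(dag, treatment, outcome, z)
    n = len(table)
    if folds <= 1:
        raise EstimationError("folds must be at least 2")
    if n < 10 * folds:
        raise EstimationError(f"n = {n} < 10 * folds = {10 * folds}")
    t = _design(table, [treatment]).ravel()
    y = _design(table, [outcome]).ravel()
    Z = _design(table, sorted(z)) if z else np.empty((n, 0))

    m_hat = _cross_fit_predict(Z, t, folds, learner, seed)
    l_hat = _cross_fit_predict(Z, y, folds, learner, seed)
    rt = t - m_hat
    ry = y - l_hat
    denom = float(np.sum(rt * rt))
    if denom <= 0 or np.allclose(rt, 0):
        raise EstimationError("constant treatment residuals")
    theta = float(np.sum(rt * ry) / denom)

    psi = rt * (ry - theta * rt)  # orthogonal score at theta-hat
    var = float(np.mean(psi**2)) / float(np.mean(rt * rt)) ** 2
    se = float(np.sqrt(var / n))
    if se <= 0:
        raise EstimationError("zero standard error")
    t_val = theta / se
    half = float(stats.norm.ppf(0.975) * se)
    p_one = float(stats.norm.cdf(t_val))
    return EffectEstimate(
        method="dml",
        target=target or f"ace({treatment}->{outcome})",
        theta_hat=theta,
        ci_low=theta - half,
        ci_high=theta + half,
        t_value=float(t_val),
        p_one_sided=p_one,
        adjustment_set=z,
        n=n,
        alpha=alpha,
    )


_INTERACTION_COL = "F_x_S"


def interaction_ace(
    table: pd.DataFrame,
    outcome: str = "D",
    z: Iterable[str] = (),
    method: str = "regression",
    folds: int = 5,
    seed: int = 0,
    learner: str = "boosted",
    alpha: float | None = None,
) -> EffectEstimate:
    """Estimate the fatigue x self-efficacy interaction effect on depression.

    For ``method="regression"`` this is least squares of D on F, S, F*S and
    ``z``, reading off the product-term coefficient (the structural
    interaction ``th10``).  For the propensity and DML routes the product
    F*S is treated as the continuous treatment with {F, S} added to the
    controls.  One-sided inference in the negative direction throughout.
    """
    for col in ("F", "S"):
        if col not in table.columns:
            raise KeyError(f"table lacks required column {col!r}")
    z = frozenset(z)
    if {"F", "S", outcome} & z:
        raise EstimationError("z must not contain F, S, or the outcome")
    work = table.copy()
    work[_INTERACTION_COL] = work["F"] * work["S"]

    if method == "regression":
        est = ace_regression(
            work, _INTERACTION_COL, outcome, z | {"F", "S"},
            target="theta10", alpha=alpha,
        )
    elif method == "propensity":
        est = ace_propensity(
            work, _INTERACTION_COL, outcome, z | {"F", "S"},
            target="theta10", alpha=alpha,
        )
    elif method == "dml":
        est = ace_dml(
            work, _INTERACTION_COL, outcome, z | {"F", "S"},
            folds=folds, seed=seed, learner=learner,
            target="theta10", alpha=alpha,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    # report the user's covariate set, not the augmented controls
    object.__setattr__(est, "adjustment_set", z)
    return est


def estimates_to_frame(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Tidy table of effect estimates (one row per method x adjustment set)."""
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method,
            "target": e.target,
            "theta_hat": e.theta_hat,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "t_value": e.t_value,
            "p_one_sided": e.p_one_sided,
            "adjustment_set": ",".join(sorted(e.adjustment_set)),
            "n": e.n,
            "alpha": e.alpha,
            "rejected": e.rejected,
        })
    return pd.DataFrame(rows)
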