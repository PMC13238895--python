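"""Single-hit limiting-dilution estimation of tumor-initiating-cell frequency.

Under the single-hit Poisson model, an inoculation of ``d`` cells grows a
tumor with probability ``1 - exp(-f d)`` where ``f`` is the frequency of
tumor-initiating cells.  The frequency is estimated by maximizing the
binomial likelihood of the take/no-take table over ``log f``; 95% confidence
limits come from the profile likelihood (chi-square(1) cutoff 3.84) and are
reported on the familiar "1 in N" scale.  Two generalized-model tests
accompany the fit: the single-hit adequacy test frees the slope of
``cloglog P = beta * log(dose) + c`` (single-hit means beta = 1) and the
heterogeneity test compares per-group frequencies against one shared
frequency, both as likelihood-ratio chi-square tests.

Doses where every inoculation (or none) grew are retained in the likelihood;
unlike log-transform regression, the ML fit uses them as one-sided evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = ["EldaFit", "EldaTest", "elda_fit", "elda_single_hit_test", "elda_heterogeneity_test"]

log = logging.getLogger(__name__)

_LOGF_LO, _LOGF_HI = -34.5, 0.0  # f from ~1e-15 to 1
_CHI2_95 = stats.chi2.ppf(0.95, df=1)  # 3.841...
_XATOL = 1e-12


def _columns(table: pd.DataFrame):
    required = {"dose", "n", "tumors"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dilution table missing columns: {sorted(missing)}")
    d = table["dose"].to_numpy(float)
    n = table["n"].to_numpy(int)
    k = table["tumors"].to_numpy(int)
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if np.any((k < 0) | (k > n)):
        raise ValueError("tumors must lie in [0, n] per dose")
    return d, n, k


def _loglik(logf: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood kernel at frequency exp(logf).

    log(1-p) = -f*d is used directly so all-negative doses stay exact even
    when p underflows.
    """
    f = np.exp(logf)
    log_q = -f * d                      # log P(no tumor)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(log_q))  # log P(tumor)
    terms = np.where(k > 0, k * log_p, 0.0) + (n - k) * log_q
    return float(terms.sum())


def _score(logf: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """d/dlogf of the log-likelihood kernel."""
    f = np.exp(logf)
    fd = f * d
    with np.errstate(over="ignore"):
        ratio = fd * np.exp(-fd) / (-np.expm1(-fd))  # f*d*q/p
    terms = np.where(k > 0, k * ratio, 0.0) - (n - k) * fd
    return float(terms.sum())


def _polish_mle(logf_hat: float, d, n, k) -> float:
    """Sharpen the bounded-search optimum by solving the score equation."""
    for width in (1e-6, 1e-4, 1e-2, 1.0):
        lo, hi = logf_hat - width, logf_hat + width
        try:
            if _score(lo, d, n, k) > 0 > _score(hi, d, n, k):
                return float(optimize.brentq(
                    _score, lo, hi, args=(d, n, k), xtol=1e-14, rtol=1e-15))
        except ValueError:
            continue
    return logf_hat


@dataclass(frozen=True)
class EldaFit:
    """Maximum-likelihood single-hit fit of a dilution table."""

    frequency: float
    one_in_n: float
    ci_one_in_n: tuple[float, float]  # (lower, upper), lower <= point <= upper
    log_likelihood: float
    fitted: pd.DataFrame  # dose, n, tumors, p_fitted
    bounded: str = "two-sided"  # or "upper-only" / "lower-only"


def elda_fit(table: pd.DataFrame) -> EldaFit:
    """Estimate tumor-initiating-cell frequency from take/no-take outcomes.

    All-positive tables leave the frequency unbounded above (an upper-bound-
    only fit is returned with a warning); all-negative tables are the mirror
    case.  On a single informative dose the estimate reduces to the closed
    form ``-ln(fraction negative) / dose``.
    """
    d, n, k = _columns(table)
    if n.sum() == 0:
        raise ValueError("no inoculations in table")

    all_pos = bool(np.all(k == n))
    all_neg = bool(np.all(k == 0))

    res = optimize.minimize_scalar(
        lambda x: -_loglik(x, d, n, k),
        bounds=(_LOGF_LO, _LOGF_HI),
        method="bounded",
        options={"xatol": _XATOL},
    )
    logf_hat = float(res.x)
    if not (all_pos or all_neg):
        logf_hat = _polish_mle(logf_hat, d, n, k)
    ll_max = _loglik(logf_hat, d, n, k)
    cut = ll_max - _CHI2_95 / 2.0

    def profile_root(lo: float, hi: float) -> float:
        return float(optimize.brentq(
            lambda x: _loglik(x, d, n, k) - cut, lo, hi, xtol=1e-12))

    if all_pos:
        log.warning("all inoculations positive: frequency unbounded above")
        logf_lo = profile_root(_LOGF_LO, _LOGF_HI) if _loglik(_LOGF_LO, d, n, k) < cut else _LOGF_LO
        f, one_in = np.inf, 0.0
        ci = (0.0, 1.0 / np.exp(logf_lo))
        bounded = "lower-only"  # only a lower bound on f, an upper bound on N
        ll = _loglik(_LOGF_HI, d, n, k)
    elif all_neg:
        log.warning("all inoculations negative: frequency unbounded below")
        logf_hi = (profile_root(_LOGF_LO, _LOGF_HI)
                   if _loglik(_LOGF_HI, d, n, k) < cut else _LOGF_HI)
        f, one_in = 0.0, np.inf
        ci = (1.0 / np.exp(logf_hi), np.inf)
        bounded = "upper-only"
        ll = _loglik(_LOGF_LO, d, n, k)
    else:
        f = float(np.exp(logf_hat))
        one_in = 1.0 / f
        ll = ll_max
        logf_lo = (profile_root(_LOGF_LO, logf_hat)
                   if _loglik(_LOGF_LO, d, n, k) < cut else _LOGF_LO)
        logf_hi = (profile_root(logf_hat, _LOGF_HI)
                   if _loglik(_LOGF_HI, d, n, k) < cut else _LOGF_HI)
        ci = (1.0 / np.exp(logf_hi), 1.0 / np.exp(logf_lo))
        bounded = "two-sided"

    f_for_p = np.exp(logf_hat) if not (all_pos or all_neg) else (
        np.exp(_LOGF_HI) if all_pos else np.exp(_LOGF_LO))
    fitted = pd.DataFrame({
        "dose": d, "n": n, "tumors": k,
        "p_fitted": 1.0 - np.exp(-f_for_p * d),
    })
    return EldaFit(
        frequency=f, one_in_n=one_in, ci_one_in_n=ci,
        log_likelihood=ll, fitted=fitted, bounded=bounded,
    )


@dataclass(frozen=True)
class EldaTest:
    """Likelihood-ratio test result for dilution-assay model checks."""

    name: str  # "single_hit" or "heterogeneity"
    chi_square: float
    df: int
    p_value: float
    slope: float | None = None


def _glm_cloglog(d: np.ndarray, n: np.ndarray, k: np.ndarray, free_slope: bool):
    """Binomial GLM with cloglog link; slope on log(dose) free or fixed at 1."""
    logd = np.log(d)
    prop = k / n
    family = sm.families.Binomial(link=sm.families.links.CLogLog())
    if free_slope:
        exog = sm.add_constant(logd)
        model = sm.GLM(prop, exog, family=family, var_weights=n)
    else:
        exog = np.ones((len(d), 1))
        model = sm.GLM(prop, exog, family=family, var_weights=n, offset=logd)
    return model.fit(maxiter=200)


def elda_single_hit_test(table: pd.DataFrame) -> EldaTest:
    """Adequacy of the single-hit model via the generalized dose-response slope.

    Fits ``cloglog P(tumor) = beta * log(dose) + c``; beta = 1 recovers the
    single-hit model.  Reports the estimated slope and the likelihood-ratio
    chi-square (1 df) of freeing beta.  A small p-value means tumor take does
    not scale with dose the way one initiating cell per tumor would imply.
    """
    d, n, k = _columns(table)
    informative = len(np.unique(d[n > 0])) >= 2 and not (np.all(k == 0) or np.all(k == n))
    if not informative:
        raise ValueError("single-hit test needs >= 2 informative doses")
    full = _glm_cloglog(d, n, k, free_slope=True)
    constrained = _glm_cloglog(d, n, k, free_slope=False)
    chi2 = max(0.0, 2.0 * (full.llf - constrained.llf))
    return EldaTest(
        name="single_hit",
        chi_square=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        slope=float(full.params[1]),
    )


def elda_heterogeneity_test(tables: dict[str, pd.DataFrame]) -> EldaTest:
    """Likelihood-ratio test of per-group frequencies vs one shared frequency."""
    if len(tables) < 2:
        raise ValueError("heterogeneity test needs >= 2 groups")

    def max_ll(frame: pd.DataFrame) -> float:
        d, n, k = _columns(frame)
        res = optimize.minimize_scalar(
            lambda x: -_loglik(x, d, n, k),
            bounds=(_LOGF_LO, _LOGF_HI), method="bounded",
            options={"xatol": _XATOL},
        )
        return -float(res.fun)

    ll_separate = sum(max_ll(t) for t in tables.values())
    pooled = pd.concat(list(tables.values()), ignore_index=True)
    ll_pooled = max_ll(pooled)
    chi2 = max(0.0, 2.0 * (ll_separate - ll_pooled))
    df = len(tables) - 1
    return EldaTest(
        name="heterogeneity",
        chi_square=float(chi2),
        df=df,
        p_value=float(stats.chi2.sf(chi2, df=df)),
    )
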