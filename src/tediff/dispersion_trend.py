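"""Mean-dispersion trend and empirical-Bayes shrinkage.

Per-gene dispersion MLEs from a handful of replicates are noisy.  The
genome-wide relationship between a gene's mean normalized count and its
dispersion is summarized by the hyperbolic trend

    f(mu) = lambda0 + lambda1 / mu,

fitted by least squares on genes whose raw estimate is away from the
search boundaries, with two re-fits after discarding gross outliers.
Each gene's dispersion is then shrunk toward the trend by maximizing
its NB log-likelihood penalized with a log-normal prior centred at
f(mu) — a MAP estimate on the log-dispersion scale.  The prior width is
estimated from the spread of log(raw/trend) residuals by a robust MAD
estimator, floored so that clean data are not over-shrunk.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize
from scipy.stats import median_abs_deviation

from .glm_core import KAPPA_MAX, KAPPA_MIN, nb_log_likelihood

#: lower bound on the estimated prior standard deviation (log scale)
PRIOR_SD_FLOOR = 0.25


class TrendFitError(ValueError):
    """Too few usable genes to fit the mean-dispersion trend."""


def _non_boundary(kappas: np.ndarray) -> np.ndarray:
    k = np.asarray(kappas, dtype=float)
    return (k > KAPPA_MIN * 1.001) & (k < KAPPA_MAX * 0.999)


def fit_trend(means, raw_kappas, min_genes: int = 10):
    """Least-squares fit of the trend kappa = lambda0 + lambda1 / mean.

    Genes whose raw dispersion sits at the search boundary are excluded
    (boundary values are not MLEs).  After the initial fit the
    regression is repeated twice, each time discarding genes whose
    ratio to the fitted trend exceeds 10 or falls below 0.1.  Negative
    coefficient estimates are clipped to zero with a warning.

    Returns
    -------
    (lambda0, lambda1) : floats >= 0

    Raises
    ------
    TrendFitError
        If fewer than ``min_genes`` usable genes remain; use joint
        dispersion mode or more replicates in that case.
    """
    means = np.asarray(means, dtype=float)
    raw_kappas = np.asarray(raw_kappas, dtype=float)
    usable = (
        _non_boundary(raw_kappas)
        & np.isfinite(means)
        & (means > 0)
        & np.isfinite(raw_kappas)
    )
    if usable.sum() < min_genes:
        raise TrendFitError(
            f"only {int(usable.sum())} usable genes for the dispersion trend "
            f"(need >= {min_genes}); consider joint mode or more replicates"
        )
    lam = None
    for _ in range(3):
        A = np.column_stack([np.ones(usable.sum()), 1.0 / means[usable]])
        lam, *_ = np.linalg.lstsq(A, raw_kappas[usable], rcond=None)
        fitted = np.maximum(lam[0] + lam[1] / means, 1e-12)
        ratio = raw_kappas / fitted
        keep = usable & (ratio <= 10.0) & (ratio >= 0.1)
        if keep.sum() < min_genes or keep.sum() == usable.sum():
            break
        usable = keep
    lam0, lam1 = float(lam[0]), float(lam[1])
    if lam0 < 0 or lam1 < 0:
        warnings.warn(
            f"negative trend coefficient clipped to 0 (lambda0={lam0:.3g}, "
            f"lambda1={lam1:.3g})",
            stacklevel=2,
        )
        lam0, lam1 = max(lam0, 0.0), max(lam1, 0.0)
    return lam0, lam1


def trend_kappa(means, lambda0: float, lambda1: float) -> np.ndarray:
    """Evaluate the fitted trend, clipped into the dispersion bounds."""
    means = np.asarray(means, dtype=float)
    with np.errstate(divide="ignore"):
        k = lambda0 + lambda1 / means
    return np.clip(k, KAPPA_MIN, KAPPA_MAX)


def estimate_prior_sd(raw_kappas, trend_kappas) -> float:
    """Robust width of the log(raw/trend) residual distribution.

    1.4826 * MAD of the log-ratios over non-boundary genes, floored at
    0.25 so that essentially noise-free data keep a proper prior.
    """
    raw = np.asarray(raw_kappas, dtype=float)
    trend = np.asarray(trend_kappas, dtype=float)
    ok = _non_boundary(raw) & (trend > 0) & np.isfinite(raw) & np.isfinite(trend)
    if not ok.any():
        return PRIOR_SD_FLOOR
    resid = np.log(raw[ok] / trend[ok])
    sd = float(median_abs_deviation(resid, scale="normal"))
    return max(sd, PRIOR_SD_FLOOR)


def shrink_dispersion(raw_kappa, trend_kappa, prior_sd, y, mu_hat) -> float:
    """MAP dispersion under a log-normal prior centred on the trend.

    Maximizes ``nb_log_likelihood(y, mu_hat, kappa)`` minus the squared
    log-distance to ``trend_kappa`` scaled by ``prior_sd``, over the
    bounded dispersion range, on the log scale.  The optimum lies
    between the raw MLE and the trend on the log scale (clamped there
    as a numerical safeguard); with raw == trend the estimate is the
    common value, and as ``prior_sd`` grows it reverts to the raw MLE.
    """
    y = np.asarray(y, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    lt = np.log(trend_kappa)

    def neg(log_kappa):
        return -(
            nb_log_likelihood(y, mu_hat, np.exp(log_kappa))
            - 0.5 * ((log_kappa - lt) / prior_sd) ** 2
        )

    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(KAPPA_MIN), np.log(KAPPA_MAX)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    lo = min(raw_kappa, trend_kappa)
    hi = max(raw_kappa, trend_kappa)
    return float(np.clip(np.exp(res.x), lo, hi))
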