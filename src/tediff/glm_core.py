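"""Negative-binomial GLM machinery for paired RNA-Seq / RF counts.

Counts for gene *i* in library *j* are modelled as NB with mean mu_ij
and dispersion kappa (variance mu + kappa * mu^2; kappa = 0 recovers
the Poisson).  The mean is linked through the log:

    log mu_ij = log s_j + x_j . beta_i

where s_j is the library size factor (an offset) and the design row
x_j encodes intercept, protocol (RF vs RNA-Seq), condition (treatment
vs control) and — under the alternative model — their interaction.
The interaction coefficient is the log fold change of translation
efficiency between conditions; the null model constrains it to zero.

Because the two sequencing protocols have different statistical
characteristics, the dispersion may be estimated separately for the
RNA-Seq and the RF libraries of a gene (``DispersionMode.SEPARATE``)
while the mean model stays shared; ``JOINT`` shares a single kappa.
Coefficients given dispersions and dispersions given coefficients are
maximized in alternation until the joint log-likelihood stabilizes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import optimize
from scipy.special import gammaln

from .count_io import Condition, ExperimentDesign, Protocol, ValidationError

KAPPA_MIN = 1e-6
KAPPA_MAX = 10.0
#: below this the NB log-pmf is evaluated in its Poisson limit
_KAPPA_POISSON = 1e-8
#: floor on fitted means; bounds coefficients of structurally zero groups
MU_FLOOR = 1e-8
_ETA_MIN = np.log(MU_FLOOR)
_ETA_MAX = 45.0


class ModelKind(str, enum.Enum):
    NULL = "null"
    ALT = "alt"


class DispersionMode(str, enum.Enum):
    JOINT = "joint"
    SEPARATE = "separate"


def nb_log_likelihood(y, mu, kappa) -> float:
    """Sum of NB log-pmf terms with per-sample mean and dispersion.

    ``kappa`` may be a scalar or a per-sample vector; entries below
    1e-8 are evaluated with the Poisson log-pmf (the kappa -> 0 limit).

    Raises
    ------
    ValueError
        If any dispersion is negative.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), y.shape)
    if np.any(kappa < 0):
        raise ValueError("dispersion must be non-negative")
    if np.any(mu <= 0):
        raise ValueError("means must be strictly positive")
    out = np.empty_like(y)
    pois = kappa < _KAPPA_POISSON
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = yp * np.log(mp) - mp - gammaln(yp + 1.0)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = 1.0 / kappa[nb]
        out[nb] = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        )
    return float(out.sum())


@dataclass(frozen=True)
class ModelSpec:
    """A design matrix together with its hypothesis kind and labels."""

    kind: ModelKind
    X: np.ndarray
    labels: tuple
    design: ExperimentDesign

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design(design: ExperimentDesign, kind: ModelKind) -> ModelSpec:
    """Construct the null or alternative design matrix.

    Columns in order: intercept, protocol indicator (1 = RF),
    condition indicator (1 = treatment) and, for the alternative
    model, their interaction — the translation-efficiency effect.
    """
    kind = ModelKind(kind)
    rf = design.protocol_mask(Protocol.RIBO).astype(float)
    treat = design.condition_mask(Condition.TREATMENT).astype(float)
    if rf.all() or not rf.any():
        raise ValidationError("design must contain both protocols")
    if treat.all() or not treat.any():
        raise ValidationError("design must contain both conditions")
    cols = [np.ones(design.n_samples), rf, treat]
    labels = ["intercept", "protocol_rf", "condition_treatment"]
    if kind == ModelKind.ALT:
        cols.append(rf * treat)
        labels.append("te_interaction")
    X = np.column_stack(cols)
    return ModelSpec(kind, X, tuple(labels), design)


@dataclass
class GeneFit:
    """Result of fitting one gene's coefficient vector."""

    beta: np.ndarray
    mu_hat: np.ndarray
    loglik: float
    converged: bool
    iterations: int


def _mu_from_beta(X, beta, offsets):
    eta = np.clip(offsets + X @ beta, _ETA_MIN, _ETA_MAX)
    return np.exp(eta)


def fit_coefficients(
    y,
    spec: ModelSpec,
    offsets,
    kappa,
    init: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GeneFit:
    """Maximize the NB log-likelihood over the design's coefficients.

    Newton–Raphson on the log link using the Fisher information, with
    step halving so the log-likelihood never decreases; a Nelder–Mead
    polish is applied if Newton stalls before converging.  Fitted means
    are floored at 1e-8, which bounds the coefficients of structurally
    zero (all-count-zero) groups under the saturated design.
    """
    y = np.asarray(y, dtype=float)
    X = spec.X
    offsets = np.asarray(offsets, dtype=float)
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), y.shape).copy()
    if not np.any(y > 0):
        raise ValidationError("cannot fit a gene with no positive count")

    if init is None:
        with np.errstate(divide="ignore"):
            target = np.log(y * np.exp(-offsets) + 0.5)
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    else:
        beta = np.asarray(init, dtype=float).copy()

    def ll(b):
        return nb_log_likelihood(y, _mu_from_beta(X, b, offsets), kappa)

    cur = ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _mu_from_beta(X, beta, offsets)
        denom = 1.0 + kappa * mu
        score = X.T @ ((y - mu) / denom)
        W = mu / denom
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(X.shape[1]), score)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(info, score, rcond=None)
        scale = 1.0
        new = cur
        cand = beta
        for _ in range(40):
            cand = beta + scale * step
            new = ll(cand)
            if new >= cur - 1e-13:
                break
            scale *= 0.5
        if new < cur:
            break  # no uphill direction left
        delta = new - cur
        beta, cur = cand, new
        if delta < tol:
            converged = True
            break

    if not converged:
        res = optimize.minimize(
            lambda b: -ll(b),
            beta,
            method="Nelder-Mead",
            options={"maxiter": 400 * X.shape[1], "fatol": 1e-10, "xatol": 1e-8},
        )
        if -res.fun > cur:
            beta, cur = res.x, -res.fun
        converged = abs(res.fun + cur) < 1e-6
        if not converged:
            warnings.warn("coefficient fit did not converge", stacklevel=2)
    mu = _mu_from_beta(X, beta, offsets)
    return GeneFit(beta=beta, mu_hat=mu, loglik=cur, converged=converged, iterations=it)


class DispersionEstimate(NamedTuple):
    value: float
    at_boundary: bool


def dispersion_mle(
    y, mu_hat, bounds: tuple = (KAPPA_MIN, KAPPA_MAX)
) -> DispersionEstimate:
    """Bounded 1-D maximum-likelihood estimate of a shared dispersion.

    The search runs on the log-kappa scale over ``bounds``; the flag is
    set when the optimum sits at a boundary (for example underdispersed
    counts, whose MLE is pinned at the lower bound).
    """
    y = np.asarray(y, dtype=float)
    mu_hat = np.asarray(mu_hat, dtype=float)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def neg(log_kappa):
        return -nb_log_likelihood(y, mu_hat, np.exp(log_kappa))

    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-9}
    )
    kappa = float(np.exp(res.x))
    # the bounded search cannot sit exactly on a bound; snap within 1%
    at_boundary = res.x < lo + 1e-2 or res.x > hi - 1e-2
    if at_boundary:
        kappa = bounds[0] if res.x < lo + 1e-2 else bounds[1]
    return DispersionEstimate(kappa, at_boundary)


def bias_corrected_dispersion(kappa: float, mu_hat, n_params: int) -> float:
    """First-order small-sample correction of a plug-in dispersion MLE.

    Maximizing the NB likelihood in kappa at *fitted* means ignores the
    ``n_params`` mean parameters consumed by the fit, deflating the
    implied variance by roughly (n - p) / n — the same effect that
    biases a residual variance computed with denominator n.  The
    correction rescales the implied variance mu + kappa * mu^2 by
    n / (n - p) and solves back for kappa.  Lower-boundary estimates
    (underdispersed data) are returned unchanged: there the MLE is not
    interior and the variance-scaling argument does not apply.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    n = mu_hat.size
    if n <= n_params or kappa <= KAPPA_MIN:
        return float(kappa)
    c = n / (n - n_params)
    adj = c * kappa + (c - 1.0) * mu_hat.sum() / (mu_hat**2).sum()
    return float(np.clip(adj, KAPPA_MIN, KAPPA_MAX))


def _mom_kappa(y, offsets):
    x = np.asarray(y, dtype=float) * np.exp(-np.asarray(offsets, dtype=float))
    m = x.mean()
    if m <= 0 or x.size < 2:
        return KAPPA_MIN
    v = x.var(ddof=1)
    return float(np.clip((v - m) / m**2, KAPPA_MIN, KAPPA_MAX))


def dispersion_groups(design: ExperimentDesign, mode: DispersionMode) -> dict:
    """Sample masks over which dispersions are shared: one group in
    JOINT mode, one per protocol in SEPARATE mode."""
    mode = DispersionMode(mode)
    if mode == DispersionMode.JOINT:
        return {"all": np.ones(design.n_samples, dtype=bool)}
    return {
        "rna": design.protocol_mask(Protocol.RNASEQ),
        "rf": design.protocol_mask(Protocol.RIBO),
    }


def kappa_vector(design: ExperimentDesign, kappas: dict) -> np.ndarray:
    """Expand per-group dispersions to a per-sample vector."""
    out = np.empty(design.n_samples, dtype=float)
    for label, mask in dispersion_groups(
        design, DispersionMode.JOINT if "all" in kappas else DispersionMode.SEPARATE
    ).items():
        out[mask] = kappas[label]
    return out


def alternating_fit(
    y,
    spec: ModelSpec,
    offsets,
    mode: DispersionMode = DispersionMode.SEPARATE,
    init_kappa: Optional[dict] = None,
    tol: float = 1e-6,
    max_outer: int = 50,
    correct_bias: bool = True,
):
    """Alternate coefficient and dispersion maximization for one gene.

    Coefficients are re-fit given the current dispersions, then each
    dispersion group's kappa is re-estimated given the fitted means,
    until the joint log-likelihood changes by less than ``tol`` (or 50
    outer rounds).  Both partial steps maximize the same objective, so
    the joint log-likelihood is non-decreasing.  After the loop the
    per-group dispersion estimates receive the small-sample plug-in
    bias correction of :func:`bias_corrected_dispersion` (skipped with
    ``correct_bias=False``).

    Returns
    -------
    (GeneFit, dict of DispersionEstimate)
        The final coefficient fit and the raw dispersion estimate per
        group ("all", or "rna"/"rf" in separate mode).
    """
    mode = DispersionMode(mode)
    y = np.asarray(y, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    groups = dispersion_groups(spec.design, mode)
    if init_kappa is not None:
        kappas = {k: float(v) for k, v in init_kappa.items()}
    else:
        kappas = {label: _mom_kappa(y[mask], offsets[mask]) for label, mask in groups.items()}
    estimates = {label: DispersionEstimate(kappas[label], False) for label in groups}

    kv = np.empty_like(y)
    prev_ll = -np.inf
    fit = None
    beta = None
    for _ in range(max_outer):
        for label, mask in groups.items():
            kv[mask] = kappas[label]
        fit = fit_coefficients(y, spec, offsets, kv, init=beta)
        beta = fit.beta
        for label, mask in groups.items():
            est = dispersion_mle(y[mask], fit.mu_hat[mask])
            estimates[label] = est
            kappas[label] = est.value
        for label, mask in groups.items():
            kv[mask] = kappas[label]
        joint_ll = nb_log_likelihood(y, fit.mu_hat, kv)
        if joint_ll - prev_ll < tol:
            prev_ll = joint_ll
            break
        prev_ll = joint_ll
    fit.loglik = prev_ll
    if correct_bias:
        for label, mask in groups.items():
            est = estimates[label]
            p_eff = int(np.linalg.matrix_rank(spec.X[mask]))
            estimates[label] = DispersionEstimate(
                bias_corrected_dispersion(est.value, fit.mu_hat[mask], p_eff),
                est.at_boundary,
            )
    return fit, estimates
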