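"""Per-gene likelihood-ratio test of translation-efficiency change.

For each testable gene the alternative model (free TE interaction) and
the null model (interaction fixed at zero) are fitted with the same
shrunken dispersions held fixed, and twice their log-likelihood
difference is referred to a chi-square distribution with one degree of
freedom.  Benjamini–Hochberg correction is applied over the testable
genes, and translation efficiencies per condition are reported from
size-factor-normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .count_io import Condition, ExperimentDesign, JoinedDataset, Protocol
from .dispersion_trend import (
    TrendFitError,
    estimate_prior_sd,
    fit_trend,
    shrink_dispersion,
    trend_kappa,
)
from .glm_core import (
    DispersionMode,
    KAPPA_MAX,
    KAPPA_MIN,
    ModelKind,
    alternating_fit,
    build_design,
    dispersion_groups,
    fit_coefficients,
)
from .normalization import SizeFactors, size_factors

#: slack below which a negative LRT statistic is treated as numerical noise
_NESTING_SLACK = 1e-9


def lrt_pvalue(loglik_null: float, loglik_alt: float):
    """Likelihood-ratio statistic and chi-square(1) upper-tail p-value.

    The alternative adds exactly one parameter (the TE interaction), so
    the reference distribution has one degree of freedom.  NaN
    log-likelihoods propagate to a missing p-value.
    """
    if not (np.isfinite(loglik_null) and np.isfinite(loglik_alt)):
        return np.nan, np.nan
    stat = 2.0 * max(0.0, loglik_alt - loglik_null)
    return stat, float(chi2.sf(stat, df=1))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, missing values preserved.

    ``m`` is the number of non-missing p-values; missing entries stay
    missing and do not enter the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        if np.any((p[mask] < 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def compute_te(norm_counts: np.ndarray, design: ExperimentDesign) -> pd.DataFrame:
    """Per-gene translation efficiency per condition and its log2 ratio.

    TE in a condition is the mean normalized RF count divided by the
    mean normalized RNA-Seq count over that condition's libraries.
    Whenever a denominator (or a numerator, for the log ratio) is zero
    the value is reported as missing.
    """
    rna = design.protocol_mask(Protocol.RNASEQ)
    rf = design.protocol_mask(Protocol.RIBO)
    treat = design.condition_mask(Condition.TREATMENT)
    out = {}
    for name, cmask in (("control", ~treat), ("treatment", treat)):
        num = norm_counts[:, rf & cmask].mean(axis=1)
        den = norm_counts[:, rna & cmask].mean(axis=1)
        te = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[f"TE_{name}"] = te
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["TE_treatment"] / out["TE_control"]
        out["log2FC_TE"] = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)
    return pd.DataFrame(out)


@dataclass
class PipelineResult:
    """Results table plus the fitted normalization and prior metadata."""

    table: pd.DataFrame
    size_factors: SizeFactors
    trend: dict = field(default_factory=dict)
    prior_sd: dict = field(default_factory=dict)
    mode: DispersionMode = DispersionMode.SEPARATE
    fdr: float = 0.1

    def significant_counts(self, fdr: float | None = None):
        """(up, down) counts at the FDR threshold, split by the sign of
        the log2 TE fold change; genes with a fold change of exactly
        zero count as neither."""
        fdr = self.fdr if fdr is None else fdr
        t = self.table
        sig = t["padj"].to_numpy() <= fdr
        lfc = t["log2FC_TE"].to_numpy()
        up = int(np.nansum(sig & (lfc > 0)))
        down = int(np.nansum(sig & (lfc < 0)))
        return up, down


def run_pipeline(
    joined: JoinedDataset,
    mode: DispersionMode = DispersionMode.SEPARATE,
    fdr: float = 0.1,
) -> PipelineResult:
    """Full differential translation-efficiency analysis.

    Per testable gene: alternating NB fit under the alternative model
    yields raw dispersions; a genome-wide mean-dispersion trend is
    fitted per dispersion group and gene-wise estimates are shrunk
    toward it; coefficients are then re-fitted under both hypotheses
    with the shrunken dispersions frozen (so the LRT statistic is
    structurally non-negative); finally chi-square p-values, BH
    adjustment and TE summaries are assembled into one table whose row
    order is the input gene order.  Per-gene fit failures are flagged
    and do not abort the run.
    """
    mode = DispersionMode(mode)
    design = joined.design
    sf = size_factors(joined, design)
    offsets = np.log(sf.factors)
    norm = joined.counts / sf.factors
    spec_alt = build_design(design, ModelKind.ALT)
    spec_null = build_design(design, ModelKind.NULL)
    groups = dispersion_groups(design, mode)
    n = joined.n_genes

    raw = {g: np.full(n, np.nan) for g in groups}
    boundary = {g: np.zeros(n, dtype=bool) for g in groups}
    abscissa = {g: np.full(n, np.nan) for g in groups}
    mu_store = np.full((n, design.n_samples), np.nan)
    beta_store: list = [None] * n
    flags = [list(f) for f in joined.flags]
    fit_ok = joined.testable.copy()

    for i in range(n):
        if not joined.testable[i]:
            continue
        y = joined.counts[i]
        try:
            # tight alternation tolerance keeps the test invariant to
            # relabelling the conditions (the stopping point of a looser
            # loop depends on the label encoding)
            fit, est = alternating_fit(
                y, spec_alt, offsets, mode=mode, tol=1e-11, max_outer=200
            )
        except Exception as exc:  # keep going; record the failure
            warnings.warn(f"fit failed for gene {joined.gene_ids[i]}: {exc}", stacklevel=2)
            flags[i].append("fit_error")
            fit_ok[i] = False
            continue
        if not fit.converged:
            flags[i].append("no_convergence")
        mu_store[i] = fit.mu_hat
        beta_store[i] = fit.beta
        for g, mask in groups.items():
            raw[g][i] = est[g].value
            boundary[g][i] = est[g].at_boundary
            abscissa[g][i] = norm[i, mask].mean()

    # genome-wide trend and shrinkage, once per dispersion group
    shrunk = {g: np.full(n, np.nan) for g in groups}
    trend_store = {g: np.full(n, np.nan) for g in groups}
    trend_coef: dict = {}
    prior: dict = {}
    for g, mask in groups.items():
        ok = fit_ok & np.isfinite(raw[g]) & (abscissa[g] > 0)
        try:
            lam0, lam1 = fit_trend(abscissa[g][ok], raw[g][ok])
        except TrendFitError:
            med = (
                float(np.median(raw[g][ok & ~boundary[g]]))
                if (ok & ~boundary[g]).any()
                else float(np.median(raw[g][ok]))
            )
            lam0, lam1 = np.clip(med, KAPPA_MIN, KAPPA_MAX), 0.0
            warnings.warn(
                f"too few genes for the {g} dispersion trend; "
                f"using a flat trend at the median raw dispersion {lam0:.3g}",
                stacklevel=2,
            )
        trend_coef[g] = (lam0, lam1)
        tk = trend_kappa(abscissa[g], lam0, lam1)
        trend_store[g] = np.where(fit_ok, tk, np.nan)
        sd = estimate_prior_sd(raw[g][ok], tk[ok])
        prior[g] = sd
        for i in np.flatnonzero(ok):
            shrunk[g][i] = shrink_dispersion(
                raw[g][i], tk[i], sd, joined.counts[i][mask], mu_store[i][mask]
            )
        rest = np.flatnonzero(fit_ok & ~ok)
        shrunk[g][rest] = raw[g][rest]
        for i in np.flatnonzero(fit_ok & boundary[g]):
            flags[i].append(f"boundary_{g}")

    # re-fit both hypotheses with shrunken dispersions frozen
    ll_null = np.full(n, np.nan)
    ll_alt = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    beta_te = np.full(n, np.nan)
    kv = np.empty(design.n_samples)
    for i in range(n):
        if not fit_ok[i]:
            continue
        for g, mask in groups.items():
            kv[mask] = shrunk[g][i]
        y = joined.counts[i]
        try:
            fa = fit_coefficients(y, spec_alt, offsets, kv, init=beta_store[i])
            fn = fit_coefficients(y, spec_null, offsets, kv)
            if fa.loglik < fn.loglik - _NESTING_SLACK:
                retry = fit_coefficients(
                    y, spec_alt, offsets, kv, init=np.append(fn.beta, 0.0)
                )
                if retry.loglik > fa.loglik:
                    fa = retry
        except Exception as exc:
            warnings.warn(
                f"re-fit failed for gene {joined.gene_ids[i]}: {exc}", stacklevel=2
            )
            flags[i].append("fit_error")
            fit_ok[i] = False
            continue
        ll_null[i], ll_alt[i] = fn.loglik, fa.loglik
        beta_te[i] = fa.beta[-1]
        stat[i], pval[i] = lrt_pvalue(fn.loglik, fa.loglik)

    padj = adjust_bh(pval)
    te = compute_te(norm, design)

    cols = {"geneID": joined.gene_ids}
    for g in groups:
        suffix = "" if g == "all" else f"_{g}"
        cols[f"dispersion_raw{suffix}"] = raw[g]
        cols[f"dispersion_trend{suffix}"] = trend_store[g]
        cols[f"dispersion_shrunken{suffix}"] = shrunk[g]
    cols.update(
        {
            "loglik_null": ll_null,
            "loglik_alt": ll_alt,
            "beta_te": beta_te,
            "lrt_stat": stat,
            "pval": pval,
            "padj": padj,
            "TE_control": te["TE_control"].to_numpy(),
            "TE_treatment": te["TE_treatment"].to_numpy(),
            "log2FC_TE": te["log2FC_TE"].to_numpy(),
            "flags": [";".join(f) if f else "." for f in flags],
        }
    )
    table = pd.DataFrame(cols)
    return PipelineResult(
        table=table,
        size_factors=sf,
        trend=trend_coef,
        prior_sd=prior,
        mode=mode,
        fdr=fdr,
    )


def write_results(result: PipelineResult, path) -> None:
    """Write the results TSV with size factors as comment header lines."""
    with open(path, "w") as fh:
        for sid, f in zip(result.size_factors.sample_ids, result.size_factors.factors):
            fh.write(f"# size_factor {sid} {f:.6g}\n")
        result.table.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")
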