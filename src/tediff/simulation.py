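"""Synthetic paired RNA-Seq / ribosome-footprint data with known truth.

The generator follows the model under test: per gene a baseline
expression level is drawn log-normally; RNA-Seq means equal that
baseline in both conditions (transcription unchanged unless the
``rna_effect_size`` knob is used), while RF means carry an additional
multiplicative translation-efficiency effect in the treatment
condition for the affected fraction of genes.  Counts are drawn from
negative binomials with protocol-specific dispersion — the defining
feature of the benchmark is that the RF libraries can be far more
dispersed than the RNA-Seq libraries.  All randomness flows from one
seeded generator.

The module also provides ROC evaluation against the simulated truth
and a Z-score baseline detector that scales each gene's TE log-ratio
by the spread among genes of similar expression — the classical
approach whose low-count bias motivates the likelihood model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm as normal_dist
from sklearn import metrics as _skmetrics

from .count_io import (
    Condition,
    CountTable,
    ExperimentDesign,
    JoinedDataset,
    Protocol,
    ValidationError,
)
from .normalization import size_factors

#: dispersion below which counts are drawn as Poisson
_POISSON_EPS = 1e-8

KappaSpec = Union[float, tuple]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic experiment.

    Defaults describe the benchmark regime this framework targets: a
    genome-scale set of genes with log-normal baseline expression
    around 100 reads, lightly dispersed RNA-Seq counts, strongly
    dispersed RF counts (a 50-fold dispersion gap), ten percent of
    genes with a four-fold translation-efficiency change, and three
    replicates per (protocol, condition) group.

    ``kappa_rna`` / ``kappa_rf`` are either scalars or ``(lambda0,
    lambda1)`` pairs giving a mean-dependent dispersion
    ``lambda0 + lambda1 / mu``.  ``effect_direction`` chooses whether
    affected genes go up, down, or either with equal probability.
    """

    n_genes: int = 2000
    replicates: int = 3
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.5
    kappa_rna: KappaSpec = 0.01
    kappa_rf: KappaSpec = 0.5
    fraction_affected: float = 0.1
    effect_size: float = math.log(4.0)
    effect_direction: str = "both"
    rna_effect_size: float = 0.0
    te_base: float = 1.0
    library_multipliers: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValidationError("fraction_affected must lie in [0, 1]")
        if self.n_genes < 1 or self.replicates < 1:
            raise ValidationError("n_genes and replicates must be positive")
        if self.effect_direction not in ("up", "down", "both"):
            raise ValidationError("effect_direction must be 'up', 'down' or 'both'")
        if self.te_base <= 0:
            raise ValidationError("te_base must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, aligned with its genes."""

    gene_ids: list
    affected: np.ndarray
    true_log_te_fc: np.ndarray  # natural-log TE fold change (treatment/control)
    baseline_mean: np.ndarray
    kappa_rna: np.ndarray
    kappa_rf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "affected": self.affected.astype(int),
                "true_log2_te_fc": self.true_log_te_fc / math.log(2.0),
                "baseline_mean": self.baseline_mean,
                "kappa_rna": self.kappa_rna,
                "kappa_rf": self.kappa_rf,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=[str(g) for g in df["gene_id"]],
            affected=df["affected"].to_numpy(bool),
            true_log_te_fc=df["true_log2_te_fc"].to_numpy(float) * math.log(2.0),
            baseline_mean=df["baseline_mean"].to_numpy(float),
            kappa_rna=df["kappa_rna"].to_numpy(float),
            kappa_rf=df["kappa_rf"].to_numpy(float),
        )


def _kappa_per_gene(spec: KappaSpec, mu: np.ndarray) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(mu.shape, float(spec))
    lam0, lam1 = spec
    return lam0 + lam1 / mu


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    out = np.empty(mean.shape, dtype=np.int64)
    pois = kappa < _POISSON_EPS
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / kappa[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_dataset(cfg: SimConfig):
    """Draw one synthetic experiment under the NB interaction model.

    Returns
    -------
    (rna, ribo, design, truth)
        Two :class:`CountTable` objects, the matching
        :class:`ExperimentDesign`, and the :class:`SimTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    n_affected = int(round(cfg.fraction_affected * n))
    affected = np.zeros(n, dtype=bool)
    if n_affected:
        affected[rng.choice(n, size=n_affected, replace=False)] = True
    beta_delta = np.zeros(n)
    if cfg.effect_direction == "up":
        sign = np.ones(n)
    elif cfg.effect_direction == "down":
        sign = -np.ones(n)
    else:
        sign = rng.choice([-1.0, 1.0], size=n)
    beta_delta[affected] = cfg.effect_size * sign[affected]
    rna_shift = np.zeros(n)
    if cfg.rna_effect_size:
        rna_shift[affected] = cfg.rna_effect_size * rng.choice([-1.0, 1.0], size=n)[affected]

    kap_rna = np.clip(_kappa_per_gene(cfg.kappa_rna, mu), 0.0, np.inf)
    kap_rf = np.clip(_kappa_per_gene(cfg.kappa_rf, mu), 0.0, np.inf)

    layout = []  # (protocol, condition, replicate)
    for protocol in (Protocol.RNASEQ, Protocol.RIBO):
        for condition in (Condition.CONTROL, Condition.TREATMENT):
            for r in range(cfg.replicates):
                layout.append((protocol, condition, r))
    n_samples = len(layout)
    if cfg.library_multipliers is None:
        mult = np.ones(n_samples)
    else:
        mult = np.asarray(cfg.library_multipliers, dtype=float)
        if mult.shape != (n_samples,) or np.any(mult <= 0):
            raise ValidationError(
                f"library_multipliers must be {n_samples} positive values"
            )

    sample_ids, protocols, conditions = [], [], []
    columns = []
    for j, (protocol, condition, r) in enumerate(layout):
        tag = "rna" if protocol == Protocol.RNASEQ else "rf"
        cond = "ctrl" if condition == Condition.CONTROL else "trt"
        sample_ids.append(f"{tag}_{cond}_{r + 1}")
        protocols.append(protocol)
        conditions.append(condition)
        treat = float(condition == Condition.TREATMENT)
        if protocol == Protocol.RNASEQ:
            mean_j = mu * np.exp(rna_shift * treat)
            kap = kap_rna
        else:
            mean_j = mu * np.exp(rna_shift * treat) * cfg.te_base * np.exp(beta_delta * treat)
            kap = kap_rf
        columns.append(_draw_nb(rng, mean_j * mult[j], kap))
    counts = np.column_stack(columns)

    rna_mask = np.array([p == Protocol.RNASEQ for p in protocols])
    rna = CountTable(gene_ids, [s for s, m in zip(sample_ids, rna_mask) if m], counts[:, rna_mask])
    ribo = CountTable(
        gene_ids, [s for s, m in zip(sample_ids, rna_mask) if not m], counts[:, ~rna_mask]
    )
    design = ExperimentDesign(tuple(sample_ids), tuple(protocols), tuple(conditions))
    truth = SimTruth(
        gene_ids=gene_ids,
        affected=affected,
        true_log_te_fc=beta_delta,
        baseline_mean=mu,
        kappa_rna=kap_rna,
        kappa_rf=kap_rf,
    )
    return rna, ribo, design, truth


def roc_curve(scores, truth, higher_is_better: bool = False):
    """ROC points and AUC of per-gene scores against the truth labels.

    ``scores`` follow the p-value convention by default (smaller means
    stronger evidence); pass ``higher_is_better=True`` for statistics.
    Missing scores are assigned the least significant rank.

    Returns
    -------
    (fpr, tpr, auc)
    """
    labels = truth.affected if isinstance(truth, SimTruth) else np.asarray(truth, bool)
    s = np.asarray(scores, dtype=float).copy()
    if labels.shape != s.shape:
        raise ValidationError("scores not aligned with truth")
    if labels.all() or not labels.any():
        raise ValidationError("truth must contain both affected and unaffected genes")
    if not higher_is_better:
        s = -s
    worst = np.nanmin(s) - 1.0 if np.isfinite(np.nanmin(s)) else 0.0
    s = np.where(np.isfinite(s), s, worst)
    fpr, tpr, _ = _skmetrics.roc_curve(labels.astype(int), s)
    return fpr, tpr, float(_skmetrics.auc(fpr, tpr))


def zscore_baseline(joined: JoinedDataset, n_bins: int = 20) -> pd.DataFrame:
    """Z-score detector: standardized TE log-ratio within expression bins.

    Each gene's difference of log TE between treatment and control is
    centred and scaled by the mean and standard deviation of that
    difference among genes in the same mRNA-expression bin (equal-
    occupancy bins over the mean normalized RNA-Seq count; under-filled
    bins are merged with a neighbour).  ``n_bins=1`` gives the unbinned
    statistic, which over-weights lowly expressed genes.  Two-sided
    normal p-values are attached.
    """
    design = joined.design
    sf = size_factors(joined, design)
    norm = joined.counts / sf.factors
    rna = design.protocol_mask(Protocol.RNASEQ)
    rf = design.protocol_mask(Protocol.RIBO)
    treat = design.condition_mask(Condition.TREATMENT)

    means = {}
    for label, mask in (
        ("rna_c", rna & ~treat),
        ("rna_t", rna & treat),
        ("rf_c", rf & ~treat),
        ("rf_t", rf & treat),
    ):
        means[label] = norm[:, mask].mean(axis=1)
    valid = joined.testable & np.all(
        np.column_stack([means[k] > 0 for k in means]), axis=1
    )
    d = np.full(joined.n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        lte_c = np.log(means["rf_c"] / means["rna_c"])
        lte_t = np.log(means["rf_t"] / means["rna_t"])
    d[valid] = (lte_t - lte_c)[valid]

    abscissa = norm[:, rna].mean(axis=1)
    bin_id = np.full(joined.n_genes, -1)
    if valid.any():
        ranks = pd.Series(abscissa[valid]).rank(method="first").to_numpy()
        k = min(n_bins, int(valid.sum()))
        ids = np.minimum((ranks - 1) * k // int(valid.sum()), k - 1).astype(int)
        bin_id[valid] = ids
        # merge bins too small to estimate a spread
        for b in range(k):
            if 0 < (bin_id == b).sum() < 3 and k > 1:
                neighbor = b - 1 if b > 0 else b + 1
                bin_id[bin_id == b] = neighbor

    z = np.full(joined.n_genes, np.nan)
    for b in np.unique(bin_id[bin_id >= 0]):
        m = bin_id == b
        vals = d[m]
        sd = vals.std(ddof=1)
        if sd > 0:
            z[m] = (vals - vals.mean()) / sd
    p = 2.0 * normal_dist.sf(np.abs(z))
    return pd.DataFrame(
        {
            "gene_id": joined.gene_ids,
            "z": z,
            "pvalue": p,
            "bin": bin_id,
            "mean_rna": abscissa,
        }
    )
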