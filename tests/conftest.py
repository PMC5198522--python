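import numpy as np
import pytest
from scipy.special import gammaln

from tediff import (
    Condition,
    CountTable,
    ExperimentDesign,
    Protocol,
    join_datasets,
)


def make_design(rna_reps=3, rf_reps=None):
    """Balanced design: ``rna_reps`` per RNA condition, ``rf_reps`` per RF."""
    rf_reps = rna_reps if rf_reps is None else rf_reps
    ids, prot, cond = [], [], []
    for p, tag, reps in ((Protocol.RNASEQ, "rna", rna_reps), (Protocol.RIBO, "rf", rf_reps)):
        for c, ctag in ((Condition.CONTROL, "c"), (Condition.TREATMENT, "t")):
            for r in range(reps):
                ids.append(f"{tag}_{ctag}{r + 1}")
                prot.append(p)
                cond.append(c)
    return ExperimentDesign(tuple(ids), tuple(prot), tuple(cond))


def make_joined(rna_counts, ribo_counts, design, gene_ids=None):
    """Assemble a JoinedDataset from two count matrices and a design."""
    rna_counts = np.asarray(rna_counts)
    ribo_counts = np.asarray(ribo_counts)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(rna_counts.shape[0])]
    n_rna = rna_counts.shape[1]
    rna = CountTable(gene_ids, list(design.sample_ids[:n_rna]), rna_counts)
    ribo = CountTable(gene_ids, list(design.sample_ids[n_rna:]), ribo_counts)
    return join_datasets(rna, ribo, design)


def grid_refine_loglik(y, X, offsets, kappa, center, span=3.0, rounds=10, points=9):
    """Independent oracle: maximize the NB log-likelihood over the
    coefficient space by iteratively refined dense grid search."""
    y = np.asarray(y, float)
    offsets = np.asarray(offsets, float)
    kappa = np.broadcast_to(np.asarray(kappa, float), y.shape)
    r = 1.0 / kappa
    const = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)).sum()
    center = np.asarray(center, float).copy()
    best_ll = -np.inf
    for _ in range(rounds):
        axes = [np.linspace(c - span, c + span, points) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=-1)
        eta = np.clip(offsets + grid @ X.T, np.log(1e-8), 45.0)
        mu = np.exp(eta)
        ll = const + (r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))).sum(axis=1)
        i = int(np.argmax(ll))
        best_ll = ll[i]
        center = grid[i]
        span /= 2.5
    return best_ll, center


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
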