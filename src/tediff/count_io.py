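"""Reading, validation and joining of paired RNA-Seq / ribosome-footprint count tables.

A translation-efficiency experiment produces two gene-by-sample count
matrices: one from RNA-Seq libraries (mRNA abundance) and one from
ribosome-footprint (RF) libraries (ribosome occupancy).  An experiment
design maps every sample column to its sequencing protocol and to a
condition (control or treatment).  This module reads the plain-text
tables, enforces the invariants the model relies on (non-negative
integer counts, unique identifiers, at least one replicated group per
protocol) and joins the two matrices on the shared gene set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A cell of an input table could not be interpreted."""


class ValidationError(ValueError):
    """An input violates a structural invariant of the model."""


class Protocol(str, enum.Enum):
    """Sequencing protocol of a library."""

    RNASEQ = "RNA"
    RIBO = "RF"


class Condition(enum.IntEnum):
    """Experimental condition of a library."""

    CONTROL = 0
    TREATMENT = 1


_PROTOCOL_ALIASES = {
    "rna": Protocol.RNASEQ,
    "rnaseq": Protocol.RNASEQ,
    "rna-seq": Protocol.RNASEQ,
    "rna_seq": Protocol.RNASEQ,
    "mrna": Protocol.RNASEQ,
    "rf": Protocol.RIBO,
    "ribo": Protocol.RIBO,
    "riboseq": Protocol.RIBO,
    "ribo-seq": Protocol.RIBO,
}

_CONDITION_ALIASES = {
    "control": Condition.CONTROL,
    "ctrl": Condition.CONTROL,
    "0": Condition.CONTROL,
    "treatment": Condition.TREATMENT,
    "treated": Condition.TREATMENT,
    "treat": Condition.TREATMENT,
    "1": Condition.TREATMENT,
}


@dataclass
class CountTable:
    """Gene-by-sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, in file order.
    sample_ids : list of str
        Column identifiers, unique, in file order.
    counts : ndarray of int, shape (n_genes, n_samples)
    """

    gene_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicated gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicated sample id {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def write(self, path, delimiter: str = "\t") -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep=delimiter)


def _first_duplicate(items: Sequence) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_count_table(path, delimiter: str = "\t") -> CountTable:
    """Read a gene-by-sample count table from a delimited text file.

    The first column holds gene identifiers (its header is ignored), the
    header row holds sample identifiers, and all remaining cells must be
    non-negative integers.

    Raises
    ------
    ParseError
        If a cell is non-numeric, negative, or non-integral; the error
        names the offending gene and sample.
    ValidationError
        If a gene or sample identifier is duplicated.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(
            f"duplicated gene id {_first_duplicate(gene_ids)!r} in {path}"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(
            f"duplicated sample id {_first_duplicate(sample_ids)!r} in {path}"
        )
    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce")).to_numpy(float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric count {raw.iat[i, j]!r} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"negative count at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    if (np.mod(values, 1) != 0).any():
        i, j = np.argwhere(np.mod(values, 1) != 0)[0]
        raise ParseError(
            f"non-integer count {values[i, j]} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return CountTable(gene_ids, sample_ids, values.astype(np.int64))


@dataclass(frozen=True)
class ExperimentDesign:
    """Assignment of each sample to a (protocol, condition) group.

    Sample identifiers are globally unique across the two protocols.
    Every one of the four (protocol, condition) groups must contain at
    least one sample, and within each protocol at least one condition
    must be replicated (two or more samples), otherwise the dispersion
    is inestimable.
    """

    sample_ids: tuple
    protocols: tuple
    conditions: tuple

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "protocols", tuple(self.protocols))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not (len(self.sample_ids) == len(self.protocols) == len(self.conditions)):
            raise ValidationError("design columns have unequal lengths")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError(
                f"duplicated sample id {_first_duplicate(self.sample_ids)!r} in design"
            )
        counts = {}
        for p, c in zip(self.protocols, self.conditions):
            counts[(p, c)] = counts.get((p, c), 0) + 1
        for p in (Protocol.RNASEQ, Protocol.RIBO):
            for c in (Condition.CONTROL, Condition.TREATMENT):
                if counts.get((p, c), 0) < 1:
                    raise ValidationError(
                        f"design has no sample for protocol={p.value}, "
                        f"condition={c.name.lower()}"
                    )
            if max(counts[(p, Condition.CONTROL)], counts[(p, Condition.TREATMENT)]) < 2:
                raise ValidationError(
                    f"protocol {p.value} has no replicated condition; "
                    "dispersion cannot be estimated"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def protocol_mask(self, protocol: Protocol) -> np.ndarray:
        return np.array([p == protocol for p in self.protocols], dtype=bool)

    def condition_mask(self, condition: Condition) -> np.ndarray:
        return np.array([c == condition for c in self.conditions], dtype=bool)

    def subset(self, sample_ids: Sequence[str]) -> "ExperimentDesign":
        """Design restricted to ``sample_ids``, in the order given."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        idx = [index[s] for s in sample_ids]
        return ExperimentDesign(
            tuple(self.sample_ids[i] for i in idx),
            tuple(self.protocols[i] for i in idx),
            tuple(self.conditions[i] for i in idx),
        )

    def swap_conditions(self) -> "ExperimentDesign":
        flip = {
            Condition.CONTROL: Condition.TREATMENT,
            Condition.TREATMENT: Condition.CONTROL,
        }
        return ExperimentDesign(
            self.sample_ids, self.protocols, tuple(flip[c] for c in self.conditions)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "protocol": [p.value for p in self.protocols],
                "condition": [
                    "control" if c == Condition.CONTROL else "treatment"
                    for c in self.conditions
                ],
            }
        )

    def write(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def read_design(path) -> ExperimentDesign:
    """Read an experiment design table (CSV or TSV, delimiter sniffed).

    Required columns: ``sample_id``, ``protocol`` ("RNA" or "RF", with
    common aliases accepted), ``condition`` ("control" or "treatment").
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "protocol", "condition"):
        if col not in df.columns:
            raise ValidationError(f"design file missing column {col!r}")
    protocols = []
    conditions = []
    for _, row in df.iterrows():
        p = _PROTOCOL_ALIASES.get(str(row["protocol"]).strip().lower())
        if p is None:
            raise ParseError(
                f"unknown protocol {row['protocol']!r} for sample {row['sample_id']!r}"
            )
        c = _CONDITION_ALIASES.get(str(row["condition"]).strip().lower())
        if c is None:
            raise ParseError(
                f"unknown condition {row['condition']!r} for sample {row['sample_id']!r}"
            )
        protocols.append(p)
        conditions.append(c)
    return ExperimentDesign(
        tuple(str(s).strip() for s in df["sample_id"]), tuple(protocols), tuple(conditions)
    )


# Per-gene flags used downstream.
FLAG_ALL_ZERO = "all_zero"
FLAG_ZERO_RNA = "zero_rna"
FLAG_ZERO_RF = "zero_rf"
FLAG_ZERO_GROUP = "zero_group"


@dataclass
class JoinedDataset:
    """The two count tables joined on their shared gene set.

    Columns are ordered RNA-Seq samples first (in the RNA table's
    order), then RF samples; ``design`` is reordered to match.  A gene
    is testable only when it carries reads in both protocols; genes
    that are all-zero overall or within one protocol are flagged and
    excluded from testing (their p-values are reported as missing).
    """

    gene_ids: list
    sample_ids: list
    counts: np.ndarray
    design: ExperimentDesign
    testable: np.ndarray
    flags: list

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def join_datasets(
    rna: CountTable, ribo: CountTable, design: ExperimentDesign
) -> JoinedDataset:
    """Join RNA-Seq and RF count tables on their common genes.

    The joined gene set is the intersection of the two tables' gene
    sets, ordered as in the RNA table.  Raises on an empty intersection
    or on samples missing from the design.
    """
    overlap = set(rna.sample_ids) & set(ribo.sample_ids)
    if overlap:
        raise ValidationError(
            f"sample ids shared between tables (must be unique): {sorted(overlap)[:3]}"
        )
    all_samples = list(rna.sample_ids) + list(ribo.sample_ids)
    design_index = set(design.sample_ids)
    missing = [s for s in all_samples if s not in design_index]
    if missing:
        raise ValidationError(f"samples absent from design: {missing[:5]}")
    sub = design.subset(all_samples)
    for sid, p in zip(rna.sample_ids, sub.protocols[: rna.n_samples]):
        if p != Protocol.RNASEQ:
            raise ValidationError(
                f"sample {sid!r} is in the RNA-Seq table but labelled {p.value} in design"
            )
    for sid, p in zip(ribo.sample_ids, sub.protocols[rna.n_samples :]):
        if p != Protocol.RIBO:
            raise ValidationError(
                f"sample {sid!r} is in the RF table but labelled {p.value} in design"
            )

    ribo_rows = {g: i for i, g in enumerate(ribo.gene_ids)}
    gene_ids = [g for g in rna.gene_ids if g in ribo_rows]
    if not gene_ids:
        raise ValidationError("no genes shared between the RNA-Seq and RF tables")
    rna_rows = {g: i for i, g in enumerate(rna.gene_ids)}
    ri = [rna_rows[g] for g in gene_ids]
    bi = [ribo_rows[g] for g in gene_ids]
    counts = np.hstack([rna.counts[ri], ribo.counts[bi]]).astype(np.int64)

    rna_mask = sub.protocol_mask(Protocol.RNASEQ)
    rf_mask = sub.protocol_mask(Protocol.RIBO)
    treat_mask = sub.condition_mask(Condition.TREATMENT)
    rna_tot = counts[:, rna_mask].sum(axis=1)
    rf_tot = counts[:, rf_mask].sum(axis=1)

    testable = np.ones(len(gene_ids), dtype=bool)
    flags: list = [[] for _ in gene_ids]
    group_masks = [
        rna_mask & ~treat_mask,
        rna_mask & treat_mask,
        rf_mask & ~treat_mask,
        rf_mask & treat_mask,
    ]
    for i in range(len(gene_ids)):
        if rna_tot[i] == 0 and rf_tot[i] == 0:
            flags[i].append(FLAG_ALL_ZERO)
            testable[i] = False
            continue
        if rna_tot[i] == 0:
            flags[i].append(FLAG_ZERO_RNA)
            testable[i] = False
            continue
        if rf_tot[i] == 0:
            flags[i].append(FLAG_ZERO_RF)
            testable[i] = False
            continue
        if any(counts[i, m].sum() == 0 for m in group_masks):
            flags[i].append(FLAG_ZERO_GROUP)
    return JoinedDataset(gene_ids, all_samples, counts, sub, testable, flags)
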