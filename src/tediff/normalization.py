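"""Library-size normalization via median-of-ratios size factors.

RNA-Seq and ribosome-footprint libraries have very different depth
characteristics, so size factors are estimated independently within
each protocol.  For a protocol the reference pseudo-sample is the
per-gene geometric mean over that protocol's libraries, computed on
genes with strictly positive counts in all of them; each library's
factor is the median across reference genes of count/reference.
Factors are rescaled so their geometric mean within a protocol is 1 —
the absolute scale is absorbed by the GLM's protocol coefficients.

Size factors enter the model as offsets on the log scale, never by
dividing the raw counts used in the likelihood; normalized counts are
used only for reporting translation efficiencies and as the abscissa
of the dispersion trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .count_io import ExperimentDesign, Protocol, ValidationError


@dataclass(frozen=True)
class SizeFactors:
    """Per-library positive scale factors, aligned with ``sample_ids``."""

    sample_ids: tuple
    factors: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if f.shape != (len(self.sample_ids),):
            raise ValidationError("size factors not aligned with sample ids")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("size factors must be positive and finite")


def _protocol_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios factors for one protocol's columns."""
    counts = np.asarray(counts, dtype=float)
    all_positive = np.all(counts > 0, axis=1)
    if all_positive.any():
        ref = np.exp(np.mean(np.log(counts[all_positive]), axis=1))
        ratios = counts[all_positive] / ref[:, None]
    else:
        # Fallback reference set: genes positive in at least half the
        # libraries, geometric mean over their positive entries only.
        pos_frac = np.mean(counts > 0, axis=1)
        usable = pos_frac >= 0.5
        if not usable.any():
            raise ValidationError(
                "no gene is sufficiently covered to build a size-factor "
                "reference; relax the reference set or provide deeper libraries"
            )
        warnings.warn(
            "no gene has positive counts in every library of a protocol; "
            "falling back to genes covered in >= 50% of its libraries",
            stacklevel=2,
        )
        sub = counts[usable]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValidationError(
            "degenerate size factor (a library shares no covered genes "
            "with the reference)"
        )
    # identifiability: geometric mean 1 within the protocol
    return factors / np.exp(np.mean(np.log(factors)))


def size_factors(counts, design: ExperimentDesign) -> SizeFactors:
    """Estimate per-library size factors, independently per protocol.

    Parameters
    ----------
    counts : CountTable or JoinedDataset
        Any object with ``counts`` (genes x samples) and ``sample_ids``.
    design : ExperimentDesign
        Must cover every sample in ``counts``.
    """
    matrix = np.asarray(counts.counts, dtype=float)
    sample_ids = list(counts.sample_ids)
    sub = design.subset(sample_ids)
    factors = np.empty(len(sample_ids), dtype=float)
    for protocol in (Protocol.RNASEQ, Protocol.RIBO):
        mask = sub.protocol_mask(protocol)
        if mask.any():
            factors[mask] = _protocol_factors(matrix[:, mask])
    return SizeFactors(tuple(sample_ids), factors)


def normalized_counts(counts, sf: SizeFactors) -> np.ndarray:
    """Counts divided by their library's size factor (reporting scale)."""
    if tuple(counts.sample_ids) != tuple(sf.sample_ids):
        raise ValidationError("size factors not aligned with count table samples")
    return np.asarray(counts.counts, dtype=float) / sf.factors
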