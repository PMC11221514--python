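"""Interval quantification and normalization.

Counting is a coverage sum over intervals (a desk-scale stand-in for
read counting); TPM and RPKM share that counting core.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack

__all__ = [
    "count_over_intervals",
    "tpm_normalize",
    "rpkm_normalize",
    "read_depth_ratio",
    "log2_condition_ratio",
]


def count_over_intervals(coverage: CoverageTrack, intervals) -> pd.DataFrame:
    """Sum per-base depth over intervals.

    ``intervals`` is an iterable of (feature_id, chrom, start, end,
    strand); on a stranded track the matching strand is counted.
    Returns a DataFrame indexed by feature_id with ``count`` and
    ``length`` columns.
    """
    rows = {}
    for feature_id, chrom, start, end, strand in intervals:
        n = coverage.chrom_sizes.get(chrom)
        if n is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > n or start >= end:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        depth = coverage.depth(chrom, strand if coverage.stranded else None)
        rows[feature_id] = (float(depth[start:end].sum()), end - start)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["count", "length"])
    df.index.name = "feature_id"
    return df


def tpm_normalize(counts: pd.DataFrame) -> pd.Series:
    """Transcripts-per-million from a count/length table.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum(rate).
    An all-zero sample yields an all-zero column with a warning.
    """
    if (counts["length"] <= 0).any():
        raise ValueError("all feature lengths must be positive")
    rate = counts["count"] / counts["length"]
    total = rate.sum()
    if total == 0:
        warnings.warn("all-zero sample: TPM undefined, returning zeros")
        return rate * 0.0
    return 1e6 * (rate / total)


def rpkm_normalize(counts: pd.DataFrame, library_size: float | None = None) -> pd.Series:
    """Reads per kilobase per million mapped; ``library_size`` defaults
    to the sum of counts in the table."""
    if library_size is None:
        library_size = float(counts["count"].sum())
    if library_size == 0:
        warnings.warn("zero library size: RPKM undefined, returning zeros")
        return counts["count"] * 0.0
    return counts["count"] / (counts["length"] / 1e3) / (library_size / 1e6)


def read_depth_ratio(gene_tpm, dog_tpm, orientation: str = "dog_over_gene") -> float:
    """Ratio of median readthrough TPM to median host-gene TPM over
    paired DoG-producing genes.

    The orientation of the ratio is explicit because either convention
    appears in practice; ``gene_over_dog`` inverts it.  Returns NaN when
    the denominator median is zero.
    """
    gene_tpm = np.asarray(gene_tpm, dtype=float)
    dog_tpm = np.asarray(dog_tpm, dtype=float)
    if gene_tpm.size == 0 or gene_tpm.size != dog_tpm.size:
        raise ValueError("gene and DoG TPM vectors must be paired and non-empty")
    med_gene, med_dog = np.median(gene_tpm), np.median(dog_tpm)
    if orientation == "dog_over_gene":
        num, den = med_dog, med_gene
    elif orientation == "gene_over_dog":
        num, den = med_gene, med_dog
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(num / den) if den != 0 else float("nan")


def log2_condition_ratio(a, b, pseudocount: float = 1.0):
    """Per-feature log2((a + pc) / (b + pc)) between matched expression
    columns; the pseudocount keeps condition-specific features finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise ValueError("features of a and b do not match")
    return np.log2((a + pseudocount) / (b + pseudocount))
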