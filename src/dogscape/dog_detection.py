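"""Readthrough (downstream-of-gene, DoG) region calling.

A DoG is called when consecutive fixed-width windows immediately
downstream of a gene's transcription end site (TES) each show at least
``min_dog_cov`` of their bases with non-zero signal, and the run of
passing windows — which must begin at the TES itself — spans at least
``min_dog_len`` bases.  The run length is the region's *extension
strength* and is window-quantized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, DoGParams, GeneModel

__all__ = [
    "DoGCall",
    "DoGSetComparison",
    "call_dogs",
    "filter_adjacent_genes",
    "compare_dog_sets",
    "write_dog_bed",
    "read_dog_bed",
    "write_dog_gtf",
]


@dataclass(frozen=True)
class DoGCall:
    """A called readthrough region abutting its host gene's TES.

    ``dog_start``/``dog_end`` are 0-based half-open; on '+' the region
    is [TES, TES + extension) and on '-' it is [TES - extension, TES).
    """

    host_gene_id: str
    chrom: str
    strand: str
    dog_start: int
    dog_end: int
    n_windows: int

    @property
    def extension_strength(self) -> int:
        return self.dog_end - self.dog_start


@dataclass(frozen=True)
class DoGSetComparison:
    set_a_only: frozenset
    set_b_only: frozenset
    shared: frozenset

    @property
    def n_a_only(self) -> int:
        return len(self.set_a_only)

    @property
    def n_b_only(self) -> int:
        return len(self.set_b_only)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def _window_passes(depth: np.ndarray, min_cov: float) -> bool:
    return (depth > 0).mean() >= min_cov


def call_dogs(
    genes,
    coverage: CoverageTrack,
    params: DoGParams | None = None,
) -> list[DoGCall]:
    """Scan downstream of each gene's TES for a readthrough region.

    Windows are walked in the direction of transcription starting at the
    TES; the first failing window (or the chromosome edge, or a partial
    trailing window) ends the run.  A call is emitted when the run is at
    least ``params.min_dog_len`` bases.  On a stranded track the host
    gene's strand selects the signal; an unstranded track is used as-is.

    Genes whose TES leaves no room for a single full window are skipped
    with a warning.
    """
    if params is None:
        params = DoGParams()
    w = params.window
    calls: list[DoGCall] = []
    for g in genes:
        chrom_len = coverage.chrom_sizes.get(g.chrom)
        if chrom_len is None:
            raise KeyError(f"coverage lacks chromosome {g.chrom!r} for {g.gene_id}")
        depth = coverage.depth(g.chrom, g.strand if coverage.stranded else None)
        if g.strand == "+":
            room = (chrom_len - g.tes) // w
        else:
            room = g.tes // w
        if room < 1:
            warnings.warn(
                f"{g.gene_id}: no room for one {w}-bp window downstream of TES; skipped"
            )
            continue
        n_pass = 0
        for i in range(room):
            if g.strand == "+":
                s = g.tes + i * w
                win = depth[s : s + w]
            else:
                e = g.tes - i * w
                win = depth[e - w : e]
            if _window_passes(win, params.min_dog_cov):
                n_pass += 1
            else:
                break
        ext = n_pass * w
        if ext >= params.min_dog_len:
            if g.strand == "+":
                start, end = g.tes, g.tes + ext
            else:
                start, end = g.tes - ext, g.tes
            calls.append(DoGCall(g.gene_id, g.chrom, g.strand, start, end, n_pass))
    return calls


def filter_adjacent_genes(
    calls,
    genes,
    params: DoGParams | None = None,
    stranded: bool = False,
) -> list[DoGCall]:
    """Drop calls whose host has another gene annotated within
    ``adjacent_filter_distance`` downstream of the TES.

    The exclusion interval is (TES, TES + d] in the direction of
    transcription; any other gene overlapping it triggers removal.  In
    stranded mode only genes on the host's strand count (an antisense
    neighbour cannot contaminate strand-resolved readthrough signal);
    unstranded mode ignores strand.  Non-increasing and idempotent.
    """
    if params is None:
        params = DoGParams()
    d = params.adjacent_filter_distance
    genes = list(genes)
    chroms = np.array([g.chrom for g in genes])
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    strands = np.array([g.strand for g in genes])
    ids = np.array([g.gene_id for g in genes])

    kept = []
    for call in calls:
        if call.strand == "+":
            lo, hi = call.dog_start, call.dog_start + d  # (TES, TES+d]
        else:
            lo, hi = call.dog_end - d, call.dog_end
        mask = (
            (chroms == call.chrom)
            & (ids != call.host_gene_id)
            & (starts < hi)
            & (ends > lo)
        )
        if stranded:
            mask &= strands == call.strand
        if not mask.any():
            kept.append(call)
    return kept


def compare_dog_sets(a, b) -> DoGSetComparison:
    """Partition two sets of DoG host gene ids into condition-specific
    and shared hosts."""
    a, b = frozenset(a), frozenset(b)
    return DoGSetComparison(
        set_a_only=a - b, set_b_only=b - a, shared=a & b
    )


def write_dog_bed(calls, path) -> None:
    """BED6: chrom, start, end, host gene id, extension strength, strand."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.dog_start)):
            fh.write(
                f"{c.chrom}\t{c.dog_start}\t{c.dog_end}\t{c.host_gene_id}\t"
                f"{c.extension_strength}\t{c.strand}\n"
            )


def read_dog_bed(path, window: int = 200) -> list[DoGCall]:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str},
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        DoGCall(
            host_gene_id=r.name, chrom=r.chrom, strand=r.strand,
            dog_start=int(r.start), dog_end=int(r.end),
            n_windows=(int(r.end) - int(r.start)) // window,
        )
        for r in df.itertuples(index=False)
    ]


def write_dog_gtf(calls, path) -> None:
    """One ``exon`` feature per DoG, for interval counting downstream."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.dog_start)):
            attrs = f'gene_id "do{c.host_gene_id}";'
            fh.write(
                f"{c.chrom}\tdogscape\texon\t{c.dog_start + 1}\t{c.dog_end}\t.\t"
                f"{c.strand}\t.\t{attrs}\n"
            )
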