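"""RNAPII pausing indices and metagene profiles from occupancy coverage.

The pause index (PI) at a site is the signal density in a short pause
window divided by the density in a longer reference window:

    PI_TSS = (counts in [TSS-50, TSS+300) / 350)
             / (counts in [TSS+300, gene end) / body length)

    PI_TES = (counts in [TES+500, TES+1500) / 1000)
             / (counts in [TES+1500, downstream end) / its length)

where the TES downstream end is the end of the gene's readthrough
region when one exists, or TES+10,000 otherwise.  All offsets follow
the direction of transcription.  A gene with PI > 2 is flagged paused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel

__all__ = [
    "PauseWindows",
    "PauseIndexRecord",
    "pause_index",
    "pause_index_table",
    "expression_quartile_groups",
    "compute_metaprofile",
]

PAUSED_PI_THRESHOLD = 2.0


@dataclass(frozen=True)
class PauseWindows:
    """Window offsets (bases, in the direction of transcription).

    TSS pause window: [tss + tss_pause_up, tss + tss_pause_down), body
    from tss + tss_pause_down to the gene end.  TES pause window:
    [tes + tes_pause_start, tes + tes_pause_end), downstream reference
    from tes + tes_pause_end to the end of the readthrough region (DoG
    genes) or tes + tes_downstream_end (others).  Alternate presets
    (e.g. 0-3 kb vs 3-8 kb past the TES) are built by overriding the
    TES offsets.
    """

    tss_pause_up: int = -50
    tss_pause_down: int = 300
    tes_pause_start: int = 500
    tes_pause_end: int = 1500
    tes_downstream_end: int = 10_000


@dataclass
class PauseIndexRecord:
    gene_id: str
    pi_tss: float = float("nan")
    pi_tes: float = float("nan")
    tss_pause_count: float = float("nan")
    tss_body_count: float = float("nan")
    tes_pause_count: float = float("nan")
    tes_downstream_count: float = float("nan")

    @property
    def paused_tss(self) -> bool | None:
        return None if np.isnan(self.pi_tss) else bool(self.pi_tss > PAUSED_PI_THRESHOLD)

    @property
    def paused_tes(self) -> bool | None:
        return None if np.isnan(self.pi_tes) else bool(self.pi_tes > PAUSED_PI_THRESHOLD)


def _directional_window(gene: GeneModel, anchor: int, off_start: int, off_end: int):
    """Genomic [start, end) for offsets measured along transcription."""
    if gene.strand == "+":
        return anchor + off_start, anchor + off_end
    return anchor - off_end, anchor - off_start


def _window_sum(coverage: CoverageTrack, gene: GeneModel, start: int, end: int):
    """(signal sum, effective length) after clipping to the chromosome;
    returns (nan, 0) when the window vanishes."""
    n = coverage.chrom_sizes[gene.chrom]
    s, e = max(0, start), min(n, end)
    if e <= s:
        return float("nan"), 0
    depth = coverage.depth(gene.chrom, gene.strand if coverage.stranded else None)
    return float(depth[s:e].sum()), e - s


def pause_index(
    gene: GeneModel,
    coverage: CoverageTrack,
    windows: PauseWindows | None = None,
    site: str = "both",
    dog_end: int | None = None,
) -> PauseIndexRecord:
    """Compute the pause index at the TSS and/or TES of one gene.

    ``dog_end`` is the far genomic edge of the gene's readthrough region
    (its ``dog_end`` on '+', ``dog_start`` on '-'); when omitted the TES
    downstream reference runs to ``windows.tes_downstream_end``.  A
    zero-signal reference window yields PI = NA.
    """
    if windows is None:
        windows = PauseWindows()
    rec = PauseIndexRecord(gene.gene_id)

    if site in ("TSS", "both"):
        ps, pe = _directional_window(gene, gene.tss, windows.tss_pause_up,
                                     windows.tss_pause_down)
        bs, be = _directional_window(gene, gene.tss, windows.tss_pause_down,
                                     gene.length)
        pc, pl = _window_sum(coverage, gene, ps, pe)
        bc, bl = _window_sum(coverage, gene, bs, be)
        rec.tss_pause_count, rec.tss_body_count = pc, bc
        if pl == 0 or bl == 0:
            warnings.warn(f"{gene.gene_id}: degenerate TSS window; PI_TSS = NA")
        elif bc > 0:
            rec.pi_tss = (pc / pl) / (bc / bl)

    if site in ("TES", "both"):
        ps, pe = _directional_window(gene, gene.tes, windows.tes_pause_start,
                                     windows.tes_pause_end)
        if dog_end is not None:
            ds_end = abs(dog_end - gene.tes)
        else:
            ds_end = windows.tes_downstream_end
        ds, de = _directional_window(gene, gene.tes, windows.tes_pause_end, ds_end)
        pc, pl = _window_sum(coverage, gene, ps, pe)
        dc, dl = _window_sum(coverage, gene, ds, de)
        rec.tes_pause_count, rec.tes_downstream_count = pc, dc
        if pl == 0 or dl == 0:
            warnings.warn(f"{gene.gene_id}: degenerate TES window; PI_TES = NA")
        elif dc > 0:
            rec.pi_tes = (pc / pl) / (dc / dl)

    return rec


def pause_index_table(
    genes,
    coverage: CoverageTrack,
    windows: PauseWindows | None = None,
    site: str = "both",
    dog_ends: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pause indices for a gene set as a DataFrame indexed by gene_id;
    ``dog_ends`` maps host gene ids to their readthrough region's far
    edge."""
    dog_ends = dog_ends or {}
    recs = [
        pause_index(g, coverage, windows, site, dog_ends.get(g.gene_id))
        for g in genes
    ]
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in recs],
            "pi_tss": [r.pi_tss for r in recs],
            "pi_tes": [r.pi_tes for r in recs],
            "paused_tss": [r.paused_tss for r in recs],
            "paused_tes": [r.paused_tes for r in recs],
        }
    ).set_index("gene_id")
    return df


def expression_quartile_groups(expression) -> pd.Series:
    """Three expression groups split at the bottom and top quartiles:
    low (<= Q1), high (>= Q3), medium otherwise.

    Quartiles use the linear-interpolation quantile.  In the fully
    degenerate case (every value satisfies both bounds, i.e. Q1 == Q3
    and all values equal them) the tie rule assigns medium.
    """
    expr = pd.Series(expression, dtype=float)
    if len(expr) < 4:
        raise ValueError("need at least 4 genes for quartile grouping")
    q1, q3 = expr.quantile(0.25), expr.quantile(0.75)
    out = pd.Series("medium", index=expr.index, dtype=object)
    low = expr <= q1
    high = expr >= q3
    both = low & high
    out[low & ~both] = "low"
    out[high & ~both] = "high"
    return out


def compute_metaprofile(
    genes,
    coverage: CoverageTrack,
    upstream: int = 2000,
    downstream: int = 5000,
    body_bins: int = 100,
) -> np.ndarray:
    """Average signal profile over genes: fixed-width flanks at per-base
    resolution around a gene body rescaled to ``body_bins`` bins.

    Minus-strand genes are reversed so every profile reads 5'->3'.
    Flank bases beyond the chromosome contribute 0.  Genes shorter than
    one body bin are skipped with a warning.  Returns a vector of length
    ``upstream + body_bins + downstream``.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene set is empty")
    profiles = []
    for g in genes:
        if g.length < body_bins:
            warnings.warn(f"{g.gene_id}: shorter than one body bin; skipped")
            continue
        n = coverage.chrom_sizes[g.chrom]
        depth = coverage.depth(g.chrom, g.strand if coverage.stranded else None)

        def flank(start, end):
            out = np.zeros(end - start)
            s, e = max(0, start), min(n, end)
            if e > s:
                out[s - start : e - start] = depth[s:e]
            return out

        body = depth[g.start : g.end]
        edges = np.linspace(0, body.size, body_bins + 1).astype(int)
        body_binned = np.add.reduceat(body, edges[:-1]) / np.diff(edges)
        if g.strand == "+":
            up = flank(g.start - upstream, g.start)
            down = flank(g.end, g.end + downstream)
            prof = np.concatenate([up, body_binned, down])
        else:
            up = flank(g.end, g.end + upstream)[::-1]
            down = flank(g.start - downstream, g.start)[::-1]
            prof = np.concatenate([up, body_binned[::-1], down])
        profiles.append(prof)
    if not profiles:
        raise ValueError("no gene was long enough to profile")
    return np.mean(profiles, axis=0)
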