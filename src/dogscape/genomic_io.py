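"""Gene annotation and coverage I/O.

Internal coordinates are 0-based half-open everywhere; GTF conversion
(1-based closed) happens only at the file boundary.  Coverage is held
per-base in numpy arrays, one array per chromosome, optionally resolved
by strand (a stranded track stores a '+' and a '-' array per chromosome;
an unstranded track stores a single '.' array).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "DoGParams",
    "read_chrom_sizes",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_coverage",
    "write_coverage",
    "downsample_coverage",
    "pool_tracks",
]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene locus.

    ``tss``/``tes`` are derived from strand: on '+' the TSS is ``start``
    and the TES is ``end``; on '-' they swap.  Multi-transcript genes are
    collapsed to the union span before construction.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DoGParams:
    """Windowed readthrough-calling parameters.

    Defaults: 200-bp windows, a window passes at >=60% covered bases,
    and a readthrough region must extend at least 5 kb; called regions
    are discarded when another gene lies within 5 kb downstream of the
    host TES.
    """

    min_dog_len: int = 5000
    min_dog_cov: float = 0.6
    window: int = 200
    adjacent_filter_distance: int = 5000

    def __post_init__(self) -> None:
        if not 0 < self.min_dog_cov <= 1:
            raise ValueError("min_dog_cov must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_dog_len <= 0:
            raise ValueError("min_dog_len must be positive")

    @property
    def min_windows(self) -> int:
        """Smallest number of consecutive passing windows that reaches
        ``min_dog_len`` (the run length is window-quantized)."""
        return -(-self.min_dog_len // self.window)


class CoverageTrack:
    """Per-base non-negative signal, per chromosome, optionally stranded.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bases.
    stranded
        If True the track stores separate '+' and '-' arrays.
    """

    UNSTRANDED_KEY = "."

    def __init__(self, chrom_sizes: dict[str, int], stranded: bool = False):
        self.chrom_sizes = dict(chrom_sizes)
        self.stranded = stranded
        keys = ("+", "-") if stranded else (self.UNSTRANDED_KEY,)
        self._data: dict[tuple[str, str], np.ndarray] = {
            (c, k): np.zeros(n, dtype=np.float64)
            for c, n in self.chrom_sizes.items()
            for k in keys
        }

    def _key(self, chrom: str, strand: str | None) -> tuple[str, str]:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not self.stranded:
            return (chrom, self.UNSTRANDED_KEY)
        if strand not in ("+", "-"):
            raise ValueError("stranded track requires strand '+' or '-'")
        return (chrom, strand)

    def depth(self, chrom: str, strand: str | None = None) -> np.ndarray:
        """Per-base depth array.  On a stranded track with ``strand=None``
        the two strands are summed."""
        if self.stranded and strand is None:
            return self._data[(chrom, "+")] + self._data[(chrom, "-")]
        return self._data[self._key(chrom, strand)]

    def add_interval(
        self, chrom: str, start: int, end: int, value: float, strand: str | None = None
    ) -> None:
        if value < 0:
            raise ValueError(f"negative coverage value {value}")
        n = self.chrom_sizes.get(chrom)
        if n is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > n or start >= end:
            raise ValueError(f"interval {chrom}:{start}-{end} outside bounds [0,{n})")
        self._data[self._key(chrom, strand)][start:end] += value

    @property
    def total_signal(self) -> float:
        # canonical summation order: sorted keys, so pooling is exactly
        # commutative/associative at fixed precision
        return float(sum(self._data[k].sum() for k in sorted(self._data)))

    def copy(self) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_sizes, self.stranded)
        for k, v in self._data.items():
            out._data[k] = v.copy()
        return out

    def scale(self, factor: float) -> "CoverageTrack":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = self.copy()
        for k in out._data:
            out._data[k] *= factor
        return out

    def _compatible(self, other: "CoverageTrack") -> bool:
        return (
            self.chrom_sizes == other.chrom_sizes and self.stranded == other.stranded
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self._compatible(other) and all(
            np.array_equal(self._data[k], other._data[k]) for k in self._data
        )


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_gene_annotation(
    path,
    feature: str = "gene",
    biotype_filter: str | None = "protein_coding",
) -> list[GeneModel]:
    """Read gene models from a GTF file.

    GTF 1-based closed coordinates become internal 0-based half-open.
    Records sharing a ``gene_id`` (multi-transcript genes, or repeated
    ``gene`` lines) are collapsed to ``min(start)..max(end)``; a repeated
    gene_id on a different chromosome or strand is an error.

    Parameters
    ----------
    biotype_filter
        Keep only genes whose ``gene_type`` (or ``gene_biotype``)
        attribute equals this value; ``None`` keeps everything.
    """
    spans: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                fields = line.split(None, 8)  # tolerate space-separated GTF
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _source, feat, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feat != feature:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed coordinates on line {lineno}") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: bad strand {strand!r} on line {lineno}")
            attr = _parse_gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: missing gene_id on line {lineno}")
            biotype = attr.get("gene_type", attr.get("gene_biotype"))
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            start, end = start1 - 1, end1  # to 0-based half-open
            if gene_id in spans:
                c0, s0, lo, hi = spans[gene_id]
                if c0 != chrom or s0 != strand:
                    raise ValueError(
                        f"{path}: gene_id {gene_id!r} re-declared with conflicting "
                        f"chrom/strand on line {lineno}"
                    )
                spans[gene_id] = [c0, s0, min(lo, start), max(hi, end)]
            else:
                spans[gene_id] = [chrom, strand, start, end]
    return [
        GeneModel(gid, chrom, strand, start, end)
        for gid, (chrom, strand, start, end) in spans.items()
    ]


def write_gene_annotation(genes, path, biotype: str = "protein_coding") -> None:
    """Write gene models as GTF ``gene`` features (1-based closed)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "{biotype}";'
            fh.write(
                f"{g.chrom}\tdogscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_coverage(
    path,
    chrom_sizes: dict[str, int],
    strand_label: str | None = None,
    track: CoverageTrack | None = None,
) -> CoverageTrack:
    """Read a bedGraph file into a per-base coverage track.

    Overlapping intervals are summed; bases not covered by any interval
    stay 0.  Pass ``track`` (with ``strand_label``) to layer the '-'
    strand file onto an existing stranded track.
    """
    if track is None:
        track = CoverageTrack(chrom_sizes, stranded=strand_label is not None)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return track
    for row in df.itertuples(index=False):
        track.add_interval(row.chrom, int(row.start), int(row.end), float(row.value),
                           strand=strand_label)
    return track


def write_coverage(track: CoverageTrack, path, strand: str | None = None) -> None:
    """Write one strand (or the unstranded signal) as bedGraph with
    maximal runs of equal depth; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            depth = track.depth(chrom, strand)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def downsample_coverage(
    track: CoverageTrack, target_total: float, seed: int
) -> CoverageTrack:
    """Binomially thin per-base signal to an expected total of
    ``target_total``.

    Each integer unit of signal is retained independently with
    probability ``target_total / total_signal``; fractional depth is
    thinned on its integer part plus a Bernoulli trial on the remainder.
    Deterministic given ``seed``.  Upsampling is refused.
    """
    total = track.total_signal
    if not 0 < target_total <= total:
        raise ValueError(
            f"target_total must be in (0, {total}], got {target_total}"
        )
    p = target_total / total
    rng = np.random.default_rng(seed)
    out = track.copy()
    for key in sorted(out._data):
        arr = out._data[key]
        whole = np.floor(arr).astype(np.int64)
        frac = arr - whole
        thinned = rng.binomial(whole, p).astype(np.float64)
        thinned += rng.binomial(1, frac * p).astype(np.float64)
        out._data[key] = thinned
    return out


def pool_tracks(tracks) -> CoverageTrack:
    """Base-wise sum of coverage tracks with identical chromosome sets,
    lengths and strandedness."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("pool_tracks requires at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first._compatible(t):
            raise ValueError("tracks have mismatched chromosomes or strandedness")
    out = CoverageTrack(first.chrom_sizes, first.stranded)
    for k in out._data:
        # canonical summation order (sorted by content) makes pooling
        # exactly commutative at fixed precision
        rows = sorted((t._data[k] for t in tracks), key=lambda a: a.tobytes())
        acc = np.zeros_like(out._data[k])
        for r in rows:
            acc += r
        out._data[k] = acc
    return out
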