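import numpy as np
import pandas as pd
import pytest

from dogscape import CoverageTrack, DoGParams, GeneModel, SimulationConfig


def brute_force_call_dogs(genes, track, params):
    """Independent readthrough caller: tests every window explicitly
    with per-base python loops.  Deliberately naive; used as the oracle
    for the windowed scanner."""
    calls = {}
    for g in genes:
        n = track.chrom_sizes[g.chrom]
        depth = track.depth(g.chrom, g.strand if track.stranded else None)
        w = params.window
        ext = 0
        i = 0
        while True:
            if g.strand == "+":
                lo = g.tes + i * w
                hi = lo + w
                if hi > n:
                    break
            else:
                hi = g.tes - i * w
                lo = hi - w
                if lo < 0:
                    break
            covered = sum(1 for b in range(lo, hi) if depth[b] > 0)
            if covered / w >= params.min_dog_cov:
                ext += w
                i += 1
            else:
                break
        if ext >= params.min_dog_len:
            calls[g.gene_id] = ext
    return calls


@pytest.fixture
def one_gene():
    return GeneModel("G1", "chr1", "+", 1000, 10_000)


@pytest.fixture
def flat_track():
    """Unstranded track: depth 1 on chr1 bases 10,000-16,399, 0 after."""
    t = CoverageTrack({"chr1": 30_000})
    t.add_interval("chr1", 10_000, 16_400, 1.0)
    return t


@pytest.fixture
def default_params():
    return DoGParams()


@pytest.fixture
def two_group_design():
    return pd.Series({f"s{i}": ("A" if i < 5 else "B") for i in range(10)})


@pytest.fixture
def caller_world():
    """A seeded synthetic genome + coverage + truth for the caller."""
    from dogscape import simulate_annotation_and_coverage

    cfg = SimulationConfig(seed=11, n_genes=80, dog_prevalence=0.3)
    return simulate_annotation_and_coverage(cfg)
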