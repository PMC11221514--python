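import numpy as np
import pytest

from dogscape import (
    CoverageTrack,
    DoGParams,
    GeneModel,
    SimulationConfig,
    call_dogs,
    compare_dog_sets,
    filter_adjacent_genes,
    read_dog_bed,
    simulate_annotation_and_coverage,
    write_dog_bed,
)
from conftest import brute_force_call_dogs


class TestCallDogs:
    def test_direct_rule(self, one_gene, flat_track, default_params):
        """Depth 1 over TES..TES+6400 yields a 32-window, 6.4 kb call."""
        (call,) = call_dogs([one_gene], flat_track, default_params)
        assert call.n_windows == 32
        assert call.extension_strength == 6400
        assert (call.dog_start, call.dog_end) == (10_000, 16_400)

    def test_zero_downstream_no_call(self, one_gene, default_params):
        t = CoverageTrack({"chr1": 30_000})
        t.add_interval("chr1", 1000, 10_000, 5.0)  # gene body only
        assert call_dogs([one_gene], t, default_params) == []

    def test_run_must_start_at_tes(self, one_gene, default_params):
        """A failing first window blocks a passing run farther downstream."""
        t = CoverageTrack({"chr1": 30_000})
        t.add_interval("chr1", 10_200, 17_000, 1.0)  # starts one window late
        assert call_dogs([one_gene], t, default_params) == []

    def test_sub_threshold_window_fraction(self, one_gene, default_params):
        """59% covered bases in the first window fails the 60% rule."""
        t = CoverageTrack({"chr1": 30_000})
        t.add_interval("chr1", 10_000, 10_118, 1.0)  # 118/200 = 59%
        t.add_interval("chr1", 10_200, 17_000, 1.0)
        assert call_dogs([one_gene], t, default_params) == []
        t2 = CoverageTrack({"chr1": 30_000})
        t2.add_interval("chr1", 10_000, 10_120, 1.0)  # 120/200 = 60%: passes
        t2.add_interval("chr1", 10_200, 17_000, 1.0)
        (call,) = call_dogs([one_gene], t2, default_params)
        assert call.extension_strength == 7000

    def test_minus_strand(self, default_params):
        g = GeneModel("G1", "chr1", "-", 20_000, 28_000)  # TES at 20,000
        t = CoverageTrack({"chr1": 30_000})
        t.add_interval("chr1", 13_600, 20_000, 1.0)  # 6.4 kb upstream in genome
        (call,) = call_dogs([g], t, default_params)
        assert (call.dog_start, call.dog_end) == (13_600, 20_000)
        assert call.extension_strength == 6400

    def test_stranded_track_uses_host_strand(self, one_gene, default_params):
        t = CoverageTrack({"chr1": 30_000}, stranded=True)
        t.add_interval("chr1", 10_000, 17_000, 1.0, strand="-")  # antisense only
        assert call_dogs([one_gene], t, default_params) == []
        t.add_interval("chr1", 10_000, 17_000, 1.0, strand="+")
        assert len(call_dogs([one_gene], t, default_params)) == 1

    def test_tes_at_chromosome_edge_skipped(self, default_params):
        g = GeneModel("G1", "chr1", "+", 100, 9_950)
        t = CoverageTrack({"chr1": 10_000})
        with pytest.warns(UserWarning, match="skipped"):
            assert call_dogs([g], t, default_params) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, seed, default_params):
        """The windowed scanner matches an exhaustive per-base oracle on
        seeded random genomes (the acceptance suite widens this to 100)."""
        cfg = SimulationConfig(
            seed=seed, n_genes=30, dog_prevalence=0.5,
            window_coverage_fraction=0.55 + 0.08 * (seed % 5),
            dog_length_log_mean=np.log(4000 + 1500 * (seed % 4)),
            dog_length_range=(2000, 15000),
        )
        genes, track, _ = simulate_annotation_and_coverage(cfg)
        got = {c.host_gene_id: c.extension_strength
               for c in call_dogs(genes, track, default_params)}
        assert got == brute_force_call_dogs(genes, track, default_params)

    def test_monotonic_in_min_cov(self, caller_world):
        genes, track, _ = caller_world
        lo = {c.host_gene_id: c.extension_strength
              for c in call_dogs(genes, track, DoGParams(min_dog_cov=0.5))}
        hi = {c.host_gene_id: c.extension_strength
              for c in call_dogs(genes, track, DoGParams(min_dog_cov=0.8))}
        assert set(hi) <= set(lo)
        for g, ext in hi.items():
            assert ext <= lo[g]

    def test_monotonic_in_min_len(self, caller_world):
        genes, track, _ = caller_world
        l1 = {c.host_gene_id: c.extension_strength
              for c in call_dogs(genes, track, DoGParams(min_dog_len=4000))}
        l2 = {c.host_gene_id: c.extension_strength
              for c in call_dogs(genes, track, DoGParams(min_dog_len=8000))}
        assert set(l2) <= set(l1)
        assert all(l1[g] == e for g, e in l2.items())

    def test_strand_mirror_symmetry(self, default_params):
        """Mirroring the genome and flipping strands mirrors the calls
        with identical extension strengths."""
        cfg = SimulationConfig(seed=42, n_genes=30, dog_prevalence=0.4)
        genes, track, _ = simulate_annotation_and_coverage(cfg)
        n = {c: track.chrom_sizes[c] for c in track.chrom_sizes}
        mirror = CoverageTrack(track.chrom_sizes)
        for c in n:
            mirror._data[(c, ".")] = track.depth(c)[::-1].copy()
        flipped = [
            GeneModel(g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                      n[g.chrom] - g.end, n[g.chrom] - g.start)
            for g in genes
        ]
        orig = {c.host_gene_id: c.extension_strength
                for c in call_dogs(genes, track, default_params)}
        mirr = {c.host_gene_id: c.extension_strength
                for c in call_dogs(flipped, mirror, default_params)}
        assert orig == mirr


class TestAdjacentFilter:
    def _setup(self, neighbor_strand):
        host = GeneModel("host", "chr1", "+", 1000, 10_000)
        neighbor = GeneModel("nbr", "chr1", neighbor_strand, 13_000, 14_000)
        t = CoverageTrack({"chr1": 40_000})
        t.add_interval("chr1", 10_000, 17_000, 1.0)
        calls = call_dogs([host], t)
        assert len(calls) == 1
        return calls, [host, neighbor]

    def test_same_strand_removed(self):
        calls, genes = self._setup("+")
        assert filter_adjacent_genes(calls, genes, stranded=True) == []

    def test_opposite_strand_rule(self):
        calls, genes = self._setup("-")
        assert len(filter_adjacent_genes(calls, genes, stranded=True)) == 1
        assert filter_adjacent_genes(calls, genes, stranded=False) == []

    def test_no_neighbor_identity(self):
        calls, genes = self._setup("+")
        assert filter_adjacent_genes(calls, [genes[0]]) == calls

    def test_neighbor_beyond_5kb_kept(self):
        host = GeneModel("host", "chr1", "+", 1000, 10_000)
        far = GeneModel("far", "chr1", "+", 15_100, 16_000)  # starts past TES+5kb
        t = CoverageTrack({"chr1": 40_000})
        t.add_interval("chr1", 10_000, 17_000, 1.0)
        calls = call_dogs([host], t)
        assert filter_adjacent_genes(calls, [host, far]) == calls

    def test_non_increasing_and_idempotent(self, caller_world):
        genes, track, _ = caller_world
        calls = call_dogs(genes, track)
        once = filter_adjacent_genes(calls, genes)
        assert len(once) <= len(calls)
        assert filter_adjacent_genes(once, genes) == once


class TestCompareSets:
    def test_set_algebra(self):
        cmp = compare_dog_sets({"g1", "g2", "g3"}, {"g2"})
        assert cmp.set_a_only == {"g1", "g3"}
        assert cmp.shared == {"g2"}
        assert cmp.set_b_only == frozenset()

    def test_counts_partition(self):
        a = {f"a{i}" for i in range(494)} | {f"s{i}" for i in range(38)}
        b = {f"b{i}" for i in range(517)} | {f"s{i}" for i in range(38)}
        cmp = compare_dog_sets(a, b)
        assert (cmp.n_a_only, cmp.n_shared, cmp.n_b_only) == (494, 38, 517)
        assert cmp.n_a_only + cmp.n_shared == len(a)
        assert cmp.n_b_only + cmp.n_shared == len(b)

    def test_identity(self):
        cmp = compare_dog_sets({"x", "y"}, {"x", "y"})
        assert cmp.shared == {"x", "y"}
        assert not cmp.set_a_only and not cmp.set_b_only


def test_bed_round_trip(tmp_path, one_gene, flat_track):
    calls = call_dogs([one_gene], flat_track)
    p = tmp_path / "dogs.bed"
    write_dog_bed(calls, p)
    assert read_dog_bed(p) == calls
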