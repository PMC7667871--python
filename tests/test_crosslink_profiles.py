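import numpy as np
import pytest
from scipy import stats as scistats

from clipflow.align_map import AlignmentRecord
from clipflow.crosslink_profiles import (
    CrosslinkTrack,
    assign_crosslinks,
    boundary_profile,
    decile_profile,
    extract_motif_windows,
    operon_profile,
    operon_units,
)
from clipflow.io_formats import GeneRecord, Genome, ValidationError, revcomp
from clipflow.synthetic_data import (
    GroundTruthManifest,
    build_annotation,
    build_genome,
    sample_crosslinks,
)


@pytest.fixture(scope="module")
def genome():
    return Genome({"chr": "ACGT" * 1000})


def gene(start, end, strand="+", biotype="protein_coding", gene_id="g1", operon=None):
    return GeneRecord("chr", start, end, strand, biotype, gene_id, operon)


class TestAssignCrosslinks:
    def test_plus_convention(self, genome):
        aln = AlignmentRecord("r", "chr", 100, 150, "+", 0)
        track = assign_crosslinks([aln], genome)
        assert track["+"]["chr"][99] == 1
        assert track.total() == 1

    def test_minus_convention(self, genome):
        aln = AlignmentRecord("r", "chr", 100, 150, "-", 0)
        track = assign_crosslinks([aln], genome)
        assert track["-"]["chr"][150] == 1

    def test_edge_positions_dropped(self, genome):
        alns = [
            AlignmentRecord("a", "chr", 0, 50, "+", 0),      # crosslink at -1
            AlignmentRecord("b", "chr", 3950, 4000, "-", 0),  # crosslink at 4000
        ]
        assert assign_crosslinks(alns, genome).total() == 0

    def test_min_count_threshold(self, genome):
        alns = [AlignmentRecord(f"r{i}", "chr", 100, 150, "+", 0) for i in range(3)]
        alns.append(AlignmentRecord("s", "chr", 200, 250, "+", 0))
        track = assign_crosslinks(alns, genome, min_count=2)
        assert track["+"]["chr"][99] == 3
        assert track["+"]["chr"][199] == 0

    def test_total_equals_alignments(self, genome50k, genes50k, index50k):
        from clipflow.align_map import map_reads
        from clipflow.io_formats import ReadRecord
        from clipflow.synthetic_data import simulate_iclip_library

        m = GroundTruthManifest(seed=3)
        lib = simulate_iclip_library(genome50k, genes50k, m, "target_1", 100, 2)
        reads = [ReadRecord(r.read_id, r.insert, "I" * len(r.insert))
                 for r in lib.truth.itertuples()]
        aligned, _, _ = map_reads(genome50k, reads, index=index50k)
        track = assign_crosslinks(aligned, genome50k)
        # every crosslink equals its planted position
        planted = {(r.replicon, r.crosslink, r.strand) for r in lib.truth.itertuples()}
        called = {(rep, pos, s) for rep, pos, s, _ in track.sites()}
        assert called == planted


class TestDecileProfile:
    def track_at(self, genome, positions, strand="+"):
        return CrosslinkTrack.from_sites(genome, [("chr", p, strand) for p in positions])

    def test_sense_first_decile(self, genome):
        track = self.track_at(genome, [5])
        prof = decile_profile(track, [gene(0, 100)], biotype="protein_coding")
        assert prof.counts[0] == 1 and prof.counts.sum() == 1

    def test_antisense_last_decile_not_flipped(self, genome):
        track = self.track_at(genome, [95], strand="-")
        prof = decile_profile(track, [gene(0, 100)], orientation="antisense")
        assert prof.counts[9] == 1

    def test_minus_gene_orientation(self, genome):
        track = self.track_at(genome, [95], strand="-")
        prof = decile_profile(track, [gene(0, 100, strand="-")])
        assert prof.counts[0] == 1  # position 95 is in the minus gene's first decile

    def test_short_gene_excluded(self, genome):
        track = self.track_at(genome, [3])
        prof = decile_profile(track, [gene(0, 9)])
        assert prof.n_genes == 0

    def test_remainder_rule(self, genome):
        # L=103: bin 1 covers [0, 10), bin 10 covers [92, 103)
        track = self.track_at(genome, [9, 10, 92])
        prof = decile_profile(track, [gene(0, 103)])
        assert prof.counts[0] == 1 and prof.counts[1] == 1 and prof.counts[9] == 1

    def test_uniform_multinomial(self, genome):
        rng = np.random.default_rng(0)
        g = gene(0, 1000)
        positions = rng.integers(0, 1000, size=2000)
        track = self.track_at(genome, positions)
        prof = decile_profile(track, [g])
        sd = np.sqrt(2000 * 0.1 * 0.9)
        assert (np.abs(prof.counts - 200) <= 3 * sd).all()

    def test_conservation(self, genome):
        rng = np.random.default_rng(1)
        genes = [gene(0, 100), gene(200, 400, strand="-", gene_id="g2")]
        sites = [("chr", int(p), s) for p in rng.integers(0, 500, 300)
                 for s in ["+" if rng.random() < 0.5 else "-"]]
        track = CrosslinkTrack.from_sites(genome, sites)
        total_in_genes = sum(
            1 for rep, p, s in sites
            if any(g.start <= p < g.end for g in genes)
        )
        got = sum(
            decile_profile(track, genes, orientation=o).counts.sum()
            for o in ("sense", "antisense")
        )
        assert got == total_in_genes

    def test_percent_sums_to_100(self, genome):
        track = self.track_at(genome, [5, 15, 25, 77])
        prof = decile_profile(track, [gene(0, 100)])
        assert abs(prof.percent().sum() - 100) < 0.01


class TestOperons:
    def test_unit_span(self):
        genes = [gene(0, 100, operon="op1"), gene(150, 250, gene_id="g2", operon="op1")]
        (unit,) = operon_units(genes)
        assert (unit.start, unit.end) == (0, 250)

    def test_singleton(self):
        genes = [gene(10, 120, operon="op1")]
        (unit,) = operon_units(genes)
        assert (unit.start, unit.end) == (10, 120)

    def test_strand_discordant_error(self):
        genes = [gene(0, 100, operon="op1"),
                 gene(150, 250, strand="-", gene_id="g2", operon="op1")]
        with pytest.raises(ValidationError, match="op1"):
            operon_units(genes)

    def test_gap_counts_in_unit(self, genome):
        genes = [gene(0, 100, operon="op1"), gene(150, 250, gene_id="g2", operon="op1")]
        track = CrosslinkTrack.from_sites(genome, [("chr", 120, "+")])
        prof = operon_profile(track, genes)
        assert prof.counts.sum() == 1


class TestBoundaryProfile:
    def test_minus_one_upstream_plus(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 999, "+")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="start")
        assert prof.counts[list(prof.offsets).index(-1)] == 1

    def test_minus_one_upstream_minus_gene(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 1100, "-")])
        prof = boundary_profile(track, [gene(1000, 1100, strand="-")], anchor="start")
        assert prof.counts[list(prof.offsets).index(-1)] == 1

    def test_first_gene_base_is_plus_one(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 1000, "+")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="start")
        assert prof.counts[list(prof.offsets).index(1)] == 1

    def test_end_anchor_downstream_plus_one(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 1100, "+")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="end")
        assert prof.counts[list(prof.offsets).index(1)] == 1

    def test_end_anchor_last_base_minus_one(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 1099, "+")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="end")
        assert prof.counts[list(prof.offsets).index(-1)] == 1

    def test_sense_only_by_default(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 999, "-")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="start")
        assert prof.counts.sum() == 0
        prof2 = boundary_profile(track, [gene(1000, 1100)], anchor="start",
                                 include_antisense=True)
        assert prof2.counts.sum() == 1

    def test_binning(self, genome):
        track = CrosslinkTrack.from_sites(
            genome, [("chr", 999, "+"), ("chr", 995, "+"), ("chr", 1005, "+")]
        )
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="start", bin_width=10)
        assert prof.counts.size == 20
        assert prof.counts[9] == 2  # offsets -10..-1
        assert prof.counts[10] == 1  # offsets +1..+10

    def test_planted_hotspot_is_maximum(self, genome50k, genes50k):
        m = GroundTruthManifest(seed=12, hotspot_offset=-30, hotspot_weight=0.15)
        sites = sample_crosslinks(genome50k, genes50k, m, 3000, 4)
        track = CrosslinkTrack.from_sites(genome50k, sites)
        prof = boundary_profile(track, genes50k, anchor="start", window=100, bin_width=1)
        assert prof.offsets[np.argmax(prof.counts)] == -30

    def test_normalize_percent(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 999, "+"), ("chr", 995, "+")])
        prof = boundary_profile(track, [gene(1000, 1100)], anchor="start", normalize=True)
        assert abs(prof.counts.sum() - 100) < 1e-9


class TestMotifWindows:
    def test_window_extraction(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 50, "+")])
        ((name, seq),) = extract_motif_windows(track, genome, flank=10)
        assert seq == genome["chr"][40:61]
        assert len(seq) == 21

    def test_edge_dropped(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 5, "+")])
        assert extract_motif_windows(track, genome, flank=10) == []

    def test_minus_strand_revcomp(self, genome):
        track = CrosslinkTrack.from_sites(genome, [("chr", 50, "-")])
        ((_, seq),) = extract_motif_windows(track, genome, flank=10)
        assert seq == revcomp(genome["chr"][40:61])

    def test_top_k(self, genome):
        sites = [("chr", 50, "+")] * 3 + [("chr", 80, "+")]
        track = CrosslinkTrack.from_sites(genome, sites)
        windows = extract_motif_windows(track, genome, top_k_sites=1)
        assert len(windows) == 1 and "50" in windows[0][0]


class TestUniformityProperty:
    def test_chi_square_uniform_placement(self):
        """Uniform placement is non-significant at alpha=0.01 in >= 95%
        of seeds (reduced seed count here; the full 100 run in the
        acceptance suite)."""
        genome = build_genome(seed=30, length=50_000)
        genes = build_annotation(genome, 31, n_genes=20)
        passes = 0
        n_seeds = 20
        for seed in range(n_seeds):
            m = GroundTruthManifest(seed=seed)
            sites = sample_crosslinks(genome, genes, m, 2000, seed)
            track = CrosslinkTrack.from_sites(genome, sites)
            prof = decile_profile(track, genes)
            _, p = scistats.chisquare(prof.counts)
            passes += p >= 0.01
        assert passes >= int(0.95 * n_seeds)

    def test_first_decile_enrichment_argmax(self):
        genome = build_genome(seed=30, length=50_000)
        genes = build_annotation(genome, 31, n_genes=20)
        for seed in range(10):
            m = GroundTruthManifest(seed=seed, decile_weights=np.array([3.0] + [1.0] * 9))
            sites = sample_crosslinks(genome, genes, m, 2000, seed)
            track = CrosslinkTrack.from_sites(genome, sites)
            prof = decile_profile(track, genes)
            assert int(np.argmax(prof.counts)) == 0
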