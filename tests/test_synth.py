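from collections import Counter

import numpy as np
import pytest
from Bio import Align

from mitoforge import (CircularSequence, ReadProfile,
                       default_primer_tiling, generate_mitogenome,
                       plant_numts, simulate_pcr_evidence, simulate_reads)
from mitoforge.seqs import FeatureKind, revcomp
from mitoforge.synth import PlacementError, SpecError

from conftest import small_spec


def oracle_global_identity(a: str, b: str, denominator: str = "bases") -> float:
    """Independent global aligner (Biopython, edit-distance scoring) for
    checking identities."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 0
    al.mismatch_score = -1
    al.open_gap_score = -1
    al.extend_gap_score = -1
    aln = al.align(a, b)[0]
    matches = both = 0
    qa, sa = aln.aligned
    for (qs, qe), (ss, se) in zip(qa, sa):
        x, y = a[qs:qe], b[ss:se]
        both += len(x)
        matches += sum(1 for u, v in zip(x, y) if u == v)
    if denominator == "bases":
        return matches / both
    return matches / aln.length


class TestGenerateMitogenome:
    def test_default_gene_complement(self, default_genome):
        # parrot-style annotation: 23 tRNA features, 14 protein-coding
        # features, 2 rRNAs and both control-region copies
        _, anns = default_genome
        kinds = Counter(a.kind for a in anns)
        assert kinds[FeatureKind.TRNA] == 23
        assert kinds[FeatureKind.PCG] == 14
        assert kinds[FeatureKind.RRNA] == 2
        assert kinds[FeatureKind.CR] == 2
        assert kinds[FeatureKind.TR] == 2

    def test_annotation_within_bounds(self, default_genome):
        genome, anns = default_genome
        for a in anns:
            assert 0 <= a.start < genome.length
            assert a.start < a.end <= 2 * genome.length

    def test_identical_cr_copies_at_identity_one(self):
        spec = small_spec(seed=7)
        spec.cr_copy_identity = 1.0
        genome, anns = generate_mitogenome(spec)
        cr = {a.name: genome.slice_circular(a.start, a.end)
              for a in anns if a.kind == FeatureKind.CR}
        assert cr["CR1"] == cr["CR2"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cr_divergence_tracks_target(self, seed):
        spec = small_spec(seed=seed)
        genome, anns = generate_mitogenome(spec)
        cr = {a.name: genome.slice_circular(a.start, a.end)
              for a in anns if a.kind == FeatureKind.CR}
        ident = oracle_global_identity(cr["CR1"], cr["CR2"])
        assert 0.97 <= ident <= 0.99

    def test_deterministic_for_fixed_seed(self):
        g1, a1 = generate_mitogenome(small_spec(seed=5))
        g2, a2 = generate_mitogenome(small_spec(seed=5))
        g3, _ = generate_mitogenome(small_spec(seed=6))
        assert g1.seq == g2.seq and a1 == a2
        assert g1.seq != g3.seq

    def test_infeasible_spec_rejected(self):
        spec = small_spec()
        spec.total_length = 1000
        with pytest.raises(SpecError):
            generate_mitogenome(spec)

    def test_tr_tract_must_fit_in_cr(self):
        spec = small_spec()
        spec.tr_copies_cr1 = 50
        with pytest.raises(SpecError):
            generate_mitogenome(spec)


class TestPlantNumts:
    def test_zero_copies(self, small_genome):
        genome, _ = small_genome
        bg = plant_numts(20_000, genome, 0, length_range=(54, 2000), seed=1)
        assert bg.planted == []
        assert len(bg.seq) == 20_000

    def test_count_and_coordinates(self, small_genome):
        genome, _ = small_genome
        bg = plant_numts(50_000, genome, 6, length_range=(54, 2000), seed=2)
        assert len(bg.planted) == 6
        for p in bg.planted:
            inserted = bg.seq[p.insertion_pos:p.insertion_pos + p.length]
            oriented = inserted if p.strand == "+" else revcomp(inserted)
            source = genome.slice_circular(p.mito_start, p.mito_end)
            # the recorded coordinates recover the planted copy: an
            # independent aligner agrees with the recorded identity
            # (different optimal alignments move it by a few percent)
            oracle = oracle_global_identity(oriented, source, "columns")
            assert oracle == pytest.approx(p.realized_identity, abs=0.05)

    def test_realized_identity_tracks_target(self, small_genome):
        genome, _ = small_genome
        bg = plant_numts(60_000, genome, 8, length_range=(200, 2000), seed=3)
        for p in bg.planted:
            assert abs(p.realized_identity - p.target_identity) <= 0.02

    def test_overcrowded_placement_fails(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(PlacementError):
            plant_numts(30, genome, 10, length_range=(54, 60), seed=4)

    def test_invalid_ranges(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            plant_numts(1000, genome, 1, length_range=(0, 100), seed=0)
        with pytest.raises(ValueError):
            plant_numts(1000, genome, 1, identity_range=(0.5, 1.0), seed=0)


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, small_genome):
        genome, _ = small_genome
        rs = simulate_reads(genome, ReadProfile(coverage=10.0), seed=5)
        doubled = genome.doubled()
        for pr in rs.paired[:200]:
            r1, r2 = pr.read1, pr.read2
            ok = ((r1 in doubled and revcomp(r2) in doubled)
                  or (revcomp(r1) in doubled and r2 in doubled))
            assert ok

    def test_true_origins_reconstruct_genome(self, small_genome):
        genome, _ = small_genome
        rs = simulate_reads(genome, ReadProfile(coverage=30.0), seed=6)
        doubled = genome.doubled()
        for pr in rs.paired[:200]:
            frag = doubled[pr.true_origin:pr.true_origin + pr.true_insert]
            # either mate may carry the forward strand (FR orientation)
            assert frag[:150] in (pr.read1, pr.read2)
            assert revcomp(frag[-150:]) in (pr.read1, pr.read2)

    def test_long_read_lengths_in_band(self, default_genome):
        genome, _ = default_genome
        rs = simulate_reads(genome, ReadProfile(coverage=0.1, n_long=40),
                            seed=7)
        mean_len = np.mean([len(lr.seq) for lr in rs.long_reads])
        assert 3000 <= mean_len <= 4000

    def test_long_read_error_rate_calibrated(self, default_genome):
        # >= 1e6 simulated bases; empirical substitution rate within
        # 3 standard errors of the configured 0.10
        genome, _ = default_genome
        rs = simulate_reads(
            genome, ReadProfile(coverage=0.1, n_long=300, long_error=0.10),
            seed=8)
        doubled = genome.doubled()
        mism = total = 0
        for lr in rs.long_reads:
            truth = doubled[lr.true_origin:lr.true_origin + len(lr.seq)]
            read = lr.seq if lr.true_strand == "+" else revcomp(lr.seq)
            mism += sum(1 for a, b in zip(read, truth) if a != b)
            total += len(read)
        assert total >= 1_000_000
        se = (0.1 * 0.9 / total) ** 0.5
        assert abs(mism / total - 0.10) <= 3 * se

    def test_read_longer_than_genome_rejected(self):
        tiny = CircularSequence("t", "ACGT" * 30)
        with pytest.raises(ValueError):
            simulate_reads(tiny, ReadProfile(coverage=1.0, read_length=200),
                           seed=0)


class TestPcrEvidence:
    def test_half_open_length(self, small_genome):
        genome, _ = small_genome
        ev = simulate_pcr_evidence(genome, [(0, 500)])
        assert ev.amplicons[0].expected_length == 500

    def test_wraparound_length(self, small_genome):
        genome, _ = small_genome
        L = genome.length
        ev = simulate_pcr_evidence(genome, [(L - 200, 300)])
        assert ev.amplicons[0].expected_length == 500

    def test_zero_length_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError):
            simulate_pcr_evidence(genome, [(100, 100)])

    def test_default_tiling_in_pcr_practical_range(self, default_genome):
        genome, _ = default_genome
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome))
        assert all(500 <= a.expected_length <= 3100 for a in ev.amplicons)

    def test_primer_sites_match_genome(self, small_genome):
        genome, _ = small_genome
        ev = simulate_pcr_evidence(genome, [(10, 900)], primer_length=20)
        a = ev.amplicons[0]
        assert a.fwd_seq == genome.seq[10:30]
        assert revcomp(a.rev_seq) == genome.seq[880:900]
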