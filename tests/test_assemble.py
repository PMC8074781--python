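import numpy as np
import pytest

from mitoforge import (AmbiguousForkError, AssemblyConfig, CircularSequence,
                       EvidenceSet, ReadProfile, SeedNotFoundError,
                       assemble_mitogenome, classify_mito_kmers, count_kmers,
                       default_primer_tiling, extend_path, normalize_rotation,
                       resolve_fork, select_seed, simulate_pcr_evidence,
                       simulate_reads, validate_assembly)
from mitoforge.assemble import (CoverageHistogramError, ForkEvent, WalkState,
                                estimate_coverage_modes, _amplicon_verdict)
from mitoforge.kmers import KmerTable, canonical_code, encode_kmer
from mitoforge.seqs import FeatureAnnotation, FeatureKind, revcomp

from conftest import diverged_reference


def _table_from_counts(seqs_counts, k=23):
    table = KmerTable(k=k)
    for seq, count in seqs_counts:
        for i in range(len(seq) - k + 1):
            code = canonical_code(encode_kmer(seq[i:i + k]), k)
            table.counts[code] = table.counts.get(code, 0) + count
    return table


def _random_genome(length, seed, max_repeat=22):
    """A circular genome with no exact repeat of length > max_repeat, so
    the de Bruijn walk at k=23 has a unique path."""
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        doubled = seq + seq
        k = max_repeat + 1
        wins = {doubled[i:i + k] for i in range(length)}
        wins |= {revcomp(doubled[i:i + k]) for i in range(length)}
        if len(wins) == 2 * length:
            return CircularSequence("plain", seq)


class TestClassification:
    def test_geometric_mean_threshold(self):
        rng = np.random.default_rng(0)
        nuclear = "".join(rng.choice(list("ACGT"), size=4000))
        mito = "".join(rng.choice(list("ACGT"), size=2000))
        table = _table_from_counts([(nuclear, 5), (mito, 100)])
        clf = classify_mito_kmers(table, mito_cov_estimate=100,
                                  autosomal_cov_estimate=5)
        assert clf.threshold == pytest.approx((5 * 100) ** 0.5)
        mito_pass = sum(clf(mito[i:i + 23]) for i in range(len(mito) - 22))
        assert mito_pass / (len(mito) - 22) > 0.99

    def test_modes_inferred_from_bimodal_histogram(self):
        rng = np.random.default_rng(1)
        nuclear = "".join(rng.choice(list("ACGT"), size=6000))
        mito = "".join(rng.choice(list("ACGT"), size=2000))
        table = _table_from_counts([(nuclear, 5), (mito, 100)])
        low, high = estimate_coverage_modes(table)
        assert 3 <= low <= 8
        assert 70 <= high <= 140
        clf = classify_mito_kmers(table)
        assert 15 <= clf.threshold <= 32

    def test_unimodal_histogram_demands_estimates(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        table = _table_from_counts([(seq, 7)])
        with pytest.raises(CoverageHistogramError):
            classify_mito_kmers(table)

    def test_predicate_monotone_in_count(self):
        table = KmerTable(k=23, counts={1: 5, 2: 50, 3: 500})
        clf = classify_mito_kmers(table, 100, 1)
        passing = sorted(c for code, c in table.counts.items()
                         if table.counts[code] >= clf.threshold)
        for code, c in table.counts.items():
            if any(c >= p for p in passing):
                assert c >= clf.threshold or c < min(passing)


class TestSeedSelection:
    def test_seed_lies_in_named_feature(self, small_genome, small_reads):
        genome, anns = small_genome
        table = count_kmers(small_reads.all_short_sequences(), 23)
        clf = classify_mito_kmers(table, 100, 1)
        ref = diverged_reference(genome)
        seed = select_seed(ref, anns, "12S rRNA", table, clf)
        feat = next(a for a in anns if a.name == "12S rRNA")
        # provenance: the chosen seed's true origin lies inside the feature
        pos = genome.doubled().find(seed)
        assert feat.start <= pos <= feat.end - 23

    def test_missing_feature(self, small_genome, small_reads):
        genome, anns = small_genome
        table = count_kmers(small_reads.all_short_sequences(), 23)
        with pytest.raises(SeedNotFoundError):
            select_seed(genome, anns, "no such gene", table)

    def test_feature_absent_from_reads(self, small_genome):
        genome, anns = small_genome
        rng = np.random.default_rng(3)
        other = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(50)]
        table = count_kmers(other, 23)
        with pytest.raises(SeedNotFoundError):
            select_seed(genome, anns, "12S rRNA", table)


class TestExtension:
    def test_repeat_free_genome_walks_to_circle_without_forks(self):
        genome = _random_genome(1500, seed=10)
        table = count_kmers([genome.doubled()[:genome.length + 22]], 23)
        clf = classify_mito_kmers(table, 10, 0.1)
        seed = genome.seq[:23]
        state = WalkState(contig=seed, frontier=seed)
        state, outcome = extend_path(state, clf, seed=seed)
        assert outcome.kind == "circular"
        assert normalize_rotation(state.contig[:-23]) == \
            normalize_rotation(genome.seq)

    def test_exact_repeat_creates_fork_where_oracle_says(self):
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), size=800))
        repeat = "".join(rng.choice(list("ACGT"), size=60))
        seq = base[:300] + repeat + base[300:600] + repeat + base[600:]
        genome = CircularSequence("rep", seq)
        table = count_kmers([genome.doubled()[:genome.length + 22]], 23)
        clf = classify_mito_kmers(table, 10, 0.1)
        # oracle: first position along the true path whose successor k-mer
        # set (substring occurrence on either genome strand) is not unique
        doubled = genome.doubled()
        rc_doubled = revcomp(doubled)
        expected_fork = None
        for i in range(genome.length):
            stem = doubled[i + 1:i + 23]
            succ = {b for b in "ACGT"
                    if (stem + b) in doubled or (stem + b) in rc_doubled}
            if len(succ) > 1:
                expected_fork = i
                break
        seed = genome.seq[:23]
        state = WalkState(contig=seed, frontier=seed)
        state, outcome = extend_path(state, clf, seed=seed)
        assert outcome.kind == "fork"
        assert expected_fork is not None
        assert len(state.contig) - 23 == expected_fork

    def test_dead_end_on_linear_fragment(self):
        rng = np.random.default_rng(12)
        frag = "".join(rng.choice(list("ACGT"), size=400))
        table = count_kmers([frag], 23)
        clf = classify_mito_kmers(table, 10, 0.1)
        seed = frag[:23]
        state = WalkState(contig=seed, frontier=seed)
        state, outcome = extend_path(state, clf)
        assert outcome.kind == "deadend"
        assert state.contig == frag

    def test_left_extension_mirrors_right(self):
        genome = _random_genome(1200, seed=13)
        table = count_kmers([genome.doubled()[:genome.length + 22]], 23)
        clf = classify_mito_kmers(table, 10, 0.1)
        seed = genome.seq[500:523]
        state = WalkState(contig=seed, frontier=seed, direction="left")
        state, outcome = extend_path(state, clf, seed=seed)
        assert outcome.kind == "circular"
        assert normalize_rotation(state.contig[23:]) == \
            normalize_rotation(genome.seq)


class TestForkResolution:
    def test_amplicon_length_mismatch_rejects_branch(self, small_genome):
        genome, _ = small_genome
        contig = genome.seq[:2000]
        good = genome.seq[2000:2600]
        # wrong branch: 300 bp deletion relative to the true continuation
        bad = genome.seq[2300:2900]
        ev = simulate_pcr_evidence(genome, [(1800, 2550)])
        cfg = AssemblyConfig()
        assert _amplicon_verdict(good, contig, ev, cfg) == "consistent"
        assert _amplicon_verdict(bad, contig, ev, cfg) == "inconsistent"

    def test_no_informative_evidence_is_ambiguous(self, small_genome):
        genome, _ = small_genome
        contig = genome.seq[:2000]
        fork = ForkEvent(position=2000,
                         branches=[genome.seq[2000:2400], "A" * 400])
        ev = EvidenceSet([], (500.0, 50.0), [])
        resolve_fork(fork, ev, contig=contig, cfg=AssemblyConfig())
        assert fork.ambiguous
        assert fork.resolution is None

    def test_spanning_long_read_picks_true_branch(self, small_genome):
        genome, _ = small_genome
        contig = genome.seq[:2000]
        good = genome.seq[2000:2600]
        rng = np.random.default_rng(14)
        bad = good[:80] + "".join(rng.choice(list("ACGT"), size=520))
        read = genome.seq[1200:2900]   # error-free spanning read
        from mitoforge.synth import LongRead
        ev = EvidenceSet([], (500.0, 50.0),
                         [LongRead(read, 1200, "+", 0.0)])
        fork = ForkEvent(position=2000, branches=[good, bad])
        resolve_fork(fork, ev, contig=contig, cfg=AssemblyConfig())
        assert fork.resolution == 0
        assert fork.verdicts[1]["long_read"] == "inconsistent"


class TestEndToEnd:
    def test_duplicated_cr_genome_recovered_exactly(self, small_genome,
                                                    small_reads):
        genome, anns = small_genome
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome),
                                   long_reads=small_reads.long_reads)
        ref = diverged_reference(genome)
        cfg = AssemblyConfig(mito_cov_estimate=100.0,
                             autosomal_cov_estimate=1.0)
        report = assemble_mitogenome(small_reads, ref, anns, ev, cfg)
        assert report.circularized
        assert report.assembled.length == genome.length
        assert report.assembled.seq == normalize_rotation(genome.seq)
        assert all(c.passed for c in report.validation.values())

    def test_without_long_reads_fork_is_ambiguous(self, small_genome):
        genome, anns = small_genome
        reads = simulate_reads(genome, ReadProfile(coverage=100.0), seed=55)
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome))
        ref = diverged_reference(genome)
        cfg = AssemblyConfig(mito_cov_estimate=100.0,
                             autosomal_cov_estimate=1.0)
        with pytest.raises(AmbiguousForkError) as exc:
            assemble_mitogenome(reads, ref, anns, ev, cfg)
        assert len(exc.value.fork.branches) >= 2

    def test_strand_invariance_of_normalized_assembly(self, small_genome,
                                                      small_reads):
        # assembling against the reverse-complemented reference (with
        # flipped annotations) yields the identical canonical sequence
        genome, anns = small_genome
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome),
                                   long_reads=small_reads.long_reads)
        ref = diverged_reference(genome)
        L = ref.length
        ref_rc = CircularSequence("ref_rc", revcomp(ref.seq))
        anns_rc = [FeatureAnnotation(a.name, a.kind,
                                     (L - a.end) % L,
                                     (L - a.end) % L + a.length,
                                     "-" if a.strand == "+" else "+")
                   for a in anns]
        cfg = AssemblyConfig(mito_cov_estimate=100.0,
                             autosomal_cov_estimate=1.0)
        fwd = assemble_mitogenome(small_reads, ref, anns, ev, cfg)
        rev = assemble_mitogenome(small_reads, ref_rc, anns_rc, ev, cfg)
        assert fwd.assembled.seq == rev.assembled.seq

    def test_repeat_free_genome_short_reads_only_no_forks(self):
        genome = _random_genome(3000, seed=15)
        anns = [FeatureAnnotation("12S rRNA", FeatureKind.RRNA, 100, 500)]
        reads = simulate_reads(genome, ReadProfile(coverage=80.0), seed=16)
        ev = simulate_pcr_evidence(genome, default_primer_tiling(
            genome, amplicon_length=1000, overlap=200))
        cfg = AssemblyConfig(mito_cov_estimate=80.0, autosomal_cov_estimate=1.0)
        report = assemble_mitogenome(reads, genome, anns, ev, cfg)
        assert report.forks == []
        assert report.assembled.seq == normalize_rotation(genome.seq)


class TestValidation:
    def test_truth_passes_all_three_checks(self, small_genome, small_reads):
        genome, _ = small_genome
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome),
                                   long_reads=small_reads.long_reads)
        checks = validate_assembly(genome, ev, small_reads)
        assert all(c.passed for c in checks.values())
        assert set(checks) == {"long_read_consistency",
                               "amplicon_length_consistency",
                               "coverage_continuity"}

    def test_deletion_fails_amplicon_check(self, small_genome, small_reads):
        genome, _ = small_genome
        ev = simulate_pcr_evidence(genome, default_primer_tiling(genome),
                                   long_reads=small_reads.long_reads)
        broken = CircularSequence("del", genome.seq[:1000] + genome.seq[1500:])
        checks = validate_assembly(broken, ev, small_reads)
        assert not checks["amplicon_length_consistency"].passed

    def test_novel_insertion_fails_coverage_continuity(self, small_genome,
                                                       small_reads):
        genome, _ = small_genome
        rng = np.random.default_rng(17)
        insert = "".join(rng.choice(list("ACGT"), size=50))
        broken = CircularSequence("ins",
                                  genome.seq[:1000] + insert + genome.seq[1000:])
        ev = simulate_pcr_evidence(genome, [])
        checks = validate_assembly(broken, ev, small_reads)
        assert not checks["coverage_continuity"].passed
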