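"""Replicated parameter-recovery benchmarks for the assembler and the NUMT
finder, run on freshly generated synthetic data.

These are the package's headline operating characteristics: exact-recovery
and ambiguity rates of the walkthrough assembler with and without spanning
long reads, and recall/precision of NUMT discovery against planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np

from .assemble import AmbiguousForkError, AssemblyConfig, assemble_mitogenome
from .numt import NumtConfig, local_search
from .seqs import CircularSequence, normalize_rotation
from .synth import (MitogenomeSpec, ReadProfile, default_primer_tiling,
                    generate_mitogenome, mutate_substitutions, plant_numts,
                    simulate_pcr_evidence, simulate_reads)


def _sub_seed(seed: int, salt: str) -> int:
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class AssemblyBenchmarkResult:
    n_replicates: int
    n_exact: int                # exact recovery with spanning long reads
    n_ambiguous: int            # AMBIGUOUS outcome with long reads withheld
    failures: list[str]

    @property
    def exact_recovery_rate(self) -> float:
        return self.n_exact / self.n_replicates

    @property
    def ambiguous_rate(self) -> float:
        return self.n_ambiguous / self.n_replicates


def assembly_recovery_benchmark(n_replicates: int = 20,
                                seed: int = 0,
                                coverage: float = 100.0,
                                n_long: int = 3,
                                long_error: float = 0.10,
                                spec: MitogenomeSpec | None = None
                                ) -> AssemblyBenchmarkResult:
    """Replicate the default assembly scenario: a genome with a
    0.98-identity duplicated control region, deep error-free paired reads,
    and three long reads spanning the duplicated-CR block at the given
    error rate.  Each replicate is assembled twice — with the long reads
    (expected outcome: exact sequence recovery after rotation/strand
    normalization) and without them (expected outcome: an AMBIGUOUS fork
    report, the automated analogue of needing manual intervention)."""
    base = spec or MitogenomeSpec()
    n_exact = n_ambiguous = 0
    failures: list[str] = []
    for i in range(n_replicates):
        gspec = dataclasses.replace(base, rng_seed=_sub_seed(seed, f"g{i}"))
        genome, anns = generate_mitogenome(gspec)
        cr1 = next(a for a in anns if a.name == "CR1")
        cr2 = next(a for a in anns if a.name == "CR2")
        span = (max(0, cr1.start - 300), cr2.end + 300)
        ref = CircularSequence(
            "reference",
            mutate_substitutions(genome.seq, round(0.02 * genome.length),
                                 np.random.default_rng(_sub_seed(seed, f"r{i}"))))
        cfg = AssemblyConfig(mito_cov_estimate=coverage,
                             autosomal_cov_estimate=1.0)

        reads = simulate_reads(
            genome, ReadProfile(coverage=coverage, n_long=n_long,
                                long_error=long_error, long_span=span),
            seed=_sub_seed(seed, f"reads{i}"))
        evidence = simulate_pcr_evidence(genome, default_primer_tiling(genome),
                                         long_reads=reads.long_reads)
        try:
            report = assemble_mitogenome(reads, ref, anns, evidence, cfg)
            if report.assembled.seq == normalize_rotation(genome.seq):
                n_exact += 1
            else:
                failures.append(f"replicate {i}: assembled != truth")
        except Exception as exc:    # noqa: BLE001 - recorded, not raised
            failures.append(f"replicate {i}: {type(exc).__name__}: {exc}")

        reads_nolong = simulate_reads(
            genome, ReadProfile(coverage=coverage, n_long=0),
            seed=_sub_seed(seed, f"nl{i}"))
        evidence_nolong = simulate_pcr_evidence(genome,
                                                default_primer_tiling(genome))
        try:
            assemble_mitogenome(reads_nolong, ref, anns, evidence_nolong, cfg)
            failures.append(f"replicate {i}: resolved without long reads")
        except AmbiguousForkError:
            n_ambiguous += 1
        except Exception as exc:    # noqa: BLE001
            failures.append(f"replicate {i} (no long reads): "
                            f"{type(exc).__name__}: {exc}")
    return AssemblyBenchmarkResult(n_replicates, n_exact, n_ambiguous, failures)


@dataclass
class NumtBenchmarkResult:
    n_replicates: int
    recall: float
    precision: float
    n_planted: int
    n_hits: int


def numt_recovery_benchmark(n_replicates: int = 20,
                            seed: int = 0,
                            background_length: int = 200_000,
                            n_planted: int = 10,
                            length_range: tuple[int, int] = (150, 3000),
                            identity_range: tuple[float, float] = (0.70, 0.95),
                            config: NumtConfig | None = None
                            ) -> NumtBenchmarkResult:
    """Plant mitogenome copies in random nuclear backgrounds and measure
    recovery.  A planted copy counts as found when a hit covers at least
    half of it; a hit counts as true when at least half of it lies inside
    a planted copy."""
    spec = MitogenomeSpec(rng_seed=_sub_seed(seed, "numt-genome"))
    genome, _ = generate_mitogenome(spec)
    cfg = config or NumtConfig()
    tp = planted_total = hit_total = hit_tp = 0
    for i in range(n_replicates):
        bg = plant_numts(background_length, genome, n_planted,
                         length_range=length_range,
                         identity_range=identity_range,
                         seed=_sub_seed(seed, f"bg{i}"))
        hits = local_search(genome, [("background", bg.seq)], cfg)
        spans = [(p.insertion_pos, p.insertion_pos + p.length)
                 for p in bg.planted]

        def overlap(a0, a1, b0, b1):
            return max(0, min(a1, b1) - max(a0, b0))

        for lo, hi in spans:
            planted_total += 1
            if any(overlap(h.nuclear_start, h.nuclear_end, lo, hi)
                   >= 0.5 * (hi - lo) for h in hits):
                tp += 1
        for h in hits:
            hit_total += 1
            if any(overlap(h.nuclear_start, h.nuclear_end, lo, hi)
                   >= 0.5 * h.nuclear_span() for lo, hi in spans):
                hit_tp += 1
    return NumtBenchmarkResult(
        n_replicates,
        recall=tp / planted_total if planted_total else 0.0,
        precision=hit_tp / hit_total if hit_total else 1.0,
        n_planted=planted_total, n_hits=hit_total)
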