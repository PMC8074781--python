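"""Synthetic mitogenomics data generator.

Produces ground-truth circular mitogenomes with a duplicated control region,
NUMT-bearing nuclear backgrounds, short/long read sets and PCR amplicon
evidence, so that every downstream stage of the pipeline can be exercised
against known truth.

Conventions
-----------
* One seeded :class:`numpy.random.Generator` threads through all sampling;
  identical spec + seed gives byte-identical output.
* Control-region copies diverge by substitutions only (no indels), applied
  as an exact count per segment so the realised identity tracks the target
  tightly.  NUMT copies diverge by substitutions plus indels at a 10:1
  ratio, exercising gapped alignment downstream.
* Read errors are substitutions at a uniform per-base rate.  Platform error
  profiles (indel-rich long reads, quality models, chimeras) are
  deliberately not emulated; users with real data correct long reads with
  their usual tools before assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqs import CircularSequence, FeatureAnnotation, FeatureKind, revcomp
from .seqs import global_identity

BASES = "ACGT"


class SpecError(ValueError):
    """An infeasible synthetic-genome specification."""


class PlacementError(RuntimeError):
    """Requested NUMT copies cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# mitogenome specification
# ---------------------------------------------------------------------------

def default_feature_template() -> list[tuple[str, FeatureKind, int]]:
    """An avian-style gene complement: 14 protein-coding features (13 genes
    plus one pseudogene), 23 tRNA features (22 genes plus one pseudogene)
    and 2 rRNAs, in a parrot-like order with the duplicated control region
    and its flanking duplicated block near the end.

    Control regions appear as ``("CR1"|"CR2", CR, 0)`` placeholders; their
    length comes from the spec's ``cr_length``.
    """
    P, T, R, C = FeatureKind.PCG, FeatureKind.TRNA, FeatureKind.RRNA, FeatureKind.CR
    trna = lambda n: (f"tRNA-{n}", T, 70)
    return [
        trna("Phe"), ("12S rRNA", R, 975), trna("Val"), ("16S rRNA", R, 1600),
        trna("Leu1"), ("ND1", P, 975), trna("Ile"), trna("Gln"), trna("Met"),
        ("ND2", P, 1035), trna("Trp"), trna("Ala"), trna("Asn"), trna("Cys"),
        trna("Tyr"), ("COX1", P, 1545), trna("Ser1"), trna("Asp"),
        ("COX2", P, 684), trna("Lys"), ("ATP8", P, 165), ("ATP6", P, 681),
        ("COX3", P, 783), trna("Gly"), ("ND3", P, 348), trna("Arg"),
        ("ND4L", P, 294), ("ND4", P, 1374), trna("His"), trna("Ser2"),
        trna("Leu2"), ("ND5", P, 1812), ("CYTB", P, 1140), trna("Thr"),
        trna("Pro"), ("ND6", P, 519), trna("Glu"), ("CR1", C, 0),
        ("psi-ND6", P, 300), ("psi-tRNA-Glu", T, 70), ("CR2", C, 0),
    ]


@dataclass
class MitogenomeSpec:
    """Parameters of a synthetic circular mitogenome.

    Defaults emulate a parrot-scale mitogenome: ~18 kb total, two ~1 kb
    control-region copies at 0.98 identity, each carrying a 50 bp x 6
    tandem-repeat tract.
    """

    total_length: int = 18000
    feature_template: list[tuple[str, FeatureKind, int]] = field(
        default_factory=default_feature_template)
    cr_length: int = 1000
    cr_copy_identity: float = 0.98
    tr_unit: int = 50
    tr_copies_cr1: int = 6
    tr_copies_cr2: int = 6
    gc_target: float = 0.45
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.cr_copy_identity <= 1.0):
            raise SpecError("cr_copy_identity must lie in [0, 1]")
        if self.tr_unit * max(self.tr_copies_cr1, self.tr_copies_cr2) >= self.cr_length:
            raise SpecError("tandem-repeat tract must fit inside the control region")
        total = sum(ln if kind is not FeatureKind.CR else self.cr_length
                    for _, kind, ln in self.feature_template)
        if total > self.total_length:
            raise SpecError(
                f"feature lengths sum to {total} > total_length {self.total_length}")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=n, p=p))


def mutate_substitutions(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_sub`` substitutions at distinct random positions."""
    if n_sub <= 0:
        return seq
    if n_sub > len(seq):
        raise ValueError("more substitutions than bases")
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


def mutate_substitutions_dispersed(seq: str, n_sub: int,
                                   rng: np.random.Generator) -> str:
    """Exactly ``n_sub`` substitutions, one per equal-width window (at a
    random offset within each), so identical runs between variant sites are
    bounded by about twice the mean spacing.

    Used for control-region copy divergence: the bounded runs keep every
    read-length window of either copy anchored by at least one diagnostic
    site, while still leaving shared stretches far longer than k to fork
    the k-mer walk.  See the methods note for what this does and does not
    emulate about real control-region pairs.
    """
    if n_sub <= 0:
        return seq
    if n_sub > len(seq):
        raise ValueError("more substitutions than bases")
    edges = np.linspace(0, len(seq), n_sub + 1).astype(int)
    out = list(seq)
    for lo, hi in zip(edges[:-1], edges[1:]):
        p = int(rng.integers(lo, max(hi, lo + 1)))
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


def mutate_with_indels(seq: str, n_sub: int, n_indel: int,
                       rng: np.random.Generator) -> str:
    """Exact-count substitutions plus ``n_indel`` single-base indels
    (insertions and deletions in roughly equal numbers)."""
    out = list(mutate_substitutions(seq, n_sub, rng))
    for _ in range(n_indel):
        p = int(rng.integers(len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            del out[p]
        else:
            out.insert(p, BASES[rng.integers(4)])
    return "".join(out)


def _build_cr_pair(spec: MitogenomeSpec, rng: np.random.Generator
                   ) -> tuple[str, str, tuple[int, int], tuple[int, int]]:
    """Returns (cr1, cr2, tr_span_in_cr1, tr_span_in_cr2).

    CR2 is CR1 with exact-count substitutions applied per segment; its
    tandem-repeat unit is mutated once and then repeated, so each copy's
    tract stays internally exact (mimicking concerted homogenisation of
    repeat units).
    """
    core = spec.cr_length - spec.tr_unit * spec.tr_copies_cr1
    left = core // 2
    a = _random_seq(rng, left, spec.gc_target)
    unit = _random_seq(rng, spec.tr_unit, spec.gc_target)
    b = _random_seq(rng, core - left, spec.gc_target)
    div = 1.0 - spec.cr_copy_identity

    def nsub(n: int, at_least_one: bool = False) -> int:
        k = round(div * n)
        if at_least_one and div > 0:
            k = max(k, 1)
        return k

    a2 = mutate_substitutions_dispersed(a, nsub(len(a)), rng)
    unit2 = mutate_substitutions(unit, nsub(len(unit), at_least_one=True), rng)
    b2 = mutate_substitutions_dispersed(b, nsub(len(b)), rng)
    cr1 = a + unit * spec.tr_copies_cr1 + b
    cr2 = a2 + unit2 * spec.tr_copies_cr2 + b2
    tr1 = (len(a), len(a) + spec.tr_unit * spec.tr_copies_cr1)
    tr2 = (len(a2), len(a2) + spec.tr_unit * spec.tr_copies_cr2)
    return cr1, cr2, tr1, tr2


def generate_mitogenome(spec: MitogenomeSpec
                        ) -> tuple[CircularSequence, list[FeatureAnnotation]]:
    """Generate a circular mitogenome and its feature annotation.

    The two control-region copies have pairwise identity approximately
    ``spec.cr_copy_identity`` and each contains a tandem-repeat tract
    (annotated with kind ``TR``).  Remaining length is distributed as
    intergenic spacer between features.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    cr1, cr2, tr1, tr2 = _build_cr_pair(spec, rng)
    cr_seqs = {"CR1": (cr1, tr1), "CR2": (cr2, tr2)}

    feature_total = sum(ln if kind is not FeatureKind.CR else len(cr_seqs[name][0])
                       for name, kind, ln in spec.feature_template)
    slack = spec.total_length - feature_total
    n_feat = len(spec.feature_template)
    # distribute spacer bases uniformly between features
    gaps = np.zeros(n_feat, dtype=int)
    if slack > 0:
        gaps += slack // n_feat
        extra = rng.choice(n_feat, size=slack % n_feat, replace=False)
        gaps[extra] += 1

    parts: list[str] = []
    anns: list[FeatureAnnotation] = []
    pos = 0
    for i, (name, kind, ln) in enumerate(spec.feature_template):
        if kind is FeatureKind.CR:
            seq, tr_span = cr_seqs[name]
            anns.append(FeatureAnnotation(name, kind, pos, pos + len(seq)))
            anns.append(FeatureAnnotation(f"{name}-TR", FeatureKind.TR,
                                          pos + tr_span[0], pos + tr_span[1]))
        else:
            seq = _random_seq(rng, ln, spec.gc_target)
            strand = "-" if name in ("ND6", "psi-ND6", "tRNA-Glu", "psi-tRNA-Glu") else "+"
            anns.append(FeatureAnnotation(name, kind, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)
        if gaps[i]:
            parts.append(_random_seq(rng, int(gaps[i]), spec.gc_target))
            pos += int(gaps[i])

    genome = CircularSequence("synthetic_mitogenome", "".join(parts))
    return genome, anns


# ---------------------------------------------------------------------------
# NUMT planting
# ---------------------------------------------------------------------------

@dataclass
class NumtPlant:
    mito_start: int
    mito_end: int           # may exceed mito length (wraparound)
    strand: str
    target_identity: float
    realized_identity: float
    insertion_pos: int      # final coordinate in the assembled background
    length: int             # length of the planted (mutated) copy


@dataclass
class NuclearBackground:
    seq: str
    planted: list[NumtPlant]


def plant_numts(background_length: int,
                mito: CircularSequence,
                n: int,
                length_range: tuple[int, int] = (54, 5499),
                identity_range: tuple[float, float] = (0.648, 0.952),
                seed: int = 0) -> NuclearBackground:
    """Plant ``n`` mutated copies of mitogenome intervals in a random
    nuclear background.

    Interval lengths are drawn log-uniformly from ``length_range`` (giving
    the strongly right-skewed size distribution real NUMT censuses show) and
    target identities uniformly from ``identity_range``; divergence is
    substitutions at rate ``1 - identity`` plus single-base indels at one
    tenth of the substitution count.  The realised identity of each copy
    against its source interval is measured by global alignment and
    recorded.
    """
    lo, hi = length_range
    if not (0 < lo <= hi <= mito.length):
        raise ValueError("length_range must lie within (0, mito.length]")
    ilo, ihi = identity_range
    if not (0.0 < ilo <= ihi < 1.0):
        raise ValueError("identity_range must be a subset of (0, 1)")
    rng = np.random.default_rng(seed)
    background = _random_seq(rng, background_length, 0.41)
    if n == 0:
        return NuclearBackground(background, [])

    # choose distinct, well-separated insertion points in the raw background
    min_gap = 10
    for _ in range(1000):
        points = np.sort(rng.integers(0, background_length, size=n))
        if n == 1 or np.all(np.diff(points) >= min_gap):
            break
    else:
        raise PlacementError(
            f"could not place {n} non-overlapping copies in {background_length} bp")

    copies: list[tuple[int, NumtPlant, str]] = []
    for point in points:
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        length = min(max(length, lo), hi)
        start = int(rng.integers(0, mito.length))
        end = start + length
        source = mito.slice_circular(start, end)
        ident = float(rng.uniform(ilo, ihi))
        # a minimum-edit global alignment recovers fewer differences than
        # were planted (it exploits chance re-alignments, increasingly so at
        # low identity), so the mutation load is calibrated against the
        # measured identity rather than applied open-loop
        scale = 1.0
        best: tuple[float, str, float] | None = None
        for _ in range(8):
            n_sub = min(round((1.0 - ident) * length * scale),
                        int(0.45 * length))
            planted_try = mutate_with_indels(source, n_sub,
                                             round(n_sub / 10), rng)
            realized_try = global_identity(planted_try, source,
                                           denominator="columns")
            err = abs(realized_try - ident)
            if best is None or err < abs(best[0] - ident):
                best = (realized_try, planted_try, err)
            if err <= 0.01:
                break
            scale *= (1.0 - ident) / max(1e-9, 1.0 - realized_try)
            scale = min(scale, 2.5)
        realized, planted = best[0], best[1]
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = planted if strand == "+" else revcomp(planted)
        copies.append((int(point),
                       NumtPlant(start, end, strand, ident, realized, -1,
                                 len(planted)),
                       inserted))

    # splice right-to-left so earlier coordinates stay valid, then shift
    out = background
    for point, _, inserted in sorted(copies, key=lambda c: -c[0]):
        out = out[:point] + inserted + out[point:]
    shift = 0
    plants = []
    for point, plant, inserted in sorted(copies, key=lambda c: c[0]):
        plant.insertion_pos = point + shift
        shift += len(inserted)
        plants.append(plant)
    return NuclearBackground(out, plants)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class PairedRead:
    read1: str
    read2: str
    true_origin: int     # insert start on the forward strand, mod genome length
    true_insert: int
    genome_id: str = ""


@dataclass
class LongRead:
    seq: str
    true_origin: int
    true_strand: str
    error_rate: float
    genome_id: str = ""


@dataclass
class ReadSet:
    paired: list[PairedRead] = field(default_factory=list)
    long_reads: list[LongRead] = field(default_factory=list)
    sanger_like: list[tuple[str, str]] = field(default_factory=list)

    def all_short_sequences(self) -> list[str]:
        out = []
        for pr in self.paired:
            out.append(pr.read1)
            out.append(pr.read2)
        return out


@dataclass
class ReadProfile:
    """Sampling parameters for :func:`simulate_reads`.

    Long reads default to a 3.5 kb mean so sampled lengths fall in the
    3-4 kb band typical of the mitogenome-spanning reads the assembler
    relies on.  ``long_span``, when set to a (start, end) interval, forces
    every long read to cover that interval fully — emulating reads selected
    because they bridge the duplicated control-region block.
    """

    coverage: float = 100.0
    read_length: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    pe_error: float = 0.0
    n_long: int = 0
    long_length_mean: float = 3500.0
    long_length_sd: float = 300.0
    long_error: float = 0.10
    long_span: tuple[int, int] | None = None


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for p in hit:
        alts = base_codes[base_codes != arr[p]]
        arr[p] = alts[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(genomes: list[CircularSequence] | CircularSequence,
                   profile: ReadProfile,
                   seed: int = 0) -> ReadSet:
    """Simulate paired-end and long reads from one or more genomes.

    Paired reads are FR-oriented with normally distributed insert sizes;
    wraparound inserts are supported on circular genomes.  Errors are
    substitutions at the profile's per-base rates.  Every read records its
    true origin.
    """
    if isinstance(genomes, CircularSequence):
        genomes = [genomes]
    rng = np.random.default_rng(seed)
    rs = ReadSet()
    if not (0.0 <= profile.pe_error <= 0.3 and 0.0 <= profile.long_error <= 0.3):
        raise ValueError("error rates must lie in [0, 0.3]")
    for g in genomes:
        L = g.length
        if profile.read_length >= L:
            raise ValueError(f"read length {profile.read_length} >= genome {L}")
        doubled = g.doubled()
        n_pairs = int(round(profile.coverage * L / (2 * profile.read_length)))
        min_insert = 2 * profile.read_length
        for _ in range(n_pairs):
            ins = int(round(rng.normal(profile.insert_mean, profile.insert_sd)))
            ins = max(min_insert, min(ins, L - 1))
            p = int(rng.integers(0, L))
            frag = doubled[p:p + ins]
            r1 = frag[:profile.read_length]
            r2 = revcomp(frag[-profile.read_length:])
            if rng.random() < 0.5:      # which mate got the forward strand
                r1, r2 = r2, r1
            r1 = _apply_errors(r1, profile.pe_error, rng)
            r2 = _apply_errors(r2, profile.pe_error, rng)
            rs.paired.append(PairedRead(r1, r2, p, ins, g.id))
        for _ in range(profile.n_long):
            ln = int(round(rng.normal(profile.long_length_mean,
                                      profile.long_length_sd)))
            ln = max(200, min(ln, L))
            if profile.long_span is not None:
                s0, e0 = profile.long_span
                span = (e0 - s0) % L or L
                if span + 100 > L:
                    raise ValueError("long_span larger than the genome")
                ln = max(ln, span + 100)    # a spanning read must cover the interval
                lo = (s0 - (ln - span)) % L
                offset = int(rng.integers(0, ln - span + 1))
                p = (lo + offset) % L
            else:
                p = int(rng.integers(0, L))
            raw = doubled[p:p + ln]
            strand = "+" if rng.random() < 0.5 else "-"
            seq = raw if strand == "+" else revcomp(raw)
            seq = _apply_errors(seq, profile.long_error, rng)
            rs.long_reads.append(LongRead(seq, p, strand, profile.long_error, g.id))
    return rs


# ---------------------------------------------------------------------------
# PCR amplicon evidence
# ---------------------------------------------------------------------------

@dataclass
class Amplicon:
    id: str
    fwd_pos: int
    rev_pos: int
    expected_length: int
    fwd_seq: str            # forward-primer annealing site, forward strand
    rev_seq: str            # reverse primer (reverse complement of the site)


@dataclass
class EvidenceSet:
    """PCR amplicon definitions, the paired-end insert model, and long
    reads — the three evidence classes arbitrating assembly forks."""

    amplicons: list[Amplicon]
    insert_model: tuple[float, float] = (500.0, 50.0)
    long_reads: list[LongRead] = field(default_factory=list)
    length_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.length_tolerance < 0.5):
            raise ValueError("length_tolerance must lie in (0, 0.5)")


def simulate_pcr_evidence(genome: CircularSequence,
                          primer_pairs: list[tuple[int, int]],
                          primer_length: int = 20,
                          insert_model: tuple[float, float] = (500.0, 50.0),
                          long_reads: list[LongRead] | None = None,
                          length_tolerance: float = 0.10) -> EvidenceSet:
    """Build an :class:`EvidenceSet` from primer positions on a genome.

    Each pair is (forward primer start, reverse end), both 0-based; the
    expected product length is the half-open span, wrapping the origin on
    circular genomes.
    """
    L = genome.length
    amplicons = []
    for i, (fwd, rev) in enumerate(primer_pairs):
        if not (0 <= fwd < L and 0 <= rev <= L):
            raise ValueError(f"primer positions ({fwd}, {rev}) outside genome")
        length = (rev - fwd) % L
        if length == 0:
            raise ValueError(f"zero-length amplicon at ({fwd}, {rev})")
        fwd_seq = genome.slice_circular(fwd, fwd + primer_length)
        rev_site_start = (rev - primer_length) % L
        rev_seq = revcomp(genome.slice_circular(rev_site_start,
                                                rev_site_start + primer_length))
        amplicons.append(Amplicon(f"amp{i:03d}", fwd, rev % L, length,
                                  fwd_seq, rev_seq))
    return EvidenceSet(amplicons, insert_model, list(long_reads or []),
                       length_tolerance)


def default_primer_tiling(genome: CircularSequence,
                          amplicon_length: int = 2000,
                          overlap: int = 500) -> list[tuple[int, int]]:
    """Overlapping amplicon design around the circle; default products are
    2 kb, inside the 0.5-3.1 kb range practical for long-range PCR."""
    step = amplicon_length - overlap
    L = genome.length
    pairs = []
    for start in range(0, L, step):
        pairs.append((start, (start + amplicon_length) % L))
    return pairs
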