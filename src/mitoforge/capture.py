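"""Hybridization-capture computations: bait tiling design, a simple
gapless read placer against a reference mitogenome, and per-individual
consensus calling.

The placer exists to make the capture-and-resequence stage of the pipeline
self-testable on simulated reads; it is exact-seeded and Hamming-extended
(no indels), with ambiguous placements (ties between repeat copies)
deliberately left unplaced rather than guessed.  Real datasets with indels
relative to the reference should be mapped externally and supplied as
consensus FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqs import CircularSequence, revcomp
from .synth import ReadSet


@dataclass
class BaitSet:
    reference_id: str
    bait_length: int
    tiling: int
    step: int
    baits: list[tuple[int, str]]    # (start on reference, sequence)


def design_baits(reference: CircularSequence,
                 bait_length: int = 80,
                 tiling: int = 4) -> BaitSet:
    """Tile capture baits around the reference: probes of ``bait_length``
    starting every ``bait_length / tiling`` bases, so every position of a
    circular reference is covered exactly ``tiling`` times (when the step
    divides the length)."""
    if bait_length % tiling != 0:
        raise ValueError("bait_length must be divisible by tiling")
    if bait_length > reference.length:
        raise ValueError("bait longer than reference")
    step = bait_length // tiling
    L = reference.length
    baits = []
    if reference.is_circular:
        for start in range(0, L, step):
            baits.append((start, reference.slice_circular(start, start + bait_length)))
    else:
        for start in range(0, L - bait_length + 1, step):
            baits.append((start, reference.seq[start:start + bait_length]))
    return BaitSet(reference.id, bait_length, tiling, step, baits)


def bait_coverage(bait_set: BaitSet, reference_length: int) -> np.ndarray:
    """Per-position probe coverage implied by a bait set (circular)."""
    cov = np.zeros(reference_length, dtype=int)
    for start, seq in bait_set.baits:
        idx = (start + np.arange(len(seq))) % reference_length
        np.add.at(cov, idx, 1)
    return cov


# ---------------------------------------------------------------------------
# read placement
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    seq: str        # read sequence oriented to the reference forward strand
    start: int      # 0-based start on the reference (mod length)
    strand: str
    mismatches: int


def place_reads(reads, reference: CircularSequence,
                max_mismatch_frac: float = 0.05,
                seed_length: int = 20) -> list[Placement]:
    """Place each read at the position minimising mismatches.

    Candidate positions come from exact seed lookups at several read
    offsets; each candidate is scored by Hamming distance (gapless).  A
    read is unplaced when its best placement exceeds ``max_mismatch_frac``
    or when two distinct placements tie for best — e.g. reads wholly inside
    an exact two-copy repeat.
    """
    L = reference.length
    doubled = reference.doubled()
    dbytes = np.frombuffer(doubled.encode(), dtype=np.uint8)
    index: dict[str, list[int]] = {}
    for i in range(min(len(doubled) - seed_length + 1, L + seed_length)):
        index.setdefault(doubled[i:i + seed_length], []).append(i % L)

    if isinstance(reads, ReadSet):
        seqs = reads.all_short_sequences()
    else:
        seqs = list(reads)

    placements = []
    for read in seqs:
        n = len(read)
        if n < seed_length or n > L:
            continue
        candidates: set[tuple[int, str]] = set()
        for oriented, strand in ((read, "+"), (revcomp(read), "-")):
            for off in range(0, n - seed_length + 1, seed_length):
                for pos in index.get(oriented[off:off + seed_length], ()):
                    candidates.add(((pos - off) % L, strand))
        best: tuple[int, int, str] | None = None
        tie = False
        for start, strand in sorted(candidates):
            oriented = read if strand == "+" else revcomp(read)
            window = dbytes[start:start + n]
            if window.size < n:
                continue
            mism = int(np.count_nonzero(
                window != np.frombuffer(oriented.encode(), dtype=np.uint8)))
            if best is None or mism < best[0]:
                best = (mism, start, strand)
                tie = False
            elif mism == best[0] and (start, strand) != (best[1], best[2]):
                tie = True
        if best is None or tie or best[0] > max_mismatch_frac * n:
            continue
        oriented = read if best[2] == "+" else revcomp(read)
        placements.append(Placement(oriented, best[1], best[2], best[0]))
    return placements


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSequence:
    individual_id: str
    seq: str                # N at uncalled sites
    depth: np.ndarray
    min_depth: int


_BASE_ORD = {b: i for i, b in enumerate("ACGT")}


def call_consensus(placements: list[Placement],
                   reference: CircularSequence,
                   min_depth: int = 3,
                   individual_id: str = "consensus") -> ConsensusSequence:
    """Per-position majority base over placed reads; positions with depth
    below ``min_depth`` or with an exact tie are called N."""
    L = reference.length
    counts = np.zeros((4, L), dtype=np.int64)
    for pl in placements:
        enc = np.frombuffer(pl.seq.encode(), dtype=np.uint8)
        idx = (pl.start + np.arange(len(enc))) % L
        for bi, base in enumerate(b"ACGT"):
            sel = idx[enc == base]
            if sel.size:
                np.add.at(counts[bi], sel, 1)
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    argtop = counts.argmax(axis=0)
    n_top = (counts == top[None, :]).sum(axis=0)
    called = (depth >= min_depth) & (n_top == 1) & (top > 0)
    seq = np.full(L, ord("N"), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq[called] = bases[argtop[called]]
    return ConsensusSequence(individual_id, seq.tobytes().decode(), depth, min_depth)
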