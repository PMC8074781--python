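"""Core sequence types shared across the package.

Coordinates are 0-based, half-open everywhere.  On a circular sequence they
are interpreted modulo the sequence length, and a feature whose interval
wraps the origin is encoded with ``end > length`` (never ``end > 2*length``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import edlib

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureKind(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CR = "CR"
    TR = "TR"
    SSA = "ssA"
    OTHER = "other"


@dataclass
class CircularSequence:
    """A (possibly circular) DNA sequence.

    The unit of assembly, annotation and comparison.  ``slice_circular``
    accepts any 0 <= start < length and end <= 2*length so that intervals
    wrapping the origin can be extracted without special-casing.
    """

    id: str
    seq: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in sequence {self.id!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice_circular(self, start: int, end: int) -> str:
        L = self.length
        if not (0 <= start < L):
            raise ValueError(f"start {start} outside [0, {L})")
        if end < start or end - start > L:
            raise ValueError(f"bad interval [{start}, {end}) on length {L}")
        if end <= L:
            return self.seq[start:end]
        if not self.is_circular:
            raise ValueError("interval wraps origin of a linear sequence")
        return self.seq[start:] + self.seq[: end - L]

    def doubled(self) -> str:
        """Sequence concatenated with itself; the standard trick for
        circular substring/alignment operations."""
        return self.seq + self.seq if self.is_circular else self.seq


@dataclass
class FeatureAnnotation:
    name: str
    kind: FeatureKind
    start: int
    end: int  # half-open; may exceed length to denote wraparound
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# rotation / strand normalisation
# ---------------------------------------------------------------------------

def _least_rotation(s: str) -> int:
    """Index of the lexicographically minimal rotation (Booth's algorithm)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def normalize_rotation(seq: str) -> str:
    """Canonical representative of a circular sequence: the lexicographically
    minimal rotation over both strands.

    Two circular molecules are the same iff their canonical forms are equal,
    which is how assemblies are compared to ground truth.
    """
    if not seq:
        return seq
    fwd = seq
    rev = revcomp(seq)
    best_f = _least_rotation(fwd)
    best_r = _least_rotation(rev)
    cand_f = fwd[best_f:] + fwd[:best_f]
    cand_r = rev[best_r:] + rev[:best_r]
    return min(cand_f, cand_r)


# ---------------------------------------------------------------------------
# pairwise identity helpers (edlib-backed)
# ---------------------------------------------------------------------------

def _identity_from_cigar(cigar: str) -> tuple[int, int, int]:
    """(matches, columns with a base on both sides, total columns) from an
    edlib CIGAR."""
    matches = 0
    both = 0
    total = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            total += num
            if ch == "=":
                matches += num
                both += num
            elif ch == "X":
                both += num
            # I / D columns have a gap on one side
            num = 0
    return matches, both, total


def global_identity(a: str, b: str, denominator: str = "bases") -> float:
    """Global-alignment identity of two sequences.

    ``denominator="bases"``: matches over aligned columns where both
    sequences have a base (gap columns excluded) — the convention used for
    mitogenome-panel identities.  ``denominator="columns"``: matches over
    all alignment columns including gaps, which keeps tracking divergence
    down to much lower identities (a minimum-edit alignment of even random
    sequences shows ~70% identity under the gap-excluded convention).
    """
    if not a or not b:
        raise ValueError("empty sequence in identity computation")
    res = edlib.align(a, b, mode="NW", task="path")
    matches, both, total = _identity_from_cigar(res["cigar"])
    denom = both if denominator == "bases" else total
    if denom == 0:
        return 0.0
    return matches / denom


def locate_infix(query: str, target: str) -> tuple[int, int, float] | None:
    """Best gapped placement of ``query`` inside ``target``.

    Returns (start, end, identity) of the best infix alignment, or None if
    nothing aligns.  Identity counts matches over all alignment columns
    (gaps included): under a minimum-edit alignment the gap-excluded
    convention saturates near 0.7 even for unrelated sequences, which would
    make identity thresholds meaningless.  Used for anchoring long reads
    and transferring annotations.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    matches, _, total = _identity_from_cigar(res["cigar"])
    ident = matches / total if total else 0.0
    return start, end + 1, ident
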