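"""Alignment-based diversity statistics: per-pair difference lists,
fixed-window variant-density tracks, nucleotide diversity (pi) and a
pairwise identity matrix.

All operations work on an :class:`AlignmentMatrix` — a taxa x columns
character matrix over {A,C,G,T,N,-} — typically read from an aligned
multi-FASTA.  Non-ACGT characters are treated as missing per pair of
sequences (pairwise deletion), matching the average-pairwise-difference
estimator of nucleotide diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_GAP = ord("-")
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AlignmentMatrix:
    taxa: list[str]
    matrix: np.ndarray          # uint8, shape (n_taxa, n_columns)

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs at least two taxa")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")

    @classmethod
    def from_sequences(cls, named_seqs) -> "AlignmentMatrix":
        items = list(named_seqs.items()) if isinstance(named_seqs, dict) else list(named_seqs)
        taxa = [t for t, _ in items]
        seqs = [s.upper() for _, s in items]
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("aligned sequences must have equal length")
        mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
        return cls(taxa, mat)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None


@dataclass
class DifferenceList:
    reference_taxon: str
    other_taxon: str
    positions: list[int]        # strictly increasing alignment columns


@dataclass
class DensityTrack:
    window: int
    counts: np.ndarray
    total: int


def pairwise_differences(aln: AlignmentMatrix, ref_taxon: str, other: str,
                         count_gaps: bool = False) -> DifferenceList:
    """Columns where the two taxa disagree.  Columns where either has N
    are skipped; a gap opposite a base counts only when ``count_gaps``."""
    a = aln.row(ref_taxon)
    b = aln.row(other)
    n = ord("N")
    informative = (a != n) & (b != n)
    if not count_gaps:
        informative &= (a != _GAP) & (b != _GAP)
    diff = (a != b) & informative
    return DifferenceList(ref_taxon, other, np.nonzero(diff)[0].tolist())


def block_density(diffs: DifferenceList, length: int,
                  window: int = 100) -> DensityTrack:
    """Fixed-window counts of difference positions; block i covers
    [i*window, (i+1)*window), and the final partial block keeps its raw
    count (no per-bp normalisation)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n_blocks = max(1, -(-length // window))
    counts = np.zeros(n_blocks, dtype=int)
    for p in diffs.positions:
        counts[p // window] += 1
    return DensityTrack(window, counts, len(diffs.positions))


def nucleotide_diversity(aln: AlignmentMatrix) -> float:
    """Nucleotide diversity pi: the mean over all unordered sequence pairs
    of (differences / comparable columns), where a column is comparable for
    a pair when both characters are in {A,C,G,T} (pairwise deletion)."""
    mat = aln.matrix
    acgt = np.isin(mat, _ACGT)
    n = mat.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            comp = acgt[i] & acgt[j]
            m = int(comp.sum())
            if m == 0:
                warnings.warn(
                    f"no comparable columns for pair ({aln.taxa[i]}, {aln.taxa[j]}); "
                    "pair excluded from pi")
                continue
            d = int(np.count_nonzero((mat[i] != mat[j]) & comp))
            vals.append(d / m)
    if not vals:
        raise ValueError("no pair had comparable columns")
    return float(np.mean(vals))


def identity_matrix(aln: AlignmentMatrix) -> np.ndarray:
    """Symmetric percent-identity matrix: matches over columns where both
    taxa have an unambiguous base (gap and N columns excluded); the
    diagonal is 100."""
    mat = aln.matrix
    acgt = np.isin(mat, _ACGT)
    n = mat.shape[0]
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            comp = acgt[i] & acgt[j]
            m = int(comp.sum())
            ident = 100.0 * int(np.count_nonzero((mat[i] == mat[j]) & comp)) / m if m else 0.0
            out[i, j] = out[j, i] = ident
    return out
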