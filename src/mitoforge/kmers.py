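"""Canonical k-mer counting, reference coverage profiling, k-mer read
recruitment, and solid/weak long-read classification.

k-mers are packed 2 bits/base into Python ints (k <= 31 fits in 62 bits);
counting is vectorised with numpy over all reads at once.  A k-mer
containing N (or any non-ACGT character) is skipped entirely.  The
canonical form of a k-mer is the lexicographic minimum of the k-mer and its
reverse complement, which with the A<C<G<T encoding equals the numeric
minimum of the two packed codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import CircularSequence

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = "ACGT"


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer string into an integer code (first base most
    significant).  Raises on non-ACGT characters."""
    code = 0
    for ch in kmer:
        v = _ENC[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_DEC[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> int:
    return min(code, revcomp_code(code, k))


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical codes, validity mask) for every length-k window of an
    encoded uint8 array (values 0-3 valid, >=4 invalid/separator)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    a = arr.astype(np.int64)
    for j in range(k):
        win = a[j:j + n]
        fwd = (fwd << 2) | np.where(win < 4, win, 0)
        rc |= np.where(win < 4, 3 - win, 0) << (2 * j)
    bad = (arr >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return np.minimum(fwd, rc), valid


@dataclass
class KmerTable:
    """Canonical k-mer -> count map.

    ``counts`` is keyed by packed integer codes; use :func:`encode_kmer` /
    :func:`decode_kmer` at the string boundary.  ``solid_min`` is the
    minimum count for a k-mer to be considered solid (genuine rather than a
    sequencing error); the default of 3 suppresses singleton errors at the
    deep short-read coverage this pipeline assumes.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)
    solid_min: int = 3

    def get(self, kmer: str) -> int:
        return self.counts.get(canonical_code(encode_kmer(kmer), self.k), 0)

    def get_code(self, code: int) -> int:
        """Count for a packed code (caller must pass the canonical form or
        either strand; both are looked up)."""
        c = self.counts.get(code)
        if c is not None:
            return c
        return self.counts.get(revcomp_code(code, self.k), 0)

    def total_mass(self) -> int:
        return int(sum(self.counts.values()))

    def __len__(self) -> int:
        return len(self.counts)


def count_kmers(reads, k: int = 23) -> KmerTable:
    """Count canonical k-mers over a collection of sequences.

    ``reads`` may be a ReadSet (paired + long + sanger sequences are all
    counted), or any iterable of strings.  Every length-k window of every
    sequence is counted once; reads shorter than k contribute nothing.
    """
    if not (11 <= k <= 31 and k % 2 == 1):
        raise ValueError("k must be odd and in [11, 31]")
    seqs = _as_sequences(reads)
    chunks = []
    sep = np.array([4], dtype=np.uint8)
    for s in seqs:
        chunks.append(_ENC[np.frombuffer(s.encode(), dtype=np.uint8)])
        chunks.append(sep)
    if not chunks:
        return KmerTable(k=k)
    arr = np.concatenate(chunks)
    codes, valid = _window_codes(arr, k)
    uniq, cnt = np.unique(codes[valid], return_counts=True)
    return KmerTable(k=k, counts=dict(zip(uniq.tolist(), cnt.tolist())))


def _as_sequences(reads) -> list[str]:
    if hasattr(reads, "paired"):        # a ReadSet
        seqs = reads.all_short_sequences()
        seqs += [lr.seq for lr in reads.long_reads]
        seqs += [s for s, _ in reads.sanger_like]
        return seqs
    if isinstance(reads, str):
        return [reads]
    return list(reads)


# ---------------------------------------------------------------------------
# reference coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    reference_id: str
    per_start_coverage: np.ndarray   # one entry per k-mer start position


def map_kmer_coverage(table: KmerTable, reference: CircularSequence
                      ) -> CoverageProfile:
    """Table count of the canonical k-mer starting at each reference
    position (0 where absent).  On a circular reference there is one start
    per base (windows wrap the origin); on a linear one, length - k + 1."""
    k = table.k
    if k > reference.length:
        raise ValueError("k exceeds reference length")
    s = reference.doubled() if reference.is_circular else reference.seq
    arr = _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
    codes, valid = _window_codes(arr, k)
    n = reference.length if reference.is_circular else reference.length - k + 1
    cov = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if valid[i]:
            cov[i] = table.counts.get(int(codes[i]), 0)
    return CoverageProfile(reference.id, cov)


# ---------------------------------------------------------------------------
# read recruitment (bait-k-mer filtering)
# ---------------------------------------------------------------------------

def _shared_windows(seq: str, bait: KmerTable) -> int:
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    codes, valid = _window_codes(arr, bait.k)
    return sum(1 for c, v in zip(codes.tolist(), valid.tolist())
               if v and c in bait.counts)


def recruit_reads(reads, bait: KmerTable, min_shared: int = 1):
    """Retain reads (pairs jointly) sharing at least ``min_shared``
    canonical k-mer windows with the bait set.

    This is the in-silico analogue of pulling mitochondrial reads out of a
    whole-genome library with k-mers from a draft mitogenome.  Returns a
    new ReadSet restricted to the recruited reads.
    """
    from .synth import ReadSet   # local import to avoid a cycle
    if len(bait) == 0:
        raise ValueError("bait k-mer table is empty")
    out = ReadSet()
    for pr in reads.paired:
        if _shared_windows(pr.read1, bait) + _shared_windows(pr.read2, bait) >= min_shared:
            out.paired.append(pr)
    for lr in reads.long_reads:
        if _shared_windows(lr.seq, bait) >= min_shared:
            out.long_reads.append(lr)
    for s, aid in reads.sanger_like:
        if _shared_windows(s, bait) >= min_shared:
            out.sanger_like.append((s, aid))
    return out


# ---------------------------------------------------------------------------
# solid/weak long-read classification
# ---------------------------------------------------------------------------

@dataclass
class SolidityMask:
    read_id: str
    mask: np.ndarray                 # per-base bool, True = solid
    trimmed: tuple[int, int]         # longest solid run, half-open


def trim_weak_regions(long_read: str, table: KmerTable,
                      read_id: str = "") -> SolidityMask:
    """Classify each base of a long read as solid or weak and trim to the
    longest solid run.

    A base is solid iff at least one k-mer window covering it has canonical
    count >= ``table.solid_min`` in the short-read table.  A read shorter
    than k is entirely weak.  Ties between equally long runs keep the
    leftmost.
    """
    n = len(long_read)
    mask = np.zeros(n, dtype=bool)
    if n >= table.k:
        arr = _ENC[np.frombuffer(long_read.encode(), dtype=np.uint8)]
        codes, valid = _window_codes(arr, table.k)
        solid_starts = np.nonzero(
            valid & np.array([table.counts.get(int(c), 0) >= table.solid_min
                              for c in codes]))[0]
        for s in solid_starts:
            mask[s:s + table.k] = True
    best = (0, 0)
    run_start = None
    for i in range(n + 1):
        if i < n and mask[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best[1] - best[0]:
                best = (run_start, i)
            run_start = None
    return SolidityMask(read_id, mask, best)
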