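"""NUMT (nuclear copy of mitochondrial DNA) discovery.

A mitogenome is searched against a nuclear assembly with a BLASTN-style
seed-and-extend gapped local alignment: exact word seeds, two-hit
triggering on a diagonal band, windowed Smith-Waterman extension with
affine gaps, and Karlin-Altschul e-values.  Hits above an e-value cutoff
are dropped; identical matches are collapsed; and hits whose identity
exceeds a threshold calibrated from a panel of complete mitogenomes (the
largest interspecific pairwise identity) are discarded as genuine mtDNA
misassigned to the nuclear assembly rather than true NUMTs.

The mitogenome is searched as a doubled string so insertions spanning the
arbitrary origin of the circular molecule are found once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seqs import CircularSequence, global_identity, revcomp


@dataclass
class NumtHit:
    nuclear_id: str
    nuclear_start: int
    nuclear_end: int
    mito_start: int
    mito_end: int            # may exceed mito length when the hit wraps the origin
    strand: str
    aligned_length: int      # alignment columns, gaps included
    identity: float          # percent, gap-excluded denominator
    evalue: float
    score: float

    def nuclear_span(self) -> int:
        return self.nuclear_end - self.nuclear_start


@dataclass
class NumtConfig:
    """Search parameters.

    Scoring defaults (+2/-3, gap open 5, gap extend 2) are the classic
    megablast-era nucleotide defaults, with the published gapped
    Karlin-Altschul parameters for that scheme; they are recorded on the
    report so hit lists are auditable.  ``identity_threshold`` is meant to
    be calibrated with :func:`calibrate_identity_threshold`, not fixed.
    """

    evalue_max: float = 1e-4
    word_size: int = 10
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41
    window_margin: int = 400
    two_hit_max_gap: int = 1000
    diag_tolerance: int = 12
    identity_threshold: float | None = None   # percent


def _as_named_seqs(obj) -> list[tuple[str, str]]:
    if isinstance(obj, str):
        return [("seq", obj)]
    if isinstance(obj, CircularSequence):
        return [(obj.id, obj.seq)]
    if isinstance(obj, dict):
        return [(k, v.seq if isinstance(v, CircularSequence) else str(v))
                for k, v in obj.items()]
    out = []
    for i, s in enumerate(obj):
        if isinstance(s, CircularSequence):
            out.append((s.id, s.seq))
        elif isinstance(s, tuple):
            out.append((s[0], s[1]))
        else:
            out.append((f"seq{i}", str(s)))
    return out


def _aligner(cfg: NumtConfig) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = cfg.match
    al.mismatch_score = cfg.mismatch
    al.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    al.extend_gap_score = -cfg.gap_extend
    return al


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i:i + w]
        if "N" in word:
            continue
        idx.setdefault(word, []).append(i)
    return idx


def _cluster_seeds(seeds: list[tuple[int, int]], cfg: NumtConfig
                   ) -> list[list[tuple[int, int]]]:
    """Group (qpos, spos) seeds into two-hit clusters: diagonals within
    ``diag_tolerance`` (allowing indel drift) and subject positions within
    the two-hit window.  Only clusters with >= 2 seeds trigger extension."""
    if not seeds:
        return []
    keyed = sorted(((s - q), s, q) for q, s in seeds)
    clusters: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int, int]] = [keyed[0]]
    for item in keyed[1:]:
        d, s, q = item
        pd, ps, _ = cur[-1]
        if d - pd <= cfg.diag_tolerance and abs(s - ps) <= cfg.two_hit_max_gap:
            cur.append(item)
        else:
            clusters.append([(q, s) for _, s, q in cur])
            cur = [item]
    clusters.append([(q, s) for _, s, q in cur])
    # a genuine two-hit needs two non-overlapping words, not one chance
    # match of word_size+1 bases seen through two overlapping windows
    return [c for c in clusters
            if len(c) >= 2 and max(s for _, s in c) - min(s for _, s in c)
            >= cfg.word_size]


def _alignment_stats(aln) -> tuple[int, int, int, tuple[int, int], tuple[int, int]]:
    """(matches, both-base columns, total columns, query span, subject span)
    from a Bio.Align alignment."""
    qa, sa = aln.aligned
    matches = 0
    both = 0
    qseq, sseq = aln.sequences
    for (qs, qe), (ss, se) in zip(qa, sa):
        a = qseq[qs:qe]
        b = sseq[ss:se]
        both += len(a)
        matches += sum(1 for x, y in zip(a, b) if x == y)
    q_span = (int(qa[0][0]), int(qa[-1][1]))
    s_span = (int(sa[0][0]), int(sa[-1][1]))
    columns = both
    # add gap columns between consecutive blocks
    for i in range(1, len(qa)):
        columns += (qa[i][0] - qa[i - 1][1]) + (sa[i][0] - sa[i - 1][1])
    return matches, both, columns, q_span, s_span


def local_search(mito: CircularSequence,
                 nuclear,
                 config: NumtConfig | None = None) -> list[NumtHit]:
    """Seed-and-extend local search of a mitogenome against nuclear
    sequences.

    Returns hits with e-value <= ``config.evalue_max``, sorted by nuclear
    coordinate.  Mito coordinates are reported on the circular molecule
    (``mito_end`` may exceed its length for origin-spanning hits); hits
    duplicated across the doubled-string junction are collapsed.
    """
    cfg = config or NumtConfig()
    targets = _as_named_seqs(nuclear)
    if not targets:
        raise ValueError("no nuclear sequences supplied")
    L = mito.length
    doubled = mito.doubled()
    queries = [("+", doubled), ("-", revcomp(doubled))]
    aligner = _aligner(cfg)
    n_total = sum(len(s) for _, s in targets)
    hits: list[NumtHit] = []
    for nuc_id, nuc_seq in targets:
        index = _word_index(nuc_seq, cfg.word_size)
        for strand, query in queries:
            seeds = []
            for q in range(len(query) - cfg.word_size + 1):
                word = query[q:q + cfg.word_size]
                for s in index.get(word, ()):
                    seeds.append((q, s))
            clusters = sorted(_cluster_seeds(seeds, cfg), key=len, reverse=True)
            done_windows: list[tuple[int, int, int, int]] = []
            for cluster in clusters:
                q0 = max(0, min(q for q, _ in cluster) - cfg.window_margin)
                q1 = min(len(query),
                         max(q for q, _ in cluster) + cfg.word_size + cfg.window_margin)
                s0 = max(0, min(s for _, s in cluster) - cfg.window_margin)
                s1 = min(len(nuc_seq),
                         max(s for _, s in cluster) + cfg.word_size + cfg.window_margin)
                # a cluster wholly inside an already-aligned window is the
                # same locus rediscovered through another seed chain
                if any(q0 >= dq0 and q1 <= dq1 and s0 >= ds0 and s1 <= ds1
                       for dq0, dq1, ds0, ds1 in done_windows):
                    continue
                qwin = query[q0:q1]
                swin = nuc_seq[s0:s1]
                try:
                    aln = aligner.align(qwin, swin)[0]
                except (IndexError, ValueError):
                    continue
                done_windows.append((q0, q1, s0, s1))
                score = float(aln.score)
                evalue = cfg.karlin_k * L * n_total * math.exp(
                    -cfg.karlin_lambda * score)
                if evalue > cfg.evalue_max:
                    continue
                matches, both, columns, (qs, qe), (ss, se) = _alignment_stats(aln)
                if both == 0:
                    continue
                mq0, mq1 = q0 + qs, q0 + qe
                if strand == "-":
                    mq0, mq1 = len(query) - (q0 + qe), len(query) - (q0 + qs)
                if mq0 >= L:
                    mq0, mq1 = mq0 - L, mq1 - L
                hits.append(NumtHit(
                    nuclear_id=nuc_id,
                    nuclear_start=s0 + ss, nuclear_end=s0 + se,
                    mito_start=mq0, mito_end=mq1, strand=strand,
                    aligned_length=columns,
                    identity=100.0 * matches / both,
                    evalue=evalue, score=score))
    return _collapse_redundant(hits)


def _collapse_redundant(hits: list[NumtHit]) -> list[NumtHit]:
    """Keep the best-scoring hit among near-duplicate alignments of the
    same nuclear locus (windows from different seed clusters, junction
    duplicates of the doubled mitogenome)."""
    kept: list[NumtHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for g in kept:
            if g.nuclear_id != h.nuclear_id or g.strand != h.strand:
                continue
            ov = min(g.nuclear_end, h.nuclear_end) - max(g.nuclear_start, h.nuclear_start)
            if ov > 0 and ov >= 0.8 * h.nuclear_span():
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.nuclear_id, h.nuclear_start, h.nuclear_end))
    return kept


# ---------------------------------------------------------------------------
# identity-threshold calibration
# ---------------------------------------------------------------------------

def calibrate_identity_threshold(mitogenomes) -> float:
    """Largest pairwise global-alignment identity (percent) over a panel of
    complete mitogenomes.

    Any candidate NUMT more similar to the mitogenome than the closest pair
    of distinct species is more plausibly real mtDNA misassembled into the
    nuclear assembly, so this maximum is the discard threshold.  Accepts
    aligned (gapped) or unaligned sequences; identity counts matches over
    columns where both sequences have a base.
    """
    seqs = [s for _, s in _as_named_seqs(mitogenomes)]
    if len(seqs) < 2:
        raise ValueError("identity calibration needs at least two mitogenomes")
    best = 0.0
    aligned_input = any("-" in s for s in seqs) and len({len(s) for s in seqs}) == 1
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if aligned_input:
                a = np.frombuffer(seqs[i].encode(), dtype=np.uint8)
                b = np.frombuffer(seqs[j].encode(), dtype=np.uint8)
                gap = ord("-")
                mask = (a != gap) & (b != gap)
                ident = float(np.count_nonzero((a == b) & mask)) / max(1, int(mask.sum()))
            else:
                ident = global_identity(seqs[i], seqs[j])
            best = max(best, ident)
    return 100.0 * best


# ---------------------------------------------------------------------------
# filtering and reporting
# ---------------------------------------------------------------------------

def filter_and_dedupe(hits: list[NumtHit], threshold: float) -> list[NumtHit]:
    """Drop hits with identity above the calibrated threshold (percent) and
    collapse identical matches — same nuclear interval, same mito interval,
    same strand — to one.  Idempotent; output sorted by nuclear coordinate."""
    seen = set()
    out = []
    for h in sorted(hits, key=lambda h: (h.nuclear_id, h.nuclear_start,
                                         h.nuclear_end, h.strand)):
        if h.identity > threshold:
            continue
        key = (h.nuclear_id, h.nuclear_start, h.nuclear_end,
               h.mito_start, h.mito_end, h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


@dataclass
class NumtReport:
    n_hits: int
    min_length: int | None
    max_length: int | None
    mean_length: float | None
    sd_length: float | None
    n_over_1000: int
    total_bp: int
    genome_bp: int
    percent_of_genome: float
    identity_min: float | None
    identity_max: float | None
    config: dict = field(default_factory=dict)


def summarize_numts(hits: list[NumtHit], genome_bp: int,
                    config: NumtConfig | None = None) -> NumtReport:
    """Census-style summary of a deduplicated hit list: count, length range
    and moments, number of segments over 1 kb, total NUMT content and its
    fraction of the nuclear genome, and the identity range."""
    lengths = np.array([h.nuclear_span() for h in hits], dtype=float)
    idents = np.array([h.identity for h in hits], dtype=float)
    total = int(lengths.sum()) if hits else 0
    return NumtReport(
        n_hits=len(hits),
        min_length=int(lengths.min()) if hits else None,
        max_length=int(lengths.max()) if hits else None,
        mean_length=float(lengths.mean()) if hits else None,
        sd_length=float(lengths.std(ddof=1)) if len(hits) > 1 else None,
        n_over_1000=int(np.count_nonzero(lengths > 1000)),
        total_bp=total,
        genome_bp=genome_bp,
        percent_of_genome=100.0 * total / genome_bp if genome_bp else 0.0,
        identity_min=float(idents.min()) if hits else None,
        identity_max=float(idents.max()) if hits else None,
        config={} if config is None else {
            "evalue_max": config.evalue_max,
            "word_size": config.word_size,
            "scoring": (config.match, config.mismatch,
                        config.gap_open, config.gap_extend),
            "karlin_params": (config.karlin_lambda, config.karlin_k),
            "identity_threshold": config.identity_threshold,
        })
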