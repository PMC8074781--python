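"""Supervised, reference-assisted de Bruijn k-mer walkthrough assembly of a
circular mitogenome.

The algorithm mirrors a manual hybrid-assembly workflow: count k-mers in the
whole-genome short reads, separate mitochondrial from autosomal k-mers by
their coverage difference, seed the walk at the first k-mer of a named
reference feature (12S rRNA by default) with an exact match in the read
table, and extend base by base until the path bifurcates because of repeats
— here, the duplicated control region and its tandem-repeat tracts.  Where
the original workflow resolved each bifurcation by hand against PCR product
sizes, paired-end inserts and spanning long reads, this module automates
the arbitration: every candidate path extension from a bifurcation is
scored against the three evidence classes and a branch is committed only
when it is the unique one consistent with all informative evidence.
Ambiguity is a first-class outcome, never silently resolved by counts.

Two k-mer orders work together during the walk.  The order-k (default 23)
table separates mitochondrial from nuclear k-mers; a longer "support" order
(default 101, bounded by the short-read length) additionally requires every
extension window to occur verbatim in some short read, which suppresses
chimeric switches between the two control-region copies that order-23
k-mers cannot see.  Long-read comparisons are gapless within a small offset
band, which suits substitution-dominated (or pre-corrected) long reads; see
the methods note for the rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kmers import KmerTable, count_kmers, encode_kmer, map_kmer_coverage, trim_weak_regions
from .seqs import CircularSequence, FeatureAnnotation, locate_infix, normalize_rotation, revcomp
from .synth import EvidenceSet, ReadSet

BASES = "ACGT"


class SeedNotFoundError(RuntimeError):
    """No k-mer of the requested reference feature is present (mito-class)
    in the read k-mer table."""


class AmbiguousForkError(RuntimeError):
    """A bifurcation could not be resolved by the available evidence; the
    automatic walkthrough stops here (the manual-intervention analogue)."""

    def __init__(self, fork: "ForkEvent", forks_so_far: list["ForkEvent"]):
        super().__init__(
            f"ambiguous fork at contig position {fork.position} "
            f"({len(fork.branches)} candidate branches)")
        self.fork = fork
        self.forks = forks_so_far


class CircularizationError(RuntimeError):
    """The walk dead-ended or exceeded the length budget without returning
    to the seed k-mer."""


class CoverageHistogramError(ValueError):
    """The k-mer count histogram is unimodal, so mitochondrial and
    autosomal coverage cannot be inferred; supply explicit estimates."""


# ---------------------------------------------------------------------------
# mito/autosomal k-mer classification
# ---------------------------------------------------------------------------

@dataclass
class MitoKmerClassifier:
    """Predicate deciding whether a k-mer belongs to the high-coverage
    (mitochondrial) class: count >= geometric mean of the mitochondrial and
    autosomal coverage estimates.  Monotone in the count by construction."""

    table: KmerTable
    threshold: float

    def passes_code(self, canonical: int) -> bool:
        return self.table.counts.get(canonical, 0) >= self.threshold

    def __call__(self, kmer: str) -> bool:
        return self.table.get(kmer) >= self.threshold


def estimate_coverage_modes(table: KmerTable) -> tuple[float, float]:
    """Estimate (autosomal, mitochondrial) coverage from the two modes of
    the k-mer count histogram (log2-binned, lightly smoothed).  Raises
    :class:`CoverageHistogramError` when fewer than two separated modes are
    visible."""
    counts = np.fromiter(table.counts.values(), dtype=np.int64)
    if counts.size == 0:
        raise CoverageHistogramError("empty k-mer table")
    logc = np.log2(counts.astype(float))
    span = logc.max() - logc.min()
    if span < 0.5:
        raise CoverageHistogramError(
            "k-mer count histogram is unimodal; supply explicit coverage estimates")
    nbins = max(8, int(span / 0.25))
    hist, edges = np.histogram(logc, bins=nbins)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    modes: list[float] = []
    for i in range(len(smooth)):
        if smooth[i] <= 0 or smooth[i] < 0.01 * smooth.max():
            continue
        if (i == 0 or smooth[i] >= smooth[i - 1]) and \
           (i == len(smooth) - 1 or smooth[i] > smooth[i + 1]):
            center = 2 ** ((edges[i] + edges[i + 1]) / 2.0)
            if not modes or center > modes[-1] * 1.8:
                modes.append(center)
    if len(modes) < 2:
        raise CoverageHistogramError(
            "k-mer count histogram is unimodal; supply explicit coverage estimates")
    return float(modes[0]), float(modes[-1])


def classify_mito_kmers(table: KmerTable,
                        mito_cov_estimate: float | None = None,
                        autosomal_cov_estimate: float | None = None
                        ) -> MitoKmerClassifier:
    """Build the mito-class predicate from coverage estimates, inferring
    them from the count histogram when not supplied."""
    if mito_cov_estimate is None or autosomal_cov_estimate is None:
        low, high = estimate_coverage_modes(table)
        autosomal_cov_estimate = autosomal_cov_estimate or low
        mito_cov_estimate = mito_cov_estimate or high
    if not (mito_cov_estimate > autosomal_cov_estimate > 0):
        raise ValueError("need mito_cov_estimate > autosomal_cov_estimate > 0")
    thr = math.sqrt(mito_cov_estimate * autosomal_cov_estimate)
    return MitoKmerClassifier(table, thr)


# ---------------------------------------------------------------------------
# read-support structures
# ---------------------------------------------------------------------------

class ReadSupport:
    """Membership structure over every length-``k2`` window of the short
    reads (both orientations).  An extension window absent from all reads is
    evidence of a chimeric path even when its order-k k-mers are all
    genuine.  Windows are stored hashed; collisions can only make support
    more permissive, never reject a genuine window."""

    def __init__(self, sequences, k2: int = 101):
        self.k2 = k2
        s: set[int] = set()
        for seq in sequences:
            for src in (seq, revcomp(seq)):
                for i in range(len(src) - k2 + 1):
                    s.add(hash(src[i:i + k2]))
        self._set = s

    def supports(self, window: str) -> bool:
        return hash(window) in self._set


class PairIndex:
    """Exact-anchor index of read pairs for the paired-end insert check."""

    ANCHOR = 31

    def __init__(self, pairs):
        self.pairs = pairs
        self.read_length = len(pairs[0].read1) if pairs else 0
        idx: dict[str, list[tuple[int, int, str]]] = {}
        for i, pr in enumerate(pairs):
            for mate, seq in ((1, pr.read1), (2, pr.read2)):
                for orient, s in (("+", seq), ("-", revcomp(seq))):
                    if len(s) >= self.ANCHOR:
                        idx.setdefault(s[:self.ANCHOR], []).append((i, mate, orient))
        self.index = idx

    def oriented(self, pair_id: int, mate: int, orient: str) -> str:
        pr = self.pairs[pair_id]
        seq = pr.read1 if mate == 1 else pr.read2
        return seq if orient == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# configuration and report types
# ---------------------------------------------------------------------------

@dataclass
class AssemblyConfig:
    """Tunables of the walkthrough.

    ``max_branch_depth`` bounds candidate-branch enumeration at a fork; the
    default of 2500 bp spans a control-region copy plus enough flank for
    the evidence to discriminate.  The long-read identity floor of 0.8 is
    permissive at 10-15% uncorrected long-read error; the paired-end window
    is mean +/- 4 sd; amplicon lengths are checked at gel-estimate
    precision (10%).
    """

    k: int = 23
    support_k: int = 101
    seed_feature: str = "12S rRNA"
    mito_cov_estimate: float | None = None
    autosomal_cov_estimate: float | None = None
    max_branch_depth: int = 2500
    max_branches: int = 48
    length_tolerance: float = 0.10
    insert_sd_mult: float = 4.0
    longread_identity_floor: float = 0.80
    anchor_len: int = 300
    anchor_back: int = 1200
    band: int = 8
    min_informative_overlap: int = 100
    amplicon_context: int = 4000
    pe_context: int = 1200
    max_length_factor: float = 2.0
    force_first: bool = False
    use_read_support: bool = True
    exact_support_screen: bool = True


@dataclass
class CheckResult:
    name: str
    passed: bool
    metric: float | None = None
    detail: str = ""


@dataclass
class ForkEvent:
    position: int                       # bp offset in contig where branches start
    branches: list[str] = field(default_factory=list)
    verdicts: list[dict[str, str]] = field(default_factory=list)
    resolution: int | None = None       # set only when a unique branch is consistent
    ambiguous: bool = False
    committed: str = ""                 # sequence actually appended


@dataclass
class AssemblyReport:
    assembled: CircularSequence | None
    forks: list[ForkEvent]
    circularized: bool
    validation: dict[str, CheckResult] = field(default_factory=dict)


@dataclass
class WalkState:
    contig: str
    frontier: str
    direction: str = "right"   # or "left"
    steps: int = 0


class _Terminal:
    """Outcome of a walk segment: 'fork', 'deadend', 'circular' or 'budget'."""

    def __init__(self, kind: str):
        self.kind = kind

    def __repr__(self) -> str:
        return f"<terminal {self.kind}>"


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

def select_seed(reference: CircularSequence,
                ref_annotations: list[FeatureAnnotation],
                feature_name: str,
                table: KmerTable,
                classifier: MitoKmerClassifier | None = None) -> str:
    """The first k-mer of the named reference feature (scanning left to
    right on the feature strand) with an exact, mito-class match in the
    read k-mer table."""
    feats = [a for a in ref_annotations if a.name == feature_name]
    if not feats:
        raise SeedNotFoundError(f"feature {feature_name!r} absent from annotation")
    feat = feats[0]
    k = table.k
    seq = reference.slice_circular(feat.start, feat.end)
    if feat.strand == "-":
        seq = revcomp(seq)
    present = classifier if classifier is not None else (lambda s: table.get(s) > 0)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) <= set(BASES) and present(kmer):
            return kmer
    raise SeedNotFoundError(
        f"no k-mer of feature {feature_name!r} found in the read table")


# ---------------------------------------------------------------------------
# low-level stepping
# ---------------------------------------------------------------------------

def _succ(f: int, r: int, b: int, k: int) -> tuple[int, int]:
    nf = ((f << 2) | b) & ((1 << (2 * k)) - 1)
    nr = (r >> 2) | ((3 - b) << (2 * (k - 1)))
    return nf, nr


def _passing(f: int, r: int, tail: str, classifier: MitoKmerClassifier,
             support: ReadSupport | None, k: int) -> list[tuple[int, int, int]]:
    """Successor bases (b, new_fwd, new_rc) passing the mito-class predicate
    and, once the context is long enough, the read-support predicate."""
    out = []
    counts = classifier.table.counts
    thr = classifier.threshold
    check_support = support is not None and len(tail) == support.k2 - 1
    for b in range(4):
        nf, nr = _succ(f, r, b, k)
        if counts.get(nf if nf < nr else nr, 0) >= thr:
            if check_support and not support.supports(tail + BASES[b]):
                continue
            out.append((b, nf, nr))
    return out


def extend_path(state: WalkState,
                mito_kmers: MitoKmerClassifier,
                support: ReadSupport | None = None,
                seed: str | None = None,
                max_steps: int | None = None) -> tuple[WalkState, _Terminal]:
    """Extend the walk while exactly one successor k-mer passes.

    Stops at a fork (>=2 successors), a dead end (0 successors), or
    circularization (the frontier k-mer returns to ``seed``).  A
    left-direction walk extends the contig's 5' end symmetrically.
    """
    k = mito_kmers.table.k
    left = state.direction == "left"
    work = revcomp(state.contig) if left else state.contig
    seed_f = None
    if seed is not None:
        seed_f = encode_kmer(revcomp(seed)) if left else encode_kmer(seed)
    f = encode_kmer(work[-k:])
    r = encode_kmer(revcomp(work[-k:]))
    k2m1 = support.k2 - 1 if support is not None else 0
    budget = max_steps if max_steps is not None else 10 ** 9
    outcome = _Terminal("budget")
    while state.steps < budget:
        tail = work[-k2m1:] if support is not None else ""
        succ = _passing(f, r, tail, mito_kmers, support, k)
        if len(succ) == 0:
            outcome = _Terminal("deadend")
            break
        if len(succ) > 1:
            outcome = _Terminal("fork")
            break
        b, f, r = succ[0]
        work += BASES[b]
        state.steps += 1
        if seed_f is not None and f == seed_f:
            outcome = _Terminal("circular")
            break
    state.contig = revcomp(work) if left else work
    state.frontier = state.contig[:k] if left else state.contig[-k:]
    return state, outcome


# ---------------------------------------------------------------------------
# branch enumeration
# ---------------------------------------------------------------------------

class _Path:
    __slots__ = ("chars", "tail", "f", "r", "done")

    def __init__(self, chars, tail, f, r, done=None):
        self.chars = chars
        self.tail = tail
        self.f = f
        self.r = r
        self.done = done


def _enumerate_branches(tail0: str, f0: int, r0: int,
                        classifier: MitoKmerClassifier,
                        support: ReadSupport | None,
                        seed_f: int | None,
                        anchors: list[tuple[np.ndarray, int]],
                        cfg: AssemblyConfig) -> list[str]:
    """Breadth-first candidate path extensions from a fork.

    Paths split at nested bifurcations.  When the live path count exceeds
    ``max_branches``, paths clearly contradicted by an anchored spanning
    long read are pruned (this is what keeps tandem-repeat copy-number
    enumeration tractable); if pruning does not help — e.g. with no long
    reads — enumeration stops deepening and returns the paths truncated at
    the current length, leaving the decision to the evidence checks.
    """
    k = classifier.table.k
    k2 = support.k2 if support is not None else 0

    def clip(t: str) -> str:
        return t[-(k2 - 1):] if support is not None else ""

    paths: list[_Path] = []
    for b, nf, nr in _passing(f0, r0, tail0, classifier, support, k):
        done = "circular" if (seed_f is not None and nf == seed_f) else None
        paths.append(_Path([BASES[b]], clip(tail0 + BASES[b]), nf, nr, done))

    depth = 1
    while depth < cfg.max_branch_depth:
        grew = False
        new_paths: list[_Path] = []
        for p in paths:
            if p.done is not None:
                new_paths.append(p)
                continue
            succ = _passing(p.f, p.r, p.tail, classifier, support, k)
            if not succ:
                p.done = "deadend"
                new_paths.append(p)
                continue
            grew = True
            if len(succ) == 1:
                b, nf, nr = succ[0]
                p.chars.append(BASES[b])
                p.tail = clip(p.tail + BASES[b])
                p.f, p.r = nf, nr
                if seed_f is not None and nf == seed_f:
                    p.done = "circular"
                new_paths.append(p)
            else:
                for b, nf, nr in succ:
                    q = _Path(p.chars + [BASES[b]], clip(p.tail + BASES[b]),
                              nf, nr)
                    if seed_f is not None and nf == seed_f:
                        q.done = "circular"
                    new_paths.append(q)
        paths = new_paths
        depth += 1
        if not grew:
            break
        if len(paths) > cfg.max_branches:
            paths = _prune_paths(paths, anchors, cfg)
            if len(paths) > cfg.max_branches:
                break
    return ["".join(p.chars) for p in paths]


def _prune_paths(paths: list[_Path],
                 anchors: list[tuple[np.ndarray, int]],
                 cfg: AssemblyConfig) -> list[_Path]:
    """Drop paths whose prefix clearly contradicts an anchored spanning
    long read (identity below the floor minus a small noise margin)."""
    if not anchors:
        return paths
    margin = 0.03
    kept = []
    for p in paths:
        seq = "".join(p.chars)
        score = _branch_read_identity(seq, anchors, cfg, min_len=150)
        if score is None or score >= cfg.longread_identity_floor - margin:
            kept.append(p)
    return kept if kept else paths


# ---------------------------------------------------------------------------
# evidence checks
# ---------------------------------------------------------------------------

def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _amplicon_verdict(branch: str, contig: str, evidence: EvidenceSet,
                      cfg: AssemblyConfig) -> str:
    """Every amplicon whose primers both land on the extended contig (with
    the product end inside the branch) must imply a length within tolerance
    of the expected product size."""
    if not evidence.amplicons:
        return "uninformative"
    context = contig[-cfg.amplicon_context:]
    ext = context + branch
    bstart = len(context)
    informative = False
    for a in evidence.amplicons:
        best = None
        # orientation 1: contig follows the genome's forward strand
        # orientation 2: contig is the reverse complement
        for p_start, p_end in (
                (a.fwd_seq, revcomp(a.rev_seq)),
                (a.rev_seq, revcomp(a.fwd_seq))):
            starts = _find_all(ext, p_start)
            ends = _find_all(ext, p_end)
            if not starts or not ends:
                continue
            plen = len(p_end)
            for pf in starts:
                for pr in ends:
                    end = pr + plen
                    if end <= pf or end <= bstart:
                        continue
                    implied = end - pf
                    if best is None or (abs(implied - a.expected_length)
                                        < abs(best - a.expected_length)):
                        best = implied
        if best is not None:
            informative = True
            if abs(best - a.expected_length) > cfg.length_tolerance * a.expected_length:
                return "inconsistent"
    return "consistent" if informative else "uninformative"


def _pe_verdict(branch: str, contig: str, evidence: EvidenceSet,
                pair_index: PairIndex | None, cfg: AssemblyConfig) -> str:
    """Short-read consistency of a candidate branch, two ways.

    Mate placements on the extended contig must yield insert sizes within
    mean +/- ``insert_sd_mult`` sd for every pair anchored in the branch
    region.  Additionally (``exact_support_screen``, for error-free or
    corrected short reads): every screened branch position must be covered
    by at least one read placed with zero mismatches — a chimeric base
    swapped in from the other repeat copy leaves a hole no genuine read
    spans exactly.
    """
    if pair_index is None or not pair_index.pairs:
        return "uninformative"
    context = contig[-cfg.pe_context:]
    ext = context + branch
    bstart = len(context)
    rl = pair_index.read_length
    A = PairIndex.ANCHOR
    ext_b = np.frombuffer(ext.encode(), dtype=np.uint8)
    placements: dict[int, dict[int, list[tuple[str, int]]]] = {}
    exact_cov = np.zeros(len(ext) + 1, dtype=np.int32)
    index = pair_index.index
    for pos in range(len(ext) - A + 1):
        entries = index.get(ext[pos:pos + A])
        if not entries or pos + rl > len(ext):
            continue
        for pid, mate, orient in entries:
            seq = pair_index.oriented(pid, mate, orient)
            sb = np.frombuffer(seq.encode(), dtype=np.uint8)
            mism = int(np.count_nonzero(ext_b[pos:pos + rl] != sb))
            if mism <= 2:
                placements.setdefault(pid, {}).setdefault(mate, []).append((orient, pos))
            if mism == 0:
                exact_cov[pos] += 1
                exact_cov[pos + rl] -= 1
    if cfg.exact_support_screen:
        cov = np.cumsum(exact_cov[:-1])
        lo_s, hi_s = bstart, len(ext) - rl
        if hi_s > lo_s and np.any(cov[lo_s:hi_s] == 0):
            return "inconsistent"
    mean, sd = evidence.insert_model
    lo = mean - cfg.insert_sd_mult * sd
    hi = mean + cfg.insert_sd_mult * sd
    informative = False
    n_discordant = 0
    for pid, mates in placements.items():
        if 1 not in mates or 2 not in mates:
            continue
        touches_branch = False
        combo_ok = False
        for o1, p1 in mates[1]:
            for o2, p2 in mates[2]:
                (lpos, lori), (rpos, rori) = sorted(
                    [(p1, o1), (p2, o2)])
                if lori != "+" or rori != "-":
                    continue
                if rpos + rl > bstart:
                    touches_branch = True
                if lo <= rpos + rl - lpos <= hi:
                    combo_ok = True
        # repeat copies can yield several placements per mate; the pair only
        # contradicts the branch when no proper placement pair explains it
        if touches_branch:
            informative = True
            if not combo_ok:
                n_discordant += 1
    # a lone discordant pair is a legitimate insert-size tail draw, not
    # evidence of misassembly; structural errors displace many pairs
    if n_discordant >= 2:
        return "inconsistent"
    return "consistent" if informative else "uninformative"


def _anchor_long_reads(contig: str, long_reads, cfg: AssemblyConfig
                       ) -> list[tuple[np.ndarray, int]]:
    """Locate the contig's pre-fork anchor in each long read.

    The anchor (last ``anchor_len`` bases of the contig) is slid gaplessly
    over both read orientations; candidate locations are validated by a
    longer backward comparison against the contig, which disambiguates
    between near-identical repeat copies inside the read.  Returns
    (oriented read bytes, read offset corresponding to the fork) per read
    that spans the fork.
    """
    anchors = []
    alen = min(cfg.anchor_len, len(contig))
    if alen < 50:
        return []
    anchor_b = np.frombuffer(contig[-alen:].encode(), dtype=np.uint8)
    for lr in long_reads:
        best = None     # (back_identity, -mismatches, read bytes, fork offset)
        for oriented in (lr.seq, revcomp(lr.seq)):
            if len(oriented) < alen:
                continue
            rb = np.frombuffer(oriented.encode(), dtype=np.uint8)
            wins = np.lib.stride_tricks.sliding_window_view(rb, alen)
            mism = np.count_nonzero(wins != anchor_b, axis=1)
            for o in np.nonzero(mism <= 0.25 * alen)[0]:
                o = int(o)
                back_w = min(cfg.anchor_back, o, len(contig) - alen)
                back_id = 1.0
                if back_w >= 100:
                    cb = np.frombuffer(
                        contig[-(alen + back_w):-alen].encode(), dtype=np.uint8)
                    back_id = 1.0 - np.count_nonzero(cb != rb[o - back_w:o]) / back_w
                    if back_id < 0.75:
                        continue
                key = (back_id, -int(mism[o]))
                if best is None or key > best[0]:
                    best = (key, rb, o + alen)
        if best is not None:
            anchors.append((best[1], best[2]))
    return anchors


def _branch_read_identity(branch: str,
                          anchors: list[tuple[np.ndarray, int]],
                          cfg: AssemblyConfig,
                          min_len: int | None = None) -> float | None:
    """Minimum over spanning reads of the best offset-banded gapless
    identity of the branch against the read past the anchor; None when no
    read overlaps the branch informatively."""
    need = min_len if min_len is not None else cfg.min_informative_overlap
    bb = np.frombuffer(branch.encode(), dtype=np.uint8)
    scores = []
    for rb, e in anchors:
        avail = len(rb) - e
        Lc = min(len(bb), avail)
        if Lc < need:
            continue
        best = 0.0
        for d in range(-cfg.band, cfg.band + 1):
            s = e + d
            if s < 0 or s + Lc > len(rb):
                continue
            mism = int(np.count_nonzero(bb[:Lc] != rb[s:s + Lc]))
            ident = 1.0 - mism / Lc
            if ident > best:
                best = ident
        scores.append(best)
    if not scores:
        return None
    return min(scores)


def _lr_verdict(branch: str, anchors: list[tuple[np.ndarray, int]],
                cfg: AssemblyConfig) -> str:
    score = _branch_read_identity(branch, anchors, cfg)
    if score is None:
        return "uninformative"
    return "consistent" if score >= cfg.longread_identity_floor else "inconsistent"


def _common_prefix(seqs: list[str]) -> str:
    if not seqs:
        return ""
    first = min(seqs, key=len)
    for i, ch in enumerate(first):
        for s in seqs:
            if s[i] != ch:
                return first[:i]
    return first


def resolve_fork(fork: "ForkEvent", evidence: EvidenceSet, *,
                 contig: str, cfg: AssemblyConfig | None = None,
                 pair_index: PairIndex | None = None,
                 anchors: list[tuple[np.ndarray, int]] | None = None) -> "ForkEvent":
    """Score every candidate branch against the three evidence classes and
    set the fork's resolution.

    A branch is rejected when any informative class finds it inconsistent.
    Exactly one survivor: it is committed in full.  Several survivors that
    agree on a non-empty common prefix: only the prefix is committed and
    the walk re-encounters the remaining ambiguity with a fresh, deeper
    look.  Otherwise the fork is AMBIGUOUS.
    """
    cfg = cfg or AssemblyConfig()
    if anchors is None:
        anchors = _anchor_long_reads(contig, evidence.long_reads, cfg)
    fork.verdicts = []
    for br in fork.branches:
        fork.verdicts.append({
            "amplicon": _amplicon_verdict(br, contig, evidence, cfg),
            "paired_end": _pe_verdict(br, contig, evidence, pair_index, cfg),
            "long_read": _lr_verdict(br, anchors, cfg),
        })
    candidates = [i for i, v in enumerate(fork.verdicts)
                  if "inconsistent" not in v.values()]
    if len(candidates) == 1:
        fork.resolution = candidates[0]
        fork.committed = fork.branches[candidates[0]]
    elif candidates:
        lcp = _common_prefix([fork.branches[i] for i in candidates])
        if lcp:
            fork.committed = lcp
        else:
            fork.ambiguous = True
    else:
        fork.ambiguous = True
    return fork


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def assemble_mitogenome(reads: ReadSet,
                        reference: CircularSequence,
                        annotations: list[FeatureAnnotation],
                        evidence: EvidenceSet,
                        config: AssemblyConfig | None = None) -> AssemblyReport:
    """Count -> classify -> seed -> extend/resolve until circularization.

    The returned assembly is rotation-normalized (lexicographically minimal
    rotation over both strands) and carries the fork log and the three
    validation checks.  Raises :class:`AmbiguousForkError` when evidence
    cannot arbitrate a bifurcation (unless ``config.force_first``),
    :class:`CircularizationError` on a dead end or when the walk exceeds
    ``max_length_factor`` times the reference length.
    """
    cfg = config or AssemblyConfig()
    short = reads.all_short_sequences()
    if not short:
        raise ValueError("no short reads supplied")
    table = count_kmers(short, cfg.k)
    classifier = classify_mito_kmers(table, cfg.mito_cov_estimate,
                                     cfg.autosomal_cov_estimate)
    support = None
    if cfg.use_read_support:
        k2 = min(cfg.support_k, min(len(s) for s in short))
        if k2 > cfg.k + 2:
            support = ReadSupport(short, k2)
    pair_index = PairIndex(reads.paired) if reads.paired else None
    seed = select_seed(reference, annotations, cfg.seed_feature, table, classifier)
    k = cfg.k
    seed_f = encode_kmer(seed)
    contig = seed
    f, r = seed_f, encode_kmer(revcomp(seed))
    k2m1 = support.k2 - 1 if support is not None else 0
    forks: list[ForkEvent] = []
    max_len = int(cfg.max_length_factor * reference.length) + k
    circular = False
    while True:
        if len(contig) > max_len:
            raise CircularizationError(
                f"no circularization within {max_len} bp "
                f"({cfg.max_length_factor}x reference length)")
        tail = contig[-k2m1:] if support is not None else ""
        succ = _passing(f, r, tail, classifier, support, k)
        if len(succ) == 1:
            b, f, r = succ[0]
            contig += BASES[b]
            if f == seed_f and len(contig) > k:
                circular = True
                break
            continue
        if len(succ) == 0:
            raise CircularizationError(f"dead end at contig position {len(contig)}")
        anchors = _anchor_long_reads(contig, evidence.long_reads, cfg)
        fork = ForkEvent(position=len(contig))
        fork.branches = _enumerate_branches(tail, f, r, classifier, support,
                                            seed_f, anchors, cfg)
        resolve_fork(fork, evidence, contig=contig, cfg=cfg,
                     pair_index=pair_index, anchors=anchors)
        forks.append(fork)
        if fork.ambiguous:
            if not cfg.force_first:
                raise AmbiguousForkError(fork, forks)
            fork.committed = fork.branches[0]
        contig += fork.committed
        idx = contig.find(seed, 1)
        if idx != -1:
            contig = contig[:idx + k]
            circular = True
            break
        f = encode_kmer(contig[-k:])
        r = encode_kmer(revcomp(contig[-k:]))

    raw = contig[:-k]       # drop the duplicated seed overlap
    assembled = CircularSequence("assembly", normalize_rotation(raw))
    report = AssemblyReport(assembled=assembled, forks=forks, circularized=circular)
    report.validation = validate_assembly(assembled, evidence, reads,
                                          table=table, config=cfg)
    return report


def validate_assembly(assembled: CircularSequence,
                      evidence: EvidenceSet,
                      reads: ReadSet,
                      table: KmerTable | None = None,
                      config: AssemblyConfig | None = None
                      ) -> dict[str, CheckResult]:
    """The three independent assembly checks: long-read consistency,
    amplicon-length consistency, and short-read k-mer coverage continuity."""
    cfg = config or AssemblyConfig()
    if table is None:
        table = count_kmers(reads.all_short_sequences(), cfg.k)
    checks: dict[str, CheckResult] = {}

    # (1) banded identity of each trimmed long read against the assembly
    target = assembled.doubled()
    long_reads = evidence.long_reads or reads.long_reads
    idents = []
    for lr in long_reads:
        mask = trim_weak_regions(lr.seq, table)
        s, e = mask.trimmed
        if e - s < 50:
            continue
        seg = lr.seq[s:e]
        best = None
        for q in (seg, revcomp(seg)):
            loc = locate_infix(q, target)
            if loc is not None and (best is None or loc[2] > best):
                best = loc[2]
        if best is not None:
            idents.append(best)
    if idents:
        med = float(np.median(idents))
        checks["long_read_consistency"] = CheckResult(
            "long_read_consistency", med >= cfg.longread_identity_floor, med,
            f"median identity over {len(idents)} trimmed reads")
    else:
        checks["long_read_consistency"] = CheckResult(
            "long_read_consistency", True, None, "no usable long reads")

    # (2) amplicon implied lengths on the circular assembly
    L = assembled.length
    n_bad = 0
    n_checked = 0
    for a in evidence.amplicons:
        best = None
        for strand_seq in (target, revcomp(assembled.seq) + revcomp(assembled.seq)):
            starts = [p for p in _find_all(strand_seq, a.fwd_seq) if p < L]
            site_r = revcomp(a.rev_seq)
            ends = [p + len(site_r) for p in _find_all(strand_seq, site_r)]
            for pf in starts:
                for pe in ends:
                    implied = pe - pf
                    if 0 < implied <= L:
                        if best is None or (abs(implied - a.expected_length)
                                            < abs(best - a.expected_length)):
                            best = implied
        n_checked += 1
        if best is None or abs(best - a.expected_length) > \
                cfg.length_tolerance * a.expected_length:
            n_bad += 1
    checks["amplicon_length_consistency"] = CheckResult(
        "amplicon_length_consistency", n_bad == 0,
        float(n_bad), f"{n_bad}/{n_checked} amplicons out of tolerance")

    # (3) short-read k-mer coverage continuity around the circle
    cov = map_kmer_coverage(table, assembled).per_start_coverage
    n_zero = int(np.count_nonzero(cov == 0))
    checks["coverage_continuity"] = CheckResult(
        "coverage_continuity", n_zero == 0, float(n_zero),
        f"{n_zero} zero-coverage k-mer starts")
    return checks
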