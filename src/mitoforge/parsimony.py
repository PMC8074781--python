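"""Maximum-parsimony statistics on fixed topologies.

No tree search happens here: given an alignment and a newick topology this
module computes the Fitch small-parsimony tree length and the classical
homoplasy indices —

* consistency index  CI = M / S,
* retention index    RI = (G - S) / (G - M),
* rescaled (composite) index RC = CI * RI,

where S is the Fitch length, M the site-wise minimum number of changes
(states observed - 1) and G the site-wise maximum on a completely
unresolved tree (occurrences - modal state count).  Both the all-sites and
the parsimony-informative-only site sets are supported, since published
values are reported either way.

Missing data (gaps, N, ambiguity codes) are treated at the leaves as the
full state set {A,C,G,T}, the standard union-compatible convention; a
complete-deletion flag drops every column containing missing data instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .diversity import AlignmentMatrix

_STATE = np.zeros(256, dtype=np.uint8)
for _b, _m in zip(b"ACGT", (1, 2, 4, 8)):
    _STATE[_b] = _m
# anything not ACGT (gap, N, IUPAC codes) acts as the full state set
_FULL = 15


@dataclass
class Tree:
    """A fixed topology for parsimony scoring (unrooted; polytomies are
    arbitrarily resolved with zero-information nodes, which does not change
    the Fitch length)."""

    dtree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        dt.resolve_polytomies()
        return cls(dt)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]


def _leaf_states(tree: Tree, aln: AlignmentMatrix) -> dict:
    rows = {}
    for lf in tree.dtree.leaf_node_iter():
        label = lf.taxon.label
        if label not in aln.taxa:
            raise ValueError(f"tree leaf {label!r} not in alignment")
        states = _STATE[aln.row(label)].copy()
        states[states == 0] = _FULL
        rows[lf] = states
    return rows


def fitch_steps_per_site(tree: Tree, aln: AlignmentMatrix) -> np.ndarray:
    """Fitch small-parsimony minimum changes per alignment column,
    vectorised across columns."""
    leaf_states = _leaf_states(tree, aln)
    steps = np.zeros(aln.length, dtype=np.int64)
    node_state: dict = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            node_state[node] = leaf_states[node]
            continue
        children = node.child_nodes()
        acc = node_state.pop(children[0])
        for ch in children[1:]:
            other = node_state.pop(ch)
            inter = acc & other
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | other, inter)
        node_state[node] = acc
    return steps


def fitch_length(tree: Tree, aln: AlignmentMatrix) -> int:
    """Total Fitch tree length (sum of per-site minimum changes).
    Invariant to the arbitrary rooting of the topology."""
    return int(fitch_steps_per_site(tree, aln).sum())


def _site_state_counts(aln: AlignmentMatrix) -> np.ndarray:
    """Per-site counts of each of A,C,G,T across taxa, shape (4, columns)."""
    mat = aln.matrix
    return np.vstack([(mat == b).sum(axis=0) for b in b"ACGT"])


def count_informative_sites(aln: AlignmentMatrix) -> int:
    """Parsimony-informative sites: columns with at least two distinct
    states each present in at least two taxa (non-ACGT ignored)."""
    counts = _site_state_counts(aln)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def informative_mask(aln: AlignmentMatrix) -> np.ndarray:
    counts = _site_state_counts(aln)
    return (counts >= 2).sum(axis=0) >= 2


def min_steps_per_site(aln: AlignmentMatrix) -> np.ndarray:
    """M_i: observed ACGT states minus one (0 for constant/empty sites)."""
    counts = _site_state_counts(aln)
    observed = (counts > 0).sum(axis=0)
    return np.maximum(observed - 1, 0)


def max_steps_per_site(aln: AlignmentMatrix) -> np.ndarray:
    """G_i: changes on a completely unresolved tree — ACGT occurrences
    minus the modal state count."""
    counts = _site_state_counts(aln)
    occ = counts.sum(axis=0)
    modal = counts.max(axis=0)
    return np.maximum(occ - modal, 0)


@dataclass
class ParsimonyStats:
    tree_length: int            # S
    min_steps: int              # M
    max_steps: int              # G
    ci: float | None
    ri: float | None
    rc: float | None
    n_informative: int
    site_set: str               # "all" or "informative"


def rescaled_index(ci: float, ri: float) -> float:
    """The composite (rescaled consistency) index, CI * RI."""
    return ci * ri


def homoplasy_indices(tree: Tree, aln: AlignmentMatrix,
                      sites: str = "all",
                      complete_deletion: bool = False) -> ParsimonyStats:
    """CI, RI and the composite index over the chosen site set.

    ``sites`` selects all columns or parsimony-informative columns only.
    When no variation exists (S == 0) the indices are undefined and
    reported as None.
    """
    if complete_deletion:
        keep = np.isin(aln.matrix, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=0)
        aln = AlignmentMatrix(aln.taxa, aln.matrix[:, keep])
    s_i = fitch_steps_per_site(tree, aln)
    m_i = min_steps_per_site(aln)
    g_i = max_steps_per_site(aln)
    mask = informative_mask(aln)
    n_inf = int(mask.sum())
    if sites == "informative":
        sel = mask
    elif sites == "all":
        sel = np.ones(aln.length, dtype=bool)
    else:
        raise ValueError("sites must be 'all' or 'informative'")
    S = int(s_i[sel].sum())
    M = int(m_i[sel].sum())
    G = int(g_i[sel].sum())
    if S == 0:
        return ParsimonyStats(S, M, G, None, None, None, n_inf, sites)
    ci = M / S
    ri = (G - S) / (G - M) if G > M else None
    rc = rescaled_index(ci, ri) if ri is not None else None
    return ParsimonyStats(S, M, G, ci, ri, rc, n_inf, sites)
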