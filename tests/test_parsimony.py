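import itertools
import subprocess
import textwrap

import numpy as np
import pytest

from mitoforge import (AlignmentMatrix, Tree, count_informative_sites,
                       fitch_length, homoplasy_indices)


def _aln(rows):
    return AlignmentMatrix.from_sequences(rows)


def brute_force_parsimony(newick_splits, leaf_rows):
    """Exhaustive small parsimony: minimise changes over all internal-node
    state assignments of an explicitly rooted binary tree given as nested
    tuples, e.g. ((\"a\",\"b\"),(\"c\",\"d\"))."""
    leaves = dict(leaf_rows)
    n_sites = len(next(iter(leaves.values())))

    def tree_nodes(node):
        if isinstance(node, str):
            return []
        return [node] + tree_nodes(node[0]) + tree_nodes(node[1])

    internals = tree_nodes(newick_splits)
    total = 0
    for site in range(n_sites):
        best = None
        for states in itertools.product("ACGT", repeat=len(internals)):
            assign = dict(zip(map(id, internals), states))

            def state_of(node):
                if isinstance(node, str):
                    return leaves[node][site]
                return assign[id(node)]

            cost = 0
            for node in internals:
                for child in node:
                    ps, cs = state_of(node), state_of(child)
                    if cs in "ACGT" and ps != cs:
                        cost += 1
                    # non-ACGT leaf: free to match its parent (missing data)
            best = cost if best is None else min(best, cost)
        total += best
    return total


def tuples_to_newick(node):
    if isinstance(node, str):
        return node
    return f"({tuples_to_newick(node[0])},{tuples_to_newick(node[1])})"


def random_tree(labels, rng):
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


class TestInformativeSites:
    def test_constant_alignment(self):
        aln = _aln([(f"t{i}", "AAAA") for i in range(5)])
        assert count_informative_sites(aln) == 0

    def test_definition_cases(self):
        aln = _aln([("a", "AA"), ("b", "AA"), ("c", "CA"), ("d", "CC")])
        # site 0: A,A,C,C informative; site 1: A,A,A,C not
        assert count_informative_sites(aln) == 1

    def test_matches_bruteforce_column_scan(self):
        rng = np.random.default_rng(0)
        rows = [(f"t{i}", "".join(rng.choice(list("ACGTN-"), size=200)))
                for i in range(6)]
        aln = _aln(rows)
        expected = 0
        for col in range(200):
            counts = {}
            for _, s in rows:
                if s[col] in "ACGT":
                    counts[s[col]] = counts.get(s[col], 0) + 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                expected += 1
        assert count_informative_sites(aln) == expected


class TestFitch:
    def test_identical_sequences_zero_length(self):
        aln = _aln([(t, "ACGTACGT") for t in "abcd"])
        tree = Tree.from_newick("((a,b),(c,d));")
        assert fitch_length(tree, aln) == 0

    def test_matches_exhaustive_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for rep in range(10):
            labels = [f"t{i}" for i in range(4)]
            shape = random_tree(labels, rng)
            rows = [(t, "".join(rng.choice(list("ACGT"), size=30)))
                    for t in labels]
            tree = Tree.from_newick(tuples_to_newick(shape) + ";")
            assert fitch_length(tree, _aln(rows)) == \
                brute_force_parsimony(shape, rows)

    def test_missing_data_union_compatible(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(5)]
        shape = random_tree(labels, rng)
        rows = [(t, "".join(rng.choice(list("ACGTN-"), size=25)))
                for t in labels]
        tree = Tree.from_newick(tuples_to_newick(shape) + ";")
        assert fitch_length(tree, _aln(rows)) == \
            brute_force_parsimony(shape, rows)

    def test_invariant_to_rooting(self):
        rng = np.random.default_rng(3)
        rows = [(t, "".join(rng.choice(list("ACGT"), size=50)))
                for t in "abcdef"]
        aln = _aln(rows)
        t1 = Tree.from_newick("((a,b),((c,d),(e,f)));")
        t2 = Tree.from_newick("(a,(b,((c,d),(e,f))));")   # same unrooted tree
        assert fitch_length(t1, aln) == fitch_length(t2, aln)

    def test_leaf_taxon_mismatch(self):
        aln = _aln([("a", "AC"), ("b", "AC")])
        tree = Tree.from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            fitch_length(tree, aln)

    def test_agrees_with_phangorn(self, tmp_path):
        """Independent cross-check against R phangorn's Fitch parsimony."""
        rng = np.random.default_rng(4)
        rows = [(t, "".join(rng.choice(list("ACGT"), size=120)))
                for t in "abcdef"]
        newick = "((a,b),(c,(d,(e,f))));"
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{t}\n{s}\n" for t, s in rows))
        script = textwrap.dedent(f"""
            suppressMessages(library(phangorn))
            aln <- read.phyDat("{fasta}", format = "fasta")
            tree <- read.tree(text = "{newick}")
            cat(fitch(tree, aln))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.strip()
        tree = Tree.from_newick(newick)
        assert fitch_length(tree, _aln(rows)) == int(float(out))


class TestHomoplasyIndices:
    def test_homoplasy_free_data_gives_unit_indices(self):
        # one mutation per site on distinct branches of the generating tree
        base = list("A" * 12)
        rows = {t: base[:] for t in "abcd"}
        rows["a"][0] = "C"                      # tip branches
        rows["b"][1] = "G"
        rows["c"][2] = "T"
        for t in ("a", "b"):                    # internal branch (a,b)
            rows[t][3] = "G"
        for t in ("c", "d"):
            rows[t][4] = "T"
        aln = _aln([(t, "".join(s)) for t, s in rows.items()])
        tree = Tree.from_newick("((a,b),(c,d));")
        stats = homoplasy_indices(tree, aln)
        assert stats.ci == 1.0
        assert stats.ri == 1.0
        assert stats.rc == 1.0

    def test_rc_equals_ci_times_ri(self):
        rng = np.random.default_rng(5)
        for rep in range(10):
            rows = [(t, "".join(rng.choice(list("ACGT"), size=60)))
                    for t in "abcdef"]
            tree = Tree.from_newick("((a,b),((c,d),(e,f)));")
            stats = homoplasy_indices(tree, _aln(rows))
            if stats.rc is not None:
                assert stats.rc == pytest.approx(stats.ci * stats.ri,
                                                 abs=1e-12)

    def test_no_variation_undefined(self):
        aln = _aln([(t, "AAAA") for t in "abcd"])
        tree = Tree.from_newick("((a,b),(c,d));")
        stats = homoplasy_indices(tree, aln)
        assert stats.tree_length == 0
        assert stats.ci is None and stats.ri is None and stats.rc is None

    def test_constant_column_changes_nothing(self):
        rng = np.random.default_rng(6)
        rows = [(t, "".join(rng.choice(list("ACGT"), size=40)))
                for t in "abcde"]
        tree = Tree.from_newick("((a,b),(c,(d,e)));")
        s1 = homoplasy_indices(tree, _aln(rows))
        padded = [(t, s + "G") for t, s in rows]
        s2 = homoplasy_indices(tree, _aln(padded))
        assert (s1.tree_length, s1.min_steps, s1.max_steps) == \
            (s2.tree_length, s2.min_steps, s2.max_steps)

    def test_informative_only_site_set(self):
        rng = np.random.default_rng(7)
        rows = [(t, "".join(rng.choice(list("ACGT"), size=80)))
                for t in "abcdef"]
        tree = Tree.from_newick("((a,b),((c,d),(e,f)));")
        aln = _aln(rows)
        s_all = homoplasy_indices(tree, aln, sites="all")
        s_inf = homoplasy_indices(tree, aln, sites="informative")
        assert s_inf.tree_length <= s_all.tree_length
        assert s_all.n_informative == s_inf.n_informative == \
            count_informative_sites(aln)

    def test_bound_relation(self):
        rng = np.random.default_rng(8)
        rows = [(t, "".join(rng.choice(list("ACGT"), size=100)))
                for t in "abcdef"]
        tree = Tree.from_newick("(((a,b),c),((d,e),f));")
        stats = homoplasy_indices(tree, _aln(rows))
        assert stats.min_steps <= stats.tree_length <= stats.max_steps
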