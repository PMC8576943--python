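import dendropy
import numpy as np
import pandas as pd
import pytest

from multiregion import phylo as p
from multiregion.errors import ValidationError


def matrix_from_rows(rows, samples):
    presence = pd.DataFrame(
        np.asarray(rows, dtype=bool),
        index=[f"v{i}" for i in range(len(rows))],
        columns=samples,
    )
    return p.build_matrix(presence)


def sankoff_score(topology, matrix):
    """Independent small-parsimony oracle: DP over binary states."""

    def rec(node, state_of):
        if isinstance(node, str):
            s = state_of[node]
            return {s: 0, 1 - s: 10**9}
        lc = rec(node[0], state_of)
        rc = rec(node[1], state_of)
        out = {}
        for st in (0, 1):
            out[st] = min(lc[c] + (c != st) for c in (0, 1)) + min(
                rc[c] + (c != st) for c in (0, 1)
            )
        return out

    total = 0.0
    index = {s: i for i, s in enumerate(matrix.samples)}
    for pat, w in matrix.patterns.items():
        state_of = {s: pat[index[s]] for s in matrix.samples}
        costs = rec(topology, state_of)
        total += w * min(costs[0], costs[1] + 1)  # outgroup fixes root state 0
    return total


class TestBuildMatrix:
    def test_collapses_duplicate_patterns_with_weights(self):
        rows = [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 1, 1, 1],
            [0, 0, 0, 0],  # dropped
        ]
        m = matrix_from_rows(rows, list("ABCD"))
        assert m.patterns[(1, 1, 0, 0)] == 2
        assert m.patterns[(1, 1, 1, 1)] == 1
        assert (0, 0, 0, 0) not in m.patterns
        assert sum(m.patterns.values()) == 4

    def test_collapse_matches_hashing_oracle(self):
        rng = np.random.default_rng(2)
        rows = (rng.uniform(size=(30, 4)) < 0.5).astype(int)
        m = matrix_from_rows(rows, list("ABCD"))
        from collections import Counter

        oracle = Counter(tuple(r) for r in rows if any(r))
        assert m.patterns == {k: float(v) for k, v in oracle.items()}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            matrix_from_rows([[1, 0]], ["A", "B"])


class TestFitchScore:
    def test_ubiquitous_variant_costs_one_anywhere(self):
        m = matrix_from_rows([[1, 1, 1, 1]], list("ABCD"))
        for topo in p.enumerate_topologies(list("ABCD")):
            assert p.fitch_score(topo, m) == 1

    def test_pair_pattern_depends_on_topology(self):
        m = matrix_from_rows([[1, 1, 0, 0]], list("ABCD"))
        good = (("A", "B"), ("C", "D"))
        bad = (("A", "C"), ("B", "D"))
        assert p.fitch_score(good, m) == 1
        assert p.fitch_score(bad, m) == 2

    def test_matches_sankoff_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        samples = list("ABCDE")
        for _ in range(25):
            rows = (rng.uniform(size=(12, 5)) < 0.5).astype(int)
            if not rows.any():
                continue
            m = matrix_from_rows(rows, samples)
            topos = p.enumerate_topologies(samples)
            for topo in (topos[0], topos[len(topos) // 2], topos[-1]):
                assert p.fitch_score(topo, m) == sankoff_score(topo, m)

    def test_leaf_mismatch_rejected(self):
        m = matrix_from_rows([[1, 0, 0]], list("ABC"))
        with pytest.raises(ValidationError):
            p.fitch_score(("A", "B"), m)


class TestMaxParsimony:
    def test_perfect_phylogeny_unique_optimum(self):
        rows = [
            [1, 1, 1, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 0],
            [0, 0, 1, 0],
        ]
        trees = p.max_parsimony(matrix_from_rows(rows, list("ABCD")))
        assert len(trees) == 1
        assert trees[0].score == 5
        clades = {frozenset(c) for c in trees[0].branch_variants}
        assert frozenset("AB") in clades and frozenset("CD") in clades
        assert not trees[0].unresolved

    def test_conflicting_variant_raises_score_keeps_topology(self):
        rows = [
            [1, 1, 1, 1],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 0],
            [0, 0, 1, 0],
            [0, 1, 1, 0],  # conflicts with the AB|CD split
        ]
        trees = p.max_parsimony(matrix_from_rows(rows, list("ABCD")))
        assert trees[0].score == 7
        # AB|CD topology still among the optima
        splits = set()
        for t in trees:
            def collect(node):
                if not isinstance(node, str):
                    splits.add(frozenset(p._leaves(node)))
                    collect(node[0]); collect(node[1])
            collect(t.topology)
        assert frozenset("AB") in splits or frozenset("CD") in splits
        assert "v5" in trees[0].unresolved

    def test_identical_samples_all_topologies_cooptimal(self):
        rows = [[1, 1, 1, 1]] * 3
        trees = p.max_parsimony(matrix_from_rows(rows, list("ABCD")))
        assert len(trees) == len(p.enumerate_topologies(list("ABCD")))
        assert all(t.score == 3 for t in trees)

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_s = int(rng.integers(4, 7))
            rows = (rng.uniform(size=(10, n_s)) < 0.5).astype(int)
            if not rows.any():
                continue
            m = matrix_from_rows(rows, [f"S{i}" for i in range(n_s)])
            bnb = p.max_parsimony(m)
            brute = min(p.fitch_score(t, m) for t in p.enumerate_topologies(m.samples))
            assert bnb[0].score == brute

    def test_score_invariant_under_sample_reorder_and_duplication(self):
        rng = np.random.default_rng(13)
        rows = (rng.uniform(size=(8, 4)) < 0.5).astype(int)
        m = matrix_from_rows(rows, list("ABCD"))
        perm = [2, 0, 3, 1]
        m_perm = matrix_from_rows(rows[:, perm], [list("ABCD")[i] for i in perm])
        m_dup = matrix_from_rows(np.vstack([rows, rows]), list("ABCD"))
        s0 = p.max_parsimony(m)[0].score
        assert p.max_parsimony(m_perm)[0].score == s0
        assert p.max_parsimony(m_dup)[0].score == 2 * s0

    def test_simulated_tumor_without_homoplasy(self, branched_tumor):
        # use truth-level presence (no read noise): every variant occupies
        # exactly its host clone's regions, so the matrix is a perfect
        # phylogeny and each variant costs exactly one change
        _, (tree_sim, truth, _) = branched_tumor
        presence = pd.DataFrame(
            {
                f"R{r+1}": [
                    rec.cell_fractions[r] > 0.0 for rec in truth.records.values()
                ]
                for r in range(tree_sim.n_regions)
            },
            index=list(truth.records),
        )
        presence = presence.loc[presence.any(axis=1)]
        matrix = p.build_matrix(presence)
        trees = p.max_parsimony(matrix)
        assert trees[0].score == sum(matrix.patterns.values())
        # samples of the same subclone cluster together
        splits = set()

        def collect(node):
            if not isinstance(node, str):
                splits.add(frozenset(p._leaves(node)))
                collect(node[0])
                collect(node[1])

        collect(trees[0].topology)
        assert frozenset({"R1", "R2"}) in splits
        assert frozenset({"R3", "R4"}) in splits

    def test_sample_bound_enforced(self):
        rows = [[1] * 13]
        with pytest.raises(ValidationError, match="exact-search bound"):
            p.max_parsimony(matrix_from_rows(rows, [f"S{i}" for i in range(13)]))


class TestNewick:
    def test_round_trip_preserves_topology(self, tmp_path):
        m = matrix_from_rows([[1, 1, 1], [1, 1, 0], [1, 0, 0]], list("ABC"))
        tree = p.max_parsimony(m)[0]
        path = tmp_path / "tree.nwk"
        p.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert labels == {"A", "B", "C", p.OUTGROUP}
        bipartitions = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in parsed.preorder_edge_iter()
            if e.head_node.parent_node
        }
        assert frozenset({"A", "B"}) in bipartitions

    def test_branch_labels_sum_to_assigned_variants(self, tmp_path):
        m = matrix_from_rows([[1, 1, 1], [1, 1, 0], [1, 0, 0]], list("ABC"))
        tree = p.max_parsimony(m)[0]
        path = tmp_path / "tree.nwk"
        p.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        total = sum(e.length or 0 for e in parsed.preorder_edge_iter())
        assert total == sum(len(vs) for vs in tree.branch_variants.values())
        assert total == tree.score - len(tree.unresolved)


class TestCcfOrdering:
    def test_dominance_makes_ancestry_admissible(self):
        ccf = pd.DataFrame({"s1": [1.0, 0.6], "s2": [1.0, 0.2]}, index=["X", "Y"])
        rel = p.ccf_order_check(ccf)
        assert ("X", "Y") in rel["ancestral"]
        assert ("Y", "X") not in rel["ancestral"]

    def test_crossing_clusters_are_sibling_candidates(self):
        ccf = pd.DataFrame(
            {"s1": [1.0, 0.6, 0.3], "s2": [1.0, 0.2, 0.5]}, index=["X", "Y", "Z"]
        )
        rel = p.ccf_order_check(ccf, epsilon=0.1)
        assert ("Y", "Z") in rel["crossing"]
        assert ("Y", "Z", "X") in rel["siblings"]

    def test_exact_simulated_ccfs_reproduce_clone_relations(self, branched_tumor):
        _, (tree, truth, _) = branched_tumor
        ccf = pd.DataFrame(
            {f"R{r+1}": [tree.clones[cid].fractions[r] for cid in sorted(tree.clones)]
             for r in range(tree.n_regions)},
            index=[str(cid) for cid in sorted(tree.clones)],
        )
        rel = p.ccf_order_check(ccf, epsilon=0.0)
        for cid, clone in tree.clones.items():
            if clone.parent is not None:
                assert (str(clone.parent), str(cid)) in rel["ancestral"]
        # the two region-confined subclones cannot order against each other
        assert ("1", "2") in rel["crossing"]

    def test_empty_ccf_rejected(self):
        with pytest.raises(ValidationError):
            p.ccf_order_check(pd.DataFrame())
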