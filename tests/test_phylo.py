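"""Anchored MSA, p-distances, neighbor joining, bootstrap, Newick round trips."""

import random

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from curculigo.phylo import (
    MultipleAlignment,
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    reference_anchored_msa,
    write_newick,
)
from curculigo.seq import GAP, ProteinRecord, global_align

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_additive_tree(n_taxa: int, rng: random.Random):
    """Random unrooted binary tree; returns (ids, path-length DistanceMatrix,
    bipartition set). Built by random sequential joins with positive lengths."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths, grown by attaching leaves to random edges
    next_node = n_taxa
    edges = {}

    def add_edge(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del edges[u][v]
        del edges[v][u]

    add_edge(0, 1, rng.uniform(0.1, 1.0))
    for leaf in range(2, n_taxa):
        u = rng.choice(list(edges))
        v = rng.choice(list(edges[u]))
        w = edges[u][v]
        drop_edge(u, v)
        mid = next_node
        next_node += 1
        split = rng.uniform(0.3, 0.7)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, rng.uniform(0.1, 1.0))

    def path_length(src, dst):
        stack = [(src, 0.0, None)]
        while stack:
            node, acc, prev = stack.pop()
            if node == dst:
                return acc
            for nxt, w in edges[node].items():
                if nxt != prev:
                    stack.append((nxt, acc + w, node))
        raise AssertionError("disconnected")

    mat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            mat[i, j] = mat[j, i] = path_length(i, j)

    def leaves_below(node, prev):
        if node < n_taxa:
            return frozenset([ids[node]])
        out = frozenset()
        for nxt in edges[node]:
            if nxt != prev:
                out |= leaves_below(nxt, node)
        return out

    anchor = min(ids)
    splits = set()
    for u in edges:
        for v in edges[u]:
            if u < v:
                side = leaves_below(u, v)
                if anchor in side:
                    side = frozenset(ids) - side
                if 1 < len(side) < n_taxa - 1:
                    splits.add(side)
    return ids, DistanceMatrix(mat, ids), splits


class TestAnchoredMSA:
    def test_identical_sequences_give_gapless_alignment(self, panel_records):
        nbs = panel_records["NBS"]
        msa = reference_anchored_msa([nbs, nbs, nbs], nbs)
        assert all(GAP not in row for row in msa.rows)
        assert msa.n_columns == len(nbs)

    def test_anchor_plus_one_reduces_to_pairwise(self, panel_records, scheme):
        nbs, nas = panel_records["NBS"], panel_records["NAS"]
        msa = reference_anchored_msa([nbs, nas], nbs)
        aln = global_align(nas, nbs, scheme)
        assert msa.rows[0] == aln.aligned_subject
        assert msa.rows[1] == aln.aligned_query

    def test_planted_indels_respect_anchor_coordinates(self, panel_records):
        nbs = panel_records["NBS"]
        with_ins = ProteinRecord("ins", nbs.residues[:40] + "WWW" + nbs.residues[40:])
        with_del = ProteinRecord("del", nbs.residues[:49] + nbs.residues[50:])
        msa = reference_anchored_msa([nbs, with_ins, with_del], nbs)
        anchor_row = msa.rows[0]
        # anchor has a 3-column padded insertion block; its own row carries gaps there
        assert anchor_row.count(GAP) == 3
        # at every anchor-residue column the inserted sequence matches the anchor
        for col, res in enumerate(anchor_row):
            if res != GAP:
                assert msa.rows[1][col] == res
        # the deletion sequence shows exactly one gap at an anchor column
        assert msa.rows[2].count(GAP) == 1 + 3

    def test_empty_input_is_an_error(self, panel_records):
        with pytest.raises(ValueError):
            reference_anchored_msa([], panel_records["NBS"])


class TestPDistance:
    def test_identical_rows_are_zero(self):
        msa = MultipleAlignment(["a", "b"], ["MKTAY", "MKTAY"])
        assert np.allclose(p_distance_matrix(msa).data, 0.0)

    def test_three_of_ten_mismatches(self):
        msa = MultipleAlignment(["a", "b"], ["AAAAAAAAAA", "AAACCCAAAA"])
        assert p_distance_matrix(msa)["a", "b"] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_column_count(self, seed):
        rng = random.Random(seed)
        rows = [
            "".join(rng.choice(AA + "-") for _ in range(50)) for _ in range(4)
        ]
        rows = [r if r.strip("-") else "A" * 50 for r in rows]
        msa = MultipleAlignment(list("abcd"), rows)
        dm = p_distance_matrix(msa)
        for i in range(4):
            for j in range(i + 1, 4):
                both = [
                    (x, y) for x, y in zip(rows[i], rows[j]) if "-" not in (x, y)
                ]
                expected = sum(1 for x, y in both if x != y) / len(both)
                assert dm[i, j] == pytest.approx(expected)

    def test_poisson_correction_is_minus_log_one_minus_p(self):
        msa = MultipleAlignment(["a", "b"], ["AAAAAAAAAA", "AAACCCAAAA"])
        dm = p_distance_matrix(msa, correction="poisson")
        assert dm["a", "b"] == pytest.approx(-np.log(0.7))

    def test_no_comparable_columns_names_the_pair(self):
        msa = MultipleAlignment(["left", "right"], ["AA--", "--AA"])
        with pytest.raises(ValueError, match="left.*right"):
            p_distance_matrix(msa)


class TestNeighborJoining:
    def test_two_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        tree = neighbor_joining(dm)
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([0.2, 0.2])

    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.3, 0.5, 0.6
        dm = DistanceMatrix(
            np.array([[0, d12, d13], [d12, 0, d23], [d13, d23, 0]]), list("abc")
        )
        tree = neighbor_joining(dm)
        by_name = {t.name: t.length for t in tree.tips()}
        assert by_name["a"] == pytest.approx((d12 + d13 - d23) / 2)
        assert by_name["b"] == pytest.approx((d12 + d23 - d13) / 2)
        assert by_name["c"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((a,b),(c,d)) with known branch lengths
        ids, dm, truth_splits = random_additive_tree(4, random.Random(4))
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == truth_splits
        assert np.allclose(
            tree.tip_tip_distances(set(ids)).filter(ids).data, dm.filter(ids).data,
            atol=1e-9,
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_random_additive_trees_up_to_eight_taxa(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 8)
        ids, dm, truth_splits = random_additive_tree(n, rng)
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set(ids)
        assert bipartitions(tree) == truth_splits
        path = tree.tip_tip_distances(set(ids)).filter(ids)
        assert np.allclose(path.data, dm.filter(ids).data, atol=1e-9)

    def test_agrees_with_library_nj_topology(self):
        ids, dm, _ = random_additive_tree(7, random.Random(99))
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert bipartitions(ours) == bipartitions(theirs)

def test_negative_entry_matrix_is_an_error():
    class Fake:
        ids = ("a", "b")
        data = np.array([[0.0, -0.1], [-0.1, 0.0]])

    with pytest.raises(ValueError, match="negative"):
        neighbor_joining(Fake())


def two_clade_msa(n_per_clade=4, n_cols=200, within=0.02, between=0.6, seed=0):
    rng = random.Random(seed)
    base = "".join(rng.choice(AA) for _ in range(n_cols))
    other = list(base)
    for i in range(n_cols):
        if rng.random() < between:
            other[i] = rng.choice([a for a in AA if a != other[i]])
    clades = {"x": base, "y": "".join(other)}
    ids, rows = [], []
    for label, root in clades.items():
        for k in range(n_per_clade):
            row = list(root)
            for i in range(n_cols):
                if rng.random() < within:
                    row[i] = rng.choice([a for a in AA if a != row[i]])
            ids.append(f"{label}{k}")
            rows.append("".join(row))
    return MultipleAlignment(ids, rows)


class TestBootstrap:
    def test_same_seed_gives_identical_supports(self):
        msa = two_clade_msa(seed=5)
        t1 = bootstrap_support(msa, replicates=50, seed=7)
        t2 = bootstrap_support(msa, replicates=50, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = two_clade_msa(seed=3)
        tree = bootstrap_support(msa, replicates=1, seed=1)
        supports = [
            int(n.name) for n in tree.non_tips(include_self=False) if n.name is not None
        ]
        assert supports and set(supports) <= {0, 100}

    def test_deep_split_has_high_support(self):
        msa = two_clade_msa(seed=11)
        tree = bootstrap_support(msa, replicates=200, seed=2)
        central = frozenset(f"y{k}" for k in range(4))
        found = False
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if side == central or side == frozenset(msa.ids) - central:
                found = True
                assert int(node.name) >= 95
        assert found

    def test_supports_bounded_and_variance_shrinks_with_replicates(self):
        msa = two_clade_msa(seed=13, within=0.15, between=0.3, n_cols=60)

        def support_spread(replicates):
            values = []
            for seed in range(5):
                tree = bootstrap_support(msa, replicates=replicates, seed=seed)
                for node in tree.non_tips(include_self=False):
                    if node.name is not None:
                        values.append(int(node.name))
            assert all(0 <= v <= 100 for v in values)
            return np.var(np.array(values).reshape(5, -1).mean(axis=1))

        assert support_spread(400) <= support_spread(25) + 1e-9

    def test_too_few_columns_rejected(self):
        msa = MultipleAlignment(["a", "b"], ["A", "C"])
        with pytest.raises(ValueError, match="columns"):
            bootstrap_support(msa, replicates=10)


class TestNewick:
    def test_simple_round_trip(self):
        tree = read_newick("(A:0.1,B:0.1);")
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]
        again = read_newick(write_newick(tree))
        assert {t.name for t in again.tips()} == {"A", "B"}

    def test_support_label_preserved(self):
        text = "((A:0.1,B:0.2)87:0.05,C:0.3,D:0.4);"
        tree = read_newick(text)
        assert write_newick(tree).count("87") == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_random_trees_preserve_bipartitions(self, seed):
        _, dm, _ = random_additive_tree(random.Random(seed).randint(4, 8), random.Random(seed))
        tree = neighbor_joining(dm)
        again = read_newick(write_newick(tree))
        assert bipartitions(again) == bipartitions(tree)

    def test_malformed_newick_raises_parse_error(self):
        with pytest.raises(Exception):
            read_newick("((A:0.1,B: ;")
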