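"""Presence matrices, prevalence, co-occurrence and ancestral states."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from motortrace.census import CORE_FAMILIES, CensusResult
from motortrace.models import HomologCall, ValidationError
from motortrace.profiling import (
    PresenceMatrix,
    build_matrix,
    cooccurrence,
    dollo_ancestral,
    export_tree_annotations,
    fitch_ancestral,
    parse_itol_binary,
    prevalence,
)


def call(family: str, sp: str, tier: str = "context_validated") -> HomologCall:
    return HomologCall(
        family=family, genome_id=sp, locus_tag=f"{sp}_1", tier=tier,
        evidence=("test",),
    )


def census(sp: str, count: int) -> CensusResult:
    presence = {f: i < count for i, f in enumerate(CORE_FAMILIES)}
    return CensusResult(species_id=sp, presence=presence)


class TestBuildMatrix:
    def test_context_validated_call_scores_one(self):
        m = build_matrix([call("FlgY", "a")], [census("a", 24)], ["a"])
        assert m.column("FlgY").loc["a"] == 1
        assert m.column("flagellar_gene_set").loc["a"] == 1

    def test_rescue_candidate_not_counted_by_default(self):
        m = build_matrix(
            [call("FlgY", "a", tier="rescue_candidate")], [census("a", 10)], ["a"]
        )
        assert m.column("FlgY").loc["a"] == 0

    def test_composite_requires_all_three_cage_genes(self):
        calls = [call("FcpM", "a"), call("FcpN", "a")]
        m = build_matrix(calls, [census("a", 24)], ["a"])
        assert m.column("FcpMNO").loc["a"] == 0
        m2 = build_matrix(calls + [call("FcpO", "a")], [census("a", 24)], ["a"])
        assert m2.column("FcpMNO").loc["a"] == 1

    def test_unknown_trait_errors(self):
        with pytest.raises(ValidationError, match="no family mapping"):
            build_matrix([], [], ["a"], traits=("mystery_trait",))

    def test_extra_trait_column(self):
        m = build_matrix(
            [], [], ["a", "b"], traits=("T4P",),
            extra_traits={"T4P": {"a": True}},
        )
        assert m.column("T4P").tolist() == [1, 0]


class TestPrevalence:
    def test_three_of_four(self):
        data = pd.DataFrame({"x": [1, 1, 1, 0]}, index=list("abcd"))
        frac, num, den = prevalence(PresenceMatrix(data), "x")
        assert (frac, num, den) == (0.75, 3, 4)
        assert frac * den == num

    def test_absent_everywhere(self):
        data = pd.DataFrame({"x": [0, 0]}, index=list("ab"))
        assert prevalence(PresenceMatrix(data), "x")[0] == 0.0

    def test_matches_naive_recount_on_random_matrix(self, rng):
        data = pd.DataFrame(
            rng.integers(0, 2, size=(50, 5)),
            index=[f"s{i}" for i in range(50)],
            columns=list("abcde"),
        )
        m = PresenceMatrix(data)
        for trait in "abcde":
            frac, num, den = prevalence(m, trait)
            naive = sum(data.loc[sp, trait] for sp in data.index)
            assert num == naive and den == 50 and frac == naive / 50

    def test_empty_subset_errors(self):
        data = pd.DataFrame({"x": [1]}, index=["a"])
        with pytest.raises(ValidationError, match="empty"):
            prevalence(PresenceMatrix(data), "x", [])


class TestCooccurrence:
    def test_identical_columns(self):
        data = pd.DataFrame({"x": [1, 0, 1], "y": [1, 0, 1]}, index=list("abc"))
        co = cooccurrence(PresenceMatrix(data), "x", "y")
        assert co.jaccard == 1.0 and co.both == 2 and co.neither == 1

    def test_disjoint_columns(self):
        data = pd.DataFrame({"x": [1, 0], "y": [0, 1]}, index=list("ab"))
        assert cooccurrence(PresenceMatrix(data), "x", "y").jaccard == 0.0

    def test_hypergeometric_tail_matches_exhaustive_enumeration(self):
        """P(overlap >= k) versus enumeration over all C(20,10) draws."""
        n, k_a, k_b = 20, 10, 10
        a_set = set(range(k_a))
        for observed in (10, 7, 5):
            count = sum(
                1
                for draw in itertools.combinations(range(n), k_b)
                if len(a_set.intersection(draw)) >= observed
            )
            expected = count / math.comb(n, k_b)
            x = [1] * k_a + [0] * (n - k_a)
            # construct a B column with the observed overlap
            y = (
                [1] * observed
                + [0] * (k_a - observed)
                + [1] * (k_b - observed)
                + [0] * (n - k_a - (k_b - observed))
            )
            data = pd.DataFrame(
                {"A": x, "B": y}, index=[f"s{i}" for i in range(n)]
            )
            co = cooccurrence(PresenceMatrix(data), "A", "B")
            assert co.both == observed
            assert co.p_enrichment == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# parsimony oracles


def topologies(leaves: tuple[str, ...]):
    """All rooted, strictly bifurcating topologies on a labeled leaf set."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for r in range(len(rest)):
        for subset in itertools.combinations(rest, r):
            left = (first,) + subset
            right = tuple(l for l in rest if l not in subset)
            for lt in topologies(left):
                for rt in topologies(right):
                    yield (lt, rt)


def to_dendropy(shape, leaves: tuple[str, ...]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(list(leaves))

    def build(node_shape):
        if isinstance(node_shape, str):
            return dendropy.Node(taxon=tns.get_taxon(node_shape))
        node = dendropy.Node()
        node.add_child(build(node_shape[0]))
        node.add_child(build(node_shape[1]))
        return node

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=build(shape))
    tree.is_rooted = True
    return tree


def exhaustive_min_changes(shape, leaves, leaf_states: dict[str, int]) -> int:
    """Minimum changes over every internal labeling (brute force)."""
    nodes: list = []
    edges: list[tuple[int, int]] = []
    leaf_idx: dict[str, int] = {}
    internal: list[int] = []

    def walk(s) -> int:
        i = len(nodes)
        nodes.append(s)
        if isinstance(s, str):
            leaf_idx[s] = i
            return i
        internal.append(i)
        for child in s:
            j = walk(child)
            edges.append((i, j))
        return i

    walk(shape)
    best = None
    labels = [0] * len(nodes)
    for leaf, i in leaf_idx.items():
        labels[i] = leaf_states[leaf]
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        for i, v in zip(internal, assignment):
            labels[i] = v
        changes = sum(labels[p] != labels[c] for p, c in edges)
        if best is None or changes < best:
            best = changes
    return best


class TestFitch:
    def test_uniform_leaves_mean_no_changes(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = True
        rec = fitch_ancestral(tree, {l: 1 for l in "abcd"})
        assert rec.changes == 0
        assert all(s == frozenset({1}) for s in rec.states.values())

    def test_balanced_split_has_one_change_ambiguous_root(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = True
        rec = fitch_ancestral(tree, {"a": 1, "b": 1, "c": 0, "d": 0})
        assert rec.changes == 1
        assert rec.root_states == frozenset({0, 1})
        assert rec.changes == exhaustive_min_changes(
            (("a", "b"), ("c", "d")), "abcd", {"a": 1, "b": 1, "c": 0, "d": 0}
        )

    def test_unlabelled_leaf_errors(self):
        tree = dendropy.Tree.get(data="(a,b);", schema="newick")
        tree.is_rooted = True
        with pytest.raises(ValidationError, match="no trait state"):
            fitch_ancestral(tree, {"a": 1})

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_exhaustive_oracle_on_all_small_trees(self, n):
        leaves = tuple(f"t{i}" for i in range(n))
        for shape in topologies(leaves):
            tree = to_dendropy(shape, leaves)
            for states in itertools.product((0, 1), repeat=n):
                leaf_states = dict(zip(leaves, states))
                rec = fitch_ancestral(tree, leaf_states)
                assert rec.changes == exhaustive_min_changes(
                    shape, leaves, leaf_states
                )

    def test_invariant_under_leaf_order_permutation(self, rng):
        leaves = tuple("abcdef")
        shape = (("a", ("b", "c")), (("d", "e"), "f"))
        states = {l: int(rng.integers(0, 2)) for l in leaves}
        tree = to_dendropy(shape, leaves)
        base = fitch_ancestral(tree, states).changes
        swapped = ((("e", "d"), "f"), (("c", "b"), "a"))
        tree2 = to_dendropy(swapped, leaves)
        assert fitch_ancestral(tree2, states).changes == base


class TestDollo:
    def test_single_clade_gain(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = True
        rec = dollo_ancestral(tree, {"a": 1, "b": 1, "c": 0, "d": 0})
        assert rec.changes == 1  # one gain, no losses
        assert rec.root_states == frozenset({0})

    def test_loss_counted_inside_clade(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = True
        rec = dollo_ancestral(tree, {"a": 1, "b": 0, "c": 1, "d": 0})
        assert rec.root_states == frozenset({1})
        assert rec.changes == 3  # gain at root plus two losses

    def test_absent_everywhere(self):
        tree = dendropy.Tree.get(data="(a,b);", schema="newick")
        tree.is_rooted = True
        assert dollo_ancestral(tree, {"a": 0, "b": 0}).changes == 0


class TestItolExport:
    def test_one_trait_three_species(self, tmp_path):
        data = pd.DataFrame({"FlgY": [1, 0, 1]}, index=list("abc"))
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        files = export_tree_annotations(PresenceMatrix(data), tree, tmp_path)
        binary = [f for f in files if "FlgY" in f.name]
        assert len(binary) == 1
        lines = binary[0].read_text().splitlines()
        assert sum("," in l and l.split(",")[0] in "abc" for l in lines) == 3

    def test_round_trip_recovers_column(self, tmp_path):
        data = pd.DataFrame(
            {"x": [1, 0, 1, 0], "y": [0, 0, 1, 1]}, index=list("abcd")
        )
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        files = export_tree_annotations(PresenceMatrix(data), tree, tmp_path)
        for trait in ("x", "y"):
            path = next(f for f in files if f.name == f"itol_{trait}.txt")
            parsed = parse_itol_binary(path.read_text())
            assert parsed == {sp: int(data.loc[sp, trait]) for sp in "abcd"}

    def test_species_missing_from_tree_errors(self, tmp_path):
        data = pd.DataFrame({"x": [1, 1]}, index=["a", "zzz"])
        tree = dendropy.Tree.get(data="(a,b);", schema="newick")
        with pytest.raises(ValidationError, match="zzz"):
            export_tree_annotations(PresenceMatrix(data), tree, tmp_path)

    def test_empty_trait_list_gives_colorstrip_only(self, tmp_path):
        data = pd.DataFrame(index=list("ab"))
        tree = dendropy.Tree.get(data="(a,b);", schema="newick")
        files = export_tree_annotations(
            PresenceMatrix(data), tree, tmp_path,
            taxon_groups={"a": "G1", "b": "G2"},
        )
        assert [f.name for f in files] == ["itol_taxon_colorstrip.txt"]
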