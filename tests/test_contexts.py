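"""Context algebra: folding, shapes, enumeration, composition, grafting."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mertree import contexts as ctx
from mertree.contexts import (
    ContextKey,
    ContextTree,
    MutationType,
    MUTATION_TYPES,
    canonical_fold,
    children,
    enumerate_level,
    flank_widths,
    graft,
    make_tree_set,
    n_contexts,
    parent_context,
    reverse_complement,
)

windows = st.text(alphabet="ACGT", min_size=1, max_size=9)


class TestFolding:
    @pytest.mark.parametrize(
        "bases,central,alt,expected",
        [
            ("TGG", 1, "A", ("CCA", "T", 1)),
            ("ACG", 1, "T", ("ACG", "T", 1)),
            ("T", 0, "C", ("A", "G", 0)),
        ],
    )
    def test_examples(self, bases, central, alt, expected):
        assert canonical_fold(bases, central, alt) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_fold("ANG", 1, "T")

    @settings(derandomize=True, max_examples=200)
    @given(windows, st.sampled_from("ACGT"), st.data())
    def test_idempotent_and_unique_canonical(self, bases, alt, data):
        central = data.draw(st.integers(0, len(bases) - 1))
        folded = canonical_fold(bases, central, alt)
        assert folded[0][folded[2]] in "AC"
        assert canonical_fold(folded[0], folded[2], folded[1]) == folded
        # exactly one of (window, revcomp window) is canonical unless palindromic center
        rc = reverse_complement(bases)
        rc_central = len(bases) - 1 - central
        assert (bases[central] in "AC") != (rc[rc_central] in "AC") or bases == rc


class TestShapes:
    @pytest.mark.parametrize(
        "level,arch,expected",
        [
            (2, ctx.RIGHT_ASYMMETRIC, (0, 1)),
            (9, ctx.RIGHT_ASYMMETRIC, (4, 4)),
            (5, ctx.SYMMETRIC, (2, 2)),
            (2, ctx.LEFT_ASYMMETRIC, (1, 0)),
            (4, ctx.LEFT_ASYMMETRIC, (2, 1)),
        ],
    )
    def test_flank_widths(self, level, arch, expected):
        assert flank_widths(level, arch) == expected

    def test_widths_sum_to_level(self):
        for arch in (ctx.RIGHT_ASYMMETRIC, ctx.LEFT_ASYMMETRIC):
            for level in range(1, 10):
                n5, n3 = flank_widths(level, arch)
                assert n5 + n3 + 1 == level

    def test_symmetric_even_level_invalid(self):
        with pytest.raises(ctx.InvalidShapeError):
            flank_widths(4, ctx.SYMMETRIC)


class TestChildrenAndEnumeration:
    def test_right_asymmetric_extends_3prime_first(self):
        kids = children(ContextKey("A", ctx.RIGHT_ASYMMETRIC))
        assert [k.bases for k in kids] == ["AA", "AC", "AG", "AT"]

    def test_symmetric_sixteen_children(self):
        kids = children(ContextKey("A", ctx.SYMMETRIC))
        assert len(kids) == 16
        assert all(k.bases[1] == "A" and len(k.bases) == 3 for k in kids)

    def test_asymmetric_one_to_three_mer_needs_twenty_edges(self):
        # 4 intermediate 2-mer edges plus 16 3-mer edges
        mid = children(ContextKey("A", ctx.RIGHT_ASYMMETRIC))
        deep = [c for k in mid for c in children(k)]
        assert len(mid) + len(deep) == 20

    @pytest.mark.parametrize("level", [1, 2, 3, 4])
    def test_enumeration_size_and_order(self, level):
        names = enumerate_level("C", level, ctx.RIGHT_ASYMMETRIC)
        assert len(names) == 4 ** (level - 1)
        assert names == sorted(names)
        assert len(set(names)) == len(names)

    def test_enumerate_examples(self):
        assert enumerate_level("C", 1, ctx.RIGHT_ASYMMETRIC) == ["C"]
        assert len(enumerate_level(MutationType("C", "T"), 3, ctx.RIGHT_ASYMMETRIC)) == 16
        assert n_contexts(9) == 65536

    @pytest.mark.parametrize("arch", [ctx.RIGHT_ASYMMETRIC, ctx.LEFT_ASYMMETRIC])
    def test_children_partition_next_level(self, arch):
        for level in (1, 2, 3):
            parents = enumerate_level("A", level, arch)
            all_children = [
                c.bases for p in parents for c in children(ContextKey(p, arch))
            ]
            assert sorted(all_children) == enumerate_level("A", level + 1, arch)

    def test_every_context_has_single_parent(self):
        for arch, level in [(ctx.RIGHT_ASYMMETRIC, 4), (ctx.SYMMETRIC, 5)]:
            parents = set(enumerate_level("C", ctx.parent_level(level, arch), arch))
            for name in enumerate_level("C", level, arch):
                assert parent_context(name, arch) in parents

    def test_edge_count_closed_forms(self):
        # verified by enumeration at shallow K, closed form beyond
        for K in (2, 3, 4, 5):
            enumerated = sum(
                len(enumerate_level("A", lvl, ctx.RIGHT_ASYMMETRIC))
                for lvl in range(2, K + 1)
            )
            assert enumerated == sum(4 ** (k - 1) for k in range(2, K + 1))
        assert sum(4 ** (k - 1) for k in range(2, 10)) == 87_380
        assert sum(4 ** (k - 1) for k in (3, 5, 7, 9)) == 69_904


class TestTreeComposition:
    def test_all_zero_shifts_give_base_probability_everywhere(self):
        tree = ContextTree(MutationType("C", "T"), 4, theta=math.log(0.01))
        for level in (1, 2, 3, 4):
            for name in enumerate_level("C", level, tree.architecture)[:8]:
                assert tree.node_probability(name) == pytest.approx(0.01)

    def test_path_product_example(self):
        # 0.01 * 2 * 1.5 = 0.03 through a two-edge path
        tree = ContextTree(MutationType("C", "T"), 3, theta=math.log(0.01))
        tree.phi[2][ctx.context_index("CG", tree.architecture)] = math.log(2)
        tree.phi[3][ctx.context_index("ACG", tree.architecture)] = math.log(1.5)
        assert tree.node_probability("ACG") == pytest.approx(0.03)

    def test_sibling_log_difference_equals_phi_difference(self, rng):
        tree = ContextTree(MutationType("A", "G"), 3)
        tree.theta = math.log(0.02)
        tree.phi[3] = rng.normal(0, 0.3, 16)
        i, j = ctx.context_index("AAC", tree.architecture), ctx.context_index("AAG", tree.architecture)
        d = tree.node_log_probability("AAC") - tree.node_log_probability("AAG")
        assert d == pytest.approx(tree.phi[3][i] - tree.phi[3][j])

    def test_cumulative_matches_per_node_path(self, rng):
        tree = ContextTree(MutationType("C", "A"), 3, theta=-4.0)
        tree.phi[2] = rng.normal(0, 0.2, 4)
        tree.phi[3] = rng.normal(0, 0.2, 16)
        cum = tree.cumulative_log_p(3)
        for name in enumerate_level("C", 3, tree.architecture):
            assert cum[ctx.context_index(name, tree.architecture)] == pytest.approx(
                tree.node_log_probability(name)
            )

    def test_unknown_context_raises(self):
        tree = ContextTree(MutationType("C", "T"), 2, theta=-4.0)
        with pytest.raises(ctx.UnknownContextError):
            tree.node_log_probability("AG")  # central base A, not C


def _random_tree_set(K, rng, architecture=ctx.RIGHT_ASYMMETRIC):
    trees = make_tree_set(K, architecture)
    for tree in trees.values():
        tree.theta = float(rng.uniform(math.log(0.005), math.log(0.02)))
        for lvl in tree.levels[1:]:
            tree.phi[lvl] = rng.normal(0, 0.2, n_contexts(lvl))
    return trees


class TestGraft:
    def test_graft_at_max_level_is_model_a(self, rng):
        a, b = _random_tree_set(3, rng), _random_tree_set(3, rng)
        g = graft(a, b, 3)
        for name in a:
            for ctxname in enumerate_level(a[name].mutation_type.ref, 3, a[name].architecture):
                assert g[name].node_log_probability(ctxname) == pytest.approx(
                    a[name].node_log_probability(ctxname)
                )

    def test_graft_with_itself_is_identity(self, rng):
        a = _random_tree_set(3, rng)
        for boundary in (1, 2, 3):
            g = graft(a, a, boundary)
            for name in a:
                assert g[name].theta == a[name].theta
                for lvl in (2, 3):
                    np.testing.assert_allclose(g[name].phi[lvl], a[name].phi[lvl])

    def test_composition_across_boundary(self):
        # theta from A, 2-mer edge from A, 3-mer edge from B: 0.01 * 2 * 1.5
        a, b = make_tree_set(3), make_tree_set(3)
        a["C>T"].theta = math.log(0.01)
        for t in a.values():
            if math.isnan(t.theta):
                t.theta = math.log(0.01)
        for t in b.values():
            t.theta = math.log(0.5)
        a["C>T"].phi[2][ctx.context_index("CG", "right_asymmetric")] = math.log(2)
        b["C>T"].phi[3][ctx.context_index("ACG", "right_asymmetric")] = math.log(1.5)
        g = graft(a, b, 2)
        assert g["C>T"].node_probability("ACG") == pytest.approx(0.03)

    def test_boundary_idempotence(self, rng):
        a, b = _random_tree_set(4, rng), _random_tree_set(4, rng)
        g1 = graft(a, b, 2)
        g2 = graft(g1, b, 2)
        for name in a:
            assert g2[name].theta == g1[name].theta
            for lvl in (2, 3, 4):
                np.testing.assert_array_equal(g2[name].phi[lvl], g1[name].phi[lvl])

    def test_architecture_mismatch_rejected(self, rng):
        a = _random_tree_set(3, rng)
        b = _random_tree_set(3, rng, architecture=ctx.SYMMETRIC)
        with pytest.raises(ctx.IncompatibleModelsError):
            graft(a, b, 2)


class TestSerialization:
    def test_round_trip_lossless(self, rng, tmp_path):
        trees = _random_tree_set(3, rng)
        path = tmp_path / "model.json"
        ctx.save_tree_set(trees, path)
        loaded = ctx.load_tree_set(path)
        for name in trees:
            assert abs(loaded[name].theta - trees[name].theta) < 1e-12
            for lvl in (2, 3):
                np.testing.assert_allclose(
                    loaded[name].phi[lvl], trees[name].phi[lvl], atol=1e-12
                )

    def test_version_check(self, tmp_path):
        trees = make_tree_set(2)
        for t in trees.values():
            t.theta = -4.0
        doc = ctx.tree_set_to_dict(trees)
        doc["format_version"] = "0.0"
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ctx.IncompatibleModelsError):
            ctx.load_tree_set(path)
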