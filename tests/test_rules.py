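"""Tests for rule induction, contribution ranking, distillation, inference."""

import json

import numpy as np
import pytest

import pupilforest as pf
from pupilforest.forest import Leaf, LeafModel, RegressionTree, SplitNode
from pupilforest.rules import (
    Condition,
    Rule,
    RuleSet,
    predict_eyes_ruleset,
    ruleset_from_json,
    ruleset_to_json,
)


def constant_leaf(mean):
    mean = np.asarray(mean, dtype=float)
    return Leaf(
        mean_displacement=mean,
        model=LeafModel(kind="constant", value=mean),
        n_samples=1,
    )


def depth1_tree(feature=3, threshold=0.5, left_mean=(0, 0), right_mean=(1, 1)):
    root = SplitNode(
        feature_index=feature,
        threshold=threshold,
        mean_displacement=np.array([0.5, 0.5]),
        left=constant_leaf(left_mean),
        right=constant_leaf(right_mean),
    )
    return RegressionTree(root=root, n_features=8, max_depth=1, min_samples_leaf=1)


def make_rule(contribution, output=(0.0, 0.0), n_conditions=1):
    return Rule(
        conditions=tuple(
            Condition(i, ">", 0.1) for i in range(n_conditions)
        ),
        output=np.asarray(output, dtype=float),
        node_importances=(contribution,) * n_conditions,
        provenance=(0, 0, 0, 0),
    )


class TestNodeImportance:
    @pytest.mark.parametrize(
        "parent,child,expected",
        [
            ((0.5, 0.5), (0.0, 0.0), np.sqrt(0.5)),
            ((0.3, -0.2), (0.3, -0.2), 0.0),
            ((0.002, -0.002), (0.001, -0.001), np.sqrt(2) * 0.001),
        ],
    )
    def test_magnitude(self, parent, child, expected):
        assert pf.node_importance(np.array(parent), np.array(child)) == pytest.approx(
            expected
        )


class TestInduceRules:
    def test_depth1_tree_two_rules(self):
        rules = pf.induce_rules(depth1_tree())
        assert len(rules) == 2
        assert rules[0].conditions == (Condition(3, "<=", 0.5),)
        assert rules[1].conditions == (Condition(3, ">", 0.5),)
        np.testing.assert_allclose(rules[0].output, [0, 0])
        np.testing.assert_allclose(rules[1].output, [1, 1])

    def test_single_leaf_tree_unconditional(self):
        tree = RegressionTree(
            root=constant_leaf([0.2, 0.1]), n_features=4, max_depth=0,
            min_samples_leaf=1,
        )
        rules = pf.induce_rules(tree)
        assert len(rules) == 1
        assert rules[0].conditions == ()
        assert rules[0].contribution == 0.0

    def test_rule_count_equals_leaf_count(self, small_model):
        tree = small_model.forests[0][0].trees[0]

        def count_leaves(node):
            if isinstance(node, Leaf):
                return 1
            return count_leaves(node.left) + count_leaves(node.right)

        assert len(pf.induce_rules(tree)) == count_leaves(tree.root)

    def test_importances_follow_path_edges(self):
        rules = pf.induce_rules(depth1_tree())
        # edge importance = |parent mean - leaf mean|
        assert rules[0].node_importances == (pytest.approx(np.sqrt(0.5)),)
        assert rules[0].contribution == pytest.approx(np.sqrt(0.5))


class TestRuleContribution:
    @pytest.mark.parametrize(
        "importances,expected",
        [((0.001, 0.003), 0.002), ((0.0029,), 0.0029), ((0.0, 0.0, 0.0), 0.0)],
    )
    def test_mean_of_path(self, importances, expected):
        r = Rule(
            conditions=tuple(Condition(0, ">", 0.0) for _ in importances),
            output=np.zeros(2),
            node_importances=importances,
            provenance=(0, 0, 0, 0),
        )
        assert pf.rule_contribution(r) == pytest.approx(expected)

    def test_contribution_independent_of_other_rules(self):
        a = make_rule(0.004)
        assert pf.rule_contribution(a) == pytest.approx(0.004)
        # embedding the rule in different rule sets cannot change its score
        rs1 = RuleSet(layers=[pf.LayerConfig(1, 1)], rules=[[[[a]]]])
        rs2 = RuleSet(
            layers=[pf.LayerConfig(1, 1)],
            rules=[[[[a, make_rule(0.1), make_rule(0.0001)]]]],
        )
        assert rs1.rules[0][0][0][0].contribution == rs2.rules[0][0][0][0].contribution


class TestDistill:
    def test_reordering_places_highest_first(self):
        """Three rules scored 0.0021 / 0.0029 / 0.0004 reorder to 29, 21, 4."""
        rules = [make_rule(c) for c in (0.0021, 0.0029, 0.0004)]
        rs = RuleSet(layers=[pf.LayerConfig(1, 1)], rules=[[[rules]]])
        out = pf.distill(rs, 1.0)
        contribs = [r.contribution for r in out.rules[0][0][0]]
        assert contribs == pytest.approx([0.0029, 0.0021, 0.0004])
        assert len(out.rules[0][0][0]) == 3

    def test_keep_half_of_ten(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=10)
        rules = [make_rule(float(c)) for c in scores]
        rs = RuleSet(layers=[pf.LayerConfig(1, 1)], rules=[[[rules]]])
        out = pf.distill(rs, 0.5)
        kept = [r.contribution for r in out.rules[0][0][0]]
        assert kept == sorted(scores, reverse=True)[:5]

    @pytest.mark.parametrize("ratio", [0.9, 0.7, 0.5])
    def test_count_law_per_tree(self, small_model, ratio):
        rs = pf.ruleset_from_cascade(small_model)
        out = pf.distill(rs, ratio)
        for (key, before), (_, after) in zip(rs.iter_trees(), out.iter_trees()):
            expected = max(1, int(np.floor(ratio * len(before) + 0.5)))
            assert len(after) == expected

    def test_parameters_monotone_in_pruning(self, small_model):
        rs = pf.ruleset_from_cascade(small_model)
        params = [
            pf.model_stats(pf.distill(rs, rho)).n_parameters
            for rho in (1.0, 0.9, 0.7, 0.5, 0.2)
        ]
        assert params == sorted(params, reverse=True)

    def test_floor_one_rule_per_tree(self):
        rules = [make_rule(0.01), make_rule(0.02)]
        rs = RuleSet(layers=[pf.LayerConfig(1, 1)], rules=[[[rules]]])
        out = pf.distill(rs, 0.01)
        assert len(out.rules[0][0][0]) == 1
        assert out.rules[0][0][0][0].contribution == pytest.approx(0.02)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_keep_ratio(self, small_model, bad):
        rs = pf.ruleset_from_cascade(small_model)
        with pytest.raises(ValueError):
            pf.distill(rs, bad)


class TestPredictRuleset:
    def test_equivalence_with_cascade(self, small_model, held_out):
        images, annotations, _ = held_out
        rs = pf.ruleset_from_cascade(small_model)
        for img, ann in zip(images, annotations):
            cl, cr = pf.predict_eyes(small_model, img, ann)
            rl, rr = predict_eyes_ruleset(rs, img, ann)
            np.testing.assert_allclose(rl, cl, atol=1e-12)
            np.testing.assert_allclose(rr, cr, atol=1e-12)

    def test_disjointness_exactly_one_rule_fires(self, small_model):
        rs = pf.ruleset_from_cascade(small_model)
        rng = np.random.default_rng(3)
        side = small_model.layers[0].patch_side
        trees = [rules for _, rules in rs.iter_trees()]
        for _ in range(20):
            x = rng.uniform(size=side * side)
            for tree_rules in trees:
                fired = sum(
                    all(c.holds(x) for c in r.conditions) for r in tree_rules
                )
                assert fired == 1

    def test_all_layers_abstaining_returns_midpoint(self):
        impossible = Rule(
            conditions=(Condition(0, ">", 2.0),),  # features live in [0, 1]
            output=np.array([0.5, 0.5]),
            node_importances=(0.1,),
            provenance=(0, 0, 0, 0),
        )
        rs = RuleSet(
            layers=[pf.LayerConfig(1, 1, crop_scale=1.0, patch_side=8)],
            rules=[[[[impossible]]]],
        )
        img = np.full((40, 40), 0.5)
        pred = pf.predict_ruleset(
            rs, img, np.array([10.0, 20.0]), np.array([30.0, 20.0])
        )
        np.testing.assert_allclose(pred, [20.0, 20.0])

    def test_depth1_rule_traversal(self):
        rules = pf.induce_rules(depth1_tree(feature=3, threshold=0.5))
        x_low = np.zeros(8)
        x_low[3] = 0.2
        firing = [r for r in rules if all(c.holds(x_low) for c in r.conditions)]
        assert len(firing) == 1
        np.testing.assert_allclose(firing[0].output, [0, 0])


class TestModelStats:
    def test_parameter_convention(self):
        rs = RuleSet(
            layers=[pf.LayerConfig(1, 1)],
            rules=[[[[make_rule(0.01, n_conditions=4)]]]],
        )
        assert pf.model_stats(rs).n_parameters == 10
        assert pf.model_stats(rs).n_rules == 1

    def test_halving_uniform_rules_halves_parameters(self):
        rules = [make_rule(float(c), n_conditions=3) for c in np.linspace(0.1, 1, 10)]
        rs = RuleSet(layers=[pf.LayerConfig(1, 1)], rules=[[[rules]]])
        full = pf.model_stats(rs).n_parameters
        half = pf.model_stats(pf.distill(rs, 0.5)).n_parameters
        assert half * 2 == full

    def test_stats_nonnegative_and_floored(self, small_model):
        rs = pf.distill(pf.ruleset_from_cascade(small_model), 0.01)
        s = pf.model_stats(rs)
        n_trees = sum(1 for _ in rs.iter_trees())
        assert s.n_rules == n_trees  # floor of one rule per tree
        assert s.n_parameters > 0 and s.n_operations_per_inference > 0


class TestExport:
    def test_json_round_trip_bit_exact(self, small_model):
        rs = pf.distill(pf.ruleset_from_cascade(small_model), 0.8)
        s1 = ruleset_to_json(rs)
        s2 = ruleset_to_json(ruleset_from_json(s1))
        assert s1 == s2

    def test_round_trip_preserves_predictions(self, small_model, held_out):
        images, annotations, _ = held_out
        rs = pf.distill(pf.ruleset_from_cascade(small_model), 0.7)
        clone = ruleset_from_json(ruleset_to_json(rs))
        for img, ann in zip(images[:5], annotations[:5]):
            a = predict_eyes_ruleset(rs, img, ann)
            b = predict_eyes_ruleset(clone, img, ann)
            np.testing.assert_array_equal(a[0], b[0])
            np.testing.assert_array_equal(a[1], b[1])

    def test_text_listing_format(self, small_model):
        rs = pf.ruleset_from_cascade(small_model)
        text = pf.format_rules(rs, max_rules=2)
        assert "IF" in text and "THEN" in text and "x_" in text
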