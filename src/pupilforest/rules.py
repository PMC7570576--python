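"""IF-THEN rule extraction, contribution ranking, and distillation.

Every root-to-leaf path of every tree in a trained cascade becomes one rule:
a conjunction of threshold conditions on patch features with a frozen
constant output (the leaf's mean displacement).  Each split edge along the
path carries an importance — the Euclidean magnitude of the change in mean
displacement from parent to child — and a rule's contribution is the mean of
its edge importances.  Distillation sorts each tree's rules by contribution
and keeps the top ``round(keep_ratio * n)`` of them (at least one per tree),
trading a controlled amount of coverage for a much smaller, human-readable
model.

Inference over a distilled rule set mirrors cascade inference, except that a
sample routed to a deleted rule makes that tree abstain; forests average the
non-abstaining trees, layers average the non-abstaining forests, and a layer
with no surviving vote contributes zero displacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .cascade import (
    CascadeModel,
    LayerConfig,
    from_normalized,
    initial_position,
    patch_features,
)
from .forest import Leaf, RegressionTree, SplitNode

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "ModelStats",
    "node_importance",
    "induce_rules",
    "rule_contribution",
    "ruleset_from_cascade",
    "distill",
    "predict_ruleset",
    "predict_eyes_ruleset",
    "model_stats",
    "ruleset_to_json",
    "ruleset_from_json",
    "format_rules",
]


@dataclass(frozen=True)
class Condition:
    feature_index: int
    comparator: str  # "<=" | ">"
    threshold: float

    def holds(self, features: np.ndarray) -> bool:
        v = features[self.feature_index]
        return v <= self.threshold if self.comparator == "<=" else v > self.threshold


@dataclass
class Rule:
    """One root-to-leaf path with its frozen output and contribution score."""

    conditions: Tuple[Condition, ...]
    output: np.ndarray  # (2,) normalized displacement
    node_importances: Tuple[float, ...]
    provenance: Tuple[int, int, int, int]  # (layer, forest, tree, leaf)
    contribution: float = field(init=False)

    def __post_init__(self) -> None:
        self.output = np.asarray(self.output, dtype=float)
        self.contribution = rule_contribution_values(self.node_importances)


def rule_contribution_values(importances: Sequence[float]) -> float:
    if len(importances) == 0:
        return 0.0
    return float(np.mean(importances))


def rule_contribution(rule: Rule) -> float:
    """Mean of the per-edge importance magnitudes along the rule's path."""
    return rule_contribution_values(rule.node_importances)


def node_importance(parent_mean: np.ndarray, child_mean: np.ndarray) -> float:
    """Magnitude of the mean-displacement change across one split edge."""
    diff = np.asarray(parent_mean, dtype=float) - np.asarray(child_mean, dtype=float)
    return float(np.linalg.norm(diff))


def induce_rules(
    tree: RegressionTree, provenance: Tuple[int, int, int] = (0, 0, 0)
) -> List[Rule]:
    """Convert a tree into rules, one per leaf, in left-to-right leaf order.

    Conditions accumulate along the path ("<=" for the left branch, ">" for
    the right); the output freezes the leaf's constant mean displacement.  A
    single-leaf tree yields one unconditional rule with contribution 0.
    """
    layer, forest_i, tree_i = provenance
    rules: List[Rule] = []

    def walk(node, conds: Tuple[Condition, ...], imps: Tuple[float, ...]) -> None:
        if isinstance(node, Leaf):
            rules.append(
                Rule(
                    conditions=conds,
                    output=node.mean_displacement.copy(),
                    node_importances=imps,
                    provenance=(layer, forest_i, tree_i, len(rules)),
                )
            )
            return
        assert isinstance(node, SplitNode)
        for comparator, child in (("<=", node.left), (">", node.right)):
            cond = Condition(node.feature_index, comparator, float(node.threshold))
            imp = node_importance(
                node.mean_displacement,
                child.mean_displacement,
            )
            walk(child, conds + (cond,), imps + (imp,))

    walk(tree.root, (), ())
    return rules


@dataclass
class ModelStats:
    """Size accounting for a rule set.

    ``n_parameters`` counts 2 per condition (feature index, threshold) plus 2
    per rule output; ``n_operations_per_inference`` is the worst case for one
    patch: the longest retained rule's comparison count summed over trees,
    plus one accumulate per tree and one per forest for the averaging.
    """

    n_rules: int
    n_parameters: int
    n_operations_per_inference: int


@dataclass
class RuleSet:
    """Rules grouped by (layer, forest, tree), plus the cascade geometry."""

    layers: List[LayerConfig]
    rules: List[List[List[List[Rule]]]]  # [layer][forest][tree] -> ordered rules
    keep_ratio: float = 1.0
    mirrored_right: bool = True
    _compiled: dict = field(default_factory=dict, repr=False, compare=False)

    def iter_trees(self):
        for li, layer in enumerate(self.rules):
            for fi, forest in enumerate(layer):
                for ti, tree_rules in enumerate(forest):
                    yield (li, fi, ti), tree_rules


def ruleset_from_cascade(model: CascadeModel) -> RuleSet:
    """Induce the full (keep_ratio 1) ordered rule set from a trained cascade.

    Within each tree, rules are sorted by contribution descending (ties keep
    the original leaf order); the set still covers the whole feature space.
    """
    all_rules: List[List[List[List[Rule]]]] = []
    for li, forests in enumerate(model.forests):
        layer_rules = []
        for fi, forest in enumerate(forests):
            forest_rules = []
            for ti, tree in enumerate(forest.trees):
                items = induce_rules(tree, provenance=(li, fi, ti))
                order = sorted(
                    range(len(items)), key=lambda i: (-items[i].contribution, i)
                )
                forest_rules.append([items[i] for i in order])
            layer_rules.append(forest_rules)
        all_rules.append(layer_rules)
    return RuleSet(
        layers=list(model.layers),
        rules=all_rules,
        keep_ratio=1.0,
        mirrored_right=model.mirrored_right,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def distill(ruleset: RuleSet, keep_ratio: float) -> RuleSet:
    """Keep the top ``round(keep_ratio * n)`` rules per tree (floor of 1).

    ``keep_ratio`` is the retained fraction; a removal percentage ``d`` maps
    to ``keep_ratio = 1 - d/100``.
    """
    if not 0 < keep_ratio <= 1:
        raise ValueError("keep_ratio must lie in (0, 1]")
    new_rules = []
    for layer in ruleset.rules:
        new_layer = []
        for forest in layer:
            new_forest = []
            for tree_rules in forest:
                ordered = sorted(
                    range(len(tree_rules)),
                    key=lambda i: (-tree_rules[i].contribution, i),
                )
                n_keep = max(1, _round_half_up(keep_ratio * len(tree_rules)))
                new_forest.append([tree_rules[i] for i in ordered[:n_keep]])
            new_layer.append(new_forest)
        new_rules.append(new_layer)
    return RuleSet(
        layers=list(ruleset.layers),
        rules=new_rules,
        keep_ratio=keep_ratio,
        mirrored_right=ruleset.mirrored_right,
    )


# ---------------------------------------------------------------------------
# inference


def _compile_tree(tree_rules: List[Rule]):
    """Flatten a tree's rule conditions into arrays for vectorized firing."""
    feat, is_gt, thr, starts = [], [], [], []
    unconditional = []
    pos = 0
    for i, rule in enumerate(tree_rules):
        if not rule.conditions:
            unconditional.append(i)
        starts.append(pos)
        for c in rule.conditions:
            feat.append(c.feature_index)
            is_gt.append(c.comparator == ">")
            thr.append(c.threshold)
        pos += len(rule.conditions)
    outputs = np.array([r.output for r in tree_rules], dtype=float)
    return (
        np.array(feat, dtype=int),
        np.array(is_gt, dtype=bool),
        np.array(thr, dtype=float),
        np.array(starts, dtype=int),
        outputs,
        unconditional,
    )


def _fire(compiled, features: np.ndarray) -> Optional[np.ndarray]:
    """Output of the first rule whose conditions all hold, or None."""
    feat, is_gt, thr, starts, outputs, unconditional = compiled
    if unconditional:
        return outputs[unconditional[0]]
    if len(feat) == 0:
        return None
    vals = features[feat]
    ok = np.where(is_gt, vals > thr, vals <= thr)
    satisfied = np.logical_and.reduceat(ok, starts)
    idx = np.flatnonzero(satisfied)
    if idx.size == 0:
        return None
    return outputs[idx[0]]


def _compiled_for(ruleset: RuleSet, key, tree_rules):
    cache = ruleset._compiled
    if key not in cache:
        cache[key] = _compile_tree(tree_rules)
    return cache[key]


def predict_ruleset(
    ruleset: RuleSet,
    image: np.ndarray,
    lm0: np.ndarray,
    lm1: np.ndarray,
    mirror: bool = False,
) -> np.ndarray:
    """Cascade inference executed purely from the IF-THEN rules.

    Trees whose firing rule was pruned abstain; averages are taken over the
    surviving members, and a fully abstaining layer adds zero displacement.
    """
    estimate = initial_position(lm0, lm1)
    cd = float(np.linalg.norm(np.asarray(lm1, float) - np.asarray(lm0, float)))
    for li, (layer, layer_rules) in enumerate(zip(ruleset.layers, ruleset.rules)):
        feats = patch_features(
            image, estimate, layer.crop_scale * cd, layer.patch_side, mirror=mirror
        )
        forest_outputs = []
        for fi, forest in enumerate(layer_rules):
            tree_outputs = []
            for ti, tree_rules in enumerate(forest):
                compiled = _compiled_for(ruleset, (li, fi, ti), tree_rules)
                out = _fire(compiled, feats)
                if out is not None:
                    tree_outputs.append(out)
            if tree_outputs:
                forest_outputs.append(np.stack(tree_outputs).mean(axis=0))
        if forest_outputs:
            pred = np.stack(forest_outputs).mean(axis=0)
        else:
            pred = np.zeros(2)
        if mirror:
            pred = np.array([-pred[0], pred[1]])
        estimate = estimate + from_normalized(pred, cd)
    return estimate


def predict_eyes_ruleset(ruleset: RuleSet, image: np.ndarray, annotation):
    """Predict (left, right) pupil centers from the rule set."""
    left = predict_ruleset(
        ruleset, image, annotation.left.lm0, annotation.left.lm1, mirror=False
    )
    right = predict_ruleset(
        ruleset,
        image,
        annotation.right.lm0,
        annotation.right.lm1,
        mirror=ruleset.mirrored_right,
    )
    return left, right


# ---------------------------------------------------------------------------
# accounting and export


def model_stats(ruleset: RuleSet) -> ModelStats:
    """Rule, parameter, and worst-case operation counts (see ModelStats)."""
    n_rules = 0
    n_parameters = 0
    comparisons = 0
    n_trees = 0
    n_forests = 0
    for layer in ruleset.rules:
        for forest in layer:
            n_forests += 1
            for tree_rules in forest:
                n_trees += 1
                n_rules += len(tree_rules)
                n_parameters += sum(2 * len(r.conditions) + 2 for r in tree_rules)
                comparisons += max((len(r.conditions) for r in tree_rules), default=0)
    return ModelStats(
        n_rules=n_rules,
        n_parameters=n_parameters,
        n_operations_per_inference=comparisons + n_trees + n_forests,
    )


def format_rules(ruleset: RuleSet, max_rules: Optional[int] = None) -> str:
    """Human-readable IF-THEN listing, one rule per line per tree."""
    lines = []
    for (li, fi, ti), tree_rules in ruleset.iter_trees():
        lines.append(f"# layer {li} forest {fi} tree {ti}")
        shown = tree_rules if max_rules is None else tree_rules[:max_rules]
        for rank, rule in enumerate(shown, start=1):
            if rule.conditions:
                cond_text = " and ".join(
                    f"(x_{c.feature_index} {c.comparator} {c.threshold:.6g})"
                    for c in rule.conditions
                )
            else:
                cond_text = "(always)"
            lines.append(
                f"{rank}:{{{rule.contribution:.6g}}} IF {cond_text} "
                f"THEN {{{rule.output[0]:.6g}, {rule.output[1]:.6g}}}"
            )
    return "\n".join(lines) + "\n"


def _rule_to_dict(rule: Rule) -> dict:
    return {
        "conditions": [
            {"feature": c.feature_index, "comparator": c.comparator, "threshold": float(c.threshold)}
            for c in rule.conditions
        ],
        "output": [float(rule.output[0]), float(rule.output[1])],
        "node_importances": [float(v) for v in rule.node_importances],
        "provenance": list(rule.provenance),
    }


def _rule_from_dict(d: dict) -> Rule:
    return Rule(
        conditions=tuple(
            Condition(int(c["feature"]), str(c["comparator"]), float(c["threshold"]))
            for c in d["conditions"]
        ),
        output=np.array(d["output"], dtype=float),
        node_importances=tuple(float(v) for v in d["node_importances"]),
        provenance=tuple(int(v) for v in d["provenance"]),
    )


def ruleset_to_json(ruleset: RuleSet) -> str:
    doc = {
        "format": "pupilforest-rules-v1",
        "keep_ratio": float(ruleset.keep_ratio),
        "mirrored_right": ruleset.mirrored_right,
        "counting_convention": (
            "parameters: 2 per condition + 2 per output; operations: worst-case "
            "comparisons per tree + one accumulate per tree and per forest"
        ),
        "layers": [
            {
                "n_forests": l.n_forests,
                "n_trees_per_forest": l.n_trees_per_forest,
                "crop_scale": l.crop_scale,
                "patch_side": l.patch_side,
            }
            for l in ruleset.layers
        ],
        "rules": [
            [[[_rule_to_dict(r) for r in tree] for tree in forest] for forest in layer]
            for layer in ruleset.rules
        ],
    }
    return json.dumps(doc)


def ruleset_from_json(text: str) -> RuleSet:
    doc = json.loads(text)
    if doc.get("format") != "pupilforest-rules-v1":
        raise ValueError("not a pupilforest rule-set file")
    return RuleSet(
        layers=[LayerConfig(**l) for l in doc["layers"]],
        rules=[
            [[[_rule_from_dict(r) for r in tree] for tree in forest] for forest in layer]
            for layer in doc["rules"]
        ],
        keep_ratio=float(doc["keep_ratio"]),
        mirrored_right=bool(doc["mirrored_right"]),
    )
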