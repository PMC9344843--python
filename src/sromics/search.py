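"""Evolutionary search over expression trees with a learned proposal.

The loop mirrors classic population-based symbolic regression with one
distinguishing ingredient: candidate trees are not sampled uniformly.
Features receive prior weights proportional to their mutual information with
the target, and both the feature and operator sampling distributions are
reinforced each generation toward the tokens used by the elite models, so the
proposal distribution improves as the search proceeds.

Each generation is composed of three groups: the elites of the previous
generation (kept as-is), mutated copies of elites, and freshly sampled trees.
Every distinct structure (by canonical signature) is fitted once and kept in
a hall of fame; the final answer is the ten best unique models ranked by BIC
(default), AIC, or raw training loss.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FitDivergenceError, SearchError, ValidationError
from .expr_core import (
    OPERATORS,
    SAMPLED_OPERATORS,
    ExpressionTree,
    FittedModel,
    Node,
)
from .fitting import FitConfig, fit_parameters
from .interpret import mutual_information

__all__ = [
    "PriorDistribution",
    "SamplingState",
    "SearchConfig",
    "estimate_priors",
    "sample_tree",
    "mutate",
    "update_state",
    "score",
    "run_search",
]

_PROB_FLOOR = 1e-4   # smoothing floor on every sampling probability
_REINFORCE = 0.2     # multiplicative reinforcement (1 + eta) for elite tokens
_MI_SMOOTHING = 0.1  # nats added to every feature's MI before normalisation
_N_RETURNED = 10


def _floor_normalize(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    w = w / total
    w = np.maximum(w, _PROB_FLOOR)
    return w / w.sum()


@dataclass
class PriorDistribution:
    """Normalised non-negative weights over candidate features."""

    features: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        self.features = tuple(self.features)
        self.weights = _floor_normalize(self.weights)
        if len(self.features) != self.weights.size:
            raise ValidationError("feature names and weights disagree in length")

    def weight_of(self, feature: str) -> float:
        return float(self.weights[self.features.index(feature)])


@dataclass
class SamplingState:
    """The learned categorical proposal over features and operators."""

    feature_probs: PriorDistribution
    operator_probs: dict[str, float]
    generation: int = 0

    def __post_init__(self):
        names = tuple(self.operator_probs)
        w = _floor_normalize(np.array([self.operator_probs[n] for n in names]))
        self.operator_probs = dict(zip(names, w))


@dataclass(frozen=True)
class SearchConfig:
    n_generations: int = 30
    population_size: int = 200
    n_elites: int = 20
    fraction_mutated: float = 0.4
    max_features: int = 3
    max_depth: int = 3
    criterion: str = "bic"
    seed: int = 0
    fit: FitConfig = field(
        default_factory=lambda: FitConfig(
            max_iterations=80, learning_rate=0.1, method="adam", tolerance=1e-6
        )
    )
    operators: tuple[str, ...] = SAMPLED_OPERATORS
    p_internal: float = 0.6  # chance of growing an operator when depth allows

    def __post_init__(self):
        if self.n_elites >= self.population_size:
            raise ValidationError("n_elites must be smaller than population_size")
        if not 0.0 <= self.fraction_mutated <= 1.0:
            raise ValidationError("fraction_mutated must lie in [0, 1]")
        if self.max_features < 1 or self.max_depth < 1:
            raise ValidationError("max_features and max_depth must be >= 1")
        if self.criterion not in ("bic", "aic", "train_loss"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        unknown = [o for o in self.operators if o not in OPERATORS]
        if unknown:
            raise ValidationError(f"unknown operators: {', '.join(unknown)}")


# ---------------------------------------------------------------------------
# priors


def estimate_priors(data, n_bins: int = 10) -> PriorDistribution:
    """Feature weights proportional to (smoothed) MI with the target.

    A constant smoothing term keeps estimator noise from concentrating the
    prior when no feature carries signal, and guarantees every feature a
    strictly positive sampling probability.
    """
    if data.n_samples < 2:
        raise ValidationError("estimating priors requires at least 2 samples")
    y = data.y
    features = data.feature_names
    if not features:
        raise ValidationError("dataset has no feature columns")
    mis = np.array(
        [mutual_information(data.column(f), y, n_bins=n_bins) for f in features]
    )
    return PriorDistribution(tuple(features), mis + _MI_SMOOTHING)


def initial_state(data, config: SearchConfig) -> SamplingState:
    priors = estimate_priors(data)
    ops = {name: 1.0 for name in config.operators}
    return SamplingState(feature_probs=priors, operator_probs=ops, generation=0)


# ---------------------------------------------------------------------------
# proposal sampling and mutation


def _draw_feature(state: SamplingState, used: list[str], max_features: int, rng) -> str:
    distinct = set(used)
    probs = state.feature_probs
    if len(distinct) >= max_features:
        # feature budget exhausted: reuse, weighted by the current priors
        names = sorted(distinct)
        w = np.array([probs.weight_of(n) if n in probs.features else 1.0 for n in names])
        w = w / w.sum()
        return str(rng.choice(names, p=w))
    return str(rng.choice(probs.features, p=probs.weights))


def _draw_operator(state: SamplingState, config: SearchConfig, rng, arity=None) -> str:
    names = [n for n in config.operators if arity is None or OPERATORS[n].arity == arity]
    if not names:
        raise ValidationError("no operators of the requested arity are enabled")
    w = np.array([state.operator_probs.get(n, _PROB_FLOOR) for n in names])
    w = w / w.sum()
    return str(rng.choice(names, p=w))


def sample_tree(state: SamplingState, config: SearchConfig, rng) -> ExpressionTree:
    """Draw a fresh random tree honouring max_depth and max_features."""
    used: list[str] = []

    def grow(depth_budget: int) -> Node:
        if depth_budget <= 1 or rng.random() > config.p_internal:
            f = _draw_feature(state, used, config.max_features, rng)
            used.append(f)
            return Node(feature=f)
        op = _draw_operator(state, config, rng)
        kids = [grow(depth_budget - 1) for _ in range(OPERATORS[op].arity)]
        return Node(op=op, children=kids)

    return ExpressionTree(grow(config.max_depth))


def _leaf_positions(tree: ExpressionTree) -> list[int]:
    return [i for i, n in enumerate(tree._nodes) if n.is_leaf]


def _internal_positions(tree: ExpressionTree) -> list[int]:
    return [i for i, n in enumerate(tree._nodes) if not n.is_leaf]


def _rebuild(tree: ExpressionTree, target_index: int, make: "callable") -> ExpressionTree:
    """Copy the tree with the node at preorder ``target_index`` replaced."""
    counter = itertools.count()

    def rec(node: Node) -> Node:
        i = next(counter)
        replaced = make(node) if i == target_index else None
        if replaced is not None:
            # still need to advance the counter past the old subtree
            for _ in node.walk():
                pass
            skipped = sum(1 for _ in node.walk()) - 1
            for _ in range(skipped):
                next(counter)
            return replaced
        if node.is_leaf:
            return Node(feature=node.feature)
        return Node(op=node.op, children=[rec(c) for c in node.children])

    return ExpressionTree(rec(tree.root), task=tree.task)


def _node_depths(tree: ExpressionTree) -> list[int]:
    depths = [1] * tree.n_nodes
    for i, kids in enumerate(tree._child_idx):
        for j in kids:
            depths[j] = depths[i] + 1
    return depths


def _subtree_height(node: Node) -> int:
    if node.is_leaf:
        return 1
    return 1 + max(_subtree_height(c) for c in node.children)


def mutate(
    tree: ExpressionTree, state: SamplingState, config: SearchConfig, rng
) -> ExpressionTree:
    """Apply exactly one structural edit, preserving all constraints.

    Edits: swap a leaf's feature, swap an operator (same arity), grow a leaf
    into an operator node, or prune an operator node down to one child.
    Infeasible edits (e.g. growing at max_depth) are never selected.
    """
    depths = _node_depths(tree)
    leaves = _leaf_positions(tree)
    internals = _internal_positions(tree)
    features = tree.feature_set

    edits = ["feature_swap"]
    growable = [i for i in leaves if depths[i] < config.max_depth]
    if growable:
        edits.append("grow")
    if internals:
        edits.append("prune")
        swappable = [
            i
            for i in internals
            if any(
                OPERATORS[o].arity == tree._nodes[i].op.arity
                and o != tree._nodes[i].op.name
                for o in config.operators
            )
        ]
        if swappable:
            edits.append("operator_swap")
    edit = str(rng.choice(edits))

    if edit == "feature_swap":
        pos = int(rng.choice(leaves))
        old = tree._nodes[pos].feature
        others = [f for f in features if f != old]
        # a brand-new feature is admissible if the budget allows it or the
        # swapped-out leaf was the only user of its feature
        remaining = {
            n.feature for i, n in enumerate(tree._nodes) if n.is_leaf and i != pos
        }
        candidates = list(state.feature_probs.features)
        w = np.array(state.feature_probs.weights)
        admissible = [
            k
            for k, f in enumerate(candidates)
            if f != old and len(remaining | {f}) <= config.max_features
        ]
        if not admissible:
            # single candidate feature in the pool: re-draw the same leaf
            admissible = [k for k, f in enumerate(candidates)]
        ww = w[admissible] / w[admissible].sum()
        new_feature = candidates[int(rng.choice(admissible, p=ww))]
        return _rebuild(tree, pos, lambda n: Node(feature=new_feature))

    if edit == "operator_swap":
        pos = int(rng.choice(swappable))
        node = tree._nodes[pos]
        options = [
            o
            for o in config.operators
            if OPERATORS[o].arity == node.op.arity and o != node.op.name
        ]
        new_op = str(rng.choice(options))
        return _rebuild(
            tree, pos, lambda n: Node(op=new_op, children=[c.copy() for c in n.children])
        )

    if edit == "grow":
        pos = int(rng.choice(growable))
        op = _draw_operator(state, config, rng)
        if OPERATORS[op].arity == 1:
            return _rebuild(tree, pos, lambda n: Node(op=op, children=[n.copy()]))
        used = list(features)
        sibling = _draw_feature(state, used, config.max_features, rng)
        return _rebuild(
            tree,
            pos,
            lambda n: Node(op=op, children=[n.copy(), Node(feature=sibling)]),
        )

    # prune: collapse an operator node to one of its children
    pos = int(rng.choice(internals))
    node = tree._nodes[pos]
    keep = int(rng.integers(len(node.children)))
    return _rebuild(tree, pos, lambda n: n.children[keep].copy())


def update_state(state: SamplingState, elites: list[FittedModel]) -> SamplingState:
    """Reinforce tokens used by the elites (multiplicative, floored).

    Every feature/operator appearing in an elite has its weight multiplied by
    (1 + eta) once per elite containing it; renormalisation leaves the
    relative ordering of untouched tokens unchanged.
    """
    if not elites:
        raise ValidationError("update_state requires a non-empty elite list")
    fw = np.array(state.feature_probs.weights, dtype=float)
    names = state.feature_probs.features
    ow = {k: float(v) for k, v in state.operator_probs.items()}
    for model in elites:
        for f in set(model.feature_set):
            if f in names:
                fw[names.index(f)] *= 1.0 + _REINFORCE
        ops = {n.op.name for n in model.tree._nodes if not n.is_leaf}
        for o in ops:
            if o in ow:
                ow[o] *= 1.0 + _REINFORCE
    return SamplingState(
        feature_probs=PriorDistribution(names, fw),
        operator_probs=ow,
        generation=state.generation + 1,
    )


# ---------------------------------------------------------------------------
# scoring and the main loop


def score(model: FittedModel, n_samples: int, criterion: str = "bic") -> float:
    """Selection score; lower is better.

    ``bic = 2*n*train_loss + k*ln(n)`` and ``aic = 2*n*train_loss + 2*k``,
    where train_loss is the mean negative log-likelihood so that
    ``2*n*train_loss = -2 ln L``.
    """
    if n_samples < 2:
        raise ValidationError("scoring requires at least 2 samples")
    k = model.n_params
    if criterion == "bic":
        return 2.0 * n_samples * model.train_loss + k * math.log(n_samples)
    if criterion == "aic":
        return 2.0 * n_samples * model.train_loss + 2.0 * k
    if criterion == "train_loss":
        return float(model.train_loss)
    raise ValidationError(f"unknown criterion {criterion!r}")


def _rank_key(model: FittedModel, criterion: str):
    # ties: fewer parameters first, then lexicographic signature
    return (
        score(model, model.n_samples, criterion),
        model.n_params,
        repr(model.signature()),
    )


def run_search(data, config: SearchConfig | None = None) -> list[FittedModel]:
    """Run the full evolutionary search and return the best unique models.

    Returns up to ten models with pairwise-distinct canonical signatures,
    sorted ascending by the configured criterion.  Deterministic given the
    seed.  Raises :class:`SearchError` if every candidate fit diverged.
    """
    config = config or SearchConfig()
    task_loss = config.fit.loss
    y = data.y
    if task_loss == "binary_cross_entropy" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError(
            "classification search requires a 0/1 target column; "
            "configure fit.loss='mean_squared_error' for regression"
        )
    rng = np.random.default_rng(config.seed)
    state = initial_state(data, config)

    hall: dict = {}  # signature -> FittedModel (best structures ever seen)
    ranked: list[FittedModel] = []
    n_failures = 0
    for gen in range(config.n_generations):
        if gen == 0 or not ranked:
            structures = [
                sample_tree(state, config, rng) for _ in range(config.population_size)
            ]
        else:
            elites = ranked[: config.n_elites]
            n_mut = int(round(config.fraction_mutated * config.population_size))
            n_fresh = max(config.population_size - len(elites) - n_mut, 0)
            structures = []
            for _ in range(n_mut):
                parent = elites[int(rng.integers(len(elites)))]
                structures.append(mutate(parent.tree, state, config, rng))
            structures.extend(
                sample_tree(state, config, rng) for _ in range(n_fresh)
            )
        for tree in structures:
            sig = tree.signature()
            if sig in hall:
                continue
            fit_cfg = replace(config.fit, seed=int(rng.integers(2**31)))
            try:
                hall[sig] = fit_parameters(tree, data, fit_cfg)
            except FitDivergenceError:
                n_failures += 1
                continue
        if hall:
            ranked = sorted(hall.values(), key=lambda m: _rank_key(m, config.criterion))
            state = update_state(state, ranked[: config.n_elites])
    if not hall:
        raise SearchError(
            f"all {n_failures} candidate fits diverged over "
            f"{config.n_generations} generations"
        )
    return ranked[:_N_RETURNED]
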