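"""Parametric expression trees: the unit of search for symbolic regression.

A model is a rooted tree whose leaves reference named input features and whose
internal nodes apply elementary mathematical operators.  Every node owns a
small vector of learnable parameters:

* feature leaf       -- affine map ``w*x + b``                    (2 params)
* ``add``            -- ``u + v + c``                             (1 param)
* ``multiply``       -- ``u*v + c``                               (1 param)
* ``tanh``           -- ``a*tanh(u) + b``                         (2 params)
* ``exp``            -- ``a*exp(u) + b``                          (2 params)
* ``inverse``        -- ``a/u + b``                               (2 params)
* ``gaussian1``      -- ``a*exp(-u^2) + b``                       (2 params)
* ``gaussian2``      -- ``a*exp(-u^2 - v^2) + b``                 (2 params)
* ``linear``         -- ``a*u + b``                               (2 params)

Function nodes scale and shift their *output*; the input centring and
scaling they need is already supplied by the affine map of the child
(``a*exp(-u^2) + b`` over a leaf ``w*x + c`` is a full four-parameter
Gaussian bump, centre ``-c/w`` and width ``1/|w|``).  Output affines matter
at the root: without them a ``tanh`` or gaussian model could never produce
confident probabilities through the logistic wrapper.

For classification the root value ``f(X)`` is wrapped with the logistic
function ``1/(1 + exp(-f(X)))`` (written ``logreg`` in display strings), so the
model output is a probability.  For regression the root value is the
prediction.

The binary operators carry an output offset so that forms such as
``logreg(x*y - c)`` -- whose 0.5-level set is the hyperbola ``x*y = c`` -- are
expressible; without it the product of two leaf affines can never realise a
pure ``x*y + const``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import ParseError, ValidationError

__all__ = [
    "Operator",
    "OPERATORS",
    "SAMPLED_OPERATORS",
    "Node",
    "ExpressionTree",
    "FittedModel",
    "evaluate",
    "parse_model_string",
    "default_parameters",
    "count_parameters",
    "canonical_signature",
]

# numerical guards used identically in forward and backward passes
_EXP_CLIP = 60.0       # cap on exp() arguments
_INV_FLOOR = 1e-12     # |denominator| floor for inverse
_PROB_EPS = 1e-15      # keeps classification outputs strictly inside (0, 1)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class Operator:
    name: str
    arity: int
    param_count: int


OPERATORS: dict[str, Operator] = {
    "add": Operator("add", 2, 1),
    "multiply": Operator("multiply", 2, 1),
    "tanh": Operator("tanh", 1, 2),
    "exp": Operator("exp", 1, 2),
    "inverse": Operator("inverse", 1, 2),
    "gaussian1": Operator("gaussian1", 1, 2),
    "gaussian2": Operator("gaussian2", 2, 2),
    "linear": Operator("linear", 1, 2),
}

#: operators offered to the evolutionary search by default.  ``linear`` is a
#: pure affine map, already expressible through leaf parameters, so sampling
#: it would only pay an extra complexity penalty.
SAMPLED_OPERATORS: tuple[str, ...] = (
    "add",
    "multiply",
    "tanh",
    "exp",
    "inverse",
    "gaussian1",
    "gaussian2",
)

_LEAF_PARAM_COUNT = 2


class Node:
    """A single tree node: either an operator or a feature leaf."""

    __slots__ = ("op", "feature", "children")

    def __init__(
        self,
        op: str | Operator | None = None,
        feature: str | None = None,
        children: Sequence["Node"] = (),
    ):
        if (op is None) == (feature is None):
            raise ValidationError("a node is either an operator or a feature leaf")
        if op is not None:
            if isinstance(op, str):
                if op not in OPERATORS:
                    raise ValidationError(f"unknown operator {op!r}")
                op = OPERATORS[op]
            if len(children) != op.arity:
                raise ValidationError(
                    f"operator {op.name!r} takes {op.arity} children, got {len(children)}"
                )
        elif children:
            raise ValidationError("feature leaves take no children")
        self.op = op
        self.feature = feature
        self.children = tuple(children)

    @property
    def is_leaf(self) -> bool:
        return self.op is None

    @property
    def param_count(self) -> int:
        return _LEAF_PARAM_COUNT if self.is_leaf else self.op.param_count

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(feature=self.feature)
        return Node(op=self.op, children=[c.copy() for c in self.children])

    def walk(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({node_to_string(self)})"


class ExpressionTree:
    """Immutable-by-convention rooted tree with a flat parameter layout.

    Parameters are stored externally as one flat vector; each node owns a
    contiguous slice assigned in preorder.  ``task`` decides whether the root
    value is wrapped with the logistic function at evaluation time.
    """

    def __init__(self, root: Node, task: str = "classification"):
        if task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {task!r}")
        self.root = root
        self.task = task
        nodes: list[Node] = []
        child_idx: list[tuple[int, ...]] = []

        def rec(node: Node) -> int:
            i = len(nodes)
            nodes.append(node)
            child_idx.append(())
            child_idx[i] = tuple(rec(c) for c in node.children)
            return i

        rec(root)
        if len({id(n) for n in nodes}) != len(nodes):
            raise ValidationError("node graph is not a tree (shared nodes)")
        self._nodes = nodes
        self._child_idx = child_idx
        slices: list[slice] = []
        start = 0
        for n in nodes:
            slices.append(slice(start, start + n.param_count))
            start += n.param_count
        self._slices = slices
        self._n_params = start
        seen: list[str] = []
        for n in nodes:
            if n.is_leaf and n.feature not in seen:
                seen.append(n.feature)
        self._feature_set = tuple(seen)

    # -- structure ---------------------------------------------------------
    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def feature_set(self) -> tuple[str, ...]:
        """Ordered (preorder of first occurrence) unique feature names."""
        return self._feature_set

    @property
    def n_params(self) -> int:
        return self._n_params

    @property
    def depth(self) -> int:
        def d(node: Node) -> int:
            if node.is_leaf:
                return 1
            return 1 + max(d(c) for c in node.children)

        return d(self.root)

    def param_slice(self, node_index: int) -> slice:
        return self._slices[node_index]

    def copy(self) -> "ExpressionTree":
        return ExpressionTree(self.root.copy(), task=self.task)

    # -- display and identity ---------------------------------------------
    def to_string(self, parameters: np.ndarray | None = None) -> str:
        """Render the model form as printed in result tables.

        Without ``parameters`` the simplified functional form is shown
        (affine weights suppressed, commutative arguments in lexicographic
        feature order).  With ``parameters`` every weight and offset is
        printed in the tree's structural order.
        """
        if parameters is None:
            inner = node_to_string(self.root)
        else:
            parameters = np.asarray(parameters, dtype=float)
            if parameters.shape != (self._n_params,):
                raise ValidationError(
                    f"expected {self._n_params} parameters, got {parameters.shape}"
                )
            by_node = {id(n): parameters[s] for n, s in zip(self._nodes, self._slices)}
            inner, _ = _render_params(self.root, by_node)
        if self.task == "classification":
            return f"logreg({inner})"
        return inner

    def signature(self):
        """Hashable identity invariant to commutative/associative reordering."""
        return _signature(self.root)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: Node) -> dict:
            if node.is_leaf:
                return {"feature": node.feature}
            return {"op": node.op.name, "children": [enc(c) for c in node.children]}

        return {"task": self.task, "root": enc(self.root)}

    @classmethod
    def from_dict(cls, doc: dict) -> "ExpressionTree":
        def dec(d: dict) -> Node:
            if "feature" in d:
                return Node(feature=d["feature"])
            return Node(op=d["op"], children=[dec(c) for c in d.get("children", [])])

        return cls(dec(doc["root"]), task=doc.get("task", "classification"))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionTree({self.to_string()})"


# ---------------------------------------------------------------------------
# display helpers

_PREC_ADD, _PREC_MUL, _PREC_ATOM = 1, 2, 3


def _features_of(node: Node) -> tuple[str, ...]:
    return tuple(sorted({n.feature for n in node.walk() if n.is_leaf}))


def _flatten(node: Node, op_name: str) -> list[Node]:
    if not node.is_leaf and node.op.name == op_name:
        out: list[Node] = []
        for c in node.children:
            out.extend(_flatten(c, op_name))
        return out
    return [node]


def node_to_string(node: Node) -> str:
    text, _ = _render(node)
    return text


def _render(node: Node) -> tuple[str, int]:
    if node.is_leaf:
        return node.feature, _PREC_ATOM
    name = node.op.name
    if name in ("add", "multiply"):
        terms = _flatten(node, name)
        rendered = sorted(
            ((_features_of(t),) + _render(t) for t in terms),
            key=lambda r: (r[0], r[1]),
        )
        if name == "add":
            return " + ".join(r[1] for r in rendered), _PREC_ADD
        parts = [r[1] if r[2] > _PREC_ADD else f"({r[1]})" for r in rendered]
        return "*".join(parts), _PREC_MUL
    if name == "linear":
        return _render(node.children[0])
    child_texts = []
    for c in node.children:
        t, p = _render(c)
        child_texts.append((_features_of(c), t if p >= _PREC_ATOM else f"({t})"))
    if name == "tanh":
        return f"tanh({node_to_string(node.children[0])})", _PREC_ATOM
    if name == "exp":
        return f"exp({node_to_string(node.children[0])})", _PREC_ATOM
    if name == "inverse":
        return f"1/{child_texts[0][1]}", _PREC_MUL
    if name == "gaussian1":
        return f"exp(-{child_texts[0][1]})", _PREC_ATOM
    if name == "gaussian2":
        a, b = sorted(child_texts)
        return f"exp(-{a[1]} - {b[1]})", _PREC_ATOM
    raise ValidationError(f"unknown operator {name!r}")  # pragma: no cover


def _render_params(node: Node, by_node: Mapping[int, np.ndarray]) -> tuple[str, int]:
    p = by_node[id(node)]
    if node.is_leaf:
        return f"({p[0]:.6g}*{node.feature} + {p[1]:.6g})", _PREC_ATOM
    name = node.op.name
    kids = [_render_params(c, by_node)[0] for c in node.children]
    if name == "add":
        return f"({kids[0]} + {kids[1]} + {p[0]:.6g})", _PREC_ATOM
    if name == "multiply":
        return f"({kids[0]}*{kids[1]} + {p[0]:.6g})", _PREC_ATOM
    if name == "tanh":
        return f"({p[0]:.6g}*tanh({kids[0]}) + {p[1]:.6g})", _PREC_ATOM
    if name == "exp":
        return f"({p[0]:.6g}*exp({kids[0]}) + {p[1]:.6g})", _PREC_ATOM
    if name == "inverse":
        return f"({p[0]:.6g}/{kids[0]} + {p[1]:.6g})", _PREC_ATOM
    if name == "linear":
        return f"({p[0]:.6g}*{kids[0]} + {p[1]:.6g})", _PREC_ATOM
    if name == "gaussian1":
        return f"({p[0]:.6g}*exp(-{kids[0]}^2) + {p[1]:.6g})", _PREC_ATOM
    if name == "gaussian2":
        return (
            f"({p[0]:.6g}*exp(-{kids[0]}^2 - {kids[1]}^2) + {p[1]:.6g})",
            _PREC_ATOM,
        )
    raise ValidationError(f"unknown operator {name!r}")  # pragma: no cover


def _signature(node: Node):
    if node.is_leaf:
        return ("f", node.feature)
    name = node.op.name
    if name in ("add", "multiply"):
        terms = _flatten(node, name)
        return (name,) + tuple(sorted((_signature(t) for t in terms), key=repr))
    if name == "gaussian2":
        return ("gaussian2",) + tuple(
            sorted((_signature(c) for c in node.children), key=repr)
        )
    return (name, _signature(node.children[0]))


def canonical_signature(tree: ExpressionTree):
    """Signature shared by trees equal up to commutative reordering."""
    return tree.signature()


def count_parameters(tree: ExpressionTree) -> int:
    """Number of learnable parameters; the ``k`` entering BIC/AIC penalties."""
    return tree.n_params


def default_parameters(tree: ExpressionTree) -> np.ndarray:
    """Identity-style initial parameters: weights 1, offsets 0, sigmas 1."""
    out = np.empty(tree.n_params, dtype=float)
    for i, node in enumerate(tree._nodes):
        s = tree.param_slice(i)
        if node.is_leaf:
            out[s] = (1.0, 0.0)
            continue
        name = node.op.name
        if name in ("add", "multiply"):
            out[s] = (0.0,)
        else:  # unary and gaussian2: output scale 1, offset 0
            out[s] = (1.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# evaluation: vectorised forward pass and reverse-mode gradient


def forward(
    tree: ExpressionTree, parameters: np.ndarray, columns: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Evaluate the raw (pre-logistic) value and all node activations.

    Returns ``(f, activations)`` where ``activations[i]`` is the output of the
    i-th preorder node over all samples.
    """
    nodes, child_idx, slices = tree._nodes, tree._child_idx, tree._slices
    n_nodes = len(nodes)
    acts: list[np.ndarray] = [None] * n_nodes  # type: ignore[list-item]
    for i in range(n_nodes - 1, -1, -1):
        node = nodes[i]
        p = parameters[slices[i]]
        if node.is_leaf:
            x = columns[node.feature]
            acts[i] = p[0] * x + p[1]
            continue
        kids = [acts[j] for j in child_idx[i]]
        name = node.op.name
        if name == "add":
            acts[i] = kids[0] + kids[1] + p[0]
        elif name == "multiply":
            acts[i] = kids[0] * kids[1] + p[0]
        elif name == "tanh":
            acts[i] = p[0] * np.tanh(kids[0]) + p[1]
        elif name == "exp":
            acts[i] = p[0] * np.exp(np.minimum(kids[0], _EXP_CLIP)) + p[1]
        elif name == "inverse":
            d = kids[0]
            d = np.where(
                np.abs(d) < _INV_FLOOR, np.where(d < 0, -_INV_FLOOR, _INV_FLOOR), d
            )
            acts[i] = p[0] / d + p[1]
        elif name == "linear":
            acts[i] = p[0] * kids[0] + p[1]
        elif name == "gaussian1":
            u = kids[0]
            acts[i] = p[0] * np.exp(-np.minimum(u * u, _EXP_CLIP)) + p[1]
        elif name == "gaussian2":
            u, v = kids
            acts[i] = p[0] * np.exp(-np.minimum(u * u + v * v, _EXP_CLIP)) + p[1]
        else:  # pragma: no cover
            raise ValidationError(f"unknown operator {name!r}")
    return acts[0], acts


def backward(
    tree: ExpressionTree,
    parameters: np.ndarray,
    columns: Mapping[str, np.ndarray],
    acts: list[np.ndarray],
    df: np.ndarray,
) -> np.ndarray:
    """Reverse-mode gradient of a scalar loss w.r.t. all parameters.

    ``df`` is dLoss/df per sample at the root.  Numerical guards (exp clip,
    inverse floor, sigma floor) propagate zero gradient where they are active,
    matching the forward pass.
    """
    nodes, child_idx, slices = tree._nodes, tree._child_idx, tree._slices
    grad = np.zeros_like(parameters)
    bars: list[np.ndarray] = [None] * len(nodes)  # type: ignore[list-item]
    bars[0] = df
    for i, node in enumerate(nodes):
        g = bars[i]
        p = parameters[slices[i]]
        gs = grad[slices[i]]
        if node.is_leaf:
            x = columns[node.feature]
            gs[0] += float(np.dot(g, x))
            gs[1] += float(np.sum(g))
            continue
        kids = [acts[j] for j in child_idx[i]]
        name = node.op.name
        if name == "add":
            gs[0] += float(np.sum(g))
            pushes = [g, g]
        elif name == "multiply":
            gs[0] += float(np.sum(g))
            pushes = [g * kids[1], g * kids[0]]
        elif name == "tanh":
            t = np.tanh(kids[0])
            gs[0] += float(np.dot(g, t))
            gs[1] += float(np.sum(g))
            pushes = [g * p[0] * (1.0 - t * t)]
        elif name == "exp":
            u = kids[0]
            e = np.exp(np.minimum(u, _EXP_CLIP))
            gs[0] += float(np.dot(g, e))
            gs[1] += float(np.sum(g))
            pushes = [g * p[0] * e * (u < _EXP_CLIP)]
        elif name == "inverse":
            d = kids[0]
            mask = np.abs(d) >= _INV_FLOOR
            df = np.where(
                np.abs(d) < _INV_FLOOR, np.where(d < 0, -_INV_FLOOR, _INV_FLOOR), d
            )
            r = 1.0 / df
            gs[0] += float(np.dot(g, r))
            gs[1] += float(np.sum(g))
            pushes = [-g * p[0] * r * r * mask]
        elif name == "linear":
            gs[0] += float(np.dot(g, kids[0]))
            gs[1] += float(np.sum(g))
            pushes = [g * p[0]]
        elif name == "gaussian1":
            u = kids[0]
            q = u * u
            e = np.exp(-np.minimum(q, _EXP_CLIP))
            gs[0] += float(np.dot(g, e))
            gs[1] += float(np.sum(g))
            pushes = [g * p[0] * e * (-2.0 * u) * (q < _EXP_CLIP)]
        elif name == "gaussian2":
            u, v = kids
            q = u * u + v * v
            e = np.exp(-np.minimum(q, _EXP_CLIP))
            live = q < _EXP_CLIP
            gs[0] += float(np.dot(g, e))
            gs[1] += float(np.sum(g))
            pushes = [g * p[0] * e * (-2.0 * u) * live, g * p[0] * e * (-2.0 * v) * live]
        else:  # pragma: no cover
            raise ValidationError(f"unknown operator {name!r}")
        for j, push in zip(child_idx[i], pushes):
            bars[j] = push if bars[j] is None else bars[j] + push
    return grad


def extract_columns(samples, features: Sequence[str]) -> dict[str, np.ndarray]:
    """Pull named numeric columns out of a Dataset, DataFrame or mapping."""
    frame = getattr(samples, "frame", samples)
    out: dict[str, np.ndarray] = {}
    for f in features:
        if hasattr(frame, "columns"):
            if f not in frame.columns:
                raise ValidationError(f"missing feature column {f!r}")
            col = np.asarray(frame[f], dtype=float)
        else:
            if f not in frame:
                raise ValidationError(f"missing feature column {f!r}")
            col = np.asarray(frame[f], dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValidationError(f"non-finite values in feature column {f!r}")
        out[f] = col
    return out


# ---------------------------------------------------------------------------
# fitted models


@dataclass
class FittedModel:
    """An expression tree with fitted parameters and selection scores.

    ``train_loss`` is the mean negative log-likelihood (classification) or
    mean squared error (regression); BIC/AIC follow ``2*n*loss + penalty``.
    """

    tree: ExpressionTree
    parameters: np.ndarray
    train_loss: float
    bic: float
    aic: float
    n_samples: int
    task: str = "classification"

    def __post_init__(self):
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.parameters.shape != (self.tree.n_params,):
            raise ValidationError(
                f"parameter vector length {self.parameters.size} does not match "
                f"tree parameter count {self.tree.n_params}"
            )
        if not np.all(np.isfinite(self.parameters)):
            raise ValidationError("fitted parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.tree.n_params

    @property
    def feature_set(self) -> tuple[str, ...]:
        return self.tree.feature_set

    def signature(self):
        return self.tree.signature()

    def predict(self, samples) -> np.ndarray:
        return evaluate(self, samples)

    def to_string(self, show_params: bool = False) -> str:
        return self.tree.to_string(self.parameters if show_params else None)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "expression": self.to_string(),
            "tree": self.tree.to_dict(),
            "task": self.task,
            "parameters": [float(v) for v in self.parameters],
            "parameters_hex": [float(v).hex() for v in self.parameters],
            "n_params": int(self.n_params),
            "train_loss": float(self.train_loss),
            "bic": float(self.bic),
            "aic": float(self.aic),
            "n_samples": int(self.n_samples),
            "features": list(self.feature_set),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedModel":
        tree = ExpressionTree.from_dict(doc["tree"])
        hexes = doc.get("parameters_hex")
        if hexes is not None:
            params = np.array([float.fromhex(h) for h in hexes])
        else:
            params = np.array(doc["parameters"], dtype=float)
        if params.size != tree.n_params:
            raise ValidationError(
                f"model document carries {params.size} parameters but the tree "
                f"needs {tree.n_params}"
            )
        model = cls(
            tree=tree,
            parameters=params,
            train_loss=float(doc["train_loss"]),
            bic=float(doc["bic"]),
            aic=float(doc["aic"]),
            n_samples=int(doc["n_samples"]),
            task=doc.get("task", "classification"),
        )
        return model


def evaluate(model: FittedModel, samples) -> np.ndarray:
    """Per-sample predictions: probabilities in (0, 1) for classification."""
    cols = extract_columns(samples, model.tree.feature_set)
    f, _ = forward(model.tree, model.parameters, cols)
    if model.task == "classification":
        return np.clip(expit(f), _PROB_EPS, 1.0 - _PROB_EPS)
    return f


# ---------------------------------------------------------------------------
# parsing of printed model forms


_TOKEN_RE = re.compile(
    r"""(?P<ws>\s+)
      | (?P<name>[A-Za-z_][A-Za-z0-9_.]*(?:-[0-9][A-Za-z0-9_.]*)*)
      | (?P<num>\d+(?:\.\d+)?)
      | (?P<sym>[-+*/()−])
    """,
    re.X,
)

_FUNCS = {"tanh", "exp", "logreg"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            value = m.group()
            if value == "−":
                value = "-"
            tokens.append((m.lastgroup, value, pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser for the printed model grammar.

    Grammar: feature tokens, ``+``, ``*``, unary function application,
    ``1/x``, an optional outer ``logreg(...)`` wrapper, and minus signs only
    inside ``exp(...)`` where ``exp(-a)`` / ``exp(-a - b)`` denote the one- and
    two-dimensional gaussian peaks.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val, pos = self.next()
        if val != value:
            raise ParseError(f"expected {value!r}, found {val or 'end of input'!r}", pos)

    def parse(self) -> Node:
        kind, val, pos = self.peek()
        wrapped = False
        if kind == "name" and val == "logreg":
            self.next()
            self.expect("(")
            wrapped = True
        node = self.sum()
        if wrapped:
            self.expect(")")
        kind, val, pos = self.peek()
        if kind != "eof":
            raise ParseError(f"unexpected trailing input {val!r}", pos)
        return node

    def sum(self) -> Node:
        node = self.product()
        while self.peek()[1] == "+":
            self.next()
            rhs = self.product()
            node = Node(op="add", children=[node, rhs])
        return node

    def product(self) -> Node:
        node = self.atom()
        while self.peek()[1] == "*":
            self.next()
            rhs = self.atom()
            node = Node(op="multiply", children=[node, rhs])
        return node

    def atom(self) -> Node:
        kind, val, pos = self.next()
        if kind == "name":
            if val in _FUNCS:
                if val == "logreg":
                    raise ParseError("logreg is only allowed as the outer wrapper", pos)
                self.expect("(")
                if val == "exp" and self.peek()[1] == "-":
                    node = self._gaussian()
                elif val == "exp":
                    node = Node(op="exp", children=[self.sum()])
                else:
                    node = Node(op=val, children=[self.sum()])
                self.expect(")")
                return node
            if self.peek()[1] == "(":
                raise ParseError(f"unknown function {val!r}", pos)
            return Node(feature=val)
        if kind == "num":
            if val != "1":
                raise ParseError("numeric literals other than 1/x are not allowed", pos)
            self.expect("/")
            return Node(op="inverse", children=[self.atom()])
        if val == "(":
            node = self.sum()
            self.expect(")")
            return node
        raise ParseError(f"unexpected token {val or 'end of input'!r}", pos)

    def _gaussian(self) -> Node:
        self.expect("-")
        first = self.product()
        if self.peek()[1] == "-":
            self.next()
            second = self.product()
            return Node(op="gaussian2", children=[first, second])
        return Node(op="gaussian1", children=[first])


def parse_model_string(text: str, task: str = "classification") -> ExpressionTree:
    """Parse a printed model form such as ``logreg(MAPT*(AJAP1 + SERPINE2.1))``.

    Round-trips with :meth:`ExpressionTree.to_string` up to whitespace and
    commutative-argument ordering.  Parameters are not part of the grammar;
    use :func:`default_parameters` for identity defaults.
    """
    return ExpressionTree(_Parser(text).parse(), task=task)
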