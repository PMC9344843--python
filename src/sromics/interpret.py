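"""Model-interpretation machinery.

Everything here turns a fitted expression tree plus data into plain data
structures: mutual-information signal flow along the tree, partial-dependence
curves at fixed covariates, 2D decision boundaries, and class-conditional
density overlaps.  Plotting is a separate thin layer (:mod:`sromics.plots`).

The mutual-information estimator is a plug-in estimate on an equal-frequency
(quantile) binned joint histogram, natural log, 10 bins per axis by default.
Quantile bins are robust to the heavy-tailed magnitudes of raw omics features;
vectors with few distinct values (e.g. a 0/1 target) use their exact values as
bins, so MI of a discrete variable with itself equals its entropy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ValidationError
from .expr_core import FittedModel, extract_columns, forward, node_to_string

__all__ = [
    "mutual_information",
    "signal_flow",
    "partial_dependence",
    "decision_boundary_2d",
    "class_density_summary",
    "feature_correlations",
    "SignalFlow",
    "SignalNode",
    "PartialDependenceCurve",
    "DecisionBoundary",
    "DensityOverlap",
]


# ---------------------------------------------------------------------------
# mutual information


def _discretize(v: np.ndarray, n_bins: int) -> tuple[np.ndarray, int]:
    unique = np.unique(v)
    if unique.size == 1:
        return np.zeros(v.size, dtype=np.intp), 1
    if unique.size <= n_bins:
        return np.searchsorted(unique, v), unique.size
    edges = np.quantile(v, np.linspace(0.0, 1.0, n_bins + 1))
    interior = np.unique(edges)[1:-1]
    return np.searchsorted(interior, v, side="right"), interior.size + 1


def mutual_information(x, y, n_bins: int = 10) -> float:
    """Binned mutual information between two numeric vectors, in nats.

    Non-negative and symmetric; a constant vector gives 0 by convention.
    Equal-frequency binning makes the estimate invariant to strictly monotone
    transforms of either argument (up to ties created by binning).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("mutual_information requires equal-length vectors")
    if x.size < 2:
        raise ValidationError("mutual_information requires at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("mutual_information requires finite inputs")
    cx, nx = _discretize(x, n_bins)
    cy, ny = _discretize(y, n_bins)
    if nx == 1 or ny == 1:
        return 0.0
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    p = joint / x.size
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# signal flow


@dataclass
class SignalNode:
    index: int
    label: str
    mutual_information: float
    is_root: bool
    is_leaf: bool


@dataclass
class SignalFlow:
    nodes: list[SignalNode]

    @property
    def model_mi(self) -> float:
        """The root node's MI with the target: the model's overall signal."""
        return next(n.mutual_information for n in self.nodes if n.is_root)

    def to_records(self) -> list[dict]:
        return [
            {
                "node": n.index,
                "label": n.label,
                "mutual_information": n.mutual_information,
                "is_root": n.is_root,
                "is_leaf": n.is_leaf,
            }
            for n in self.nodes
        ]


def signal_flow(model: FittedModel, data, n_bins: int = 10) -> SignalFlow:
    """Mutual information between every node's activation and the target.

    The per-node numbers show where predictive signal accumulates as leaf
    features are combined on the way to the root.
    """
    cols = extract_columns(data, model.tree.feature_set)
    y = np.asarray(data.y, dtype=float)
    _, acts = forward(model.tree, model.parameters, cols)
    records = []
    for i, node in enumerate(model.tree._nodes):
        label = node.feature if node.is_leaf else node_to_string(node)
        mi = mutual_information(acts[i], y, n_bins=n_bins)
        records.append(
            SignalNode(
                index=i,
                label=label,
                mutual_information=mi,
                is_root=(i == 0),
                is_leaf=node.is_leaf,
            )
        )
    return SignalFlow(records)


# ---------------------------------------------------------------------------
# partial dependence and decision boundaries


@dataclass
class PartialDependenceCurve:
    varied: str
    grid: np.ndarray
    fixed: dict[str, float]
    predictions: np.ndarray
    threshold_crossing: float | None  # smallest grid value with prediction > 0.5


def _fixed_assignment(model: FittedModel, data, exclude: set[str], fixed) -> dict:
    features = [f for f in model.feature_set if f not in exclude]
    if fixed is None:
        if data is None:
            raise ValidationError("either data or a full fixed assignment is required")
        fixed = {f: float(np.median(data.column(f))) for f in features}
    missing = [f for f in features if f not in fixed]
    if missing:
        raise ValidationError(f"fixed assignment missing features: {', '.join(missing)}")
    return {f: float(fixed[f]) for f in features}


def partial_dependence(
    model: FittedModel,
    varied: str,
    fixed: dict[str, float] | None = None,
    grid_size: int = 100,
    data=None,
    grid_range: tuple[float, float] | None = None,
) -> PartialDependenceCurve:
    """Exact model output along one feature with all others held fixed.

    ``fixed`` must cover every model feature except ``varied``; when omitted,
    the medians of ``data`` are used.  The grid spans the observed range of
    ``varied`` in ``data`` unless ``grid_range`` overrides it.
    """
    if varied not in model.feature_set:
        raise ValidationError(f"{varied!r} is not a feature of the model")
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    fixed = _fixed_assignment(model, data, {varied}, fixed)
    if grid_range is None:
        if data is None:
            raise ValidationError("either data or grid_range is required")
        col = data.column(varied)
        grid_range = (float(np.min(col)), float(np.max(col)))
    grid = np.linspace(grid_range[0], grid_range[1], grid_size)
    columns = {varied: grid}
    for f, v in fixed.items():
        columns[f] = np.full(grid_size, v)
    preds = model.predict(columns)
    above = np.nonzero(preds > 0.5)[0]
    crossing = float(grid[above[0]]) if above.size else None
    return PartialDependenceCurve(
        varied=varied,
        grid=grid,
        fixed=fixed,
        predictions=preds,
        threshold_crossing=crossing,
    )


@dataclass
class DecisionBoundary:
    feature_x: str
    feature_y: str
    xs: np.ndarray  # shape (nx,)
    ys: np.ndarray  # shape (ny,)
    predictions: np.ndarray  # shape (ny, nx)
    fixed: dict[str, float]
    boundary_cells: list[tuple[int, int]]  # (ix, iy) cells crossed by the 0.5 level


def decision_boundary_2d(
    model: FittedModel,
    feature_x: str,
    feature_y: str,
    fixed: dict[str, float] | None = None,
    grid: tuple[int, int] = (50, 50),
    data=None,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> DecisionBoundary:
    """Exact model output over a 2D grid plus the cells crossed by p = 0.5."""
    if feature_x == feature_y:
        raise ValidationError("feature_x and feature_y must differ")
    for f in (feature_x, feature_y):
        if f not in model.feature_set:
            raise ValidationError(f"{f!r} is not a feature of the model")
    fixed = _fixed_assignment(model, data, {feature_x, feature_y}, fixed)
    if x_range is None or y_range is None:
        if data is None:
            raise ValidationError("either data or explicit ranges are required")
        cx, cy = data.column(feature_x), data.column(feature_y)
        x_range = x_range or (float(np.min(cx)), float(np.max(cx)))
        y_range = y_range or (float(np.min(cy)), float(np.max(cy)))
    nx, ny = grid
    xs = np.linspace(x_range[0], x_range[1], nx)
    ys = np.linspace(y_range[0], y_range[1], ny)
    gx, gy = np.meshgrid(xs, ys)
    columns = {feature_x: gx.ravel(), feature_y: gy.ravel()}
    for f, v in fixed.items():
        columns[f] = np.full(gx.size, v)
    preds = model.predict(columns).reshape(ny, nx)
    cells: list[tuple[int, int]] = []
    side = preds > 0.5
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            corners = side[iy : iy + 2, ix : ix + 2]
            if corners.any() and not corners.all():
                cells.append((ix, iy))
    return DecisionBoundary(
        feature_x=feature_x,
        feature_y=feature_y,
        xs=xs,
        ys=ys,
        predictions=preds,
        fixed=fixed,
        boundary_cells=cells,
    )


def quantile_assignments(data, features, quantiles=(0.25, 0.5, 0.75)) -> list[dict]:
    """Fixed-covariate assignments at training-data quantiles.

    The 0.25/0.50/0.75 convention is the standard way to show how a boundary
    moves as a held-out covariate varies.
    """
    out = []
    for q in quantiles:
        out.append({f: float(np.quantile(data.column(f), q)) for f in features})
    return out


# ---------------------------------------------------------------------------
# class-conditional densities


@dataclass
class DensityOverlap:
    grid: np.ndarray
    density_0: np.ndarray
    density_1: np.ndarray
    overlap: float  # integral of min(f0, f1), in [0, 1]


def class_density_summary(values, labels, n_points: int = 256) -> DensityOverlap:
    """Smoothed class-conditional densities and their overlap coefficient.

    Gaussian kernel density with Silverman's bandwidth on each class; the
    overlap coefficient is the trapezoid integral of the pointwise minimum.
    Identical class distributions give overlap near 1, disjoint supports near 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if values.size != labels.size:
        raise ValidationError("values and labels must have equal length")
    v0 = values[labels == 0]
    v1 = values[labels == 1]
    if v0.size < 2 or v1.size < 2:
        raise ValidationError("both classes need at least 2 members")
    k0 = gaussian_kde(v0, bw_method="silverman")
    k1 = gaussian_kde(v1, bw_method="silverman")
    pad = 3.0 * max(np.sqrt(k0.covariance[0, 0]), np.sqrt(k1.covariance[0, 0]))
    lo = min(v0.min(), v1.min()) - pad
    hi = max(v0.max(), v1.max()) + pad
    grid = np.linspace(lo, hi, n_points)
    f0 = k0(grid)
    f1 = k1(grid)
    overlap = float(np.trapezoid(np.minimum(f0, f1), grid))
    return DensityOverlap(grid=grid, density_0=f0, density_1=f1, overlap=overlap)


def feature_correlations(data, features=None):
    """Absolute pairwise Pearson correlations among features (utility)."""
    features = list(features) if features is not None else data.feature_names
    return data.frame[features].corr().abs()
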