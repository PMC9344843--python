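"""Optional thin plotting layer over the interpretation data structures.

Every function takes the already-computed data object and writes/returns a
matplotlib figure; no statistics are computed here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .interpret import (
    DecisionBoundary,
    DensityOverlap,
    PartialDependenceCurve,
    SignalFlow,
)

__all__ = [
    "plot_signal_flow",
    "plot_partial_dependence",
    "plot_decision_boundary",
    "plot_class_densities",
]


def plot_signal_flow(flow: SignalFlow, path=None):
    records = flow.to_records()
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(records) + 1))
    labels = [r["label"] for r in records]
    mis = [r["mutual_information"] for r in records]
    ax.barh(range(len(records)), mis, color="seagreen")
    ax.set_yticks(range(len(records)), labels)
    ax.invert_yaxis()
    ax.set_xlabel("mutual information with target (nats)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_partial_dependence(curves: list[PartialDependenceCurve] | PartialDependenceCurve, path=None):
    if isinstance(curves, PartialDependenceCurve):
        curves = [curves]
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        fixed = ", ".join(f"{k}={v:.3g}" for k, v in c.fixed.items())
        ax.plot(c.grid, c.predictions, label=fixed or "model")
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel(curves[0].varied)
    ax.set_ylabel("predicted probability")
    if any(c.fixed for c in curves):
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_decision_boundary(db: DecisionBoundary, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(db.xs, db.ys, db.predictions, shading="auto", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="predicted probability")
    ax.contour(db.xs, db.ys, db.predictions, levels=[0.5], colors="white")
    ax.set_xlabel(db.feature_x)
    ax.set_ylabel(db.feature_y)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_class_densities(d: DensityOverlap, path=None, label: str = "value"):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(d.grid, d.density_0, alpha=0.5, label="class 0")
    ax.fill_between(d.grid, d.density_1, alpha=0.5, label="class 1")
    ax.set_xlabel(label)
    ax.set_ylabel("density")
    ax.set_title(f"overlap = {d.overlap:.3f}")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
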