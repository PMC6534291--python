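"""Diagnostic plots: persistence diagrams and barcodes (presentation only)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .persistence import PersistenceDiagram


def plot_diagram(diagrams: list[PersistenceDiagram], path=None, ax=None):
    """Scatter of (birth, death) pairs, one marker set per dimension."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lo = min((d.births.min() for d in diagrams if len(d)), default=0.0)
    hi = max((d.deaths.max() for d in diagrams if len(d)), default=1.0)
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    for dgm, marker in zip(diagrams, "o^sv"):
        if len(dgm):
            ax.scatter(dgm.births, dgm.deaths, s=8, marker=marker, label=f"dim {dgm.dimension}")
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_barcode(diagram: PersistenceDiagram, path=None, ax=None):
    """Horizontal bars from birth to death, sorted by birth."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, (b, d) in enumerate(diagram.pairs):
        ax.hlines(i, b, d, lw=1.5)
    ax.set_xlabel("filtration value")
    ax.set_ylabel(f"dim-{diagram.dimension} feature")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
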