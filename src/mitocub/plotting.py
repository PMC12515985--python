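"""Simple matplotlib charts for the three diagnostic plots."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .nucdiv import PiWindow
from .selection import NeutralityFit, PR2Point


def plot_pr2(points: Sequence[PR2Point], path: str) -> None:
    """PR2 plane with the neutral centre cross at (0.5, 0.5)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.scatter([p.x for p in points], [p.y for p in points], s=18)
    for p in points:
        ax.annotate(p.label, (p.x, p.y), fontsize=6, alpha=0.7)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_neutrality(
    points: Sequence[tuple[float, float]], fit: NeutralityFit, path: str
) -> None:
    """GC12 vs GC3 scatter with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p[0] for p in points]
    ax.scatter(xs, [p[1] for p in points], s=18)
    lo, hi = min(xs), max(xs)
    ax.plot(
        [lo, hi],
        [fit.intercept + fit.slope * lo, fit.intercept + fit.slope * hi],
        color="firebrick",
        label=f"slope {fit.slope:.3f}, r {fit.pearson_r:.3f}",
    )
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_sliding_pi(windows: Iterable[PiWindow], path: str) -> None:
    """Windowed nucleotide diversity along the alignment (x = window start)."""
    windows = list(windows)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot([w.start for w in windows], [w.pi for w in windows], lw=1)
    ax.set_xlabel("alignment position (window start)")
    ax.set_ylabel("pi")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
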