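"""Mutation-pressure vs. natural-selection analyses of codon usage.

Two classic diagnostics:

* **PR2 bias plot** — for each gene, plot A3/(A3+T3) against G3/(G3+C3)
  over third codon positions.  Under parity rule 2 (no strand-specific
  mutation or selection bias) both coordinates sit at 0.5; displacement
  and its quadrant indicate which bases are favoured.

* **Neutrality plot** — regress GC12 (mean GC at codon positions 1 and 2)
  on GC3 across genes or species.  Mutation pressure acts on all three
  positions alike, so a slope near 1 with a significant Pearson
  correlation indicates mutation pressure dominates; a slope near 0, or a
  non-significant correlation, indicates selection constrains positions
  1+2 independently of 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .composition import PositionalComposition
from .errors import InsufficientDataError, UndefinedStatisticError


@dataclass(frozen=True)
class PR2Point:
    """One gene's coordinates in the PR2 plane."""

    label: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)

    @property
    def quadrant(self) -> Optional[int]:
        """Cartesian quadrant about (0.5, 0.5); None on a boundary.

        I: x>0.5, y>0.5;  II: x<0.5, y>0.5;  III: x<0.5, y<0.5;
        IV: x>0.5, y<0.5.
        """
        if self.x == 0.5 or self.y == 0.5:
            return None
        if self.x > 0.5:
            return 1 if self.y > 0.5 else 4
        return 2 if self.y > 0.5 else 3


def pr2_point(pc: PositionalComposition, label: str = "") -> PR2Point:
    """PR2 coordinates from third-position counts over all sense codons."""
    gc3 = pc.g3 + pc.c3
    at3 = pc.a3 + pc.t3
    if gc3 == 0:
        raise UndefinedStatisticError(f"{label}: G3+C3 is zero, x undefined")
    if at3 == 0:
        raise UndefinedStatisticError(f"{label}: A3+T3 is zero, y undefined")
    return PR2Point(label=label, x=pc.g3 / gc3, y=pc.a3 / at3)


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with Pearson correlation.

    ``classification`` applies the standard decision rule at alpha and a
    slope cut of 0.5 (see :func:`classify_forces`).
    """

    n: int
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    stderr: float
    alpha: float = 0.05
    slope_cut: float = 0.5

    @property
    def classification(self) -> str:
        return classify_forces(self, self.alpha, self.slope_cut)

    def summary(self) -> str:
        lines = [
            "Neutrality plot: GC12 ~ GC3 (ordinary least squares)",
            f"  n points        {self.n}",
            f"  slope           {self.slope: .4f}  (SE {self.stderr:.4f})",
            f"  intercept       {self.intercept: .4f}",
            f"  Pearson r       {self.pearson_r: .4f}",
            f"  p (two-sided)   {self.p_value: .4g}"
            + ("  **" if self.p_value < 0.01 else "  *" if self.p_value < 0.05 else ""),
            f"  classification  {self.classification}",
        ]
        return "\n".join(lines)


def neutrality_fit(
    points: Sequence[tuple[float, float]],
    alpha: float = 0.05,
    slope_cut: float = 0.5,
) -> NeutralityFit:
    """Fit GC12 on GC3 by OLS; Pearson p from the exact t-transform (n-2 df).

    ``points`` is a sequence of (gc3, gc12) pairs, one per gene or species.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InsufficientDataError(
            f"neutrality fit needs >= 3 (gc3, gc12) points, got {len(pts)}"
        )
    gc3, gc12 = pts[:, 0], pts[:, 1]
    if np.ptp(gc3) == 0:
        raise InsufficientDataError("all GC3 values equal: degenerate fit")
    if np.ptp(gc12) == 0:
        # constant response: flat line, zero correlation (r is 0/0 otherwise)
        return NeutralityFit(
            n=len(pts), slope=0.0, intercept=float(gc12[0]), pearson_r=0.0,
            p_value=1.0, stderr=0.0, alpha=alpha, slope_cut=slope_cut,
        )
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        n=len(pts),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        alpha=alpha,
        slope_cut=slope_cut,
    )


def classify_forces(
    fit: NeutralityFit, alpha: float = 0.05, slope_cut: float = 0.5
) -> str:
    """Classify the dominant force shaping codon usage.

    * correlation not significant (p >= alpha) -> ``selection_dominant``
      (GC3 tells us nothing about GC12; selection constrains 1+2);
    * significant and slope >= slope_cut -> ``mutation_dominant``;
    * significant but slope < slope_cut -> ``co_dominant``.
    """
    if fit.p_value >= alpha:
        return "selection_dominant"
    if fit.slope >= slope_cut:
        return "mutation_dominant"
    return "co_dominant"
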