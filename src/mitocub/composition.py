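"""Base composition, AT/GC content, strand skews and codon-position composition.

Skews follow the standard conventions

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the deposited (H) strand as-is.  N bases are excluded from both
numerator and denominator of every statistic; a skew whose denominator is
zero is reported as undefined (``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import EmptySelectionError, MitocubError
from .io import CodingSeq, GenomeRecord, concat_gene_set


@dataclass(frozen=True)
class BaseComposition:
    """A/C/G/T counts with derived content and skew statistics."""

    a: int
    c: int
    g: int
    t: int
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.total

    @property
    def at_skew(self) -> Optional[float]:
        at = self.a + self.t
        return (self.a - self.t) / at if at else None

    @property
    def gc_skew(self) -> Optional[float]:
        gc = self.g + self.c
        return (self.g - self.c) / gc if gc else None

    def __add__(self, other: "BaseComposition") -> "BaseComposition":
        return BaseComposition(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.n_excluded + other.n_excluded,
        )


def base_composition(seq: str) -> BaseComposition:
    """Count bases of a sequence; everything outside A/C/G/T is excluded."""
    if not seq:
        raise MitocubError("empty sequence")
    a, c, g, t = seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T")
    comp = BaseComposition(a, c, g, t, n_excluded=len(seq) - (a + c + g + t))
    if comp.total == 0:
        raise MitocubError("sequence contains no A/C/G/T bases")
    return comp


@dataclass(frozen=True)
class PositionalComposition:
    """Base counts split by codon position (1, 2, 3).

    The third-position entries are the A3/T3/C3/G3 of codon-usage work;
    GC12 is the arithmetic mean of GC1 and GC2.  All sense codons
    contribute (no restriction to synonymous families).
    """

    by_position: tuple[BaseComposition, BaseComposition, BaseComposition]

    @property
    def a3(self) -> int:
        return self.by_position[2].a

    @property
    def t3(self) -> int:
        return self.by_position[2].t

    @property
    def c3(self) -> int:
        return self.by_position[2].c

    @property
    def g3(self) -> int:
        return self.by_position[2].g

    def gc(self, position: int) -> float:
        """GC fraction at codon position 1, 2 or 3."""
        return self.by_position[position - 1].gc_content

    @property
    def gc1(self) -> float:
        return self.gc(1)

    @property
    def gc2(self) -> float:
        return self.gc(2)

    @property
    def gc3(self) -> float:
        return self.gc(3)

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def positional_composition(cds: CodingSeq) -> PositionalComposition:
    """Per-codon-position composition of a coding sequence.

    Computed over ``trimmed_nt`` only, so stop codons and incomplete stop
    tails never contribute.
    """
    t = cds.trimmed_nt
    if not t:
        raise MitocubError(f"{cds.gene}: no codons to analyse")
    comps = tuple(base_composition(t[p::3]) for p in range(3))
    return PositionalComposition(by_position=comps)  # type: ignore[arg-type]


_DATASETS = (("whole", None), ("PCGs", "PCG"), ("tRNAs", "tRNA"), ("rRNAs", "rRNA"))


def dataset_composition(genome: GenomeRecord) -> pd.DataFrame:
    """Composition table over the standard mitogenome datasets.

    One row per dataset in {whole, PCGs, tRNAs, rRNAs} with length, base
    percentages, AT content and both skews.  A missing category yields no
    row.  Overlapping genes are each counted in full, so dataset lengths
    may exceed the span of unique genome positions.
    """
    rows = []
    for name, category in _DATASETS:
        if category is None:
            seq = genome.sequence
        else:
            try:
                seq, _ = concat_gene_set(genome, category)
            except EmptySelectionError:
                import warnings

                warnings.warn(f"{genome.accession}: no {category} features; "
                              f"dataset {name!r} omitted")
                continue
        comp = base_composition(seq)
        rows.append(
            {
                "accession": genome.accession,
                "dataset": name,
                "length": len(seq),
                "A_pct": 100 * comp.a / comp.total,
                "T_pct": 100 * comp.t / comp.total,
                "G_pct": 100 * comp.g / comp.total,
                "C_pct": 100 * comp.c / comp.total,
                "AT_pct": 100 * comp.at_content,
                "AT_skew": comp.at_skew,
                "GC_skew": comp.gc_skew,
            }
        )
    return pd.DataFrame(rows)
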