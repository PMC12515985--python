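"""Codon counting, RSCU and the start/stop codon census.

RSCU (relative synonymous codon usage) of codon *c* in a synonymous family
of size *k* with family total *N* is

    RSCU(c) = count(c) / (N / k) = count(c) * k / N

so 1.0 means the codon is used exactly as often as expected under uniform
use within its family.  Following common practice for mitochondrial PCGs
the universe is the sense codons only (62 under the invertebrate
mitochondrial code, table 5); stop codons are censused separately, as are
start codons, which are otherwise counted at face value.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigError, MitocubError
from .io import CodingSeq

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in product("TCAG", repeat=3)
)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon→amino-acid map plus synonymous family structure."""

    id: int
    name: str
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            id=table_id,
            name=table.names[0],
            codon_to_aa=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> its synonymous codons (in fixed codon order)."""
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families()[self.codon_to_aa[codon]]


INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


@dataclass
class CodonCounts:
    """A 64-entry codon count table for one species or gene set."""

    label: str
    counts: Counter = field(default_factory=Counter)
    code: GeneticCode = INVERTEBRATE_MITO

    @property
    def n_sense(self) -> int:
        return sum(self.counts[c] for c in self.code.sense_codons)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        if other.code.id != self.code.id:
            raise MitocubError("cannot add counts under different codes")
        return CodonCounts(
            label=f"{self.label}+{other.label}",
            counts=self.counts + other.counts,
            code=self.code,
        )


@dataclass(frozen=True)
class RscuEntry:
    codon: str
    amino_acid: str
    count: int
    rscu: Optional[float]  # None when the whole family is unobserved
    bias_class: str  # overrepresented | underrepresented | unbiased | undefined


def count_codons(
    cds_list: Iterable[CodingSeq],
    code: GeneticCode = INVERTEBRATE_MITO,
    label: str = "",
) -> CodonCounts:
    """Count codons over the trimmed (stop-free, in-frame) sequences.

    Start codons are counted as their literal triplet; per-gene tables sum
    to per-species tables because counting is plain addition.
    """
    counts: Counter = Counter()
    for cds in cds_list:
        if len(cds.trimmed_nt) % 3:
            raise MitocubError(
                f"{cds.gene}: trimmed length {len(cds.trimmed_nt)} not a "
                "multiple of 3"
            )
        counts.update(cds.codons())
    return CodonCounts(label=label, counts=counts, code=code)


def compute_rscu(counts: CodonCounts) -> list[RscuEntry]:
    """RSCU for every sense codon of the table, in fixed codon order.

    A family with zero total observations yields ``rscu=None`` and class
    ``undefined`` for each member.
    """
    code = counts.code
    if counts.n_sense == 0:
        raise MitocubError(f"{counts.label or 'table'}: no sense codons counted")
    entries = []
    fams = code.families()
    totals = {aa: sum(counts.counts[c] for c in cs) for aa, cs in fams.items()}
    for codon in code.sense_codons:
        aa = code.codon_to_aa[codon]
        family = fams[aa]
        total = totals[aa]
        n = counts.counts[codon]
        if total == 0:
            entries.append(RscuEntry(codon, aa, n, None, "undefined"))
        else:
            entries.append(
                RscuEntry(codon, aa, n, n * len(family) / total, "unbiased")
            )
    return classify_rscu(entries)


def classify_rscu(
    entries: Sequence[RscuEntry], hi: float = 1.6, lo: float = 0.6
) -> list[RscuEntry]:
    """Attach bias classes: strictly > hi over-, strictly < lo under-represented.

    Values exactly at a threshold (and everything between) are unbiased.
    """
    if hi <= lo:
        raise ConfigError(f"hi ({hi}) must exceed lo ({lo})")
    if lo <= 0:
        raise ConfigError(f"lo must be positive, got {lo}")
    out = []
    for e in entries:
        if e.rscu is None:
            cls = "undefined"
        elif e.rscu > hi:
            cls = "overrepresented"
        elif e.rscu < lo:
            cls = "underrepresented"
        else:
            cls = "unbiased"
        out.append(RscuEntry(e.codon, e.amino_acid, e.count, e.rscu, cls))
    return out


def rscu_table(entries: Sequence[RscuEntry], label: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "codon": [e.codon for e in entries],
            "amino_acid": [e.amino_acid for e in entries],
            "count": [e.count for e in entries],
            "rscu": [math.nan if e.rscu is None else e.rscu for e in entries],
            "bias_class": [e.bias_class for e in entries],
        }
    )
    if label:
        df.insert(0, "label", label)
    return df


def mean_rscu(per_species: Sequence[Sequence[RscuEntry]]) -> pd.DataFrame:
    """Arithmetic mean of per-species RSCU vectors (codon-wise).

    This is the per-species-then-average pooling; it is NOT the RSCU of the
    summed count table (use ``compute_rscu(sum of counts)`` for that —
    both are legitimate summaries but they answer different questions and
    differ whenever species sizes differ).
    Undefined entries are dropped from a codon's average.
    """
    rows: dict[str, dict] = {}
    for entries in per_species:
        for e in entries:
            r = rows.setdefault(
                e.codon, {"amino_acid": e.amino_acid, "values": [], "counts": []}
            )
            if e.rscu is not None:
                r["values"].append(e.rscu)
            r["counts"].append(e.count)
    data = [
        {
            "codon": codon,
            "amino_acid": r["amino_acid"],
            "mean_count": sum(r["counts"]) / len(r["counts"]),
            "mean_rscu": (sum(r["values"]) / len(r["values"])) if r["values"] else math.nan,
            "n_species": len(r["values"]),
        }
        for codon, r in rows.items()
    ]
    return pd.DataFrame(data)


def start_stop_census(cds_list: Iterable[CodingSeq]) -> tuple[Counter, Counter]:
    """Frequency maps of start codons and stop kinds over a gene set.

    Stops are binned as TAA / TAG / "TA-" / "T-" (the latter two are
    incomplete stops completed by polyadenylation).
    """
    starts: Counter = Counter()
    stops: Counter = Counter()
    cds_list = list(cds_list)
    if not cds_list:
        raise MitocubError("empty coding-sequence list")
    for cds in cds_list:
        starts[cds.start_codon] += 1
        if cds.stop_kind == "complete":
            stops[cds.stop_codon] += 1
        elif cds.stop_kind == "incomplete_TA":
            stops["TA-"] += 1
        else:
            stops["T-"] += 1
    return starts, stops
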