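"""Nucleotide diversity (pi) over multi-species alignments.

pi is the mean, over all unordered pairs of rows, of the proportion of
compared sites at which the pair differs.  With *pairwise deletion* a
column enters a pair's comparison only when both rows carry a plain base
(A/C/G/T) there, so each pair has its own denominator; with *complete
deletion* only columns where every row carries a plain base are used.
Sliding windows (default 200 bp at 20 bp steps) localise diversity along a
concatenated gene alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParseError, UndefinedStatisticError
from .io import parse_fasta

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


@dataclass
class MultiAlignment:
    """An aligned sequence matrix with optional per-gene column partitions.

    ``partitions`` maps gene -> list of 0-based half-open column ranges.
    """

    taxa: list[str]
    rows: list[str]
    partitions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise InsufficientDataError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ParseError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(self.taxa) != len(self.rows):
            raise ParseError("taxa/rows length mismatch")
        bad = set("".join(self.rows)) - set(_CODE)
        if bad:
            raise ParseError(f"alignment symbols outside A/C/G/T/N/-: {sorted(bad)}")
        n = self.n_columns
        for gene, ranges in self.partitions.items():
            for s, e in ranges:
                if not (0 <= s < e <= n):
                    raise ParseError(f"partition {gene}: [{s}, {e}) out of bounds")

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 matrix; 0-3 bases, 4 N, 5 gap."""
        return np.array(
            [[_CODE[ch] for ch in row] for row in self.rows], dtype=np.uint8
        )


@dataclass(frozen=True)
class PiWindow:
    start: int
    end: int
    n_sites_used: int
    pi: float


def _pairwise_pi(mat: np.ndarray) -> tuple[float, int]:
    """(pi, usable columns) by pairwise deletion over a base-coded matrix."""
    valid = mat < 4  # A/C/G/T only
    n = mat.shape[0]
    ratios = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                continue  # pair contributes nothing rather than 0/0
            diffs = int((mat[i, both] != mat[j, both]).sum())
            ratios.append(diffs / compared)
    if not ratios:
        raise UndefinedStatisticError("no comparable pair at any column")
    # a column is "used" if at least one pair compares it
    pair_any = np.zeros(mat.shape[1], dtype=bool)
    for i in range(n - 1):
        for j in range(i + 1, n):
            pair_any |= valid[i] & valid[j]
    return float(np.mean(ratios)), int(pair_any.sum())


def nucleotide_diversity(
    aln: MultiAlignment,
    columns: Optional[Union[Sequence[int], slice]] = None,
    deletion: str = "pairwise",
) -> float:
    """Global pi over the given columns (default: all).

    ``deletion`` is ``"pairwise"`` (default; per-pair comparable sites) or
    ``"complete"`` (only columns with a plain base in every row).
    """
    pi, _ = pi_with_sites(aln, columns, deletion)
    return pi


def pi_with_sites(
    aln: MultiAlignment,
    columns: Optional[Union[Sequence[int], slice]] = None,
    deletion: str = "pairwise",
) -> tuple[float, int]:
    mat = aln.matrix()
    if columns is not None:
        mat = mat[:, columns]
    if mat.shape[1] == 0:
        raise UndefinedStatisticError("no columns selected")
    if deletion == "complete":
        keep = (mat < 4).all(axis=0)
        mat = mat[:, keep]
        if mat.shape[1] == 0:
            raise UndefinedStatisticError("complete deletion removed every column")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    return _pairwise_pi(mat)


def sliding_window_pi(
    aln: MultiAlignment,
    window: int = 200,
    step: int = 20,
    deletion: str = "pairwise",
) -> list[PiWindow]:
    """Windowed pi anchored at column 0.

    Windows start at 0, step, 2*step, ...; trailing partial windows are
    dropped, so the last window is the last one of full length.  A window
    longer than the alignment yields a single truncated window with a
    warning.
    """
    if step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got {window}/{step}")
    length = aln.n_columns
    if window > length:
        warnings.warn(
            f"window {window} exceeds alignment length {length}; "
            "returning one truncated window"
        )
        starts = [0]
        window = length
    else:
        starts = list(range(0, length - window + 1, step))
    out = []
    for s in starts:
        pi, used = pi_with_sites(aln, slice(s, s + window), deletion)
        out.append(PiWindow(start=s, end=s + window, n_sites_used=used, pi=pi))
    return out


def per_partition_pi(
    aln: MultiAlignment, deletion: str = "pairwise"
) -> tuple[dict[str, float], str, str]:
    """Per-gene pi plus the most and least variable genes.

    Returns ``(pi_by_gene, argmax_gene, argmin_gene)``.  Genes whose
    partitions contain no usable columns are skipped with a warning.
    """
    if not aln.partitions:
        raise InsufficientDataError("alignment has no partitions")
    out: dict[str, float] = {}
    for gene, ranges in aln.partitions.items():
        if not ranges:
            warnings.warn(f"partition {gene}: empty; skipped")
            continue
        cols = np.concatenate([np.arange(s, e) for s, e in ranges])
        try:
            out[gene] = nucleotide_diversity(aln, cols, deletion)
        except UndefinedStatisticError:
            warnings.warn(f"partition {gene}: no usable columns; skipped")
    if not out:
        raise UndefinedStatisticError("no partition had usable columns")
    hi = max(out, key=lambda g: out[g])
    lo = min(out, key=lambda g: out[g])
    return out, hi, lo


# ---------------------------------------------------------------------------
# file boundary

def read_alignment(
    fasta: Union[str, TextIO], partition_tsv: Optional[Union[str, TextIO]] = None
) -> MultiAlignment:
    """Load an aligned FASTA plus optional partition table.

    The partition TSV has columns (gene, start, end) with 1-based inclusive
    coordinates, converted to 0-based half-open on load.
    """
    records = parse_fasta(fasta)
    taxa = [r[0] for r in records]
    rows = [r[1].replace("U", "T") for r in records]
    partitions: dict[str, list[tuple[int, int]]] = {}
    if partition_tsv is not None:
        df = pd.read_csv(partition_tsv, sep="\t")
        required = {"gene", "start", "end"}
        if not required.issubset(df.columns):
            raise ParseError(f"partition table needs columns {sorted(required)}")
        for _, row in df.iterrows():
            partitions.setdefault(str(row["gene"]), []).append(
                (int(row["start"]) - 1, int(row["end"]))
            )
    return MultiAlignment(taxa=taxa, rows=rows, partitions=partitions)


def windows_table(windows: Iterable[PiWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"start": w.start, "end": w.end, "n_sites_used": w.n_sites_used,
             "pi": w.pi}
            for w in windows
        ]
    )
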