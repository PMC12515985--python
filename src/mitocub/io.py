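"""Reading annotated mitogenomes and extracting strand-corrected coding sequences.

Coordinates are 0-based half-open everywhere inside the package; GenBank's
1-based inclusive convention exists only at the file boundary (handled by
Biopython).  The deposited strand is called H; features on the complement
are strand L and are reverse-complemented on extraction.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    CoordinateError,
    EmptySelectionError,
    ExtractionError,
    FrameError,
    ParseError,
)
from .vocab import category_of, normalize_gene_label

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated gene.

    ``intervals`` are 0-based half-open [start, end) pairs in transcription
    order; more than one interval occurs only for origin-spanning features
    on circular genomes.
    """

    gene: str
    category: str  # PCG | tRNA | rRNA | other
    strand: str  # H | L
    intervals: tuple[tuple[int, int], ...]
    codon_table: int = 5

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval [{s}, {e})")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        """Leftmost genome coordinate (for sorting into genome order)."""
        return min(s for s, _ in self.intervals)


@dataclass
class GenomeRecord:
    """An annotated (possibly circular) mitochondrial genome."""

    accession: str
    organism: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ParseError(
                f"{self.accession}: ambiguity codes other than N not supported: "
                f"{sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < n and 0 < e <= n):
                    raise CoordinateError(
                        f"{self.accession}:{f.gene} interval [{s}, {e}) outside "
                        f"[0, {n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_by_category(self, category: str) -> list[Feature]:
        return [f for f in self.features if f.category == category]

    def feature_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.category] = out.get(f.category, 0) + 1
        return out


@dataclass(frozen=True)
class CodingSeq:
    """A strand-corrected, in-frame protein-coding gene.

    ``nt`` is the full coding-strand sequence including start and any
    (possibly incomplete) stop; ``trimmed_nt`` drops the stop codon or the
    trailing 1–2 nt of an incomplete stop, so it is always a whole number
    of sense codons.
    """

    gene: str
    nt: str
    start_codon: str
    stop_kind: str  # complete | incomplete_T | incomplete_TA
    stop_codon: str  # TAA/TAG or the trailing fragment
    trimmed_nt: str
    codon_table: int = 5

    @property
    def n_codons(self) -> int:
        return len(self.trimmed_nt) // 3

    def codons(self) -> list[str]:
        t = self.trimmed_nt
        return [t[i:i + 3] for i in range(0, len(t), 3)]


# ---------------------------------------------------------------------------
# parsing

def _as_handle(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        if "\n" in source:
            return _stdio.StringIO(source)
        return open(source)
    return source


def parse_genbank(source: Union[str, TextIO]) -> GenomeRecord:
    """Parse one GenBank flat file into a :class:`GenomeRecord`.

    ``source`` may be a path, an open handle, or the raw text itself.
    CDS/tRNA/rRNA features are kept; gene labels are normalised onto the
    canonical vocabulary; `complement(...)` becomes strand L and
    `join(...)` is preserved as ordered intervals.
    """
    handle = _as_handle(source)
    try:
        rec = SeqIO.read(handle, "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise ParseError(f"malformed GenBank record: {exc}") from exc

    topology = rec.annotations.get("topology", "linear")
    features: list[Feature] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        label = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or feat.qualifiers.get("label", [None])[0]
        )
        if label is None:
            warnings.warn(f"{rec.id}: unlabelled {feat.type} feature skipped")
            continue
        gene = normalize_gene_label(label)
        category = category_of(gene)
        if gene == "other":
            category = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}[feat.type]
        strand = "L" if feat.location.strand == -1 else "H"
        # Biopython lists compound-location parts in transcription order
        # (reversed relative to the file for complement joins) — keep as-is.
        intervals = tuple(
            (int(p.start), int(p.end)) for p in feat.location.parts
        )
        table = int(feat.qualifiers.get("transl_table", [5])[0])
        features.append(Feature(gene, category, strand, intervals, table))

    return GenomeRecord(
        accession=rec.id or rec.name,
        organism=rec.annotations.get("organism", rec.description),
        sequence=str(rec.seq).upper().replace("U", "T"),
        topology=topology,
        features=features,
    )


def parse_fasta(source: Union[str, TextIO]) -> list[tuple[str, str]]:
    """Parse FASTA into ``[(id, sequence), ...]`` preserving order.

    Sequences are upper-cased and U is mapped to T.  Empty input and
    duplicate ids are errors.
    """
    handle = _as_handle(source)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not out:
        raise ParseError("no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# extraction

def feature_sequence(genome: GenomeRecord, feature: Feature) -> str:
    """Strand-corrected nucleotide sequence of any feature.

    Intervals are concatenated in transcription order; L-strand pieces are
    reverse-complemented.
    """
    pieces = []
    for s, e in feature.intervals:
        piece = genome.sequence[s:e]
        pieces.append(revcomp(piece) if feature.strand == "L" else piece)
    return "".join(pieces)


def _classify_stop(nt: str) -> tuple[str, str, str]:
    """Split coding sequence into (stop_kind, stop_codon, trimmed_nt)."""
    tail = len(nt) % 3
    if tail == 0:
        last = nt[-3:]
        if last in ("TAA", "TAG"):
            return "complete", last, nt[:-3]
        raise ExtractionError(
            f"coding sequence ends in {last!r}: no complete or incomplete stop"
        )
    frag = nt[-tail:]
    if tail == 1 and frag == "T":
        return "incomplete_T", "T", nt[:-1]
    if tail == 2 and frag == "TA":
        return "incomplete_TA", "TA", nt[:-2]
    raise ExtractionError(
        f"trailing {frag!r} is not an incomplete stop (expected T or TA)"
    )


def extract_coding_seq(genome: GenomeRecord, feature: Feature) -> CodingSeq:
    """Extract a PCG as an in-frame :class:`CodingSeq`.

    The stop is classified from the final 3/2/1 nt: TAA/TAG complete,
    trailing TA or T an incomplete stop completed by polyadenylation.
    The trimmed sequence is validated to contain no internal stop under
    the feature's genetic code.
    """
    if feature.category != "PCG":
        raise ExtractionError(f"{feature.gene} is not a PCG")
    nt = feature_sequence(genome, feature)
    if len(nt) < 6:
        raise ExtractionError(f"{feature.gene}: {len(nt)} nt is too short for a CDS")
    stop_kind, stop_codon, trimmed = _classify_stop(nt)
    table = CodonTable.unambiguous_dna_by_id[feature.codon_table]
    stops = set(table.stop_codons)
    for i in range(0, len(trimmed), 3):
        codon = trimmed[i:i + 3]
        if codon in stops:
            raise FrameError(
                f"{feature.gene}: internal stop {codon} at codon {i // 3}"
            )
    return CodingSeq(
        gene=feature.gene,
        nt=nt,
        start_codon=nt[:3],
        stop_kind=stop_kind,
        stop_codon=stop_codon,
        trimmed_nt=trimmed,
        codon_table=feature.codon_table,
    )


def coding_seqs(genome: GenomeRecord) -> list[CodingSeq]:
    """All PCGs of a genome as CodingSeqs, in genome order."""
    feats = sorted(genome.features_by_category("PCG"), key=lambda f: f.start)
    return [extract_coding_seq(genome, f) for f in feats]


def concat_gene_set(
    genome: GenomeRecord,
    selector: Union[str, Iterable[str]],
) -> tuple[str, int]:
    """Concatenate strand-corrected gene sequences in genome order.

    ``selector`` is a category name (``"PCG"``, ``"tRNA"``, ``"rRNA"``) or an
    iterable of canonical gene labels.  Overlapping genes are each counted in
    full (overlaps double-counted).  Returns ``(sequence, total_length)``.
    """
    if isinstance(selector, str):
        feats = genome.features_by_category(selector)
    else:
        wanted = set(selector)
        feats = [f for f in genome.features if f.gene in wanted]
    if not feats:
        raise EmptySelectionError(f"no features match {selector!r}")
    feats = sorted(feats, key=lambda f: f.start)
    seq = "".join(feature_sequence(genome, f) for f in feats)
    return seq, len(seq)


# ---------------------------------------------------------------------------
# writing

def to_seqrecord(genome: GenomeRecord) -> SeqRecord:
    """Convert to a Biopython SeqRecord (for GenBank output)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16],
        description=genome.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "organism": genome.organism,
        },
    )
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "misc_feature"}
    for f in genome.features:
        strand = -1 if f.strand == "L" else 1
        # parts in transcription order, matching Biopython's own convention;
        # the GenBank writer re-orders complement joins for the file.
        parts = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {"gene": [f.gene]}
        if f.category == "PCG":
            quals["transl_table"] = [str(f.codon_table)]
        rec.features.append(SeqFeature(loc, type=type_of[f.category], qualifiers=quals))
    return rec


def write_genbank(genome: GenomeRecord, path: str) -> None:
    SeqIO.write(to_seqrecord(genome), path, "genbank")


def write_fasta(records: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def feature_table(genome: GenomeRecord) -> "pandas.DataFrame":  # noqa: F821
    """Per-feature TSV-ready table (one row per feature, genome order)."""
    import pandas as pd

    rows = [
        {
            "accession": genome.accession,
            "gene": f.gene,
            "category": f.category,
            "strand": f.strand,
            "start": f.start,
            "end": max(e for _, e in f.intervals),
            "length": f.length,
        }
        for f in sorted(genome.features, key=lambda f: f.start)
    ]
    return pd.DataFrame(rows)
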