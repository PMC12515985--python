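"""Synthetic mitogenomes, coding-sequence sets and alignments with known truth.

Every generator records exactly what it emitted (base counts, codon counts,
expectations) in a :class:`SynthTruth`, so the analysis modules can be
tested end-to-end without external data: the pipeline must recover the
generator's bookkeeping.

The default genome emulates a stylommatophoran land-snail mitogenome: a
circular ~14.5 kb molecule carrying 13 PCGs (~10.9 kb), 22 tRNAs (~60 nt
each) and 2 rRNAs (~1.7 kb) split across both strands (9 PCGs + rrnL + 13
tRNAs on H; the rest on L), AT-rich with a negative AT skew on the
deposited strand.  Alignments use a star phylogeny with a single-hit
Jukes–Cantor-like mutation per site per lineage, chosen so that expected
nucleotide diversity has the closed form

    E[pi] = 2 p (1 - p) + (2/3) p^2

for per-lineage substitution probability p.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .codon import INVERTEBRATE_MITO, GeneticCode
from .errors import FeasibilityError
from .io import CodingSeq, Feature, GenomeRecord, revcomp
from .nucdiv import MultiAlignment
from .vocab import PCG_GENES, RRNA_GENES, TRNA_GENES

_BASES = np.array(list("ACGT"))

# sense-codon counts per PCG (start codon included), Camaenidae-like sizes
_PCG_CODONS = {
    "ATP6": 220, "ATP8": 52, "COX1": 510, "COX2": 225, "COX3": 260,
    "CYTB": 380, "NAD1": 300, "NAD2": 320, "NAD3": 115, "NAD4": 445,
    "NAD4L": 96, "NAD5": 560, "NAD6": 165,
}
_L_STRAND_PCGS = frozenset({"NAD1", "NAD4L", "NAD5", "NAD6"})
_L_STRAND_TRNAS = frozenset(
    {"trnC", "trnF", "trnH", "trnL1", "trnP", "trnQ", "trnS1", "trnV", "trnY"}
)
_TRNA_LEN = 60
_RRNA_LEN = {"rrnS": 800, "rrnL": 900}

DEFAULT_START_MIX = {"ATG": 0.70, "ATA": 0.15, "ATT": 0.10, "TTG": 0.05}
DEFAULT_STOP_MIX = {"TAA": 0.70, "TAG": 0.15, "T": 0.10, "TA": 0.05}


def default_gene_layout() -> list[tuple[str, str, str, int]]:
    """(gene, category, strand, length-in-nt) for the 37 canonical genes.

    PCG lengths here are the sense-codon span (start included, stop
    excluded: the realised stop adds 1-3 nt depending on the stop mix).
    """
    layout: list[tuple[str, str, str, int]] = []
    for g in PCG_GENES:
        strand = "L" if g in _L_STRAND_PCGS else "H"
        layout.append((g, "PCG", strand, 3 * _PCG_CODONS[g]))
    for g in RRNA_GENES:
        strand = "L" if g == "rrnS" else "H"
        layout.append((g, "rRNA", strand, _RRNA_LEN[g]))
    for g in TRNA_GENES:
        strand = "L" if g in _L_STRAND_TRNAS else "H"
        layout.append((g, "tRNA", strand, _TRNA_LEN))
    return layout


@dataclass
class GenomeSpec:
    """Targets for one synthetic mitogenome."""

    length_target: int = 14_500
    gene_layout: list[tuple[str, str, str, int]] = field(
        default_factory=default_gene_layout
    )
    at_target: float = 0.70
    at_skew_target: float = -0.10
    gc_skew_target: float = 0.10
    codon_freqs: Optional[Mapping[str, float]] = None  # None: derived from bases
    start_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_START_MIX)
    )
    stop_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_MIX)
    )
    seed: int = 0
    accession: str = "SYNTH0001"
    organism: str = "synthetic land snail"

    def base_probs(self) -> dict[str, float]:
        """Per-base probabilities realising the AT/GC content and skew targets."""
        at, gc = self.at_target, 1.0 - self.at_target
        probs = {
            "A": at * (1 + self.at_skew_target) / 2,
            "T": at * (1 - self.at_skew_target) / 2,
            "G": gc * (1 + self.gc_skew_target) / 2,
            "C": gc * (1 - self.gc_skew_target) / 2,
        }
        if not all(0 <= p <= 1 for p in probs.values()):
            raise FeasibilityError(f"infeasible base targets: {probs}")
        return probs

    def effective_codon_freqs(self, code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
        """Codon frequencies: user-supplied, or derived from base targets.

        Derived frequencies weight each sense codon by the product of its
        base probabilities (i.i.d. bases conditioned on not being a stop),
        so PCG composition tracks the genome-wide targets.
        """
        if self.codon_freqs is not None:
            freqs = {c: float(p) for c, p in self.codon_freqs.items() if p > 0}
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise FeasibilityError(f"codon_freqs sum to {total}, not 1")
            bad = set(freqs) - set(code.sense_codons)
            if bad:
                raise FeasibilityError(f"non-sense codons in codon_freqs: {sorted(bad)}")
            if self.at_target >= 0.999 and any(
                set(c) & {"G", "C"} for c in freqs
            ):
                raise FeasibilityError(
                    "at_target ~1.0 incompatible with GC-containing codons"
                )
            return freqs
        p = self.base_probs()
        w = {c: p[c[0]] * p[c[1]] * p[c[2]] for c in code.sense_codons}
        total = sum(w.values())
        if total == 0:
            raise FeasibilityError("base targets give zero mass to every sense codon")
        return {c: v / total for c, v in w.items()}


@dataclass
class SynthTruth:
    """Generator bookkeeping: everything the pipeline should recover.

    Only the sections relevant to the generator that produced it are
    populated.
    """

    seed: int
    # genome section
    dataset_counts: Optional[dict[str, dict[str, int]]] = None
    concatenations: Optional[dict[str, str]] = None
    per_gene_codon_counts: Optional[dict[str, dict[str, int]]] = None
    start_census: Optional[dict[str, int]] = None
    stop_census: Optional[dict[str, int]] = None
    # coding-seq section
    codon_freqs: Optional[dict[str, float]] = None
    expected_rscu: Optional[dict[str, float]] = None
    # alignment section
    p_sub: Optional[Union[float, dict[str, float]]] = None
    expected_pi: Optional[Union[float, dict[str, float]]] = None

    def to_json(self, path: str) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _sample_iid(rng: np.random.Generator, n: int, probs: Mapping[str, float]) -> str:
    return "".join(rng.choice(_BASES, size=n, p=[probs[b] for b in "ACGT"]))


def _sample_choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = sorted(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return str(keys[rng.choice(len(keys), p=p / p.sum())])


def expected_rscu_from_freqs(
    freqs: Mapping[str, float], code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, float]:
    """Expected RSCU when codons are drawn i.i.d. from ``freqs``.

    RSCU(c) = f(c) * family_size / family total frequency (0 counts as 0).
    """
    out = {}
    for aa, family in code.families().items():
        fam_total = sum(freqs.get(c, 0.0) for c in family)
        for c in family:
            out[c] = (
                freqs.get(c, 0.0) * len(family) / fam_total if fam_total else 0.0
            )
    return out


def simulate_codingseqs(
    codon_freqs: Mapping[str, float],
    n_genes: int,
    codons_per_gene: int,
    seed: int,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[list[CodingSeq], SynthTruth]:
    """Sample gene sets of i.i.d. codons for RSCU calibration tests.

    Every codon (including the first, which doubles as the start) is drawn
    from ``codon_freqs``, so codon counts are exactly multinomial and the
    expected RSCU has the closed form stored in the truth record.
    """
    rng = np.random.default_rng(seed)
    codons = sorted(codon_freqs)
    p = np.array([codon_freqs[c] for c in codons], dtype=float)
    p = p / p.sum()
    out = []
    for i in range(n_genes):
        draws = rng.choice(len(codons), size=codons_per_gene, p=p)
        body = "".join(codons[d] for d in draws)
        out.append(
            CodingSeq(
                gene=f"SIM{i + 1}",
                nt=body + "TAA",
                start_codon=body[:3],
                stop_kind="complete",
                stop_codon="TAA",
                trimmed_nt=body,
                codon_table=code.id,
            )
        )
    truth = SynthTruth(
        seed=seed,
        codon_freqs={c: float(codon_freqs[c]) for c in codons},
        expected_rscu=expected_rscu_from_freqs(codon_freqs, code),
    )
    return out, truth


def simulate_mitogenome(
    spec: GenomeSpec, code: GeneticCode = INVERTEBRATE_MITO
) -> tuple[GenomeRecord, SynthTruth]:
    """Build one annotated circular mitogenome from a :class:`GenomeSpec`.

    PCGs are a start codon (from ``start_mix``) followed by codons sampled
    from the spec's codon frequencies and a complete or incomplete stop
    (from ``stop_mix``); tRNAs, rRNAs and intergenic filler are i.i.d.
    bases at the target composition.  L-strand genes are stored
    reverse-complemented.  The truth record holds the realised per-dataset
    base counts, per-gene codon counts and the start/stop census.
    """
    rng = np.random.default_rng(spec.seed)
    base_probs = spec.base_probs()
    freqs = spec.effective_codon_freqs(code)
    codons = sorted(freqs)
    pcod = np.array([freqs[c] for c in codons], dtype=float)
    pcod /= pcod.sum()

    gene_nt: dict[str, str] = {}  # coding/annotated-strand sequence
    per_gene_codon_counts: dict[str, dict[str, int]] = {}
    start_census: Counter = Counter()
    stop_census: Counter = Counter()

    for gene, category, strand, length in spec.gene_layout:
        if category == "PCG":
            n_codons = max(length // 3, 2)
            start = _sample_choice(rng, spec.start_mix)
            draws = rng.choice(len(codons), size=n_codons - 1, p=pcod)
            body = "".join(codons[d] for d in draws)
            stop = _sample_choice(rng, spec.stop_mix)
            gene_nt[gene] = start + body + stop
            counts = Counter([start])
            counts.update(codons[d] for d in draws)
            per_gene_codon_counts[gene] = dict(counts)
            start_census[start] += 1
            stop_census[stop if len(stop) == 3 else stop + "-"] += 1
        else:
            gene_nt[gene] = _sample_iid(rng, length, base_probs)

    # assemble: genes in layout order, small spacers, remainder as a
    # terminal non-coding (control-region-like) block
    total_gene_nt = sum(len(s) for s in gene_nt.values())
    n_genes = len(spec.gene_layout)
    filler_total = spec.length_target - total_gene_nt
    if filler_total < 0:
        raise FeasibilityError(
            f"length target {spec.length_target} < gene total {total_gene_nt}"
        )
    spacer = min(2, filler_total // max(n_genes, 1))

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for gene, category, strand, _length in spec.gene_layout:
        seq = gene_nt[gene]
        stored = revcomp(seq) if strand == "L" else seq
        features.append(
            Feature(gene, category, strand, ((pos, pos + len(stored)),), code.id)
        )
        parts.append(stored)
        pos += len(stored)
        pad = _sample_iid(rng, spacer, base_probs)
        parts.append(pad)
        pos += spacer
    tail = spec.length_target - pos
    if tail > 0:
        parts.append(_sample_iid(rng, tail, base_probs))

    genome = GenomeRecord(
        accession=spec.accession,
        organism=spec.organism,
        sequence="".join(parts),
        topology="circular",
        features=features,
    )

    concat = {
        cat: "".join(
            gene_nt[g] for g, c, _s, _l in spec.gene_layout if c == cat
        )
        for cat in ("PCG", "tRNA", "rRNA")
    }
    counts = {"whole": _base_counts(genome.sequence)}
    for cat, label in (("PCG", "PCGs"), ("tRNA", "tRNAs"), ("rRNA", "rRNAs")):
        counts[label] = _base_counts(concat[cat])
    truth = SynthTruth(
        seed=spec.seed,
        dataset_counts=counts,
        concatenations=concat,
        per_gene_codon_counts=per_gene_codon_counts,
        start_census=dict(start_census),
        stop_census=dict(stop_census),
        codon_freqs={c: float(freqs[c]) for c in codons},
        expected_rscu=expected_rscu_from_freqs(freqs, code),
    )
    return genome, truth


def _base_counts(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in "ACGT"}


def expected_pi(p_sub: float) -> float:
    """Expected pairwise diversity on a star phylogeny.

    A site differs between two taxa if exactly one lineage mutated
    (2p(1-p), always a difference) or both did (p^2) and landed on
    different bases (2/3 under uniform choice among the three others).
    """
    return 2 * p_sub * (1 - p_sub) + (2.0 / 3.0) * p_sub**2


def simulate_alignment(
    n_taxa: int,
    n_columns: int,
    p_sub: Union[float, Sequence[float]],
    seed: int,
    partitions: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> tuple[MultiAlignment, SynthTruth]:
    """Star-phylogeny alignment with known expected diversity.

    The ancestral row is i.i.d. uniform over A/C/G/T; each taxon then
    independently substitutes each site with probability ``p_sub``
    (uniformly to one of the other three bases — single hit, no rate
    variation within a partition).  With ``partitions``, ``p_sub`` may be a
    sequence giving one rate per partition (in partition-dict order) for
    rate heterogeneity; the truth then stores per-gene expectations.
    """
    rng = np.random.default_rng(seed)
    per_part = not np.isscalar(p_sub)
    if per_part:
        if partitions is None or len(partitions) != len(p_sub):  # type: ignore[arg-type]
            raise ValueError("per-partition p_sub needs matching partitions")
        rates = [float(r) for r in p_sub]  # type: ignore[union-attr]
    else:
        rates = [float(p_sub)]  # type: ignore[arg-type]
    for r in rates:
        if not (0.0 <= r <= 0.75):
            raise ValueError(f"p_sub must be in [0, 0.75], got {r}")

    # per-column substitution probability
    col_rate = np.full(n_columns, rates[0])
    if per_part:
        for rate, ranges in zip(rates, partitions.values()):  # type: ignore[union-attr]
            for s, e in ranges:
                col_rate[s:e] = rate

    anc = rng.integers(0, 4, size=n_columns)
    rows = []
    for _ in range(n_taxa):
        mutate = rng.random(n_columns) < col_rate
        shift = rng.integers(1, 4, size=n_columns)
        derived = np.where(mutate, (anc + shift) % 4, anc)
        rows.append("".join(_BASES[derived]))
    aln = MultiAlignment(
        taxa=[f"taxon{i + 1}" for i in range(n_taxa)],
        rows=rows,
        partitions=partitions or {},
    )
    if per_part:
        exp: Union[float, dict[str, float]] = {
            gene: expected_pi(rate)
            for gene, rate in zip(partitions.keys(), rates)  # type: ignore[union-attr]
        }
        p_store: Union[float, dict[str, float]] = {
            gene: rate for gene, rate in zip(partitions.keys(), rates)  # type: ignore[union-attr]
        }
    else:
        exp = expected_pi(rates[0])
        p_store = rates[0]
    return aln, SynthTruth(seed=seed, p_sub=p_store, expected_pi=exp)
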