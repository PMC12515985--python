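"""Shared fixtures: tiny genomes built in memory, no external data."""

from __future__ import annotations

import pytest
from hypothesis import settings

from mitocub.io import Feature, GenomeRecord, revcomp, to_seqrecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def genbank_text(genome: GenomeRecord) -> str:
    """Serialise a GenomeRecord to GenBank flat-file text via Biopython."""
    from io import StringIO

    from Bio import SeqIO

    buf = StringIO()
    SeqIO.write(to_seqrecord(genome), buf, "genbank")
    return buf.getvalue()


def tiny_genome(seq: str, features: list[Feature], accession: str = "TEST1") -> GenomeRecord:
    return GenomeRecord(
        accession=accession,
        organism="test organism",
        sequence=seq,
        topology="circular",
        features=features,
    )


@pytest.fixture
def simple_pcg_genome() -> GenomeRecord:
    """120-nt genome with one H-strand and one L-strand PCG.

    H CDS at [10, 22): ATGAAATTTTAA (start ATG, Lys, Phe, stop TAA).
    L CDS at [40, 52): genome carries revcomp("ATGCCCAAATAG").
    """
    seq = ["A"] * 120
    h_cds = "ATGAAATTTTAA"
    l_cds = revcomp("ATGCCCAAATAG")
    seq[10:22] = h_cds
    seq[40:52] = l_cds
    seq[100:110] = "GCGCGCGCGC"  # some GC so skews are defined
    features = [
        Feature("COX1", "PCG", "H", ((10, 22),)),
        Feature("NAD2", "PCG", "L", ((40, 52),)),
    ]
    return tiny_genome("".join(seq), features)


@pytest.fixture
def default_synth():
    """One default synthetic mitogenome plus its truth (module-scope cache)."""
    from mitocub.synth import GenomeSpec, simulate_mitogenome

    return simulate_mitogenome(GenomeSpec(seed=42))
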