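"""Canonical mitochondrial gene vocabulary and synonym normalisation.

Metazoan mitogenomes carry 37 genes: 13 protein-coding genes (PCGs),
22 tRNAs and 2 rRNAs.  Deposited records name them inconsistently
(COI vs COX1, ND2 vs NAD2, 16S vs rrnL, trnL(CUN) vs trnL1 ...); this module
maps every common variant onto one canonical label so downstream grouping
and concatenation are stable across records from different submitters.
"""

from __future__ import annotations

import re
import warnings

PCG_GENES: tuple[str, ...] = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
)

TRNA_GENES: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_GENES: tuple[str, ...] = ("rrnS", "rrnL")

ALL_GENES: tuple[str, ...] = PCG_GENES + TRNA_GENES + RRNA_GENES

CATEGORY_OF: dict[str, str] = (
    {g: "PCG" for g in PCG_GENES}
    | {g: "tRNA" for g in TRNA_GENES}
    | {g: "rRNA" for g in RRNA_GENES}
)

# One-letter amino acid -> canonical trn label (unsplit Leu/Ser handled below).
_AA_TO_TRNA = {
    "A": "trnA", "C": "trnC", "D": "trnD", "E": "trnE", "F": "trnF",
    "G": "trnG", "H": "trnH", "I": "trnI", "K": "trnK", "M": "trnM",
    "N": "trnN", "P": "trnP", "Q": "trnQ", "R": "trnR", "T": "trnT",
    "V": "trnV", "W": "trnW", "Y": "trnY",
}

# Uppercased variant -> canonical label.  Extend as new spellings turn up.
_SYNONYMS: dict[str, str] = {
    # cytochrome oxidase subunits
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1", "COX1": "COX1", "MT-CO1": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2", "COX2": "COX2", "MT-CO2": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3", "COX3": "COX3", "MT-CO3": "COX3",
    # NADH dehydrogenase
    "ND1": "NAD1", "NAD1": "NAD1", "NADH1": "NAD1",
    "ND2": "NAD2", "NAD2": "NAD2", "NADH2": "NAD2",
    "ND3": "NAD3", "NAD3": "NAD3", "NADH3": "NAD3",
    "ND4": "NAD4", "NAD4": "NAD4", "NADH4": "NAD4",
    "ND4L": "NAD4L", "NAD4L": "NAD4L", "NADH4L": "NAD4L",
    "ND5": "NAD5", "NAD5": "NAD5", "NADH5": "NAD5",
    "ND6": "NAD6", "NAD6": "NAD6", "NADH6": "NAD6",
    # ATP synthase, cytochrome b
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP8": "ATP8", "ATPASE8": "ATP8",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB", "MT-CYB": "CYTB",
    # rRNAs
    "RRNS": "rrnS", "12S": "rrnS", "12S RRNA": "rrnS", "S-RRNA": "rrnS",
    "RRN12": "rrnS", "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS", "MT-RNR1": "rrnS",
    "RRNL": "rrnL", "16S": "rrnL", "16S RRNA": "rrnL", "L-RRNA": "rrnL",
    "RRN16": "rrnL", "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL", "MT-RNR2": "rrnL",
}

# split Leu/Ser isoacceptors keyed by anticodon family
_TRNA_SPLIT = {
    ("L", "CUN"): "trnL1", ("L", "UUR"): "trnL2", ("L", "TAG"): "trnL1",
    ("L", "TAA"): "trnL2",
    ("S", "AGN"): "trnS1", ("S", "UCN"): "trnS2", ("S", "GCU"): "trnS1",
    ("S", "UGA"): "trnS2", ("S", "TCT"): "trnS1", ("S", "TGA"): "trnS2",
}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}


def normalize_gene_label(raw: str) -> str:
    """Map a raw gene label onto the canonical 37-gene vocabulary.

    Unknown labels are returned as ``"other"`` with a warning rather than
    raising: published records carry ORFs, duplicated control-region
    features and submitter idiosyncrasies that must not abort a parse.
    """
    label = raw.strip()
    up = label.upper().replace("_", " ")
    if up in _SYNONYMS:
        return _SYNONYMS[up]
    if label in ALL_GENES:
        return label

    # tRNA spellings: trnM, tRNA-Met, trnL(CUN), trnL2, TRNS-UCU ...
    m = re.match(
        r"^T?RNA?[-_ ]?(?:(?P<three>[A-Z]{3})|(?P<one>[A-Z]))"
        r"(?P<num>\d)?\s*(?:[-_(]\s*(?P<anti>[A-Z]{3})\s*\)?)?$",
        up,
    )
    if m:
        aa = m.group("one") or _THREE_TO_ONE.get(m.group("three") or "", "")
        if aa:
            if aa in ("L", "S"):
                if m.group("num") in ("1", "2"):
                    return f"trn{aa}{m.group('num')}"
                anti = m.group("anti")
                if anti and (aa, anti) in _TRNA_SPLIT:
                    return _TRNA_SPLIT[(aa, anti)]
                if anti:
                    # fall back on wobble position heuristics
                    key = (aa, anti.replace("U", "T"))
                    if key in _TRNA_SPLIT:
                        return _TRNA_SPLIT[key]
            elif aa in _AA_TO_TRNA:
                return _AA_TO_TRNA[aa]

    warnings.warn(f"unrecognised gene label {raw!r}; keeping as 'other'",
                  stacklevel=2)
    return "other"


def category_of(gene: str) -> str:
    """Category (PCG / tRNA / rRNA / other) of a canonical label."""
    return CATEGORY_OF.get(gene, "other")
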