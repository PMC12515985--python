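#!/usr/bin/env python
"""Optional validation against deposited GenBank records (needs network).

Fetches the three newly deposited Camaenidae mitogenomes plus published
relatives from NCBI and re-runs the pipeline on real annotations: genome
length and 37-gene inventory, whole-genome AT/GC skews, per-species RSCU
bias-class counts.  This is a validation job, not part of the test suite —
run it on a machine with internet access:

    python scripts/validate_deposited.py --email you@example.org --outdir scratch/deposited
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

ACCESSIONS = [
    "PQ166711",  # Acusta ravida
    "PQ180368",  # Bradybaena similaris
    "PQ180369",  # Trichobradybaena submissa
    "NC_029419",  # Aegista aubryana
    "NC_024935",  # Mastigeulota kiangsinensis
    "NC_027493",  # Dolicheulota formosensis
]


def fetch(accession: str, email: str, dest: Path) -> Path:
    from Bio import Entrez

    Entrez.email = email
    path = dest / f"{accession}.gb"
    if not path.exists():
        with Entrez.efetch(db="nucleotide", id=accession, rettype="gb",
                           retmode="text") as handle:
            path.write_text(handle.read())
        time.sleep(0.4)  # NCBI rate limit
    return path


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--email", required=True, help="Contact email for NCBI Entrez")
    ap.add_argument("--outdir", default="scratch/deposited")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    from mitocub.codon import compute_rscu, count_codons
    from mitocub.composition import base_composition
    from mitocub.io import coding_seqs, parse_genbank

    report = {}
    for acc in ACCESSIONS:
        path = fetch(acc, args.email, outdir)
        genome = parse_genbank(str(path))
        comp = base_composition(genome.sequence)
        entry = {
            "organism": genome.organism,
            "length": len(genome),
            "feature_counts": genome.feature_counts(),
            "at_percent": round(100 * comp.at_content, 1),
            "at_skew": round(comp.at_skew, 3),
            "gc_skew": round(comp.gc_skew, 3),
        }
        try:
            entries = compute_rscu(count_codons(coding_seqs(genome)))
            entry["rscu_overrepresented"] = sum(
                e.bias_class == "overrepresented" for e in entries
            )
            entry["rscu_underrepresented"] = sum(
                e.bias_class == "underrepresented" for e in entries
            )
        except Exception as exc:  # annotation quirks in deposited records
            entry["rscu_error"] = str(exc)
        report[acc] = entry
        print(acc, json.dumps(entry))

    (outdir / "validation.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
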