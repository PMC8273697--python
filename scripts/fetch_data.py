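#!/usr/bin/env python
"""Fetch the accession-pinned inputs used by the acceptance targets into
``data/real/``. Requires network access to NCBI E-utilities; run once
before ``scripts/acceptance.py`` or the data-dependent acceptance tests.

Protein/cDNA sequences are fetched by accession. The synteny gene-order
tables (lamprey kPetMar1.pri vs human GRCh38.p13, chicken GRCg6a and skate
sAmbRad1.pri neighborhoods) must be exported from the corresponding NCBI
genome annotation tracks; this script documents the expected TSV layout
(chrom, ordinal, symbol, strand) but does not automate the export.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
REAL = ROOT / "data" / "real"

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

# file name -> (db, accession). Human PMEL/TMEM130 use the RefSeq proteins
# matching the named transcripts (ENST00000548493.5 -> NP_001186983.1,
# 661 aa; ENST00000416379.6 -> NP_004035 equivalent isoform, 435 aa).
SEQUENCES = {
    "human_pmel.fasta": ("protein", "NP_001186983.1"),
    "human_gpnmb.fasta": ("protein", "NP_001005340.1"),
    "human_tmem130.fasta": ("protein", "NP_056322.2"),
    "zebrafish_pmela.fasta": ("protein", "NP_001038795.1"),
    "zebrafish_pmela_cdna.fasta": ("nuccore", "NM_001045330.1"),
    "clingfish_pmel.fasta": ("protein", "XP_028323358.1"),
    "herring_pmela_cdna.fasta": ("nuccore", "XM_031565635.1"),
    "clingfish_pmela_cdna.fasta": ("nuccore", "XM_028467557.1"),
    "sperm_whale_pmel.fasta": ("protein", "XP_007126470.1"),
    "thorny_skate_pmel.fasta": ("protein", "XP_032891020.1"),
    "tasmanian_devil_pmel.fasta": ("protein", "XP_031814475.1"),
}


def efetch(db: str, accession: str) -> str:
    params = urllib.parse.urlencode({
        "db": db, "id": accession, "rettype": "fasta", "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    REAL.mkdir(parents=True, exist_ok=True)
    failures = []
    for name, (db, accession) in SEQUENCES.items():
        dest = REAL / name
        if dest.exists():
            print(f"{name}: already present", file=sys.stderr)
            continue
        try:
            text = efetch(db, accession)
        except Exception as exc:
            failures.append((name, accession, str(exc)))
            print(f"{name}: FAILED ({accession}): {exc}", file=sys.stderr)
            continue
        if not text.startswith(">"):
            failures.append((name, accession, "not FASTA"))
            continue
        dest.write_text(text)
        print(f"{name}: fetched {accession}", file=sys.stderr)
        time.sleep(0.4)  # E-utilities rate limit
    print(
        "\nGene-order tables for the synteny targets are not automated:\n"
        "export chrom/ordinal/symbol/strand TSVs for the +/-100-gene\n"
        "neighborhoods of lamprey gpnmb/pmel (kPetMar1.pri), human GPNMB\n"
        "Ch7 / PMEL Ch12 (GRCh38.p13), chicken Ch2/Ch33 (GRCg6a) and skate\n"
        "Ch2/Ch46 (sAmbRad1.pri) as data/real/{lamprey,human,chicken,"
        "skate}.tsv.",
        file=sys.stderr,
    )
    if failures:
        print(f"{len(failures)} fetch(es) failed; XP/XM accessions may have "
              "been superseded — search NCBI for the current versions.",
              file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
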