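"""Substitution scoring shared by the repeat detector and unit aligner.

Protein scoring uses BLOSUM62; DNA scoring is +1 match / -1 mismatch.
Both are exposed as plain ``(a, b) -> float`` callables so the period
scan and the alignment code stay backend-agnostic.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices


@lru_cache(maxsize=None)
def _blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def protein_score(a: str, b: str) -> float:
    """BLOSUM62 score for one residue pair; unknown residues score as X."""
    table = _blosum62()
    key = (a if (a, a) in table else "X", b if (b, b) in table else "X")
    return table[key]


def dna_score(a: str, b: str) -> float:
    return 1.0 if a == b and a != "N" else -1.0


def normalized_protein_score(a: str, b: str) -> float:
    """BLOSUM62 score scaled by the geometric mean of the self-scores, so
    an identical pair scores exactly 1 regardless of residue. Self-scores
    <= 0 (only X) are floored at 1 to keep the scale defined."""
    saa = max(protein_score(a, a), 1.0)
    sbb = max(protein_score(b, b), 1.0)
    return protein_score(a, b) / (saa * sbb) ** 0.5


def normalized_scorer_for(moltype: str):
    if moltype == "protein":
        return normalized_protein_score
    if moltype == "dna":
        return dna_score
    raise ValueError(f"unknown moltype {moltype!r}")


def scorer_for(moltype: str):
    if moltype == "protein":
        return protein_score
    if moltype == "dna":
        return dna_score
    raise ValueError(f"unknown moltype {moltype!r}")
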