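"""Pairwise global alignment and the percent-identity statistic.

Percent identity is reported as identities over the full alignment length,
gap columns included in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices

from pkat.seq_io import SeqRecord

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus the alignment score."""

    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("gapped rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.row_a)

    @property
    def identities(self) -> int:
        return sum(1 for a, b in zip(self.row_a, self.row_b)
                   if a == b and a != "-")

    def degapped(self) -> tuple[str, str]:
        return self.row_a.replace("-", ""), self.row_b.replace("-", "")


def _seq_and_moltype(x) -> tuple[str, str | None]:
    if isinstance(x, SeqRecord):
        return x.seq, x.moltype
    return str(x).upper(), None


def global_align(a, b, matrix: str = "BLOSUM62",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND,
                 ) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    ``a``/``b`` are :class:`SeqRecord` (moltypes must match) or raw
    strings. Proteins use the named substitution matrix (default
    BLOSUM62); DNA uses +1/-1 match/mismatch. The backend's first
    reported alignment is returned, which is deterministic.
    """
    seq_a, mt_a = _seq_and_moltype(a)
    seq_b, mt_b = _seq_and_moltype(b)
    if mt_a and mt_b and mt_a != mt_b:
        raise ValueError(f"moltype mismatch: {mt_a} vs {mt_b}")
    moltype = mt_a or mt_b or "protein"

    if not seq_a or not seq_b:
        if not seq_a and not seq_b:
            return PairwiseAlignment("", "", 0.0)
        row_a = seq_a or "-" * len(seq_b)
        row_b = seq_b or "-" * len(seq_a)
        n = max(len(seq_a), len(seq_b))
        score = gap_open + gap_extend * (n - 1) if n else 0.0
        return PairwiseAlignment(row_a, row_b, score)

    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "global"
    if moltype == "protein":
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identities / alignment length (gap columns included)."""
    if aln.length == 0:
        raise ValueError("zero-length alignment")
    return 100.0 * aln.identities / aln.length


def identity_between(a, b, **kwargs) -> float:
    return percent_identity(global_align(a, b, **kwargs))
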