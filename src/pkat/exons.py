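"""Exon/domain mapping and the +/-5% exon-length conservation statistic.

Exon indices are 1-based in every report; UTR-only exons keep their index
but never carry domain labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from pkat.architecture import ArchitectureModel
from pkat.seq_io import ExonTable

DEFAULT_TOLERANCE = 0.05
_EPS = 1e-9


@dataclass(frozen=True)
class ConservationCount:
    """How many orthologs keep an exon's length within tolerance."""

    exon_key: str
    reference_length: int
    k: int
    n: int
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ValueError("reference_length must be > 0")
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")

    def render(self) -> str:
        """Format like ``"85 bp (9/11)"``."""
        return f"{self.reference_length} bp ({self.k}/{self.n})"


def map_domains_to_exons(exons: ExonTable, model: ArchitectureModel,
                         ) -> dict[int, list[str]]:
    """Map protein domain spans to 1-based exon indices.

    Residue i (0-based) occupies transcript bases
    ``[cds_offset + 3i, cds_offset + 3i + 3)``; an exon carries every
    domain overlapping it by at least one base.
    """
    total = exons.transcript_length
    protein_len = len(model.record.seq)
    if exons.cds_offset + 3 * protein_len > total:
        raise ValueError(
            f"{exons.gene}: coding region ({3 * protein_len} bp from offset "
            f"{exons.cds_offset}) exceeds transcript ({total} bp)"
        )
    # cumulative transcript intervals per exon
    bounds = []
    pos = 0
    for length in exons.exon_lengths:
        bounds.append((pos, pos + length))
        pos += length

    out: dict[int, list[str]] = {i + 1: [] for i in range(len(bounds))}
    for dom in model.domains:
        lo = exons.cds_offset + 3 * dom.start
        hi = exons.cds_offset + 3 * dom.end
        if hi > total:
            raise ValueError(
                f"{exons.gene}: domain {dom.label} extends past the CDS")
        for idx, (a, b) in enumerate(bounds, start=1):
            if lo < b and hi > a:
                out[idx].append(dom.label)
    return out


def exon_length_conservation(orthologs: Iterable[ExonTable], exon_key: int,
                             tolerance: float = DEFAULT_TOLERANCE,
                             ) -> ConservationCount:
    """Count orthologs whose exon ``exon_key`` (1-based) is within
    ``tolerance`` of the reference length.

    The reference length is the observed length maximizing the count
    (ties broken toward the smallest length); the comparison
    ``|len - ref| / ref <= tolerance`` is inclusive at the boundary.
    """
    if exon_key < 1:
        raise ValueError("exon_key is a 1-based exon index")
    lengths = [t.exon_lengths[exon_key - 1] for t in orthologs
               if len(t.exon_lengths) >= exon_key]
    n = len(lengths)
    if n < 2:
        raise ValueError(f"exon {exon_key}: fewer than 2 orthologs provide it")

    def count_within(ref: int) -> int:
        return sum(1 for x in lengths if abs(x - ref) / ref <= tolerance + _EPS)

    best_ref, best_k = None, -1
    for ref in sorted(set(lengths)):
        k = count_within(ref)
        if k > best_k:
            best_ref, best_k = ref, k
    return ConservationCount(exon_key=f"ex{exon_key}",
                             reference_length=best_ref, k=best_k, n=n,
                             tolerance=tolerance)


def conservation_table(orthologs: Sequence[ExonTable],
                       tolerance: float = DEFAULT_TOLERANCE,
                       ) -> list[ConservationCount]:
    """Conservation counts for every exon index provided by >= 2 orthologs."""
    max_exons = max(len(t.exon_lengths) for t in orthologs)
    out = []
    for idx in range(1, max_exons + 1):
        provided = sum(1 for t in orthologs if len(t.exon_lengths) >= idx)
        if provided >= 2:
            out.append(exon_length_conservation(orthologs, idx, tolerance))
    return out
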