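"""Windowed paralogon comparison: neighborhoods of gene symbols around a
focal gene, shared-symbol counts against reference regions, the A:B ratio
and an inparalog classification.

Symbols are matched case-insensitively and exactly by default; stripping
of teleost "a"/"b" or "-like" paralog suffixes is opt-in.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from pkat.seq_io import GeneTableRow

DEFAULT_WINDOW = 100
DEFAULT_MIN_FOLD = 3.0

_SUFFIX_RE = re.compile(r"(-LIKE|[AB])$")


def normalize_symbol(symbol: str, strip_suffixes: bool = False) -> str:
    s = symbol.upper()
    if strip_suffixes:
        s = _SUFFIX_RE.sub("", s)
    return s


@dataclass(frozen=True)
class Neighborhood:
    """Up to ``window`` gene symbols on each side of a focal gene."""

    focal: str
    chrom: str
    window: int
    symbols: tuple[str, ...]
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        if len(self.symbols) > 2 * self.window:
            raise ValueError("neighborhood larger than 2 x window")


@dataclass(frozen=True)
class SyntenyResult:
    focal: str
    shared_a: int
    shared_b: int
    symbols_a: frozenset[str]
    symbols_b: frozenset[str]
    ratio: float
    classification: str

    def ratio_str(self) -> str:
        if math.isinf(self.ratio):
            return "inf"
        return format_ratio(self.ratio)


def extract_neighborhood(table: Sequence[GeneTableRow], focal_symbol: str,
                         window: int = DEFAULT_WINDOW) -> Neighborhood:
    """Up to ``window`` genes each side of the focal gene in ordinal order,
    truncated without error at chromosome ends."""
    if window < 1:
        raise ValueError("window must be >= 1")
    focal_norm = normalize_symbol(focal_symbol)
    hits = [r for r in table if r.symbol == focal_norm]
    if not hits:
        raise ValueError(f"focal gene {focal_symbol!r} absent from table")
    chroms = {r.chrom for r in hits}
    if len(hits) > 1:
        raise ValueError(
            f"focal gene {focal_symbol!r} occurs {len(hits)} times "
            f"(chromosomes: {sorted(chroms)})"
        )
    focal_row = hits[0]
    chrom_rows = sorted((r for r in table if r.chrom == focal_row.chrom),
                        key=lambda r: r.ordinal)
    idx = next(i for i, r in enumerate(chrom_rows)
               if r.symbol == focal_norm)
    left = chrom_rows[max(0, idx - window): idx]
    right = chrom_rows[idx + 1: idx + 1 + window]
    return Neighborhood(
        focal=focal_norm, chrom=focal_row.chrom, window=window,
        symbols=tuple(r.symbol for r in left + right),
        truncated_left=len(left) < window,
        truncated_right=len(right) < window,
    )


def shared_genes(focal: Neighborhood, references: Iterable[Neighborhood],
                 strip_suffixes: bool = False) -> tuple[int, frozenset[str]]:
    """Focal symbols present in the union of the reference neighborhoods.

    Each symbol counts once regardless of multiplicity; the focal gene's
    own symbol never counts.
    """
    focal_syms = {normalize_symbol(s, strip_suffixes) for s in focal.symbols}
    focal_syms.discard(normalize_symbol(focal.focal, strip_suffixes))
    ref_syms: set[str] = set()
    for ref in references:
        ref_syms.update(normalize_symbol(s, strip_suffixes)
                        for s in ref.symbols)
    shared = frozenset(focal_syms & ref_syms)
    return len(shared), shared


def format_ratio(ratio: float) -> str:
    """Round half-up to one decimal for reporting (47/3 -> "15.7")."""
    return str(Decimal(repr(ratio)).quantize(Decimal("0.1"),
                                             rounding=ROUND_HALF_UP))


def paralogon_ratio(shared_a: int, shared_b: int) -> float:
    """shared_a / shared_b; infinite when shared_b is 0.

    Raises when both counts are zero (no syntenic evidence either way).
    """
    if shared_a < 0 or shared_b < 0:
        raise ValueError("counts must be >= 0")
    if shared_a == 0 and shared_b == 0:
        raise ValueError("no syntenic evidence: both shared counts are 0")
    if shared_b == 0:
        return math.inf
    return shared_a / shared_b


def classify_inparalog(ratio: float,
                       min_fold: float = DEFAULT_MIN_FOLD) -> str:
    """A-like if ratio >= min_fold (inclusive), B-like if <= 1/min_fold,
    ambiguous otherwise."""
    if math.isinf(ratio):
        return "A-like"
    if ratio >= min_fold:
        return "A-like"
    if ratio <= 1.0 / min_fold:
        return "B-like"
    return "ambiguous"


def compare_neighborhoods(focal: Neighborhood,
                          references_a: Iterable[Neighborhood],
                          references_b: Iterable[Neighborhood],
                          min_fold: float = DEFAULT_MIN_FOLD,
                          strip_suffixes: bool = False) -> SyntenyResult:
    na, syms_a = shared_genes(focal, references_a, strip_suffixes)
    nb, syms_b = shared_genes(focal, references_b, strip_suffixes)
    ratio = paralogon_ratio(na, nb)
    return SyntenyResult(
        focal=focal.focal, shared_a=na, shared_b=nb,
        symbols_a=syms_a, symbols_b=syms_b, ratio=ratio,
        classification=classify_inparalog(ratio, min_fold),
    )
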