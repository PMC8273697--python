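"""Imperfect tandem repeat (RPT) detection, segmentation and statistics.

The detector scores self-similarity at every candidate period, segments the
region into units with a bounded per-unit length drift, aligns the units
progressively against a running consensus, and derives ladder columns
(regularly spaced T/S or D/E positions) and per-unit motif counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import ceil
from typing import Callable, Iterable, Sequence

from pkat.scoring import normalized_scorer_for, scorer_for
from pkat.seq_io import SeqRecord

DEFAULT_PMIN = 8
DEFAULT_PMAX = 40
DEFAULT_GAP_PENALTY = -4.0
DEFAULT_LADDER_THRESHOLD = 0.7
DEFAULT_MIN_PERIOD_SCORE = 0.5
DEFAULT_HARMONIC_TOLERANCE = 0.1
MAX_UNIT_DRIFT = 3
MIN_TAIL_FRACTION = 0.5

LADDER_CLASSES = {"TS": frozenset("TS"), "DE": frozenset("DE")}


class NoTandemStructureError(ValueError):
    """Raised when a region does not contain at least two repeat units."""


@dataclass(frozen=True)
class LadderColumn:
    column: int
    residue_class: str
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class RepeatModel:
    source: SeqRecord
    region: tuple[int, int]
    period: int
    period_score: float
    unit_spans: tuple[tuple[int, int], ...]
    unit_alignment: tuple[str, ...]
    consensus: str
    column_freqs: tuple[dict[str, float], ...]
    ladders: dict[str, tuple[LadderColumn, ...]] = field(default_factory=dict)
    motif_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_spans)

    def units(self) -> list[str]:
        return [self.source.seq[a:b] for a, b in self.unit_spans]

    def has_clear_ladder(self, residue_class: str) -> bool:
        return bool(self.ladders.get(residue_class))


def _region_of(record: SeqRecord, region: tuple[int, int] | None) -> tuple[int, int]:
    if region is None:
        return 0, len(record.seq)
    a, b = region
    if not (0 <= a < b <= len(record.seq)):
        raise ValueError(f"region {region} outside sequence of length {len(record.seq)}")
    return a, b


# ---------------------------------------------------------------------------
# Period detection
# ---------------------------------------------------------------------------

def period_scores(record: SeqRecord, region: tuple[int, int] | None = None,
                  pmin: int = DEFAULT_PMIN, pmax: int = DEFAULT_PMAX,
                  ) -> dict[int, float]:
    """Self-similarity score for every candidate period.

    score(p) is the mean substitution score between residue i and residue
    i+p over the region, normalized per aligned pair (identical residues
    score 1) — the quantity detect_period maximizes.
    """
    a, b = _region_of(record, region)
    s = record.seq[a:b]
    length = len(s)
    if pmin < 2:
        raise ValueError("pmin must be >= 2")
    if length < 2 * pmin:
        raise ValueError(f"region too short ({length}) for pmin={pmin}")
    pmax = min(pmax, length // 2)
    if pmax < pmin:
        raise ValueError("no candidate periods: pmax < pmin after clipping")
    score = normalized_scorer_for(record.moltype)
    out: dict[int, float] = {}
    for p in range(pmin, pmax + 1):
        total = 0.0
        npairs = length - p
        for i in range(npairs):
            total += score(s[i], s[i + p])
        out[p] = total / npairs
    return out


def detect_period(record: SeqRecord, region: tuple[int, int] | None = None,
                  pmin: int = DEFAULT_PMIN, pmax: int = DEFAULT_PMAX,
                  harmonic_tolerance: float = DEFAULT_HARMONIC_TOLERANCE,
                  ) -> tuple[int, float]:
    """Period maximizing the normalized self-similarity score.

    The smallest period scoring within ``harmonic_tolerance`` of the best
    is returned, preventing harmonic doubling (an imperfect 13-periodic
    repeat scores nearly identically at 13 and 26; exact ties also go to
    the smallest period).
    """
    scores = period_scores(record, region, pmin, pmax)
    best = max(scores.values())
    for p in sorted(scores):
        if scores[p] >= best - harmonic_tolerance:
            return p, scores[p]
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Alignment primitives (linear gap penalty; used on unit-sized strings)
# ---------------------------------------------------------------------------

def _nw_align(a: str, b: str, score: Callable[[str, str], float],
              gap: float = DEFAULT_GAP_PENALTY) -> tuple[str, str, float]:
    """Global alignment of two short strings, linear gap penalty.

    Tie-break prefers diagonal, then a gap in ``b``, for determinism.
    """
    n, m = len(a), len(b)
    best = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 0 diag, 1 up (gap in b), 2 left
    for i in range(1, n + 1):
        best[i][0] = gap * i
        move[i][0] = 1
    for j in range(1, m + 1):
        best[0][j] = gap * j
        move[0][j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = best[i - 1][j - 1] + score(ai, b[j - 1])
            up = best[i - 1][j] + gap
            left = best[i][j - 1] + gap
            if diag >= up and diag >= left:
                best[i][j], move[i][j] = diag, 0
            elif up >= left:
                best[i][j], move[i][j] = up, 1
            else:
                best[i][j], move[i][j] = left, 2
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 0:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif mv == 1:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), best[n][m]


def _column_consensus(rows: Sequence[str]) -> tuple[str, tuple[dict[str, float], ...]]:
    """Majority consensus with the >=50% / X rule.

    A column's consensus residue is its most frequent residue when that
    residue's frequency over non-gap rows is >= 50% and the top residue is
    unique; otherwise the column is X. Frequencies are over non-gap rows.
    """
    ncols = len(rows[0])
    consensus = []
    freqs: list[dict[str, float]] = []
    for c in range(ncols):
        col = [r[c] for r in rows if r[c] != "-"]
        if not col:
            consensus.append("-")
            freqs.append({})
            continue
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        freqs.append({ch: n / len(col) for ch, n in sorted(counts.items())})
        top = max(counts.values())
        winners = [ch for ch, n in counts.items() if n == top]
        if len(winners) == 1 and top / len(col) >= 0.5:
            consensus.append(winners[0])
        else:
            consensus.append("X")
    return "".join(consensus), tuple(freqs)


def _tail_free_score(a: str, b: str, score: Callable[[str, str], float],
                     gap: float = DEFAULT_GAP_PENALTY) -> float:
    """Best global alignment score with cost-free trailing gaps.

    Used to rank candidate unit lengths: a unit truncated by a deletion
    should not pay for the consensus residues it legitimately lacks.
    """
    n, m = len(a), len(b)
    best = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        best[i][0] = gap * i
    for j in range(1, m + 1):
        best[0][j] = gap * j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            best[i][j] = max(best[i - 1][j - 1] + score(ai, b[j - 1]),
                             best[i - 1][j] + gap,
                             best[i][j - 1] + gap)
    return max(max(best[n][j] for j in range(m + 1)),
               max(best[i][m] for i in range(n + 1)))


def _modal_string(blocks: Sequence[str], width: int) -> str:
    """Columnwise modal residue over equal-width blocks (alphabetic ties)."""
    out = []
    for c in range(width):
        counts: dict[str, int] = {}
        for blk in blocks:
            if len(blk) > c:
                counts[blk[c]] = counts.get(blk[c], 0) + 1
        out.append(min((ch for ch, n in counts.items()
                        if n == max(counts.values()))))
    return "".join(out)


# ---------------------------------------------------------------------------
# Unit segmentation
# ---------------------------------------------------------------------------

def segment_units(record: SeqRecord, region: tuple[int, int] | None,
                  period: int, max_drift: int = MAX_UNIT_DRIFT,
                  min_tail_fraction: float = MIN_TAIL_FRACTION,
                  ) -> tuple[tuple[int, int], ...]:
    """Segment a region into tandem units of length ``period`` +/- drift.

    A greedy phase search picks the start offset whose fixed-width blocks
    agree best with their running consensus; a second pass realigns each
    unit locally, allowing per-unit lengths in ``period +/- max_drift``.
    Partial terminal units are kept when they cover at least
    ``min_tail_fraction`` of the period, otherwise dropped.
    """
    a, b = _region_of(record, region)
    s = record.seq[a:b]
    length = len(s)
    p = period
    if p < 2 or p > length // 2:
        raise ValueError(f"period {p} unusable for region of length {length}")
    score = scorer_for(record.moltype)

    # Phase search on fixed-width blocks.
    best_offset, best_total = 0, None
    for offset in range(p):
        blocks = [s[offset + k * p: offset + (k + 1) * p]
                  for k in range((length - offset) // p)]
        if len(blocks) < 2:
            continue
        total = 0.0
        for k in range(1, len(blocks)):
            cons = _modal_string(blocks[:k], p)
            total += sum(score(x, y) for x, y in zip(blocks[k], cons))
        if best_total is None or total > best_total + 1e-9:
            best_offset, best_total = offset, total
    if best_total is None:
        raise NoTandemStructureError("no tandem structure: fewer than 2 units")

    min_tail = max(1, ceil(p * min_tail_fraction))
    spans: list[tuple[int, int]] = []
    if best_offset >= min_tail:
        spans.append((0, best_offset))

    full_units: list[str] = []
    pos = best_offset
    while length - pos >= min_tail:
        rem = length - pos
        if rem < p - max_drift:
            q = rem  # trailing partial unit
        elif not full_units:
            q = p
        else:
            cons = _modal_string(full_units, p)
            best_q, best_s = p, None
            # identity scoring for length ranking: substitution-matrix
            # similarity between non-homologous residues would otherwise
            # shift unit boundaries by chance
            ident = (lambda x, y: 1.0 if x == y else -1.0)
            for q_cand in range(max(1, p - max_drift),
                                min(rem, p + max_drift) + 1):
                sc = _tail_free_score(s[pos:pos + q_cand], cons, ident,
                                      gap=-2.0)
                # prefer lengths closer to the period on ties
                key = (sc, -abs(q_cand - p))
                if best_s is None or key > best_s:
                    best_q, best_s = q_cand, key
            q = best_q
        spans.append((pos, pos + q))
        if q >= p - max_drift:
            full_units.append(s[pos:pos + q][:p].ljust(p, "X")[:p]
                              if q < p else s[pos:pos + p])
        pos += q

    if len(spans) < 2:
        raise NoTandemStructureError("no tandem structure: fewer than 2 units")
    return tuple((a + x, a + y) for x, y in spans)


# ---------------------------------------------------------------------------
# Unit alignment / consensus
# ---------------------------------------------------------------------------

def align_units(units: Sequence[str], moltype: str = "protein",
                gap: float = DEFAULT_GAP_PENALTY,
                ) -> tuple[tuple[str, ...], str, tuple[dict[str, float], ...]]:
    """Progressively align units against an incrementally updated consensus.

    Returns (aligned rows, consensus, per-column residue frequencies).
    Consensus follows the >=50% rule with X for sub-threshold or tied
    columns; frequencies are over non-gap rows and sum to 1 per column.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    score = scorer_for(moltype)
    rows: list[str] = [units[0]]
    consensus, freqs = units[0], None
    for unit in units[1:]:
        aligned_unit, aligned_cons, _ = _nw_align(unit, consensus, score, gap)
        # Propagate new gap columns (gaps inserted into the consensus) into
        # every previously aligned row.
        new_rows = []
        for row in rows:
            out, k = [], 0
            for ch in aligned_cons:
                if ch == "-":
                    out.append("-")
                else:
                    out.append(row[k]); k += 1
            new_rows.append("".join(out))
        new_rows.append(aligned_unit)
        rows = new_rows
        consensus, freqs = _column_consensus(rows)
    consensus, freqs = _column_consensus(rows)
    return tuple(rows), consensus, freqs


# ---------------------------------------------------------------------------
# Ladders and motifs
# ---------------------------------------------------------------------------

def detect_ladders(rows: Sequence[str], residue_class: str,
                   occupancy_threshold: float = DEFAULT_LADDER_THRESHOLD,
                   ) -> tuple[LadderColumn, ...]:
    """Columns where >= threshold of units carry a class member.

    ``residue_class`` is "TS" or "DE". Occupancy denominators count all
    units (rows), so gapped rows lower occupancy. A domain "has a clear
    ladder" iff at least one such column exists.
    """
    members = LADDER_CLASSES[residue_class]
    out = []
    nrows = len(rows)
    for c in range(len(rows[0])):
        occ = sum(1 for r in rows if r[c] in members) / nrows
        if occ >= occupancy_threshold:
            out.append(LadderColumn(column=c, residue_class=residue_class,
                                    occupancy=occ))
    return tuple(out)


def compile_motif(pattern: str) -> str:
    """Translate a degenerate motif (X wildcard, [..] classes) to regex."""
    if not pattern:
        raise ValueError("empty motif pattern")
    out, i = [], 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "X":
            out.append(".")
            i += 1
        elif ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i:j + 1])
            i = j + 1
        else:
            out.append(re.escape(ch))
            i += 1
    return "".join(out)


def motif_census(units: Sequence[str], motif: str,
                 max_spacer: int | None = None) -> int:
    """Number of units containing >= 1 motif match.

    A motif containing ``...`` is a paired pattern: the upstream part must
    be followed by the downstream part within ``max_spacer`` positions.
    """
    if not motif:
        raise ValueError("empty motif pattern")
    if "..." in motif:
        if max_spacer is None:
            raise ValueError("paired motif requires max_spacer")
        up, down = motif.split("...", 1)
        regex = compile_motif(up) + ".{0,%d}" % max_spacer + compile_motif(down)
    else:
        regex = compile_motif(motif)
    rx = re.compile(regex)
    return sum(1 for u in units if rx.search(u.replace("-", "")))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def repeat_report(record: SeqRecord, region: tuple[int, int] | None = None,
                  pmin: int = DEFAULT_PMIN, pmax: int = DEFAULT_PMAX,
                  ladder_threshold: float = DEFAULT_LADDER_THRESHOLD,
                  motifs: Iterable[tuple[str, int | None]] = (),
                  min_period_score: float = DEFAULT_MIN_PERIOD_SCORE,
                  ) -> RepeatModel:
    """Run the full repeat pipeline on a region and collect statistics.

    Raises :class:`NoTandemStructureError` when the best period's
    self-similarity falls below ``min_period_score`` (unrelated sequence
    scores negative under BLOSUM62) or fewer than two units are found.
    """
    a, b = _region_of(record, region)
    period, pscore = detect_period(record, (a, b), pmin, pmax)
    if pscore < min_period_score:
        raise NoTandemStructureError(
            f"best period {period} scores {pscore:.2f} < {min_period_score}"
        )
    spans = segment_units(record, (a, b), period)
    units = [record.seq[x:y] for x, y in spans]
    rows, consensus, freqs = align_units(units, record.moltype)
    ladders = {
        cls: detect_ladders(rows, cls, ladder_threshold)
        for cls in LADDER_CLASSES
    }
    counts = {}
    for motif, spacer in motifs:
        counts[motif] = motif_census(units, motif, spacer)
    return RepeatModel(
        source=record, region=(a, b), period=period, period_score=pscore,
        unit_spans=spans, unit_alignment=rows, consensus=consensus,
        column_freqs=freqs, ladders=ladders, motif_counts=counts,
    )
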