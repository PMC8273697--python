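"""Domain-architecture annotation for PKAT-family proteins.

Finders implement explicit sequence heuristics: an N-terminal signal
peptide bounded by charged residues, PKD core motifs, a six-cysteine
Kringle-like domain matched against a spacing template, a nonpolar
transmembrane window and the C-terminal dileucine endocytic signal. The
composer assembles them into a single non-overlapping architecture and
maps variant positions onto domain labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from pkat import repeats as _repeats
from pkat.scoring import protein_score
from pkat.seq_io import SeqRecord

# Side-chain polarity classes (used for TM detection and reporting).
NONPOLAR = frozenset("GAVLIPFMW")
POLAR_UNCHARGED = frozenset("STCYNQ")
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")

# For signal-peptide boundary detection histidine is treated as uncharged:
# its charge is pH-dependent and the detection rule asks for unambiguous
# basic/acidic residues.
SP_CHARGED = frozenset("DEKR")

DOMAIN_ORDER = ("SP", "NTR", "CAF", "PKD", "RPT", "KLD", "TM", "Cyt")

# Overlap precedence: profile/motif-based calls beat window heuristics.
PRECEDENCE = {"SP": 6, "RPT": 5, "PKD": 4, "KLD": 3, "TM": 2,
              "CAF": 1, "NTR": 0, "Cyt": 0}

DILEUCINE_PATTERN = "[DE]XXXL[LI]"
PKD_CORE_MOTIF = "WDFGDGS"
PKD_DEGENERATE_MOTIF = "[LI][HY]DP"

DEFAULT_TAIL_WINDOW = 40

# Kringle-like domain: successive cysteine gaps with a per-gap tolerance.
# The default spacing is a configuration value (calibrate against curated
# sequences for real data); tests pair it with the synthetic generator.
DEFAULT_KLD_GAPS = (14, 22, 5, 12, 8)
DEFAULT_KLD_GAP_TOLERANCE = 3


@dataclass(frozen=True)
class ResidueClassMap:
    """Partition of the 20 amino acids into polarity classes."""

    nonpolar: frozenset = NONPOLAR
    polar_uncharged: frozenset = POLAR_UNCHARGED
    acidic: frozenset = ACIDIC
    basic: frozenset = BASIC

    def __post_init__(self) -> None:
        groups = [self.nonpolar, self.polar_uncharged, self.acidic, self.basic]
        union = frozenset().union(*groups)
        if len(union) != 20 or sum(len(g) for g in groups) != 20:
            raise ValueError("classes must partition the 20 amino acids")

    def of(self, residue: str) -> str:
        for name in ("nonpolar", "polar_uncharged", "acidic", "basic"):
            if residue in getattr(self, name):
                return name
        return "other"


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled span on a protein; 0-based half-open internally."""

    label: str
    start: int
    end: int
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.label not in DOMAIN_ORDER:
            raise ValueError(f"unknown domain label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span [{self.start}, {self.end})")

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    @property
    def start1(self) -> int:
        """1-based inclusive start for reports."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end for reports."""
        return self.end


@dataclass(frozen=True)
class MotifMatch:
    label: str
    start: int
    end: int
    mismatches: int = 0


@dataclass
class ArchitectureModel:
    record: SeqRecord
    domains: tuple[DomainAnnotation, ...]
    is_pkat: bool
    flags: dict = field(default_factory=dict)

    def get(self, label: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.label == label:
                return d
        return None

    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.domains)


def _require_protein(record: SeqRecord) -> None:
    if record.moltype != "protein":
        raise ValueError(f"record {record.id!r} is not a protein")


# ---------------------------------------------------------------------------
# Signal peptide
# ---------------------------------------------------------------------------

def find_signal_peptide(record: SeqRecord,
                        min_uncharged_run: int = 8,
                        max_first_charge: int = 13,
                        min_total: int = 7,
                        max_total: int = 33) -> DomainAnnotation | None:
    """Earliest N-terminal span matching the SP rule.

    Requires a charged (D/E/K/R) residue within positions 1..13 after the
    start methionine, followed by a run of >= 8 uncharged residues, with
    the whole peptide 7..33 residues long and terminated by the next
    charged residue.
    """
    _require_protein(record)
    seq = record.seq
    if not seq.startswith("M"):
        return None
    limit = min(max_first_charge, len(seq) - 1)
    for c in range(1, limit + 1):
        if seq[c] not in SP_CHARGED:
            continue
        t = c + 1
        while t < len(seq) and seq[t] not in SP_CHARGED:
            t += 1
        run = t - c - 1
        if run >= min_uncharged_run and min_total <= t <= max_total:
            return DomainAnnotation(
                "SP", 0, t,
                evidence=(f"charge at {c + 1}, uncharged run "
                          f"{c + 2}-{t} ({run} aa)"),
            )
    return None


# ---------------------------------------------------------------------------
# Dileucine endocytic signal
# ---------------------------------------------------------------------------

def find_dileucine_motif(record: SeqRecord,
                         tail_window: int = DEFAULT_TAIL_WINDOW,
                         ) -> tuple[int, int] | None:
    """Last [DE]XXXL[LI] match within ``tail_window`` of the C-terminus."""
    _require_protein(record)
    if tail_window < 6:
        raise ValueError("tail_window must be >= 6")
    seq = record.seq
    tail_start = max(0, len(seq) - tail_window)
    rx = re.compile("(?=([DE]...L[LI]))")
    last = None
    for m in rx.finditer(seq):
        if m.start() >= tail_start:
            last = (m.start(), m.start() + 6)
    return last


# ---------------------------------------------------------------------------
# PKD motifs
# ---------------------------------------------------------------------------

def find_pkd_motifs(record: SeqRecord, max_mismatch: int = 1,
                    ) -> tuple[MotifMatch, ...]:
    """WDFGDGS (allowing substitutions) and [LI][HY]DP matches."""
    _require_protein(record)
    seq = record.seq
    out: list[MotifMatch] = []
    core = PKD_CORE_MOTIF
    for i in range(len(seq) - len(core) + 1):
        mm = sum(1 for a, b in zip(seq[i:i + len(core)], core) if a != b)
        if mm <= max_mismatch:
            out.append(MotifMatch(core, i, i + len(core), mm))
    rx = re.compile("(?=([LI][HY]DP))")
    for m in rx.finditer(seq):
        out.append(MotifMatch(PKD_DEGENERATE_MOTIF, m.start(), m.start() + 4))
    return tuple(sorted(out, key=lambda m: (m.start, m.label)))


# ---------------------------------------------------------------------------
# Kringle-like domain
# ---------------------------------------------------------------------------

def kld_template(gaps: Sequence[int] = DEFAULT_KLD_GAPS,
                 tolerance: int = DEFAULT_KLD_GAP_TOLERANCE,
                 ) -> tuple[tuple[int, int], ...]:
    """Build per-gap (lo, hi) bands from nominal cysteine gaps."""
    if len(gaps) != 5:
        raise ValueError("KLD template needs exactly 5 inter-cysteine gaps")
    return tuple((max(1, g - tolerance), g + tolerance) for g in gaps)


def _chain_search(cys: Sequence[int], bands: Sequence[tuple[int, int]],
                  start_idx: int) -> list[int] | None:
    chain = [cys[start_idx]]

    def extend(prev: int, level: int) -> bool:
        if level == len(bands):
            return True
        lo, hi = bands[level]
        for nxt in cys:
            if prev + lo <= nxt <= prev + hi:
                chain.append(nxt)
                if extend(nxt, level + 1):
                    return True
                chain.pop()
        return False

    return chain if extend(cys[start_idx], 0) else None


def find_kld(record: SeqRecord,
             cys_template: Sequence[tuple[int, int]] | None = None,
             mode: str = "strict") -> DomainAnnotation | None:
    """Six cysteines whose successive gaps fall within the template bands.

    ``mode="strict"`` requires all six (the GPNMB/PMEL-style call);
    ``mode="weak"`` additionally accepts five cysteines with one internal
    cysteine missing (the TMEM130-style weak call), flagged in evidence.
    """
    _require_protein(record)
    bands = tuple(cys_template) if cys_template is not None else kld_template()
    if len(bands) != 5:
        raise ValueError("KLD template needs exactly 5 gaps")
    cys = [i for i, ch in enumerate(record.seq) if ch == "C"]
    for start_idx in range(len(cys)):
        chain = _chain_search(cys, bands, start_idx)
        if chain:
            return DomainAnnotation(
                "KLD", chain[0], chain[-1] + 1,
                evidence="6 cysteines at " + ",".join(str(c + 1) for c in chain),
            )
    if mode == "weak":
        for drop in range(1, 5):  # merge bands around one missing internal cys
            merged = (bands[:drop - 1]
                      + ((bands[drop - 1][0] + bands[drop][0],
                          bands[drop - 1][1] + bands[drop][1]),)
                      + bands[drop + 1:])
            for start_idx in range(len(cys)):
                chain = _chain_search(cys, merged, start_idx)
                if chain:
                    return DomainAnnotation(
                        "KLD", chain[0], chain[-1] + 1,
                        evidence=("weak call: 5 of 6 cysteines at "
                                  + ",".join(str(c + 1) for c in chain)),
                    )
    return None


# ---------------------------------------------------------------------------
# Transmembrane domain
# ---------------------------------------------------------------------------

def find_tm(record: SeqRecord, min_len: int = 15,
            min_nonpolar_fraction: float = 0.9,
            search_start: int = 0) -> DomainAnnotation | None:
    """Longest window >= min_len with >= 90% nonpolar residues.

    Candidate windows are trimmed so they start and end on a nonpolar
    residue (a membrane span cannot terminate on a polar side chain);
    ties go to the most C-terminal window (Type I topology places the TM
    near the C-terminus). ``search_start`` restricts the search, e.g. to
    the region C-terminal of a KLD call.
    """
    _require_protein(record)
    seq = record.seq
    n = len(seq)
    prefix = [0] * (n + 1)
    for i, ch in enumerate(seq):
        prefix[i + 1] = prefix[i] + (1 if ch in NONPOLAR else 0)
    best = None  # (length, end, start)
    for i in range(search_start, n - min_len + 1):
        for j in range(i + min_len, n + 1):
            np_count = prefix[j] - prefix[i]
            if np_count / (j - i) < min_nonpolar_fraction:
                continue
            a, b = i, j
            while a < b and seq[a] not in NONPOLAR:
                a += 1
            while b > a and seq[b - 1] not in NONPOLAR:
                b -= 1
            if b - a < min_len:
                continue
            key = (b - a, b)
            if best is None or key > best[:2]:
                best = (b - a, b, a)
    if best is None:
        return None
    length, end, start = best
    frac = (prefix[end] - prefix[start]) / length
    return DomainAnnotation("TM", start, end,
                            evidence=f"{length} aa window, {frac:.0%} nonpolar")


# ---------------------------------------------------------------------------
# CAF profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CafProfile:
    """Position-specific profile for the core amyloid fragment.

    ``consensus`` is scored columnwise with BLOSUM62; positions listed in
    ``essential`` (0-based; the aromatic residues critical for fibril
    formation) are weighted 2x. A window qualifies when it reaches
    ``threshold`` of the profile's self-score.
    """

    consensus: str
    essential: frozenset = frozenset()
    threshold: float = 0.6

    def weight(self, i: int) -> float:
        return 2.0 if i in self.essential else 1.0

    def self_score(self) -> float:
        return sum(self.weight(i) * protein_score(c, c)
                   for i, c in enumerate(self.consensus))

    def score(self, window: str) -> float:
        return sum(self.weight(i) * protein_score(window[i], c)
                   for i, c in enumerate(self.consensus))


# Default CAF profile used by the synthetic generator and tests; replace
# with a profile built from curated alignments for real data.
DEFAULT_CAF_PROFILE = CafProfile(
    consensus="WGYFFQLPHW", essential=frozenset({0, 3, 4, 9})
)


def find_caf(record: SeqRecord, region: tuple[int, int] | None = None,
             profile: CafProfile = DEFAULT_CAF_PROFILE,
             ) -> DomainAnnotation | None:
    """Best profile hit above threshold inside ``region`` (default: all)."""
    _require_protein(record)
    a, b = (0, len(record.seq)) if region is None else region
    width = len(profile.consensus)
    cutoff = profile.threshold * profile.self_score()
    best = None
    for i in range(a, b - width + 1):
        sc = profile.score(record.seq[i:i + width])
        if sc >= cutoff and (best is None or sc > best[0]):
            best = (sc, i)
    if best is None:
        return None
    sc, i = best
    return DomainAnnotation("CAF", i, i + width,
                            evidence=f"profile score {sc:.0f}/{profile.self_score():.0f}")


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _resolve_overlaps(domains: list[DomainAnnotation]) -> list[DomainAnnotation]:
    """Trim lower-precedence spans so that no two domains overlap."""
    kept: list[DomainAnnotation] = []
    for dom in sorted(domains, key=lambda d: (-PRECEDENCE[d.label], d.start)):
        start, end = dom.start, dom.end
        for other in kept:
            if other.end <= start or other.start >= end:
                continue
            # trim the side that overlaps; drop if fully covered
            if other.start <= start and other.end >= end:
                start = end = -1
                break
            if other.start <= start:
                start = other.end
            elif other.end >= end:
                end = other.start
            else:  # other strictly inside: keep the left part
                end = other.start
        if start >= 0 and start < end:
            kept.append(replace(dom, start=start, end=end))
    return sorted(kept, key=lambda d: d.start)


def annotate_architecture(record: SeqRecord,
                          kld_mode: str = "strict",
                          caf_profile: CafProfile | None = DEFAULT_CAF_PROFILE,
                          cys_template: Sequence[tuple[int, int]] | None = None,
                          rpt_pmin: int = _repeats.DEFAULT_PMIN,
                          rpt_pmax: int = _repeats.DEFAULT_PMAX,
                          ) -> ArchitectureModel:
    """Compose all finders into a non-overlapping architecture."""
    _require_protein(record)
    seq = record.seq
    calls: list[DomainAnnotation] = []

    sp = find_signal_peptide(record)
    if sp:
        calls.append(sp)

    pkd_matches = find_pkd_motifs(record, max_mismatch=1)
    pkd = None
    if pkd_matches:
        lo = min(m.start for m in pkd_matches)
        hi = max(m.end for m in pkd_matches)
        pkd = DomainAnnotation(
            "PKD", lo, hi,
            evidence="motifs: " + ",".join(sorted({m.label for m in pkd_matches})),
        )
        calls.append(pkd)

    kld = find_kld(record, cys_template=cys_template, mode=kld_mode)
    if kld:
        calls.append(kld)

    tm_start = kld.end if kld else (pkd.end if pkd else 0)
    tm = find_tm(record, search_start=tm_start)
    if tm:
        calls.append(tm)

    # RPT: tandem structure between the PKD and KLD calls.
    if pkd and kld and kld.start - pkd.end >= 2 * rpt_pmin:
        try:
            model = _repeats.repeat_report(record, (pkd.end, kld.start),
                                           pmin=rpt_pmin, pmax=rpt_pmax)
        except (ValueError, _repeats.NoTandemStructureError):
            model = None
        if model is not None:
            first = model.unit_spans[0][0]
            last = model.unit_spans[-1][1]
            calls.append(DomainAnnotation(
                "RPT", first, last,
                evidence=f"period {model.period}, {model.n_units} units",
            ))

    calls = _resolve_overlaps(calls)

    by_label = {d.label: d for d in calls}
    sp, pkd = by_label.get("SP"), by_label.get("PKD")
    if sp and pkd and pkd.start > sp.end:
        ntr = DomainAnnotation("NTR", sp.end, pkd.start,
                               evidence="between SP and PKD")
        calls.append(ntr)
        if caf_profile is not None:
            caf = find_caf(record, (ntr.start, ntr.end), caf_profile)
            if caf:
                calls.append(caf)
    tm = by_label.get("TM")
    if tm and tm.end < len(seq):
        calls.append(DomainAnnotation("Cyt", tm.end, len(seq),
                                      evidence="C-terminal to TM"))

    calls = _resolve_overlaps(calls)
    ordered = [d.label for d in calls]
    rank = {lbl: i for i, lbl in enumerate(DOMAIN_ORDER)}
    in_order = all(rank[a] < rank[b] for a, b in zip(ordered, ordered[1:]))

    required = {"SP", "PKD", "KLD", "TM"}
    is_pkat = required <= set(ordered) and in_order

    flags = {}
    if pkd:
        # conserved cysteine just past the PKD span (PMEL/GPNMB dimerization
        # residue) is reported as a flag, not an extension of the span
        tail = seq[pkd.end:pkd.end + 10]
        if "C" in tail:
            flags["pkd_terminal_cysteine"] = pkd.end + tail.index("C") + 1
    dileu = find_dileucine_motif(record)
    if dileu:
        flags["dileucine"] = (dileu[0] + 1, dileu[1])

    return ArchitectureModel(record=record, domains=tuple(calls),
                             is_pkat=is_pkat, flags=flags)


def locate_variant(model: ArchitectureModel, position: int) -> str:
    """Domain label containing a 1-based residue position."""
    if not 1 <= position <= len(model.record.seq):
        raise ValueError(
            f"position {position} outside 1..{len(model.record.seq)}")
    pos0 = position - 1
    for d in model.domains:
        if d.contains(pos0):
            return d.label
    return "inter-domain"
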