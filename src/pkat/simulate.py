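"""Synthetic inputs with ground truth for every pipeline stage.

Each generator draws from a seeded ``numpy`` Generator, returns its output
together with a :class:`SyntheticTruth` record, and is byte-reproducible:
identical seed and parameters give identical outputs.

Backgrounds deliberately exclude the residues each detector keys on
(T/S/D/E inside repeat units so planted ladders stand out; C and P outside
planted motifs so cysteine chains and [LI][HY]DP never arise by accident).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Mapping, Sequence

import numpy as np

from pkat.architecture import (
    DEFAULT_CAF_PROFILE,
    DEFAULT_KLD_GAPS,
    NONPOLAR,
    SP_CHARGED,
)
from pkat.seq_io import AMINO_ACIDS, ExonTable, GeneTableRow, SeqRecord
from pkat.phylo import PhyloTree

# Background alphabets (sorted for determinism).
_GENERAL_BG = "".join(sorted(set(AMINO_ACIDS) - set("CP")))
_RPT_BG = "".join(sorted(set(AMINO_ACIDS) - set("TSDECP")))
_UNCHARGED = "".join(sorted(set(AMINO_ACIDS) - SP_CHARGED - set("CP")))
_NONPOLAR = "".join(sorted(NONPOLAR))
_CHARGED = "".join(sorted(SP_CHARGED))
_DNA = "ACGT"


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generator output."""

    architecture: dict[str, tuple[int, int]] | None = None
    repeat_period: int | None = None
    repeat_units: int | None = None
    unit_spans: tuple[tuple[int, int], ...] | None = None
    mutation_rate: float | None = None
    ladder_columns: dict[str, tuple[int, ...]] | None = None
    shared_counts: tuple[int, int] | None = None
    tree: PhyloTree | None = None
    exon_jitter: float | None = None
    within_tolerance: tuple[tuple[bool, ...], ...] | None = None
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {}
        for key in ("architecture", "repeat_period", "repeat_units",
                    "unit_spans", "mutation_rate", "ladder_columns",
                    "shared_counts", "exon_jitter", "within_tolerance",
                    "extra"):
            val = getattr(self, key)
            if val is not None and val != {}:
                out[key] = val
        if self.tree is not None:
            out["tree"] = self.tree.to_newick()
        return out


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def gen_rpt(period: int, n_units: int, mutation_rate: float,
            ladder_spec: Mapping[str, Sequence[int]] | None = None,
            seed: int = 0, strict_ladders: bool = True,
            unit_length_edits: Mapping[int, int] | None = None,
            ) -> tuple[SeqRecord, SyntheticTruth]:
    """Imperfect tandem repeat array with planted T/S and/or D/E ladders.

    ``ladder_spec`` maps "TS"/"DE" to column indices (< period). Ladder
    columns carry a class member in every unit before mutation; when
    ``strict_ladders`` they are never mutated. ``unit_length_edits`` maps a
    0-based unit index to a length delta (negative deletes residues from
    the unit's tail, positive inserts background residues).
    """
    if not 8 <= period <= 40:
        raise ValueError("period must be in 8..40")
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must be a fraction in [0, 1)")
    ladder_spec = dict(ladder_spec or {})
    for cls, cols in ladder_spec.items():
        if cls not in ("TS", "DE"):
            raise ValueError(f"unknown ladder class {cls!r}")
        if any(not 0 <= c < period for c in cols):
            raise ValueError("ladder columns must be < period")
    cols_ts = set(ladder_spec.get("TS", ()))
    cols_de = set(ladder_spec.get("DE", ()))
    if cols_ts & cols_de:
        raise ValueError("TS and DE ladder columns overlap")
    edits = dict(unit_length_edits or {})

    rng = np.random.default_rng(seed)
    base = list(_draw(rng, _RPT_BG, period))
    # ladder residues fixed per column so the zero-noise array is a perfect
    # repeat; mutations are what introduce unit-to-unit variation
    for c in sorted(cols_ts):
        base[c] = "TS"[rng.integers(0, 2)]
    for c in sorted(cols_de):
        base[c] = "DE"[rng.integers(0, 2)]

    units: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    ladder_cols = cols_ts | cols_de
    for u in range(n_units):
        unit = base.copy()
        if mutation_rate > 0:
            for c in range(period):
                if strict_ladders and c in ladder_cols:
                    continue
                if rng.random() < mutation_rate:
                    choices = _RPT_BG.replace(unit[c], "")
                    unit[c] = choices[rng.integers(0, len(choices))]
        text = "".join(unit)
        delta = edits.get(u, 0)
        if delta < 0:
            if -delta >= period:
                raise ValueError("cannot delete a whole unit")
            text = text[:delta]
        elif delta > 0:
            text = text + _draw(rng, _RPT_BG, delta)
        units.append(text)
        spans.append((pos, pos + len(text)))
        pos += len(text)

    seq = "".join(units)
    record = SeqRecord(id=f"rpt_p{period}_n{n_units}_s{seed}", seq=seq,
                       gene="RPT", moltype="protein")
    truth = SyntheticTruth(
        repeat_period=period, repeat_units=n_units,
        unit_spans=tuple(spans), mutation_rate=mutation_rate,
        ladder_columns={cls: tuple(sorted(cols))
                        for cls, cols in ladder_spec.items()},
    )
    return record, truth


# ---------------------------------------------------------------------------
# Full PKAT-like proteins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PkatParams:
    """Which domains to plant and their length ranges (inclusive)."""

    include_sp: bool = True
    include_caf: bool = True
    include_rpt: bool = True
    include_kld: bool = True
    include_tm: bool = True
    include_dileucine: bool = True
    sp_charge_pos: tuple[int, int] = (1, 13)
    sp_run: tuple[int, int] = (8, 18)
    ntr_len: tuple[int, int] = (40, 70)
    pkd_len: tuple[int, int] = (60, 90)
    rpt_period: tuple[int, int] = (10, 16)
    rpt_units: tuple[int, int] = (4, 8)
    rpt_mutation_rate: float = 0.0
    kld_gaps: tuple[int, ...] = DEFAULT_KLD_GAPS
    tm_len: tuple[int, int] = (18, 24)
    cyt_len: tuple[int, int] = (18, 30)

    def validate(self) -> None:
        lo, hi = self.sp_charge_pos
        if not 1 <= lo <= hi <= 13:
            raise ValueError("sp_charge_pos must lie within 1..13")
        if self.sp_run[0] < 8:
            raise ValueError("SP uncharged run must be >= 8")
        if self.sp_charge_pos[1] + 1 + self.sp_run[1] > 33:
            raise ValueError("SP total length would exceed 33")
        if len(self.kld_gaps) != 5:
            raise ValueError("kld_gaps needs exactly 5 gaps")
        if self.tm_len[0] < 15:
            raise ValueError("TM length must be >= 15")


def _randint(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def gen_pkat_protein(params: PkatParams | None = None, seed: int = 0,
                     ) -> tuple[SeqRecord, SyntheticTruth]:
    """Protein with a planted SP-NTR/CAF-PKD-[RPT]-KLD-TM-Cyt architecture.

    Every planted domain obeys the corresponding detector's rule exactly,
    and the truth records its span (0-based half-open).
    """
    params = params or PkatParams()
    params.validate()
    rng = np.random.default_rng(seed)
    arch: dict[str, tuple[int, int]] = {}
    parts: list[str] = []
    pos = 0

    def emit(text: str, label: str | None = None) -> None:
        nonlocal pos
        if label:
            arch[label] = (pos, pos + len(text))
        parts.append(text)
        pos += len(text)

    # SP: M + uncharged filler + charged + uncharged run; the next segment
    # begins with a charged terminator.
    if params.include_sp:
        c = _randint(rng, params.sp_charge_pos)
        run_hi = min(params.sp_run[1], 33 - c - 1)
        run = _randint(rng, (params.sp_run[0], max(params.sp_run[0], run_hi)))
        sp = ("M" + _draw(rng, _UNCHARGED, c - 1)
              + _CHARGED[rng.integers(0, len(_CHARGED))]
              + _draw(rng, _UNCHARGED, run))
        emit(sp, "SP")
    else:
        emit("M" + _draw(rng, _CHARGED + _CHARGED + _UNCHARGED, 6))

    # NTR starts with the charged residue that terminates the SP.
    ntr_len = _randint(rng, params.ntr_len)
    ntr = _CHARGED[rng.integers(0, len(_CHARGED))] + _draw(rng, _GENERAL_BG,
                                                           ntr_len - 1)
    if params.include_caf:
        caf = DEFAULT_CAF_PROFILE.consensus
        at = int(rng.integers(5, ntr_len - len(caf) - 2))
        ntr = ntr[:at] + caf + ntr[at + len(caf):]
        arch["CAF"] = (pos + at, pos + at + len(caf))
    emit(ntr, "NTR")

    # PKD: [LI][HY]DP early, WDFGDGS later; truth span covers both motifs.
    pkd_len = _randint(rng, params.pkd_len)
    lhdp = ("LI"[rng.integers(0, 2)] + "HY"[rng.integers(0, 2)] + "DP")
    body = _draw(rng, _GENERAL_BG, pkd_len)
    at1 = int(rng.integers(2, pkd_len // 3))
    at2 = int(rng.integers(pkd_len // 2, pkd_len - 9))
    body = (body[:at1] + lhdp + body[at1 + 4:at2] + "WDFGDGS"
            + body[at2 + 7:])
    arch["PKD"] = (pos + at1, pos + at2 + 7)
    emit(body)

    if params.include_rpt:
        period = _randint(rng, params.rpt_period)
        n_units = _randint(rng, params.rpt_units)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rpt_rec, rpt_truth = gen_rpt(
            period, n_units, params.rpt_mutation_rate,
            ladder_spec={"TS": (1,), "DE": (period - 2,)}, seed=sub_seed,
        )
        arch["RPT"] = (pos, pos + len(rpt_rec.seq))
        emit(rpt_rec.seq)
    else:
        rpt_truth = None

    if params.include_kld:
        gaps = params.kld_gaps
        kld = "C"
        for g in gaps:
            kld += _draw(rng, _GENERAL_BG, g - 1) + "C"
        emit(kld, "KLD")

    # polar/charged buffers around the TM keep its window boundaries crisp:
    # with >= 4 non-nonpolar residues on each side, a >= 90%-nonpolar window
    # can over-extend a planted 18-24 aa TM by at most 2 residues in total
    polar_buffer = _CHARGED + "NQ"
    emit(_draw(rng, polar_buffer, 5))

    if params.include_tm:
        tm = _draw(rng, _NONPOLAR, _randint(rng, params.tm_len))
        emit(tm, "TM")
        emit(_draw(rng, polar_buffer, 5))

    cyt_len = _randint(rng, params.cyt_len)
    cyt_bg = _GENERAL_BG.replace("L", "")
    cyt = _draw(rng, cyt_bg, cyt_len)
    if params.include_dileucine:
        # middle positions avoid D/E and the following residue avoids I/L
        # so the planted hexamer is the only (and last) match
        mid_bg = "".join(sorted(set(cyt_bg) - set("DE")))
        motif = ("DE"[rng.integers(0, 2)] + _draw(rng, mid_bg, 3)
                 + "L" + "LI"[rng.integers(0, 2)])
        after = _draw(rng, "".join(sorted(set(cyt_bg) - set("I"))), 1)
        at = cyt_len - 8
        cyt = cyt[:at] + motif + after + cyt[at + 7:]
        arch["dileucine"] = (pos + at, pos + at + 6)
    emit(cyt)
    arch["Cyt"] = arch.get("TM", (pos, pos))[1], pos
    if not params.include_tm:
        arch.pop("Cyt")

    seq = "".join(parts)
    record = SeqRecord(id=f"pkat_s{seed}", seq=seq, gene="PKAT-sim",
                       moltype="protein")
    truth = SyntheticTruth(
        architecture=arch,
        repeat_period=rpt_truth.repeat_period if rpt_truth else None,
        repeat_units=rpt_truth.repeat_units if rpt_truth else None,
        ladder_columns=rpt_truth.ladder_columns if rpt_truth else None,
        mutation_rate=params.rpt_mutation_rate,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Gene neighborhoods
# ---------------------------------------------------------------------------

def gen_neighborhoods(n_shared_a: int, n_shared_b: int, window: int = 100,
                      decoys: int = 20, seed: int = 0, shared_both: int = 0,
                      ) -> tuple[dict[str, list[GeneTableRow]], SyntheticTruth]:
    """Three gene tables whose focal neighborhood shares exactly
    ``n_shared_a`` symbols with reference A and ``n_shared_b`` with B.

    No symbol is shared with both references unless ``shared_both`` > 0.
    Returns ``{"focal": [...], "ref_a": [...], "ref_b": [...]}`` tables;
    the focal gene is ``FOCAL1``, references ``REFA1``/``REFB1``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    total = n_shared_a + n_shared_b + shared_both + decoys
    if total > 2 * window:
        raise ValueError("neighborhood contents exceed 2 x window")
    rng = np.random.default_rng(seed)
    sym_a = [f"SHA{i:04d}" for i in range(n_shared_a)]
    sym_b = [f"SHB{i:04d}" for i in range(n_shared_b)]
    sym_ab = [f"SHAB{i:04d}" for i in range(shared_both)]
    sym_dec = [f"DEC{i:04d}" for i in range(decoys)]

    focal_syms = sym_a + sym_b + sym_ab + sym_dec
    order = rng.permutation(len(focal_syms))
    focal_syms = [focal_syms[i] for i in order]
    insert_at = int(rng.integers(0, len(focal_syms) + 1))
    focal_syms.insert(insert_at, "FOCAL1")
    focal_table = [GeneTableRow("chrF", i, s) for i, s in enumerate(focal_syms)]

    def ref_table(name: str, chrom: str, shared: list[str]) -> list[GeneTableRow]:
        own_dec = [f"{name}DEC{i:04d}" for i in range(decoys)]
        syms = shared + sym_ab + own_dec
        order = rng.permutation(len(syms))
        syms = [syms[i] for i in order]
        at = int(rng.integers(0, len(syms) + 1))
        syms.insert(at, f"{name}1")
        return [GeneTableRow(chrom, i, s) for i, s in enumerate(syms)]

    tables = {
        "focal": focal_table,
        "ref_a": ref_table("REFA", "chrA", sym_a),
        "ref_b": ref_table("REFB", "chrB", sym_b),
    }
    truth = SyntheticTruth(
        shared_counts=(n_shared_a + shared_both, n_shared_b + shared_both),
        extra={"focal_gene": "FOCAL1", "ref_a_gene": "REFA1",
               "ref_b_gene": "REFB1", "window": window},
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Sequence families along a tree
# ---------------------------------------------------------------------------

def gen_ortholog_family(tree: PhyloTree, root_seq: SeqRecord,
                        subst_rate: float, seed: int = 0,
                        ) -> tuple[list[SeqRecord], SyntheticTruth]:
    """Evolve ``root_seq`` along ``tree`` by i.i.d. per-site substitution.

    Along a branch of length t each site substitutes with probability
    ``1 - exp(-subst_rate * t)``, to a uniformly random different residue.
    No indels, so the true alignment is columnwise.
    """
    if not root_seq.seq:
        raise ValueError("root sequence must be non-empty")
    alphabet = _DNA if root_seq.moltype == "dna" else AMINO_ACIDS
    rng = np.random.default_rng(seed)
    leaves: list[SeqRecord] = []

    def evolve(seq: str, node) -> None:
        for child in sorted(node.children, key=lambda c: min(c.leaf_names())):
            if child.length < 0:
                raise ValueError("branch lengths must be >= 0")
            p = 1.0 - exp(-subst_rate * child.length)
            chars = list(seq)
            if p > 0:
                hits = np.nonzero(rng.random(len(chars)) < p)[0]
                for i in hits:
                    choices = alphabet.replace(chars[i], "")
                    chars[i] = choices[rng.integers(0, len(choices))]
            child_seq = "".join(chars)
            if child.is_leaf:
                leaves.append(SeqRecord(id=child.name, seq=child_seq,
                                        moltype=root_seq.moltype))
            else:
                evolve(child_seq, child)

    evolve(root_seq.seq, tree.root)
    truth = SyntheticTruth(tree=tree, mutation_rate=subst_rate)
    return leaves, truth


# ---------------------------------------------------------------------------
# Exon tables
# ---------------------------------------------------------------------------

def gen_exon_tables(reference_lengths: Sequence[int], n_orthologs: int,
                    jitter_sd: float, outlier_prob: float = 0.0,
                    seed: int = 0, tolerance: float = 0.05,
                    ) -> tuple[list[ExonTable], SyntheticTruth]:
    """Ortholog exon tables with multiplicative length jitter.

    Each ortholog's exon k is ``round(reference * (1 + noise))`` with
    Gaussian noise (sd ``jitter_sd``); with probability ``outlier_prob``
    the noise is instead a large offset (10-30%). Truth records which
    lengths land within ``tolerance`` of the reference.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not reference_lengths or any(x <= 0 for x in reference_lengths):
        raise ValueError("reference lengths must be positive")
    rng = np.random.default_rng(seed)
    tables: list[ExonTable] = []
    within: list[tuple[bool, ...]] = []
    for o in range(n_orthologs):
        lengths = []
        flags = []
        for ref in reference_lengths:
            if outlier_prob > 0 and rng.random() < outlier_prob:
                noise = float(rng.uniform(0.1, 0.3)) * (1 if rng.random() < 0.5 else -1)
            else:
                noise = float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0
            length = max(1, round(ref * (1.0 + noise)))
            lengths.append(length)
            flags.append(abs(length - ref) / ref <= tolerance + 1e-9)
        tables.append(ExonTable(gene=f"orth{o}", species=f"sp{o}",
                                exon_lengths=tuple(lengths)))
        within.append(tuple(flags))
    truth = SyntheticTruth(exon_jitter=jitter_sd,
                           within_tolerance=tuple(within),
                           extra={"reference_lengths": list(reference_lengths),
                                  "tolerance": tolerance})
    return tables, truth
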