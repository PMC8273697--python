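import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkat.repeats import (
    NoTandemStructureError,
    align_units,
    detect_ladders,
    detect_period,
    motif_census,
    repeat_report,
    segment_units,
)
from pkat.scoring import normalized_protein_score
from pkat.seq_io import SeqRecord
from pkat.simulate import gen_rpt


def oracle_period(seq: str, pmin: int, pmax: int, tol: float = 0.1) -> int:
    """Independent exhaustive scan: smallest period scoring within ``tol``
    of the best mean pair-normalized similarity."""
    scores = {}
    for p in range(pmin, min(pmax, len(seq) // 2) + 1):
        pairs = [(seq[i], seq[i + p]) for i in range(len(seq) - p)]
        scores[p] = sum(normalized_protein_score(a, b) for a, b in pairs) / len(pairs)
    best = max(scores.values())
    return min(p for p, s in scores.items() if s >= best - tol)


class TestDetectPeriod:
    def test_perfect_repeat(self):
        rec = SeqRecord(id="x", seq="ABCABCABCABC".replace("B", "R"),
                        moltype="protein")
        period, score = detect_period(rec, pmin=2, pmax=6)
        assert period == 3
        assert score == pytest.approx(1.0)

    def test_noisy_plant_recovers_truth(self):
        rec, truth = gen_rpt(9, 8, 0.05, seed=3)
        period, _ = detect_period(rec)
        assert period == truth.repeat_period == 9

    def test_region_too_short(self):
        rec = SeqRecord(id="x", seq="MDLVWKRA", moltype="protein")
        with pytest.raises(ValueError, match="too short"):
            detect_period(rec, pmin=8, pmax=40)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_equals_exhaustive_oracle(self, seed):
        # inputs <= 200 residues with genuine repeat structure
        rec, _ = gen_rpt(period=8 + seed % 9, n_units=3 + seed % 10,
                         mutation_rate=0.08, seed=seed)
        assert len(rec.seq) <= 200
        period, _ = detect_period(rec, pmin=2, pmax=40)
        assert period == oracle_period(rec.seq, 2, 40)

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=20,
                       max_size=200))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_on_arbitrary_text(self, seq):
        rec = SeqRecord(id="x", seq=seq, moltype="protein")
        period, _ = detect_period(rec, pmin=2, pmax=len(seq) // 2)
        assert period == oracle_period(seq, 2, len(seq) // 2)


class TestSegmentUnits:
    def test_perfect_13mers(self, clean_rpt):
        rec, truth = clean_rpt
        spans = segment_units(rec, None, 13)
        assert len(spans) == 10
        assert all(b - a == 13 for a, b in spans)
        assert spans == truth.unit_spans

    def test_planted_deletion_shortens_one_unit(self):
        rec, truth = gen_rpt(13, 8, 0.0, seed=5, unit_length_edits={3: -3})
        spans = segment_units(rec, None, 13)
        lengths = [b - a for a, b in spans]
        assert len(spans) == 8
        assert lengths == [13, 13, 13, 10, 13, 13, 13, 13]
        assert spans == truth.unit_spans

    def test_too_short_for_two_units(self):
        rec = SeqRecord(id="x", seq="MDLVWKRAGHTYMDLVWK", moltype="protein")
        with pytest.raises(ValueError):
            segment_units(rec, None, 12)

    def test_reversed_region_same_period_and_count(self, noisy_rpt):
        rec, _ = noisy_rpt
        rev = SeqRecord(id="rev", seq=rec.seq[::-1], moltype="protein")
        assert detect_period(rec)[0] == detect_period(rev)[0]
        assert len(segment_units(rec, None, 13)) == len(
            segment_units(rev, None, 13))


class TestAlignUnits:
    def test_hand_counted_consensus(self):
        rows, consensus, freqs = align_units(["TAT", "TAT", "TAC"])
        assert consensus == "TAT"
        assert freqs[2] == {"C": pytest.approx(1 / 3), "T": pytest.approx(2 / 3)}

    def test_fifty_fifty_tie_is_x(self):
        _, consensus, _ = align_units(["TA", "TG"])
        assert consensus == "TX"

    def test_exactly_half_unique_top_is_consensus(self):
        # A has 50% frequency and is the unique most frequent residue
        _, consensus, _ = align_units(["AR", "AR", "GR", "CR"])
        assert consensus[0] == "A"

    def test_below_half_is_x(self):
        _, consensus, _ = align_units(["AR", "GR", "CR"])
        assert consensus[0] == "X"

    def test_freqs_sum_to_one(self, noisy_rpt):
        rec, _ = noisy_rpt
        model = repeat_report(rec)
        for col in model.column_freqs:
            assert sum(col.values()) == pytest.approx(1.0)

    def test_consensus_length_matches_columns(self, noisy_rpt):
        rec, _ = noisy_rpt
        model = repeat_report(rec)
        assert len(model.consensus) == len(model.unit_alignment[0])
        assert len({len(r) for r in model.unit_alignment}) == 1

    def test_unique_top_at_exactly_half_wins(self):
        # G is at exactly 50% but uniquely most frequent -> consensus G
        _, consensus, _ = align_units(["AK", "GK", "CK", "GK"])
        assert consensus[0] == "G"

    def test_raising_frequency_flips_consensus(self):
        # monotonicity: pushing a residue above 50% makes it the consensus
        _, cons_before, _ = align_units(["AK", "GK", "CK"])
        assert cons_before[0] == "X"
        _, cons_after, _ = align_units(["GK", "GK", "CK"])
        assert cons_after[0] == "G"


class TestLadders:
    def test_full_occupancy_column(self):
        cols = detect_ladders(["TAAAA"] * 4, "TS")
        assert len(cols) == 1
        assert cols[0].column == 0
        assert cols[0].occupancy == 1.0

    def test_planted_de_ladder_recovered(self):
        rec, truth = gen_rpt(13, 8, 0.05, ladder_spec={"DE": (2, 9)}, seed=3)
        model = repeat_report(rec)
        found = tuple(c.column for c in model.ladders["DE"])
        assert found == truth.ladder_columns["DE"] == (2, 9)

    def test_no_ladder_when_class_absent(self):
        rec, _ = gen_rpt(13, 8, 0.0, seed=2)  # background excludes T/S/D/E
        model = repeat_report(rec)
        assert not model.has_clear_ladder("TS")
        assert not model.has_clear_ladder("DE")

    def test_occupancy_invariant_under_unit_permutation(self):
        units = ["TAAAA", "TAAGA", "AAAAA", "TACAA"]
        a = detect_ladders(units, "TS", 0.5)
        b = detect_ladders(list(reversed(units)), "TS", 0.5)
        assert a == b


class TestMotifCensus:
    def test_simple_count(self):
        assert motif_census(["GTTPTAE", "GTTPTQE", "AAAAAAA"], "GTT") == 2

    def test_degenerate_classes_and_wildcard(self):
        units = ["TAAATAAD", "TRRRTKKE", "AAAAAAAA"]
        assert motif_census(units, "TXXXTXX[DE]") == 2

    def test_equals_brute_force(self):
        import itertools, random
        rng = random.Random(0)
        units = ["".join(rng.choice("TPAEDG") for _ in range(12))
                 for _ in range(30)]
        pattern_hits = 0
        for u in units:  # brute-force scan for TXXXTXX[DE]
            hit = any(u[i] == "T" and u[i + 4] == "T" and u[i + 7] in "DE"
                      for i in range(len(u) - 7))
            pattern_hits += hit
        assert motif_census(units, "TXXXTXX[DE]") == pattern_hits

    def test_paired_motif_with_spacer(self):
        units = ["GATGCAAAGCT", "GATGCAAAAAAAAAAAGCT", "GATGCAAA", "AAAGCT"]
        assert motif_census(units, "GATGC...GCT", max_spacer=5) == 1
        assert motif_census(units, "GATGC...GCT", max_spacer=20) == 2

    def test_empty_pattern_error(self):
        with pytest.raises(ValueError):
            motif_census(["AAA"], "")

    def test_paired_requires_spacer(self):
        with pytest.raises(ValueError):
            motif_census(["AAA"], "GATGC...GCT")


class TestRepeatReport:
    def test_full_pipeline_on_plant(self, noisy_rpt):
        rec, truth = noisy_rpt
        model = repeat_report(rec, motifs=[("GTT", None)])
        assert model.period == truth.repeat_period
        assert abs(model.n_units - truth.repeat_units) <= 1
        assert model.has_clear_ladder("TS")
        assert model.has_clear_ladder("DE")
        assert "GTT" in model.motif_counts

    def test_rejects_unstructured_sequence(self):
        rng_seq = ("MKWVTFISLLFLFSSAYSRGVFRRDAHKSEVAHRFKDLGEENFKALVLIA"
                   "FAQYLQQCPFEDHVKLVNEVTEFAK")
        rec = SeqRecord(id="alb", seq=rng_seq, moltype="protein")
        with pytest.raises(NoTandemStructureError):
            repeat_report(rec)

    def test_deterministic(self, noisy_rpt):
        rec, _ = noisy_rpt
        a = repeat_report(rec)
        b = repeat_report(rec)
        assert a.unit_spans == b.unit_spans
        assert a.consensus == b.consensus
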