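import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkat.architecture import (
    ArchitectureModel,
    DomainAnnotation,
    ResidueClassMap,
    annotate_architecture,
    find_dileucine_motif,
    find_kld,
    find_pkd_motifs,
    find_signal_peptide,
    find_tm,
    kld_template,
    locate_variant,
)
from pkat.seq_io import SeqRecord
from pkat.simulate import PkatParams, gen_pkat_protein


def brute_force_dileucine(seq: str, tail_window: int):
    """Exhaustive scan of every 6-mer for [DE]XXXL[LI], last match in tail."""
    tail_start = max(0, len(seq) - tail_window)
    last = None
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if w[0] in "DE" and w[4] == "L" and w[5] in "LI" and i >= tail_start:
            last = (i, i + 6)
    return last


class TestResidueClassMap:
    def test_default_partitions_twenty(self):
        m = ResidueClassMap()
        assert m.of("L") == "nonpolar"
        assert m.of("S") == "polar_uncharged"
        assert m.of("D") == "acidic"
        assert m.of("K") == "basic"

    def test_rejects_overlapping_classes(self):
        with pytest.raises(ValueError):
            ResidueClassMap(nonpolar=frozenset("GAVLIPFMWS"))


class TestSignalPeptide:
    def test_minimal_satisfying_case(self):
        # M, charge at 2, ten leucines, terminated by D
        rec = SeqRecord(id="x", seq="MKLLLLLLLLLLDAAAAAAAAAA",
                        moltype="protein")
        sp = find_signal_peptide(rec)
        assert sp is not None
        assert (sp.start, sp.end) == (0, 12)

    def test_poly_charged_n_terminus_has_no_sp(self):
        rec = SeqRecord(id="x", seq="MDKRDEKRDEKRDEKRDEKRDEKRDE",
                        moltype="protein")
        assert find_signal_peptide(rec) is None

    def test_histidine_does_not_terminate(self):
        # H is treated as uncharged: run continues through it
        rec = SeqRecord(id="x", seq="MKLLLLHLLLLLDAAAAAAAAAA", moltype="protein")
        sp = find_signal_peptide(rec)
        assert sp is not None and sp.end == 12

    def test_short_run_rejected(self):
        # K at 1 starts a run of only 5; D at 7 starts a run whose
        # terminator lies beyond the 33-residue cap
        rec = SeqRecord(id="x", seq="MKLLLLLD" + "A" * 30 + "KAAA",
                        moltype="protein")
        assert find_signal_peptide(rec) is None

    def test_dna_record_rejected(self):
        rec = SeqRecord(id="x", seq="ACGTACGT", moltype="dna")
        with pytest.raises(ValueError, match="not a protein"):
            find_signal_peptide(rec)

    def test_recovery_on_100_plants(self):
        hits = 0
        for seed in range(100):
            rec, truth = gen_pkat_protein(seed=seed)
            sp = find_signal_peptide(rec)
            lo, hi = truth.architecture["SP"]
            if sp and abs(sp.start - lo) <= 2 and abs(sp.end - hi) <= 2:
                hits += 1
        assert hits >= 95


class TestDileucine:
    def test_terminal_match(self):
        rec = SeqRecord(id="x", seq="MAAAAAAAAAAERRRLL", moltype="protein")
        assert find_dileucine_motif(rec) == (11, 17)

    def test_leucines_substituted_no_match(self):
        # emulates a C-terminus whose two leucines are replaced
        rec = SeqRecord(id="x", seq="MAAAAAAAAAAERRRAA", moltype="protein")
        assert find_dileucine_motif(rec) is None

    def test_tail_window_too_small(self):
        rec = SeqRecord(id="x", seq="MAAAAERRRLL", moltype="protein")
        with pytest.raises(ValueError):
            find_dileucine_motif(rec, tail_window=5)

    def test_outside_tail_window_ignored(self):
        rec = SeqRecord(id="x", seq="ERRRLL" + "A" * 50, moltype="protein")
        assert find_dileucine_motif(rec, tail_window=20) is None

    @given(seq=st.text(alphabet="ADELRIK", min_size=6, max_size=80),
           tail=st.integers(6, 60))
    @settings(max_examples=200, deadline=None)
    def test_equals_brute_force_scan(self, seq, tail):
        rec = SeqRecord(id="x", seq=seq, moltype="protein")
        assert find_dileucine_motif(rec, tail) == brute_force_dileucine(seq, tail)


class TestPkdMotifs:
    def test_exact_core_motif(self):
        seq = "A" * 50 + "WDFGDGS" + "A" * 20
        rec = SeqRecord(id="x", seq=seq, moltype="protein")
        matches = [m for m in find_pkd_motifs(rec) if m.label == "WDFGDGS"]
        assert len(matches) == 1
        assert matches[0].start == 50

    def test_degenerate_four_mer_semantics(self):
        rec = SeqRecord(id="x", seq="AAALHDPAAAIYDPAAAVHDPAAA",
                        moltype="protein")
        hits = [m.start for m in find_pkd_motifs(rec)
                if m.label == "[LI][HY]DP"]
        assert hits == [3, 10]  # VHDP does not match

    def test_one_mismatch_allowed(self):
        rec = SeqRecord(id="x", seq="AAAAWDFGDGTAAAA", moltype="protein")
        labels = [m for m in find_pkd_motifs(rec, max_mismatch=1)
                  if m.label == "WDFGDGS"]
        assert len(labels) == 1 and labels[0].mismatches == 1
        assert not [m for m in find_pkd_motifs(rec, max_mismatch=0)
                    if m.label == "WDFGDGS"]


class TestKld:
    def test_planted_kld_recovered(self, pkat_protein):
        rec, truth = pkat_protein
        kld = find_kld(rec)
        assert kld is not None
        assert (kld.start, kld.end) == truth.architecture["KLD"]

    def test_cysteine_free_sequence(self):
        rec = SeqRecord(id="x", seq="MAGAGAGAGAGAGAGAGAGA", moltype="protein")
        assert find_kld(rec) is None

    def test_five_cysteine_near_miss(self):
        # build a KLD with the default gaps, then remove one internal cysteine
        from pkat.architecture import DEFAULT_KLD_GAPS
        seq = "C"
        for g in DEFAULT_KLD_GAPS:
            seq += "A" * (g - 1) + "C"
        cys_positions = [i for i, ch in enumerate(seq) if ch == "C"]
        third = cys_positions[2]
        broken = seq[:third] + "A" + seq[third + 1:]
        rec = SeqRecord(id="x", seq="M" + broken + "AAAAA", moltype="protein")
        assert find_kld(rec, mode="strict") is None
        weak = find_kld(rec, mode="weak")
        assert weak is not None and "weak" in weak.evidence

    def test_bad_template_length(self):
        rec = SeqRecord(id="x", seq="MCCCCCC", moltype="protein")
        with pytest.raises(ValueError, match="5"):
            find_kld(rec, cys_template=((1, 2), (1, 2)))

    def test_template_builder(self):
        bands = kld_template((10, 20, 5, 12, 8), tolerance=3)
        assert bands[0] == (7, 13)
        assert bands[2] == (2, 8)


class TestTm:
    def test_long_leucine_run(self):
        seq = "M" + "QENK" * 10 + "L" * 20 + "QENK" * 3
        rec = SeqRecord(id="x", seq=seq, moltype="protein")
        tm = find_tm(rec)
        assert tm is not None
        assert rec.seq[tm.start:tm.end] == "L" * 20

    def test_most_cterminal_run_wins_tie(self):
        seq = "MEEE" + "L" * 18 + "QENKDERK" * 4 + "V" * 18 + "QENK"
        rec = SeqRecord(id="x", seq=seq, moltype="protein")
        tm = find_tm(rec)
        assert rec.seq[tm.start:tm.end] == "V" * 18

    def test_no_window_below_min_len(self):
        rec = SeqRecord(id="x", seq="M" + "LQ" * 30, moltype="protein")
        assert find_tm(rec) is None

    def test_recovery_on_100_plants(self):
        hits = 0
        for seed in range(100):
            rec, truth = gen_pkat_protein(seed=seed)
            tm = find_tm(rec, search_start=truth.architecture["KLD"][1])
            lo, hi = truth.architecture["TM"]
            if tm and abs(tm.start - lo) <= 2 and abs(tm.end - hi) <= 2:
                hits += 1
        assert hits >= 95


class TestAnnotate:
    def test_full_plant_recovers_all_labels_in_order(self):
        rec, truth = gen_pkat_protein(seed=7)
        model = annotate_architecture(rec)
        assert model.labels() == ("SP", "NTR", "CAF", "PKD", "RPT", "KLD",
                                  "TM", "Cyt")
        assert model.is_pkat

    def test_no_rpt_gives_gpnmb_style_model(self):
        rec, _ = gen_pkat_protein(PkatParams(include_rpt=False), seed=7)
        model = annotate_architecture(rec)
        assert "RPT" not in model.labels()
        assert model.is_pkat  # GPNMB-style: PKAT without RPT

    def test_omitting_dileucine_motif(self):
        rec, _ = gen_pkat_protein(PkatParams(include_dileucine=False), seed=7)
        assert find_dileucine_motif(rec) is None

    def test_unstructured_protein_not_pkat(self):
        rec = SeqRecord(id="x", seq="MAGAGAGAGAGAGAGAGAGAHHHH",
                        moltype="protein")
        model = annotate_architecture(rec)
        assert not model.is_pkat

    def test_domains_never_overlap(self):
        for seed in range(25):
            rec, _ = gen_pkat_protein(seed=seed)
            model = annotate_architecture(rec)
            doms = sorted(model.domains, key=lambda d: d.start)
            for a, b in zip(doms, doms[1:]):
                assert a.end <= b.start

    def test_position_stable_under_cterminal_extension(self):
        # SP/PKD/KLD calls must not move when unrelated sequence is appended
        rec, _ = gen_pkat_protein(seed=3)
        ext = SeqRecord(id="ext", seq=rec.seq + "NQNQNQNQNQ", moltype="protein")
        for finder in (find_signal_peptide, find_kld):
            a, b = finder(rec), finder(ext)
            assert (a.start, a.end) == (b.start, b.end)

    def test_sweep_is_pkat_and_boundaries(self):
        good = 0
        for seed in range(50):
            rec, truth = gen_pkat_protein(seed=seed)
            model = annotate_architecture(rec)
            ok = model.is_pkat
            for lbl in ("SP", "KLD", "TM"):
                d, (lo, hi) = model.get(lbl), truth.architecture[lbl]
                ok = ok and d and abs(d.start - lo) <= 2 and abs(d.end - hi) <= 2
            good += bool(ok)
        assert good == 50


class TestLocateVariant:
    @pytest.fixture
    def model(self):
        rec, _ = gen_pkat_protein(seed=7)
        return annotate_architecture(rec)

    def test_position_one_is_sp(self, model):
        assert locate_variant(model, 1) == "SP"

    def test_each_domain_maps_back(self, model):
        for d in model.domains:
            assert locate_variant(model, d.start1) == d.label
            assert locate_variant(model, d.end1) == d.label

    def test_gap_positions_are_interdomain(self, model):
        covered = {p for d in model.domains
                   for p in range(d.start, d.end)}
        gaps = [p for p in range(len(model.record.seq)) if p not in covered]
        assert gaps, "fixture should leave at least one inter-domain residue"
        assert locate_variant(model, gaps[0] + 1) == "inter-domain"

    def test_out_of_range(self, model):
        with pytest.raises(ValueError):
            locate_variant(model, 0)
        with pytest.raises(ValueError):
            locate_variant(model, len(model.record.seq) + 1)


class TestDomainAnnotation:
    def test_one_based_reporting(self):
        d = DomainAnnotation("SP", 0, 24)
        assert (d.start1, d.end1) == (1, 24)

    def test_rejects_unknown_label(self):
        with pytest.raises(ValueError):
            DomainAnnotation("XX", 0, 5)
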