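"""Divergence, lineage polarisation, dinucleotide masking, consensus calling."""

import numpy as np
import pytest

from palinconv.evo import (
    ARM,
    SPACER,
    Lineage,
    NO_CALL,
    RegionMask,
    TriadAlignment,
    WsClass,
    assign_lineage,
    collect_replacements,
    consensus_from_pileup,
    gc_content_test,
    mask_dinucleotide_contexts,
    region_divergence,
    replacement_table,
    summarize_replacements,
)


def two_region_mask(arm_len, spacer_len):
    return RegionMask([(0, arm_len, ARM), (arm_len, arm_len + spacer_len, SPACER)])


class TestRegionDivergence:
    def test_counts_substitutions_per_region(self):
        #            arm....  spacer..
        a = "ACGTACGT" + "AAAATTTT"
        b = "ACGAACGT" + "AATATTTA"
        div = region_divergence(a, b, two_region_mask(8, 8))
        arm = div[div.region == ARM].iloc[0]
        spc = div[div.region == SPACER].iloc[0]
        assert arm.n_substitutions == 1 and arm.ungapped_length == 8
        assert spc.n_substitutions == 2
        assert arm.divergence_pct == pytest.approx(12.5)

    def test_gapped_columns_excluded_from_both_counts(self):
        a = "AC-TACGT"
        b = "ACG-ACGA"
        div = region_divergence(a, b, RegionMask([(0, 8, ARM)]))
        row = div.iloc[0]
        assert row.ungapped_length == 6
        assert row.n_substitutions == 1

    def test_identical_sequences_have_zero_divergence(self):
        a = "ACGTACGTACGT" * 4
        div = region_divergence(a, a, two_region_mask(24, 24))
        assert (div.divergence_pct == 0).all()

    def test_symmetric_in_sequence_order(self):
        a, b = "ACGTACGTAAAA", "ACCTACGTATAA"
        m = two_region_mask(6, 6)
        d1 = region_divergence(a, b, m)
        d2 = region_divergence(b, a, m)
        assert (d1.n_substitutions == d2.n_substitutions).all()

    def test_arm_vs_spacer_contrast_attached(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, 2000))
        b_list = list(a)
        # plant 10 arm and 60 spacer substitutions
        for i in range(0, 10):
            b_list[i * 10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b_list[i * 10]]
        for i in range(60):
            pos = 1000 + i * 15
            b_list[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[b_list[pos]]
        div = region_divergence(a, "".join(b_list), two_region_mask(1000, 1000))
        assert div.attrs["arm_vs_spacer_p"] < 1e-6


class TestAssignLineage:
    @pytest.mark.parametrize(
        "h,c,g,lineage,change,ws",
        [
            ("A", "G", "G", Lineage.HUMAN, ("G", "A"), WsClass.S_TO_W),
            ("T", "C", "T", Lineage.CHIMP, ("T", "C"), WsClass.W_TO_S),
            ("A", "T", "T", Lineage.HUMAN, ("T", "A"), WsClass.W_TO_W),
        ],
    )
    def test_outgroup_polarisation(self, h, c, g, lineage, change, ws):
        rec = assign_lineage(h, c, g)
        assert rec.lineage is lineage
        assert (rec.from_base, rec.to_base) == change
        assert rec.ws is ws

    def test_identical_column_is_none(self):
        assert assign_lineage("A", "A", "A") is None

    def test_three_way_difference_unassigned(self):
        assert assign_lineage("A", "G", "T").lineage is Lineage.UNASSIGNED

    def test_gorilla_only_difference_unassigned(self):
        assert assign_lineage("A", "A", "G").lineage is Lineage.UNASSIGNED

    def test_non_acgt_symbol_raises(self):
        with pytest.raises(ValueError):
            assign_lineage("N", "A", "A")

    def test_outgroup_identity_property(self):
        # replacing gorilla by the human sequence leaves no assignable
        # human-lineage replacement at any two-state column
        rng = np.random.default_rng(1)
        bases = "ACGT"
        for _ in range(200):
            h, c = rng.choice(list(bases)), rng.choice(list(bases))
            rec = assign_lineage(h, c, h)
            assert rec is None or rec.lineage is not Lineage.HUMAN


class TestDinucleotideMasking:
    def _triad(self, seq):
        return TriadAlignment(seq, seq, seq)

    def test_cpg_masks_both_members(self):
        masked = mask_dinucleotide_contexts(self._triad("ACGA"))
        assert list(masked) == [False, True, True, False]

    def test_all_t_has_no_context(self):
        masked = mask_dinucleotide_contexts(self._triad("TTTT"))
        assert not masked.any()

    def test_tpg_and_cpa_also_masked(self):
        assert mask_dinucleotide_contexts(self._triad("ATGT"))[1:3].all()
        assert mask_dinucleotide_contexts(self._triad("TCAT"))[1:3].all()

    def test_context_in_any_species_masks_column(self):
        triad = TriadAlignment("ATTA", "ACGA", "ATTA")
        assert mask_dinucleotide_contexts(triad)[1:3].all()

    def test_gaps_skipped_when_reading_dinucleotides(self):
        # C and G are sequence-adjacent across the gap: still a CpG
        triad = TriadAlignment("AC-GA", "AC-GA", "AC-GA")
        masked = mask_dinucleotide_contexts(triad)
        assert masked[1] and masked[3] and not masked[2]

    def test_masking_only_reduces_counts(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 600)) for _ in range(3)]
        triad = TriadAlignment(*seqs)
        mask = two_region_mask(300, 300)
        raw, raw_denom, _ = collect_replacements(triad, mask, None)
        dmask = mask_dinucleotide_contexts(triad)
        cut, cut_denom, _ = collect_replacements(triad, mask, dmask)
        assert len(cut) <= len(raw)
        assert cut_denom["n"].sum() <= raw_denom["n"].sum()


class TestReplacementTable:
    @pytest.mark.parametrize(
        "n_ws,w_nt,n_sw,s_nt,pct_ws,ratio",
        [
            (235, 51201, 161, 32892, 0.46, 1.07),   # human arm
            (72, 19687, 124, 11404, 0.37, 2.97),    # human spacer
            (366, 51201, 181, 32892, 0.71, 0.77),   # chimp arm
        ],
    )
    def test_summary_arithmetic(self, n_ws, w_nt, n_sw, s_nt, pct_ws, ratio):
        s = summarize_replacements(n_ws, w_nt, n_sw, s_nt)
        assert s["pct_ws"] == pytest.approx(pct_ws, abs=0.005)
        assert s["ratio_to_w_over_to_s"] == pytest.approx(ratio, abs=0.005)

    def test_symmetric_rates_give_unit_ratio(self):
        s = summarize_replacements(10, 1000, 20, 2000)
        assert s["ratio_to_w_over_to_s"] == pytest.approx(1.0)

    def test_zero_denominator_reported_as_none(self):
        s = summarize_replacements(5, 0, 3, 100)
        assert s["pct_ws"] is None and s["ratio_to_w_over_to_s"] is None

    def test_class_counts_sum_to_total_per_lineage(self):
        from palinconv.simulate import SimParams, simulate_triad

        triad, mask, _ = simulate_triad(SimParams(seed=4, arm_length=3000,
                                                  spacer_length=1500))
        records, _, _ = collect_replacements(triad, mask, None)
        table = replacement_table(triad, mask)
        for row in table.itertuples():
            lineage = Lineage(row.lineage)
            recs = [r for r in records
                    if r.lineage is lineage and r.region == row.region]
            assert row.total_replacements == len(recs)
            by_class = sum(
                sum(r.ws is w for r in recs) for w in WsClass
            )
            assert by_class == len(recs)

    def test_truth_log_matches_polarisation(self):
        """Simulator-logged single-hit columns polarise to the right lineage."""
        from palinconv.simulate import SimParams, simulate_triad

        triad, mask, truth = simulate_triad(SimParams(seed=6, arm_length=5000,
                                                      spacer_length=2500))
        by_col = {}
        for rep in truth.triad_replacements:
            by_col.setdefault(rep["column"], []).append(rep)
        checked = 0
        for col, reps in by_col.items():
            if len(reps) != 1 or reps[0]["lineage"] not in ("human", "chimp"):
                continue
            rec = assign_lineage(triad.human[col], triad.chimp[col],
                                 triad.gorilla[col], column=col)
            assert rec is not None
            assert rec.lineage.value == reps[0]["lineage"]
            assert (rec.from_base, rec.to_base) == (reps[0]["from"], reps[0]["to"])
            checked += 1
        assert checked > 20


class TestGcContent:
    def test_identical_sequences_null(self):
        r = gc_content_test("ACGTACGT", "ACGTACGT")
        assert r["gc_a_pct"] == r["gc_b_pct"]
        assert r["p"] == pytest.approx(1.0)

    def test_planted_gc_difference_detected(self):
        rng = np.random.default_rng(8)

        def seq(gc, n=10_000):
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            return "".join(rng.choice(list("ACGT"), n, p=p))

        r = gc_content_test(seq(0.40), seq(0.35))
        assert r["gc_a_pct"] > r["gc_b_pct"]
        assert r["p"] < 0.01

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content_test("", "ACGT")


class TestConsensusFromPileup:
    def test_unanimous_deep_column_called(self):
        assert consensus_from_pileup([("G", 30)] * 10) == "G"

    def test_too_few_reads_no_call(self):
        assert consensus_from_pileup([("G", 30)] * 4) == NO_CALL

    def test_low_quality_reads_do_not_count(self):
        assert consensus_from_pileup([("G", 19)] * 6) == NO_CALL

    def test_single_discordant_read_blocks_call(self):
        reads = [("G", 30)] * 6 + [("A", 30)]
        assert consensus_from_pileup(reads) == NO_CALL

    def test_discordance_below_quality_floor_ignored(self):
        reads = [("G", 30)] * 6 + [("A", 10)]
        assert consensus_from_pileup(reads) == "G"

    def test_tolerance_knob_allows_minor_discordance(self):
        reads = [("G", 30)] * 9 + [("A", 30)]
        assert consensus_from_pileup(reads, max_discordant_fraction=0.2) == "G"
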