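import numpy as np
import pytest

from dualdemux import (
    AMBIGUOUS,
    Classification,
    Sample,
    SampleSheet,
    TheoreticalModel,
    TripletAssignment,
    build_report,
    classify,
    compute_rates,
    enumerate_control_pairs,
    estimate_epsilon,
    independent_misread_prob,
    misread_tail_exact,
    rate_vs_distance_table,
    theoretical_misassignment_rate,
)
from oracles import enumerate_misassignment_rate, index_at_distance


def _assign(i5, i7, ref, p=0.001):
    return TripletAssignment(
        matched_i5=i5, matched_i7=i7, matched_ref=ref,
        seq_mean_p=p, i5_mean_p=p, i7_mean_p=p,
    )


class TestClassify:
    def test_taxonomy(self, toy_sheet):
        s1, s2 = toy_sheet.samples[0], toy_sheet.samples[1]
        cases = [
            ((s1.i5, s1.i7, "ref_s1"), Classification.CORRECT),
            # expected pair, foreign sequence
            ((s1.i5, s1.i7, "ref_s2"), Classification.SEQ_MIS),
            # sequence anchors s1; i5 from s2
            ((s2.i5, s1.i7, "ref_s1"), Classification.INDEX_MIS_I5),
            ((s1.i5, s2.i7, "ref_s1"), Classification.INDEX_MIS_I7),
            # a full foreign pair with yet another sample's sequence is still
            # a sequence misassignment from that pair's point of view
            ((s2.i5, s2.i7, "ref_s3"), Classification.SEQ_MIS),
            # two wrong steps: unexpected pair, both indices foreign to anchor
            ((s2.i5, toy_sheet.samples[2].i7, "ref_s1"), Classification.MULTI_MIS),
            ((None, s1.i7, "ref_s1"), Classification.UNASSIGNED),
            ((s1.i5, AMBIGUOUS, "ref_s1"), Classification.UNASSIGNED),
            ((s1.i5, s1.i7, None), Classification.UNASSIGNED),
        ]
        for (i5, i7, ref), expected in cases:
            assert classify(_assign(i5, i7, ref), toy_sheet) is expected, (i5, i7, ref)

    def test_foreign_index_rejected(self, toy_sheet):
        with pytest.raises(ValueError, match="not in sample sheet"):
            classify(_assign("TTTTTTTA", toy_sheet.samples[0].i7, "ref_s1"), toy_sheet)

    def test_unclaimed_reference_rejected(self, toy_sheet):
        s1 = toy_sheet.samples[0]
        with pytest.raises(ValueError, match="not claimed"):
            classify(_assign(s1.i5, s1.i7, "ref_zzz"), toy_sheet)


class TestComputeRates:
    def test_simple_fraction(self):
        r = compute_rates({"CORRECT": 9990, "SEQ_MIS": 10})
        assert r.seq_mis_rate == pytest.approx(0.001)
        assert r.index_mis_rate == 0.0
        assert r.overall_incorrect_rate == pytest.approx(0.001)

    def test_all_correct(self):
        r = compute_rates({"CORRECT": 500})
        assert (r.seq_mis_rate, r.index_mis_rate, r.overall_incorrect_rate) == (0, 0, 0)

    def test_zero_denominator_flagged_not_zero(self):
        r = compute_rates({"UNASSIGNED": 10})
        assert r.seq_mis_rate is None
        assert r.undefined == {
            "seq_mis_rate", "index_mis_rate", "overall_incorrect_rate",
        }

    def test_index_rate_over_mapped(self):
        r = compute_rates(
            {"CORRECT": 900, "INDEX_MIS_I5": 50, "INDEX_MIS_I7": 30,
             "MULTI_MIS": 20, "UNASSIGNED": 1000}
        )
        assert r.index_mis_rate == pytest.approx(80 / 1000)
        assert r.overall_incorrect_rate == pytest.approx(100 / 1000)


class TestControlPairs:
    def test_unique_dual_design_combinatorics(self):
        # 14 samples, unique i5 and i7 each: 14*14 - 14 unused combinations
        sheet = SampleSheet(
            [
                Sample(f"s{i}", f"{b}AAACCC", f"{b}GGGTTT", ())
                for i, b in enumerate(
                    ["AA", "CC", "GG", "TT", "AC", "AG", "AT", "CA", "CG", "CT",
                     "GA", "GC", "GT", "TA"]
                )
            ]
        )
        assert len(enumerate_control_pairs(sheet)) == 14 * 14 - 14

    def test_shared_index_leaves_no_controls(self):
        sheet = SampleSheet(
            [Sample("a", "AAAA", "CCCC"), Sample("b", "AAAA", "GGGG")]
        )
        assert enumerate_control_pairs(sheet) == []

    def test_single_sample_no_controls(self):
        sheet = SampleSheet([Sample("a", "AAAA", "CCCC")])
        assert enumerate_control_pairs(sheet) == []


class TestEpsilon:
    def test_counts_reads_on_control_pairs(self):
        controls = [("AAAA", "GGGG"), ("CCCC", "TTTT")]
        counts = {
            ("AAAA", "GGGG", "ref1"): 4,
            ("AAAA", "GGGG", "<none>"): 3,
            ("AAAA", "TTTT", "ref1"): 5,  # not a control pair
        }
        eps, total = estimate_epsilon(counts, controls)
        assert eps == {("AAAA", "GGGG"): 7, ("CCCC", "TTTT"): 0}
        assert total == 7

    def test_no_hits(self):
        eps, total = estimate_epsilon({("A", "C", "r"): 10}, [("G", "T")])
        assert eps == {("G", "T"): 0} and total == 0

    def test_empty_control_list(self):
        assert estimate_epsilon({("A", "C", "r"): 1}, []) == ({}, 0)


class TestTheoreticalModel:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TheoreticalModel(p=1.5, L=8, k=1)
        with pytest.raises(ValueError):
            TheoreticalModel(p=0.1, L=0, k=1)
        with pytest.raises(ValueError):
            theoretical_misassignment_rate(TheoreticalModel(0.1, 4, 1), d=5)

    def test_no_errors_no_crossover(self):
        model = TheoreticalModel(p=0.0, L=8, k=1)
        assert theoretical_misassignment_rate(model, d=3) == 0.0

    def test_self_match_at_distance_zero(self):
        model = TheoreticalModel(p=0.1, L=8, k=1)
        # P(at most 1 misread among 8 at p=0.1)
        expected = 0.9**8 + 8 * 0.1 * 0.9**7
        assert theoretical_misassignment_rate(model, 0) == pytest.approx(expected)

    @pytest.mark.parametrize("L", [4, 5, 6])
    @pytest.mark.parametrize("p", [0.01, 0.1])
    @pytest.mark.parametrize("conditioned", [True, False])
    def test_matches_exhaustive_enumeration(self, L, p, conditioned):
        model = TheoreticalModel(p=p, L=L, k=1)
        for d in range(1, L + 1):
            a, b = index_at_distance(L, d)
            oracle = enumerate_misassignment_rate(p, a, b, k=1,
                                                  condition_on_true_reject=conditioned)
            got = theoretical_misassignment_rate(model, d, conditioned)
            assert got == pytest.approx(oracle, abs=1e-12), (L, p, d)

    def test_geometric_decay_with_distance(self):
        model = TheoreticalModel(p=0.1, L=8, k=1)
        rates = [theoretical_misassignment_rate(model, d) for d in range(2, 9)]
        assert all(r1 > r2 > 0 for r1, r2 in zip(rates, rates[1:]))


class TestRateVsDistance:
    def test_distance_independent_swaps_are_flat_but_model_decays(self, sim_outcomes, sim_run):
        # injected swaps ignore index distance: observed rates should not
        # fall off geometrically the way the substitution null predicts
        _, sheet, _, _ = sim_run
        report = build_report(sim_outcomes, sheet)
        model = TheoreticalModel(p=0.1, L=8, k=1)
        table = rate_vs_distance_table(model, sheet, report)
        populated = table[table["observed_rate"] > 0]
        assert len(populated) >= 2
        d_lo, d_hi = populated.iloc[0], populated.iloc[-1]
        theo_ratio = d_lo["theoretical_rate"] / d_hi["theoretical_rate"]
        obs_ratio = d_lo["observed_rate"] / d_hi["observed_rate"]
        # model predicts orders of magnitude of decay; observations do not show it
        assert theo_ratio > 100
        assert obs_ratio < 100

    def test_no_misassignments_gives_zero_column(self, toy_sheet):
        import pandas as pd

        outcomes = pd.DataFrame(
            {
                "label": ["CORRECT"] * 3,
                "i5": [s.i5 for s in toy_sheet],
                "i7": [s.i7 for s in toy_sheet],
                "ref": [s.reference_ids[0] for s in toy_sheet],
                "seq_mean_p": [1e-3] * 3,
                "i5_mean_p": [1e-3] * 3,
                "i7_mean_p": [1e-3] * 3,
            }
        )
        report = build_report(outcomes, toy_sheet)
        table = rate_vs_distance_table(TheoreticalModel(0.1, 8, 1), toy_sheet, report)
        assert (table["observed_rate"] == 0).all()
        assert len(table) >= 1


class TestReportConservation:
    def test_counts_sum_to_total(self, sim_outcomes, sim_run):
        _, sheet, _, _ = sim_run
        report = build_report(sim_outcomes, sheet)
        assert sum(report.label_counts.values()) == report.total_reads
        assert sum(report.triplet_counts.values()) == report.total_reads
        assert 0 <= report.rates.overall_incorrect_rate <= 1

    def test_json_and_tsv_serialization(self, sim_outcomes, sim_run, tmp_path):
        import json

        _, sheet, _, _ = sim_run
        report = build_report(sim_outcomes, sheet)
        report.write_json(tmp_path / "r.json")
        report.write_triplet_tsv(tmp_path / "t.tsv")
        with open(tmp_path / "r.json") as fh:
            data = json.load(fh)
        assert data["total_reads"] == report.total_reads
        assert len(data["control_estimates"]) == 14 * 14 - 14
        assert len(data["per_sample"]) == 14


class TestMisreadEnvelope:
    def test_leading_order_figures(self):
        # three misreads at Q20 ~ 1e-6; both 8-bp indices crossing ~ 1e-12
        assert independent_misread_prob(0.01, 3) == pytest.approx(1e-6)
        assert independent_misread_prob(0.01, 3) ** 2 == pytest.approx(1e-12)

    def test_exact_tail_dominates_leading_order(self):
        # the exact binomial tail keeps the C(L, n) prefactor
        exact = misread_tail_exact(8, 0.01, 3)
        assert exact > independent_misread_prob(0.01, 3)
        from math import comb

        assert exact == pytest.approx(
            sum(comb(8, i) * 0.01**i * 0.99 ** (8 - i) for i in range(3, 9))
        )
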