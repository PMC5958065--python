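"""Additive copy-count logistic model, grouped-count reconstruction,
Bonferroni thresholds, and the replication protocol."""

import math

import numpy as np
import pytest
from scipy.special import expit

from haplogic.assoc import (AdditiveHaplotypeModel, GroupedCounts,
                            bonferroni_threshold, fit_additive,
                            reconstruct_group_counts, replicate_candidates)
from haplogic.selection import Candidate, PermStat
from haplogic.search import FitResult
from haplogic.tree import AND, OR, LogicTree

from conftest import make_cohort


class TestFitAdditive:
    def test_symmetric_counts_give_unit_or(self):
        g = GroupedCounts([0, 1], [100, 100], [50, 50])
        res = fit_additive(grouped=g)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_grouped_and_subject_level_agree(self, rng):
        L = rng.integers(0, 3, 400).astype(float)
        y = (rng.random(400) < expit(-0.3 + 0.5 * L)).astype(int)
        a = fit_additive(L, y)
        b = fit_additive(grouped=GroupedCounts.from_subject_data(L, y))
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-10)
        assert a.bse[1] == pytest.approx(b.bse[1], rel=1e-10)

    def test_two_group_closed_form(self):
        # two support points: beta1 = logit difference
        g = GroupedCounts([0, 1], [2802, 84], [1376, 5])
        res = fit_additive(grouped=g)
        expected = math.log(5 / 79) - math.log(1376 / 1426)
        assert res.beta1 == pytest.approx(expected, rel=1e-8)
        assert res.odds_ratio == pytest.approx(0.066, abs=5e-4)

    def test_label_inversion_maps_or_to_reciprocal(self, rng):
        L = rng.integers(0, 3, 300).astype(float)
        y = (rng.random(300) < expit(0.2 + 0.4 * L)).astype(int)
        a = fit_additive(L, y)
        b = fit_additive(L, 1 - y)
        assert b.odds_ratio == pytest.approx(1 / a.odds_ratio, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            fit_additive(grouped=GroupedCounts([1], [50], [20]))

    def test_one_outcome_class_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            fit_additive(grouped=GroupedCounts([0, 1], [50, 50], [0, 0]))

    def test_separation_flagged_and_p_omitted(self):
        res = fit_additive(grouped=GroupedCounts([0, 1], [40, 40], [0, 40]))
        assert res.separation
        assert math.isnan(res.pvalue)

    def test_parameter_recovery_within_monte_carlo_error(self):
        # simulate from the model itself: L ~ Bin(2, 0.3), known slope
        rng = np.random.default_rng(5)
        beta0, beta1, n = -0.5, 0.7, 5000
        est = []
        for _ in range(200):
            L = rng.binomial(2, 0.3, n).astype(float)
            y = (rng.random(n) < expit(beta0 + beta1 * L)).astype(int)
            est.append(fit_additive(L, y).beta1)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - beta1) < 3 * mc_se

    def test_lrt_close_to_wald_at_moderate_n(self, rng):
        L = rng.integers(0, 3, 800).astype(float)
        y = (rng.random(800) < expit(-0.2 + 0.3 * L)).astype(int)
        res = fit_additive(L, y)
        assert 0 < res.pvalue_lrt < 1
        assert np.log10(res.pvalue_lrt) == pytest.approx(
            np.log10(res.pvalue), abs=0.5)

    def test_summary_reports_key_quantities(self):
        g = GroupedCounts([0, 1, 2], [775, 1434, 677], [274, 698, 409])
        s = AdditiveHaplotypeModel(g).fit().summary()
        assert "OR per copy = 1.672" in s


class TestReconstructCounts:
    def test_chr9_row_unique_solution(self):
        g = reconstruct_group_counts((775, 1434, 677), (35.4, 48.7, 60.4),
                                     1381)
        assert g.n_cases.tolist() == [274, 698, 409]

    def test_btn_row_resolved_by_total(self):
        g = reconstruct_group_counts((2571, 304, 11), (50.4, 27.3, 9.1), 1381)
        assert g.n_cases.tolist() == [1297, 83, 1]

    def test_no_consistent_solution_raises(self):
        with pytest.raises(ValueError, match="consistent"):
            reconstruct_group_counts((10,), (33.3,), 99)

    def test_round_half_up_convention(self):
        # 78/360 = 21.666..% rounds (half-up) to 21.7
        g = reconstruct_group_counts((360,), (21.7,), 78)
        assert g.n_cases.tolist() == [78]


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [
        (74, 0.05 / 74), (1_567_361, 0.05 / 1_567_361), (1, 0.05)])
    def test_threshold(self, m, expected):
        assert bonferroni_threshold(0.05, m) == expected

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _signal_cohorts(rng, n=400, flip=False):
    """Discovery/replication cohorts where snp0's alt allele raises risk."""
    haps = (rng.random((2 * n, 3)) < 0.3).astype(np.int8)
    L = haps[0::2, 0] + haps[1::2, 0]
    sign = -1.0 if flip else 1.0
    y = (rng.random(n) < expit(-0.5 + sign * 1.2 * L)).astype(int)
    return make_cohort(haps, y)


def _candidate(tree_root):
    fit = FitResult(tree=LogicTree(tree_root), deviance=1.0, beta=0.5,
                    n_used=10, null_deviance=2.0)
    return Candidate(fit=fit, stat=PermStat(1.0, np.zeros(20), None, 0.0,
                                            1.0, -20.0), window_ids=["w"])


class TestReplication:
    def test_consistent_signal_replicates(self, rng):
        disc = _signal_cohorts(rng)
        rep = _signal_cohorts(rng)
        verdicts = replicate_candidates([_candidate((0, 1))], disc, rep,
                                        alpha=0.05)
        assert verdicts[0].replicated
        assert verdicts[0].threshold == 0.05

    def test_opposite_direction_fails_regardless_of_p(self, rng):
        disc = _signal_cohorts(rng)
        rep = _signal_cohorts(rng, flip=True)
        verdicts = replicate_candidates([_candidate((0, 1))], disc, rep)
        assert not verdicts[0].replicated

    def test_threshold_divided_among_candidates(self, rng):
        disc = _signal_cohorts(rng)
        rep = _signal_cohorts(rng)
        cands = [_candidate((0, 1)), _candidate((1, 1)),
                 _candidate((2, 1)), _candidate((AND, (0, 1), (1, 1)))]
        verdicts = replicate_candidates(cands, disc, rep)
        assert verdicts[0].threshold == pytest.approx(0.05 / 4)

    def test_untestable_when_tree_monomorphic_in_replication(self, rng):
        disc = _signal_cohorts(rng)
        haps = np.zeros((40, 3), dtype=np.int8)  # snp0 monomorphic
        rep = make_cohort(haps, [0, 1] * 10)
        verdicts = replicate_candidates([_candidate((0, 1))], disc, rep)
        assert verdicts[0].untestable and not verdicts[0].replicated

    def test_empty_candidate_list_rejected(self, rng):
        disc = _signal_cohorts(rng)
        with pytest.raises(ValueError):
            replicate_candidates([], disc, disc)
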