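"""Chromosome-level deviance scoring and the simulated-annealing search."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from haplogic.search import (FitResult, HaplotypeLogicRegression, SearchConfig,
                             accept_probability, anneal_once,
                             exhaustive_search, haplotype_deviance,
                             indicator_deviance, search_window)
from haplogic.tree import AND, OR

from conftest import full_window, make_cohort, random_cohort


def _cohort_with_indicator(case_true, case_false, ctrl_true, ctrl_false):
    """One-SNP cohort whose allele-1 chromosomes count as indicator-true."""
    chroms = ([1] * case_true + [0] * case_false
              + [1] * ctrl_true + [0] * ctrl_false)
    n_case = (case_true + case_false) // 2
    n = len(chroms) // 2
    haps = np.array(chroms, dtype=np.int8).reshape(-1, 1)
    y = [1] * n_case + [0] * (n - n_case)
    return make_cohort(haps, y)


class TestDeviance:
    def test_constant_indicator_gives_null_deviance(self):
        # 8 chromosomes, 4 case-derived / 4 control-derived
        c = _cohort_with_indicator(4, 0, 4, 0)
        res = haplotype_deviance((0, 1), c)
        assert res.deviance == pytest.approx(16 * math.log(2), rel=1e-12)
        assert res.constant and res.beta == 0.0

    def test_closed_form_mixed_groups(self):
        # true: 6 case / 2 control; false: 2 case / 6 control
        c = _cohort_with_indicator(6, 2, 2, 6)
        res = haplotype_deviance((0, 1), c)
        expected = -2 * (12 * math.log(0.75) + 4 * math.log(0.25))
        assert res.deviance == pytest.approx(expected, rel=1e-12)
        assert res.beta == pytest.approx(2 * math.log(3), rel=1e-12)

    def test_perfect_separation_zero_deviance(self):
        c = _cohort_with_indicator(4, 0, 0, 4)
        res = haplotype_deviance((0, 1), c)
        assert res.deviance == 0.0 and res.separation

    def test_deviance_never_exceeds_null(self, rng):
        for _ in range(20):
            c = random_cohort(rng, n_subjects=40, n_snps=3)
            tree = (OR, (0, 1), (AND, (1, 1), (2, 0)))
            res = haplotype_deviance(tree, c)
            assert res.deviance <= res.null_deviance + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_glm(self, seed):
        rng = np.random.default_rng(seed)
        c = random_cohort(rng, n_subjects=80, n_snps=3)
        tree = (OR, (0, 1), (AND, (1, 1), (2, 1)))
        res = haplotype_deviance(tree, c)
        # independent route: evaluate the indicator per chromosome, fit GLM
        h = c.haps
        indicator = ((h[:, 0] == 1) | ((h[:, 1] == 1) & (h[:, 2] == 1))
                     ).astype(float)
        y2 = np.repeat(c.phenotype, 2).astype(float)
        glm = sm.GLM(y2, sm.add_constant(indicator),
                     family=sm.families.Binomial()).fit()
        assert res.deviance == pytest.approx(glm.deviance, rel=1e-9)

    def test_missing_drops_whole_subject(self):
        haps = np.array([[1], [1], [1], [-1], [0], [0], [0], [0]],
                        dtype=np.int8)
        c = make_cohort(haps, [1, 1, 0, 0])
        res = haplotype_deviance((0, 1), c)
        assert res.n_used == 6  # subject 1 dropped entirely


class TestAcceptRule:
    def test_zero_delta_always_accepted(self):
        assert accept_probability(0.0, 5.0) == 1.0

    def test_greedy_descent_at_low_temperature(self):
        assert accept_probability(0.1, 1e-9) == pytest.approx(0.0, abs=1e-300)
        assert accept_probability(-0.1, 1e-9) == 1.0

    def test_random_walk_at_high_temperature(self):
        assert accept_probability(10.0, 1e9) == pytest.approx(1.0, rel=1e-6)


class TestSearch:
    def test_deterministic_under_fixed_seed(self, rng):
        c = random_cohort(rng, n_subjects=60, n_snps=5)
        w = full_window(c)
        cfg = SearchConfig(seed=42, n_restarts=5, n_iterations=300)
        r1 = search_window(c, w, cfg)
        r2 = search_window(c, w, cfg)
        assert r1.deviance == r2.deviance
        assert r1.tree.key == r2.tree.key

    def test_anneal_once_deterministic(self, rng):
        c = random_cohort(rng, n_subjects=60, n_snps=5)
        w = full_window(c)
        cfg = SearchConfig(seed=7, n_iterations=300)
        a = anneal_once(c, w, cfg, restart_seed=3)
        b = anneal_once(c, w, cfg, restart_seed=3)
        assert a.deviance == b.deviance and a.tree.key == b.tree.key

    def test_deterministic_snp_recovered_at_global_minimum(self, rng):
        # one SNP's alt allele equals phenotype exactly on every chromosome
        n = 40
        haps = (rng.random((2 * n, 4)) < 0.4).astype(np.int8)
        y = rng.integers(0, 2, n)
        haps[:, 2] = np.repeat(y, 2)
        c = make_cohort(haps, y)
        w = full_window(c)
        res = search_window(c, w, SearchConfig(seed=1, n_restarts=10,
                                               n_iterations=500))
        ex = exhaustive_search(c, w)
        assert 2 in res.tree.snps
        assert res.deviance == pytest.approx(ex.deviance, abs=1e-9)

    def test_search_equals_enumeration_on_small_windows(self, rng):
        cfg = SearchConfig(seed=11, n_restarts=30, n_iterations=800)
        for _ in range(5):
            c = random_cohort(rng, n_subjects=120, n_snps=5)
            w = full_window(c)
            sa = search_window(c, w, cfg)
            ex = exhaustive_search(c, w)
            assert sa.deviance == pytest.approx(ex.deviance, abs=1e-9)

    def test_best_deviance_monotone_in_restarts(self, rng):
        c = random_cohort(rng, n_subjects=80, n_snps=6)
        w = full_window(c)
        devs = [search_window(c, w, SearchConfig(seed=5, n_restarts=k,
                                                 n_iterations=200)).deviance
                for k in (1, 3, 10)]
        assert devs[0] >= devs[1] >= devs[2]

    def test_identical_snp_columns_give_identical_results(self, rng):
        c = random_cohort(rng, n_subjects=60, n_snps=4)
        w1 = full_window(c, "wa")
        w2 = full_window(c, "wa")  # same id -> same restart seeds
        r1 = search_window(c, w1, SearchConfig(seed=3, n_restarts=3,
                                               n_iterations=200))
        r2 = search_window(c, w2, SearchConfig(seed=3, n_restarts=3,
                                               n_iterations=200))
        assert r1.deviance == r2.deviance and r1.tree.key == r2.tree.key

    def test_two_snp_window_reports_two_snp_tree(self, rng):
        c = random_cohort(rng, n_subjects=50, n_snps=2)
        res = search_window(c, full_window(c),
                            SearchConfig(seed=1, n_restarts=3,
                                         n_iterations=200))
        assert len(res.tree.snps) == 2

    def test_model_wrapper_fits(self, rng):
        c = random_cohort(rng, n_subjects=50, n_snps=4)
        model = HaplotypeLogicRegression(c, full_window(c),
                                         SearchConfig(seed=2, n_restarts=3,
                                                      n_iterations=200))
        res = model.fit()
        assert isinstance(res, FitResult)
        assert res.deviance <= res.null_deviance + 1e-9


class TestIndicatorDeviance:
    def test_agrees_with_direct_formula(self):
        dev, beta, const, sep = indicator_deviance(6, 8, 8, 16)
        expected = -2 * (12 * math.log(0.75) + 4 * math.log(0.25))
        assert dev == pytest.approx(expected, rel=1e-12)
        assert not const and not sep
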