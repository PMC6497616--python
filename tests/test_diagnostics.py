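"""Heterogeneity (Cochran's Q) and influence diagnostics against refit oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from bwmr.diagnostics import (
    cochran_q,
    cooks_distances,
    cooks_influence,
    leave_one_out,
    stepwise_q_prune,
    studentised_outliers,
    studentised_residuals,
)
from bwmr.estimators import ivw
from bwmr.instruments import InstrumentSet

from conftest import FIVE_BX, FIVE_BY, FIVE_SY, make_instruments


def _outlier_set(seed=17, n=20, shift=0.25):
    """Homogeneous instruments plus one grossly pleiotropic SNP (the first)."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.2, n)
    by = 0.3 * bx + rng.normal(0, 0.004, n)
    by[0] += shift
    return InstrumentSet("planted", make_instruments(bx, by, np.full(n, 0.01)))


class TestCochranQ:
    def test_identical_ratios_give_zero_q_p_one(self):
        bx = np.array([0.1, 0.2, 0.3])
        report = cochran_q(make_instruments(bx, 0.4 * bx, [0.01, 0.01, 0.01]))
        assert report.q == pytest.approx(0.0, abs=1e-18)
        assert report.pvalue == pytest.approx(1.0)
        assert report.df == 2

    def test_contributions_are_nonnegative_and_sum_to_q(self, five_snp_instruments):
        report = cochran_q(five_snp_instruments)
        assert all(v >= 0 for v in report.per_snp_q.values())
        assert sum(report.per_snp_q.values()) == pytest.approx(report.q, rel=1e-12)
        assert report.df == 4

    def test_q_is_order_invariant(self, five_snp_instruments):
        a = cochran_q(five_snp_instruments)
        b = cochran_q(list(reversed(five_snp_instruments)))
        assert a.q == pytest.approx(b.q, rel=1e-12)

    def test_null_distribution_matches_chi_square(self):
        """Valid instruments: empirical Q across replicates ~ chi2(L-1)."""
        rng = np.random.default_rng(99)
        L, theta = 10, 0.2
        bx = rng.uniform(0.05, 0.2, L)
        sy = np.full(L, 0.01)
        qs = np.empty(1000)
        for i in range(1000):
            by = theta * bx + rng.normal(0, sy)
            qs[i] = cochran_q(make_instruments(bx, by, sy)).q
        ks = stats.kstest(qs, stats.chi2(df=L - 1).cdf)
        assert ks.pvalue > 0.001
        # rejection rate of the Q test at 5% within binomial error
        rej = np.mean(stats.chi2.sf(qs, L - 1) < 0.05)
        assert abs(rej - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 1000)


class TestStepwisePruning:
    def test_homogeneous_set_needs_no_removal(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        s = InstrumentSet("hom", make_instruments(bx, 0.4 * bx, np.full(4, 0.01)))
        pruned, removed = stepwise_q_prune(s)
        assert removed == []
        assert len(pruned) == 4

    def test_planted_outlier_is_removed_first(self):
        s = _outlier_set()
        pruned, removed = stepwise_q_prune(s)
        assert removed[0] == "rs1"
        assert "rs1" not in pruned.snp_ids

    def test_q_decreases_at_every_removal_step(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.2, 15)
        by = 0.3 * bx + rng.normal(0, 0.02, 15)
        s = InstrumentSet("het", make_instruments(bx, by, np.full(15, 0.01)))
        _, removed = stepwise_q_prune(s, alpha=0.05)
        remaining = list(s.instruments)
        q_prev = cochran_q(remaining).q
        for snp in removed:
            remaining = [i for i in remaining if i.snp_id != snp]
            q_now = cochran_q(remaining).q
            assert q_now < q_prev
            q_prev = q_now

    def test_non_refit_mode_also_removes_the_outlier(self):
        pruned, removed = stepwise_q_prune(_outlier_set(), refit=False)
        assert "rs1" in removed


class TestCooksDistance:
    def test_default_threshold_is_four_over_l(self):
        s = _outlier_set(n=41)
        # flagging with the explicit 4/41 threshold equals the default
        assert cooks_influence(s) == cooks_influence(s, threshold=4.0 / 41)

    def test_exact_fit_has_zero_distances(self):
        # dyadic values so 0.5 * bx is exactly representable and residuals vanish
        bx = np.array([0.25, 0.5, 1.0])
        d = cooks_distances(make_instruments(bx, 0.5 * bx, [0.015625, 0.015625, 0.015625]))
        assert all(v == 0.0 for v in d.values())

    def test_distances_match_leave_one_out_refit_oracle(self, five_snp_instruments):
        """D_j = (theta - theta_{-j})^2 * sum(w bx^2) / s^2, by explicit refit."""
        d = cooks_distances(five_snp_instruments)
        w = 1 / FIVE_SY**2
        sxx = np.sum(w * FIVE_BX**2)
        theta = np.sum(w * FIVE_BX * FIVE_BY) / sxx
        s2 = np.sum(w * (FIVE_BY - theta * FIVE_BX) ** 2) / 4
        for j, snp in enumerate(["rs1", "rs2", "rs3", "rs4", "rs5"]):
            mask = np.arange(5) != j
            theta_loo = np.sum((w * FIVE_BX * FIVE_BY)[mask]) / np.sum((w * FIVE_BX**2)[mask])
            oracle = (theta - theta_loo) ** 2 * sxx / s2
            assert d[snp] == pytest.approx(oracle, rel=1e-10)

    def test_planted_outlier_is_flagged(self):
        assert "rs1" in cooks_influence(_outlier_set())


class TestLeaveOneOut:
    def test_row_count_is_l_plus_one_with_full_row_last(self, five_snp_set):
        rows = leave_one_out(five_snp_set)
        assert len(rows) == 6
        assert rows[-1].extras["omitted"] is None
        assert rows[-1].beta == pytest.approx(ivw(five_snp_set).beta)

    def test_homogeneous_set_rows_all_equal_full_estimate(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        s = InstrumentSet("hom", make_instruments(bx, 0.4 * bx, np.full(4, 0.01)))
        rows = leave_one_out(s)
        assert all(r.beta == pytest.approx(0.4, abs=1e-12) for r in rows)

    def test_planted_outlier_row_deviates_most(self):
        s = _outlier_set()
        rows = leave_one_out(s)
        full = rows[-1].beta
        deviations = {r.extras["omitted"]: abs(r.beta - full) for r in rows[:-1]}
        assert max(deviations, key=deviations.get) == "rs1"


class TestStudentisedResiduals:
    def test_exact_fit_flags_nothing(self):
        bx = np.array([0.25, 0.5, 1.0])
        assert studentised_outliers(make_instruments(bx, 0.5 * bx, [0.015625] * 3)) == set()

    def test_matches_delete_one_variance_oracle(self, five_snp_instruments):
        t = studentised_residuals(five_snp_instruments)
        w = 1 / FIVE_SY**2
        xs, ys = np.sqrt(w) * FIVE_BX, np.sqrt(w) * FIVE_BY
        sxx = np.sum(xs**2)
        theta = np.sum(xs * ys) / sxx
        e = ys - theta * xs
        h = xs**2 / sxx
        for j, snp in enumerate(["rs1", "rs2", "rs3", "rs4", "rs5"]):
            s2_loo = (np.sum(e**2) - e[j] ** 2 / (1 - h[j])) / 3
            oracle = e[j] / math.sqrt(s2_loo * (1 - h[j]))
            assert t[snp] == pytest.approx(oracle, rel=1e-10)

    def test_infinite_threshold_flags_nothing(self, five_snp_instruments):
        assert studentised_outliers(five_snp_instruments, threshold=math.inf) == set()

    def test_planted_outlier_is_flagged(self):
        assert "rs1" in studentised_outliers(_outlier_set())
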