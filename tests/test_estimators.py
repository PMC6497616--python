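"""Univariable estimators against independent brute-force oracles.

Each estimator is checked on a small heterogeneous table against a
direct re-derivation — matrix solve for the weighted regressions,
hand-enumerated cumulative-weight interpolation for the median,
explicitly summed kernel density for the mode — plus frozen values
computed from those oracles, and ordering/sign-flip invariance.
"""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats

from bwmr.estimators import (
    ivw,
    ivw_penalised_robust,
    mr_egger,
    weighted_median,
    weighted_mode,
)
from bwmr.simulate import SyntheticStudySpec, generate_two_sample

from conftest import FIVE_BX, FIVE_BY, FIVE_SX, FIVE_SY, make_instruments


# ---------------------------------------------------------------- oracles


def oracle_wls(bx, by, sy, intercept=False):
    """Weighted least squares by direct matrix solve (independent route)."""
    w = 1.0 / np.asarray(sy) ** 2
    X = np.column_stack([np.ones(len(bx)), bx]) if intercept else np.asarray(bx)[:, None]
    A = X.T @ (X * w[:, None])
    coef = np.linalg.solve(A, X.T @ (w * by))
    cov = np.linalg.inv(A)
    rss = float(np.sum(w * (by - X @ coef) ** 2))
    return coef, cov, rss


def oracle_weighted_median(ratios, weights):
    order = np.argsort(ratios)
    b, s = np.asarray(ratios)[order], np.asarray(weights)[order] / np.sum(weights)
    p = np.cumsum(s) - s / 2
    if 0.5 <= p[0]:
        return float(b[0])
    if 0.5 >= p[-1]:
        return float(b[-1])
    return float(np.interp(0.5, p, b))


def oracle_weighted_mode(ratios, weights, bandwidth_factor=1.0):
    """Explicitly summed kernel density maximised on the documented grid."""
    ratios = np.asarray(ratios, float)
    sd = np.std(ratios, ddof=1)
    mad = np.median(np.abs(ratios - np.median(ratios))) / stats.norm.ppf(0.75)
    h = bandwidth_factor * 0.9 * min(x for x in (sd, mad) if x > 0) * len(ratios) ** (-1 / 5)
    w = np.asarray(weights) / np.sum(weights)

    def dens(x):
        return sum(wj * math.exp(-0.5 * ((x - rj) / h) ** 2) for rj, wj in zip(ratios, w))

    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 1024)
    j = int(np.argmax([dens(x) for x in grid]))
    fine = np.linspace(grid[max(j - 1, 0)], grid[min(j + 1, 1023)], 201)
    return float(fine[np.argmax([dens(x) for x in fine])])


# ---------------------------------------------------------------- IVW


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        est = ivw(make_instruments([0.1], [0.05], [0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.extras["re_scale_factor"] == 1.0

    def test_homogeneous_ratios_give_the_common_ratio_and_unit_scale(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = ivw(make_instruments(bx, 0.4 * bx, [0.01, 0.01, 0.01]))
        assert est.beta == pytest.approx(0.4)
        assert est.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert est.extras["re_scale_factor"] == 1.0

    def test_five_snp_fixture_equals_wls_oracle(self, five_snp_instruments):
        est = ivw(five_snp_instruments)
        coef, cov, _ = oracle_wls(FIVE_BX, FIVE_BY, FIVE_SY)
        assert est.beta == pytest.approx(float(coef[0]), rel=1e-12)
        assert est.extras["fe_se"] == pytest.approx(float(np.sqrt(cov[0, 0])), rel=1e-12)
        # frozen from the oracle solve
        assert est.beta == pytest.approx(0.4972939938154953, rel=1e-10)
        assert est.extras["q"] == pytest.approx(1.9057917343918724, rel=1e-10)

    def test_random_effects_se_is_floored_at_fixed_effects(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.3 * bx + rng.normal(0, 0.05, 20)
        instruments = make_instruments(bx, by, np.full(20, 0.02))
        re = ivw(instruments, random_effects=True)
        fe = ivw(instruments, random_effects=False)
        assert re.se >= fe.se
        assert re.beta == pytest.approx(fe.beta)

    def test_requires_at_least_one_instrument(self):
        with pytest.raises(ValueError):
            ivw([])


# ---------------------------------------------------------------- MR-Egger


class TestMREgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        c, theta = 0.01, 0.4
        est = mr_egger(make_instruments(bx, c + theta * bx, np.full(5, 0.01)))
        assert est.beta == pytest.approx(theta, abs=1e-12)
        assert est.extras["egger_intercept"] == pytest.approx(c, abs=1e-12)
        assert est.extras["re_scale_factor"] == 1.0

    def test_five_snp_fixture_equals_wls_oracle(self, five_snp_instruments):
        est = mr_egger(five_snp_instruments)
        coef, cov, rss = oracle_wls(FIVE_BX, FIVE_BY, FIVE_SY, intercept=True)
        scale = max(1.0, math.sqrt(rss / 3))
        assert est.beta == pytest.approx(float(coef[1]), rel=1e-12)
        assert est.extras["egger_intercept"] == pytest.approx(float(coef[0]), rel=1e-12)
        assert est.se == pytest.approx(scale * float(np.sqrt(cov[1, 1])), rel=1e-12)
        # frozen from the oracle solve
        assert est.beta == pytest.approx(0.8961765739933212, rel=1e-9)
        assert est.extras["egger_intercept"] == pytest.approx(-0.039349169227397125, rel=1e-9)

    def test_intercept_test_is_near_nominal_under_balanced_pleiotropy(self):
        # balanced pleiotropy, intercept truly zero: rejections ~ 5%
        spec = SyntheticStudySpec(
            n_snps=30, theta=0.0, pleiotropy="balanced", pleio_sd=0.08, n_invalid=30, seed=42
        )
        rejections = 0
        n_reps = 1000
        for rep in range(n_reps):
            exp_df, out_df, _ = generate_two_sample(spec, rep=rep)
            instruments = make_instruments(
                exp_df.beta.to_numpy(), out_df.beta.to_numpy() * np.where(
                    out_df.effect_allele.to_numpy() == exp_df.effect_allele.to_numpy(), 1, -1
                ), out_df.se.to_numpy(), sx=exp_df.se.to_numpy()
            )
            est = mr_egger(instruments)
            rejections += est.extras["egger_intercept_p"] < 0.05
        rate = rejections / n_reps
        # 3 binomial SDs around 0.05 at 1000 reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_reps) + 0.01

    def test_directional_pleiotropy_intercept_recovers_planted_mean(self):
        mu = 0.02
        spec = SyntheticStudySpec(
            n_snps=41, theta=-0.15, pleiotropy="directional", pleio_mean=mu,
            pleio_sd=0.005, n_invalid=41, seed=7,
        )
        intercepts = []
        for rep in range(200):
            exp_df, out_df, _ = generate_two_sample(spec, rep=rep)
            sign = np.where(out_df.effect_allele.to_numpy() == exp_df.effect_allele.to_numpy(), 1, -1)
            instruments = make_instruments(
                exp_df.beta.to_numpy(), out_df.beta.to_numpy() * sign,
                out_df.se.to_numpy(), sx=exp_df.se.to_numpy(),
            )
            intercepts.append(mr_egger(instruments).extras["egger_intercept"])
        mean = np.mean(intercepts)
        sem = np.std(intercepts, ddof=1) / math.sqrt(len(intercepts))
        assert abs(mean - mu) < 5 * sem

    def test_underdetermined_raises(self, five_snp_instruments):
        with pytest.raises(ValueError, match="egger_underdetermined"):
            mr_egger(five_snp_instruments[:2])


# ---------------------------------------------------------------- median / mode


class TestWeightedMedian:
    def test_equal_weight_middle_element(self):
        instruments = make_instruments([0.1, 0.1, 0.1], [0.01, 0.05, 0.09], [0.01, 0.01, 0.01])
        est = weighted_median(instruments, n_boot=0)
        assert est.beta == pytest.approx(0.5)

    def test_degenerate_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(make_instruments(bx, 0.7 * bx, [0.01, 0.03, 0.02]), n_boot=0)
        assert est.beta == pytest.approx(0.7)

    def test_five_snp_fixture_matches_interpolation_oracle(self, five_snp_instruments):
        est = weighted_median(five_snp_instruments, n_boot=0)
        ratios = FIVE_BY / FIVE_BX
        weights = (FIVE_BX / FIVE_SY) ** 2
        assert est.beta == pytest.approx(oracle_weighted_median(ratios, weights), rel=1e-12)
        # frozen from the hand-enumerated cumulative weights
        assert est.beta == pytest.approx(0.4994553691480259, rel=1e-10)

    def test_bootstrap_se_is_reproducible_and_positive(self, five_snp_instruments):
        a = weighted_median(five_snp_instruments, n_boot=300, seed=9)
        b = weighted_median(five_snp_instruments, n_boot=300, seed=9)
        assert a.se == b.se > 0


class TestWeightedMode:
    def test_majority_cluster_wins_over_outliers(self):
        bx = np.full(9, 0.1)
        ratios = np.array([0.38, 0.39, 0.40, 0.40, 0.41, 0.42, 0.40, 2.0, 2.1])
        est = weighted_mode(make_instruments(bx, ratios * bx, np.full(9, 0.01)), n_boot=0)
        assert abs(est.beta - 0.4) < abs(est.beta - 2.0)

    def test_degenerate_equal_ratios_return_common_ratio(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = weighted_mode(make_instruments(bx, 0.25 * bx, [0.01, 0.01, 0.01]), n_boot=0)
        assert est.beta == pytest.approx(0.25)

    def test_five_snp_fixture_matches_density_oracle(self, five_snp_instruments):
        est = weighted_mode(five_snp_instruments, n_boot=0)
        ratios = FIVE_BY / FIVE_BX
        weights = (FIVE_BX / FIVE_SY) ** 2
        assert est.beta == pytest.approx(oracle_weighted_mode(ratios, weights), rel=1e-10)


# ---------------------------------------------------------------- penalised robust


class TestPenalisedRobustIVW:
    def test_homogeneous_data_matches_plain_ivw(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, 15)
        by = 0.3 * bx + rng.normal(0, 0.002, 15)
        instruments = make_instruments(bx, by, np.full(15, 0.02))
        pen = ivw_penalised_robust(instruments)
        plain = ivw(instruments, random_effects=False)
        assert pen.extras["n_penalised"] == 0
        assert pen.beta == pytest.approx(plain.beta, abs=5e-3)

    def test_penalty_inactive_when_all_tail_probabilities_large(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        instruments = make_instruments(bx, 0.5 * bx, np.full(4, 0.02))
        assert ivw_penalised_robust(instruments).extras["n_penalised"] == 0

    def test_planted_outlier_is_downweighted_and_estimate_moves_toward_clean_ivw(self):
        rng = np.random.default_rng(17)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.3 * bx + rng.normal(0, 0.005, 20)
        sy = np.full(20, 0.01)
        clean = ivw(make_instruments(bx, by, sy)).beta
        by_out = by.copy()
        by_out[0] += 0.2  # gross pleiotropic outlier
        contaminated = make_instruments(bx, by_out, sy)
        naive = ivw(contaminated, random_effects=False).beta
        pen = ivw_penalised_robust(contaminated)
        assert pen.extras["n_penalised"] >= 1
        assert abs(pen.beta - clean) < abs(naive - clean)

    def test_se_floored_at_fixed_effects_ivw(self, five_snp_instruments):
        pen = ivw_penalised_robust(five_snp_instruments)
        fe = ivw(five_snp_instruments, random_effects=False)
        assert pen.se >= fe.se


# ---------------------------------------------------------------- shared invariants


@st.composite
def instrument_tables(draw):
    n = draw(st.integers(min_value=3, max_value=8))
    bx = draw(
        st.lists(st.floats(0.02, 0.5), min_size=n, max_size=n).map(np.array)
    )
    ratios = draw(st.lists(st.floats(-1.0, 1.0), min_size=n, max_size=n).map(np.array))
    sy = draw(st.lists(st.floats(0.005, 0.05), min_size=n, max_size=n).map(np.array))
    return bx, ratios * bx, sy


@given(instrument_tables(), st.randoms(use_true_random=False))
@settings(max_examples=50, deadline=None)
def test_estimators_invariant_to_order_and_joint_sign_flips(table, pyrandom):
    """Permuting SNPs or jointly flipping (bx, by) signs never changes estimates."""
    bx, by, sy = table
    assume(np.std(bx) > 1e-3)  # constant exposure betas make the Egger design singular
    n = len(bx)
    perm = list(range(n))
    pyrandom.shuffle(perm)
    flips = np.array([pyrandom.choice([1.0, -1.0]) for _ in range(n)])

    base = make_instruments(bx, by, sy)
    transformed = make_instruments((bx * flips)[perm], (by * flips)[perm], sy[perm])

    for fn, kwargs in [
        (ivw, {}),
        (mr_egger, {}),
        (weighted_median, {"n_boot": 0}),
        (weighted_mode, {"n_boot": 0}),
    ]:
        a, b = fn(base, **kwargs), fn(transformed, **kwargs)
        assert a.beta == pytest.approx(b.beta, rel=1e-9, abs=1e-12), fn.__name__
        if not math.isnan(a.se):
            assert a.se == pytest.approx(b.se, rel=1e-9, abs=1e-12), fn.__name__


@given(instrument_tables())
@settings(max_examples=50, deadline=None)
def test_weighted_median_lies_within_ratio_range(table):
    bx, by, sy = table
    est = weighted_median(make_instruments(bx, by, sy), n_boot=0)
    ratios = by / bx
    assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


def test_ci_and_or_scale_are_consistent(five_snp_instruments):
    est = ivw(five_snp_instruments)
    assert est.ci_low < est.beta < est.ci_high
    or_, lo, hi = est.or_scale
    assert lo == pytest.approx(math.exp(est.ci_low))
    assert hi == pytest.approx(math.exp(est.ci_high))
    assert est.ci_high - est.beta == pytest.approx(stats.norm.ppf(0.975) * est.se)
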