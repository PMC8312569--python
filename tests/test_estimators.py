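import math

import numpy as np
import pytest
from scipy import stats

from ivmr.estimators import (
    cochran_q,
    contamination_mixture,
    ivw_fixed_effects,
    ivw_random_effects,
    mr_egger,
    weighted_median,
    weighted_mode,
)
from ivmr.exceptions import EstimationError
from ivmr.harmonize import flip_variant

from conftest import hv


def ratio_variants(thetas, ses, gammas=None):
    """Build instruments whose Wald ratios/SEs are exactly the given values."""
    gammas = gammas if gammas is not None else np.ones(len(thetas))
    return [
        hv(f"rs{i}", g, 0.001, th * g, s * abs(g))
        for i, (th, s, g) in enumerate(zip(thetas, ses, gammas))
    ]


class TestIVW:
    def test_single_variant_equals_wald_ratio(self):
        e = ivw_random_effects([hv("rs1", 0.2, 0.01, 0.1, 0.05)])
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.25)
        assert e.n_variants == 1

    def test_two_variant_hand_weighted_least_squares(self):
        # gamma=1, se_y=0.1, Gamma={0.4,0.6}: w=100 each, beta=0.5,
        # Q=100*0.01+100*0.01=2, fixed SE=1/sqrt(200), RE SE=fixed*sqrt(2)=0.1
        vs = [hv("a", 1.0, 0.01, 0.4, 0.1), hv("b", 1.0, 0.01, 0.6, 0.1)]
        e = ivw_random_effects(vs)
        assert e.beta == pytest.approx(0.5)
        assert e.q_stat == pytest.approx(2.0)
        assert e.se == pytest.approx(0.1)
        assert ivw_fixed_effects(vs).se == pytest.approx(0.070711, abs=1e-6)

    def test_perfect_fit_floors_scale_at_one(self, rng):
        gammas = rng.uniform(0.05, 0.2, 10)
        vs = [hv(f"rs{i}", g, 0.01, 0.3 * g, 0.1) for i, g in enumerate(gammas)]
        e = ivw_random_effects(vs)
        assert e.beta == pytest.approx(0.3)
        assert e.q_stat == pytest.approx(0.0, abs=1e-20)
        assert e.se == pytest.approx(ivw_fixed_effects(vs).se)

    def test_equal_weights_equals_mean_of_ratios(self):
        thetas = [0.1, 0.4, 0.7]
        e = ivw_random_effects(ratio_variants(thetas, [0.2] * 3))
        assert e.beta == pytest.approx(np.mean(thetas))

    def test_all_zero_gamma_is_estimation_error(self):
        with pytest.raises(EstimationError):
            ivw_random_effects([hv("rs1", 0.0, 0.01, 0.1, 0.05)])

    def test_random_effects_se_never_below_fixed(self, rng):
        for trial in range(20):
            th = rng.normal(0, 0.3, 8)
            s = rng.uniform(0.05, 0.4, 8)
            vs = ratio_variants(th, s)
            assert ivw_random_effects(vs).se >= ivw_fixed_effects(vs).se - 1e-15


class TestEgger:
    def test_exact_proportional_data_no_pleiotropy(self, rng):
        gammas = rng.uniform(0.05, 0.2, 5)
        vs = [hv(f"rs{i}", g, 0.01, 0.2 * g, 0.1) for i, g in enumerate(gammas)]
        e = mr_egger(vs)
        assert e.beta == pytest.approx(0.2, abs=1e-12)
        assert e.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data(self, affine_instruments):
        e = mr_egger(affine_instruments)
        assert e.beta == pytest.approx(0.2, abs=1e-10)
        assert e.intercept == pytest.approx(0.05, abs=1e-10)

    def test_directional_pleiotropy_recovered_in_simulation(self):
        # mean pleiotropic offset 0.05 on every variant, J=100: the average
        # intercept over replicates recovers it within 2 Monte-Carlo SEs
        intercepts = []
        for k in range(200):
            r = np.random.default_rng(700 + k)
            j = 100
            g = np.abs(r.normal(0, 0.08, j)) + 0.02
            alpha = r.normal(0.05, 0.02, j)
            gh = g + 0.006 * r.standard_normal(j)
            big = 0.2 * g + alpha + 0.03 * r.standard_normal(j)
            vs = [hv(f"rs{i}", gh[i], 0.006, big[i], 0.03) for i in range(j)]
            intercepts.append(mr_egger(vs).intercept)
        mc_se = np.std(intercepts, ddof=1) / math.sqrt(len(intercepts))
        assert np.mean(intercepts) == pytest.approx(0.05, abs=2 * mc_se)

    def test_collinear_gammas_rejected(self):
        vs = [hv(f"rs{i}", 0.1, 0.01, 0.02 + 0.01 * i, 0.1) for i in range(4)]
        with pytest.raises(EstimationError, match="separable"):
            mr_egger(vs)

    def test_origin_constrained_fit_reproduces_fixed_ivw(self, rng):
        """Dropping the Egger intercept must give the fixed-effect IVW slope:
        both are the same weighted regression through the origin."""
        gammas = rng.uniform(0.05, 0.2, 8)
        big = 0.25 * gammas + rng.normal(0, 0.05, 8)
        se_y = rng.uniform(0.05, 0.15, 8)
        vs = [hv(f"rs{i}", g, 0.01, b, s) for i, (g, b, s) in enumerate(zip(gammas, big, se_y))]
        w = se_y**-2.0
        slope_origin = np.sum(w * gammas * big) / np.sum(w * gammas**2)
        assert ivw_fixed_effects(vs).beta == pytest.approx(slope_origin, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_equals_simple_median(self):
        e = weighted_median(ratio_variants([0.2, 0.5, 0.9], [0.1] * 3), n_boot=0)
        assert e.beta == pytest.approx(0.5)

    def test_textbook_median_for_odd_j(self, rng):
        thetas = sorted(rng.normal(0, 1, 7))
        e = weighted_median(ratio_variants(thetas, [0.1] * 7), n_boot=0)
        assert e.beta == pytest.approx(float(np.median(thetas)))

    def test_hand_interpolated_weighted_median(self):
        # ratios {1,2,3}, normalized weights {0.1,0.2,0.7}:
        # S={0.05,0.20,0.65}; estimate = 2+(0.5-0.2)/(0.65-0.2) = 2.667
        ses = [1 / math.sqrt(w) for w in (0.1, 0.2, 0.7)]
        e = weighted_median(ratio_variants([1.0, 2.0, 3.0], ses), n_boot=0)
        assert e.beta == pytest.approx(2.667, abs=5e-4)

    def test_majority_valid_recovers_theta(self):
        # 10 valid instruments at theta=0.3 plus 4 pleiotropic outliers
        # (balanced, <50% of total weight): estimate stays near 0.3
        reps = []
        for k in range(50):
            r = np.random.default_rng(500 + k)
            th = np.concatenate(
                [
                    0.3 + 0.05 * r.standard_normal(10),
                    1.5 + 0.3 * r.standard_normal(2),
                    -1.0 + 0.3 * r.standard_normal(2),
                ]
            )
            reps.append(weighted_median(ratio_variants(th, [0.08] * 14), n_boot=0).beta)
        reps = np.asarray(reps)
        mc_se = reps.std(ddof=1) / math.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(0.3, abs=2 * mc_se + 0.005)

    def test_bootstrap_se_is_reported(self):
        e = weighted_median(ratio_variants([0.2, 0.3, 0.4, 0.5], [0.1] * 4), n_boot=200, seed=1)
        assert e.se > 0
        assert e.ci_low < e.beta < e.ci_high

    def test_consistency_as_instruments_grow_stronger_and_more_numerous(self):
        """Bias under 40%-weight directional contamination shrinks along the
        joint asymptotics of a growing GWAS: more instruments with tighter
        per-variant ratio SEs."""
        def mean_bias(j, s, base):
            vals = []
            for k in range(60):
                r = np.random.default_rng(base + k)
                n_bad = int(0.4 * j)
                th = np.concatenate(
                    [0.3 + s * r.standard_normal(j - n_bad), r.normal(1.0, 0.2, n_bad)]
                )
                vals.append(weighted_median(ratio_variants(th, [s] * j), n_boot=0).beta)
            return abs(np.mean(vals) - 0.3)

        biases = [mean_bias(20, 0.16, 8_000), mean_bias(50, 0.08, 8_500), mean_bias(200, 0.02, 9_000)]
        assert biases[2] < biases[1] < biases[0]


class TestWeightedMode:
    def test_degenerate_density_returns_common_ratio(self):
        e = weighted_mode(ratio_variants([0.4, 0.4, 0.4], [0.1] * 3), n_boot=0)
        assert e.beta == pytest.approx(0.4)

    def test_outlier_resistant_mode(self):
        rng = np.random.default_rng(42)
        th = np.concatenate([0.5 + 0.01 * rng.standard_normal(9), [3.0]])
        e = weighted_mode(ratio_variants(th, [0.1] * 10), n_boot=0)
        assert e.beta == pytest.approx(0.5, abs=0.05)

    def test_symmetric_bimodal_ties_resolve_to_a_mode(self):
        th = [-1.0] * 5 + [1.0] * 5
        e = weighted_mode(ratio_variants(th, [0.1] * 10), n_boot=0)
        assert min(abs(e.beta - 1.0), abs(e.beta + 1.0)) < 0.05


class TestContaminationMixture:
    def test_exact_concordance(self):
        e = contamination_mixture(ratio_variants([0.3] * 5, [0.01] * 5))
        assert e.beta == pytest.approx(0.3, abs=1e-9)
        assert len(e.ci_set) == 1
        lo, hi = e.ci_set[0]
        assert lo <= 0.3 <= hi

    def test_majority_valid_recovers_theta(self):
        est = []
        for k in range(40):
            r = np.random.default_rng(4_000 + k)
            s = r.uniform(0.03, 0.08, 50)
            th = np.where(np.arange(50) < 30, 0.25, 0.0)
            spread = np.where(np.arange(50) < 30, 0.0, 0.25)
            ratios = th + r.standard_normal(50) * np.sqrt(s**2 + spread**2)
            est.append(contamination_mixture(ratio_variants(ratios, s)).beta)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert est.mean() == pytest.approx(0.25, abs=2 * mc_se + 0.005)

    def test_two_cluster_instance_gives_disjoint_confidence_set(self):
        rng = np.random.default_rng(7)
        th = np.concatenate([rng.normal(0, 0.005, 6), 1 + rng.normal(0, 0.005, 6)])
        e = contamination_mixture(ratio_variants(th, [0.02] * 12), psi=1.5)
        assert len(e.ci_set) == 2
        (l0, h0), (l1, h1) = e.ci_set
        assert l0 <= 0 <= h0 and l1 <= 1 <= h1

    def test_confidence_set_matches_direct_grid_oracle(self):
        """Re-evaluate the profile log-likelihood directly on the same grid
        and confirm the reported set is exactly the sub-3.841 region."""
        rng = np.random.default_rng(11)
        th = np.concatenate([rng.normal(0.2, 0.02, 8), rng.normal(0.9, 0.02, 4)])
        s = np.full(12, 0.05)
        psi = 0.6
        e = contamination_mixture(ratio_variants(th, s), psi=psi, n_grid=2001)
        grid = np.linspace(th.min() - 2 * s.max(), th.max() + 2 * s.max(), 2001)
        valid = stats.norm.logpdf(th[None, :], grid[:, None], s[None, :])
        invalid = stats.norm.logpdf(th, 0.0, np.sqrt(s**2 + psi**2))
        ll = np.maximum(valid, invalid[None, :]).sum(axis=1)
        inside = 2 * (ll.max() - ll) <= stats.chi2.ppf(0.95, 1)
        covered = np.zeros_like(inside)
        for lo, hi in e.ci_set:
            covered |= (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
        assert np.array_equal(inside, covered)
        assert e.beta == pytest.approx(grid[np.argmax(ll)])

    def test_pvalue_is_lr_test_at_null(self):
        e = contamination_mixture(ratio_variants([0.3] * 6, [0.05] * 6))
        assert e.pval < 1e-4  # strong common signal far from 0


class TestCochranQ:
    def test_perfect_fit(self):
        vs = ratio_variants([0.3, 0.3, 0.3], [0.1] * 3)
        q, df, p = cochran_q(vs, 0.3)
        assert q == pytest.approx(0.0, abs=1e-25)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_two_variant_hand_arithmetic(self):
        vs = [hv("a", 1.0, 0.01, 0.4, 0.1), hv("b", 1.0, 0.01, 0.6, 0.1)]
        q, df, p = cochran_q(vs, 0.5)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_q_over_df_near_one_under_homogeneity(self):
        qs = []
        for k in range(80):
            r = np.random.default_rng(6_000 + k)
            th = 0.2 + 0.1 * r.standard_normal(50)
            vs = ratio_variants(th, [0.1] * 50)
            q, df, _ = cochran_q(vs, ivw_random_effects(vs).beta)
            qs.append(q / df)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.05)


def test_all_estimators_invariant_to_subset_sign_flips(rng):
    """Re-expressing any subset of variants for the other allele leaves every
    estimate unchanged."""
    j = 12
    g = rng.uniform(0.05, 0.2, j)
    big = 0.25 * g + rng.normal(0, 0.03, j)
    vs = [hv(f"rs{i}", g[i], 0.01, big[i], 0.1) for i in range(j)]
    flip_mask = rng.random(j) < 0.5
    flipped = [flip_variant(v) if m else v for v, m in zip(vs, flip_mask)]
    for fn, kwargs in [
        (ivw_random_effects, {}),
        (mr_egger, {}),
        (weighted_median, {"n_boot": 0}),
        (weighted_mode, {"n_boot": 0}),
        (contamination_mixture, {}),
    ]:
        a, b = fn(vs, **kwargs), fn(flipped, **kwargs)
        assert a.beta == pytest.approx(b.beta, abs=1e-12), fn.__name__
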