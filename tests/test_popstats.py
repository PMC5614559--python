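"""Population statistics: co-tuning, dBF relations, axis sweep, paired tests."""

import itertools

import numpy as np
import pytest

from boutonmap.popstats import (co_tuning, compare_paired, delta_bf,
                                depth_cotuning_relation, distance_tuning_relation,
                                effect_size_r, normalized_bf_distribution,
                                region_bf_matching, tonotopic_axis)
from boutonmap.synth import BoutonPopulation, sample_bouton_population


class TestCoTuning:
    def test_identical_bfs_zero(self):
        assert co_tuning([2.0, 2.0, 2.0]) == 0.0

    def test_two_octave_spread(self):
        # BFs at f and 4f: log2 values {x, x+2}, sample SD = sqrt(2)
        assert co_tuning([1.0, 3.0]) == pytest.approx(np.sqrt(2.0))

    def test_matches_bruteforce_two_pass_sd(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.random(rng.integers(2, 30))
            mean = sum(v) / len(v)
            brute = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
            assert co_tuning(v) == pytest.approx(brute, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.random(20)
        assert co_tuning(v) == pytest.approx(co_tuning(v + 3.3), rel=1e-12)

    def test_monte_carlo_recovery_of_unit_sd(self):
        rng = np.random.default_rng(42)
        draws = rng.normal(3.0, 1.0, 10_000)
        assert co_tuning(draws) == pytest.approx(1.0, abs=0.03)

    def test_single_bouton_rejected(self):
        with pytest.raises(ValueError):
            co_tuning([1.0])


class TestDeltaBf:
    def test_identical_zero(self):
        assert delta_bf(2.5, 2.5) == 0.0

    def test_two_octaves_between_10_and_40_khz(self):
        assert delta_bf(np.log2(10), np.log2(40)) == pytest.approx(2.0)

    def test_symmetric(self):
        assert delta_bf(1.2, 4.5) == delta_bf(4.5, 1.2)


class TestDistanceTuning:
    def test_affine_gradient_perfect_rank_correlation(self):
        # irregular spacing avoids tied pair distances (ties deflate rho)
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.random(30) + 0.01)
        pop = BoutonPopulation(x, np.zeros_like(x), 0.02 * x)
        out = distance_tuning_relation(pop)
        assert out["R"] == pytest.approx(1.0)

    def test_shuffled_bfs_uncorrelated(self):
        rng = np.random.default_rng(3)
        pop = sample_bouton_population(300, 500, 0, 0.01, 0.0,
                                       bf_range_oct=(-50, 50), seed=3)
        shuffled = BoutonPopulation(pop.x_um, pop.y_um,
                                    rng.permutation(pop.bf_oct))
        out = distance_tuning_relation(shuffled)
        assert abs(out["R"]) < 0.05

    def test_equal_bf_exclusion_removes_exact_count(self):
        # 4 boutons, two sharing a BF -> exactly one zero-dBF pair
        pop = BoutonPopulation([0, 10, 20, 30], [0, 0, 0, 0],
                               [1.0, 2.0, 1.0, 3.0])
        full = distance_tuning_relation(pop, exclude_equal_bf=False)
        excl = distance_tuning_relation(pop, exclude_equal_bf=True)
        assert full["n_pairs"] == 6
        assert excl["n_pairs"] == 5
        assert (full["pairs"]["dbf_oct"] == 0).sum() == 1
        assert (excl["pairs"]["dbf_oct"] == 0).sum() == 0

    def test_invariant_to_translation_and_relabeling(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(40) * 100, rng.random(40) * 100
        bf = rng.random(40) * 4
        base = distance_tuning_relation(BoutonPopulation(x, y, bf))["R"]
        shifted = distance_tuning_relation(
            BoutonPopulation(x + 55, y - 30, bf))["R"]
        order = rng.permutation(40)
        relabeled = distance_tuning_relation(
            BoutonPopulation(x[order], y[order], bf[order]))["R"]
        assert shifted == pytest.approx(base, rel=1e-9)
        assert relabeled == pytest.approx(base, rel=1e-9)


class TestNormalizedBfDistribution:
    def test_single_region_centered_histogram(self):
        bfs = np.array([1.0, 2.0, 3.0])
        edges, avg = normalized_bf_distribution([bfs], bin_width_oct=1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        assert avg.sum() == pytest.approx(1.0)
        assert avg[np.abs(centers).argmin()] > 0  # mass at zero after centering

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        a = rng.random(41) * 3
        b = a + 1.0  # identical region, one octave up
        _, ha = normalized_bf_distribution([a])
        _, hb = normalized_bf_distribution([b])
        _, avg = normalized_bf_distribution([a, b])
        np.testing.assert_allclose(ha, hb)
        np.testing.assert_allclose(avg, ha)

    def test_median_of_centered_bfs_is_zero(self):
        rng = np.random.default_rng(6)
        bfs = rng.random(31)
        assert np.median(bfs - np.median(bfs)) == 0.0


class TestTonotopicAxis:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 125.0, 278.0])
    def test_noiseless_gradient_exact_on_isotropic_positions(self, angle):
        # positions on a regular circle: isotropic sample covariance, so the
        # Pearson profile peaks exactly at the generative angle
        t = np.arange(360) * np.pi / 180
        x, y = 100 * np.cos(t), 100 * np.sin(t)
        theta = np.deg2rad(angle)
        bf = 0.01 * (x * np.cos(theta) + y * np.sin(theta))
        est = tonotopic_axis(BoutonPopulation(x, y, bf), step_deg=1.0)
        assert est.angle_deg == angle

    def test_profile_antisymmetry(self):
        pop = sample_bouton_population(100, 300, 70, 0.01, 0.3, seed=7,
                                       bf_range_oct=(-50, 50))
        est = tonotopic_axis(pop, step_deg=1.0)
        np.testing.assert_allclose(est.profile, -np.roll(est.profile, 180),
                                   atol=1e-12)

    def test_rotation_equivariance(self):
        pop = sample_bouton_population(150, 300, 40, 0.01, 0.2, seed=8,
                                       bf_range_oct=(-50, 50))
        base = tonotopic_axis(pop).angle_deg
        phi = 90.0
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        rot = BoutonPopulation(c * pop.x_um - s * pop.y_um,
                               s * pop.x_um + c * pop.y_um, pop.bf_oct)
        rotated = tonotopic_axis(rot).angle_deg
        assert (rotated - base) % 360 == pytest.approx(phi, abs=1e-9)

    def test_noisy_gradient_within_ten_degrees(self):
        hits = 0
        for seed in range(100):
            pop = sample_bouton_population(300, 500, 125.0, 0.02, 0.5,
                                           bf_range_oct=(-50, 50), seed=seed)
            est = tonotopic_axis(pop)
            err = abs((est.angle_deg - 125.0 + 180) % 360 - 180)
            hits += err <= 10.0
        assert hits >= 95

    def test_zero_bf_variance_rejected(self):
        with pytest.raises(ValueError):
            tonotopic_axis(BoutonPopulation([0, 1, 2], [0, 1, 2], [1, 1, 1]))


def _exact_signed_rank_two_sided_p(diffs):
    """Enumeration oracle: all 2^n sign assignments of the ranked |diffs|."""
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[np.asarray(diffs) > 0].sum()
    w_all = [np.sum(ranks[list(signs)]) for r in range(n + 1)
             for signs in itertools.combinations(range(n), r)]
    w_all = np.array(w_all)
    mu = n * (n + 1) / 4
    p = np.mean(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-12)
    return p


class TestComparePaired:
    def test_identical_samples_null_result(self):
        a = np.arange(10.0)
        out = compare_paired(a, a)
        assert out.p_value == 1.0
        assert out.effect_size_r == 0.0

    def test_effect_size_formula(self):
        assert effect_size_r(3.0, 36) == pytest.approx(0.5)

    def test_six_positive_differences_exact_p(self):
        # all-positive differences, n=6: the two-sided signed-rank tail is
        # 2/2^6 = 0.03125 by exhaustive enumeration
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 30.0])
        b = np.array([4.5, 5.0, 6.2, 6.6, 7.5, 10.0])
        out = compare_paired(a, b, method="wilcoxon")
        oracle = _exact_signed_rank_two_sided_p(a - b)
        assert oracle == pytest.approx(2 / 64)
        assert out.p_value == pytest.approx(oracle)

    def test_normality_gate_switches_test(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 40)
        normal_out = compare_paired(base + rng.normal(0.5, 0.5, 40), base)
        skewed_out = compare_paired(base + rng.lognormal(0, 1.5, 40), base)
        assert normal_out.test == "ttest"
        assert skewed_out.test == "wilcoxon"

    def test_effect_size_matches_back_transformed_z(self):
        rng = np.random.default_rng(10)
        a = rng.normal(1.0, 1.0, 25)
        b = rng.normal(0.0, 1.0, 25)
        out = compare_paired(a, b)
        assert abs(out.effect_size_r) <= 1.0
        assert out.effect_size_r == pytest.approx(out.z / np.sqrt(25))


class TestRegionMatching:
    def test_identical_vectors_r_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, n = region_bf_matching(a, a)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_reversed_linear_sequence_r_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, _, _ = region_bf_matching(a, a[::-1])
        assert r == pytest.approx(-1.0)

    def test_attenuation_matches_shared_signal_fraction(self):
        # oracle: with shared signal sigma_s and independent noise sigma_e,
        # E[r] ~= sigma_s^2 / (sigma_s^2 + sigma_e^2)
        sigma_s, sigma_e = 1.0, 0.5
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(1000):
            s = rng.normal(0, sigma_s, 36)
            r, _, _ = region_bf_matching(s + rng.normal(0, sigma_e, 36),
                                         s + rng.normal(0, sigma_e, 36))
            rs.append(r)
        expected = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        assert np.mean(rs) == pytest.approx(expected, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            region_bf_matching([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDepthCotuning:
    def test_monotone_relation_r_one(self):
        depths = np.array([50.0, 100.0, 200.0, 300.0])
        cots = np.array([0.5, 0.8, 1.0, 1.4])
        r, _ = depth_cotuning_relation(depths, cots)
        assert r == pytest.approx(1.0)

    def test_constant_cotuning_flagged(self):
        with pytest.raises(ValueError):
            depth_cotuning_relation([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_shuffled_depths_mostly_nonsignificant(self):
        rng = np.random.default_rng(12)
        cots = rng.random(36)
        nonsig = 0
        for _ in range(100):
            r, p = depth_cotuning_relation(rng.permutation(36.0 + np.arange(36)),
                                           cots)
            nonsig += p > 0.05
        assert nonsig >= 90
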