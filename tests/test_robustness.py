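"""Removal kernel, extinction cascades, R50 simulation and Weibull fits."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodwebtopo import (
    FoodWeb,
    cascade_extinctions,
    fit_weibull,
    removal_kernel,
    robustness_curve,
    simulate_R50,
    weibull_cdf_curve,
)
from foodwebtopo.robustness import RobustnessCurve, _fit_weibull_xy


class TestRemovalKernel:
    def test_uniform_at_zero_intentionality(self):
        kern = removal_kernel([1, 1, 2, 3], 0.0)
        probs = dict(zip(kern.k_classes.tolist(), kern.class_probs.tolist()))
        assert probs == pytest.approx({1: 0.5, 2: 0.25, 3: 0.25})

    def test_half_intentionality_weights(self):
        # weights (1-I)^(kmax-k) * N_k = 0.25*2, 0.5*1, 1*1 -> {.25,.25,.5}
        kern = removal_kernel([1, 1, 2, 3], 0.5)
        probs = dict(zip(kern.k_classes.tolist(), kern.class_probs.tolist()))
        assert probs == pytest.approx({1: 0.25, 2: 0.25, 3: 0.5})

    def test_limit_concentrates_on_max_degree(self):
        kern = removal_kernel([1, 1, 2, 3], 1 - 1e-9)
        probs = dict(zip(kern.k_classes.tolist(), kern.class_probs.tolist()))
        assert probs[3] == pytest.approx(1.0, abs=1e-8)

    def test_out_of_range_I_errors(self):
        for I in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                removal_kernel([1, 2], I)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 40), min_size=1, max_size=60),
        st.floats(0.0, 0.999),
    )
    def test_probabilities_sum_to_one(self, degrees, I):
        kern = removal_kernel(degrees, I)
        assert kern.class_probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (kern.class_probs >= 0).all()

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_node_probability_ratio_monotone_in_I(self, seed):
        """For k1 < k2 the per-node odds in favour of the higher-degree node
        never decrease as intentionality grows."""
        rng = np.random.default_rng(seed)
        degrees = rng.integers(0, 12, size=20)
        if degrees.min() == degrees.max():
            return
        k1, k2 = int(degrees.min()), int(degrees.max())
        prev_ratio = 0.0
        for I in (0.0, 0.3, 0.6, 0.9):
            kern = removal_kernel(degrees, I)
            p = kern.node_probabilities([k1, k2])
            ratio = p[1] / p[0]
            assert ratio >= prev_ratio - 1e-12
            prev_ratio = ratio

    def test_empirical_uniformity_at_I0(self):
        """At I=0 the kernel is uniform over nodes: 1e5 draws match 1/S
        within 3 sigma binomial bounds for every node."""
        degrees = [1, 1, 2, 3, 3, 5, 8, 9]
        S = len(degrees)
        kern = removal_kernel(degrees, 0.0)
        p_node = kern.node_probabilities(degrees)
        assert np.allclose(p_node, 1 / S, atol=1e-12)
        rng = np.random.default_rng(123)
        n = 100_000
        draws = rng.choice(S, size=n, p=p_node)
        counts = np.bincount(draws, minlength=S)
        sigma = math.sqrt(n * (1 / S) * (1 - 1 / S))
        assert (np.abs(counts - n / S) <= 3 * sigma).all()


class TestCascades:
    def test_chain_two_step_cascade(self, chain_3):
        assert cascade_extinctions(chain_3, {"A"}) == {"B", "C"}

    def test_complete_web_never_cascades(self):
        sp = [f"s{j}" for j in range(5)]
        web = FoodWeb("k5", sp, {(a, b) for a in sp for b in sp if a != b})
        for pair in itertools.combinations(sp, 2):
            assert cascade_extinctions(web, set(pair)) == set()

    def test_star_hub_loss_kills_all_consumers(self, star_10):
        secondary = cascade_extinctions(star_10, {"hub"})
        assert secondary == {f"c{j}" for j in range(9)}

    def test_basal_species_immune(self, double_star_12):
        # losing every consumer never kills the basal hubs
        consumers = {f"d{j}" for j in range(10)}
        assert cascade_extinctions(double_star_12, consumers) == set()

    def test_unknown_species_errors(self, chain_3):
        with pytest.raises(ValueError):
            cascade_extinctions(chain_3, {"Z"})


class TestSimulateR50:
    def test_complete_web_is_exactly_half(self, complete_10):
        for I in (0.0, 0.5, 0.95):
            r = simulate_R50(complete_10, I, 20, seed=1)
            assert np.all(r == 0.5)

    def test_star_targeted_attack_hits_hub_first(self, star_10):
        r = simulate_R50(star_10, 0.99, 100, seed=2)
        assert np.mean(r == 0.1) >= 0.95

    def test_two_species_web_forced(self):
        web = FoodWeb("pair", ["A", "B"], {("A", "B")})
        r = simulate_R50(web, 0.0, 10, seed=3)
        assert np.all(r == 0.5)

    def test_deterministic_given_seed(self, star_10):
        a = simulate_R50(star_10, 0.4, 50, seed=9)
        b = simulate_R50(star_10, 0.4, 50, seed=9)
        assert np.array_equal(a, b)

    def test_deterministic_targeting_at_I_one(self, star_10):
        r = simulate_R50(star_10, 1.0, 20, seed=4)
        assert np.all(r == 0.1)

    def test_brute_force_E_distribution_small_web(self, double_star_12):
        """On a small web at I=0 the law of E (primary removals to reach
        50%) equals the uniform-permutation enumeration: drawing uniformly
        among survivors is the same process as walking a random permutation
        and skipping the already-extinct."""
        h = ["h0", "h1"]
        cons = [f"d{j}" for j in range(4)]
        links = {(h[0], c) for c in cons[:2]} | {(h[1], c) for c in cons[2:]}
        web = FoodWeb("ds6", h + cons, links)
        S = len(web.species)
        resources = {s: web.resources_of(s) for s in web.species}

        def enumerate_E():
            counts = {}
            for perm in itertools.permutations(web.species):
                extinct, E = set(), 0
                for victim in perm:
                    if victim in extinct:
                        continue
                    extinct.add(victim)
                    E += 1
                    while True:  # cascade fixpoint
                        dying = {
                            s for s in web.species
                            if s not in extinct and resources[s]
                            and resources[s] <= extinct
                        }
                        if not dying:
                            break
                        extinct |= dying
                    if len(extinct) >= 0.5 * S:
                        counts[E] = counts.get(E, 0) + 1
                        break
            total = sum(counts.values())
            return {e: c / total for e, c in counts.items()}

        expected = enumerate_E()
        n = 4000
        sim = simulate_R50(web, 0.0, n, seed=17)
        E_sim = np.round(sim * S).astype(int)
        for e, p in expected.items():
            obs = np.mean(E_sim == e)
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 3 * sigma + 1e-9, (e, obs, p)
        assert set(np.unique(E_sim)) <= set(expected)


class TestRobustnessCurve:
    def test_complete_web_flat_curve(self, complete_10):
        curve = robustness_curve(complete_10, I_grid=[0.0, 0.3, 0.6, 0.9],
                                 n_reps=10, seed=0)
        assert np.allclose(curve.r50_mean, 0.5)

    def test_single_point_grid(self, star_10):
        curve = robustness_curve(star_10, I_grid=[0.5], n_reps=5, seed=0)
        assert curve.r50_mean.shape == (1,)

    def test_replicates_within_unit_interval(self, star_10):
        curve = robustness_curve(star_10, I_grid=[0.0, 0.5], n_reps=20, seed=1)
        assert ((curve.r50_reps > 0) & (curve.r50_reps <= 1)).all()

    def test_reruns_identical(self, double_star_12):
        c1 = robustness_curve(double_star_12, I_grid=[0.0, 0.4, 0.8], n_reps=15, seed=5)
        c2 = robustness_curve(double_star_12, I_grid=[0.0, 0.4, 0.8], n_reps=15, seed=5)
        assert np.array_equal(c1.r50_reps, c2.r50_reps)


class TestWeibullFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 0.95, 20)
        y = weibull_cdf_curve(x, 1.0, 2.0, 3.0)
        params = _fit_weibull_xy(x, y, seed=0)
        assert params.a == pytest.approx(1.0, abs=1e-3)
        assert params.b == pytest.approx(2.0, abs=1e-3)
        assert params.c == pytest.approx(3.0, abs=1e-3)

    def test_unit_parameters_closed_form(self):
        assert weibull_cdf_curve(1.0, 1, 1, 1) == pytest.approx(1 - math.exp(-1), abs=1e-12)
        assert weibull_cdf_curve(0.0, 1, 1, 1) == 0.0

    def test_flat_curve_gives_zero_amplitude(self, complete_10):
        curve = robustness_curve(complete_10, I_grid=[0, 0.3, 0.6, 0.9],
                                 n_reps=5, seed=0)
        params = fit_weibull(curve)
        assert abs(params.a) < 1e-6
        assert params.rss < 1e-10

    def test_drop_response_orientation(self):
        grid = np.linspace(0, 0.95, 8)
        means = 0.5 - weibull_cdf_curve(grid, 0.3, 2.0, 2.0)
        curve = RobustnessCurve(grid, means, np.tile(means[:, None], (1, 2)), 2, 0)
        params = fit_weibull(curve, seed=0)
        assert params.a == pytest.approx(0.3, abs=1e-3)
        assert params.b == pytest.approx(2.0, abs=1e-3)
        assert params.c == pytest.approx(2.0, abs=1e-3)

    def test_too_few_points_errors(self):
        grid = np.array([0.0, 0.5, 0.9])
        curve = RobustnessCurve(grid, np.zeros(3), np.zeros((3, 1)), 1, 0)
        with pytest.raises(ValueError):
            fit_weibull(curve)
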