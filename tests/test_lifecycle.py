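import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chisquare, norm

from habconstruct import (
    ConfigurationError,
    DispersalSpec,
    Genome,
    ModelParams,
    apply_selection,
    construction_benefit,
    displacement,
    island_disperse,
    make_gamete,
    make_profile,
    mutate,
    run_generation,
    sigma_for_rate,
    stepping_stone_disperse,
    survival_probability,
)
from habconstruct.lifecycle import reproduce_deme

from conftest import make_state

NEUTRAL = dict(phi=0.0, gamma=0.0, omega=1e9)  # W = 1 for every phenotype


class TestConstructionBenefit:
    @pytest.mark.parametrize("S, optimum, phi, expected", [
        (10.0, 10.0, 0.5, 1.0),    # at the optimum
        (0.0, 10.0, 0.5, 0.5),     # at the baseline, phi = 50%
        (5.0, 10.0, 0.5, 0.75),
        (16.0, 10.0, 0.5, 0.7),    # overshoot penalized symmetrically
        (40.0, 10.0, 0.5, -0.5),   # not floored at 1 - phi
    ])
    def test_linear_penalty(self, S, optimum, phi, expected):
        assert construction_benefit(S, optimum, phi, 10.0) == pytest.approx(expected)


class TestSurvivalProbability:
    def test_cost_of_maximal_construction_is_one_percent(self):
        p = ModelParams(phi=0.0)
        w = survival_probability(T=10.0, S=10.0, optimum_t=10.0, B=5.0, params=p)
        assert w == pytest.approx(0.99)

    def test_one_selection_width_from_optimum(self):
        p = ModelParams(phi=0.0, gamma=0.0)
        w = survival_probability(T=4.0, S=0.0, optimum_t=0.0, B=0.0, params=p)
        assert w == pytest.approx(np.exp(-0.5))

    def test_negative_values_clamp_to_zero(self):
        p = ModelParams(phi=1.0, gamma=0.5)
        w = survival_probability(T=0.0, S=0.0, optimum_t=50.0, B=5.0, params=p)
        assert w == 0.0

    def test_never_exceeds_one(self, rng):
        p = ModelParams()
        T = rng.normal(0, 10, 500)
        S = rng.normal(0, 10, 500)
        w = survival_probability(T, S, S + 1.0, np.full(500, 2.5), p)
        assert np.all((w >= 0.0) & (w <= 1.0))


class TestApplySelection:
    def test_certain_survival_and_certain_death(self, rng):
        state = make_state([0, 0, 1, 1], trait_sum=0.0)
        p = ModelParams(n_demes=2, deme_capacity=2, dispersal_rate=0.0, **NEUTRAL)
        S = np.zeros(2)
        state = apply_selection(state, S, np.zeros(2), p, rng)
        assert state.n_individuals == 4
        # phi=1 with S far from optimum makes f<=0 -> W=0 everywhere
        p0 = ModelParams(n_demes=2, deme_capacity=2, dispersal_rate=0.0, phi=1.0)
        state = apply_selection(state, S, np.full(2, 40.0), p0, rng)
        assert state.extinct

    def test_survivor_fraction_matches_bernoulli_probability(self, rng):
        n = 10_000
        # T one selection width from S, f=1, no cost: W = exp(-1/2)
        state = make_state(np.zeros(n, dtype=int), trait_sum=4.0, n_demes=1)
        p = ModelParams(n_demes=1, deme_capacity=n, dispersal_rate=0.0,
                        phi=0.0, gamma=0.0)
        w = np.exp(-0.5)
        state = apply_selection(state, np.zeros(1), np.zeros(1), p, rng)
        se = np.sqrt(w * (1 - w) / n)
        assert state.n_individuals / n == pytest.approx(w, abs=3 * se)


class TestIslandDispersal:
    def test_zero_rate_changes_nothing(self, rng):
        state = make_state([0, 1, 2, 3])
        before = state.deme.copy()
        island_disperse(state, 0.0, rng)
        np.testing.assert_array_equal(state.deme, before)

    def test_full_rate_with_two_demes_swaps_everyone(self, rng):
        state = make_state([0, 0, 1, 1])
        island_disperse(state, 1.0, rng)
        np.testing.assert_array_equal(state.deme, [1, 1, 0, 0])

    def test_single_deme_raises(self, rng):
        state = make_state([0, 0], n_demes=1)
        with pytest.raises(ConfigurationError):
            island_disperse(state, 0.5, rng)

    def test_mover_fraction_and_destination_uniformity(self, rng):
        n, n_demes, rate = 10_000, 64, 0.44
        state = make_state(np.zeros(n, dtype=int), n_demes=n_demes)
        island_disperse(state, rate, rng)
        moved = state.deme != 0
        se = np.sqrt(rate * (1 - rate) / n)
        assert moved.mean() == pytest.approx(rate, abs=3 * se)
        counts = np.bincount(state.deme[moved], minlength=n_demes)[1:]
        assert chisquare(counts).pvalue > 0.01
        assert state.n_individuals == n  # dispersal conserves individuals


class TestSteppingStone:
    @pytest.mark.parametrize("z, expected", [(0.7, 0), (-2.3, -2), (1.0, 1), (-0.99, 0)])
    def test_displacement_truncates_toward_zero(self, z, expected):
        assert displacement(z) == expected

    def test_sigma_matches_root_finder_oracle(self):
        for rate in (0.04, 0.41, 0.92):
            oracle = brentq(lambda s: 2 * (1 - norm.cdf(1 / s)) - rate, 1e-3, 50.0)
            assert sigma_for_rate(rate) == pytest.approx(oracle, rel=1e-9)
        assert sigma_for_rate(0.41) == pytest.approx(1.215, abs=2e-3)

    def test_rate_bounds(self):
        assert sigma_for_rate(0.0) == 0.0
        with pytest.raises(ConfigurationError):
            sigma_for_rate(1.0)

    def test_zero_kernel_means_no_movement(self, rng):
        state = make_state([0, 1, 2], n_demes=50)
        spec = DispersalSpec("stepping_stone", 0.0, 0.0)
        before = state.deme.copy()
        stepping_stone_disperse(state, spec, rng)
        np.testing.assert_array_equal(state.deme, before)

    def test_movers_clamp_at_gradient_ends(self, rng):
        n = 20_000
        state = make_state(np.zeros(n, dtype=int), n_demes=3)
        spec = DispersalSpec("stepping_stone", 0.9, sigma_for_rate(0.9))
        stepping_stone_disperse(state, spec, rng)
        assert state.deme.min() >= 0 and state.deme.max() <= 2
        assert np.any(state.deme == 0)  # leftward moves were clamped in place

    def test_empirical_move_fraction_and_single_step_dominance(self, rng):
        n, rate = 100_000, 0.41
        state = make_state(np.full(n, 25), n_demes=50)
        spec = DispersalSpec("stepping_stone", rate, sigma_for_rate(rate))
        stepping_stone_disperse(state, spec, rng)
        steps = np.abs(state.deme - 25)
        se = np.sqrt(rate * (1 - rate) / n)
        assert (steps > 0).mean() == pytest.approx(rate, abs=3 * se)
        # most movers go exactly one deme
        assert (steps == 1).sum() > 0.5 * (steps > 0).sum()


class TestGametesAndMutation:
    def test_homozygous_parent_gives_deterministic_gamete(self, rng):
        g = Genome(np.full((5, 2), 1.5), np.full((5, 2), -0.5))
        gam = make_gamete(g, rng)
        np.testing.assert_array_equal(gam[0], np.full(5, 1.5))
        np.testing.assert_array_equal(gam[1], np.full(5, -0.5))

    def test_mendelian_segregation_and_independent_assortment(self, rng):
        # homolog 0 carries 0s, homolog 1 carries 1s at every locus
        alleles = np.zeros((5, 2))
        alleles[:, 1] = 1.0
        g = Genome(alleles, alleles)
        draws = np.array([make_gamete(g, rng)[0] for _ in range(10_000)])
        n = draws.shape[0]
        se = np.sqrt(0.25 / n)
        np.testing.assert_allclose(draws.mean(axis=0), 0.5, atol=3 * se)
        corr = np.corrcoef(draws, rowvar=False)
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off_diag) < 4 / np.sqrt(n))

    def test_zero_rate_leaves_alleles_unchanged(self, rng):
        a = rng.normal(size=(100, 5))
        np.testing.assert_array_equal(mutate(a, 0.0, 0.1, rng), a)

    def test_mutated_fraction_and_increment_variance(self, rng):
        n = 100_000
        a = np.zeros(n)
        out = mutate(a, 0.1, 0.1, rng)
        hit = out != 0.0
        se = np.sqrt(0.1 * 0.9 / n)
        assert hit.mean() == pytest.approx(0.1, abs=3 * se)
        incr = out[hit]
        m = incr.size
        # SE of a sample variance of N(0, 0.01): 0.01 * sqrt(2/(m-1))
        assert incr.var(ddof=1) == pytest.approx(0.01, abs=3 * 0.01 * np.sqrt(2 / (m - 1)))


class TestReproduction:
    def _arrays(self, sums, rng):
        state = make_state(np.zeros(len(sums), dtype=int), trait_sum=np.array(sums),
                           constr_sum=np.array(sums), n_demes=1)
        return state.trait, state.constr

    def test_no_survivors_no_offspring(self, rng):
        t, c = self._arrays([], rng)
        off_t, off_c = reproduce_deme(t, c, 8, ModelParams(), rng)
        assert off_t.shape[0] == 0

    def test_soft_selection_refills_to_capacity(self, rng):
        t, c = self._arrays([1.0, 2.0, 3.0], rng)
        off_t, off_c = reproduce_deme(t, c, 8, ModelParams(), rng)
        assert off_t.shape == (8, 5, 2) and off_c.shape == (8, 5, 2)

    def test_single_survivor_selfs(self, rng):
        t, c = self._arrays([7.0], rng)
        p = ModelParams(mutation_rate=0.0)
        off_t, off_c = reproduce_deme(t, c, 6, p, rng)
        # every offspring allele is a copy of the lone parent's (0.7 each)
        np.testing.assert_allclose(off_t, 0.7)
        np.testing.assert_allclose(off_c, 0.7)


class TestRunGeneration:
    def test_clonal_neutral_generation_is_closed(self, rng):
        # identical homozygous genomes, W=1, no dispersal, no mutation:
        # the offspring cohort is genetically identical to the parents
        p = ModelParams(n_demes=4, deme_capacity=4, dispersal_rate=0.0,
                        mutation_rate=0.0, **NEUTRAL)
        state = make_state(np.repeat(np.arange(4), 4), trait_sum=3.0, constr_sum=-2.0)
        profile = make_profile("uniform", 4)
        state = run_generation(state, profile, p, rng)
        assert state.generation == 1
        np.testing.assert_allclose(state.trait, 0.3)
        np.testing.assert_allclose(state.constr, -0.2)
        assert np.all(state.occupancy() == 4)

    def test_clonal_max_construction_converges_to_decay_balance(self, rng):
        # A large -> B = 5 per individual; N = 8 -> dH = 40/9; E -> dH/delta
        p = ModelParams(n_demes=4, deme_capacity=8, delta=0.5, dispersal_rate=0.0,
                        mutation_rate=0.0, **NEUTRAL)
        state = make_state(np.repeat(np.arange(4), 8), constr_sum=50.0, capacity=8)
        profile = make_profile("uniform", 4)
        for _ in range(60):
            state = run_generation(state, profile, p, rng)
        expected = (40.0 / 9.0) / 0.5
        np.testing.assert_allclose(state.env, expected, rtol=1e-6)

    def test_life_histories_differ_only_in_dispersal_timing(self, rng):
        # with a zero dispersal rate the two orderings are the same process
        base = dict(n_demes=4, deme_capacity=4, dispersal_rate=0.0, generations=5)
        out = {}
        for lh in ("move_first", "select_first"):
            p = ModelParams(life_history=lh, **base)
            r = np.random.default_rng(7)
            profile = make_profile("uniform", 4)
            from habconstruct import init_metapopulation
            s = init_metapopulation(p, r, profile)
            for _ in range(5):
                s = run_generation(s, profile, p, r)
            out[lh] = (s.trait.copy(), s.env.copy())
        np.testing.assert_array_equal(out["move_first"][0], out["select_first"][0])
        np.testing.assert_array_equal(out["move_first"][1], out["select_first"][1])

    def test_extinct_state_is_a_warned_noop(self, rng):
        state = make_state([], n_demes=4)
        profile = make_profile("uniform", 4)
        p = ModelParams(n_demes=4, deme_capacity=4)
        with pytest.warns(UserWarning):
            run_generation(state, profile, p, rng)
        assert state.generation == 0
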