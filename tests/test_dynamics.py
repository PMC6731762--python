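"""Deterministic dynamics: conservation, limits, steady states, stability."""

import numpy as np
import pytest

from territorysim import (
    CommunityState,
    ModelParams,
    NutrientSupply,
    StrategySet,
    growth_rates,
    integrate_to_steady_state,
    relaxation_time,
    well_mixed_rates,
)

from conftest import fd_steady_state, grid_aligned_lengths, random_instance


class TestGrowthRates:
    def test_mirror_symmetric_pair_is_stationary(self):
        state = CommunityState(np.array([0.5, 0.5]), 1.0)
        strat = StrategySet(np.array([[0.4, 0.6], [0.6, 0.4]]))
        sup = NutrientSupply(np.array([0.5, 0.5]))
        for tau in (1.0, 50.0, 400.0):
            r = growth_rates(state, strat, sup, ModelParams.from_tau_D(tau))
            np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_total_territory_conserved(self, rng):
        for _ in range(10):
            state, strat, sup, params = random_instance(rng)
            r = growth_rates(state, strat, sup, params)
            scale = params.v * sup.total * state.L
            assert abs(r.sum()) <= 1e-10 * scale

    def test_rates_match_fd_plus_quadrature_oracle(self, rng):
        # End-to-end: nutrient FD oracle + trapezoidal territory integrals.
        state, strat, sup, params = random_instance(
            rng, m=3, p=2, tau_range=(10.0, 10.0)
        )
        r = growth_rates(state, strat, sup, params)
        x, C = fd_steady_state(state.n, strat.alpha, sup.S, params.D, N=16384)
        h = state.L / x.size
        bounds = np.cumsum(state.n)
        seg = np.clip(np.searchsorted(bounds, x, side="right"), 0, state.m - 1)
        uptake = np.zeros((state.m, sup.p))
        for s in range(state.m):
            uptake[s] = C[seg == s].sum(axis=0) * h
        r_oracle = params.v * (strat.alpha * uptake).sum(axis=1) \
            - params.delta * state.n
        np.testing.assert_allclose(r, r_oracle, atol=1e-4 * np.abs(r).max())

    def test_extinct_species_has_zero_rate(self):
        state = CommunityState(np.array([0.6, 0.0, 0.4]), 1.0)
        strat = StrategySet(
            np.array([[0.5, 0.5], [0.3, 0.7], [0.6, 0.4]])
        )
        sup = NutrientSupply(np.array([0.4, 0.6]))
        r = growth_rates(state, strat, sup, ModelParams.from_tau_D(10.0))
        assert r[1] == 0.0

    def test_rotation_equivariance(self, rng):
        # Rotating the ring labels rotates the rates identically.
        state, strat, sup, params = random_instance(rng, m=4, p=2)
        r = growth_rates(state, strat, sup, params)
        shift = 2
        state2 = CommunityState(np.roll(state.n, shift), state.L)
        strat2 = StrategySet(np.roll(strat.alpha, shift, axis=0))
        r2 = growth_rates(state2, strat2, sup, params)
        np.testing.assert_allclose(r2, np.roll(r, shift), rtol=1e-9, atol=1e-14)


class TestWellMixedRates:
    def test_isolated_species_matches_spatial_uniform_solution(self):
        state = CommunityState(np.array([1.0]), 1.0)
        strat = StrategySet(np.array([[0.5, 0.5]]))
        sup = NutrientSupply(np.array([0.4, 0.6]))
        r = well_mixed_rates(state, strat, sup, ModelParams.from_tau_D(0.0))
        np.testing.assert_allclose(r, 0.0, atol=1e-15)

    def test_degenerate_manifold_is_stationary(self, rng):
        # Any community whose aggregate consumption yields c_i = S/E is fixed.
        # Construct one: for m=3, p=2 solve sum_sigma n alpha_i = s_i L.
        alpha = np.array([[0.2, 0.8], [0.5, 0.5], [0.8, 0.2]])
        sup = NutrientSupply(np.array([0.4, 0.6]))
        A = np.vstack([alpha.T, np.ones(3)])
        target = np.array([0.4, 0.6, 1.0])
        n, *_ = np.linalg.lstsq(A, target, rcond=None)
        assert np.all(n > 0)
        state = CommunityState(n, 1.0)
        r = well_mixed_rates(state, StrategySet(alpha), sup,
                             ModelParams.from_tau_D(0.0))
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_no_consumer_for_supplied_nutrient_raises(self):
        state = CommunityState(np.array([1.0]), 1.0)
        strat = StrategySet(np.array([[1.0, 0.0]]), budgets=np.array([1.0]))
        sup = NutrientSupply(np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="no consumer"):
            well_mixed_rates(state, strat, sup, ModelParams.from_tau_D(0.0))

    def test_spatial_rates_approach_well_mixed_limit(self, rng):
        # tau_D = 1e-4 spatial rates within 1% of the tau_D = 0 rates.
        for _ in range(5):
            state, strat, sup, _ = random_instance(rng, m=5, p=2)
            spatial = growth_rates(state, strat, sup,
                                   ModelParams.from_tau_D(1e-4))
            mixed = well_mixed_rates(state, strat, sup,
                                     ModelParams.from_tau_D(0.0))
            scale = np.abs(mixed).max()
            assert np.max(np.abs(spatial - mixed)) <= 1e-2 * scale


class TestIntegration:
    def test_snapshots_conserve_territory(self, supply_46):
        strat = StrategySet(np.array([[0.3, 0.7], [0.45, 0.55], [0.7, 0.3]]))
        traj = integrate_to_steady_state(
            CommunityState.equal(3), strat, supply_46,
            ModelParams.from_tau_D(10.0), rate_tol=1e-9,
        )
        sums = traj.populations.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-8)
        assert np.all(np.diff(traj.times) > 0)

    def test_well_mixed_typically_all_survive(self, supply_46):
        # Random 10-species sets at tau_D = 0 nearly always fully coexist.
        from territorysim import sample_strategies, survival_fraction

        fracs = []
        for r in range(10):
            strat = sample_strategies(10, 2, seed=100 + r)
            traj = integrate_to_steady_state(
                CommunityState.equal(10), strat, supply_46,
                ModelParams.from_tau_D(0.0), record=False,
            )
            assert traj.converged
            fracs.append(survival_fraction(traj.steady_state))
        assert np.mean(fracs) > 0.9

    def test_extinction_removal_and_mask(self, supply_46):
        # A strategy hopeless against the supply goes extinct and is clamped.
        strat = StrategySet(np.array([[0.45, 0.55], [0.98, 0.02]]))
        traj = integrate_to_steady_state(
            CommunityState.equal(2), strat, supply_46,
            ModelParams.from_tau_D(10.0), rate_tol=1e-9,
        )
        assert traj.extinct_mask[1]
        assert traj.steady_state.n[1] == 0.0
        assert traj.steady_state.n[0] == pytest.approx(1.0)

    def test_classification_only_mode_keeps_species(self, supply_46):
        strat = StrategySet(np.array([[0.45, 0.55], [0.98, 0.02]]))
        traj = integrate_to_steady_state(
            CommunityState.equal(2), strat, supply_46,
            ModelParams.from_tau_D(10.0), rate_tol=1e-9, t_max=200.0,
            remove_extinct=False,
        )
        assert traj.extinct_mask[1]
        assert traj.steady_state.n[1] > 0.0

    def test_spatial_steady_state_unique_well_mixed_degenerate(self, supply_46):
        # Two different initial conditions: the spatial community converges
        # to the same fixed point (the generic case; multistable exceptions
        # exist, cf. the Allee-effect scans); the well-mixed one lands on two
        # distinct points of its degenerate manifold.
        from territorysim import sample_strategies

        strat = sample_strategies(10, 2, seed=6)
        rng = np.random.default_rng(11)
        w = rng.dirichlet(np.ones(10))
        init_a = CommunityState.equal(10)
        init_b = CommunityState(w, 1.0)
        finals = {}
        for tag, params in (("spatial", ModelParams.from_tau_D(10.0)),
                            ("mixed", ModelParams.from_tau_D(0.0))):
            outs = []
            for init in (init_a, init_b):
                traj = integrate_to_steady_state(
                    init, strat, supply_46, params, rate_tol=1e-10,
                    t_max=1e7, record=False,
                )
                outs.append(traj.steady_state.n)
            finals[tag] = outs
        assert np.max(np.abs(finals["spatial"][0] - finals["spatial"][1])) < 1e-4
        assert np.max(np.abs(finals["mixed"][0] - finals["mixed"][1])) > 1e-3


class TestRelaxationTime:
    def test_requires_fixed_point(self, supply_46):
        strat = StrategySet(np.array([[0.3, 0.7], [0.7, 0.3]]))
        state = CommunityState(np.array([0.9, 0.1]), 1.0)
        with pytest.raises(ValueError, match="fixed point"):
            relaxation_time(state, strat, supply_46,
                            ModelParams.from_tau_D(10.0))

    def test_stable_spatial_fixed_point_spectrum(self, supply_46):
        strat = StrategySet(np.array([[0.35, 0.65], [0.45, 0.55],
                                      [0.6, 0.4]]))
        params = ModelParams.from_tau_D(40.0)
        traj = integrate_to_steady_state(
            CommunityState.equal(3), strat, supply_46, params,
            rate_tol=1e-11, t_max=1e7, record=False,
        )
        assert traj.converged
        res = relaxation_time(traj.steady_state, strat, supply_46, params)
        survivors = int((traj.steady_state.n > 0).sum())
        assert res.eigenvalues.size == survivors - 1
        assert np.all(res.eigenvalues.real <= 1e-10)
        assert res.tslow > 0

    def test_well_mixed_manifold_has_m_minus_p_zero_modes(self, supply_46):
        from territorysim import sample_strategies

        strat = sample_strategies(5, 2, seed=21)
        params = ModelParams.from_tau_D(0.0)
        traj = integrate_to_steady_state(
            CommunityState.equal(5), strat, supply_46, params,
            rate_tol=1e-12, record=False,
        )
        assert traj.converged and not traj.extinct_mask.any()
        res = relaxation_time(traj.steady_state, strat, supply_46, params)
        assert res.n_zero_modes == 5 - 2

    def test_slow_relaxation_scales_inversely_with_mixing_time(self, supply_46):
        # The degenerate well-mixed manifold becomes a slow manifold whose
        # restoring force grows like tau_D, so the slow relaxation time
        # scales as 1/tau_D in the small-tau_D regime: log tslow vs
        # log tau_D has slope about -1 over a 64-fold range.
        strat = StrategySet(np.array([[0.3, 0.7], [0.5, 0.5], [0.2, 0.8]]))
        taus = np.array([0.1, 0.4, 1.6, 6.4])
        tslows = []
        for tau in taus:
            params = ModelParams.from_tau_D(tau)
            traj = integrate_to_steady_state(
                CommunityState.equal(3), strat, supply_46, params,
                rate_tol=1e-12, t_max=1e9, record=False,
            )
            assert traj.converged
            assert traj.steady_state.n.min() > 0   # the slow mode needs m > p
            res = relaxation_time(
                traj.steady_state, strat, supply_46, params,
                step=1e-4, zero_threshold=1e-8,
            )
            tslows.append(res.tslow)
        slope = np.polyfit(np.log(taus), np.log(tslows), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)
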