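"""Simulator dynamics: growth kinetics, transfer mixing, washout, observation."""

import math

import numpy as np
import pandas as pd
import pytest

from transitqmp.reactor import ReactorConfig
from transitqmp.simulate import (
    METABOLITES,
    Influent,
    ReactorState,
    SpeciesParams,
    SpeciesSet,
    observe_chemistry,
    observe_fcm,
    observe_reads,
    simulate_experiment,
    step_growth,
    transfer_event,
)


def _state(cells, subs, mets=None):
    n_sp = len(cells)
    return ReactorState(
        0.0,
        np.tile(np.asarray(cells, dtype=float), (2, 1)),
        np.tile(np.asarray(subs, dtype=float), (2, 1)),
        np.tile(np.zeros(len(METABOLITES)) if mets is None else np.asarray(mets),
                (2, 1)),
    )


class TestStepGrowth:
    def test_saturated_growth_is_exact_exponential(self, saturated_species):
        state = _state([1e6], [50.0, 0, 0])
        out = step_growth(state, saturated_species, dt_h=0.5)
        expected = 1e6 * math.exp(0.3 * 0.5)
        assert out.cells_per_mL[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_zero_substrate_leaves_state_unchanged(self, saturated_species):
        state = _state([1e6], [0.0, 0, 0])
        out = step_growth(state, saturated_species, dt_h=1.0)
        assert np.array_equal(out.cells_per_mL, state.cells_per_mL)
        assert np.array_equal(out.metabolite_mM, state.metabolite_mM)

    def test_conservation_cells_equal_grams_times_yield(self, two_pool_species):
        state = _state([2e7, 3e7], [5.0, 4.0, 0.0])
        out = step_growth(state, two_pool_species, dt_h=0.4)
        d_cells = out.cells_per_mL[0] - state.cells_per_mL[0]
        d_simple = state.substrate_g_per_L[0, 0] - out.substrate_g_per_L[0, 0]
        d_fibre = state.substrate_g_per_L[0, 1] - out.substrate_g_per_L[0, 1]
        # species a feeds on simple carbs, species b on fibre, death = 0
        assert d_cells[0] == pytest.approx(d_simple * 2e11 / 1000.0, rel=1e-9)
        assert d_cells[1] == pytest.approx(d_fibre * 3e11 / 1000.0, rel=1e-9)

    def test_substrate_never_negative_under_large_step(self, saturated_species):
        state = _state([1e10], [0.01, 0, 0])
        out = step_growth(state, saturated_species, dt_h=2.0)
        assert (out.substrate_g_per_L >= 0).all()
        # growth was limited to what the pool could supply
        d_cells = out.cells_per_mL[0, 0] - 1e10
        assert d_cells == pytest.approx(0.01 * 1e11 / 1000.0, rel=1e-9)

    def test_invalid_state_rejected(self, saturated_species):
        state = _state([1e6], [50.0, 0, 0])
        state.cells_per_mL[0, 0] = np.nan
        with pytest.raises(ValueError, match="invalid state"):
            step_growth(state, saturated_species, dt_h=0.1)


class TestTransferEvent:
    def test_influent_identical_to_proximal_leaves_proximal_unchanged(
        self, short_config, saturated_species
    ):
        state = _state([0.0], [10.0, 5.0, 1.0], mets=np.full(len(METABOLITES), 2.0))
        influent = Influent(state.substrate_g_per_L[0].copy(),
                            state.metabolite_mM[0].copy())
        out = transfer_event(state, short_config, influent, volume_mL=50.0)
        np.testing.assert_allclose(out.substrate_g_per_L[0],
                                   state.substrate_g_per_L[0])
        np.testing.assert_allclose(out.metabolite_mM[0], state.metabolite_mM[0])

    def test_sterile_influent_dilutes_by_mixing_ratio(self, short_config):
        state = _state([1e8], [0.0, 0, 0])
        influent = Influent(np.zeros(3), np.zeros(len(METABOLITES)))
        v, vp = 50.0, short_config.proximal.volume_mL
        out = transfer_event(state, short_config, influent, volume_mL=v)
        assert out.cells_per_mL[0, 0] == pytest.approx(1e8 * (vp - v) / vp)

    def test_repeated_events_decay_geometrically(self, short_config):
        state = _state([1e8], [0.0, 0, 0])
        influent = Influent(np.zeros(3), np.zeros(len(METABOLITES)))
        v, vp = 25.0, short_config.proximal.volume_mL
        for _ in range(40):
            state = transfer_event(state, short_config, influent, volume_mL=v)
        rate = math.log(vp / (vp - v))
        assert state.cells_per_mL[0, 0] == pytest.approx(
            1e8 * math.exp(-40 * rate), rel=1e-9
        )

    def test_oversized_transfer_rejected(self, short_config):
        state = _state([1e8], [0.0, 0, 0])
        influent = Influent(np.zeros(3), np.zeros(len(METABOLITES)))
        with pytest.raises(ValueError, match="exceeds"):
            transfer_event(state, short_config, influent, volume_mL=201.0)


class TestSimulateExperiment:
    def test_washout_dichotomy_at_cycle_level(self):
        # medium arm, whole-cycle transfers: threshold ln(V/(V-v))/period
        rc = ReactorConfig.for_arm("medium")
        thresh = math.log(
            rc.proximal.volume_mL / (rc.proximal.volume_mL - rc.cycle_volume_mL)
        ) / rc.cycle_period_h  # ~0.0866/h
        species = SpeciesSet([
            SpeciesParams("below", 0.06, {"simple_carb": (0.0, 1.0)}, 1e13, {}),
            SpeciesParams("above", 0.12, {"simple_carb": (0.0, 1.0)}, 1e13, {}),
        ])
        assert species.saturated_mu()[0] < thresh < species.saturated_mu()[1]
        sim = simulate_experiment(
            rc, species, n_days=30, sample_days=[30], seed=0,
            subdoses_per_cycle=1,
            initial_cells_per_mL=np.array([1e7, 1e7]),
        )
        prox = sim.samples.loc[(30, "proximal")]
        assert prox["below"] < 1.0
        assert prox["above"] > 1e6

    def test_chemostat_residual_substrate_closed_form(self):
        # v/V -> 0: residual substrate approaches S* = K D / (mu - D)
        rc = ReactorConfig.for_arm("medium")
        D = rc.daily_flow_mL / rc.proximal.volume_mL / 24.0  # 0.0625 h^-1
        mu, K = 0.2, 1.0
        species = SpeciesSet([
            SpeciesParams("chemo", mu, {"simple_carb": (K, 1.0)}, 2e11, {})
        ])
        influent = Influent(np.array([20.0, 0, 0]), np.zeros(len(METABOLITES)))
        resids = {}
        for n_sub in (160, 800):
            sim = simulate_experiment(
                rc, species, n_days=25, sample_days=[25], seed=0,
                subdoses_per_cycle=n_sub, influent=influent,
                initial_cells_per_mL=np.array([1e8]),
            )
            resids[n_sub] = sim.samples.loc[(25, "proximal"), "sub_simple_carb"]
        s_star = K * D / (mu - D)
        # error shrinks as the dose fraction v/V shrinks, toward the
        # continuous-chemostat fixed point
        assert abs(resids[800] - s_star) < abs(resids[160] - s_star)
        assert resids[800] == pytest.approx(s_star, rel=0.05)

    def test_identical_seeds_identical_output(self, short_config, two_pool_species):
        kw = dict(n_days=3, sample_days=[2, 3], seed=42, donor="dX")
        a = simulate_experiment(short_config, two_pool_species, **kw)
        b = simulate_experiment(short_config, two_pool_species, **kw)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.cum_production_mmol, b.cum_production_mmol)

    def test_sample_day_outside_horizon_rejected(self, short_config, two_pool_species):
        with pytest.raises(ValueError, match="horizon"):
            simulate_experiment(short_config, two_pool_species, n_days=3,
                                sample_days=[5])

    def test_divergence_guard_trips(self, short_config):
        species = SpeciesSet([
            SpeciesParams("boom", 1.5, {"simple_carb": (0.0, 1.0)}, 1e18, {})
        ])
        with pytest.raises(FloatingPointError, match="diverged"):
            simulate_experiment(
                short_config, species, n_days=8, sample_days=[8], seed=0,
                initial_cells_per_mL=np.array([1e12]),
                influent=Influent(np.array([1e5, 0, 0]),
                                  np.zeros(len(METABOLITES))),
            )

    def test_flow_through_mass_balance_accounting(self, two_pool_species):
        """Independent ledger: substrate in - out - stored = consumed."""
        rc = ReactorConfig.for_arm("medium")
        influent = Influent(np.array([10.0, 8.0, 0.0]), np.zeros(len(METABOLITES)))
        state = _state([1e7, 1e7], [2.5, 2.0, 0.0])
        vols = np.array([rc.proximal.volume_mL, rc.distal.volume_mL])
        consumed = 0.0  # grams, proximal, from the cell-yield identity
        fed = 0.0
        exported = 0.0
        stored0 = state.substrate_g_per_L[0].sum() * vols[0] / 1000.0
        v = 100.0
        for _ in range(30):  # 30 cycles of 8 h at dt=0.1
            for _ in range(80):
                new = step_growth(state, two_pool_species, dt_h=0.1)
                d_cells = new.cells_per_mL[0] - state.cells_per_mL[0]
                consumed += (d_cells / two_pool_species.yield_).sum() * vols[0]
                state = new
            fed += influent.substrate_g_per_L.sum() * v / 1000.0
            exported += state.substrate_g_per_L[0].sum() * v / 1000.0
            state = transfer_event(state, rc, influent, volume_mL=v)
        stored = state.substrate_g_per_L[0].sum() * vols[0] / 1000.0
        lhs = fed - exported - (stored - stored0)
        assert lhs == pytest.approx(consumed, rel=1e-6)


class TestObservationLayer:
    def test_reads_single_species(self):
        reads = observe_reads(np.array([0.0, 5e8, 0.0]), np.array([3, 4, 5]),
                              depth=1000, seed=0)
        assert reads.tolist() == [0, 1000, 0]

    def test_reads_copy_number_bias(self, rng):
        # equal cells, copy numbers 1 and 4 -> expected proportions 0.2/0.8
        props = np.array([
            observe_reads(np.array([1e8, 1e8]), np.array([1, 4]), 500, rng)
            for _ in range(1000)
        ]) / 500.0
        se = math.sqrt(0.2 * 0.8 / 500 / 1000)
        assert abs(props[:, 0].mean() - 0.2) < 3 * se

    def test_reads_input_validation(self):
        with pytest.raises(ValueError):
            observe_reads(np.array([1e8]), np.array([4]), depth=0)
        with pytest.raises(ValueError):
            observe_reads(np.array([0.0, 0.0]), np.array([4, 4]), depth=100)

    def test_fcm_noise_free_recovers_truth(self):
        from transitqmp.fcm import build_gates, cell_concentration, gate_counts
        from transitqmp.simulate import synthetic_control_events

        truth = 2.5e9
        ev, vol, dil = observe_fcm(truth, cv=0.0, intact_fraction_true=1.0,
                                   n_events_target=20000, seed=3,
                                   noise_fraction=0.0)
        gates = build_gates(synthetic_control_events(20000, "negative", 1),
                            synthetic_control_events(20000, "heat_killed", 2))
        counts = gate_counts(ev, gates)
        conc = cell_concentration(counts["total"], vol, dil)
        one_event = cell_concentration(1, vol, dil)
        assert abs(conc - truth) <= 2 * one_event

    def test_fcm_all_intact_has_few_damaged(self):
        from transitqmp.fcm import build_gates, gate_counts
        from transitqmp.simulate import synthetic_control_events

        ev, *_ = observe_fcm(1e9, cv=0.0, intact_fraction_true=1.0,
                             n_events_target=20000, seed=5, noise_fraction=0.0)
        gates = build_gates(synthetic_control_events(20000, "negative", 1),
                            synthetic_control_events(20000, "heat_killed", 2))
        counts = gate_counts(ev, gates)
        assert counts["damaged"] <= 0.005 * len(ev)

    def test_fcm_concentration_unbiased_over_replicates(self):
        from transitqmp.fcm import build_gates, cell_concentration, gate_counts
        from transitqmp.simulate import synthetic_control_events

        gates = build_gates(synthetic_control_events(20000, "negative", 1),
                            synthetic_control_events(20000, "heat_killed", 2))
        truth = 1e9
        rng = np.random.default_rng(7)
        recovered = []
        for _ in range(200):
            ev, vol, dil = observe_fcm(truth, cv=0.05, intact_fraction_true=0.9,
                                       n_events_target=4000, seed=rng)
            counts = gate_counts(ev, gates)
            recovered.append(cell_concentration(counts["total"], vol, dil))
        assert abs(np.mean(recovered) / truth - 1.0) < 0.02

    def test_fcm_input_validation(self):
        with pytest.raises(ValueError):
            observe_fcm(1e9, cv=-0.1, intact_fraction_true=0.9,
                        n_events_target=100)
        with pytest.raises(ValueError):
            observe_fcm(1e9, cv=0.1, intact_fraction_true=1.5,
                        n_events_target=100)

    def test_chemistry_noise_contract(self, rng):
        truth = np.array([10.0, 40.0])
        assert np.array_equal(observe_chemistry(truth, 0.0), truth)
        reps = np.array([observe_chemistry(truth, 1.0, rng) for _ in range(10000)])
        se = 1.0 / math.sqrt(10000)
        assert np.all(np.abs(reps.mean(axis=0) - truth) < 3 * se)
        assert (reps >= 0).all()
        with pytest.raises(ValueError):
            observe_chemistry(np.array([-1.0]), 0.5)
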