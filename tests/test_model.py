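"""Unit and property tests for the network equations and integrators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from bgtcsim import (ConfigurationError, DBSSpec,
                     ModelParameters, SigmoidParams, SimulationConfig,
                     derivatives, load_preset, response_function, simulate,
                     simulate_batch, synaptic_drives)
from bgtcsim.model import EXCITATORY, POP_INDEX, POPULATIONS


# ---------------------------------------------------------------------------
# Sigmoid response
# ---------------------------------------------------------------------------

class TestResponseFunction:
    def test_zero_input_gives_exactly_zero(self):
        assert response_function(0.0, "e") == 0.0
        assert response_function(0.0, "i") == 0.0

    def test_value_at_threshold(self):
        # At x = theta the logistic term is 1/2, so Z = 1/2 - 1/(1+e^{b*theta})
        sig = SigmoidParams()
        expected_e = 0.5 - 1.0 / (1.0 + math.exp(sig.b_e * sig.theta_e))
        expected_i = 0.5 - 1.0 / (1.0 + math.exp(sig.b_i * sig.theta_i))
        assert response_function(sig.theta_e, "e") == pytest.approx(expected_e, abs=1e-12)
        assert response_function(sig.theta_i, "i") == pytest.approx(expected_i, abs=1e-12)
        assert expected_e == pytest.approx(0.49452, abs=1e-5)
        assert expected_i == pytest.approx(0.49939, abs=1e-5)

    def test_ceilings_match_printed_maxima(self):
        sig = SigmoidParams()
        assert response_function(1e3, "e") == pytest.approx(sig.k_e, abs=5e-4)
        assert response_function(1e3, "i") == pytest.approx(sig.k_i, abs=5e-4)
        assert sig.ceiling_consistency(tol=5e-4)

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError):
            response_function(float("nan"), "e")

    @given(x=st.floats(-10, 10), dx=st.floats(1e-3, 5))
    @hyp_settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, x, dx):
        # strict monotonicity holds where the logistic is not saturated to
        # machine precision
        sig = SigmoidParams()
        lo, hi = response_function(x, "e"), response_function(x + dx, "e")
        assert hi > lo
        offset = 1.0 / (1.0 + math.exp(sig.b_e * sig.theta_e))
        assert -offset < lo < 1.0 - offset


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class TestModelParameters:
    def test_rejects_negative_weights(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(weights=[-1.0] + [0.0] * 10)

    def test_rejects_wrong_weight_count(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(weights=[1.0] * 10)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(weights=[1.0] * 11, tau_ms=0.0)

    def test_replace_changes_exactly_one_field(self):
        base = load_preset("tremor")
        mod = base.replace(w7=22.0)
        diffs = [n for n in ("w1", "w2", "w3", "w4", "w5", "w6", "w7", "w8",
                             "w9", "w10", "w11", "ext")
                 if base.value(n) != mod.value(n)]
        assert diffs == ["w7"]
        assert mod.value("w7") == 22.0


# ---------------------------------------------------------------------------
# Drives and derivatives
# ---------------------------------------------------------------------------

class TestSynapticDrives:
    def test_zero_state_leaves_only_external_drive(self):
        p = load_preset("healthy")
        d = synaptic_drives(np.zeros(7), p)
        expected = np.zeros(7)
        expected[POP_INDEX["DCN"]] = p.ext
        np.testing.assert_array_equal(d, expected)

    def test_gpe_drive_hand_computed(self):
        # GPe argument is w7*E_STN - w8*I_GPe
        p = load_preset("tremor").replace(w7=5.0, w8=5.0)
        state = np.zeros(7)
        state[POP_INDEX["STN"]] = 0.5
        state[POP_INDEX["GPe"]] = 0.2
        d = synaptic_drives(state, p)
        assert d[POP_INDEX["GPe"]] == pytest.approx(5 * 0.5 - 5 * 0.2)

    def test_dbs_value_is_purely_additive(self, rng):
        p = load_preset("beta")
        state = rng.uniform(0, 0.5, 7)
        base = synaptic_drives(state, p)
        stim = synaptic_drives(state, p, dbs_value=2.5, dbs_target="STN")
        diff = stim - base
        assert diff[POP_INDEX["STN"]] == pytest.approx(2.5)
        mask = np.arange(7) != POP_INDEX["STN"]
        np.testing.assert_array_equal(diff[mask], 0.0)

    def test_unknown_target_rejected(self):
        with pytest.raises(ConfigurationError):
            synaptic_drives(np.zeros(7), load_preset("beta"),
                            dbs_value=1.0, dbs_target="Str")


class TestDerivatives:
    def test_origin_is_equilibrium_without_external_drive(self):
        p = ModelParameters(weights=np.arange(11, dtype=float), ext=0.0)
        d = derivatives(0.0, np.zeros(7), p)
        np.testing.assert_array_equal(d, np.zeros(7))

    def test_dcn_closed_form_fixed_point(self):
        p = load_preset("tremor")
        state = np.zeros(7)
        state[POP_INDEX["DCN"]] = p.dcn_fixed_point()
        d = derivatives(0.0, state, p)
        assert d[POP_INDEX["DCN"]] == pytest.approx(0.0, abs=1e-12)

    def test_zero_amplitude_dbs_is_inert(self, rng):
        p = load_preset("tremor")
        state = rng.uniform(0, 0.5, 7)
        quiet = DBSSpec(target="STN", amplitude=0.0, frequency=120.0)
        np.testing.assert_array_equal(derivatives(0.3, state, p, quiet),
                                      derivatives(0.3, state, p))


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_uncoupled_network_decays_exponentially(self):
        # With all weights and ext zero, each population obeys da/dt = -a/tau,
        # so the trajectory must match the closed-form exponential decay.
        p = ModelParameters(weights=[0.0] * 11, ext=0.0)
        cfg = SimulationConfig(duration=0.2, initial_state=np.full(7, 0.3))
        traj = simulate(p, cfg)
        expected = 0.3 * np.exp(-traj.times / 0.010)
        for i in range(7):
            np.testing.assert_allclose(traj.activity[:, i], expected,
                                       rtol=1e-4, atol=1e-7)
        assert np.all(np.diff(traj.activity, axis=0) <= 1e-12)

    def test_convergence_under_tolerance_tightening(self):
        p = load_preset("tremor")
        loose = simulate(p, SimulationConfig(duration=1.0))
        tight = simulate(p, SimulationConfig(duration=1.0, rel_tol=1e-7,
                                             abs_tol=1e-10))
        assert np.max(np.abs(loose.activity[-1] - tight.activity[-1])) < 1e-5

    def test_rk4_single_equals_batch_row(self):
        p = load_preset("beta")
        cfg = SimulationConfig(duration=0.5, integrator="rk4")
        single = simulate(p, cfg)
        times, batch = simulate_batch(
            np.vstack([p.weights, load_preset("tremor").weights]),
            np.array([p.ext, 3.42]), cfg)
        np.testing.assert_array_equal(single.activity, batch[0])
        np.testing.assert_array_equal(single.times, times)

    def test_dcn_is_decoupled_from_weights(self, rng):
        # DCN receives only ext, so its trace must be identical for any
        # weight vector and converge to the closed-form equilibrium.
        cfg = SimulationConfig(duration=0.5, integrator="rk4")
        p1 = load_preset("tremor")
        p2 = ModelParameters(weights=rng.uniform(0, 30, 11), ext=p1.ext)
        t1 = simulate(p1, cfg).population("DCN")
        t2 = simulate(p2, cfg).population("DCN")
        np.testing.assert_array_equal(t1, t2)
        assert t1[-1] == pytest.approx(p1.dcn_fixed_point(), abs=1e-9)

    def test_activity_stays_in_invariant_box(self, rng):
        # The shifted sigmoid can be slightly negative, so the invariant
        # box extends a little below zero: the exact lower edge for each
        # population is -k*off/(1-off) with off = 1/(1+exp(b*theta)).
        sig = SigmoidParams()
        b, theta, k, off = sig.population_constants()
        lower = -k * off / (1.0 - off)
        for _ in range(5):
            w = rng.uniform(0, 30, 11)
            p = ModelParameters(weights=w, ext=rng.uniform(0, 10))
            y0 = rng.uniform(0.0, np.where(EXCITATORY, sig.k_e, sig.k_i))
            traj = simulate(p, SimulationConfig(duration=0.3, integrator="rk4",
                                                initial_state=y0))
            assert np.all(traj.activity <= k + 1e-9)
            assert np.all(traj.activity >= lower - 1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(duration=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(duration=1.0, dt_output=0.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(integrator="euler")

    def test_random_initial_state_is_seeded(self):
        cfg1 = SimulationConfig(initial_state="random", seed=4)
        cfg2 = SimulationConfig(initial_state="random", seed=4)
        np.testing.assert_array_equal(cfg1.resolve_initial_state(),
                                      cfg2.resolve_initial_state())
        assert np.all(cfg1.resolve_initial_state() >= 0.05)
        assert np.all(cfg1.resolve_initial_state() <= 0.2)


class TestTrajectory:
    def test_population_accessor_matches_column_order(self, preset_trajectories):
        traj = preset_trajectories["tremor"]
        for i, name in enumerate(POPULATIONS):
            np.testing.assert_array_equal(traj.population(name),
                                          traj.activity[:, i])

    def test_frame_round_trip_columns(self, preset_trajectories):
        df = preset_trajectories["beta"].to_frame()
        assert list(df.columns) == ["time_s", *POPULATIONS]
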