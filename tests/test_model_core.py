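"""Cable discretization, KLT gating, integration and passive physics."""

from dataclasses import replace

import numpy as np
import pytest

from msoenergy import (AxonParams, CellSpec, IntegrationError,
                       calibrate_leak_reversal, detect_spikes,
                       discretize_cell, input_resistance,
                       klt_current_density, klt_tau_w, klt_w_inf,
                       klt_z_inf, passive_space_constant, simulate)

from conftest import analytic_input_resistance


class TestSpaceConstant:
    def test_default_matches_printed_value(self, default_spec):
        # closed form rounds to the experimentally constrained 191 um
        lam = passive_space_constant(default_spec)
        assert abs(lam - 191.0) < 0.5

    @pytest.mark.parametrize("changes,expected", [
        ({"g_L": 4 * 0.86}, 190.62321291575583 / 2),   # lambda ~ gL^-1/2
        ({"dendrite_diameter": 1.0}, 120.56),
    ])
    def test_scaling(self, default_spec, changes, expected):
        lam = passive_space_constant(replace(default_spec, **changes))
        assert lam == pytest.approx(expected, rel=1e-3)

    def test_formula_exact(self, default_spec):
        s = default_spec
        expected = np.sqrt(s.dendrite_diameter * 1e-4
                           / (4 * s.R_a * s.g_L * 1e-3)) * 1e4
        assert passive_space_constant(s) == pytest.approx(expected,
                                                          rel=1e-14)


class TestDiscretization:
    def test_default_counts(self, default_spec, default_grid):
        assert default_grid.n_per_dendrite == 40
        assert default_grid.n == 81
        assert default_grid.dx_um == pytest.approx(
            0.02 * passive_space_constant(default_spec))

    def test_long_dendrite(self, default_spec):
        grid = discretize_cell(replace(default_spec, dendrite_length=300.0))
        assert grid.n_per_dendrite == 79

    def test_point_neuron(self, default_spec):
        grid = discretize_cell(replace(default_spec, dendrite_length=0.0))
        assert grid.n == 1
        assert grid.soma_index == 0

    def test_total_area_conserved(self, default_spec, default_grid):
        total = default_grid.areas_cm2.sum() * 1e8
        assert total == pytest.approx(default_spec.total_area_um2(),
                                      rel=1e-3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CellSpec(dendrite_diameter=0.0, dendrite_length=100.0)


class TestKltGating:
    def test_resting_balance_product(self, default_spec):
        # w_inf(-60)^4 z_inf(-60) must balance the leak at rest for the
        # printed E_L = -47.4 mV
        p = float(klt_w_inf(-60.0)) ** 4 * float(klt_z_inf(-60.0))
        assert p == pytest.approx(0.01732, abs=2e-5)

    def test_tau_w_is_one_ms_at_rest(self):
        assert float(klt_tau_w(-60.0)) == pytest.approx(1.0, rel=1e-12)
        assert float(klt_tau_w(-60.0, tau_w_scale=2.5)) == pytest.approx(2.5)

    def test_current_density_zeros(self, default_spec):
        assert klt_current_density(-30.0, 0.5,
                                   replace(default_spec, g_KLT_bar=0.0)) == 0
        assert klt_current_density(default_spec.E_K, 0.7,
                                   default_spec) == 0

    def test_effective_space_constant_with_klt(self, default_spec):
        # linearized membrane conductance at rest must reproduce the
        # 100 um subthreshold length scale used to calibrate the gating
        s = default_spec
        v, dv = -60.0, 1e-4
        p0 = float(klt_w_inf(v)) ** 4 * float(klt_z_inf(v))
        dwdv = (float(klt_w_inf(v + dv)) - float(klt_w_inf(v - dv))) \
            / (2 * dv)
        g_eff = s.g_L + s.g_KLT_bar * p0 \
            + s.g_KLT_bar * 4 * float(klt_w_inf(v)) ** 3 \
            * float(klt_z_inf(v)) * dwdv * (v - s.E_K)
        lam_eff = passive_space_constant(s) * np.sqrt(s.g_L / g_eff)
        assert lam_eff == pytest.approx(100.0, rel=0.01)


class TestLeakCalibration:
    @pytest.mark.parametrize("g_klt,expected,tol", [
        (0.0, -60.0, 1e-12),
        (13.6, -47.4, 1e-6),
        (6.8, -53.7, 1e-3),   # halving the KLT density halves the offset
    ])
    def test_closed_form(self, default_spec, g_klt, expected, tol):
        el = calibrate_leak_reversal(replace(default_spec,
                                             g_KLT_bar=g_klt), -60.0)
        assert el == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_rest_is_fixed_point(self, default_spec):
        grid = discretize_cell(default_spec)
        trace = simulate(grid, default_spec, T=100.0)
        assert np.max(np.abs(trace.v_soma - default_spec.V_rest)) < 1e-4

    def test_recalibrated_variant_rests_at_target(self, default_spec):
        spec = replace(default_spec, g_KLT_bar=30.0, g_L=2.0).calibrated()
        trace = simulate(discretize_cell(spec), spec, T=100.0)
        assert abs(trace.v_soma[-1] - spec.V_rest) < 0.01


class TestIntegration:
    def test_passive_rc_charging(self, default_spec):
        # single passive compartment: exponential approach with
        # tau = C_m / g_L = 1.163 ms
        spec = replace(default_spec, dendrite_length=0.0, g_KLT_bar=0.0,
                       E_L=-60.0)
        grid = discretize_cell(spec)
        T, dt, amp = 10.0, 0.01, 0.05
        inj = np.full((1, int(T / dt) + 1), amp)
        trace = simulate(grid, spec, T, dt, i_inj=(np.array([0]), inj))
        tau = spec.C_m / spec.g_L
        g_abs = spec.g_L * grid.areas_cm2[0]          # mS
        v_inf = spec.E_L + amp * 1e-3 / g_abs         # uA / mS = mV
        t = trace.t
        exact = v_inf + (spec.E_L - v_inf) * np.exp(-t / tau)
        assert tau == pytest.approx(1.1628, abs=1e-3)
        assert np.max(np.abs(trace.v_soma - exact)) < 1e-3

    def test_second_order_convergence(self, default_spec):
        # global error on the passive step response scales as O(dt^2)
        spec = replace(default_spec, dendrite_length=0.0, g_KLT_bar=0.0,
                       E_L=-60.0)
        grid = discretize_cell(spec)
        T, amp = 5.0, 0.05

        def soma_final(dt):
            inj = np.full((1, int(round(T / dt)) + 1), amp)
            return simulate(grid, spec, T, dt,
                            i_inj=(np.array([0]), inj)).v_soma[-1]

        ref = soma_final(0.001)
        e_coarse = abs(soma_final(0.02) - ref)
        e_fine = abs(soma_final(0.01) - ref)
        assert 3.0 < e_coarse / e_fine < 5.0

    def test_gate_stays_bounded_under_strong_drive(self, default_spec):
        grid = discretize_cell(default_spec)
        n_steps = int(500.0 / 0.01)
        rng = np.random.default_rng(7)
        g = rng.uniform(0, 500.0, size=(2, n_steps + 1))
        from msoenergy import SynapticDrive
        drive = SynapticDrive(comp_idx=np.array([10, 60]), g_nS=g)
        trace = simulate(grid, default_spec, 500.0, drive=drive)
        assert 0.0 <= trace.w_bounds[0] <= trace.w_bounds[1] <= 1.0

    def test_blowup_raises(self, default_spec):
        grid = discretize_cell(default_spec)
        inj = np.full((1, 1001), np.nan)
        with pytest.raises(IntegrationError):
            simulate(grid, default_spec, 10.0, i_inj=(np.array([0]), inj))

    def test_steady_state_decay_follows_lambda(self, default_spec):
        # DC voltage profile along the dendrite matches the sealed-end
        # cable solution cosh((L-x)/lambda)/cosh(L/lambda) within 2%
        spec = replace(default_spec, g_KLT_bar=0.0, E_L=-60.0)
        grid = discretize_cell(spec)
        inj = np.full((1, int(200.0 / 0.01) + 1), 0.05)
        trace = simulate(grid, spec, 200.0, 0.01,
                         i_inj=(np.array([grid.soma_index]), inj),
                         record_idx=np.arange(grid.n))
        lam = passive_space_constant(spec)
        L = spec.dendrite_length
        order = np.argsort(trace.rec_idx)
        v_end = trace.v[order][:, -1] - spec.E_L
        dend = grid.dendrite_of == 0
        x = grid.positions_um[dend]
        profile = v_end[dend] / v_end[grid.soma_index]
        expected = np.cosh((L - x) / lam) / np.cosh(L / lam)
        assert np.max(np.abs(profile - expected) / expected) < 0.02


class TestSpikeDetection:
    def test_resting_soma_is_silent(self):
        v = np.full(5000, -60.0)
        assert detect_spikes(v, AxonParams(), 0.01).size == 0

    def test_subthreshold_epsp_is_silent(self):
        # somatic EPSPs peaking at -52 mV stay below the axonal threshold
        t = np.arange(0, 50.0, 0.01)
        v = np.full_like(t, -60.0)
        for t0 in np.arange(2.0, 48.0, 2.0):
            v += 8.0 * np.exp(-0.5 * ((t - t0) / 0.3) ** 2)
        assert v.max() == pytest.approx(-52.0, abs=0.1)
        assert detect_spikes(v, AxonParams(), 0.01).size == 0

    def test_suprathreshold_and_refractory(self):
        t = np.arange(0, 20.0, 0.01)
        v = np.full_like(t, -60.0)
        # two large EPSPs 0.5 ms apart, then one after 5 ms
        for t0 in (5.0, 5.5, 10.0):
            v += 18.0 * np.exp(-0.5 * ((t - t0) / 0.3) ** 2)
        spikes = detect_spikes(v, AxonParams(), 0.01)
        assert spikes.size == 2          # second EPSP falls in refractory
        assert spikes[1] - spikes[0] >= 1.0

    def test_invalid_axon_params(self):
        with pytest.raises(ValueError):
            AxonParams(threshold=-70.0)


class TestInputResistance:
    def test_klt_blocked_matches_experiment_and_oracle(self, default_spec):
        r = input_resistance(default_spec, "klt_blocked")
        assert r == pytest.approx(36.2, rel=0.02)
        assert r == pytest.approx(analytic_input_resistance(default_spec),
                                  rel=0.01)

    def test_control_near_experiment(self, default_spec):
        assert input_resistance(default_spec, "control") == pytest.approx(
            11.4, rel=0.10)

    def test_soma_only_closed_form(self, default_spec):
        spec = replace(default_spec, dendrite_length=0.0)
        r = input_resistance(spec, "klt_blocked")
        assert r == pytest.approx(92.6, rel=0.01)
        assert r == pytest.approx(analytic_input_resistance(spec),
                                  rel=1e-3)

    def test_unknown_mode(self, default_spec):
        with pytest.raises(ValueError):
            input_resistance(default_spec, "nonsense")
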