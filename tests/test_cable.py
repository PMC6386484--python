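"""Cable model: conductances, coupling matrix, integration and AP physics."""

import math

import numpy as np
import pytest

from tenssim.cable import (CableSimResult, CableState, axial_conductance,
                           cable_matrix, integrate_fiber, ionic_current,
                           membrane_conductances, resting_state)
from tenssim.fibers import FiberGeometry
from tenssim.kinetics import HHParams, Q10Param
from tenssim.stimulation import StimulusPulse

PULSE = StimulusPulse()
FIBER = FiberGeometry()
N = FIBER.n_nodes


def gaussian_cathodic_profile(amp_V, centre_m=0.012, width_m=0.0015, fiber=FIBER):
    """Negative (cathodic) extracellular bump centred mid-fibre."""
    x = np.arange(fiber.n_nodes) * fiber.dx_eff
    return -amp_V * np.exp(-((x - centre_m) ** 2) / (2 * width_m**2))


@pytest.fixture(scope="module")
def supra_result():
    return integrate_fiber(gaussian_cathodic_profile(0.2), PULSE, t_end=0.03)


@pytest.fixture(scope="module")
def sub_result():
    return integrate_fiber(gaussian_cathodic_profile(0.05), PULSE, t_end=0.03)


class TestFiberGeometry:
    def test_grouped_node_count_and_spacing(self):
        assert FIBER.dx_eff == pytest.approx(4 * 78.461e-6)
        assert FIBER.n_nodes == 96  # 30 mm span at the grouped spacing

    def test_rejects_bad_grouping(self):
        with pytest.raises(ValueError):
            FiberGeometry(grouping=0)


class TestConductances:
    def test_axial_conductance_uncorrected_resistivity(self):
        # pi d^2 / (4 rho dx) with rho = 0.25 ohm m and dx = 4 x 78.461 um
        params = HHParams(correct_rho_i=False)
        assert axial_conductance(FIBER, params) == pytest.approx(1.6016e-7, rel=1e-3)

    def test_axial_conductance_smaller_when_cooled(self):
        # the inverse Q10 raises rho_i below 37 degC, lowering G_a
        assert axial_conductance(FIBER, HHParams()) < axial_conductance(
            FIBER, HHParams(correct_rho_i=False)
        )

    def test_doubling_spacing_halves_axial_conductance(self):
        double = FiberGeometry(grouping=8)
        ratio = axial_conductance(FIBER) / axial_conductance(double)
        assert ratio == pytest.approx(2.0)

    def test_single_node_sodium_conductance(self):
        # ungrouped node, T = T0 so no Q10 correction:
        # G_Na,max = pi * 4e-6 * 1.061e-6 * 6400 ~ 8.53e-8 S
        fiber = FiberGeometry(grouping=1)
        params = HHParams(temperature=24.0)
        state = CableState(
            v=np.zeros(3), m=np.ones(3), n=np.ones(3), h=np.ones(3)
        )
        g_na, _, _ = membrane_conductances(state, params, fiber)
        assert g_na[0] == pytest.approx(8.533e-8, rel=1e-3)

    def test_closed_m_gate_blocks_sodium(self):
        state = CableState(v=np.zeros(2), m=np.zeros(2), n=np.ones(2), h=np.ones(2))
        g_na, _, _ = membrane_conductances(state)
        assert np.all(g_na == 0)

    def test_open_n_gate_gives_max_potassium(self):
        params, fiber = HHParams(), FIBER
        state = CableState(v=np.zeros(2), m=np.zeros(2), n=np.ones(2), h=np.ones(2))
        _, g_k, _ = membrane_conductances(state, params, fiber)
        assert g_k[0] == pytest.approx(params.g_k_at_t * fiber.membrane_area)

    def test_sodium_current_vanishes_at_reversal(self):
        params = HHParams()
        state = CableState(
            v=np.full(2, params.v_na_max), m=np.ones(2), n=np.zeros(2), h=np.ones(2)
        )
        # with K closed, only Na and leak conduct; Na's driving force is zero
        i = ionic_current(state, params)
        g_l = params.g_l_at_t * FIBER.membrane_area
        assert i[0] == pytest.approx(g_l * (params.v_na_max - params.v_l_max))

    def test_potassium_current_changes_sign_at_reversal(self):
        params = HHParams()
        for dv, sign in ((1e-3, 1), (-1e-3, -1)):
            state = CableState(
                v=np.full(1, params.v_k_max + dv),
                m=np.zeros(1), n=np.ones(1), h=np.ones(1),
            )
            i_k = ionic_current(state, params) - (
                params.g_l_at_t * FIBER.membrane_area
                * (state.v - params.v_l_max)
            )
            assert np.sign(i_k[0]) == sign


class TestCableMatrix:
    def test_rows_sum_to_zero(self):
        g = cable_matrix(17, 2.5e-7)
        assert np.allclose(g.sum(axis=1), 0.0, atol=0.0)

    def test_two_node_form(self):
        ga = 1.3e-7
        assert np.allclose(cable_matrix(2, ga), [[-ga, ga], [ga, -ga]])

    def test_annihilates_constant_vector(self):
        g = cable_matrix(9, 1e-7)
        assert np.allclose(g @ np.full(9, 0.42), 0.0)

    def test_rejects_single_node(self):
        with pytest.raises(ValueError):
            cable_matrix(1, 1e-7)


class TestRestingBehaviour:
    def test_resting_drift_below_one_millivolt(self):
        result = integrate_fiber(np.zeros(N), PULSE, t_end=0.03)
        assert np.max(np.abs(result.v)) < 1e-3

    def test_gates_stay_in_unit_interval(self, supra_result):
        result = integrate_fiber(
            gaussian_cathodic_profile(0.2), PULSE, t_end=0.02, keep_gates=True
        )
        for traj in result.gates.values():
            assert traj.min() >= 0.0 and traj.max() <= 1.0


class TestActionPotential:
    def test_all_or_none_threshold_bracketing(self):
        # over a x10 amplitude range responses split cleanly into
        # subthreshold (< 30 mV) and full APs (> 80 mV), with one switch
        peaks = []
        for amp in np.geomspace(0.05, 0.5, 8):
            r = integrate_fiber(gaussian_cathodic_profile(amp), PULSE, t_end=0.02)
            peaks.append(float(r.v.max()))
        assert all(p > 0.08 or p < 0.03 for p in peaks), peaks
        supra = [p > 0.08 for p in peaks]
        assert supra[-1] and not supra[0]
        switch = supra.index(True)
        assert all(supra[switch:])

    def test_bidirectional_propagation(self, supra_result):
        # a mid-fibre suprathreshold cathode launches spikes both ways
        v = supra_result.v
        assert v[:, 0].max() > 0.08 and v[:, -1].max() > 0.08

    def test_subthreshold_response_stays_local(self, sub_result):
        assert sub_result.v.max() < 0.03
        assert sub_result.last_node_trace().max() < 0.01

    def test_arrival_delay_scales_with_axial_conductance(self):
        # halving G_a (doubling rho_i) slows saltatory conduction
        delays = {}
        for factor in (0.5, 1.0, 2.0):
            params = HHParams(rho_i=Q10Param(0.25 / factor, 1 / 1.35, 37.0))
            r = integrate_fiber(
                gaussian_cathodic_profile(0.2), PULSE, params, t_end=0.03
            )
            trace = r.last_node_trace()
            assert trace.max() > 0.08
            delays[factor] = r.t[int(np.argmax(trace > 0.04))] - PULSE.onset
        assert delays[0.5] > delays[1.0] > delays[2.0]

    def test_cathodic_block_by_sustained_hyperpolarizing_flank(self):
        # a strong anodic flank between the excitation site and the CNS end
        # keeps that stretch hyperpolarised while current flows and kills
        # the travelling spike; without the flank the spike arrives
        pulse = StimulusPulse(onset=0.001, width=0.010)
        x = np.arange(N) * FIBER.dx_eff
        excite = -0.2 * np.exp(-((x - 0.008) ** 2) / (2 * 0.0015**2))
        # smoothstep anodic shelf: hyperpolarises the stretch beyond 16 mm
        # without the suprathreshold virtual-cathode lobes a localized bump
        # would create
        flank = 2.0 * 0.5 * (1 + np.tanh((x - 0.016) / 1.5e-3))
        blocked = integrate_fiber(excite + flank, pulse, t_end=0.011)
        free = integrate_fiber(excite, pulse, t_end=0.011)
        assert free.last_node_trace().max() > 0.08
        assert blocked.v.max() > 0.08  # the spike is initiated...
        assert blocked.last_node_trace().max() < 0.03  # ...but never arrives

    def test_tolerance_refinement_stability(self, supra_result):
        # halving solver tolerances moves the AP arrival time < 2 %
        def arrival(rtol, atol_v, atol_gate):
            r = integrate_fiber(
                gaussian_cathodic_profile(0.2), PULSE, t_end=0.03,
                rtol=rtol, atol_v=atol_v, atol_gate=atol_gate,
            )
            trace = r.last_node_trace()
            return float(r.t[int(np.argmax(trace > 0.04))] - PULSE.onset)

        base = arrival(1e-6, 1e-8, 1e-9)
        fine = arrival(5e-7, 5e-9, 5e-10)
        assert abs(fine - base) / base < 0.02


class TestResultContainer:
    def test_time_grid_and_initial_condition(self, sub_result):
        assert np.all(np.diff(sub_result.t) > 0)
        assert np.allclose(sub_result.v[0], 0.0, atol=1e-12)

    def test_snapshot_bounds_checked(self, sub_result):
        with pytest.raises(ValueError):
            sub_result.snapshot(1.0)

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_fiber(np.zeros(N + 3), PULSE)

    def test_sampling_resolves_ap_shape(self, supra_result):
        # output grid must be at least as fine as 0.05 ms
        assert np.max(np.diff(supra_result.t)) <= 5e-5 + 1e-12

    def test_long_format_export(self, sub_result):
        df = sub_result.to_frame()
        assert set(df.columns) == {"time_s", "node", "arc_length_mm", "v_mV"}
        assert len(df) == sub_result.v.size
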