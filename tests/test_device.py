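"""Drift-diffusion device core: electrostatics, transport, RFET behavior."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from rfetsense.constants import ELEMENTARY_CHARGE, EPSILON_0
from rfetsense.device import (BiasPoint, Device, DeviceSpec, MaterialParams,
                              bernoulli, build_device, gate_voltage_shift,
                              program_polarity, solve_bias_point,
                              solve_poisson_equilibrium, transfer_curve)
from rfetsense.errors import (ConfigurationError, DomainError, ValidationError)

from conftest import COARSE_MESH


class TestBuildDevice:
    def test_gate_footprints_from_printed_geometry(self, silicon):
        dev = build_device(DeviceSpec(**COARSE_MESH), silicon)
        x_nm = dev.x * 1e9
        cg = x_nm[dev.cg_mask]
        pg = x_nm[dev.pg_mask]
        assert cg.min() == 0.0 and cg.max() == pytest.approx(440.0)
        assert pg.min() == pytest.approx(560.0) and pg.max() == pytest.approx(1000.0)
        # 120 nm ungated spacer between the gates
        assert pg.min() - cg.max() == pytest.approx(120.0)

    def test_gates_may_tile_the_whole_channel(self, silicon):
        spec = DeviceSpec(gate_length_pg=500.0, gate_length_cg=500.0,
                          **COARSE_MESH)
        dev = build_device(spec, silicon)
        assert not np.any(~(dev.cg_mask | dev.pg_mask))

    def test_oversized_gates_rejected(self):
        with pytest.raises(ValidationError):
            DeviceSpec(gate_length_pg=600.0, gate_length_cg=600.0)

    def test_barrier_outside_gap_rejected(self, silicon):
        with pytest.raises(ConfigurationError):
            build_device(DeviceSpec(schottky_barrier_e=1.5, **COARSE_MESH),
                         silicon)


class TestEquilibriumPoisson:
    def test_unbiased_intrinsic_device_is_flat(self, coarse_device):
        state = solve_poisson_equilibrium(coarse_device, BiasPoint())
        assert np.abs(state.potential).max() < 1e-9
        assert state.current_drain == 0.0

    def test_mirror_symmetry_with_equal_gates(self, coarse_device):
        state = solve_poisson_equilibrium(coarse_device,
                                          BiasPoint(v_pg=1.0, v_cg=1.0))
        psi = state.potential
        assert np.abs(psi - psi[:, ::-1]).max() < 1e-8

    def test_negative_sheet_charge_lowers_pg_potential_monotonically(
            self, coarse_device):
        dev = coarse_device
        cols = dev.pg_mask.copy()
        cols[-1] = False  # the pinned drain contact column cannot move
        base = solve_poisson_equilibrium(dev, BiasPoint()).potential
        prev = base
        for sigma in (-2e-7, -5e-7, -1e-6):
            cur = solve_poisson_equilibrium(
                dev, BiasPoint(sigma_pg=sigma)).potential
            d = cur[dev.j_int][cols] - prev[dev.j_int][cols]
            assert np.all(d < 0)
            prev = cur

    def test_nonzero_vds_rejected(self, coarse_device):
        with pytest.raises(DomainError):
            solve_poisson_equilibrium(coarse_device, BiasPoint(v_ds=0.1))

    def test_mos_capacitor_depletion_oracle(self):
        """A single-gate doped reduction must match the classical depletion
        closed form V_G' = ψ_s + sqrt(2 q ε N_A ψ_s)/C_ox."""
        spec = DeviceSpec(gate_length_cg=500.0, gate_length_pg=500.0,
                          si_thickness=300.0, eot=5.0, mesh_nx=61, mesh_ny=45)
        mat = MaterialParams(acceptor_density=1e17)
        dev = build_device(spec, mat)
        na = 1e17 * 1e6
        psi_bulk = -dev.vt * math.log(na / dev.ni)
        c_ox = 3.9 * EPSILON_0 / (spec.eot * 1e-9)
        eps_si = 11.7 * EPSILON_0
        overdrive = 0.804
        vg = psi_bulk + overdrive
        state = solve_poisson_equilibrium(dev, BiasPoint(v_pg=vg, v_cg=vg))
        ic = int(np.argmin(np.abs(dev.x - 500e-9)))
        phi_num = (state.potential[dev.j_int, ic]
                   - state.potential[-1, ic])
        phi_ana = brentq(
            lambda p: p + math.sqrt(2 * ELEMENTARY_CHARGE * eps_si * na * p)
            / c_ox - overdrive, 1e-6, overdrive)
        assert phi_num == pytest.approx(phi_ana, rel=0.02)


class TestScharfetterGummel:
    def test_bernoulli_identity(self):
        x = np.array([-50.0, -3.0, -1e-4, 0.0, 1e-4, 3.0, 50.0])
        np.testing.assert_allclose(bernoulli(-x) - bernoulli(x), x,
                                   rtol=1e-12, atol=1e-12)

    def test_flux_reduces_to_pure_diffusion(self):
        # on a near-flat potential the SG flux must equal the central
        # difference to 1e-6 relative
        n1, n2 = 2.0e16, 1.0e16
        delta = 1e-9
        sg = bernoulli(-delta) * n1 - bernoulli(delta) * n2
        assert sg == pytest.approx(n1 - n2, rel=1e-6)

    def test_drift_dominates_at_large_drop(self):
        # strong field toward node 2: upwinded flux ~ δ·n1
        delta = 40.0
        n1, n2 = 1.0e16, 5.0e15
        sg = bernoulli(-delta) * n1 - bernoulli(delta) * n2
        assert sg == pytest.approx(delta * n1, rel=1e-12)


class TestTransport:
    def test_zero_drain_bias_gives_zero_current(self, coarse_device):
        state = solve_bias_point(coarse_device,
                                 BiasPoint(v_pg=5.0, v_cg=5.0, v_ds=0.0))
        assert abs(state.current_drain) < 1e-15

    def test_terminal_current_conservation(self, coarse_device):
        state = solve_bias_point(coarse_device,
                                 BiasPoint(v_pg=0.0, v_cg=5.0, v_ds=0.1,
                                           sigma_pg=6.4e-7))
        mismatch = abs(state.current_drain + state.current_source)
        assert mismatch / max(abs(state.current_drain), 1e-15) < 1e-3

    def test_carrier_densities_stay_positive(self, coarse_device):
        state = solve_bias_point(coarse_device,
                                 BiasPoint(v_pg=0.0, v_cg=5.0, v_ds=0.1))
        assert np.all(state.n > 0) and np.all(state.p > 0)

    def test_ambipolar_sign_flip_symmetry(self, coarse_symmetric_device):
        bias = BiasPoint(v_pg=2.0, v_cg=3.0, v_ds=0.1, sigma_pg=-3e-7)
        fwd = solve_bias_point(coarse_symmetric_device, bias)
        rev = solve_bias_point(coarse_symmetric_device, bias.scaled(-1.0))
        assert rev.current_drain == pytest.approx(-fwd.current_drain, rel=0.01)

    def test_n_programmed_on_exceeds_off(self, coarse_device):
        on = solve_bias_point(coarse_device,
                              BiasPoint(v_pg=5.0, v_cg=5.0, v_ds=0.1))
        off = solve_bias_point(coarse_device,
                               BiasPoint(v_pg=5.0, v_cg=0.0, v_ds=0.1))
        assert on.current_drain > 100.0 * abs(off.current_drain)

    def test_grid_refinement_stability(self, coarse_device, silicon):
        fine = build_device(DeviceSpec(mesh_nx=201, mesh_ny=32), silicon)
        bias = BiasPoint(v_pg=0.0, v_cg=5.0, v_ds=0.1, sigma_pg=6.4e-7)
        a = solve_bias_point(coarse_device, bias).current_drain
        b = solve_bias_point(fine, bias).current_drain
        assert abs(b - a) / abs(a) < 0.05

    def test_quantum_correction_toggle_runs(self, silicon):
        dev = build_device(DeviceSpec(quantum_correction=True, **COARSE_MESH),
                           silicon)
        state = solve_bias_point(dev, BiasPoint(v_pg=0.0, v_cg=3.0, v_ds=0.1))
        assert state.converged and math.isfinite(state.current_drain)


class TestTransferCurve:
    def test_n_branch_monotone_on_current(self, coarse_device):
        protocol = program_polarity("n")
        curve = transfer_curve(coarse_device, protocol.v_cg_values(6),
                               v_pg=protocol.v_pg, v_ds=protocol.v_ds)
        i = curve.current
        assert np.all(np.diff(i) >= -1e-3 * np.abs(i[1:]))
        assert i[-1] > 100.0 * abs(i[0])

    def test_p_branch_magnitude_decays_toward_zero_gate(self, coarse_device):
        protocol = program_polarity("p")
        curve = transfer_curve(coarse_device, protocol.v_cg_values(6),
                               v_pg=protocol.v_pg, v_ds=protocol.v_ds)
        mag = np.abs(curve.current)
        assert np.all(np.diff(mag) <= 1e-3 * mag[1:])
        assert np.all(curve.current[:-1] < 0)

    def test_negative_sheet_charge_suppresses_n_current(self, coarse_device):
        # device-level restatement of the virtual-doping effect: σ < 0 shifts
        # the n-branch threshold positive, lowering I_D at fixed V_CG
        base = solve_bias_point(coarse_device,
                                BiasPoint(v_cg=5.0, v_ds=0.1)).current_drain
        shifted = solve_bias_point(
            coarse_device,
            BiasPoint(v_cg=5.0, v_ds=0.1, sigma_pg=-5e-7)).current_drain
        more = solve_bias_point(
            coarse_device,
            BiasPoint(v_cg=5.0, v_ds=0.1, sigma_pg=-1e-6)).current_drain
        assert base > shifted > more > 0

    def test_positive_sheet_charge_suppresses_p_current(self, coarse_device):
        base = solve_bias_point(
            coarse_device, BiasPoint(v_cg=-5.0, v_ds=-0.1)).current_drain
        shifted = solve_bias_point(
            coarse_device,
            BiasPoint(v_cg=-5.0, v_ds=-0.1, sigma_pg=5e-7)).current_drain
        assert abs(base) > abs(shifted)

    def test_empty_sweep_rejected(self, coarse_device):
        with pytest.raises(ValidationError):
            transfer_curve(coarse_device, [])

    def test_unsorted_sweep_rejected(self, coarse_device):
        with pytest.raises(ValidationError):
            transfer_curve(coarse_device, [1.0, 0.5, 2.0])


class TestProtocols:
    def test_p_template_matches_readout_protocol(self):
        p = program_polarity("p")
        assert p.v_ds == -0.1
        assert (p.v_cg_start, p.v_cg_stop) == (-5.0, 0.0)
        assert p.v_cg_on == -5.0

    def test_n_template_matches_readout_protocol(self):
        n = program_polarity("n")
        assert n.v_ds == 0.1
        assert (n.v_cg_start, n.v_cg_stop) == (0.0, 5.0)

    def test_templates_are_sign_mirrors(self):
        n, p = program_polarity("n"), program_polarity("p")
        assert (n.v_pg, n.v_ds) == (-p.v_pg, -p.v_ds)
        np.testing.assert_allclose(n.v_cg_values(5), -p.v_cg_values(5)[::-1])

    def test_gate_voltage_shift_is_sigma_over_cox(self):
        spec = DeviceSpec()
        sigma = 1e-6  # C/cm²
        expected = sigma * 1e4 * (1e-9) / (3.9 * EPSILON_0)
        assert gate_voltage_shift(sigma, spec) == pytest.approx(expected,
                                                                rel=1e-12)
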