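"""2-D drift-diffusion simulator of a dual-gate Schottky-barrier RFET.

The device is a doping-free ultra-thin silicon channel with Schottky
source/drain contacts and two top gates: a control gate (CG) over the source
junction and a program gate (PG) over the drain junction (program-gate-at-
drain layout). The PG selects the carrier polarity by electrostatically
suppressing the unwanted species at the drain junction; the CG switches the
device by thinning (or thickening) the source-side Schottky barrier seen by
the selected carrier. Biomolecular charge enters as a sheet-charge density
on the PG gate-stack surface, the "virtual doping" by which a probe layer
programs or modulates the device.

Model summary
-------------
* Front-view 2-D cross-section: x along the channel, y through gate oxide
  plus silicon film; the 150 nm device width multiplies terminal currents.
* Poisson's equation over oxide + silicon on a tensor-product finite-volume
  mesh; gate electrodes are Dirichlet patches on the top surface, the
  molecular sheet charge is applied on the oxide/silicon interface nodes
  under the PG footprint, and the substrate side is charge-neutral Neumann.
* Boltzmann carrier statistics with quasi-Fermi potentials; electron/hole
  continuity discretized with Scharfetter–Gummel exponential-fitting fluxes.
* Schottky contacts pin the potential through the barrier height and impose
  Robin (finite surface-recombination-velocity) carrier fluxes whose
  velocity is the Richardson thermionic value multiplied by a Tsu-Esaki/WKB
  tunneling enhancement factor recomputed from the evolving band profile.
* Outer Gummel iteration (nonlinear Poisson by damped Newton, then the two
  linear continuity solves) with bias ramping for cold starts.
* Optional density-gradient quantum correction (first-order, lagged quantum
  potential), default off.

Units: SI internally; the public surface speaks nm, V, eV, cm⁻³ and A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .constants import (BOLTZMANN, ELEMENTARY_CHARGE, EPSILON_0, HBAR, NM,
                        thermal_voltage)
from .curves import ResponseCurve
from .errors import (ConfigurationError, ConvergenceError, DomainError,
                     ValidationError)
from .schottky import richardson_constant, tunneling_enhancement

Q = ELEMENTARY_CHARGE

#: terminal currents below this magnitude are treated as zero (A)
CURRENT_FLOOR = 1e-15

#: near-contact x-mesh grading (nm from each contact); resolves the
#: tunneling-relevant first few nm of the Schottky barrier independently of
#: the coarse channel mesh.
_CONTACT_GRADING_NM = (0.0, 0.3, 0.7, 1.2, 2.0, 3.0, 4.5, 6.5, 9.0, 12.0,
                       16.0, 21.0, 27.0, 34.0)
_GRADED_SPAN_NM = 40.0


@dataclass(frozen=True)
class DeviceSpec:
    """RFET geometry, gate placement and mesh resolution (lengths in nm)."""

    channel_length: float = 1000.0
    gate_length_pg: float = 440.0
    gate_length_cg: float = 440.0
    width: float = 150.0
    si_thickness: float = 10.0
    eot: float = 1.0
    schottky_barrier_e: float = 0.56
    schottky_barrier_h: float = 0.56
    pg_position: str = "drain_side"
    mesh_nx: int = 201
    mesh_ny: int = 30
    quantum_correction: bool = False

    def __post_init__(self):
        for name in ("channel_length", "gate_length_pg", "gate_length_cg",
                     "width", "si_thickness", "eot"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.gate_length_pg + self.gate_length_cg > self.channel_length:
            raise ValidationError("gate lengths exceed the channel length")
        if self.pg_position != "drain_side":
            raise ValidationError("only the PGAD layout (pg_position='drain_side') "
                                  "is supported")
        if self.mesh_nx < 16 or self.mesh_ny < 8:
            raise ValidationError("mesh_nx >= 16 and mesh_ny >= 8 required")

    @property
    def sensing_area_nm2(self) -> float:
        """Active sensing area over the PG: gate length × device width."""
        return self.gate_length_pg * self.width


@dataclass(frozen=True)
class MaterialParams:
    """Semiconductor and gate-stack material parameters (silicon defaults)."""

    bandgap: float = 1.12  # eV
    intrinsic_density: float = 1.0e10  # cm⁻³
    electron_mobility: float = 1400.0  # cm²/(V s)
    hole_mobility: float = 450.0
    effective_mass_e: float = 0.26  # m0 units (tunneling/Richardson mass)
    effective_mass_h: float = 0.36
    relative_permittivity_si: float = 11.7
    relative_permittivity_ox: float = 3.9
    temperature: float = 300.0  # K
    acceptor_density: float = 0.0  # cm⁻³, uniform (0 for the doping-free RFET)
    donor_density: float = 0.0

    def __post_init__(self):
        for name in ("bandgap", "intrinsic_density", "electron_mobility",
                     "hole_mobility", "effective_mass_e", "effective_mass_h",
                     "relative_permittivity_si", "relative_permittivity_ox",
                     "temperature"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.acceptor_density < 0 or self.donor_density < 0:
            raise ValidationError("doping densities must be >= 0")

    @classmethod
    def symmetric(cls, **overrides) -> "MaterialParams":
        """Electron/hole-symmetric parameter set (ambipolar mirror tests)."""
        base = dict(electron_mobility=900.0, hole_mobility=900.0,
                    effective_mass_e=0.30, effective_mass_h=0.30)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class BiasPoint:
    """Applied terminal biases plus the molecular sheet charge on the PG."""

    v_pg: float = 0.0
    v_cg: float = 0.0
    v_ds: float = 0.0
    sigma_pg: float = 0.0  # C/cm² on the PG sensing surface

    def __post_init__(self):
        for name in ("v_pg", "v_cg", "v_ds", "sigma_pg"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def scaled(self, s: float) -> "BiasPoint":
        return BiasPoint(self.v_pg * s, self.v_cg * s, self.v_ds * s,
                         self.sigma_pg * s)


@dataclass
class DeviceState:
    """A converged (or diagnosed) operating point of the device."""

    potential: np.ndarray  # (ny, nx) V on the full oxide+Si grid
    n: np.ndarray  # (ny_si, nx) electrons, m⁻³ (silicon sub-grid)
    p: np.ndarray  # (ny_si, nx) holes, m⁻³
    current_drain: float  # A
    current_source: float  # A
    converged: bool
    iterations: int
    bias: BiasPoint
    phi_n: np.ndarray = field(repr=False, default=None)
    phi_p: np.ndarray = field(repr=False, default=None)
    x_nm: np.ndarray = field(repr=False, default=None)
    y_nm: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class BiasProtocol:
    """A programming polarity: fixed PG bias, CG sweep range, drain bias."""

    polarity: str
    v_pg: float
    v_cg_start: float
    v_cg_stop: float
    v_ds: float

    def v_cg_values(self, n: int = 11) -> np.ndarray:
        return np.linspace(self.v_cg_start, self.v_cg_stop, n)

    @property
    def v_cg_on(self) -> float:
        """The ON read-out CG bias (the |5 V| end of the sweep)."""
        return (self.v_cg_start if abs(self.v_cg_start) >= abs(self.v_cg_stop)
                else self.v_cg_stop)


def program_polarity(sign: str) -> BiasProtocol:
    """Bias template for n- or p-programmed operation (exact sign mirrors).

    n: V_PG = +5 V, CG swept 0 → +5 V, V_DS = +0.1 V.
    p: V_PG = −5 V, CG swept −5 → 0 V, V_DS = −0.1 V.
    """
    if sign == "n":
        return BiasProtocol("n", v_pg=5.0, v_cg_start=0.0, v_cg_stop=5.0,
                            v_ds=0.1)
    if sign == "p":
        return BiasProtocol("p", v_pg=-5.0, v_cg_start=-5.0, v_cg_stop=0.0,
                            v_ds=-0.1)
    raise DomainError(f"polarity must be 'n' or 'p', got {sign!r}")


def gate_voltage_shift(sigma_pg: float, spec: DeviceSpec,
                       materials: MaterialParams | None = None) -> float:
    """Equivalent gate-voltage shift σ/C_ox (V) of a PG sheet charge (C/cm²)."""
    eps_ox = (materials.relative_permittivity_ox if materials is not None
              else 3.9) * EPSILON_0
    c_ox = eps_ox / (spec.eot * NM)  # F/m²
    return sigma_pg * 1e4 / c_ox


def bernoulli(x):
    """Bernoulli function x/(e^x − 1), numerically stable for all x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    big_neg = x < -500.0
    big_pos = x > 500.0
    mid = ~(small | big_neg | big_pos)
    out[mid] = x[mid] / np.expm1(x[mid])
    out[big_neg] = -x[big_neg]
    out[big_pos] = 0.0
    return out


def _build_x_mesh(length_m: float, nx: int) -> np.ndarray:
    """Channel mesh: uniform interior plus graded refinement at both contacts."""
    graded = np.array(_CONTACT_GRADING_NM) * NM
    span = _GRADED_SPAN_NM * NM
    interior = np.linspace(0.0, length_m, nx)
    interior = interior[(interior > span) & (interior < length_m - span)]
    x = np.concatenate([graded, [span], interior, [length_m - span],
                        length_m - graded[::-1]])
    return np.unique(np.round(np.sort(x), 14))


class Device:
    """A discretized RFET ready for electrostatic and transport solves."""

    def __init__(self, spec: DeviceSpec, materials: MaterialParams):
        eg = materials.bandgap
        for name in ("schottky_barrier_e", "schottky_barrier_h"):
            phi = getattr(spec, name)
            if not 0.0 < phi < eg:
                raise ConfigurationError(
                    f"{name}={phi} eV must lie inside the bandgap (0, {eg})")
        self.spec = spec
        self.materials = materials

        # --- mesh ---------------------------------------------------------
        length = spec.channel_length * NM
        t_ox = spec.eot * NM
        t_si = spec.si_thickness * NM
        self.x = _build_x_mesh(length, spec.mesh_nx)
        n_ox = max(2, spec.mesh_ny // 8)
        n_si = spec.mesh_ny - n_ox
        if n_si < 4:
            raise ConfigurationError("mesh_ny leaves fewer than 4 silicon rows")
        y_ox = np.linspace(0.0, t_ox, n_ox + 1)
        y_si = np.linspace(t_ox, t_ox + t_si, n_si + 1)
        self.y = np.concatenate([y_ox, y_si[1:]])
        self.j_int = n_ox  # oxide/silicon interface row
        self.nx = self.x.size
        self.ny = self.y.size
        self.nsy = self.ny - self.j_int  # silicon rows (incl. interface row)

        # gate footprints on the top surface
        tol = 1e-12
        self.cg_mask = self.x <= spec.gate_length_cg * NM + tol
        self.pg_mask = self.x >= length - spec.gate_length_pg * NM - tol
        for mask, gname in ((self.cg_mask, "CG"), (self.pg_mask, "PG")):
            if int(mask.sum()) < 5:
                raise ConfigurationError(
                    f"mesh too coarse: fewer than 4 cells under the {gname}")

        dx = np.diff(self.x)
        dy = np.diff(self.y)
        self.wx = np.concatenate([[dx[0] / 2], (dx[:-1] + dx[1:]) / 2, [dx[-1] / 2]])
        self.wy = np.concatenate([[dy[0] / 2], (dy[:-1] + dy[1:]) / 2, [dy[-1] / 2]])
        self.dx, self.dy = dx, dy

        # silicon-portion y-extent of each silicon-row control volume
        dys = dy[self.j_int:]
        self.wy_si = np.concatenate([[dys[0] / 2], (dys[:-1] + dys[1:]) / 2,
                                     [dys[-1] / 2]])

        # layer permittivity between node rows
        y_mid = (self.y[:-1] + self.y[1:]) / 2
        self.eps_layer = np.where(y_mid < t_ox,
                                  materials.relative_permittivity_ox,
                                  materials.relative_permittivity_si) * EPSILON_0

        # --- derived material quantities ---------------------------------
        self.vt = thermal_voltage(materials.temperature)
        self.ni = materials.intrinsic_density * 1e6  # cm⁻³ -> m⁻³
        self.doping = (materials.donor_density - materials.acceptor_density) * 1e6
        self.d_n = materials.electron_mobility * 1e-4 * self.vt  # m²/s
        self.d_p = materials.hole_mobility * 1e-4 * self.vt
        eg = materials.bandgap
        self.psi_bn = eg / 2.0 - spec.schottky_barrier_e  # contact pinning (V)
        self.n_contact = self.ni * math.exp(
            min((eg / 2.0 - spec.schottky_barrier_e) / self.vt, 60.0))
        self.p_contact = self.ni * math.exp(
            min((eg / 2.0 - spec.schottky_barrier_h) / self.vt, 60.0))
        kt_ev = BOLTZMANN * materials.temperature / ELEMENTARY_CHARGE
        self.kt_ev = kt_ev
        t2 = materials.temperature ** 2
        self.v_rich_n = (richardson_constant(materials.effective_mass_e) * t2
                         * math.exp(-spec.schottky_barrier_e / kt_ev)
                         / (Q * self.n_contact))
        self.v_rich_p = (richardson_constant(materials.effective_mass_h) * t2
                         * math.exp(-spec.schottky_barrier_h / kt_ev)
                         / (Q * self.p_contact))

        self._assemble_poisson()
        self._quantum_pot_n = np.zeros((self.nsy, self.nx))
        self._quantum_pot_p = np.zeros((self.nsy, self.nx))

    # ------------------------------------------------------------------ mesh
    def _idx(self, j, i):
        return j * self.nx + i

    def _assemble_poisson(self):
        nx, ny = self.nx, self.ny
        rows, cols, vals = [], [], []

        def add(a, b, c):
            rows.extend([a, a, b, b])
            cols.extend([a, b, b, a])
            vals.extend([c, -c, c, -c])

        # vertical edges (within a single material layer)
        for j in range(ny - 1):
            coef = self.eps_layer[j] / self.dy[j]
            for i in range(nx):
                add(self._idx(j, i), self._idx(j + 1, i), coef * self.wx[i])
        # horizontal edges (flanked by up to two layers)
        for j in range(ny):
            eps_w = 0.0
            if j > 0:
                eps_w += self.eps_layer[j - 1] * self.dy[j - 1] / 2
            if j < ny - 1:
                eps_w += self.eps_layer[j] * self.dy[j] / 2
            for i in range(nx - 1):
                add(self._idx(j, i), self._idx(j, i + 1), eps_w / self.dx[i])

        a = sp.coo_matrix((vals, (rows, cols)), shape=(nx * ny, nx * ny)).tocsr()

        # Dirichlet: gates on the top row, Schottky contacts on the Si columns
        dir_mask = np.zeros(nx * ny, dtype=bool)
        self._gate_cg_nodes = np.where(self.cg_mask)[0]  # j=0 row
        self._gate_pg_nodes = np.where(self.pg_mask)[0]
        dir_mask[self._gate_cg_nodes] = True
        dir_mask[self._gate_pg_nodes] = True
        si_rows = np.arange(self.j_int, ny)
        self._contact_src_nodes = self._idx(si_rows, 0)
        self._contact_drn_nodes = self._idx(si_rows, nx - 1)
        dir_mask[self._contact_src_nodes] = True
        dir_mask[self._contact_drn_nodes] = True
        self.dirichlet_mask = dir_mask

        a = a.tolil()
        for d in np.where(dir_mask)[0]:
            a.rows[d] = [d]
            a.data[d] = [1.0]
        self.a_poisson = a.tocsr()

        # semiconductor control-volume areas per silicon node (m², per depth)
        self.vol_si = np.outer(self.wy_si, self.wx)

        # sheet-charge weights: interface row, PG footprint
        w = np.zeros(nx)
        w[self.pg_mask] = self.wx[self.pg_mask]
        self._sheet_wx = w

    # ------------------------------------------------------------- statistics
    def _carrier_densities(self, psi_si, phi_n, phi_p):
        en = np.clip((psi_si - phi_n + self._quantum_pot_n) / self.vt, -120, 120)
        ep = np.clip((phi_p - psi_si + self._quantum_pot_p) / self.vt, -120, 120)
        return self.ni * np.exp(en), self.ni * np.exp(ep)

    def _dirichlet_values(self, bias: BiasPoint):
        vals = np.zeros(self.nx * self.ny)
        vals[self._gate_cg_nodes] = bias.v_cg
        vals[self._gate_pg_nodes] = bias.v_pg
        vals[self._contact_src_nodes] = self.psi_bn
        vals[self._contact_drn_nodes] = bias.v_ds + self.psi_bn
        return vals

    # ------------------------------------------------------------- Poisson
    def _newton_poisson(self, psi, phi_n, phi_p, bias: BiasPoint,
                        tol=1e-10, max_iter=80, clamp=0.5):
        nx, ny = self.nx, self.ny
        dvals = self._dirichlet_values(bias)
        dmask = self.dirichlet_mask
        sheet = np.zeros(nx * ny)
        sheet[self._idx(self.j_int, np.arange(nx))] += bias.sigma_pg * 1e4 \
            * self._sheet_wx
        psi = psi.copy()
        psi[dmask] = dvals[dmask]
        si = slice(self.j_int * nx, ny * nx)
        last = np.inf
        for it in range(max_iter):
            psi_si = psi[si].reshape(self.nsy, nx)
            n, p = self._carrier_densities(psi_si, phi_n, phi_p)
            rho = np.zeros(nx * ny)
            rho[si] = (Q * (p - n + self.doping) * self.vol_si).ravel()
            rhs = rho + sheet
            resid = self.a_poisson @ psi - rhs
            resid[dmask] = psi[dmask] - dvals[dmask]
            dq = np.zeros(nx * ny)
            dq[si] = (Q * (n + p) / self.vt * self.vol_si).ravel()
            dq[dmask] = 0.0
            jac = self.a_poisson + sp.diags(dq)
            delta = spsolve(jac, -resid)
            step = min(1.0, clamp / max(np.abs(delta).max(), 1e-30))
            psi += step * delta
            last = float(np.abs(delta).max())
            if last < tol:
                break
        else:
            raise ConvergenceError("Poisson Newton stalled", residual=last)
        return psi

    def solve_equilibrium(self, bias: BiasPoint = BiasPoint()) -> DeviceState:
        """Self-consistent equilibrium electrostatics (V_DS must be 0)."""
        if bias.v_ds != 0.0:
            raise DomainError("equilibrium solve requires v_ds = 0")
        zeros = np.zeros((self.nsy, self.nx))
        psi = np.full(self.nx * self.ny, self.psi_bn)
        # ramp gate/sheet drive for a robust cold start
        drive = max(abs(bias.v_pg), abs(bias.v_cg),
                    abs(gate_voltage_shift(bias.sigma_pg, self.spec, self.materials)))
        nsteps = max(1, math.ceil(drive / 1.0))
        for k in range(1, nsteps + 1):
            psi = self._newton_poisson(psi, zeros, zeros, bias.scaled(k / nsteps))
        psi_si = psi.reshape(self.ny, self.nx)[self.j_int:]
        n, p = self._carrier_densities(psi_si, zeros, zeros)
        return DeviceState(potential=psi.reshape(self.ny, self.nx), n=n, p=p,
                           current_drain=0.0, current_source=0.0,
                           converged=True, iterations=nsteps, bias=bias,
                           phi_n=zeros.copy(), phi_p=zeros.copy(),
                           x_nm=self.x / NM, y_nm=self.y / NM)

    # ---------------------------------------------------------- injection
    def _contact_velocities(self, psi_grid, bias: BiasPoint):
        """Per-row Robin velocities (Richardson × tunneling Γ) at both contacts."""
        eg2 = self.materials.bandgap / 2.0
        nx = self.nx
        window = min(np.searchsorted(self.x, 0.25 * self.x[-1]), nx - 1)
        v_n_src = np.empty(self.nsy)
        v_p_src = np.empty(self.nsy)
        v_n_drn = np.empty(self.nsy)
        v_p_drn = np.empty(self.nsy)
        for jj in range(self.nsy):
            psi_row = psi_grid[self.j_int + jj]
            # source (metal Fermi at 0 V)
            b_n = eg2 - psi_row[:window]
            b_p = eg2 + psi_row[:window]
            v_n_src[jj] = self.v_rich_n * self._gamma(self.x[:window], b_n,
                                                     self.materials.effective_mass_e)
            v_p_src[jj] = self.v_rich_p * self._gamma(self.x[:window], b_p,
                                                     self.materials.effective_mass_h)
            # drain (metal Fermi at −v_ds eV)
            rev = slice(nx - 1, nx - 1 - window, -1)
            s = self.x[-1] - self.x[rev]
            b_n = eg2 - psi_grid[self.j_int + jj][rev] + bias.v_ds
            b_p = eg2 + psi_grid[self.j_int + jj][rev] - bias.v_ds
            v_n_drn[jj] = self.v_rich_n * self._gamma(s, b_n,
                                                     self.materials.effective_mass_e)
            v_p_drn[jj] = self.v_rich_p * self._gamma(s, b_p,
                                                     self.materials.effective_mass_h)
        return v_n_src, v_p_src, v_n_drn, v_p_drn

    def _gamma(self, s, barrier_ev, mass):
        stop = int(np.argmin(barrier_ev))
        if stop == 0:
            return 1.0
        return tunneling_enhancement(s[:stop + 1] - s[0], barrier_ev[:stop + 1],
                                     mass, self.kt_ev)

    # ---------------------------------------------------------- continuity
    def _solve_continuity(self, carrier, psi_si, v_src, v_drn, psi_src,
                          psi_drn):
        """Scharfetter–Gummel continuity solve in Slotboom variables.

        Solves for w = u·exp(−s·ψ/Vt) (s = +1 electrons, −1 holes), in which
        the SG edge flux is a symmetric weighted graph Laplacian,
        Φ(a→b) = g·B(|δ|)·exp(max(sψa, sψb)/Vt)·(w_a − w_b). Equilibrium is
        w = const, so the terminal current — a small imbalance riding on
        large opposing fluxes in the density variable — is computed without
        catastrophic cancellation and terminal-current conservation holds to
        solver precision.

        Returns (density field, particle outflow at source, at drain), the
        outflows per unit device depth.
        """
        nx, nsy = self.nx, self.nsy
        diff = self.d_n if carrier == "e" else self.d_p
        n_b = self.n_contact if carrier == "e" else self.p_contact
        m = nsy * nx
        rhs = np.zeros(m)

        s = 1.0 if carrier == "e" else -1.0
        qp = self._quantum_pot_n if carrier == "e" else self._quantum_pot_p
        a_pot = np.clip(s * (psi_si + s * qp) / self.vt, -600.0, 600.0)
        node = np.arange(m).reshape(nsy, nx)

        def edge_weight(g, a_lo, a_hi):
            delta = np.abs(a_hi - a_lo)
            return g * bernoulli(delta) * np.exp(np.maximum(a_lo, a_hi))

        # x-directed edges
        a_x = node[:, :-1].ravel()
        b_x = node[:, 1:].ravel()
        g_x = (diff * self.wy_si[:, None] / self.dx[None, :]).ravel()
        w_x = edge_weight(g_x, a_pot[:, :-1].ravel(), a_pot[:, 1:].ravel())
        # y-directed edges
        dys = self.dy[self.j_int:]
        a_y = node[:-1, :].ravel()
        b_y = node[1:, :].ravel()
        g_y = (diff * self.wx[None, :] / dys[:, None]).ravel()
        w_y = edge_weight(g_y, a_pot[:-1, :].ravel(), a_pot[1:, :].ravel())

        a_e = np.concatenate([a_x, a_y])
        b_e = np.concatenate([b_x, b_y])
        w_e = np.concatenate([w_x, w_y])
        rows = np.concatenate([a_e, a_e, b_e, b_e])
        cols = np.concatenate([a_e, b_e, b_e, a_e])
        vals = np.concatenate([w_e, -w_e, w_e, -w_e])

        # Robin contact faces: flux out = v·a_face·E_c·(w − w_B) with the
        # contact potential pinned, so E_c·w_B = n_B exactly
        d_src = node[:, 0]
        d_drn = node[:, -1]
        e_src = math.exp(s * psi_src / self.vt)
        e_drn = math.exp(s * psi_drn / self.vt)
        rows = np.concatenate([rows, d_src, d_drn])
        cols = np.concatenate([cols, d_src, d_drn])
        vals = np.concatenate([vals, self.wy_si * v_src * e_src,
                               self.wy_si * v_drn * e_drn])
        rhs[d_src] += self.wy_si * v_src * n_b
        rhs[d_drn] += self.wy_si * v_drn * n_b

        a = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsc()
        lu = splu(a)
        w = lu.solve(rhs)
        # iterative refinement with an extended-precision residual: the edge
        # weights span ~20 decades, and the terminal-current balance depends
        # on w being the best float64 solution the factorization allows
        a_csr = a.tocsr()
        rhs_ld = rhs.astype(np.longdouble)
        row_empty = np.diff(a_csr.indptr) == 0
        for _ in range(2):
            prod = a_csr.data.astype(np.longdouble) * w[a_csr.indices]
            aw = np.add.reduceat(prod, a_csr.indptr[:-1])
            aw[row_empty] = 0.0
            w = w + lu.solve((rhs_ld - aw).astype(np.float64))
        w = np.maximum(w.reshape(nsy, nx), 1e-300)
        f_src = float(np.sum(self.wy_si * v_src * (w[:, 0] * e_src - n_b)))
        f_drn = float(np.sum(self.wy_si * v_drn * (w[:, -1] * e_drn - n_b)))
        u = np.maximum(w * np.exp(a_pot), 1e-20)
        return u, f_src, f_drn

    # ---------------------------------------------------------------- Gummel
    def _gummel(self, bias: BiasPoint, psi, phi_n, phi_p,
                max_iter=200, tol_psi=1e-5, tol_i=1e-4):
        width = self.spec.width * NM
        i_d_prev = None
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            psi = self._newton_poisson(psi, phi_n, phi_p, bias)
            psi_grid = psi.reshape(self.ny, self.nx)
            psi_si = psi_grid[self.j_int:]
            v_n_s, v_p_s, v_n_d, v_p_d = self._contact_velocities(psi_grid, bias)
            psi_src = self.psi_bn
            psi_drn = bias.v_ds + self.psi_bn
            n, fn_s, fn_d = self._solve_continuity("e", psi_si, v_n_s, v_n_d,
                                                   psi_src, psi_drn)
            p, fp_s, fp_d = self._solve_continuity("h", psi_si, v_p_s, v_p_d,
                                                   psi_src, psi_drn)
            i_drain = Q * width * (fn_d - fp_d)
            i_source = Q * width * (fn_s - fp_s)
            phi_n_new = psi_si - self.vt * np.log(n / self.ni) \
                + self._quantum_pot_n
            phi_p_new = psi_si + self.vt * np.log(p / self.ni) \
                - self._quantum_pot_p
            if self.spec.quantum_correction:
                self._update_quantum_potentials(n, p)
            dphi = max(np.abs(phi_n_new - phi_n).max(),
                       np.abs(phi_p_new - phi_p).max())
            phi_n, phi_p = phi_n_new, phi_p_new
            if i_d_prev is None:
                di_ok = False
            else:
                di = abs(i_drain - i_d_prev) / max(abs(i_drain), CURRENT_FLOOR)
                # currents at the sub-0.1 pA scale carry cancellation noise
                # far above their physical meaning; potential convergence
                # governs there
                di_ok = di < tol_i or abs(i_drain) < 1e-13 \
                    or abs(i_drain - i_d_prev) < 1e-16
            i_d_prev = i_drain
            trace.append((it, dphi, i_drain))
            if dphi < tol_psi and di_ok:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Gummel iteration did not converge in {max_iter} steps "
                f"(last dphi={trace[-1][1]:.3e}, I_D={trace[-1][2]:.3e} A)",
                residual=trace[-1][1], trace=trace)
        return DeviceState(potential=psi.reshape(self.ny, self.nx).copy(),
                           n=n, p=p, current_drain=i_drain,
                           current_source=i_source, converged=True,
                           iterations=it, bias=bias, phi_n=phi_n, phi_p=phi_p,
                           x_nm=self.x / NM, y_nm=self.y / NM)

    def _update_quantum_potentials(self, n, p):
        """Lagged first-order density-gradient quantum potential (toggle)."""
        for u, qp, m_rel in ((n, self._quantum_pot_n,
                              self.materials.effective_mass_e),
                             (p, self._quantum_pot_p,
                              self.materials.effective_mass_h)):
            s = np.sqrt(u)
            lap = np.zeros_like(s)
            dys = self.dy[self.j_int:]
            for jj in range(1, self.nsy - 1):
                lap[jj] = ((s[jj + 1] - s[jj]) / dys[jj]
                           - (s[jj] - s[jj - 1]) / dys[jj - 1]) / self.wy_si[jj]
            # quantum potential −(ħ²/6m)·∇²√u/√u: negative in decaying
            # tails, pushing carriers away from abrupt interfaces; heavily
            # under-relaxed because it is lagged one Gummel iteration
            coef = HBAR ** 2 / (6.0 * m_rel * 9.1093837015e-31 * Q)
            lam = np.clip(-coef * lap / s, -0.15, 0.15)
            qp *= 0.7
            qp += 0.3 * lam

    # ----------------------------------------------------------- public API
    def solve(self, bias: BiasPoint, initial: DeviceState | None = None,
              max_iter: int = 200) -> DeviceState:
        """Solve one bias point, ramping from equilibrium unless seeded."""
        if initial is not None:
            psi = initial.potential.ravel().copy()
            phi_n = initial.phi_n.copy()
            phi_p = initial.phi_p.copy()
            return self._gummel(bias, psi, phi_n, phi_p, max_iter=max_iter)
        drive = max(abs(bias.v_pg), abs(bias.v_cg), abs(bias.v_ds),
                    abs(gate_voltage_shift(bias.sigma_pg, self.spec,
                                           self.materials)))
        nsteps = max(1, math.ceil(drive / 0.5))
        self._quantum_pot_n[:] = 0.0
        self._quantum_pot_p[:] = 0.0
        psi = np.full(self.nx * self.ny, self.psi_bn)
        phi_n = np.zeros((self.nsy, self.nx))
        phi_p = np.zeros((self.nsy, self.nx))
        state = None
        for k in range(1, nsteps + 1):
            part = bias.scaled(k / nsteps)
            limit = max_iter if k == nsteps else 60
            state = self._gummel(part, psi, phi_n, phi_p, max_iter=limit)
            psi = state.potential.ravel().copy()
            phi_n, phi_p = state.phi_n, state.phi_p
        return state

    def transfer_curve(self, v_cg_values, v_pg: float = 0.0,
                       v_ds: float = 0.0, sigma_pg: float = 0.0,
                       initial: DeviceState | None = None) -> ResponseCurve:
        """I_D–V_CG sweep with continuation between steps."""
        v = np.asarray(v_cg_values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValidationError("v_cg_values must be a non-empty 1-D sequence")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValidationError("v_cg_values must be strictly increasing")
        # sweep from the largest |V_CG| end so continuation walks off the ON state
        order = v if abs(v[0]) >= abs(v[-1]) else v[::-1]
        currents = {}
        state = initial
        for vcg in order:
            bias = BiasPoint(v_pg=v_pg, v_cg=float(vcg), v_ds=v_ds,
                             sigma_pg=sigma_pg)
            try:
                state = self.solve(bias, initial=state)
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"transfer sweep failed at v_cg={vcg:+.3f} V: {exc}",
                    residual=exc.residual, trace=exc.trace) from exc
            currents[float(vcg)] = state.current_drain
        meta = {"v_pg_V": v_pg, "v_ds_V": v_ds, "sigma_pg_C_per_cm2": sigma_pg,
                "mesh": f"{self.nx}x{self.ny}"}
        return ResponseCurve(x=v, current=np.array([currents[float(u)] for u in v]),
                             x_kind="v_cg", metadata=meta)


# ----------------------------------------------------------- thin wrappers
def build_device(spec: DeviceSpec, materials: MaterialParams) -> Device:
    """Discretize an RFET: mesh, gate footprints, contacts, Poisson operator."""
    return Device(spec, materials)


def solve_poisson_equilibrium(device: Device,
                              bias: BiasPoint = BiasPoint()) -> DeviceState:
    return device.solve_equilibrium(bias)


def solve_bias_point(device: Device, bias: BiasPoint,
                     initial: DeviceState | None = None) -> DeviceState:
    return device.solve(bias, initial=initial)


def transfer_curve(device: Device, v_cg_values, v_pg: float = 0.0,
                   v_ds: float = 0.0, sigma_pg: float = 0.0) -> ResponseCurve:
    return device.transfer_curve(v_cg_values, v_pg=v_pg, v_ds=v_ds,
                                 sigma_pg=sigma_pg)
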