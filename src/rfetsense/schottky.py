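"""Schottky-contact injection: Tsu-Esaki integral, WKB tunneling, Richardson limit.

Carriers cross a metal–semiconductor junction by thermionic emission over the
barrier and by quantum-mechanical tunneling through it. The Tsu-Esaki current
integral combines both:

    J = (4π q m* kB T / h³) ∫ T(E) · N(E) dE
    N(E) = ln[(1 + exp((E_Fm − E)/kBT)) / (1 + exp((E_Fs − E)/kBT))]

with transmission T(E) = 1 above the barrier maximum and a WKB factor through
the sampled barrier profile below it. Energies are measured in eV relative to
the metal Fermi level at the contact (depth 0); the profile is the band-edge
energy of the injected carrier versus depth into the semiconductor.

The drift-diffusion solver consumes this physics as a tunneling enhancement
factor Γ ≥ 1 multiplying the Richardson surface-recombination velocity of a
Robin contact condition; Γ is the Boltzmann-weighted transmission of the
sub-barrier energy window, so Γ = 1 recovers pure thermionic emission and the
flux vanishes identically in equilibrium (detailed balance).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import (BOLTZMANN, ELECTRON_MASS, ELEMENTARY_CHARGE, HBAR,
                        PLANCK, NM)
from .errors import DomainError

#: Hard cap on the tunneling enhancement factor; keeps the contact conductance
#: finite when a barrier becomes essentially transparent.
GAMMA_CAP = 1e12


def richardson_constant(effective_mass: float) -> float:
    """Richardson constant A* in A/(m² K²) for a relative effective mass."""
    m = effective_mass * ELECTRON_MASS
    return 4.0 * math.pi * ELEMENTARY_CHARGE * m * BOLTZMANN ** 2 / PLANCK ** 3


def richardson_flux(barrier_max_ev: float, bias_v: float,
                    effective_mass: float, temperature: float) -> float:
    """Thermionic-emission current density (A/cm²) over a barrier maximum.

    Closed form: J = A* T² [exp((E_Fm − E_max)/kT) − exp((E_Fs − E_max)/kT)]
    with E_Fm = 0 and E_Fs = −bias_v (eV). Positive J injects carriers from
    the metal into the semiconductor.
    """
    kt_ev = BOLTZMANN * temperature / ELEMENTARY_CHARGE
    a_star = richardson_constant(effective_mass)
    j_si = a_star * temperature ** 2 * (
        math.exp(-barrier_max_ev / kt_ev)
        - math.exp((-bias_v - barrier_max_ev) / kt_ev))
    return j_si * 1e-4  # A/m² -> A/cm²


def wkb_log_transmission_many(depth_m: np.ndarray, barrier_ev: np.ndarray,
                              energies_ev: np.ndarray,
                              effective_mass: float) -> np.ndarray:
    """ln T(E) for a grid of energies through one barrier profile.

    Integrates 2 κ(s) = 2 sqrt(2 m* (U(s) − E) q) / ħ from the contact to the
    first classical turning point (linearly interpolated); entries whose
    entry point is already classically allowed get ln T = 0.
    """
    energies = np.atleast_1d(np.asarray(energies_ev, dtype=float))
    diff = barrier_ev[None, :] - energies[:, None]  # (nE, ns)
    scale = 2.0 * effective_mass * ELECTRON_MASS * ELEMENTARY_CHARGE
    kappa = np.sqrt(np.clip(diff, 0.0, None) * scale) / HBAR
    ds = np.diff(depth_m)
    seg = 0.5 * (kappa[:, :-1] + kappa[:, 1:]) * ds  # trapezoid segments
    cum = np.concatenate([np.zeros((energies.size, 1)), np.cumsum(seg, axis=1)],
                         axis=1)  # ∫0..s_j
    allowed = diff <= 0.0
    has_tp = allowed.any(axis=1)
    stop = np.where(has_tp, np.argmax(allowed, axis=1), depth_m.size - 1)
    rows = np.arange(energies.size)
    integral = cum[rows, np.maximum(stop - 1, 0)]
    # fractional segment up to the interpolated turning point
    tp = has_tp & (stop > 0)
    s1 = stop[tp]
    d_prev = diff[tp, s1 - 1]
    d_here = diff[tp, s1]
    frac = d_prev / np.maximum(d_prev - d_here, 1e-300)
    integral[tp] += 0.5 * kappa[tp, s1 - 1] * (depth_m[s1] - depth_m[s1 - 1]) * frac
    no_tp = ~has_tp
    integral[no_tp] = cum[no_tp, -1]
    out = -2.0 * integral
    out[diff[:, 0] <= 0.0] = 0.0  # classically allowed at the entry point
    return out


def wkb_log_transmission(depth_m: np.ndarray, barrier_ev: np.ndarray,
                         energy_ev: float, effective_mass: float) -> float:
    """Scalar convenience wrapper around :func:`wkb_log_transmission_many`."""
    return float(wkb_log_transmission_many(depth_m, barrier_ev,
                                           np.array([energy_ev]),
                                           effective_mass)[0])


def tsu_esaki_flux(depth_nm: np.ndarray, barrier_ev: np.ndarray, bias_v: float,
                   carrier: str, materials, n_energy: int = 400) -> float:
    """Net Tsu-Esaki injection current density in A/cm² through a contact.

    ``barrier_ev`` is the band-edge energy of the injected carrier versus
    ``depth_nm`` into the semiconductor, in eV relative to the metal Fermi
    level (so ``barrier_ev[0]`` is the contact barrier height). ``bias_v`` is
    the Fermi-level split across the junction: E_Fs = −bias_v while
    E_Fm = 0, so ``bias_v = 0`` gives exactly zero net flux. Positive return
    values inject carriers from the metal into the semiconductor.
    """
    depth = np.asarray(depth_nm, dtype=float) * NM
    barrier = np.asarray(barrier_ev, dtype=float)
    if depth.size < 8 or depth.shape != barrier.shape:
        raise DomainError("barrier profile needs >= 8 matched samples")
    if not (np.all(np.isfinite(depth)) and np.all(np.isfinite(barrier))
            and math.isfinite(bias_v)):
        raise DomainError("barrier profile and bias must be finite")
    if carrier not in ("e", "h"):
        raise DomainError(f"carrier must be 'e' or 'h', got {carrier!r}")
    if bias_v == 0.0:
        return 0.0

    m_rel = (materials.effective_mass_e if carrier == "e"
             else materials.effective_mass_h)
    temperature = materials.temperature
    kt_ev = BOLTZMANN * temperature / ELEMENTARY_CHARGE

    e_fm = 0.0
    e_fs = -bias_v
    e_max = float(barrier.max())
    band_edge = float(barrier[-1])  # semiconductor-side band edge
    e_lo = band_edge
    e_hi = e_max + 10.0 * kt_ev
    energies = np.linspace(e_lo, e_hi, n_energy)

    log_t = np.zeros(n_energy)
    below = energies < e_max
    if below.any():
        log_t[below] = wkb_log_transmission_many(depth, barrier,
                                                 energies[below], m_rel)
    supply = np.logaddexp(0.0, (e_fm - energies) / kt_ev) \
        - np.logaddexp(0.0, (e_fs - energies) / kt_ev)
    integrand = np.exp(log_t) * supply
    integral_ev = float(np.trapezoid(integrand, energies))

    prefactor = (4.0 * math.pi * ELEMENTARY_CHARGE * m_rel * ELECTRON_MASS
                 * BOLTZMANN * temperature / PLANCK ** 3)
    j_si = prefactor * integral_ev * ELEMENTARY_CHARGE  # eV -> J in the dE
    return j_si * 1e-4  # A/m² -> A/cm²


def tunneling_enhancement(depth_m: np.ndarray, barrier_ev: np.ndarray,
                          effective_mass: float, kt_ev: float,
                          n_energy: int = 101) -> float:
    """Tunneling enhancement Γ ≥ 1 of a thermionic contact flux.

    Γ = 1 + (1/kT) ∫_{E_min}^{E_ref} T_WKB(E) exp((E_ref − E)/kT) dE

    where E_ref = barrier_ev[0] is the contact barrier and E_min the lowest
    band-edge energy along the profile. The unit term is the over-the-barrier
    (Richardson) channel; the integral is the Boltzmann-weighted sub-barrier
    transmission. Enhancement applies symmetrically to injection and
    emission, so detailed balance is preserved. Capped at ``GAMMA_CAP``.
    """
    e_ref = float(barrier_ev[0])
    e_min = float(np.min(barrier_ev))
    if e_ref - e_min < 1e-9:
        return 1.0
    energies = np.linspace(e_min, e_ref, n_energy, endpoint=False)
    log_contrib = wkb_log_transmission_many(depth_m, barrier_ev, energies,
                                            effective_mass) \
        + (e_ref - energies) / kt_ev
    m = float(log_contrib.max())
    if m > 700.0:  # transparent barrier; integral overflows — cap applies
        return GAMMA_CAP
    tun = float(np.trapezoid(np.exp(log_contrib), energies)) / kt_ev
    return float(min(1.0 + tun, GAMMA_CAP))
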