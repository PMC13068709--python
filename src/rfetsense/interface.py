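"""Electrolyte screening and probe-layer electrostatics.

The charge a tethered probe layer presents to the gate of a field-effect
biosensor is not its bare charge: in electrolyte, mobile ions screen it over
the Debye length

    λD = sqrt(ε0 εr kB T / (2 NA e² I)),

so charge sitting a height ``h`` above the surface couples to the transducer
only through an attenuation factor. This module collapses each probe
conformation to a point charge at its charge centroid and attenuates it as
``exp(−h/λD)`` — a deliberate reduction of the full 3-D double layer that
keeps the height-sensitivity of the signal (the mechanism by which a
binding-induced conformational change can *reduce* the coupled charge even
when the bound complex carries more charge) while staying analytic.

In ``dry`` mode there is no electrolyte and no screening: every height
couples fully.

Out of scope: Poisson–Boltzmann double layers, pH-dependent oxide site
binding, ion-specific effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (AVOGADRO, BOLTZMANN, ELEMENTARY_CHARGE, EPSILON_0, NM)
from .errors import DomainError, NotApplicableError, ValidationError

#: Standard phosphate-buffered saline ionic strength used throughout, molar.
PBS_1X_IONIC_STRENGTH = 0.15
PBS_001X_IONIC_STRENGTH = 1.5e-3
WATER_RELATIVE_PERMITTIVITY = 78.4  # at 298 K


@dataclass(frozen=True)
class InterfaceCondition:
    """Electrolyte (or dry) environment of the sensing surface."""

    ionic_strength: float = PBS_1X_IONIC_STRENGTH  # molar
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY
    temperature: float = 298.0  # K
    mode: str = "wet"

    def __post_init__(self):
        if self.mode not in ("wet", "dry"):
            raise ValidationError(f"mode must be 'wet' or 'dry', got {self.mode!r}")
        if self.mode == "wet" and not self.ionic_strength > 0:
            raise ValidationError("ionic_strength must be > 0 in wet mode")
        if not self.relative_permittivity > 1:
            raise ValidationError("relative_permittivity must exceed 1")
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0")

    @classmethod
    def pbs(cls, dilution: float = 1.0, temperature: float = 298.0) -> "InterfaceCondition":
        """PBS at a given dilution (1.0 → 1×PBS, 0.01 → 0.01×PBS)."""
        return cls(ionic_strength=PBS_1X_IONIC_STRENGTH * dilution,
                   temperature=temperature, mode="wet")

    @classmethod
    def dry(cls, temperature: float = 298.0) -> "InterfaceCondition":
        return cls(mode="dry", temperature=temperature)


@dataclass(frozen=True)
class ProbeState:
    """One conformational state of a recognition element.

    ``net_charge`` in elementary charges (signed); ``height`` is the
    charge-centroid height above the substrate in nm.
    """

    label: str
    net_charge: float
    height: float

    def __post_init__(self):
        if self.label not in ("unbound", "bound"):
            raise ValidationError(f"label must be 'unbound' or 'bound', got {self.label!r}")
        if not (math.isfinite(self.height) and self.height >= 0):
            raise ValidationError(f"height must be >= 0 nm, got {self.height}")
        if not math.isfinite(self.net_charge):
            raise ValidationError("net_charge must be finite")


@dataclass(frozen=True)
class ProbeLayer:
    """Surface-immobilized probe layer on the sensing area."""

    density: float  # molecules per cm²
    area: float  # nm²
    bound_fraction: float = 0.0

    def __post_init__(self):
        if not self.density > 0:
            raise ValidationError(f"density must be > 0, got {self.density}")
        if not self.area > 0:
            raise ValidationError(f"area must be > 0, got {self.area}")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValidationError(
                f"bound_fraction must lie in [0, 1], got {self.bound_fraction}")


def debye_length(cond: InterfaceCondition) -> float:
    """Debye screening length in nm for a wet interface condition.

    λD = sqrt(ε0 εr kB T / (2 NA e² I)) with the ionic strength I converted
    from molar to ions/m³. Scales as I^(−1/2): a 100-fold dilution lengthens
    λD exactly 10-fold.
    """
    if cond.mode != "wet":
        raise NotApplicableError(
            "Debye length is undefined in dry mode; screening_factor handles dry")
    ions_per_m3 = cond.ionic_strength * 1e3 * AVOGADRO  # mol/L -> 1/m³
    lam = math.sqrt(
        EPSILON_0 * cond.relative_permittivity * BOLTZMANN * cond.temperature
        / (2.0 * ions_per_m3 * ELEMENTARY_CHARGE ** 2))
    return lam / NM


def screening_factor(height: float, cond: InterfaceCondition) -> float:
    """Fraction of a point charge at ``height`` nm that couples to the surface.

    Wet mode: exp(−height/λD). Dry mode: 1 at every height.
    """
    if not (math.isfinite(height) and height >= 0):
        raise DomainError(f"height must be >= 0 nm, got {height}")
    if cond.mode == "dry":
        return 1.0
    return math.exp(-height / debye_length(cond))


def sensing_area(gate_length: float, gate_width: float) -> float:
    """Active sensing area in nm² of a rectangular gate footprint."""
    if not (gate_length > 0 and gate_width > 0):
        raise DomainError("gate_length and gate_width must be > 0")
    return gate_length * gate_width


def molecule_count(layer: ProbeLayer) -> int:
    """Number of probe molecules on the sensing area (density × area)."""
    return int(round(layer.density * layer.area * 1e-14))  # nm² -> cm²


def effective_surface_charge(layer: ProbeLayer, unbound: ProbeState,
                             bound: ProbeState, cond: InterfaceCondition) -> float:
    """Fraction-weighted, screened sheet-charge density in C/cm² (signed).

    σ = N e [ f q_b S(h_b) + (1−f) q_u S(h_u) ]

    with N the probe density, f the bound fraction, q in elementary charges
    and S the height attenuation. Affine in f by construction; in dry mode S
    is 1 and σ is independent of ionic strength.
    """
    if unbound.label != "unbound":
        raise ValidationError(f"expected an unbound state, got label {unbound.label!r}")
    if bound.label != "bound":
        raise ValidationError(f"expected a bound state, got label {bound.label!r}")
    f = layer.bound_fraction
    per_probe = (f * bound.net_charge * screening_factor(bound.height, cond)
                 + (1.0 - f) * unbound.net_charge * screening_factor(unbound.height, cond))
    return layer.density * ELEMENTARY_CHARGE * per_probe


def charge_per_nm2(sigma: float) -> float:
    """Convert a sheet charge density from C/cm² to elementary charges per nm²."""
    return sigma / ELEMENTARY_CHARGE * 1e-14
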