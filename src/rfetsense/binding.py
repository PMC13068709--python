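"""Probe–target binding thermodynamics.

Single-site (1:1) equilibrium binding: a surface-tethered recognition element
(aptamer, enzyme) binds its target with dissociation constant ``KD``, giving
the Langmuir occupancy

    f_a = [T] / (KD + [T])

where ``[T]`` is the free target concentration. ``KD`` relates to the binding
free energy through ``ΔG = R·T·ln(KD / 1 M)``, so an end-point free-energy
estimate (e.g. MM-PBSA) maps directly onto an equilibrium constant.

Multi-valent, cooperative (Hill) and kinetic on/off-rate models are out of
scope: the occupancy model here is strictly 1:1 at equilibrium.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import R_KCAL_PER_MOL_K
from .errors import BracketError, DomainError, ValidationError

DEFAULT_TEMPERATURE = 298.0  # K, room temperature


@dataclass(frozen=True)
class BindingModel:
    """Dissociation constant (molar) and temperature (K) of a probe layer."""

    kd: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if not (math.isfinite(self.kd) and self.kd > 0):
            raise ValidationError(f"kd must be positive and finite, got {self.kd}")
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValidationError(
                f"temperature must be positive and finite, got {self.temperature}")

    @property
    def delta_g(self) -> float:
        """Binding free energy in kcal/mol implied by ``kd``."""
        return free_energy_from_kd(self.kd, self.temperature)


@dataclass(frozen=True)
class BindingCurve:
    """Occupancy versus concentration: f_a(c) sampled on an increasing grid."""

    concentrations: np.ndarray
    fractions: np.ndarray
    kd: float | None = field(default=None, compare=False)

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "fractions", f)
        if c.ndim != 1 or c.size == 0:
            raise ValidationError("concentrations must be a non-empty 1-D array")
        if f.shape != c.shape:
            raise ValidationError("fractions must match concentrations in length")
        if np.any(c < 0):
            raise ValidationError("concentrations must be non-negative")
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValidationError("fractions must lie in [0, 1]")
        if f.size > 1 and np.any(np.diff(f) < 0):
            raise ValidationError("fractions must be non-decreasing")

    def __len__(self) -> int:
        return int(self.concentrations.size)

    def to_csv(self, path_or_buf) -> None:
        """Write a 2-column CSV (``concentration_M``, ``bound_fraction``).

        A ``# kd_M=`` comment records the generating KD when known.
        """
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf, "w") if own else path_or_buf
        try:
            if self.kd is not None:
                fh.write(f"# kd_M={self.kd:.10g}\n")
            fh.write("concentration_M,bound_fraction\n")
            for c, f in zip(self.concentrations, self.fractions):
                fh.write(f"{c:.10g},{f:.10g}\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "BindingCurve":
        own = isinstance(path_or_buf, (str, bytes))
        fh = open(path_or_buf) if own else path_or_buf
        try:
            kd = None
            rows = []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "kd_M=" in line:
                        kd = float(line.split("kd_M=")[1].split()[0])
                    continue
                if line.startswith("concentration_M"):
                    continue
                a, b = line.split(",")
                rows.append((float(a), float(b)))
        finally:
            if own:
                fh.close()
        c, f = (np.array(x) for x in zip(*rows))
        return cls(c, f, kd=kd)


def kd_from_free_energy(delta_g: float,
                        temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a binding free energy (kcal/mol) to a dissociation constant (M).

    ``KD = exp(ΔG / (R T))`` with R = 1.9872e-3 kcal/(mol K) and the 1 M
    standard state. A favourable (negative) ΔG gives KD < 1 M.
    """
    if not math.isfinite(delta_g):
        raise DomainError(f"delta_g must be finite, got {delta_g}")
    if not (math.isfinite(temperature) and temperature > 0):
        raise DomainError(f"temperature must be positive, got {temperature}")
    return math.exp(delta_g / (R_KCAL_PER_MOL_K * temperature))


def free_energy_from_kd(kd: float,
                        temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a dissociation constant (M) to a binding free energy (kcal/mol)."""
    if not (math.isfinite(kd) and kd > 0):
        raise DomainError(f"kd must be positive and finite, got {kd}")
    if not (math.isfinite(temperature) and temperature > 0):
        raise DomainError(f"temperature must be positive, got {temperature}")
    return R_KCAL_PER_MOL_K * temperature * math.log(kd)


def bound_fraction(concentration, model: BindingModel):
    """Langmuir occupancy f_a = [T] / (KD + [T]); scalar or array-valued."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise DomainError("concentration must be finite and non-negative")
    f = c / (model.kd + c)
    return float(f) if np.isscalar(concentration) or f.ndim == 0 else f


def binding_curve(concentrations: Sequence[float],
                  model: BindingModel) -> BindingCurve:
    """Evaluate the Langmuir isotherm on a sorted concentration grid."""
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("concentrations must be a non-empty 1-D sequence")
    if c.size > 1 and np.any(np.diff(c) <= 0):
        raise ValidationError("concentrations must be strictly increasing")
    f = bound_fraction(c, model)
    return BindingCurve(c, np.atleast_1d(f), kd=model.kd)


def kd_from_binding_curve(curve: BindingCurve) -> float:
    """Read KD off a binding curve as the f = 0.5 crossing.

    Interpolates linearly in (log10 c, f), the coordinate in which a Langmuir
    isotherm is nearly straight around half-occupancy. The curve must bracket
    f = 0.5 with positive concentrations around the crossing.
    """
    c = curve.concentrations
    f = curve.fractions
    if f.min() >= 0.5 or f.max() <= 0.5:
        raise BracketError(
            f"curve does not bracket f=0.5 (range {f.min():.4g}..{f.max():.4g})")
    # first index where f >= 0.5
    hi = int(np.searchsorted(f, 0.5, side="left"))
    if f[hi] == 0.5:
        return float(c[hi])
    lo = hi - 1
    if c[lo] <= 0:
        raise BracketError("crossing abuts zero concentration; cannot log-interpolate")
    x0, x1 = math.log10(c[lo]), math.log10(c[hi])
    t = (0.5 - f[lo]) / (f[hi] - f[lo])
    return float(10.0 ** (x0 + t * (x1 - x0)))
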