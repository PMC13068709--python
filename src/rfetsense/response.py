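"""Sensing-response pipeline: from bound fraction to calibration curves.

Composes the three layers of the model:

1. binding — the Langmuir isotherm maps target concentration to the bound
   fraction f of the probe layer;
2. interface — f, the two probe conformations and the electrolyte screening
   give the effective sheet charge σ(f) presented to the program gate;
3. device — the RFET drain current at the ON read-out point (|V_CG| = 5 V,
   |V_DS| = 0.1 V) as a function of σ.

The composition yields current-versus-fraction curves, concentration
calibration curves, and the relative response ΔI/I₀ used to compare sensors.
Each case study carries a default interface condition: the aptamer–CEA
sensor reads out in 0.01×PBS, where the Debye length comfortably exceeds the
3.4 nm binding height and the binding-induced elongation of the aptamer
*reduces* the coupled charge (current suppression); the protease–inhibitor
sensor reads out dry, where the extra positive charge of the bound complex
couples fully (current enhancement).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .binding import BindingModel, bound_fraction
from .curves import ResponseCurve
from .device import BiasPoint, BiasProtocol, Device
from .errors import (DomainError, ExtrapolationError, InversionError,
                     ValidationError)
from .interface import (InterfaceCondition, ProbeLayer,
                        effective_surface_charge)
from .probes import FixtureCase

#: probe surface density used throughout the case studies, molecules/cm²
DEFAULT_PROBE_DENSITY = 1e12

#: default concentration grid: log-spaced 0.01–100 nM with c = 0 prepended
DEFAULT_CONCENTRATIONS = np.concatenate(
    [[0.0], np.logspace(-11, -7, 17)])


def default_interface_condition(case_id: str) -> InterfaceCondition:
    """Read-out environment paired with each case study (see module docs)."""
    if case_id == "aptamer_cea":
        return InterfaceCondition.pbs(0.01)
    if case_id == "protease_inhibitor":
        return InterfaceCondition.dry()
    raise KeyError(f"unknown case_id {case_id!r}")


def default_protocol_sign(case_id: str) -> str:
    """Programming polarity matched to the analyte charge of each case."""
    return {"aptamer_cea": "p", "protease_inhibitor": "n"}[case_id]


@dataclass(frozen=True)
class ResponseSummary:
    """Headline sensing metrics extracted from a calibration curve."""

    i0: float  # A, zero-target current
    max_relative_response: float  # max |ΔI| / |I0|
    response_sign: str  # 'suppression' or 'enhancement'
    half_response_concentration: float  # molar

    def to_json(self, path_or_buf=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path_or_buf is not None:
            own = isinstance(path_or_buf, (str, bytes))
            fh = open(path_or_buf, "w") if own else path_or_buf
            try:
                fh.write(text + "\n")
            finally:
                if own:
                    fh.close()
        return text


def sigma_of_fraction(fraction: float, fixture: FixtureCase,
                      cond: InterfaceCondition, device: Device,
                      density: float = DEFAULT_PROBE_DENSITY) -> float:
    """Effective PG sheet charge (C/cm²) at one bound fraction."""
    layer = ProbeLayer(density=density, area=device.spec.sensing_area_nm2,
                       bound_fraction=fraction)
    return effective_surface_charge(layer, fixture.unbound, fixture.bound, cond)


def current_vs_fraction(device: Device, protocol: BiasProtocol,
                        fixture: FixtureCase, cond: InterfaceCondition,
                        fractions, density: float = DEFAULT_PROBE_DENSITY,
                        superpose_pg: bool = False) -> ResponseCurve:
    """Drain current at the ON read-out point versus bound fraction.

    The molecular sheet charge σ(f) is the program-gate input: by default the
    metallic PG electrode is held at 0 V and the probe layer alone programs
    the drain junction (the "virtual doping" picture), which keeps the drain
    barrier in its charge-sensitive regime. ``superpose_pg=True`` adds the
    protocol's V_PG on top, driving the junction toward saturation.

    One device solve per fraction, with continuation (each solution seeds the
    next — σ is affine in f, so neighbouring points are close).
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValidationError("fractions must be a non-empty 1-D sequence")
    if np.any((f < 0) | (f > 1)):
        raise ValidationError("fractions must lie in [0, 1]")
    if f.size > 1 and np.any(np.diff(f) <= 0):
        raise ValidationError("fractions must be strictly increasing")

    v_pg = protocol.v_pg if superpose_pg else 0.0
    currents = np.empty_like(f)
    state = None
    for k, frac in enumerate(f):
        sigma = sigma_of_fraction(float(frac), fixture, cond, device, density)
        bias = BiasPoint(v_pg=v_pg, v_cg=protocol.v_cg_on,
                         v_ds=protocol.v_ds, sigma_pg=sigma)
        state = device.solve(bias, initial=state)
        currents[k] = state.current_drain
    meta = {"fixture": fixture.case_id, "polarity": protocol.polarity,
            "v_pg_V": v_pg, "v_cg_V": protocol.v_cg_on,
            "v_ds_V": protocol.v_ds, "interface_mode": cond.mode,
            "ionic_strength_M": cond.ionic_strength,
            "density_per_cm2": density}
    return ResponseCurve(x=f, current=currents, x_kind="fraction",
                         metadata=meta)


def calibration_curve(curve_f: ResponseCurve, model: BindingModel,
                      concentrations) -> ResponseCurve:
    """Map a current-vs-fraction curve to current-vs-concentration.

    Each concentration c maps to f = c/(KD + c); the current at f comes from
    monotone piecewise-cubic (PCHIP) interpolation of ``curve_f``, so the
    composition is exact at the fraction-grid points.
    """
    if curve_f.x_kind != "fraction":
        raise ValidationError("curve_f must be a fraction-indexed curve")
    if len(curve_f) < 11:
        raise ValidationError("curve_f must sample >= 11 fractions")
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("concentrations must be a non-empty 1-D sequence")
    if c.size > 1 and np.any(np.diff(c) <= 0):
        raise ValidationError("concentrations must be strictly increasing")
    f = np.atleast_1d(bound_fraction(c, model))
    lo, hi = curve_f.x.min(), curve_f.x.max()
    if np.any(f < lo - 1e-12) or np.any(f > hi + 1e-12):
        raise ExtrapolationError(
            f"concentration maps to f outside the covered range [{lo}, {hi}]")
    interp = PchipInterpolator(curve_f.x, curve_f.current)
    currents = interp(np.clip(f, lo, hi))
    meta = dict(curve_f.metadata)
    meta["kd_M"] = model.kd
    return ResponseCurve(x=c, current=np.asarray(currents, dtype=float),
                         x_kind="concentration", metadata=meta)


def relative_response(curve_c: ResponseCurve) -> ResponseSummary:
    """ΔI/I₀ metrics of a calibration curve (ΔI = I_D(c) − I_D(0)).

    ``curve_c`` must start at c = 0, which defines I₀. The response sign is
    decided on |I| (suppression if the current magnitude falls with c), so
    the negative currents of the p branch are handled symmetrically.
    """
    if curve_c.x_kind != "concentration":
        raise ValidationError("expected a concentration-indexed curve")
    if curve_c.x[0] != 0.0 or len(curve_c) < 2:
        raise ValidationError("curve must start at c = 0 and have >= 2 points")
    i0 = float(curve_c.current[0])
    if abs(i0) < 10 * np.finfo(float).tiny or i0 == 0.0:
        raise DomainError("degenerate baseline: I0 is zero within floor")
    rel = np.abs(curve_c.current - i0) / abs(i0)
    max_rel = float(rel.max())
    sign = ("suppression"
            if abs(curve_c.current[-1]) < abs(i0) else "enhancement")
    half = math.nan
    if max_rel > 0:
        target = max_rel / 2.0
        c = curve_c.x
        for k in range(1, len(c)):
            if rel[k] >= target:
                if rel[k] == rel[k - 1] or c[k - 1] == 0.0:
                    half = float(c[k])
                else:  # linear in log10(c)
                    t = (target - rel[k - 1]) / (rel[k] - rel[k - 1])
                    lg = math.log10(c[k - 1]) + t * (math.log10(c[k])
                                                     - math.log10(c[k - 1]))
                    half = 10.0 ** lg
                break
    return ResponseSummary(i0=i0, max_relative_response=max_rel,
                           response_sign=sign,
                           half_response_concentration=half)


def invert_response_for_kd(curve_c: ResponseCurve,
                           curve_f: ResponseCurve) -> float:
    """Recover KD from a calibration curve by inverting the device map.

    Maps each measured current back to a bound fraction through the monotone
    inverse of ``curve_f``, then fits the Langmuir isotherm f = c/(KD + c)
    to the (c, f) pairs by least squares in log10 KD.
    """
    if curve_f.x_kind != "fraction" or curve_c.x_kind != "concentration":
        raise ValidationError("need a fraction curve and a concentration curve")
    i_f = curve_f.current
    d = np.diff(i_f)
    if np.all(d > 0):
        x_i, y_f = i_f, curve_f.x
    elif np.all(d < 0):
        x_i, y_f = i_f[::-1], curve_f.x[::-1]
    else:
        raise InversionError("curve_f is not strictly monotone in current")
    inv = PchipInterpolator(x_i, y_f)
    mask = curve_c.x > 0
    if mask.sum() < 2:
        raise ValidationError("need >= 2 positive concentrations to fit KD")
    c = curve_c.x[mask]
    i_meas = np.clip(curve_c.current[mask], min(x_i[0], x_i[-1]),
                     max(x_i[0], x_i[-1]))
    f_hat = np.clip(inv(i_meas), 0.0, 1.0)
    # closed-form per-point guess, then least squares in log10 KD
    interior = (f_hat > 1e-6) & (f_hat < 1 - 1e-6)
    if not np.any(interior):
        raise InversionError("inverted fractions are all saturated; cannot fit KD")
    guess = float(np.median(c[interior] * (1 - f_hat[interior])
                            / f_hat[interior]))

    def resid(log10_kd):
        kd = 10.0 ** log10_kd[0]
        return c / (kd + c) - f_hat

    fit = least_squares(resid, x0=[math.log10(guess)], method="lm")
    return float(10.0 ** fit.x[0])
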