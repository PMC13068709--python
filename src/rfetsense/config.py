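"""Run configuration: one YAML file drives a reproducible study.

A config names a fixture case (or PQR files), the interface condition, the
probe layer, the device and materials, the bias protocol and the sweep
grids. Every key has a default; unknown keys are rejected by name so typos
fail loudly. ``load_config`` normalizes the file into a fully-populated
dictionary, so ``dump(load(x))`` round-trips exactly.
"""

from __future__ import annotations

import copy
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .device import DeviceSpec, MaterialParams
from .errors import ValidationError
from .interface import InterfaceCondition
from .probes import (FixtureCase, make_fixture, probe_state_from_atoms,
                     read_pqr)
from .response import (DEFAULT_PROBE_DENSITY, default_interface_condition,
                       default_protocol_sign)

_DEFAULTS: dict = {
    "fixture": {
        "case_id": "aptamer_cea",
        "seed": 0,
        "jitter": 0.0,
        "overrides": {},
        "unbound_pqr": None,
        "bound_pqr": None,
        "substrate_z_nm": 0.0,
        "kd_M": None,
    },
    "interface": {
        "mode": "auto",  # auto: per-case default; else wet/dry
        "ionic_strength_M": 1.5e-3,
        "relative_permittivity": 78.4,
        "temperature_K": 298.0,
    },
    "layer": {"density_per_cm2": DEFAULT_PROBE_DENSITY},
    "device": {
        "channel_length_nm": 1000.0,
        "gate_length_pg_nm": 440.0,
        "gate_length_cg_nm": 440.0,
        "width_nm": 150.0,
        "si_thickness_nm": 10.0,
        "eot_nm": 1.0,
        "schottky_barrier_e_eV": 0.56,
        "schottky_barrier_h_eV": 0.56,
        "mesh_nx": 201,
        "mesh_ny": 30,
        "quantum_correction": False,
    },
    "materials": {
        "bandgap_eV": 1.12,
        "intrinsic_density_per_cm3": 1.0e10,
        "electron_mobility_cm2_per_Vs": 1400.0,
        "hole_mobility_cm2_per_Vs": 450.0,
        "effective_mass_e": 0.26,
        "effective_mass_h": 0.36,
        "relative_permittivity_si": 11.7,
        "relative_permittivity_ox": 3.9,
        "temperature_K": 300.0,
    },
    "protocol": {"polarity": "auto", "v_cg_points": 11},
    "sweep": {
        "fractions": 11,
        "concentrations_nM": {"min": 0.01, "max": 100.0, "points": 17},
    },
    "output_dir": "rfetsense_out",
    "seed": 0,
    "verbosity": "info",
}

_VALID_OVERRIDES = {"unbound_charge", "unbound_height", "target_charge",
                    "bound_height", "kd"}


def _merge(section: str, defaults: dict, given: dict) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}")
    out = copy.deepcopy(defaults)
    out.update(given)
    return out


@dataclass
class RunConfig:
    """A validated, fully-defaulted run description."""

    fixture: FixtureCase
    condition: InterfaceCondition
    density: float
    spec: DeviceSpec
    materials: MaterialParams
    polarity: str
    v_cg_points: int
    fractions: np.ndarray
    concentrations: np.ndarray  # molar, with 0 prepended
    output_dir: str
    seed: int
    verbosity: str
    normalized: dict = field(repr=False, default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            dump_config(self.normalized).encode()).hexdigest()[:16]


def _build_fixture(fx: dict) -> FixtureCase:
    if fx["unbound_pqr"] or fx["bound_pqr"]:
        if not (fx["unbound_pqr"] and fx["bound_pqr"] and fx["kd_M"]):
            raise ValidationError(
                "section 'fixture': PQR input needs unbound_pqr, bound_pqr "
                "and kd_M together")
        for key in ("unbound_pqr", "bound_pqr"):
            if not os.path.exists(fx[key]):
                raise ValidationError(
                    f"section 'fixture': file {fx[key]!r} ({key}) does not exist")
        states = {}
        for key, label in (("unbound_pqr", "unbound"), ("bound_pqr", "bound")):
            with open(fx[key]) as fh:
                states[label] = probe_state_from_atoms(
                    read_pqr(fh), fx["substrate_z_nm"], label)
        return FixtureCase(case_id=fx["case_id"], unbound=states["unbound"],
                           bound=states["bound"], kd=float(fx["kd_M"]),
                           seed=int(fx["seed"]))
    overrides = dict(fx["overrides"] or {})
    unknown = set(overrides) - _VALID_OVERRIDES
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section 'fixture.overrides'")
    if fx["kd_M"] is not None:
        overrides["kd"] = float(fx["kd_M"])
    return make_fixture(fx["case_id"], overrides=overrides or None,
                        seed=int(fx["seed"]), jitter=float(fx["jitter"]))


def _normalize(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValidationError(f"unknown top-level key(s) {sorted(unknown)}")
    norm = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            norm[key] = _merge(key, default, raw.get(key) or {})
        else:
            norm[key] = raw.get(key, default)
    conc = norm["sweep"]["concentrations_nM"]
    if isinstance(conc, dict):
        norm["sweep"]["concentrations_nM"] = _merge(
            "sweep.concentrations_nM", {"min": 0.01, "max": 100.0, "points": 17},
            conc)
    return norm


def parse_config(raw: dict) -> RunConfig:
    norm = _normalize(raw)
    try:
        fixture = _build_fixture(norm["fixture"])
    except ValidationError:
        raise
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"section 'fixture': {exc}") from exc

    itf = norm["interface"]
    if itf["mode"] == "auto":
        condition = default_interface_condition(fixture.case_id)
    elif itf["mode"] == "dry":
        condition = InterfaceCondition.dry(temperature=itf["temperature_K"])
    elif itf["mode"] == "wet":
        condition = InterfaceCondition(
            ionic_strength=float(itf["ionic_strength_M"]),
            relative_permittivity=float(itf["relative_permittivity"]),
            temperature=float(itf["temperature_K"]), mode="wet")
    else:
        raise ValidationError("section 'interface': mode must be auto/wet/dry")

    density = float(norm["layer"]["density_per_cm2"])
    if density <= 0:
        raise ValidationError("section 'layer': density_per_cm2 must be > 0")

    dv = norm["device"]
    try:
        spec = DeviceSpec(
            channel_length=dv["channel_length_nm"],
            gate_length_pg=dv["gate_length_pg_nm"],
            gate_length_cg=dv["gate_length_cg_nm"],
            width=dv["width_nm"], si_thickness=dv["si_thickness_nm"],
            eot=dv["eot_nm"],
            schottky_barrier_e=dv["schottky_barrier_e_eV"],
            schottky_barrier_h=dv["schottky_barrier_h_eV"],
            mesh_nx=int(dv["mesh_nx"]), mesh_ny=int(dv["mesh_ny"]),
            quantum_correction=bool(dv["quantum_correction"]))
    except ValidationError as exc:
        raise ValidationError(f"section 'device': {exc}") from exc

    mt = norm["materials"]
    try:
        materials = MaterialParams(
            bandgap=mt["bandgap_eV"],
            intrinsic_density=mt["intrinsic_density_per_cm3"],
            electron_mobility=mt["electron_mobility_cm2_per_Vs"],
            hole_mobility=mt["hole_mobility_cm2_per_Vs"],
            effective_mass_e=mt["effective_mass_e"],
            effective_mass_h=mt["effective_mass_h"],
            relative_permittivity_si=mt["relative_permittivity_si"],
            relative_permittivity_ox=mt["relative_permittivity_ox"],
            temperature=mt["temperature_K"])
    except ValidationError as exc:
        raise ValidationError(f"section 'materials': {exc}") from exc

    polarity = norm["protocol"]["polarity"]
    if polarity == "auto":
        polarity = default_protocol_sign(fixture.case_id)
    if polarity not in ("n", "p"):
        raise ValidationError("section 'protocol': polarity must be auto/n/p")

    nfrac = int(norm["sweep"]["fractions"])
    if nfrac < 2:
        raise ValidationError("section 'sweep': fractions must be >= 2")
    conc = norm["sweep"]["concentrations_nM"]
    if isinstance(conc, dict):
        grid = np.logspace(np.log10(conc["min"]), np.log10(conc["max"]),
                           int(conc["points"])) * 1e-9
    else:
        grid = np.asarray(sorted(float(v) for v in conc)) * 1e-9
        if grid.size == 0 or np.any(grid <= 0):
            raise ValidationError(
                "section 'sweep': concentrations_nM must be positive")
    return RunConfig(
        fixture=fixture, condition=condition, density=density, spec=spec,
        materials=materials, polarity=polarity,
        v_cg_points=int(norm["protocol"]["v_cg_points"]),
        fractions=np.linspace(0.0, 1.0, nfrac),
        concentrations=np.concatenate([[0.0], grid]),
        output_dir=str(norm["output_dir"]), seed=int(norm["seed"]),
        verbosity=str(norm["verbosity"]), normalized=norm)


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run config, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def dump_config(normalized: dict) -> str:
    """Canonical YAML text of a normalized config (sorted keys)."""
    return yaml.safe_dump(normalized, sort_keys=True, default_flow_style=False)
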