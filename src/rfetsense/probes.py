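"""Per-atom charge profiles and the two built-in case-study fixtures.

Molecular inputs arrive either as PQR files (per-atom position/charge/radius
records, the standard carrier for electrostatics-ready structures) or as the
built-in fixtures that emulate the two case studies this package models:

``aptamer_cea``
    A 40-nt thiolated DNA aptamer against carcinoembryonic antigen (CEA).
    Unbound charge −39 e (one bridging phosphate per internucleotide linkage
    of a 40-mer; the thiol linker is neglected), charge-centroid height
    7.15 nm; on binding the aptamer elongates to 9.13 nm and picks up the
    target's slight negative charge (default −2 e, parameterized — CEA's net
    charge at physiological pH is only qualitatively negative). KD 1.47 nM.

``protease_inhibitor``
    Surface-tethered HIV-1 protease binding a cyclic-urea inhibitor. The free
    enzyme presents a net positive patch; the complex is more positive. The
    absolute charges (+4 → +6 e) and layer height (2.0 nm, a tethered
    globular dimer) are stated placeholders consistent with the sign and
    ordering of the underlying structural data, exposed as parameters rather
    than asserted constants. KD 0.31 nM (experimental).

Coordinate convention: z is height above the substrate plane z = 0; PQR
coordinates are Å and are converted to nm on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import EmptyInputError, ParseError, ValidationError
from .interface import ProbeState

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class AtomRecord:
    """One PQR atom: name, position (nm), partial charge (e), radius (nm)."""

    name: str
    position: tuple[float, float, float]
    charge: float
    radius: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.position):
            raise ValidationError(f"non-finite coordinates for atom {self.name!r}")
        if not (math.isfinite(self.radius) and self.radius >= 0):
            raise ValidationError(f"radius must be >= 0, got {self.radius}")


@dataclass(frozen=True)
class FixtureCase:
    """A complete synthetic case study: both probe states plus the KD."""

    case_id: str
    unbound: ProbeState
    bound: ProbeState
    kd: float
    seed: int = 0

    def __post_init__(self):
        if not self.kd > 0:
            raise ValidationError(f"kd must be > 0, got {self.kd}")
        if self.unbound.label != "unbound" or self.bound.label != "bound":
            raise ValidationError("fixture states carry wrong labels")


def read_pqr(source: TextIO | Iterable[str]) -> list[AtomRecord]:
    """Parse a PQR stream into atom records (Å → nm on read).

    Accepts the whitespace-separated PQR dialect with or without a chain-ID
    column: ``ATOM/HETATM serial name resname [chain] resid x y z q r``.
    Lines other than ATOM/HETATM are ignored. Raises :class:`ParseError` with
    the offending line number on malformed numerics and
    :class:`EmptyInputError` if no atom records are present.
    """
    records: list[AtomRecord] = []
    for lineno, raw in enumerate(source, start=1):
        fields = raw.split()
        if not fields or fields[0] not in ("ATOM", "HETATM"):
            continue
        # 10 columns: no chain ID; 11 columns: chain ID at index 4.
        if len(fields) == 10:
            name = fields[2]
            numeric = fields[5:10]
        elif len(fields) == 11:
            name = fields[2]
            numeric = fields[6:11]
        else:
            raise ParseError(
                f"expected 10 or 11 whitespace-separated fields, got {len(fields)}",
                lineno)
        try:
            x, y, z, q, r = (float(v) for v in numeric)
        except ValueError as exc:
            raise ParseError(f"malformed numeric field ({exc})", lineno) from None
        records.append(AtomRecord(
            name=name,
            position=(x / ANGSTROM_PER_NM, y / ANGSTROM_PER_NM, z / ANGSTROM_PER_NM),
            charge=q, radius=r / ANGSTROM_PER_NM))
    if not records:
        raise EmptyInputError("no ATOM/HETATM records in PQR input")
    return records


def write_pqr(records: Sequence[AtomRecord], dest: TextIO) -> None:
    """Write atom records back to the whitespace-separated PQR dialect (nm → Å)."""
    if not records:
        raise EmptyInputError("no records to write")
    for serial, rec in enumerate(records, start=1):
        x, y, z = (v * ANGSTROM_PER_NM for v in rec.position)
        dest.write(
            f"ATOM {serial} {rec.name} MOL 1 "
            f"{x:.6f} {y:.6f} {z:.6f} {rec.charge:.6f} {rec.radius * ANGSTROM_PER_NM:.6f}\n")


def probe_state_from_atoms(atoms: Sequence[AtomRecord], substrate_z: float,
                           label: str) -> ProbeState:
    """Collapse an atom list to a net charge and a charge-centroid height.

    Height is the |charge|-weighted mean of |z − substrate_z|; when the
    total absolute charge vanishes it falls back to the unweighted geometric
    centroid. Invariant under permutation of the atom list.
    """
    if not atoms:
        raise EmptyInputError("cannot derive a probe state from zero atoms")
    z = np.array([a.position[2] for a in atoms])
    q = np.array([a.charge for a in atoms])
    heights = np.abs(z - substrate_z)
    wsum = np.abs(q).sum()
    if wsum > 0:
        height = float(np.abs(q) @ heights / wsum)
    else:
        height = float(heights.mean())
    return ProbeState(label=label, net_charge=float(q.sum()), height=height)


#: Default parameters of the two case studies (all overridable).
_FIXTURE_DEFAULTS: dict[str, dict] = {
    "aptamer_cea": dict(
        unbound_charge=-39.0, unbound_height=7.15,
        target_charge=-2.0, bound_height=9.13,
        kd=1.47e-9),
    "protease_inhibitor": dict(
        unbound_charge=4.0, unbound_height=2.0,
        target_charge=2.0, bound_height=2.0,
        kd=0.31e-9),
}


def fixture_case_ids() -> tuple[str, ...]:
    return tuple(_FIXTURE_DEFAULTS)


def make_fixture(case_id: str, overrides: dict | None = None,
                 seed: int = 0, jitter: float = 0.0) -> FixtureCase:
    """Build one of the two case-study fixtures.

    ``overrides`` may replace any of ``unbound_charge``, ``unbound_height``,
    ``target_charge`` (charge the bound state gains over the unbound one),
    ``bound_height`` and ``kd``. ``jitter`` (relative, default 0) adds
    seed-controlled Gaussian perturbations to charges and heights for
    ensemble runs; identical (seed, overrides, jitter) give identical
    fixtures.
    """
    if case_id not in _FIXTURE_DEFAULTS:
        raise KeyError(
            f"unknown case_id {case_id!r}; known: {sorted(_FIXTURE_DEFAULTS)}")
    params = dict(_FIXTURE_DEFAULTS[case_id])
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ValidationError(f"unknown fixture overrides: {sorted(unknown)}")
        params.update(overrides)

    qu = params["unbound_charge"]
    hu = params["unbound_height"]
    qb = params["unbound_charge"] + params["target_charge"]
    hb = params["bound_height"]
    if jitter:
        rng = np.random.default_rng(seed)
        qu *= 1.0 + jitter * rng.standard_normal()
        qb *= 1.0 + jitter * rng.standard_normal()
        hu = max(0.0, hu * (1.0 + jitter * rng.standard_normal()))
        hb = max(0.0, hb * (1.0 + jitter * rng.standard_normal()))
    return FixtureCase(
        case_id=case_id,
        unbound=ProbeState("unbound", qu, hu),
        bound=ProbeState("bound", qb, hb),
        kd=params["kd"], seed=seed)


def fixture_config_fragment(case: FixtureCase) -> str:
    """Render a fixture as a YAML config fragment for reproducible runs."""
    return (
        "fixture:\n"
        f"  case_id: {case.case_id}\n"
        f"  kd_M: {case.kd:.6g}\n"
        f"  unbound: {{charge_e: {case.unbound.net_charge:.6g}, height_nm: {case.unbound.height:.6g}}}\n"
        f"  bound: {{charge_e: {case.bound.net_charge:.6g}, height_nm: {case.bound.height:.6g}}}\n"
        f"  seed: {case.seed}\n")
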