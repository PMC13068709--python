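# rfetsense

Multiscale response modeling for biosensors built on **reconfigurable
field-effect transistors (RFETs)** — doping-free Schottky-barrier devices
that switch between n- and p-type operation electrostatically, and can
therefore read out both positively and negatively charged analytes on a
single chip.

The package links three scales into one predictive pipeline:

1. **Binding thermodynamics.** A surface-tethered recognition element
   (an aptamer or an enzyme) binds its target with 1:1 stoichiometry; the
   occupied fraction follows the Langmuir isotherm
   `f_a = [T] / (K_D + [T])`, with `ΔG = R·T·ln K_D` connecting the
   dissociation constant to end-point free-energy estimates (MM-PBSA).
2. **Interfacial electrostatics.** Each probe conformation is reduced to a
   net charge at a centroid height `h`; in electrolyte its coupling to the
   gate is attenuated by `exp(−h/λ_D)` with the Debye length
   `λ_D = sqrt(ε₀ε_r k_B T / (2 N_A e² I))`. The fraction-weighted, screened
   sheet charge `σ(f)` is what the device sees.
3. **Device physics.** A bespoke 2-D drift-diffusion solver (Poisson +
   electron/hole continuity, Scharfetter–Gummel fluxes in Slotboom
   variables) of a 1 µm dual-gate RFET with Schottky source/drain contacts.
   Contact injection combines thermionic emission with WKB tunneling via the
   Tsu-Esaki formalism; `σ(f)` enters as a sheet charge on the program-gate
   stack — the "virtual doping" that programs the drain junction.

Composing the three layers yields transfer characteristics, drain current
versus bound fraction, concentration calibration curves and the relative
response ΔI/I₀. Two built-in case studies exercise both polarities: a 40-nt
anti-CEA DNA aptamer (negative analyte, p-programmed read-out, current
suppression) and HIV-1 protease with a cyclic-urea inhibitor (positive
analyte, n-programmed read-out, current enhancement).

Intended users: biosensor modelers and device engineers who want a
transparent, scriptable alternative to commercial TCAD for exploring
charge-based FET sensing, and a reference implementation of the
binding → screening → device composition.

## Worked example

```python
import numpy as np
from rfetsense import (BindingModel, DeviceSpec, MaterialParams, build_device,
                       kd_from_free_energy, debye_length, InterfaceCondition,
                       make_fixture, program_polarity)
from rfetsense.response import (current_vs_fraction, calibration_curve,
                                relative_response, invert_response_for_kd,
                                default_interface_condition,
                                DEFAULT_CONCENTRATIONS)

kd = kd_from_free_energy(-12.05, 298.0)        # aptamer–CEA MM-PBSA ΔG
lam = debye_length(InterfaceCondition.pbs(0.01, 298.0))

device = build_device(DeviceSpec(mesh_nx=101, mesh_ny=16), MaterialParams())
fixture = make_fixture("aptamer_cea")
cond = default_interface_condition("aptamer_cea")   # 0.01×PBS read-out
curve_f = current_vs_fraction(device, program_polarity("p"), fixture, cond,
                              np.linspace(0, 1, 11))
curve_c = calibration_curve(curve_f, BindingModel(kd=fixture.kd),
                            DEFAULT_CONCENTRATIONS)
summary = relative_response(curve_c)
```

prints, via the obvious `print` statements:

```
KD from MM-PBSA dG:      1.455 nM
Debye length, 0.01xPBS:  7.85 nm
I_D(f=0):                -1.634e-11 A
I_D(f=1):                -1.476e-11 A
response sign:           suppression
max |dI/I0|:             9.4%
half-response conc.:     2.31 nM
recovered KD:            1.470 nM
```

Reading: the −12.05 kcal/mol binding free energy corresponds to a 1.46 nM
dissociation constant. In 0.01×PBS the Debye length (7.85 nm) comfortably
exceeds the 3.4 nm binding height, so the aptamer's conformational
elongation on binding (7.15 → 9.13 nm) *reduces* the negative charge coupled
to the program gate: the p-type hole current shrinks monotonically with
occupancy (here by 9.4% at saturation), the calibration curve inherits the
Langmuir shape (half response near K_D), and inverting the pipeline hands
back the K_D it was built from. Running the protease–inhibitor fixture
n-programmed gives the opposite sign — current enhancement — on the same
device geometry.

A `rfetsense` command-line tool exposes the same pipeline
(`binding`, `debye`, `transfer`, `respond`, `calibrate`, `fixtures`) driven
by one YAML config; outputs are CSV/JSON plus a run manifest for
reproducibility.

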