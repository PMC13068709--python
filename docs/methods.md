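# Methods

This note documents the models implemented in `rfetsense`, the assumptions
behind them, the defaults and why they were chosen, and the numerical
decisions a user extending the package should know about.

## Binding layer

Single-site equilibrium binding: the bound fraction of a probe layer is
`f_a = [T]/(K_D + [T])`. Assumptions: 1:1 stoichiometry, equilibrium (no
kinetics), no cooperativity or multivalency, free-target concentration not
depleted by binding. `ΔG = R·T·ln(K_D/1 M)` with `R = 1.9872×10⁻³
kcal/(mol K)` and a default temperature of 298 K. The constant and
temperature choices reproduce nanomolar affinities from end-point
free-energy estimates to within ~1%; because the exact constants used by
any particular MM-PBSA post-processing are rarely reported, the package
never hard-codes a "known" K_D from a ΔG — it always converts.

K_D read-off from a sampled isotherm finds the f = 0.5 crossing by linear
interpolation in (log₁₀ c, f), the coordinate system in which a Langmuir
curve is almost straight around half-occupancy; on a noiseless curve with
≥ 20 points per decade the read-off error is far below 1%.

## Interface layer

A probe conformation is collapsed to a point charge (its net charge, in
elementary charges) at the |charge|-weighted centroid height above the
substrate. In electrolyte the coupling of that charge to the transducer is
attenuated by `exp(−h/λ_D)`; in dry mode the attenuation is 1. This is a
deliberate reduction of the true three-dimensional double-layer problem: it
keeps the one feature the sensing mechanism depends on — that charge moved
beyond the Debye length stops contributing — while remaining analytic. The
package does not solve Poisson–Boltzmann, does not model pH-dependent oxide
site binding, and treats the electrolyte only through λ_D.

Buffer defaults: 1×PBS is taken as ionic strength 0.15 M and 0.01×PBS as
1.5 mM, with ε_r = 78.4 at 298 K. These standard values put λ_D at 0.78 nm
and 7.85 nm respectively, straddling the 3.4 nm binding height of the
aptamer case — the computable restatement of why low-ionic-strength or dry
read-out is required.

The effective sheet charge applied to the program gate is the
fraction-weighted, screened sum over both conformations,
`σ(f) = N·e·[f·q_b·S(h_b) + (1−f)·q_u·S(h_u)]`, affine in f by
construction. Charge is mapped to the program-gate footprint only, because
the probes sit on the PG sensing surface.

## Case-study fixtures

Two parameter sets emulate the package's target chemistries. They are
*fixtures*, not measurements:

* `aptamer_cea` — a 40-nt thiolated DNA aptamer against carcinoembryonic
  antigen. Unbound net charge −39 e (one bridging phosphate per
  internucleotide linkage of a 40-mer; the thiol linker neglected), centroid
  height 7.15 nm, elongating to 9.13 nm when bound; the target adds a
  default −2 e (CEA is only qualitatively "slightly negative" at
  physiological pH, so the magnitude is a parameter, not a constant).
  K_D = 1.47 nM. Default read-out condition: wet, 0.01×PBS — the condition
  under which the height change dominates the charge change and binding
  *suppresses* the coupled charge.
* `protease_inhibitor` — surface-tethered HIV-1 protease binding a
  cyclic-urea inhibitor, K_D = 0.31 nM (experimental). The charges
  (+4 e free, +6 e bound) and the 2.0 nm layer height are placeholders
  consistent only with the documented sign and ordering (the complex is
  positive and more positive than the free enzyme); no published net-charge
  numbers exist for the tethered layer, so these are config-exposed and
  never asserted against. Default read-out: dry.

What the fixtures do **not** emulate: per-atom charge distributions (a PQR
reader is provided for users who have them), orientation disorder, partial
screening inside the molecular layer, probe–probe interactions, and any
kinetic effect. A passing test suite therefore demonstrates the internal
consistency of the composition and the device physics, not agreement with
any laboratory measurement.

## Device layer

### Geometry and discretization

Front-view 2-D cross-section of a dual-gate, doping-free RFET in the
program-gate-at-drain layout: channel length 1000 nm, control and program
gates 440 nm each (CG abutting the source, PG abutting the drain, a 120 nm
ungated spacer between), silicon film 10 nm, gate stack modeled as 1 nm
equivalent SiO₂, device width 150 nm entering as a multiplier on current.
The film thickness and EOT are not independently documented for this
geometry ("ultra-thin" and "high-K metal gate" only), so both are config
parameters with those defaults. The 440 × 150 nm PG footprint gives the
66,000 nm² sensing area used by the interface layer.

Vertex-centered finite volumes on a tensor mesh over oxide + silicon.
The x-mesh adds a graded refinement (0.3 nm first cell, 14 points over the
first 40 nm) at both contacts regardless of the nominal node count, because
the tunneling window of the Schottky barriers lives in the first few nm;
with it, doubling the nominal mesh moves the ON current by well under 5%.
Defaults: 201 nominal x-nodes, 30 y-rows (≈ 1/8 oxide, 7/8 silicon).

### Transport model

Semi-classical drift-diffusion with Boltzmann statistics and quasi-Fermi
potentials; no generation/recombination (steady state, no optical or impact
processes). Continuity is discretized with Scharfetter–Gummel
exponential-fitted fluxes, assembled in **Slotboom variables**
(`w = n·e^{−ψ/V_T}`): each edge then carries a single symmetric weight
`g·B(|δ|)·e^{max(ψ_a,ψ_b)/V_T}` and the flux is proportional to `w_a − w_b`.
This matters numerically: in density variables the terminal current is a
small difference between equilibrium-balanced fluxes that can exceed it by
ten orders of magnitude; in Slotboom variables equilibrium is `w = const`
and the cancellation disappears from the formulation. The linear solves use
sparse LU followed by two steps of iterative refinement with the residual
accumulated in extended precision, which is what holds terminal-current
conservation below 10⁻³ (typically 10⁻⁴–10⁻⁶) at operating points with
meaningful current. Below roughly 0.1 pA the remaining float64
representability floor dominates and the reported current is physically
zero; the package treats 1 fA as the "zero current" floor in assertions.

Schottky contacts pin the potential through the electron barrier height
(defaults φ_Bn = φ_Bp = 0.56 eV, symmetric mid-gap, since the contact metal
is not specified anywhere; config-exposed) and impose Robin carrier
boundary conditions `F = v_R·Γ·(n_s − n_B)`: `v_R` is the Richardson
surface-recombination velocity for the barrier, and Γ ≥ 1 is a tunneling
enhancement factor computed each Gummel iteration, per silicon row and per
contact, from the current band profile — the Boltzmann-weighted WKB
transmission of the sub-barrier energy window, normalized so that pure
thermionic emission gives Γ = 1. The enhancement multiplies injection and
emission symmetrically, so detailed balance (zero flux at equilibrium) is
exact by construction. Γ is capped at 10¹² to keep the contact conductance
finite if a barrier becomes essentially transparent. The standalone
`tsu_esaki_flux` evaluates the full Tsu-Esaki integral (trapezoid on an
energy grid from the semiconductor band edge to 10 k_BT above the barrier
maximum, ≥ 200 points; WKB on the sampled profile with interpolated turning
points) and reduces to the Richardson closed form within a few tenths of a
percent for thick barriers.

The molecular sheet charge σ enters the discrete Poisson equation on the
oxide/silicon interface nodes under the PG footprint; electrostatically
this is equivalent to a gate-voltage shift σ/C_ox in the long-channel
limit, and a helper reports that shift. In the sensing pipeline the PG
electrode is held at 0 V and σ alone programs the drain junction (the
"virtual doping" picture): a metallic PG driven to ±5 V saturates the
junction and would swamp the sub-volt molecular signal, whereas at V_PG = 0
the drain barrier stays in its charge-sensitive regime. Superposing a PG
bias on top of σ is supported but not the default.

### Nonlinear solution

Gummel iteration: damped Newton on the nonlinear Poisson equation (update
clamp 0.5 V, tolerance 10⁻¹⁰ V), then the two linear continuity solves,
then quasi-Fermi update. Convergence requires the maximum quasi-Fermi
update below 10⁻⁵ V and relative drain-current stagnation below 10⁻⁴
(waived below 0.1 pA, where current stagnation measures cancellation noise);
hard cap 200 iterations, after which a convergence error carrying the
iteration trace is raised. Cold starts ramp all drives (gate biases, V_DS
and the σ-equivalent voltage) in ≤ 0.5 V increments from equilibrium;
sweeps and fraction scans reuse the previous solution (continuation).

The density-gradient quantum correction is a config toggle, default off,
implemented as a first-order lagged quantum potential
`−(ħ²/6m)·∇²√n/√n` (clipped at ±0.15 V, under-relaxed 0.3) added to the
carrier statistics. At a 10 nm body it shifts currents slightly without
changing any qualitative behavior, which is why the default is off and all
validation properties are stated for the classical model.

### Validation oracles

The solver is checked against independent closed forms rather than against
another simulator: the classical MOS depletion relation
`V_G − V_FB = ψ_s + sqrt(2qεN_Aψ_s)/C_ox` for a doped single-gate
reduction (uniform doping exists in `MaterialParams` for exactly this
purpose; the RFET itself is doping-free), the Richardson limit of the
Tsu-Esaki integral, mirror symmetry of the equilibrium potential, exact
ambipolar antisymmetry under a full sign flip with electron/hole-symmetric
parameters, and Scharfetter–Gummel's pure-diffusion limit.

## Response pipeline

`current_vs_fraction` evaluates I_D at the ON read-out point (|V_CG| = 5 V,
|V_DS| = 0.1 V) for each bound fraction; `calibration_curve` composes it
with the Langmuir map using monotone piecewise-cubic (PCHIP) interpolation
in f, exact at the grid points; ΔI/I₀ uses the c = 0 current as baseline,
decides suppression vs enhancement on |I| (the p branch carries negative
currents), and log-interpolates the half-response concentration.
`invert_response_for_kd` inverts the monotone device map with PCHIP and
fits K_D by least squares in log₁₀ K_D — a round-trip consistency check of
the whole pipeline, not an independent measurement.

Default problem sizes — 11-point fraction grids, 17 log-spaced
concentrations over 0.01–100 nM with c = 0 prepended, and the nominal
201×30 mesh — keep a full two-case study run in the minutes range on one
CPU while leaving interpolation error far below the 5% recovery tolerance.

## Known limitations

* Absolute currents are not calibrated to any fabricated device or to
  commercial TCAD (whose parameter calibrations are unpublished); the
  package's claims are the signs, monotonicities, symmetries and
  closed-form limits listed above. The reported maximum ΔI/I₀ values
  depend directly on the fixture charge magnitudes, which for both cases
  are only sign-constrained by available data.
* Boltzmann statistics without Fermi-Dirac degeneracy; densities in deep
  accumulation are overestimated.
* The 2-D cross-section cannot represent gate-all-around nanowire
  electrostatics; the width multiplier ignores corner effects.
* Screening uses a single exponential attenuation; ion crowding,
  Stern-layer effects and intra-layer permittivity are absent.
* No noise, drift, self-heating, AC response or limit-of-detection
  statistics.
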