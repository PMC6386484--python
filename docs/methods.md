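# Methods

This note documents the models inside `tenssim`, the parameter values and
the reasoning behind the numerical and design choices, in the spirit of a
model-description appendix. Units are SI internally; reports use mm, mV,
mA, ms.

## 1. Volume conductor

### Geometry and tissues

The finger is idealised as a cylinder of diameter 20 mm and length 84 mm
with a spherical fingertip cap, containing a concentric bone core
(diameter 5 mm, absent inside the tip cap) and a 0.9 mm skin shell; the
remaining pulp is treated as fat. Conductivities (S/m, dry skin):
sigma_skin = 0.0552, sigma_fat = 0.0417, sigma_bone = 0.0202. Capacitive
and dielectric tissue properties are neglected: conduction is quasi-static,
so the potential field scales linearly and instantaneously with the
electrode currents.

Coordinates: `x` runs from the fingertip along the axis, `z` is vertical
with the pad surface at `z = -R`; "depth" is vertical distance below the
pad surface on the midline.

### Electrodes and ground

Eight 1 mm x 8.5 mm electrodes lie on the pad with 2 mm centre-to-centre
pitch (1 mm gaps). The centre of electrode 1 sits 7 mm from the fingertip,
so the first two electrodes coincide with the 7 mm / 9 mm positions used in
the two-electrode validation; the offset is configurable. Each electrode
is a uniform-current-density Neumann patch over its footprint on the
voxelised pad surface (the current-density profile of a real contact is
not modelled). The fingernail is the return: a Dirichlet phi = 0 patch,
by default 10 mm long x 8 mm wide starting 2 mm from the tip on the dorsal
surface (the exact nail extent is configurable; balanced patterns make the
solution insensitive to it, since the net ground current is ~0).

### Discretisation and solver

The conduction equation `div(sigma grad phi) = 0` is discretised on a
regular structured grid with cell-centred finite volumes: a 7-point stencil
whose face conductances use the harmonic mean of the two adjacent cell
conductivities (exact for layered media at a face), Neumann boundaries on
the free surface, half-cell Dirichlet closure on the grounded nail faces.
The resolution must not exceed the 0.9 mm skin thickness (library default
0.3 mm; the experiment drivers and the acceptance computation run at
0.6 mm, where the potential along the study fibres agrees with a 0.4 mm
solve to ~1%).

One symmetric positive-definite system serves all electrodes; the default
solver factorises it once (sparse LU) and back-substitutes the eight
unit-current right-hand sides, which is deterministic and accurate to
machine precision. An ILU-preconditioned BiCGStab route (relative residual
1e-12, iteration cap 50 000) is available for grids too large to
factorise; the test suite checks the two routes agree. Every solve is
verified for discrete current conservation: the net flux through the
grounded nail must equal the injected 1 A.

Validation of the solver against closed forms: with uniform conductivity
and a small electrode, potential *differences* along the electrode axis
match the half-space point-source form `phi = I / (2 pi sigma r)` to
within 15% at depths well beyond the electrode size (differences are
compared because any finite test domain adds a constant return-path
offset that the infinite half space lacks).

### Fibre trajectories and sampling

Fibre node positions are interpolated trilinearly from the cell-centred
field (cells outside the tissue are filled with the nearest interior value
first, so near-surface nodes interpolate cleanly). The three study fibres:

* **N1** (Merkel-type): parallel to the skin at 1.5 mm depth; near the
  spherical tip the path follows the skin surface at constant depth.
* **N2** (Meissner-type): perpendicular from 1.0 to 1.5 mm depth directly
  under electrode 4, then parallel towards the CNS.
* **N3** (Pacinian-type): parallel at 2.0 mm depth.

Each spans 30 mm of arc length; the last node is the CNS-ward end.
Per-fibre sampling matrices `S` (node x electrode) are precomputed so a
pattern's profile is the single product `S I` — this is what makes
1000-pattern screens cheap after one field solve.

## 2. Nerve fibre membrane model

### Discretisation

Fibre diameter d = 4 um, node-of-Ranvier spacing 78.461 um, nodal (active)
length L = 1.061 um. Four consecutive nodes of Ranvier are lumped into one
model compartment: `dx_eff = 4 * 78.461 um`, N = floor(30 mm / dx_eff) + 1
= 96 compartments. The lumped compartment carries the membrane of all four
nodes (`L_memb = 4 L`), which keeps nodal membrane per unit fibre length —
and hence threshold behaviour — invariant under grouping; a switch
restores the single-node-membrane reading, which is simply a uniformly
4x-more-excitable fibre. The compartment capacitance charges the same
lumped nodal membrane (`C_m = 0.028 F/m^2 * pi d L_memb`). An exploratory
option charges the full segment length `dx_eff` instead, as an
unmyelinated-cable compartment model would; it is not the default because
the resulting fibre cannot sustain saltatory propagation (the axial
current cannot charge 74x more membrane between compartments), and it is
retained only to document that finding.

### Kinetics

The ionic current is Hodgkin-Huxley: `m^3 h` sodium activation/
inactivation, `n^4` potassium activation, ohmic leak. Rates follow the
human-fibre adaptation of the classical forms: each gate's alpha/beta
carries a per-gate acceleration factor folded into the A coefficient
(4.42 for m, 1.47 for h, 0.2 for n), a Q10 correction
(`Q10^{(T - T0)/10}`, T0 = 6.3 degC; Q10 = 2.23 for m, 1.5 for h and n)
and the factor 1000 that converts the classical mV/ms laws to SI. Three
algebraic forms occur (singular, exponential, logistic; see
`kinetics.py`). The published table of A-D coefficients lists the h- and
n-gate rows against each other's algebraic forms; the assignment used here
restores the classical correspondence, for three convergent reasons: the D
column only appears in (and is required by) the singular form; the
A column then yields uniform per-gate acceleration factors; and the
resulting steady state at rest reproduces the classical values
(m = 0.053, n = 0.318, h = 0.596), yielding propagating action potentials.
The singular form's removable singularity is evaluated by series expansion
within |u| < 1e-6.

Reversal potentials come from the Nernst equation on the reduced-potential
scale, `V_ion = (R T_K / F) ln([ion]_o/[ion]_i) - V_r`, with ratios 7.210
(Na), 0.036 (K) and 0.0367 (leak — fed through the same formula as the
real ions). The resting potential -79.4 mV is tabulated at 6.3 degC with
Q10 = 1.035 and is temperature-corrected by default (V_r(20 degC) =
-83.2 mV): with the correction the printed conductance/concentration set
is equilibrated at V = 0 to ~0.2 mV, without it the fibre drifts ~4 mV.
Conductances per area (S/m^2): g_Na = 6400 (Q10 1.02 @ 24 degC), g_K = 600
(1.16 @ 20), g_L = 575 (1.418 @ 24). Axoplasmic resistivity rho_i =
0.25 ohm m at 37 degC with inverse Q10 1/1.35 (0.417 ohm m at the 20 degC
operating point; a flag reproduces the uncorrected value).

### Integration

State `(V_i, m_i, n_i, h_i)` per compartment, interleaved for a banded
Jacobian (bandwidth 4). The system is stiff — membrane time constant
~56 us against a 30 ms horizon — and is integrated with LSODA
(variable-step, banded), relative tolerance 1e-6, absolute tolerances
1e-8 (V) and 1e-9 (gates); halving the tolerances moves AP arrival times
by < 2%. Integration is split at the pulse edges so the square-wave
discontinuities never cross a solver step. Output is sampled at 0.05 ms,
fine enough to resolve the AP upstroke for classification. Initial
condition: V = 0 with gates at their V = 0 steady state; the ~10 ms
pre-pulse rest segment is identical for every pattern and fibre and is
integrated once per environment and reused.

Two robustness guards: exponent arguments are clipped and all rates
saturate at 1e8 / s. Random +/-5 mA patterns can push the membrane to
+/- volts, far outside the empirical validity of the rate laws, where the
unclipped expressions overflow; saturation keeps the ODE system finite
and does not affect dynamics in the physiological range (all rates stay
far below the cap for |V| < 300 mV at 20 degC).

### Stimulus

Monophasic square pulse, onset 10 ms, width 0.45 ms, applied as the time
course of the extracellular profile. Horizon 30 ms (≥ 15 ms post-pulse)
so a spike initiated anywhere under the array reaches the 30 mm CNS-ward
end (conduction in this model is several m/s).

## 3. Patterns and screens

Random patterns draw eight i.i.d. currents uniform in (-5, 5) mA and are
rejected until |sum| <= 0.01 mA. The tolerance is not prescribed anywhere
authoritative; 0.01 mA was chosen once because the published
eight-electrode validation pattern sums to -0.008 mA, and it is
configurable. The sampler's bias towards low-magnitude patterns is an
emergent property of the acceptance region, not an extra shaping step. A
master seed spawns one independent substream per pattern
(`numpy.random.SeedSequence.spawn`), so pattern i is the same regardless
of how many patterns are drawn and screens are byte-reproducible.

Reduced-electrode variants for paired ablations: 3-active keeps electrodes
7-8 and balances them with electrode 6; 2-active keeps electrode 8 and
inverts it on electrode 7.

Fixture patterns (mA): two-electrode validation (+3, -3 on electrodes
1-2); eight-electrode validation (-0.43, -0.453, 0.36, 0.23, -0.024,
0.36, -0.047, -0.004); anodic (main electrode 4 sources 0.07, seven
returns of -0.01); cathodic (main sinks -0.21, seven returns of +0.03).

## 4. Classification

* **Activated**: the last-node (CNS-ward) membrane potential exceeds
  +40 mV above rest at any time. The threshold is not critical: full APs
  exceed 80 mV and subthreshold responses stay under 30 mV, so any choice
  in 20-60 mV gives the same decisions; 40 mV is the midpoint.
* **Run lengths**: longest runs of consecutive nodes with V above +0.5 mV
  (depolarised) or below -0.5 mV (hyperpolarised), measured on the
  snapshot 1 ms after pulse onset (the display time used throughout the
  experiment reports). The 0.5 mV floor suppresses numerically quiet
  nodes.
* **Mechanism of inhibition**: peak |V| anywhere below 5 mV is "no
  significant response" (the stimulus was simply too weak); otherwise the
  sign of the last electrode's current splits anodic inhibition (positive)
  from cathodic block (negative). Pair-level labels for a
  (shallow, deep) fibre pair combine which fibre activated with the silent
  fibre's mechanism; the labels partition all outcomes.
* **Validation sign checks**: the anode/cathode correspondence (cathodic
  current depolarises the membrane beneath it, anodic hyperpolarises) is
  asserted on the snapshot 50 us after pulse onset — about one membrane
  time constant, late enough for the linear field-to-membrane stage to be
  established and early enough that regenerative spikes (which cross the
  whole array within a fraction of a millisecond at these drive levels)
  have not yet overrun the pattern. The 1 ms snapshot is still computed
  and exported for display.

## 5. Problem sizes

The experiment drivers and the acceptance computation use a 0.6 mm grid
(118 100 unknowns; one LU factorisation plus eight back-substitutions,
~1 minute) and 200-pattern screens (400 cable integrations, ~4 minutes);
the test suite additionally uses a 0.9 mm grid for structural checks and
miniature geometries for solver property tests. Field values at the fibre
depths change by ~1% between 0.6 mm and 0.4 mm grids, well below the
other uncertainties in play.

## 6. Operating regime and known limitations

* **The model is highly sensitive at the printed parameter set.** The
  solved extracellular potentials at 1.5-2 mm depth are ~3 V per mA of
  electrode current, with node-to-node second differences of tens to
  hundreds of mV per mA; activation thresholds for the parallel fibres are
  accordingly ~0.1 mA. Typical balanced +/-5 mA random patterns are
  therefore one to two orders of magnitude above threshold: in a
  200-pattern screen *every* pattern activates both parallel fibres, the
  depolarised regions at 1 ms span most of the fibre (minimum run ~70
  nodes), and selective inhibition of the shallow fibre essentially never
  occurs. Cathodic block exists in the model (the test suite demonstrates
  it directly with a sustained hyperpolarising shelf), but with a 0.45 ms
  pulse the hyperpolarisation ends long before most travelling spikes
  reach the blocked stretch, so block-mediated selectivity is rare in
  screens. Experimental sensation thresholds for fingertip TENS are
  closer to ~1 mA; reconciling the model with that regime would require an
  extra attenuation in the field-to-fibre coupling (e.g. perineurial
  sheathing, electrode-skin interface impedance, or a lower effective skin
  conductivity) that the present tissue description does not contain.
  This was investigated systematically: the field solver is verified
  against the analytic half-space form and grid-converged, threshold
  ratios are invariant across the node-grouping interpretations, and the
  segment-capacitance variant that would slow the membrane down abolishes
  propagation instead.
* **Anodic recruitment of the perpendicular fibre is weak.** The vertical
  potential drop across N2's 0.5 mm perpendicular leg under a
  1 x 8.5 mm uniform-density electrode is ~0.3 V/mA, so the anodic shape
  needs ~0.45 mA at the main electrode to fire N2 — and the parallel
  fibre's threshold under the same shape is slightly lower, so the anodic
  preset (0.07 mA) excites neither fibre and anodic N2-selectivity does
  not occur at any amplitude. A much smaller (point-like) electrode
  contact would steepen the vertical gradient several-fold and restore
  anodic selectivity; with the printed electrode geometry it is absent.
* The two-layer dermis/epidermis split, capacitive effects, anisotropic
  conductivity, paranodal/internodal double-cable compartments and
  electrode shapes other than fixed rectangles are out of scope.
* The synthetic stimulation patterns emulate the randomised screening
  protocol (uniform, charge-balanced); they do not emulate
  amplitude-modulated or biphasic clinical waveforms, so passing screens
  say nothing about charge-balanced pulse trains.
* The voxelised surface staircases the curved pad; electrode patches are
  column-projected onto it. At 0.6 mm this perturbs effective electrode
  areas by up to ~20%, which is visible in per-electrode field amplitudes
  but not in any of the qualitative outcomes tested.
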