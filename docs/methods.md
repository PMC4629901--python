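# Methods

## Model

Tissue is described by the monodomain reaction–diffusion equation

    ∂V/∂t = ∇·(σ(x) ∇V) − I_ion(V, …)/C_m

with the ten Tusscher–Panfilov (2006) human ventricular epicardial model
supplying I_ion: twelve membrane currents (I_Na, I_K1, I_to, I_Kr, I_Ks,
I_CaL, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa), gating variables m, h, j,
d, f, f2, fCaSS, r, s, xr1, xr2, xs, and dynamic Na⁺/K⁺/Ca²⁺ handling
(cytosol, SR, dyadic subspace, RyR adaptation).  All constants sit in
`anisoblock/constants.py`, transcribed from the TP06 epicardial parameter
set; currents are in pA/pF so dV/dt = −I_ion directly.  Reversal potentials
are recomputed from the dynamic intracellular concentrations (every 0.1 ms
in the tissue kernel; the drift over that horizon is orders of magnitude
below any tolerance here).

The domain has two regions separated by a straight border at x_c.  Fibers
are parallel to the border on the left (so x-propagation is cross-fiber,
σ_x = σ⊥) and orthogonal on the right (σ_x = σ∥); σ∥ = 0.154 mm²/ms is
fixed and σ⊥ = σ∥/AR², so the anisotropy ratio AR equals the plane-wave
speed ratio v∥/v⊥.  Conductivities live on half-integer links; a link takes
the region of its midpoint, and a midpoint exactly on the border belongs to
the left region (the border lies on a half-node plane, one of the choices
the formulation leaves open; moving the ambiguous link to the right region
shifts no measured critical AR by more than the bisection tolerance — we
checked).

## Numerics

One unsplit explicit step advances everything: the flux-difference
diffusion term (Neumann, J = 0 at edges) and the reaction term are
evaluated at step k and V, together with the ionic concentrations, is
updated by forward Euler.  Gates use Rush–Larsen exponential relaxation
toward their voltage-dependent steady states, the standard stable choice
for TP06 at these step sizes; a pure forward-Euler gate mode exists in
`step_cell` for scheme-fidelity checks (at dt = 5 µs the two agree to the
sub-mV level).  Grid presets: (dt = 0.005 ms, h = 125 µm) for 1D,
(0.02 ms, 250 µm) for 2D, (0.0008 ms, 50 µm) for refinement checks.  A
guard rejects configurations violating dt ≤ 0.9·h²/(4σ_max).

For speed, every purely voltage-dependent factor (22 gate inf/decay pairs,
the voltage parts of I_CaL, I_NaCa, I_NaK, I_pK, and the I_K1
rectification factor as a function of V − E_K) is tabulated on a 0.01 mV
grid and linearly interpolated inside a numba kernel (~50 ns per
cell-step; interpolation error ~10⁻⁶ relative).  The kernel is validated
against an independent transcription of the equations integrated by scipy:
a stimulated action potential agrees to 0.003 mV RMS over 500 ms, and a
12 mm cable integrated by the method of lines (banded LSODA) gives the
same conduction velocity within 5%.

Stimulation is a one-step voltage reset to +50 mV in a region (6-node bar
at the cable end; disc for 2D point stimuli).  No current is injected and
nothing else is touched.

## Measurement conventions

* activation: upward crossing of −20 mV, 50 ms refractory debounce;
* probes: 10 mm on each side of the border — far enough that the
  electrotonic foot of the border delay does not contaminate them;
* single pulse conducts iff the distal probe activates within 500 ms of
  the stimulus; a paced beat iff the distal probe activates within one
  period of that beat's proximal activation (a beat whose proximal
  activation is missing counts as blocked);
* pacing trains: 7 stimuli, first 3 ignored, so a 1:2 pattern is seen
  twice among the analyzed beats; target periods below the 2.7 Hz period
  are approached by a decremental ramp, 370 ms shortening 5 ms per cycle;
* APD₉₀: from the −20 mV activation to recovery below
  V_rest + 0.1 (V_peak − V_rest), V_rest taken just before the stimulus;
  incomplete repolarization is a flagged missing value (NaN);
* border-crossing delay: distal-minus-proximal activation lag minus the
  reference transit 10 mm/v⊥ + 10 mm/v∥ with both speeds measured in
  uniform cables, so the delay isolates the border effect;
* critical AR: bisection on the conduction outcome, initial bracket
  verified at both ends, tolerance 0.01 (production) with 0.05 available
  for quick scans; critical periods are bracketed to 5 ms; critical
  frequencies found on a 0.1 Hz grid by bisection (block is monotone in
  rate over the studied regime);
* equilibration: 50 s quiescent integration per condition; converged if
  the largest relative state change over the final second is below
  10⁻⁴/ms.  The TP06 concentrations still drift ~10⁻⁵/ms after 50 s, so a
  much tighter tolerance would reject the protocol's own steady state;
  strong I_K1 suppression (≤ 10%) self-oscillates and is flagged, not
  rejected.

Each critical-AR/period/frequency search equilibrates *at the scanned
condition* and broadcasts that state.  This matters only for hyperkalemia,
where accommodation (resting depolarization plus slow j-gate inactivation,
τ_j ≈ 400 ms near −65 mV) is the dominant physics: tissue that has fully
accommodated to 12 mM potassium is far less excitable than tissue exposed
to it for less than a second, and the measured critical AR differs by
several units between those protocols.  We fix the fully-accommodated
convention because it is the physiologically interpretable steady state;
`run_tissue`/`run_reentry` accept an explicit `initial` state for anything
else.

## 2D reentry

Quoted tissue sizes are (along-border) × (across-border); the border runs
along the long ("vertical") axis, which is the direction the core drifts.
The default protocol: 3.2 cm across × 6.4 cm along, AR 2.0, [K⁺]ₒ = 10 mM,
two voltage-reset disc stimuli at the same site 6 mm into the transverse
side, 500 ms apart.  Two parameters the protocol leaves open are fixed
here: the disc radius is 3 mm (in fully accommodated 10 mM tissue a 1 mm
disc cannot source enough current to capture; 2 mm is the threshold), and
the stimulus sits at 1/4 of the along-border height, breaking the up/down
symmetry so that the single oblique penetration above the stimulus sets
the chirality whose drift is upward.  Both are config-exposed.

The second wave is blocked frontally at the border, penetrates obliquely
~1.5 cm above the stimulus, and curls into a single rotor (period ≈
300 ms) whose core drifts along the border toward the upper boundary,
where it annihilates after a few rotations — transient reentry.  Wave tips
are detected per frame as 2×2 cells crossed by both the V = −40 mV isoline
and the dV/dt isoline (taken at +0.1 mV/ms to reject quiescent-tissue
noise); because the raw tip oscillates about an elliptical core each
rotation and the detector also sees wavefront free-ends at the domain
edges, drift is quantified by `drift_profile`: the excited-area centroid
averaged over one rotation period, which isolates the slow core motion.

An isotropic region around the border is supported in three forms — a
full-height strip or a local patch, with coupling σ∥ (default), σ⊥, or
their geometric mean σ∥/AR — because the two-region tensor does not
prescribe what "isotropic" means there.  The intended use is core
pinning: a locally isotropic neighbourhood removes the along-border speed
asymmetry that drives the drift.  In our hands no tested strip/patch
configuration actually pins the core of this rotor: slow or
geometric-mean coupling removes the conductivity jump (no induction
block), a wide fast strip abolishes the induction site, and narrow fast
strips preserve induction but the core drifts past the isotropic region;
the corresponding acceptance check records this as a failure rather than
weakening the assertion.  The drift rate here (~12 mm per rotation) is
large relative to the isotropic regions tried, and pinning may require a
slower-drifting rotor than this protocol produces.

## What the synthetic fixtures do and do not show

The toy two-variable excitable kernel (cubic activator + linear recovery)
exists to exercise protocol machinery — activation detection,
classification, bisection drivers — in milliseconds.  It shares the
qualitative source–sink block mechanism at a coupling jump but none of the
TP06 physiology, so toy-based tests validate plumbing, not cardiac
conclusions.  The passive-diffusion case (Gaussian vs heat kernel, < 1% L2)
validates the diffusion stencil in isolation.  Tissue-level scientific
claims are tested only through full TP06 runs in the acceptance suite.

## Problem sizes and known limitations

The production cable is 64 mm (512 nodes) with the border at the midpoint:
long enough that the sealed ends do not reach the border inside the
decision window.  The acceptance 2D runs use 4.8 cm along-border domains
and 1.6–2 s post-stimulus windows — large enough for rotor formation,
drift-sign and confinement measurements; the printed-figure domains
(6.4/25.6 cm, multi-second windows) behave the same way but are several
times more expensive and add nothing to the assertions checked here.

Discrete-lattice effects slow cross-fiber propagation at the production
h = 125 µm by a few percent (v∥/v⊥ exceeds AR by ~7% at AR 2); the ratio
converges to AR as h → 0 and is verified within 3% at h = 40 µm.  Block
classification is verified unchanged at the refined (0.0008 ms, 50 µm)
grid.

Known limitations: monodomain only; straight border; epicardial cell type
only; the critical-AR values for strongly depressed tissue (25% G_K1,
[K⁺]ₒ ≥ 8 mM under full accommodation) sit below the published fitted
asymptotes, which extrapolate paced data rather than measure single-pulse
block directly — the package reports what its own bisections measure.
Paced critical-AR thresholds also depend on how many beats are analyzed
(a block-on-any-of-4-beats criterion finds block at a few percent lower AR
than a shorter train would), and the single-pulse critical AR itself is
grid-dependent: ~3.73 at the production 125 µm spacing but ~4.35 in the
refined-grid limit, so thresholds should be compared only at matched
resolution.
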