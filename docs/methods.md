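# Methods

This note documents the physical model behind `ionrad`, the choices made
where the design was genuinely open, and what the synthetic-data studies
do and do not demonstrate about real detector data.

## Ion–matter physics

Electronic stopping power is first-order Bethe–Bloch with the maximum
energy transfer approximated by 2mₑc²β²γ² and no shell or density-effect
corrections.  Over the 10–250 MeV/u window relevant here this
approximation reproduces an independently coded adaptive-quadrature
oracle to well under 2 %, and published proton range tables in water at
the per-mille level (150 MeV → 15.77 cm, 200 MeV → 25.95 cm).  Material
constants are hard-coded: water (ρ=1.0 g/cm³, I=75 eV), PMMA (1.19,
74 eV), silicon (2.33, 173 eV), air (1.205×10⁻³, 85.7 eV), with standard
Z/A and radiation lengths.  CSDA range tables are cumulative-trapezoid
integrals on a 4096-point log grid from the 0.5 MeV/u cutoff (the
neglected sub-cutoff residual range is below 10 µm in solids) and are
cached per ion/material pair; `energy_after` inverts them.

Multiple Coulomb scattering uses the Highland parameterization with the
total projectile momentum, so helium at the same energy per nucleon
scatters half as much as a proton.  Because the formula's logarithmic
term is not additive over sub-slabs, stepwise transport evaluates it once
for the *total* material path of the run (a Lynch–Dahl-style correction);
the fine-step composition oracle in the tests uses the same convention
and agrees with the sampled exit-position variance within 10 %.
Energy-loss straggling is Gaussian with Bohr's variance
σ² = 0.1569 z² (Z/A) ρx MeV².  Fragmentation is modelled as a single
depth-uniform conversion helium→hydrogen at unchanged energy per nucleon
(the dominant light-fragment channel as seen by the detector), with an
extra angular kick of 3× the Highland angle of the remaining path;
its default probability of 0.13 per phantom traversal reproduces the
observed ~12–13 % loss of usable events to hydrogen rejection.  Nuclear
attenuation of the fluence, Landau tails and δ-ray transport are out of
scope.

## Bench geometry and the Bragg-flank operating point

The default bench: front tracker at z = −100/−90 mm, 161 mm PMMA phantom
centred at z = 0 (faces ±80.5 mm), energy layer at +95 mm (< 4 cm behind
the phantom), rear tracker at +105/+115 mm; all five sensors are 300 µm
silicon, 256×256 pixels of 55 µm.  Each layer's non-sensor material
(thinned readout chip, bump bonds) is budgeted as 0.45 mm water so the
full layer is ≈1 mm WET, the value quoted for thinned assemblies.  With
the 168.3 MeV/u beam this places the mean residual energy at the energy
layer near 22 MeV/u and the mean deposition in 300 µm silicon at
≈5.3 MeV — on the steep rising flank, inside the 5.1 ± 0.6 MeV window of
the physical bench, and sensitive to ≈0.36 MeV per millimetre of WET
change.  The deposition is computed by integrating the slowing-down
within the layer (not S·Δx), so it remains exact where the flank is
steep.

## Detector response model

The charge cloud of one ion impact is an isotropic 2-D Gaussian whose
width grows with deposited energy and shrinks with bias voltage,
σ = σ₀(V) + 0.012 mm·√(E/MeV) with σ₀ = 25 µm at 10 V and 15 µm at 40 V
(higher bias ⇒ faster collection ⇒ smaller clusters).  The constants were
chosen once so that helium clusters span ~15–25 pixels and hydrogen
fragments ~8–12 at the 4 keV threshold, with no single pixel of a clean
helium cluster above the ~1 MeV overshoot limit.  Pixel signals get 1 %
multiplicative electronics noise, pass the threshold, and are digitized
through a per-pixel response `counts = a·E + b − c/(E−t)` (the standard
linear-plus-hook surrogate; identity by default) with saturation at
11 810 counts.

Two bias-voltage regimes are modelled.  At 40 V (full depletion) the
response is linear to 2 MeV and then saturates, pinned to a >20 % deficit
at 5 MeV.  At 10 V (partial depletion, the imaging configuration) the
response is mildly sublinear, measured = (0.60 − 0.004·E)·E; the analysis
inverts it with a monotone PCHIP recalibration curve built from a
(measured, true) scan — binned medians with anchored domain ends, fitted
twice ("iterate once") — which recovers true depositions within 7 % over
0.2–17 MeV.

Artifacts are injected at configurable rates with per-primary ground
truth: 1–2-pixel photon/electron background (8/frame/layer), overshoot
distortion of clusters carrying a >1 MeV pixel (probability 0.05; tick
scatter in time mode, 2.5–4× count inflation in energy mode), temporal
cropping of energy-mode signals arriving within 65 µs of either frame
boundary (⇒ ~13 % of events, matching the observed loss to the cropping
cut; the digitization time itself is 260 ± 40 µs), and forced two-ion
merged clusters injected ≥3 pixels apart so they always carry two local
maxima.  Natural pile-up additionally occurs through frame merging at the
default 30 ions per 1 ms frame (occupancy stays below 1 %).

## Processing-chain design choices

* Cluster finding is 8-connected (round helium clusters must not shed
  corner pixels); local maxima are counted with strict-dominance plateau
  merging so flat-topped single-ion clusters are not mistaken for
  pile-up.  Centroids are value-weighted in energy mode and unweighted in
  time mode (time-mode pixel values are arrival ticks, not signal).
* Cleaning cuts: overlap = ≥2 local maxima; overshoot = tick spread >1
  tick (time) or any calibrated pixel >1 MeV (energy); background =
  ≤2 pixels and <0.3 MeV.  The cropping cut uses the arrival time the
  energy cluster inherits from its matched tracker cluster; its guard is
  100 µs per frame boundary — wide enough to cover the simulated 65 µs
  cropping window with margin while keeping the event loss near the
  ~20 % level rather than rejecting most of the frame.
* Alignment: per layer, the beam position of a phantom-free narrow-beam
  run (4.9 mm FWHM, 220.5 MeV/u, low rate) is the robust mean of
  ion-cluster centroids; offsets are differences to the energy layer.
  Because every layer sees essentially the same ions, beam-profile
  sampling noise is common mode and cancels; recovery is accurate to
  ~10 µm at 10⁴ ions, well below the half-pixel (27.5 µm) requirement.
  The alignment run uses 10 ions/frame: pile-up clusters drop out of
  different layers differently and would re-introduce beam noise.
* Tracking and matching are arrival-time driven (window: 1 tick =
  100 ns) with nearest-position tie-breaks; residual exact ties drop both
  candidates — purity over efficiency, since an image bias is worse than
  a dose inefficiency.  The rear segment extrapolated to the energy layer
  claims the nearest clean energy cluster within 220 µm (4 pixels).
* Species identification is a linear boundary in (cluster volume MeV,
  cluster size); the shipped default (volume > 2.7 MeV ⇒ helium) sits
  midway between the helium (~5.3 MeV) and hydrogen (~1.3 MeV)
  depositions; a retrainable linear discriminant (`fit_species_boundary`)
  reaches the same ≥95 % accuracy on labelled synthetic data.
* Image formation assigns each accepted event wholly to the 220 µm bin
  containing its connection-line crossing of the mid-phantom plane (no
  splatting — sub-bin interpolation would correlate neighbouring-bin
  noise).  Bins with zero counts stay undefined and are excluded from all
  metrics.  On the rising flank more WET means *higher* deposition, so
  the bulk side of the step images brighter in mean energy than the
  air-step side.
* CNR uses the symmetric pooled form |μ₁−μ₂|/√((σ₁²+σ₂²)/2) over per-bin
  mean energies in two 4.4 × 4.4 mm² ROIs centred ±3 mm from the edge.
  The definition is a package convention; only ratios between processing
  stages are meaningful, and all stage claims use it consistently.
* Spatial resolution: event distances to the step edge pooled along the
  edge into 22 µm bins (1/10 image pixel) give the oversampled ESF; the
  LSF is a 5-point Savitzky–Golay derivative and the MTF its normalized
  |DFT|.  On noisy event data the numeric MTF tail is dominated by the
  white per-bin noise floor, so the summary statistic for simulated runs
  is the error-function fit of the ESF (weighted by per-bin counts, with
  a robust loss), reported as f₁₀ = 0.3415/σ under the Gaussian-LSF
  identity; the numeric route is validated against the closed form on
  constructed Gaussian edges (within 5 %).

## Synthetic studies: sizes and scope

The stage-wise study (raw → artifact cleaning → hydrogen rejection →
tracking-based mid-plane positioning) runs on a uniform 12 × 6 mm field
at the fluence that deposits 450 µGy mean dose in the phantom
(≈9.5×10⁴ ions/cm², ≈68 000 primaries); CNR rises monotonically by a
factor ≳2.5 in total and the 1 mm step is visible (CNR ≥ 2) in the final
image.  The helium/proton comparison uses dose-matched runs (equal µGy,
hence ~4× more protons, 100 µGy each) of the same phantom with
range-matched beams (168.3 MeV/u for both, A/z² = 1).  Because binned
edge fits are statistically noisy at these event counts, the comparison
measures the mid-plane blur directly against the simulation truth
(reconstructed minus true crossing, per matched event): helium
0.49 mm vs proton 0.85 mm, i.e. helium resolves ≥1.3× finer
(f₁₀ ≈ 0.70 vs 0.40 lp/mm under the Gaussian identity) — the
scattering-limited regime the bench is designed around.  The truth-level
connection-line error alone is 0.50 mm (He) vs 1.00 mm (p); the 220 µm
energy-association radius preferentially rejects large-angle-scattered
protons, which is why the measured ratio sits below the pure Highland
factor of 2.  These sizes are an accuracy/runtime compromise
chosen for routine regression runs; the statistics scale in the obvious
way with `n_ions_total`.

What the synthetic studies do **not** show: the simulator's artifact
rates, response constants and fragmentation model are plausible
parameterizations, not fits to a specific chip, so absolute CNR/SR values
carry the model's assumptions (no Landau tails, no δ-ray escape, no
detector aging, no beam-line phase space).  Stage *ratios*, recovery
accuracies and scaling behaviours are the meaningful outputs; agreement
of absolute numbers with any physical bench should be read as order-of-
magnitude consistency only.

## Numerical edge cases

Zero-deposition impacts and sub-threshold clouds produce no cluster;
ions stopping inside the phantom leave no downstream signal and are
flagged in the truth table.  Cluster volumes above the recalibration
domain are clamped with a warning.  Degenerate ESFs (zero net step) and
empty ROIs raise instead of returning NaN.  All randomness flows from a
single `numpy` generator seeded per run; identical seeds give
byte-identical frame files.
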