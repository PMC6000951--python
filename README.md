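# ionrad — single-ion helium radiography on a pixel-detector stack

`ionrad` is a desk-scale model and analysis toolkit for energy-loss
radiography with therapeutic helium ion beams, the imaging modality that
measures, ion by ion, the energy deposited in a thin silicon layer placed
on the rising flank of the Bragg curve behind the patient (here: a
phantom).  Because the flank is steep, a millimetre-scale change in the
water-equivalent thickness (WET) of the traversed object shifts the
deposited energy measurably — the contrast mechanism that makes a 1 mm air
gap in a 161 mm PMMA block visible at diagnostic dose levels.

The package is aimed at medical-physics researchers prototyping
ion-imaging processing chains.  It contains two halves that share one
physics core:

* **a simulator** of a five-layer Timepix-like detector bench — two
  front-tracker and two rear-tracker layers in arrival-time mode, one
  energy-mode layer at the isocenter — that transports single ions
  (CSDA energy loss + Bohr straggling + Highland multiple Coulomb
  scattering + single-point helium→hydrogen fragmentation) and emits
  sparse pixel frames with realistic cluster signals and the artifact
  classes seen in practice (photon/electron background, readout-overshoot
  clusters, temporally cropped digitization, overlapping ions), plus a
  per-primary ground-truth table;
* **the processing chain** that turns raw frames into quantitative
  radiographs: cluster finding and descriptors, per-pixel energy
  calibration and partial-depletion recalibration, cleaning cuts, beam
  centroid detector alignment, arrival-time track matching, energy-cluster
  association (within 4 pixels = 220 µm), helium/hydrogen identification
  in the (cluster volume, cluster size) plane, connection-line mid-plane
  image formation, and CNR / oversampled-edge MTF quality metrics.

## The model in brief

Stopping power is first-order Bethe–Bloch,

    S/ρ = K (Z/A) z²/β² [ln(2 mₑc²β²γ²/I) − β²],

integrated to CSDA range tables; WET = thickness × RSP with RSP the
stopping-power ratio to water at the mid-phantom energy.  Scattering
follows Highland, θ₀ = 13.6 MeV/(βcp)·z·√(x/X₀)[1 + 0.038 ln(x/X₀)], with
the logarithmic factor evaluated on the total path so stepwise transport
composes consistently.  Image quality is quantified by

    CNR = |μ_step − μ_ref| / √((σ²_step + σ²_ref)/2)

over per-bin mean deposited energy in two regions of interest flanking the
step edge, and by the spatial frequency at 10 % modulation (MTF₁₀%, lp/mm)
of the oversampled edge spread function.

## Worked example

Simulate a short acquisition of the default bench (168.3 MeV/u helium,
161 mm PMMA phantom with a 1 mm air step at mid-depth) and image it:

```python
import numpy as np
from ionrad.config import RunConfig
from ionrad.simulate import simulate_run, energy_response
from ionrad.clusters import RecalibrationCurve
from ionrad.events import build_events
from ionrad.imaging import image_from_events
from ionrad.quality import cnr, default_rois

cfg = RunConfig()
res = simulate_run(cfg, seed=7, n_ions_total=20_000)

true = np.linspace(0.05, 18, 256)                 # invert the 10 V response
recal = RecalibrationCurve([energy_response(t, 10.0) for t in true], true)

events, report = build_events(res.frames, cfg, recalibration=recal)
img = image_from_events(events, cfg.phantom, cfg.plane)
step, ref = default_rois(cfg.phantom.step_edge_x_mm)
print(f"accepted {report['n_accepted']} of {len(res.truth)} primaries")
bulk = img.roi_values("mean_energy", -5, -1, -2, 2)
step_side = img.roi_values("mean_energy", 1, 5, -2, 2)
print(f"bulk-side mean deposition  {bulk.mean():.2f} MeV")
print(f"step-side mean deposition  {step_side.mean():.2f} MeV")
print(f"CNR = {cnr(img, step, ref):.2f}")
```

prints (seed 7):

```
accepted 5919 of 20000 primaries
bulk-side mean deposition  5.32 MeV
step-side mean deposition  4.86 MeV
CNR = 1.44
```

The bulk (thicker) side deposits ~0.4 MeV more than the air-step side —
more WET upstream puts the ion deeper on the rising Bragg flank — and the
1 mm step becomes clearly visible (CNR ≥ 2) once the fluence reaches the
~450 µGy diagnostic dose level.  The same pipeline can be driven from the
shell through the `ionrad` CLI (`ionrad simulate`, `ionrad clusters`,
`ionrad events`, `ionrad image`, `ionrad qa`).

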