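# ctquant

Quantification stack for microneurography studies of **C-tactile (CT)
afferents and hair-follicle coupling** in human hairy skin. CT afferents are
unmyelinated low-threshold mechanoreceptors (conduction velocity < 2 m/s,
mechanical threshold ≤ 4 mN) that respond vigorously to gentle stroking and
to deflection of single hairs. Asking whether a hair-deflection response is
mediated by the follicle itself — rather than by incidental skin deformation —
requires four quantitative instruments, all implemented here:

1. **Spike-train quantification** (`ctquant.spikes`): threshold-crossing
   detection with template-matching confirmation; spike count, mean and peak
   instantaneous frequency (IF); fibre classification by spike polarity and
   conduction velocity; Semmes-Weinstein monofilament thresholds by the
   50%-of-occasions staircase; after-discharge duration after hair plucking
   by an inter-spike gap rule.
2. **OCT micro-displacement** (`ctquant.octdisp`): skin-surface tracking in
   M-mode (single A-line over time, 10 kHz) recordings, stimulus-event
   detection, windowed displacement estimators (200 ms pre/post windows;
   500 ms consecutive windows at rest), artefact-trial rejection, top-10
   selection per condition and Tukey HSD condition comparison.
3. **Dense optical flow** (`ctquant.flow`): the polynomial-expansion
   (Farnebäck) method — quadratic local models `f(u) ≈ uᵀAu + bᵀu + c`
   solved coarse-to-fine with the study parameters (pyr_scale 0.6, 4 levels,
   winsize 7, 8 iterations, poly_n 5, poly_sigma 1.5) — plus Eulerian
   cumulative displacement fields in calibrated units (465 px/cm).
4. **Instrument-tip tracking** (`ctquant.tiptrack`): intensity segmentation
   of the dark forceps/hook, contour simplification, tip location as the
   highest-curvature contour point under a temporal-consistency radius, and
   Gaussian-smoothed tip speed (σ = 5 frames) in cm/s.

Because no recordings are distributed, every stage is driven by the
**synthetic generators** in `ctquant.synth` — stimulus-locked gamma-renewal
spike trains with fibre-specific waveforms, OCT M-mode stacks with known
surface trajectories and injected artefacts, and tip videos with known
trajectories — so each estimator is tested against exact or statistical
ground truth. `ctquant.pipeline` orchestrates both study arms end to end.

## Worked example

```bash
python examples/oct_displacement_demo.py
```

```
condition       true µm  estimated µm
idle               2.04        2.0400
hair_release       8.14        8.1400
mono_0.4          17.09       17.0900
mono_0.7          25.28       25.2800
mono_4.0          60.93       60.9300
mono_6.0          79.18       79.1800
```

Each row is a noiseless synthetic M-mode trial whose surface step equals the
calibrated condition mean; the windowed estimator recovers it to better than
0.01 µm. The scientific reading: releasing a maximally bent hair shifts the
skin surface ~8 µm — far below the 17 µm caused by the weakest (0.4 mN)
monofilament a CT would detect — so CT firing during hair deflection is not
explained by skin deformation. `examples/` contains one such narrative
script per capability (spike metrics, after-discharge, optical flow, tip
tracking, and the full two-arm study); `ctquant microneuro|oct` exposes the
two pipelines as shell commands.

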