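# dualswift

Simulator and analysis pipeline for **dual-field-of-view zero-TE MB-SWIFT
fMRI** of the brain and spinal cord.

Zero-TE radial sequences such as MB-SWIFT read out each excitation from
the center of k-space outward while the gradients stay on, making the
images nearly immune to susceptibility-induced field inhomogeneity. By
alternating excitations between two RF coils — one repetition-time pair
(1.94 ms) covers one spoke per field of view at the same gradient
orientation — a single scan samples two distant organs (rat brain and
lumbar cord, 40 mm FOVs, 64³ matrix, 625 µm isotropic) virtually
simultaneously at a 3 s volume rate (1547 spokes per volume). `dualswift`
implements that acquisition geometry, a dual-organ digital phantom with a
block stimulation paradigm, the k-space forward model, the iterative
reconstruction, and the complete functional-statistics chain, so the whole
experiment can be exercised end to end on a desk.

The pipeline stages:

- **sequence** — timing arithmetic and the interleaved spherical-spiral
  spoke schedule;
- **phantom** — ellipsoidal head and cylindrical cord with activation
  ROIs; block paradigm 60 s + 6 × (24 s on + 90 s off); responses as
  boxcar ⊗ gamma-variate IRF (delay 2.8 s, variation 1.4 s) with per-FOV
  peak fractional change (0.5% brain, 1% cord) and latency;
- **acquisition** — center-out radial Fourier sampling (exact NUDFT and
  Kaiser–Bessel gridding operators), complex k-space noise, motion frozen
  per volume;
- **recon** — RF-pulse deconvolution, spoke-end apodization,
  density-compensated gridding, monotone FISTA (13 iterations,
  non-negativity prox);
- **preprocess** — center-of-mass motion estimation, translation-only
  registration, spatial-ICA motion-component regression (|r| > 0.75 or
  >70% edge voxels), 0.01 Hz DCT high-pass, AR(1) prewhitening;
- **stats** — voxelwise GLM with t→z maps, z > 3.1 cluster tables, TFCE
  (E = 0.5, H = 2), exhaustive sign-flip permutation group inference with
  FWE control at p < 0.05, percent-signal-change time courses and peak
  latencies.

## Worked example

```python
from dualswift.config import scaled_config
from dualswift.pipeline import run_subject

cfg = scaled_config(seed=1)       # 32³ desk-scale study conditions
res = run_subject(cfg, 1)         # simulate → acquire → recon → preprocess → GLM

for f, name in enumerate(("brain", "cord")):
    tc = res["fov"][f]["timecourse"]
    print(name, round(tc["peak_value"], 3), "% peak,",
          tc["peak_latency"], "s to peak")
print(res["fov"][0]["clusters"].head(2).to_string(index=False))
```

prints (seed 1):

```
brain 0.573 % peak, 6.0 s to peak
cord 0.913 % peak, 15.0 s to peak
 cluster  n_voxels   peak_z   mean_z  centroid_x  centroid_y  centroid_z
       5        38 7.785046 4.635181    9.815789   21.315789   19.342105
      10        37 6.608504 4.375880   15.351351   19.432432    7.432432
```

The injected 0.5%/1.0% peak signal changes come back as 0.57%/0.91%
(the cord shortfall is partial-volume dilution at 32³), the cord response
lags the brain's by the injected 9 s, and the two largest brain clusters
are the lateralised cortical ROI (first row, 38 voxels, mean z 4.6 —
inside the range reported for this preparation in vivo) and the midline
cerebellar ROI.

A command-line interface mirrors the stages
(`dualswift simulate|acquire|reconstruct|preprocess|glm|group|timecourse|run`,
each with `--seed`, `--config`, `--out`); `dualswift run` executes the
whole experiment from a YAML configuration and writes NIfTI images, CSV
tables and a JSON manifest.

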