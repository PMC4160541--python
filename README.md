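# spiralcine

Single-breathhold 3-D cine cardiac MRI with **through-time spiral GRAPPA**:
a tested library + CLI for simulating, reconstructing and analysing a
six-fold angularly undersampled 3-D stack-of-spirals bSSFP acquisition of
the beating left ventricle.

## The problem

Standard left-ventricular (LV) functional CMR acquires one short-axis slice
per breathhold with a segmented 2-D bSSFP sequence; full ventricular
coverage needs many breathholds, which fatigues patients and lets the
diaphragm (and with it the heart) shift between slices. A 3-D
stack-of-spirals acquisition can encode the whole ventricle in a *single*
breathhold — if the in-plane spiral is undersampled six-fold — and a short
free-breathing, fully-sampled calibration scan lets a non-Cartesian GRAPPA
reconstruction restore the missing data.

## The method

* **Trajectory.** A variable-density spiral: 4 arms satisfy Nyquist over the
  central 8×8 region of k-space, 48 rotated arms cover a 128² matrix at FOV
  316 mm out to k_max = matrix/(2·FOV). Per partition-encoding step and
  cardiac phase only every 6th arm is acquired (R = 6), giving a temporal
  footprint of 8 × TR = 35 ms at TR 4.4 ms.
* **Through-time calibration.** The fully-sampled calibration scan repeats
  the trajectory 10 times under free breathing (≈ 34 s). For each missing
  sample, the exact local source/target constellation is extracted from
  every repetition, every partition, and the 8 neighbouring readout points
  of its trajectory segment (1×8 segmentation) — e.g. 10 × 16 × 8 = 1280
  equations for the (channels × 2 arms × 3 readout points) kernel weights,
  solved by least squares:  min‖S·w − t‖².
* **Reconstruction.** Weights are re-used at identical spiral locations in
  every partition and timeframe; filled k-space is density-compensated,
  gridded per partition by an adjoint NUFFT, inverse-FFT'd along the
  partition direction (slab oversampling discarded), and coil-combined with
  a Walsh-type adaptive matched filter.
* **Analysis.** Blood-pool volumes per phase by Simpson voxel summation give
  EDV, ESV, SV, EF = 100·(EDV−ESV)/EDV and EDM; method agreement uses
  Bland-Altman bias ± 1.96·SD limits, Welch's t-test and the Wilcoxon
  signed-rank test (exact for n ≤ 25).

Because no raw volunteer data exists to ship, the package includes a
first-class dynamic phantom — a half-ellipsoid LV shell with closed-form
blood/myocardial volumes (so EF has an exact ground truth), smooth complex
coil maps, and an exact non-uniform-DFT forward model with free-breathing
calibration motion and complex Gaussian noise.

## Worked example

Protocol arithmetic for the full-scale sequence:

```sh
$ spiralcine protocol-report
{
  ...
  "derived": {
    "acceleration_factor": 6,
    "temporal_footprint_ms": 35,
    "in_plane_resolution_mm": 2.47,
    "encoded_partitions": 16,
    "calibration_duration_s": 34,
    "calibration_arm_separation_ms": 26,
    "bssfp_band_spacing_hz": 227
  }
}
```

End-to-end desk-scale pipeline (simulate → calibrate → reconstruct →
analyse; 64² matrix, 24 arms with 4 acquired, 8 coils, ~1 min):

```sh
$ spiralcine run --seed 1 --out demo/
{
  "measured": {
    "edv_ml": 48.384,
    "esv_ml": 18.688,
    "sv_ml": 29.696,
    "ef_pct": 61.37566137566138,
    "ed_phase": 0,
    "es_phase": 4
  },
  "ground_truth": {
    "edv_ml": 52.35987755982988,
    "esv_ml": 19.373154697137057,
    "ef_pct": 63.00000000000001,
    ...
  },
  "ef_error_pct": 1.6243386243386269
}
```

The phantom beats from a 52.4 mL end-diastolic blood pool (phase 0) to
19.4 mL at end-systole (phase 4), a ground-truth EF of 63.0 %; the R = 6
through-time spiral GRAPPA reconstruction followed by threshold volumetry
recovers 61.4 % — within 2 percentage points despite six-fold
undersampling. `demo/` receives the raw k-space container (HDF5), the
GRAPPA weights (HDF5), the reconstructed 4-D magnitude series (NIfTI), the
analysis report (JSON) and a timing log.

The library surface mirrors a statsmodels fit:

```python
from spiralcine import ThroughTimeGrappa, KernelSpec
model = ThroughTimeGrappa(calibration, pattern, KernelSpec(n_channels=8))
weights = model.fit()          # least-squares calibration
print(weights.summary())       # kernel, block, residual diagnostics
filled = weights.apply(dynamic)  # fill the missing arms
```

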