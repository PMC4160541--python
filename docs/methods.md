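# Methods

This note documents the models, numerical choices and limitations behind
`spiralcine`: what is simulated, how the reconstruction is calibrated and
applied, and what the passing tests do and do not demonstrate about real
data.

## Acquisition model

The sequence modelled is an ECG-gated 3-D stack-of-spirals bSSFP cine:
in-plane spiral readouts, Fourier (partition) encoding along the slab, one
partition-encoding step per heartbeat during a single breathhold. Only
every R-th spiral interleaf is acquired per partition and cardiac phase
(R = 6 by default). A separate ungated, free-breathing scan acquires the
full interleaf set `calibration_repetitions` times (default 10) as
calibration data. Protocol records (`protocol.SequenceProtocol`,
`protocol.Protocol2D`) validate on construction; derived quantities
(temporal footprint, resolution, calibration duration, 1/TR banding
interval, encoded partition count) are always computed, never stored, and
rounded half-up to the precision at which such values are conventionally
printed. The encoded partition count rounds the oversampled slab up to the
next even integer so the partition FFT stays symmetric; this reproduces 16
encoded partitions for 12 nominal + 33 % oversampling.

## Trajectory

The spiral is designed analytically in k-space (no gradient/slew
synthesis): the radial pitch dr/dθ = N_eff(r)/(2π·FOV) with N_eff ramping
smoothly (cosine taper) from `center_arms` (4) inside the dense centre to
`arms_total` (48) beyond twice the centre radius. This guarantees ≤ 1/FOV
radial gaps for the full arm set everywhere and for the 4-arm subset within
the central 8×8 region — which is why the R = 6 dynamic scan (8 acquired
arms ≥ 4) retains a fully sampled k-space centre. Samples are laid down at
constant arc-length spacing 1/(FOV × 1.25); with a 5 µs dwell the
full-scale arm reaches the designed k-space edge at 1.85 ms (within the
published ~1.7 ms regime, readout ≤ 2.5 ms). A straight tail back to the
origin stands in for the moment-rewinding gradients; truncation at the
first sample with |k| ≥ k_max discards it before reconstruction.

Density compensation uses radial binning: samples are binned by |k| in
annuli of width 0.5/FOV and share the annulus area equally. This handles
the azimuthally oversampled centre (all arms pass through k = 0) by weight
sharing, reproduces the |k|-proportional profile of a constant-angular-rate
spiral (validated against a Voronoi-cell-area oracle), and sums to the
sampled disc area π·k_max², which keeps the adjoint reconstruction on the
object's intensity scale.

## Phantom

The left ventricle is a half-ellipsoid shell (base plane to apex): blood
pool inside the endocardial half-ellipsoid, incompressible myocardium
between endo- and epicardial surfaces (the wall thickens in systole).
Volumes are closed-form, (2/3)π·a·b·c, so EDV/ESV/EF/EDM have exact ground
truths; the default motion scales the endocardial semi-axes so that
V_ES/V_ED = 0.37, i.e. EF = 63.0 %, a healthy-volunteer mean. Defaults
(desk scale): 256 mm FOV, 64² matrix, 8 nominal + 2 oversampled partitions
of 8 mm, 8 coils, 8 cardiac phases, endocardial ED semi-axes
(25, 25, 40) mm with a 9 mm ED wall, blood/myocardium/background
intensities 1.0/0.35/0.15, plus two static abdominal blobs for calibration
diversity. Rasterization supersamples 3× per axis and averages, giving
partial-volume edges; voxel counting at the blood–myocardium midpoint
agrees with the closed form to < 1 %.

Coil maps are Gaussian magnitude lobes on a ring around the torso with
alternating slab offsets and per-channel linear phase ramps (plus a 0.3
floor so the map never vanishes); deterministic given a seed. Respiration
in the calibration scan is a rigid per-repetition translation (default
amplitude 10 mm, mostly head–foot/anterior–posterior) and each repetition
is assigned a uniformly random cardiac phase — the minimal model of
ungated free-breathing calibration. The forward model is exact: coil
weighting, orthonormal FFT along the slab, then a dense non-uniform DFT of
each kz-plane at the truncated spiral sample locations, plus complex
Gaussian noise. Using the exact transform for simulation (and a gridding
NUFFT only for reconstruction) avoids testing the reconstruction against
its own approximation.

`REALISTIC_NOISE_SD = 5.5` defines the "noisy" study condition: it is the
k-space noise level measured (from difference images of two noise
realizations of the fully sampled reconstruction) to give a blood-pool SNR
of 40, representative of 3 T bSSFP cine at this configuration's large
(4×4×8 mm) voxels.

What the phantom does **not** model: realistic torso anatomy, bSSFP
signal evolution and banding (the banding interval is reported
analytically as 1/TR instead), in-flow enhancement, papillary muscles,
arrhythmia, and non-rigid respiratory motion. Passing tests therefore show
that the calibration/reconstruction machinery is correct and noise-robust
under smooth coil maps and rigid motion — not that image quality claims
transfer to patients.

## Through-time spiral GRAPPA

Each missing sample is synthesized from the two acquired arms flanking it
(source readout offsets −1, 0, +1 per arm, all channels): with 8 channels
that is 8×2×3 = 48 unknowns per target channel (32×2×3 = 192 at full
scale). Because the kernel geometry varies along the spiral, the readout
is segmented (1 arm-gap × 8 readout points); within a segment the
geometry is treated as similar and the 8 points contribute equations to
one weight block. Every (repetition × partition × in-segment point) of the
calibration data yields one equation — partitions are valid instances only
*before* any FFT, so calibration operates on raw partition-encoded
k-space. One weight block is fitted per (segment, acquired-arm gap,
missing offset) — i.e. per missing arm per segment, since rotating the
constellation to another gap changes its relationship to the coil
geometry — and re-used across all partitions and timeframes.

The fit is plain least squares (`numpy.linalg.lstsq`, SVD-based); a
rank-deficient block falls back to the minimum-norm solution with a logged
warning. A Tikhonov ridge is available but defaults to 0. Readout offsets
at the segment ends are clamped to the valid range (the boundary-handling
choice is documented rather than inferred). Source vectors are flattened
in (channel, arm, readout) order.

Numerical caveat observed in testing: weights fitted on *noiseless*
calibration data can be rank-deficient, and the minimum-norm solution is
then unconstrained along directions the calibration never excited —
applying such weights to *noisy* dynamic data amplifies noise severely.
With matched calibration/dynamic noise (the physical situation) the
calibration noise itself regularizes the fit and no such amplification
occurs.

## Reconstruction

The gridding NUFFT uses a Kaiser–Bessel kernel (width 4, Beatty β) on a 2×
oversampled FFT grid with closed-form deapodization; forward and adjoint
share one sparse interpolator and one real deapodization, so the pair is
adjoint to machine precision, and both match the exact dense NDFT to
~6×10⁻⁴ relative. The partition direction uses a centred orthonormal
inverse FFT; the slab-oversampled slices are discarded symmetrically (an
odd surplus drops the extra high-z slice).

Coil combination is a Walsh-type adaptive matched filter: per slice,
channel covariance over 8×8 blocks with 50 % overlap, principal
eigenvector as the filter, phase anchored to the strongest channel and
averaged across overlapping blocks. Two normalization modes exist:
`"none"` (default in the analysis pipeline) keeps the |matched filter|
output — for one channel it reduces exactly to the input magnitude, and
for identical sensitivities it is proportional to any single-channel
image; `"lowpass"` additionally divides by a Gaussian-smoothed (σ = 4
voxels) copy of the combined image floored at 15 % of its maximum, which
flattens coil shading over uniform regions but compresses genuine tissue
contrast and amplifies low-signal regions toward the floor (the classic
bright-chest-wall behaviour of intensity normalization). Quantitative
volumetry therefore runs on the unnormalized combine.

## Functional analysis

Blood-pool segmentation thresholds the magnitude volumes at 0.675 of the
robust blood level (99.5th percentile at the first phase, held fixed
across phases). The fraction is the full-width-at-half-maximum boundary
criterion — the midpoint between blood (1.0) and myocardium (0.35) — which
places the boundary at the true edge under a symmetric PSF. Volumes are
Simpson voxel sums; ED/ES are the blood-volume argmax/argmin (earliest
phase on ties); EDM uses the conventional 1.05 g/mL myocardial density.
Under noise, hard-threshold volumetry inflates both volumes roughly in
proportion to surface area, which biases EF slightly downward (about 1–3
points at blood SNR 40 on the desk phantom, even for the fully sampled
reconstruction); this is a property of the estimator, not of the
parallel-imaging step.

Statistics: Bland–Altman uses the fixed 1.96 multiplier with a two-sided
one-sample t-test of the bias; Welch's t uses the Welch–Satterthwaite
degrees of freedom; the Wilcoxon signed-rank test discards zero
differences (classical handling), mid-ranks ties, computes the exact
sign-permutation distribution by dynamic programming for n ≤ 25 (ties
handled exactly under the permutation null) and a tie-corrected normal
approximation beyond.

## Problem sizes and determinism

The desk configuration (64² matrix, 24 arms / 4 acquired, 10 partitions,
8 coils, 8 phases) was chosen so the full simulate–calibrate–reconstruct–
analyse chain runs in about a minute on one CPU while preserving the
full-scale acceleration regime (R = 6, fully sampled centre, 5 missing
offsets per gap). The full-scale 48-arm/128²/32-channel protocol is a
constructor away (`protocol.protocol_3d_spiral()`); only memory and time
grow. Every stochastic element (phantom motion draws, respiration, noise,
coil-map jitter) flows from a single seed, and identical seeds give
bit-identical raw data and reconstructions.

## Known limitations

Off-resonance/banding, gradient waveform feasibility, sliding-window or
iterative reconstructions, partition-direction acceleration and coil
compression are out of scope. The radiologist image-rating study is
represented only by its statistic (Wilcoxon signed-rank). Bland–Altman
agreement against a 2-D reference is exercised with the reported summary
statistics and synthetic samples, not re-measured volunteer data.
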