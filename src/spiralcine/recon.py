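"""Image reconstruction: NUFFT gridding, partition FFT, coil combination.

The GRAPPA-filled stack-of-spirals k-space is turned into magnitude volumes
by (1) density-compensated adjoint NUFFT of each kz partition and channel,
(2) a centred inverse FFT along the partition direction with symmetric
discard of the slab-oversampled slices, and (3) adaptive (Walsh-type)
matched-filter coil combination, optionally followed by low-pass intensity
normalization.  The whole chain up to the magnitude is linear in the k-space
data and fully deterministic.

Array conventions: k-space (phase, partition, arm, readout, channel); images
(phase, z, y, x); DC at the centred index; orthonormal partition FFT so an
R = 1 acquisition round-trips on the object's intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grappa import KernelSpec, calibrate_weights
from .nufft import GriddingNufft2D
from .trajectory import SamplingPattern, SpiralTrajectory, \
    density_compensation


class ReconError(ValueError):
    pass


@dataclass
class ImageVolumeSeries:
    """Reconstructed magnitude volumes (cardiac_phase, z, y, x)."""

    volumes: np.ndarray
    voxel_mm: tuple
    phase_times_ms: np.ndarray

    def __post_init__(self) -> None:
        if (self.volumes < 0).any():
            raise ReconError("magnitude volumes must be non-negative")


def grid_nufft(filled: np.ndarray, traj: SpiralTrajectory,
               dcf: np.ndarray, nufft: GriddingNufft2D | None = None
               ) -> np.ndarray:
    """Adjoint-NUFFT each partition/channel onto the matrix grid.

    filled: (..., partitions, arms_total, readout, channels) with all arms
    present; dcf: (arms_total, readout) density weights.  Returns hybrid
    per-channel images (..., partitions, channels, ny, nx) — still kz-
    resolved along the partition axis.
    """
    filled = np.asarray(filled)
    if filled.shape[-3] != traj.arms_total or \
            filled.shape[-2] != traj.n_readout:
        raise ReconError("k-space shape does not match trajectory "
                         f"({filled.shape[-3:-1]} vs "
                         f"({traj.arms_total}, {traj.n_readout}))")
    if nufft is None:
        nufft = GriddingNufft2D(traj.normalized(),
                                (traj.matrix, traj.matrix))
    # dcf is in (cycles/mm)^2; the NUFFT works in cycles/grid, so convert the
    # quadrature weights to keep the adjoint on the object's intensity scale
    weighted = filled * (dcf * (traj.fov_mm / traj.matrix) ** 2)[..., None]
    # move channel axis before the flattened sample axis
    samples = np.moveaxis(weighted, -1, -3)  # (..., ch, arms, readout)
    samples = samples.reshape(samples.shape[:-2] + (-1,))
    return nufft.adjoint(samples)


def partition_fft(hybrid: np.ndarray, partitions_nominal: int,
                  partition_axis: int = -4) -> np.ndarray:
    """Centred inverse DFT along kz and symmetric oversampling discard.

    Keeps the central `partitions_nominal` slices; an odd surplus discards
    the extra slice on the high-z side.
    """
    n_enc = hybrid.shape[partition_axis]
    if partitions_nominal > n_enc:
        raise ReconError(
            f"partitions_nominal ({partitions_nominal}) > encoded ({n_enc})")
    vol = np.fft.fftshift(np.fft.ifft(
        np.fft.ifftshift(hybrid, axes=partition_axis), axis=partition_axis,
        norm="ortho"), axes=partition_axis)
    start = (n_enc - partitions_nominal) // 2
    sl = [slice(None)] * vol.ndim
    sl[partition_axis] = slice(start, start + partitions_nominal)
    return vol[tuple(sl)]


def adaptive_combine(coil_vols: np.ndarray, normalize: str = "lowpass",
                     block: int = 8, stride: int | None = None,
                     norm_sigma: float = 4.0,
                     norm_floor: float = 0.15) -> np.ndarray:
    """Walsh-type adaptive coil combination of (channels, nz, ny, nx).

    Per slice, channel covariance is estimated over `block` x `block`
    in-plane windows with 50 % overlap; the principal eigenvector serves as
    a matched filter, phase-anchored to the strongest channel and averaged
    across overlapping windows.  normalize:

    * ``"none"`` — plain matched-filter magnitude |v^H s| (equals the input
      magnitude for a single channel).
    * ``"lowpass"`` — additionally divides by a Gaussian-smoothed (sigma
      `norm_sigma` voxels) copy of the combined image, floored at
      `norm_floor` of its maximum, flattening the slow shading that the
      coil-array geometry imprints on a uniform object.  (Known trade-off:
      low-signal regions are amplified toward the floor.)
    """
    coil_vols = np.asarray(coil_vols)
    if coil_vols.ndim != 4:
        raise ReconError("expected (channels, nz, ny, nx)")
    nch, nz, ny, nx = coil_vols.shape
    if normalize not in ("none", "lowpass"):
        raise ReconError(f"unknown normalize mode {normalize!r}")
    if nch == 1:
        combined = np.abs(coil_vols[0])
    else:
        if stride is None:
            stride = max(block // 2, 1)
        ref = int(np.argmax(np.sum(np.abs(coil_vols) ** 2, axis=(1, 2, 3))))
        combined = np.empty((nz, ny, nx))
        for z in range(nz):
            s = coil_vols[:, z]                    # (ch, ny, nx)
            filt = np.zeros((nch, ny, nx), complex)
            hits = np.zeros((ny, nx))
            y_starts = list(range(0, max(ny - block, 0) + 1, stride))
            x_starts = list(range(0, max(nx - block, 0) + 1, stride))
            for y0 in y_starts:
                for x0 in x_starts:
                    blk = s[:, y0:y0 + block, x0:x0 + block].reshape(nch, -1)
                    cov = blk @ blk.conj().T
                    if not np.any(cov):
                        v = np.ones(nch) / np.sqrt(nch)  # unit filter
                    else:
                        _, vecs = np.linalg.eigh(cov)
                        v = vecs[:, -1]
                        # anchor the arbitrary eigenvector phase
                        v = v * np.exp(-1j * np.angle(v[ref]))
                    filt[:, y0:y0 + block, x0:x0 + block] += v[:, None, None]
                    hits[y0:y0 + block, x0:x0 + block] += 1.0
            filt /= np.maximum(hits, 1.0)
            combined[z] = np.abs(np.einsum("cyx,cyx->yx", filt.conj(), s))
    if normalize == "lowpass" and nch > 1:
        smooth = gaussian_filter(combined, sigma=(0, norm_sigma, norm_sigma))
        floor = norm_floor * smooth.max()
        combined = combined / np.maximum(smooth, floor)
    return combined


def zero_fill(dynamic: np.ndarray, pattern: SamplingPattern,
              n_readout: int) -> np.ndarray:
    """Place acquired arms in a full-arm array, leaving missing arms zero
    (the no-parallel-imaging ablation)."""
    out_shape = dynamic.shape[:-3] + (pattern.arms_total,) + dynamic.shape[-2:]
    out = np.zeros(out_shape, dynamic.dtype)
    out[..., pattern.acquired_arm_indices, :, :] = dynamic
    return out


def reconstruct_filled(filled: np.ndarray, traj: SpiralTrajectory,
                       partitions_nominal: int,
                       dcf: np.ndarray | None = None,
                       normalize: str = "lowpass",
                       nufft: GriddingNufft2D | None = None) -> np.ndarray:
    """Full-arm k-space (phases, partitions, arms, readout, ch) -> magnitude
    volumes (phases, z, y, x)."""
    if dcf is None:
        dcf = density_compensation(traj)
    hybrid = grid_nufft(filled, traj, dcf, nufft=nufft)
    vols = partition_fft(hybrid, partitions_nominal, partition_axis=-4)
    out = np.stack([
        adaptive_combine(np.moveaxis(vols[p], 1, 0), normalize=normalize)
        for p in range(vols.shape[0])])
    return out


def reconstruct_series(dynamic: np.ndarray, calibration: np.ndarray | None,
                       traj: SpiralTrajectory, pattern: SamplingPattern,
                       partitions_nominal: int,
                       spec: KernelSpec | None = None, ridge: float = 0.0,
                       tr_ms: float = 4.4, normalize: str = "lowpass",
                       ) -> ImageVolumeSeries:
    """Orchestrate calibrate -> apply -> NUFFT -> partition FFT -> combine.

    For R = 1 input the GRAPPA stage is bypassed.  Deterministic given its
    inputs; stage errors propagate with the failing stage named.
    """
    dynamic = np.asarray(dynamic)
    if pattern.r > 1:
        if calibration is None:
            raise ReconError("stage calibrate: R > 1 requires calibration data")
        try:
            weights = calibrate_weights(calibration, pattern, spec,
                                        ridge=ridge)
            filled = weights.apply(dynamic)
        except Exception as exc:
            raise ReconError(f"stage grappa: {exc}") from exc
    else:
        filled = dynamic
    try:
        vols = reconstruct_filled(filled, traj, partitions_nominal,
                                  normalize=normalize)
    except Exception as exc:
        raise ReconError(f"stage gridding: {exc}") from exc
    voxel = (traj.fov_mm / traj.matrix, traj.fov_mm / traj.matrix)
    n_phases = dynamic.shape[0]
    times = np.arange(n_phases) * pattern.n_acquired * tr_ms
    return ImageVolumeSeries(
        volumes=vols, voxel_mm=(8.0, voxel[0], voxel[1]),
        phase_times_ms=times)


def nrmse(x: np.ndarray, ref: np.ndarray,
          mask: np.ndarray | None = None) -> float:
    """Normalized RMS error ||x - ref|| / ||ref||, optionally over a mask."""
    x, ref = np.asarray(x, float), np.asarray(ref, float)
    if mask is not None:
        x, ref = x[mask], ref[mask]
    return float(np.linalg.norm(x - ref) / np.linalg.norm(ref))
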