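"""Through-time spiral GRAPPA: kernel geometry, calibration, application.

Missing spiral arms of the undersampled dynamic data are synthesized as
learned linear combinations of the two acquired arms that flank them, using
three source readout points (offsets -1, 0, +1) per arm across all receiver
channels.  Because the trajectory is non-Cartesian, the relative geometry of
sources and target changes along the readout, so the readout is cut into
short segments (default 8 points) within which the geometry is treated as
similar; each missing arm gets its own weight block per segment, calibrated
by least squares over every (repetition x partition x in-segment point)
instance extracted from the fully-sampled free-breathing calibration data.
With 10 repetitions, 16 partitions and 8 points per segment that is 1280
equations for n_channels x 2 x 3 unknowns per target channel.  The fitted
weights are then re-used at exactly the same spiral sampling location in
every partition encoding step and timeframe of the dynamic scan.

The calibration is exposed statsmodels-style: :class:`ThroughTimeGrappa` is
the model built from a calibration set; ``fit()`` returns
:class:`GrappaWeights`, which carries the weight blocks, per-block residual
diagnostics, a ``summary()`` table and the ``apply()`` step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import SamplingPattern

logger = logging.getLogger(__name__)


class GrappaError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel extent: (channels x source_arms x source_readout_points)
    unknowns per target channel; geometry presumed similar over
    segment_readout consecutive readout points of segment_arms arm gaps."""

    n_channels: int
    source_arms: int = 2
    source_readout_points: int = 3
    segment_arms: int = 1
    segment_readout: int = 8

    def __post_init__(self) -> None:
        if min(self.n_channels, self.source_arms, self.source_readout_points,
               self.segment_arms, self.segment_readout) < 1:
            raise GrappaError("kernel spec counts must be >= 1")

    @property
    def n_unknowns(self) -> int:
        return self.n_channels * self.source_arms * self.source_readout_points


@dataclass(frozen=True)
class KernelGeometry:
    """Geometry template for one (readout segment, missing-arm offset) pair.

    missing_offset m in 1..r-1 is the missing arm's index distance above its
    left acquired neighbour.  readout_points are the absolute readout indices
    of the segment; source_offsets[i] holds the clamped absolute readout
    indices of the sources for readout_points[i].  One template covers the
    corresponding missing arm in every acquired-arm gap.
    """

    segment_index: int
    missing_offset: int
    readout_points: np.ndarray
    source_offsets: np.ndarray  # (len(readout_points), source_readout_points)


def n_segments(n_readout: int, segment_readout: int) -> int:
    return -(-n_readout // segment_readout)  # ceil


def build_kernel_geometries(n_readout: int, pattern: SamplingPattern,
                            spec: KernelSpec) -> list[KernelGeometry]:
    """Enumerate (r-1) x ceil(n_readout / segment_readout) geometry
    templates; empty for r = 1 (nothing missing)."""
    if pattern.r == 1:
        return []
    half = spec.source_readout_points // 2
    rel = np.arange(spec.source_readout_points) - half
    geoms = []
    for seg in range(n_segments(n_readout, spec.segment_readout)):
        pts = np.arange(seg * spec.segment_readout,
                        min((seg + 1) * spec.segment_readout, n_readout))
        offs = np.clip(pts[:, None] + rel[None, :], 0, n_readout - 1)
        for m in range(1, pattern.r):
            geoms.append(KernelGeometry(
                segment_index=seg, missing_offset=m,
                readout_points=pts, source_offsets=offs))
    return geoms


def _gather_sources(data: np.ndarray, left: int, right: int,
                    geom: KernelGeometry) -> np.ndarray:
    """Stack source values for one geometry from (..., arm, readout, ch)
    data -> (..., n_points, ch * 2 * 3), flattened (channel, arm, readout)."""
    # (..., n_points, 3, ch) per source arm
    src_l = data[..., left, geom.source_offsets, :]
    src_r = data[..., right, geom.source_offsets, :]
    stacked = np.stack((src_l, src_r), axis=-2)       # (..., pts, 3?, 2, ch)
    # current axes: (..., n_points, n_offsets, 2, ch); reorder to
    # (..., n_points, ch, 2, n_offsets) then flatten
    stacked = np.moveaxis(stacked, (-3, -2, -1), (-1, -2, -3))
    return stacked.reshape(stacked.shape[:-3] + (-1,))


class ThroughTimeGrappa:
    """Through-time spiral GRAPPA calibration model.

    Parameters
    ----------
    calibration : ndarray, (repetitions, partitions, arms_total, readout, ch)
        Fully-sampled free-breathing calibration data (raw partition-encoded
        k-space, before any FFT: partitions are independent calibration
        instances only pre-transform).
    pattern : SamplingPattern
        The dynamic scan's stride-R acquired-arm subset.
    spec : KernelSpec, optional
        Defaults to the 2-arm x 3-point kernel with 1x8 segmentation.
    """

    def __init__(self, calibration: np.ndarray, pattern: SamplingPattern,
                 spec: KernelSpec | None = None) -> None:
        calibration = np.asarray(calibration)
        if calibration.ndim != 5:
            raise GrappaError(
                "calibration must be (repetitions, partitions, arms, "
                "readout, channels)")
        if calibration.shape[2] != pattern.arms_total:
            raise GrappaError("calibration arm count != pattern.arms_total")
        if calibration.shape[0] < 1:
            raise GrappaError("need >= 1 calibration repetition")
        self.calibration = calibration
        self.pattern = pattern
        self.spec = spec or KernelSpec(n_channels=calibration.shape[-1])
        if self.spec.n_channels != calibration.shape[-1]:
            raise GrappaError("spec.n_channels != calibration channels")
        self.n_readout = calibration.shape[3]
        self.geometries = build_kernel_geometries(
            self.n_readout, pattern, self.spec)

    @property
    def n_equations_per_block(self) -> int:
        return (self.calibration.shape[0] * self.calibration.shape[1]
                * self.spec.segment_readout)

    def fit(self, ridge: float = 0.0) -> "GrappaWeights":
        """Least-squares calibration of every weight block.

        Solves min ||S w - t||^2 (+ ridge ||w||^2) per target channel, where
        S stacks source vectors over repetitions, partitions and in-segment
        readout points.  With ridge = 0 a rank-deficient system falls back to
        the minimum-norm pseudo-inverse solution (with a warning).
        """
        pat = self.pattern
        r = pat.r
        blocks: dict = {}
        residuals: dict = {}
        gaps = pat.acquired_arm_indices
        for geom in self.geometries:
            for g, left_arm in enumerate(gaps):
                left = int(left_arm)
                right = int((left + r) % pat.arms_total)
                missing = (left + geom.missing_offset) % pat.arms_total
                src = _gather_sources(self.calibration, left, right, geom)
                s_mat = src.reshape(-1, self.spec.n_unknowns)
                tgt = self.calibration[..., missing, geom.readout_points, :]
                t_mat = tgt.reshape(-1, self.spec.n_channels)
                w, res = _solve_block(s_mat, t_mat, ridge)
                key = (geom.segment_index, geom.missing_offset, g)
                blocks[key] = w
                residuals[key] = res
        return GrappaWeights(model=self, ridge=ridge, blocks=blocks,
                             residuals=residuals)


def _solve_block(s_mat: np.ndarray, t_mat: np.ndarray,
                 ridge: float) -> tuple[np.ndarray, float]:
    if ridge > 0:
        a = s_mat.conj().T @ s_mat
        a[np.diag_indices_from(a)] += ridge
        w = np.linalg.solve(a, s_mat.conj().T @ t_mat)
    else:
        w, _, rank, _ = np.linalg.lstsq(s_mat, t_mat, rcond=None)
        if rank < s_mat.shape[1]:
            logger.warning(
                "rank-deficient calibration block (rank %d < %d unknowns); "
                "using minimum-norm solution", rank, s_mat.shape[1])
    res = float(np.linalg.norm(s_mat @ w - t_mat))
    return w, res


@dataclass
class GrappaWeights:
    """Fitted spiral GRAPPA weights (results object).

    blocks[(segment, missing_offset, gap)] is the (n_unknowns, n_channels)
    complex weight matrix; residuals holds the calibration residual norm per
    block.  The same block is applied at the same spiral sampling location
    in every partition and timeframe.
    """

    model: ThroughTimeGrappa
    ridge: float
    blocks: dict
    residuals: dict = field(repr=False)

    def apply(self, dynamic: np.ndarray) -> np.ndarray:
        """Fill missing arms of (..., partitions, n_acquired, readout, ch)
        dynamic data -> (..., partitions, arms_total, readout, ch).

        Acquired samples are copied through unchanged (bitwise); each
        missing sample is the weight block applied to its source vector.
        """
        dynamic = np.asarray(dynamic)
        pat = self.model.pattern
        spec = self.model.spec
        if dynamic.shape[-3] != pat.n_acquired:
            raise GrappaError("dynamic arm axis != pattern.n_acquired")
        if dynamic.shape[-2] != self.model.n_readout:
            raise GrappaError("dynamic readout length != calibration")
        out_shape = dynamic.shape[:-3] + (pat.arms_total,) + dynamic.shape[-2:]
        filled = np.zeros(out_shape, dynamic.dtype)
        filled[..., pat.acquired_arm_indices, :, :] = dynamic

        # positions of acquired arms within the dynamic arm axis
        pos = {int(a): i for i, a in enumerate(pat.acquired_arm_indices)}
        for geom in self.model.geometries:
            for g, left_arm in enumerate(pat.acquired_arm_indices):
                left = int(left_arm)
                right = int((left + pat.r) % pat.arms_total)
                missing = (left + geom.missing_offset) % pat.arms_total
                key = (geom.segment_index, geom.missing_offset, g)
                if key not in self.blocks:
                    raise GrappaError(
                        f"no weight block for geometry {key} "
                        f"(segment, offset, gap)")
                src = _gather_sources(dynamic, pos[left], pos[right], geom)
                est = src @ self.blocks[key]
                filled[..., missing, geom.readout_points, :] = est
        return filled

    def summary(self) -> str:
        spec = self.model.spec
        res = np.array(list(self.residuals.values()))
        scale = np.linalg.norm(self.model.calibration)
        lines = [
            "Through-time spiral GRAPPA calibration",
            "=" * 46,
            f"acquired arms / total      {self.model.pattern.n_acquired} / "
            f"{self.model.pattern.arms_total}  (R = {self.model.pattern.r})",
            f"kernel (ch x arm x read)   {spec.n_channels} x "
            f"{spec.source_arms} x {spec.source_readout_points}",
            f"segmentation               {spec.segment_arms} x "
            f"{spec.segment_readout}",
            f"weight blocks              {len(self.blocks)}",
            f"equations per block        {self.model.n_equations_per_block}",
            f"unknowns per target chan   {spec.n_unknowns}",
            f"ridge                      {self.ridge:g}",
            f"median residual norm       {np.median(res):.3e}",
            f"max residual norm          {res.max():.3e}",
            f"calibration data norm      {scale:.3e}",
        ]
        return "\n".join(lines)


# -- functional wrappers ------------------------------------------------------

def calibrate_weights(calibration: np.ndarray, pattern: SamplingPattern,
                      spec: KernelSpec | None = None,
                      ridge: float = 0.0) -> GrappaWeights:
    """Convenience wrapper: build the model and fit in one call."""
    return ThroughTimeGrappa(calibration, pattern, spec).fit(ridge=ridge)


def apply_weights(dynamic: np.ndarray, weights: GrappaWeights) -> np.ndarray:
    """Convenience wrapper for :meth:`GrappaWeights.apply`."""
    return weights.apply(dynamic)
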