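"""HDF5 raw-data container and NIfTI image export.

Layout of the raw container (all complex64, dimension order fixed and
recorded in a `dims` attribute so foreign orderings can be permuted on
read):

    /calibration/data   (repetition, partition, arm, readout, channel)
    /dynamic/data       (frame, partition, arm, readout, channel)
    /dynamic/arm_indices
    /trajectory/k       (arm, readout) complex, cycles/mm
    /trajectory/dcf     (arm, readout)
    /truth/volumes      (phase, 2) analytic blood/myo volumes, mL
    attrs: fov, matrix, dwell

Weights:  /weights/seg{i}/off{m}/gap{g} complex matrices + kernel-spec attrs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .grappa import GrappaWeights, ThroughTimeGrappa
from .phantom import CalibrationSet, DynamicSet
from .trajectory import SpiralArm, SpiralTrajectory

CANONICAL_DIMS = "repetition,partition,arm,readout,channel"


class RawContainerError(KeyError):
    pass


def write_raw(path: str | Path, calibration: CalibrationSet | None = None,
              dynamic: DynamicSet | None = None,
              traj: SpiralTrajectory | None = None,
              dcf: np.ndarray | None = None,
              truth: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        if calibration is not None:
            d = f.create_dataset("calibration/data",
                                 data=calibration.data.astype(np.complex64))
            d.attrs["dims"] = CANONICAL_DIMS
        if dynamic is not None:
            d = f.create_dataset("dynamic/data",
                                 data=dynamic.data.astype(np.complex64))
            d.attrs["dims"] = CANONICAL_DIMS.replace("repetition", "frame")
            f.create_dataset("dynamic/arm_indices", data=dynamic.arm_indices)
        if traj is not None:
            k = traj.k_all()
            f.create_dataset("trajectory/k", data=k.astype(np.complex128))
            f.attrs["fov"] = traj.fov_mm
            f.attrs["matrix"] = traj.matrix
            f.attrs["dwell"] = traj.base_arm.dwell_us
            f.attrs["arms_total"] = traj.arms_total
        if dcf is not None:
            f.create_dataset("trajectory/dcf", data=dcf)
        if truth is not None:
            f.create_dataset("truth/volumes", data=truth)


def _require(f: h5py.File, name: str):
    if name not in f:
        raise RawContainerError(f"missing dataset {name!r} in raw container")
    return f[name]


def _canonical_order(dset, canonical: str) -> np.ndarray:
    data = dset[()]
    dims = dset.attrs.get("dims", canonical)
    if isinstance(dims, bytes):
        dims = dims.decode()
    want = canonical.split(",")
    have = dims.split(",")
    if sorted(want) != sorted(have):
        raise RawContainerError(
            f"dims attribute {dims!r} does not name the axes {want}")
    perm = [have.index(w) for w in want]
    return np.transpose(data, perm) if perm != list(range(len(perm))) else data


def read_raw(path: str | Path) -> dict:
    """Read the raw container back into CalibrationSet/DynamicSet (+ extras).

    Datasets with a foreign but fully-declared `dims` attribute are permuted
    to the canonical order; missing datasets raise a named error.
    """
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "calibration" in f:
            data = _canonical_order(_require(f, "calibration/data"),
                                    CANONICAL_DIMS)
            out["calibration"] = CalibrationSet(data=data)
        if "dynamic" in f:
            data = _canonical_order(
                _require(f, "dynamic/data"),
                CANONICAL_DIMS.replace("repetition", "frame"))
            arms = _require(f, "dynamic/arm_indices")[()]
            out["dynamic"] = DynamicSet(data=data, arm_indices=arms)
        if "trajectory" in f:
            k = _require(f, "trajectory/k")[()]
            arm = SpiralArm(k=k[0], dwell_us=float(f.attrs.get("dwell", 5.0)),
                            truncation_index=k.shape[1] - 1)
            out["trajectory"] = SpiralTrajectory(
                base_arm=arm, arms_total=int(f.attrs["arms_total"]),
                fov_mm=float(f.attrs["fov"]), matrix=int(f.attrs["matrix"]))
            if "trajectory/dcf" in f:
                out["dcf"] = f["trajectory/dcf"][()]
        if "truth" in f:
            out["truth"] = _require(f, "truth/volumes")[()]
    return out


def write_weights(path: str | Path, weights: GrappaWeights) -> None:
    spec = weights.model.spec
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for (seg, off, gap), w in weights.blocks.items():
            d = g.create_dataset(f"seg{seg}/off{off}/gap{gap}", data=w)
            d.attrs["residual"] = weights.residuals[(seg, off, gap)]
        g.attrs["n_channels"] = spec.n_channels
        g.attrs["source_arms"] = spec.source_arms
        g.attrs["source_readout_points"] = spec.source_readout_points
        g.attrs["segment_arms"] = spec.segment_arms
        g.attrs["segment_readout"] = spec.segment_readout
        g.attrs["ridge"] = weights.ridge


def read_weights(path: str | Path, model: ThroughTimeGrappa) -> GrappaWeights:
    """Re-attach serialized weight blocks to a calibration model."""
    blocks, residuals = {}, {}
    with h5py.File(path, "r") as f:
        g = _require(f, "weights")
        ridge = float(g.attrs["ridge"])
        for seg_name, seg_grp in g.items():
            seg = int(seg_name[3:])
            for off_name, off_grp in seg_grp.items():
                off = int(off_name[3:])
                for gap_name, dset in off_grp.items():
                    gap = int(gap_name[3:])
                    blocks[(seg, off, gap)] = dset[()]
                    residuals[(seg, off, gap)] = float(
                        dset.attrs.get("residual", np.nan))
    return GrappaWeights(model=model, ridge=ridge, blocks=blocks,
                         residuals=residuals)


def write_nifti(path: str | Path, volumes: np.ndarray,
                voxel_mm: tuple) -> None:
    """Write (phase, z, y, x) magnitude volumes as one 4-D NIfTI file with
    the affine built from the voxel size."""
    import nibabel as nib

    # NIfTI expects (x, y, z, t)
    arr = np.transpose(np.asarray(volumes), (3, 2, 1, 0)).astype(np.float32)
    dz, dy, dx = voxel_mm
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti_masks(path: str | Path) -> tuple:
    """Read a label NIfTI (1 = blood pool, 2 = myocardium) into
    (endo, epi) boolean arrays of shape (phase, z, y, x)."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    arr = np.transpose(arr, (3, 2, 1, 0))
    endo = arr == 1
    epi = endo | (arr == 2)
    return endo, epi
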