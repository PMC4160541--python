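"""Acquisition protocol records and derived timing/resolution quantities.

The 3D acquisition is an ECG-gated, angularly undersampled stack-of-spirals
bSSFP sequence: per cardiac phase and partition-encoding step only a stride-R
subset of the spiral interleaves is acquired, while a separate free-breathing,
ungated scan repeats the fully sampled trajectory several times to provide
through-time calibration data for GRAPPA.  Everything derivable from the
protocol (temporal footprint, in-plane resolution, acceleration, calibration
scan duration, bSSFP banding interval, encoded partition count) is computed on
demand from the validated record and never stored.

All rounding of printed quantities is half-up, matching the convention of the
reported values (e.g. 35 ms from 8 x 4.4 ms = 35.2 ms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, fields
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path


class ProtocolError(ValueError):
    """Invalid protocol parameters or an irregular undersampling pattern."""


def _round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero ties upward, to `decimals` places.

    Python's built-in round() is banker's rounding; printed protocol values
    use the conventional half-up rule.
    """
    q = Decimal(1).scaleb(-decimals)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v)


@dataclass(frozen=True)
class SequenceProtocol:
    """Parameters of the 3D stack-of-spirals bSSFP sequence.

    Units: times in ms, lengths in mm, bandwidth in Hz/pixel, angles in
    degrees.  ``arms_total`` is the number of interleaves needed for Nyquist
    coverage; ``arms_acquired`` the number played per partition encoding step
    per cardiac phase in the dynamic scan.
    """

    tr_ms: float
    te_ms: float
    fov_mm: float
    matrix: int
    arms_total: int
    arms_acquired: int
    partitions_nominal: int
    partition_oversampling: float
    partition_thickness_mm: float
    readout_bandwidth_hz_per_px: float
    flip_deg: float
    calibration_repetitions: int

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ProtocolError("tr_ms must be > 0")
        if self.fov_mm <= 0 or self.matrix < 1:
            raise ProtocolError("fov_mm and matrix must be positive")
        for name in ("arms_total", "arms_acquired", "partitions_nominal",
                     "matrix"):
            if getattr(self, name) < 1:
                raise ProtocolError(f"{name} must be >= 1")
        if self.calibration_repetitions < 0:
            raise ProtocolError("calibration_repetitions must be >= 0")
        if self.partition_oversampling < 0:
            raise ProtocolError("partition_oversampling must be >= 0")
        if self.arms_total % self.arms_acquired != 0:
            raise ProtocolError(
                "arms_total must be divisible by arms_acquired "
                f"({self.arms_total} % {self.arms_acquired} != 0): "
                "irregular undersampling pattern")

    # -- derived quantities -------------------------------------------------

    @property
    def r(self) -> int:
        return acceleration_factor(self.arms_total, self.arms_acquired)

    @property
    def encoded_partitions(self) -> int:
        return encoded_partitions(self.partitions_nominal,
                                  self.partition_oversampling)

    def derived(self) -> dict:
        """All printed derived quantities as a plain dict (JSON-friendly)."""
        return {
            "acceleration_factor": self.r,
            "temporal_footprint_ms": temporal_footprint_ms(
                self.arms_acquired, self.tr_ms),
            "in_plane_resolution_mm": in_plane_resolution_mm(
                self.fov_mm, self.matrix),
            "encoded_partitions": self.encoded_partitions,
            "calibration_duration_s": calibration_duration_s(
                self.arms_total, self.encoded_partitions,
                self.calibration_repetitions, self.tr_ms),
            "calibration_arm_separation_ms": calibration_arm_separation_ms(
                self.r, self.tr_ms),
            "bssfp_band_spacing_hz": bssfp_band_spacing_hz(self.tr_ms),
        }

    # -- flat key=value config round-trip -----------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SequenceProtocol":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ProtocolError(f"unknown protocol key: {key!r}")
            caster = int if known[key] == "int" else float
            kwargs[key] = caster(val.strip())
        missing = set(known) - set(kwargs)
        if missing:
            raise ProtocolError(f"missing protocol keys: {sorted(missing)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class Protocol2D:
    """Parameters of the 2D segmented multi-breathhold Cartesian reference.

    Only its protocol arithmetic (temporal footprint, resolution, heartbeats
    per slice) is in scope; the 2D reconstruction itself is not.
    """

    tr_ms: float
    lines_acquired: int
    lines_zerofilled: int
    grappa_r: int
    segment_size: int
    fov_ro_mm: float
    matrix_ro: int
    dummy_beats: int

    def __post_init__(self) -> None:
        if self.segment_size < 1 or self.grappa_r < 1:
            raise ProtocolError("segment_size and grappa_r must be >= 1")
        if self.lines_zerofilled < self.lines_acquired:
            raise ProtocolError("lines_zerofilled < lines_acquired")
        if self.tr_ms <= 0:
            raise ProtocolError("tr_ms must be > 0")
        if self.dummy_beats < 0:
            raise ProtocolError("dummy_beats must be >= 0")


# -- operations --------------------------------------------------------------

def acceleration_factor(arms_total: int, arms_acquired: int) -> int:
    """In-plane acceleration R from the acquired-interleave subset."""
    if arms_total < 1 or arms_acquired < 1:
        raise ProtocolError("arm counts must be >= 1")
    if arms_total % arms_acquired != 0:
        raise ProtocolError(
            f"{arms_acquired} of {arms_total} arms is an irregular "
            "undersampling pattern (not an integer stride)")
    return arms_total // arms_acquired


def temporal_footprint_ms(units_per_phase: int, tr_ms: float) -> int:
    """Time spent per heartbeat collecting one cardiac phase, in whole ms."""
    if units_per_phase <= 0 or tr_ms <= 0:
        raise ProtocolError("units_per_phase and tr_ms must be > 0")
    return int(_round_half_up(units_per_phase * tr_ms))


def in_plane_resolution_mm(fov_mm: float, matrix: int) -> float:
    """Nominal in-plane resolution FOV/matrix, half-up to 2 decimals."""
    if fov_mm <= 0 or matrix <= 0:
        raise ProtocolError("fov_mm and matrix must be > 0")
    return _round_half_up(fov_mm / matrix, 2)


def calibration_duration_s(arms_total: int, partitions_encoded: int,
                           repetitions: int, tr_ms: float) -> int:
    """Duration of the free-breathing fully-sampled calibration scan, in s."""
    if arms_total <= 0 or partitions_encoded <= 0 or tr_ms <= 0:
        raise ProtocolError("counts and tr_ms must be > 0")
    if repetitions < 0:
        raise ProtocolError("repetitions must be >= 0")
    return int(_round_half_up(
        arms_total * partitions_encoded * repetitions * tr_ms / 1000.0))


def calibration_arm_separation_ms(r: int, tr_ms: float) -> int:
    """Time between consecutive acquired arms of one stride-R subset in the
    fully-sampled calibration data (R*TR); the heart is quasi-stationary on
    this timescale, which is what makes through-time calibration valid."""
    if r < 1 or tr_ms <= 0:
        raise ProtocolError("r >= 1 and tr_ms > 0 required")
    return int(_round_half_up(r * tr_ms))


def bssfp_band_spacing_hz(tr_ms: float) -> int:
    """Off-resonance interval between bSSFP signal nulls, 1/TR in Hz."""
    if tr_ms <= 0:
        raise ProtocolError("tr_ms must be > 0")
    return int(_round_half_up(1000.0 / tr_ms))


def encoded_partitions(partitions_nominal: int, oversampling: float) -> int:
    """Partition count actually encoded: nominal plus slab oversampling,
    rounded up to the next even integer (keeps the partition FFT symmetric)."""
    if partitions_nominal < 1:
        raise ProtocolError("partitions_nominal must be >= 1")
    if oversampling < 0:
        raise ProtocolError("oversampling must be >= 0")
    n = math.ceil(partitions_nominal * (1.0 + oversampling))
    return n + (n % 2)


def heartbeats_per_2d_slice(lines_acquired: int, grappa_r: int,
                            segment_size: int,
                            dummy_beats: int) -> tuple[int, int]:
    """(imaging beats, total beats) to encode one 2D slice."""
    if min(lines_acquired, grappa_r, segment_size) < 1:
        raise ProtocolError("counts must be >= 1")
    if dummy_beats < 0:
        raise ProtocolError("dummy_beats must be >= 0")
    imaging = math.ceil(lines_acquired / grappa_r / segment_size)
    return imaging, imaging + dummy_beats


def breathhold_duration_s(partitions_encoded: int, rr_ms: float) -> float:
    """Breathhold length of the dynamic scan: one RR interval per partition
    encoding step."""
    if partitions_encoded <= 0 or rr_ms <= 0:
        raise ProtocolError("partitions_encoded and rr_ms must be > 0")
    return partitions_encoded * rr_ms / 1000.0


# -- reference protocols -----------------------------------------------------

def protocol_3d_spiral() -> SequenceProtocol:
    """The full-scale 3D stack-of-spirals protocol (3 T, 32-channel array)."""
    return SequenceProtocol(
        tr_ms=4.4, te_ms=2.2, fov_mm=316.0, matrix=128,
        arms_total=48, arms_acquired=8,
        partitions_nominal=12, partition_oversampling=0.33,
        partition_thickness_mm=8.0, readout_bandwidth_hz_per_px=1563.0,
        flip_deg=29.0, calibration_repetitions=10)


def protocol_2d_reference() -> Protocol2D:
    """The segmented 2D Cartesian multi-breathhold reference protocol."""
    return Protocol2D(
        tr_ms=3.26, lines_acquired=144, lines_zerofilled=174, grappa_r=2,
        segment_size=12, fov_ro_mm=340.0, matrix_ro=208, dummy_beats=1)


def protocol_desk() -> SequenceProtocol:
    """Desk-scale analogue: 64^2 matrix, 24 arms (4 acquired, R = 6),
    8 nominal + 2 oversampled partitions, 8 channels.  Same acceleration and
    geometry regime as the full protocol at a fraction of the compute."""
    return SequenceProtocol(
        tr_ms=4.4, te_ms=2.2, fov_mm=256.0, matrix=64,
        arms_total=24, arms_acquired=4,
        partitions_nominal=8, partition_oversampling=0.25,
        partition_thickness_mm=8.0, readout_bandwidth_hz_per_px=1563.0,
        flip_deg=29.0, calibration_repetitions=10)


def protocol_report(proto: SequenceProtocol) -> str:
    """JSON report of all derived protocol quantities."""
    out = dict(asdict(proto))
    out["derived"] = proto.derived()
    return json.dumps(out, indent=2)
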