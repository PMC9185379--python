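"""Frame segmentation, frame labelling, standing calibration and attribute scaling.

The raw 100 Hz five-channel pressure stream is reduced to 20 Hz feature
vectors: each non-overlapping block of ``m = sample_rate / frame_rate``
samples yields one vector of per-sensor mean forces.  A standing-pose
calibration profile (per-sensor baselines recorded while the wearer stands
still) divides those means so that 1.0 means "standing load on this
sensor", cancelling the wearer's weight.  Min–max attribute scaling fitted
on training data equalises the spread of the five attributes before the
Euclidean distance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .phases import N_SENSORS, SENSOR_NAMES, Phase

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GaitRecording


class CalibrationError(ValueError):
    """Raised when a standing recording cannot yield valid baselines."""


@dataclass(frozen=True)
class FeatureVector:
    """One 20 Hz frame: five per-sensor mean forces plus optional phase label.

    ``values`` are the coordinates compared by the classifier's Euclidean
    distance; before calibration/scaling they are non-negative forces.
    """

    values: np.ndarray
    t_start: float = 0.0
    label: Phase | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SENSORS,):
            raise ValueError(f"feature vector must have {N_SENSORS} values, got shape {v.shape}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-sensor standing-pose baselines b1..b5 (all strictly positive)."""

    baselines: np.ndarray
    created_from: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = np.asarray(self.baselines, dtype=float)
        if b.shape != (N_SENSORS,):
            raise ValueError(f"expected {N_SENSORS} baselines, got shape {b.shape}")
        if not np.all(b > 0):
            raise CalibrationError("all baselines must be strictly positive")
        object.__setattr__(self, "baselines", b)


@dataclass(frozen=True)
class ScalingParams:
    """Per-attribute minimum and range fitted on training data (min–max scaling)."""

    mins: np.ndarray
    ranges: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        ranges = np.asarray(self.ranges, dtype=float)
        if mins.shape != (N_SENSORS,) or ranges.shape != (N_SENSORS,):
            raise ValueError("scaling params must have one min and one range per sensor")
        if np.any(ranges < 0):
            raise ValueError("attribute ranges must be non-negative")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "ranges", ranges)


def frame_signal(recording: "GaitRecording", frame_rate_hz: float = 20.0) -> list[FeatureVector]:
    """Segment a recording into non-overlapping mean-force frames.

    The frame rate must divide the sample rate to an integer block size
    ``m``; with the 100 Hz / 20 Hz defaults each frame averages 5 raw
    samples.  A trailing partial block is dropped.  Frames are returned
    unlabelled; see :func:`label_frames`.
    """
    ratio = recording.sample_rate_hz / frame_rate_hz
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 1e-9:
        raise ValueError(
            f"frame rate {frame_rate_hz} Hz does not divide sample rate "
            f"{recording.sample_rate_hz} Hz to an integer block size"
        )
    n_frames = len(recording) // m
    if n_frames == 0:
        return []
    forces = recording.forces[: n_frames * m].reshape(n_frames, m, N_SENSORS)
    means = forces.mean(axis=1)
    t_starts = recording.t[0 : n_frames * m : m]
    return [FeatureVector(values=means[i], t_start=float(t_starts[i])) for i in range(n_frames)]


def label_frames(
    frames: Sequence[FeatureVector], recording: "GaitRecording"
) -> list[FeatureVector]:
    """Attach to each frame the majority label of its source samples.

    Ties are broken in favour of the tied label that occurs earliest within
    the block, which keeps labelling deterministic and order-stable.
    """
    if recording.labels is None:
        raise ValueError("recording is unlabeled; cannot label frames")
    if not frames:
        return []
    # Recover the block size from the frame timestamps: frames are contiguous
    # blocks starting at recording.t[0].
    dt = 1.0 / recording.sample_rate_hz
    m = int(round((frames[1].t_start - frames[0].t_start) / dt)) if len(frames) > 1 else len(recording)
    labeled = []
    for i, fv in enumerate(frames):
        block = recording.labels[i * m : (i + 1) * m]
        labeled.append(replace(fv, label=_majority_label(block)))
    return labeled


def _majority_label(codes: np.ndarray) -> Phase:
    counts = np.bincount(codes, minlength=len(Phase))
    best = counts.max()
    for code in codes:  # earliest sample among tied labels wins
        if counts[code] == best:
            return Phase(int(code))
    raise AssertionError("unreachable: non-empty block always has a majority candidate")


def fit_calibration(standing: "GaitRecording") -> CalibrationProfile:
    """Fit per-sensor baselines from a quiet-standing recording.

    Baselines are the per-sensor mean forces over the whole recording, which
    must span at least one second.  A near-zero mean on any sensor (dead
    sensor, or the wearer was not standing) raises :class:`CalibrationError`
    naming the sensor.
    """
    if len(recording := standing) / standing.sample_rate_hz < 1.0:
        raise CalibrationError("standing recording must span at least 1 s")
    means = recording.forces.mean(axis=0)
    for j, mean in enumerate(means):
        if mean <= 1e-9:
            raise CalibrationError(
                f"sensor {SENSOR_NAMES[j]} has near-zero standing force "
                f"({mean:.3g}); dead sensor or wearer not standing"
            )
    meta = {
        "n_samples": len(recording),
        "sample_rate_hz": recording.sample_rate_hz,
        "weight_kg": recording.weight_kg,
        "seed": recording.seed,
    }
    return CalibrationProfile(baselines=means, created_from=meta)


def apply_calibration(frame: FeatureVector, profile: CalibrationProfile) -> FeatureVector:
    """Normalise a frame by the standing baselines (1.0 = standing load)."""
    return replace(frame, values=frame.values / profile.baselines)


def fit_scaling(train: Sequence[FeatureVector]) -> ScalingParams:
    """Fit per-attribute min–max scaling on a training collection."""
    if len(train) < 2:
        raise ValueError("need at least 2 training vectors to fit scaling")
    x = np.stack([fv.values for fv in train])
    mins = x.min(axis=0)
    ranges = x.max(axis=0) - mins
    return ScalingParams(mins=mins, ranges=ranges)


def apply_scaling(frame: FeatureVector, params: ScalingParams) -> FeatureVector:
    """Apply fitted min–max scaling; a zero-range attribute maps to 0.

    Training attributes map into [0, 1]; out-of-sample values may fall
    outside that interval and are deliberately not clipped.
    """
    out = np.zeros(N_SENSORS)
    nz = params.ranges > 0
    out[nz] = (frame.values[nz] - params.mins[nz]) / params.ranges[nz]
    return replace(frame, values=out)
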