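"""Streaming classification loop and phase-change event emission.

Mirrors the deployed device: raw samples arrive one at a time, are
buffered into 50 ms frames, each completed frame is calibrated, scaled and
classified, and a phase event is emitted whenever the predicted phase
changes.  Output latency is exactly one frame plus the injected
transmission delay; classification never looks at samples beyond the
current frame (a causality contract the tests verify by prefix
equivalence).  The wireless link is not simulated — its latency is a
constant, configurable injected delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .knn import KnnModel, classify
from .phases import N_SENSORS, Phase
from .preprocess import (
    CalibrationProfile,
    FeatureVector,
    apply_calibration,
    apply_scaling,
)
from .synthetic import ForceSample

#: Default injected transmission delay (s); configurable, not a measured quantity.
DEFAULT_DELAY_S = 0.015


@dataclass(frozen=True)
class FrameLabel:
    """One classified frame of the stream."""

    t_start: float
    label: Phase


@dataclass(frozen=True)
class PhaseEvent:
    """A detected phase change, emitted after the injected delay."""

    t: float
    from_phase: Phase
    to_phase: Phase
    emitted_t: float

    def __post_init__(self) -> None:
        if self.from_phase is self.to_phase:
            raise ValueError("a phase event requires from_phase != to_phase")
        if self.emitted_t < self.t:
            raise ValueError("emitted_t cannot precede the event time")


def stream_classify(
    model: KnnModel,
    profile: CalibrationProfile | None,
    samples: Iterable[ForceSample],
    frame_rate_hz: float = 20.0,
    sample_rate_hz: float = 100.0,
    smoother: Callable[[Phase], Phase] | None = None,
) -> Iterator[FrameLabel]:
    """Classify a raw sample stream frame by frame (a lazy generator).

    Buffers ``m = sample_rate / frame_rate`` samples; on frame completion
    applies calibration (if a profile is given), the model's attribute
    scaling, and the classifier, then yields the frame label.  ``smoother``
    is an optional post-hoc hook (e.g. a majority filter) applied to each
    predicted label; by default predictions are emitted unfiltered, so
    cross-phase errors remain observable.
    """
    ratio = sample_rate_hz / frame_rate_hz
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 1e-9:
        raise ValueError(
            f"frame rate {frame_rate_hz} Hz does not divide sample rate "
            f"{sample_rate_hz} Hz to an integer block size"
        )
    buffer: list[np.ndarray] = []
    t_start = 0.0
    for sample in samples:
        forces = np.asarray(sample.forces, dtype=float)
        if forces.shape != (N_SENSORS,):
            raise ValueError(
                f"stream sample at t={sample.t} has {forces.size} forces, expected {N_SENSORS}"
            )
        if not buffer:
            t_start = float(sample.t)
        buffer.append(forces)
        if len(buffer) == m:
            frame = FeatureVector(values=np.mean(buffer, axis=0), t_start=t_start)
            if profile is not None:
                frame = apply_calibration(frame, profile)
            if model.scaling is not None:
                frame = apply_scaling(frame, model.scaling)
            label = classify(model, frame)[0]
            if smoother is not None:
                label = smoother(label)
            yield FrameLabel(t_start=t_start, label=label)
            buffer = []


def detect_events(
    frames: Sequence[FrameLabel], delay_s: float = DEFAULT_DELAY_S
) -> list[PhaseEvent]:
    """Emit one event per frame where the label differs from the previous one.

    ``emitted_t = t + delay_s`` models the transmission delay to the
    prosthesis controller.  An empty stream yields no events.
    """
    if delay_s < 0:
        raise ValueError(f"delay_s must be >= 0, got {delay_s}")
    events: list[PhaseEvent] = []
    for prev, cur in zip(frames, frames[1:]):
        if cur.label is not prev.label:
            events.append(
                PhaseEvent(
                    t=cur.t_start,
                    from_phase=prev.label,
                    to_phase=cur.label,
                    emitted_t=cur.t_start + delay_s,
                )
            )
    return events


def reconstruct_labels(
    initial: Phase, n_frames: int, frame_period_s: float, events: Sequence[PhaseEvent],
    t0: float = 0.0,
) -> list[Phase]:
    """Rebuild the per-frame label sequence from events plus the initial label.

    Inverse of :func:`detect_events`; useful for verifying that event
    emission is lossless.
    """
    labels = []
    current = initial
    by_t = {round((e.t - t0) / frame_period_s): e for e in events}
    for i in range(n_frames):
        if i in by_t:
            current = by_t[i].to_phase
        labels.append(current)
    return labels
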