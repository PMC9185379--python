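"""Synthetic five-channel plantar-pressure signal generator.

Emulates the signal morphology of a force-sensing-resistor (FSR) insole
with five sensors S1..S5 placed anterior (toes) to posterior (heel):

* swing — foot airborne, all channels near zero;
* heel strike — posterior sensor S5 dominant;
* toe-off — anterior sensor S1 dominant;
* quiet standing and midstance — near-uniform loading on all channels;
* foot flat and heel off — transitional junction patterns between the
  primary postures.

Walking speed compresses the cycle (period = stride length x 3.6 / speed
in km/h) while the phase-boundary ramp and the sensor's first-order lag
stay fixed in absolute time, so fast walking blurs the short junction
phases first.  Wearer weight scales all amplitudes linearly relative to a
reference wearer.  All randomness is explicit: the same seed yields a
bit-identical recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.signal import lfilter

from .phases import ALL_PHASES, N_SENSORS, Phase, WALKING_CYCLE
from .preprocess import FeatureVector, frame_signal, label_frames

#: Wearer weight (kg) at which the template amplitudes apply unscaled.
REFERENCE_WEIGHT_KG = 53.0

#: Default stride length (m); cycle period = stride * 3.6 / speed_kmh.
DEFAULT_STRIDE_LENGTH_M = 1.4

#: Default additive Gaussian noise (step-to-step FSR repeatability),
#: as a fraction of full-scale amplitude.
DEFAULT_NOISE_SD = 0.05


@dataclass(frozen=True)
class GaitTemplate:
    """Normalised target force levels and timing for one gait cycle.

    Parameters
    ----------
    amplitudes:
        7 x 5 matrix of target force levels in [0, 1]; rows follow the
        :class:`~gaitphase.phases.Phase` enumeration order, columns are
        sensors S1..S5.
    phase_fractions:
        Fraction of one cycle occupied by each of the six walking phases,
        in cycle order (HS, FF, MS, HO, TO, SW); strictly positive, sums
        to 1.
    ramp_time_s:
        Absolute width of the raised-cosine blend across each phase
        boundary.  Fixed in seconds, not cycle fractions, so that faster
        walking blurs a larger share of each (especially short) phase.
    sensor_lag_s:
        Time constant of the first-order low-pass emulating the mechanical
        and electrical response of the FSR stack.
    """

    amplitudes: np.ndarray
    phase_fractions: np.ndarray
    ramp_time_s: float = 0.05
    sensor_lag_s: float = 0.02

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        frac = np.asarray(self.phase_fractions, dtype=float)
        if amp.shape != (len(ALL_PHASES), N_SENSORS):
            raise ValueError(f"amplitudes must be {len(ALL_PHASES)}x{N_SENSORS}, got {amp.shape}")
        if np.any(amp < 0) or np.any(amp > 1):
            raise ValueError("amplitudes must lie in [0, 1]")
        if frac.shape != (len(WALKING_CYCLE),):
            raise ValueError("phase_fractions must have one entry per walking phase")
        if np.any(frac <= 0):
            raise ValueError("phase_fractions must be strictly positive")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError(f"phase_fractions must sum to 1, got {frac.sum()!r}")
        if self.ramp_time_s < 0:
            raise ValueError("ramp_time_s must be >= 0")
        if self.sensor_lag_s < 0:
            raise ValueError("sensor_lag_s must be >= 0")
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "phase_fractions", frac)

    def amplitude_row(self, phase: Phase) -> np.ndarray:
        """Target amplitudes (5,) for one phase."""
        return self.amplitudes[phase.value]


@dataclass(frozen=True)
class ForceSample:
    """One time point of the five-sensor stream."""

    t: float
    forces: np.ndarray
    label: Phase | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.forces, dtype=float)
        if f.shape != (N_SENSORS,):
            raise ValueError(f"a force sample must have {N_SENSORS} forces, got shape {f.shape}")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")
        object.__setattr__(self, "forces", f)


@dataclass
class GaitRecording:
    """A fixed-rate five-channel pressure recording with optional labels.

    ``forces`` is an (n, 5) non-negative array; ``labels``, when present,
    is an (n,) array of :class:`Phase` integer codes.  Timestamps are
    strictly increasing with constant spacing ``1 / sample_rate_hz``.
    """

    t: np.ndarray
    forces: np.ndarray
    sample_rate_hz: float
    speed_kmh: float = 0.0
    weight_kg: float = REFERENCE_WEIGHT_KG
    seed: int | None = None
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != N_SENSORS:
            raise ValueError(f"forces must be (n, {N_SENSORS}), got {self.forces.shape}")
        if len(self.t) != len(self.forces):
            raise ValueError("t and forces must have equal length")
        if np.any(self.forces < 0):
            raise ValueError("forces must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(np.abs(dts - 1.0 / self.sample_rate_hz) > 1e-6):
                raise ValueError("timestamps must be equally spaced at 1/sample_rate_hz")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.t),):
                raise ValueError("labels must align with samples")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def phase_labels(self) -> list[Phase] | None:
        if self.labels is None:
            return None
        return [Phase(int(c)) for c in self.labels]

    def samples(self) -> Iterator[ForceSample]:
        """Iterate over samples — the stream interface used by ``realtime``."""
        for i in range(len(self)):
            label = Phase(int(self.labels[i])) if self.labels is not None else None
            yield ForceSample(t=float(self.t[i]), forces=self.forces[i], label=label)


# Default target amplitudes, rows in Phase enumeration order
# (ST, HS, FF, MS, HO, TO, SW), columns S1 (toe) .. S5 (heel).
# Qualitative constraints: swing near zero everywhere; S5 dominant at heel
# strike; S1 dominant at toe-off; stand identical to midstance; the junction
# rows sit between their neighbours but lean towards the phase they are
# entering (foot flat towards midstance, heel off towards toe-off), which is
# how the junction postures present on a real insole as load transfers.
_DEFAULT_AMPLITUDES = np.array(
    [
        [0.50, 0.50, 0.50, 0.50, 0.50],  # STAND
        [0.05, 0.05, 0.08, 0.15, 0.90],  # HEEL_STRIKE
        [0.35, 0.40, 0.45, 0.50, 0.65],  # FOOT_FLAT
        [0.50, 0.50, 0.50, 0.50, 0.50],  # MIDSTANCE
        [0.75, 0.35, 0.25, 0.20, 0.15],  # HEEL_OFF
        [0.90, 0.15, 0.08, 0.05, 0.05],  # TOE_OFF
        [0.02, 0.02, 0.02, 0.02, 0.02],  # SWING
    ]
)

# Cycle-order fractions (HS, FF, MS, HO, TO, SW): stance ~70%, swing 30%.
_DEFAULT_FRACTIONS = np.array([0.10, 0.15, 0.20, 0.15, 0.10, 0.30])


def make_default_template() -> GaitTemplate:
    """Return the default gait template (deterministic, no randomness)."""
    return GaitTemplate(
        amplitudes=_DEFAULT_AMPLITUDES.copy(),
        phase_fractions=_DEFAULT_FRACTIONS.copy(),
        ramp_time_s=0.05,
        sensor_lag_s=0.02,
    )


def cycle_period_s(speed_kmh: float, stride_length_m: float = DEFAULT_STRIDE_LENGTH_M) -> float:
    """Gait-cycle period in seconds at a given treadmill speed."""
    if speed_kmh <= 0:
        raise ValueError(f"speed_kmh must be positive, got {speed_kmh}")
    return stride_length_m * 3.6 / speed_kmh


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def _smooth_transitions(target: np.ndarray, ramp_time_s: float, fs: float) -> np.ndarray:
    """Blend phase boundaries with a normalized raised-cosine (Hann) kernel."""
    width = int(round(ramp_time_s * fs))
    if width <= 1:
        return target
    kernel = np.hanning(width + 2)[1:-1]
    kernel = kernel / kernel.sum()
    norm = np.convolve(np.ones(len(target)), kernel, mode="same")
    out = np.empty_like(target)
    for j in range(target.shape[1]):
        out[:, j] = np.convolve(target[:, j], kernel, mode="same") / norm
    return out


def _first_order_lag(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """First-order low-pass, initialised at steady state for x[0]."""
    if tau_s <= 0:
        return x
    alpha = 1.0 - math.exp(-1.0 / (fs * tau_s))
    b, a = [alpha], [1.0, alpha - 1.0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j], _ = lfilter(b, a, x[:, j], zi=[(1.0 - alpha) * x[0, j]])
    return out


def simulate_recording(
    template: GaitTemplate,
    speed_kmh: float,
    weight_kg: float = REFERENCE_WEIGHT_KG,
    duration_s: float = 10.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
    stride_length_m: float = DEFAULT_STRIDE_LENGTH_M,
) -> GaitRecording:
    """Simulate a labelled walking recording at a fixed treadmill speed.

    Each cycle traverses the six walking phases in cycle order with
    durations ``phase_fractions * period``.  The per-sample target force is
    ``weight_kg / 53 * amplitude`` of the current phase, blended across
    boundaries by a raised-cosine ramp of absolute width ``ramp_time_s``,
    passed through the first-order sensor lag, then perturbed by additive
    Gaussian noise truncated at zero.  Every sample is labelled with the
    phase whose interval contains the sample's midpoint.
    """
    _require_positive(speed_kmh=speed_kmh, weight_kg=weight_kg, duration_s=duration_s,
                      sample_rate_hz=sample_rate_hz)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    fs = float(sample_rate_hz)
    dt = 1.0 / fs
    n = int(round(duration_s * fs))
    t = np.arange(n) * dt
    period = cycle_period_s(speed_kmh, stride_length_m)
    edges = np.concatenate(([0.0], np.cumsum(template.phase_fractions))) * period

    def cycle_index(times: np.ndarray) -> np.ndarray:
        tau = np.mod(times, period)
        return np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, len(WALKING_CYCLE) - 1)

    cycle_codes = np.array([p.value for p in WALKING_CYCLE])
    amp_by_cycle_pos = template.amplitudes[cycle_codes]  # (6, 5)
    # Plantar load transfer anticipates the kinematic phase boundary: phase
    # labels follow foot-posture events, which trail the pressure
    # redistribution, so the SENSED transition (raised-cosine ramp followed
    # by the sensor's first-order lag) completes roughly at the boundary.
    # Implemented by advancing the target by one ramp width before the
    # centered smoothing.  Consequently the late part of each labeled phase
    # already shows the next phase's load pattern — the origin of the
    # forward "cross-phase" error mode, and increasingly so at high speed
    # where the fixed-width ramp covers a growing share of each phase.
    # Both the target and the label are evaluated at the sample midpoint
    # (a sample represents the interval [t, t + dt)).
    target = amp_by_cycle_pos[cycle_index(t + 0.5 * dt + template.ramp_time_s)]
    target = _smooth_transitions(target, template.ramp_time_s, fs)
    target = _first_order_lag(target, template.sensor_lag_s, fs)
    forces = (weight_kg / REFERENCE_WEIGHT_KG) * target
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        forces = forces + rng.normal(0.0, noise_sd, size=forces.shape)
    forces = np.maximum(forces, 0.0)
    labels = cycle_codes[cycle_index(t + 0.5 * dt)]
    return GaitRecording(
        t=t, forces=forces, sample_rate_hz=fs, speed_kmh=speed_kmh,
        weight_kg=weight_kg, seed=seed, labels=labels,
    )


def simulate_standing(
    template: GaitTemplate,
    weight_kg: float = REFERENCE_WEIGHT_KG,
    duration_s: float = 10.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
) -> GaitRecording:
    """Simulate a quiet-standing recording (all samples labelled STAND)."""
    _require_positive(weight_kg=weight_kg, duration_s=duration_s, sample_rate_hz=sample_rate_hz)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    fs = float(sample_rate_hz)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    forces = np.tile(
        (weight_kg / REFERENCE_WEIGHT_KG) * template.amplitude_row(Phase.STAND), (n, 1)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        forces = forces + rng.normal(0.0, noise_sd, size=forces.shape)
    forces = np.maximum(forces, 0.0)
    labels = np.full(n, Phase.STAND.value, dtype=np.int64)
    return GaitRecording(
        t=t, forces=forces, sample_rate_hz=fs, speed_kmh=0.0,
        weight_kg=weight_kg, seed=seed, labels=labels,
    )


def make_dataset(
    template: GaitTemplate,
    n_per_class: int,
    speed_kmh: float = 4.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    weight_kg: float = REFERENCE_WEIGHT_KG,
    sample_rate_hz: float = 100.0,
    frame_rate_hz: float = 20.0,
) -> list[FeatureVector]:
    """Build a balanced labelled frame dataset: ``n_per_class`` frames per phase.

    Simulates walking (six walking phases) and quiet standing (STAND) long
    enough to yield at least ``n_per_class`` frames of every phase, then
    subsamples each class to exactly ``n_per_class`` frames.  Deterministic
    under ``seed``.  At 70 frames per class this reproduces the 490-vector
    training-set size of the reference protocol.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    period = cycle_period_s(speed_kmh)
    frame_s = 1.0 / frame_rate_hz
    for frac, phase in zip(template.phase_fractions, WALKING_CYCLE):
        if frac * period < frame_s:
            raise ValueError(
                f"phase {phase.name} lasts {frac * period:.3f} s per cycle at "
                f"{speed_kmh} km/h, shorter than one {frame_s:.3f} s frame; "
                f"cannot guarantee frames of this phase"
            )
    rng = np.random.default_rng(seed)
    walk_seed, stand_seed, sub_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))

    min_frames_per_cycle = max(1, int(template.phase_fractions.min() * period / frame_s))
    duration = period * (math.ceil(1.3 * n_per_class / min_frames_per_cycle) + 1)
    walking_frames: list[FeatureVector] = []
    for _ in range(5):
        rec = simulate_recording(
            template, speed_kmh=speed_kmh, weight_kg=weight_kg, duration_s=duration,
            noise_sd=noise_sd, sample_rate_hz=sample_rate_hz, seed=walk_seed,
        )
        walking_frames = label_frames(frame_signal(rec, frame_rate_hz), rec)
        counts = {p: sum(1 for f in walking_frames if f.label is p) for p in WALKING_CYCLE}
        short = [p for p, c in counts.items() if c < n_per_class]
        if not short:
            break
        duration *= 2
    else:
        raise ValueError(
            f"phase {short[0].name} yielded too few frames at {speed_kmh} km/h "
            f"even after extending the simulation"
        )

    standing = simulate_standing(
        template, weight_kg=weight_kg, duration_s=n_per_class * frame_s + 1.0,
        noise_sd=noise_sd, seed=stand_seed, sample_rate_hz=sample_rate_hz,
    )
    standing_frames = label_frames(frame_signal(standing, frame_rate_hz), standing)

    all_frames = walking_frames + standing_frames
    sub_rng = np.random.default_rng(sub_seed)
    dataset: list[FeatureVector] = []
    for phase in ALL_PHASES:
        idx = [i for i, f in enumerate(all_frames) if f.label is phase]
        chosen = sorted(sub_rng.choice(len(idx), size=n_per_class, replace=False))
        dataset.extend(all_frames[idx[i]] for i in chosen)
    return dataset
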