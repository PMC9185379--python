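"""Readers and writers for the package's plain-text file formats.

All CSV files are comma-separated, ``.`` decimal, UTF-8, LF line endings,
header required.  Recording files carry time (6 decimals), five forces
(full float precision, so round-trips are lossless) and an optional phase
column with the phase enumeration name.  JSON carries templates,
calibration profiles and evaluation reports; models have their own
round-trip functions in :mod:`gaitphase.knn`.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phases import ALL_PHASES, N_SENSORS, Phase
from .preprocess import CalibrationProfile, FeatureVector
from .realtime import PhaseEvent
from .evaluation import EvalReport, SpeedResult
from .synthetic import GaitRecording, GaitTemplate

RECORDING_COLUMNS = ["t", "s1", "s2", "s3", "s4", "s5"]
FEATURE_COLUMNS = ["t_start", "f1", "f2", "f3", "f4", "f5"]


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


def write_recording(recording: GaitRecording, path: str | Path) -> None:
    """Write a recording CSV: ``t,s1..s5[,phase]``, one row per sample."""
    labeled = recording.labels is not None
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RECORDING_COLUMNS + (["phase"] if labeled else []))
        for i in range(len(recording)):
            row = [f"{recording.t[i]:.6f}"] + [repr(float(v)) for v in recording.forces[i]]
            if labeled:
                row.append(Phase(int(recording.labels[i])).name)
            writer.writerow(row)


def read_recording(
    path: str | Path,
    speed_kmh: float = 0.0,
    weight_kg: float | None = None,
) -> GaitRecording:
    """Read a recording CSV written by :func:`write_recording`.

    The sample rate is recovered from the (constant) timestamp spacing.
    Malformed rows raise :class:`ParseError` naming the 1-based line.
    """
    path = Path(path)
    times: list[float] = []
    forces: list[list[float]] = []
    labels: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        if [h.strip().lower() for h in header[: 1 + N_SENSORS]] != RECORDING_COLUMNS:
            raise ParseError(
                f"{path}, line 1: expected columns {','.join(RECORDING_COLUMNS)}[,phase], "
                f"got {','.join(header)}"
            )
        has_phase = len(header) == 2 + N_SENSORS and header[-1].strip().lower() == "phase"
        if len(header) not in (1 + N_SENSORS, 2 + N_SENSORS) or (
            len(header) == 2 + N_SENSORS and not has_phase
        ):
            raise ParseError(f"{path}, line 1: unexpected trailing columns {header[1 + N_SENSORS:]}")
        expected = len(header)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != expected:
                raise ParseError(
                    f"{path}, line {lineno}: expected {expected} fields, got {len(row)}"
                )
            try:
                times.append(float(row[0]))
                forces.append([float(v) for v in row[1 : 1 + N_SENSORS]])
            except ValueError:
                raise ParseError(f"{path}, line {lineno}: non-numeric value in {row}") from None
            if has_phase:
                name = row[-1].strip()
                try:
                    labels.append(Phase[name].value)
                except KeyError:
                    raise ParseError(
                        f"{path}, line {lineno}: unknown phase name {name!r}"
                    ) from None
            if len(times) > 1 and times[-1] <= times[-2]:
                raise ParseError(f"{path}, line {lineno}: non-monotone timestamp {row[0]}")
    if not times:
        raise ParseError(f"{path}: no data rows")
    t = np.array(times)
    if len(t) > 1:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    else:
        sample_rate = 100.0
    return GaitRecording(
        t=t,
        forces=np.array(forces),
        sample_rate_hz=round(sample_rate, 6),
        speed_kmh=speed_kmh,
        weight_kg=weight_kg if weight_kg is not None else float("nan"),
        labels=np.array(labels, dtype=np.int64) if labels else None,
    )


def write_features(frames: Sequence[FeatureVector], path: str | Path) -> None:
    """Write a features CSV: ``t_start,f1..f5[,phase]``."""
    labeled = any(fv.label is not None for fv in frames)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(FEATURE_COLUMNS + (["phase"] if labeled else []))
        for fv in frames:
            row = [f"{fv.t_start:.6f}"] + [repr(float(v)) for v in fv.values]
            if labeled:
                row.append(fv.label.name if fv.label is not None else "")
            writer.writerow(row)


def read_features(path: str | Path) -> list[FeatureVector]:
    """Read a features CSV written by :func:`write_features`."""
    path = Path(path)
    out: list[FeatureVector] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[: 1 + N_SENSORS]] != FEATURE_COLUMNS:
            raise ParseError(f"{path}, line 1: expected columns {','.join(FEATURE_COLUMNS)}[,phase]")
        has_phase = len(header) == 2 + N_SENSORS
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t_start = float(row[0])
                values = np.array([float(v) for v in row[1 : 1 + N_SENSORS]])
            except (ValueError, IndexError):
                raise ParseError(f"{path}, line {lineno}: malformed row {row}") from None
            label = None
            if has_phase and len(row) > 1 + N_SENSORS and row[-1].strip():
                try:
                    label = Phase[row[-1].strip()]
                except KeyError:
                    raise ParseError(f"{path}, line {lineno}: unknown phase {row[-1]!r}") from None
            out.append(FeatureVector(values=values, t_start=t_start, label=label))
    return out


def save_template(template: GaitTemplate, path: str | Path) -> None:
    """Serialise a template as JSON (amplitude rows in phase-enum order)."""
    payload = {
        "amplitudes": template.amplitudes.tolist(),
        "phase_fractions": template.phase_fractions.tolist(),
        "ramp_time_s": template.ramp_time_s,
        "sensor_lag_s": template.sensor_lag_s,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_template(path: str | Path) -> GaitTemplate:
    payload = json.loads(Path(path).read_text())
    return GaitTemplate(
        amplitudes=np.array(payload["amplitudes"], dtype=float),
        phase_fractions=np.array(payload["phase_fractions"], dtype=float),
        ramp_time_s=float(payload["ramp_time_s"]),
        sensor_lag_s=float(payload["sensor_lag_s"]),
    )


def save_calibration(profile: CalibrationProfile, path: str | Path) -> None:
    payload = {"baselines": profile.baselines.tolist(), "created_from": profile.created_from}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration(path: str | Path) -> CalibrationProfile:
    payload = json.loads(Path(path).read_text())
    return CalibrationProfile(
        baselines=np.array(payload["baselines"], dtype=float),
        created_from=payload.get("created_from", {}),
    )


def save_scaling(params, path: str | Path) -> None:
    payload = {"mins": params.mins.tolist(), "ranges": params.ranges.tolist()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_scaling(path: str | Path):
    from .preprocess import ScalingParams

    payload = json.loads(Path(path).read_text())
    return ScalingParams(
        mins=np.array(payload["mins"], dtype=float),
        ranges=np.array(payload["ranges"], dtype=float),
    )


def save_report(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def write_k_sweep(table: Sequence[tuple[int, float]], path: str | Path) -> None:
    pd.DataFrame(table, columns=["k", "accuracy_pct"]).to_csv(path, index=False, lineterminator="\n")


def write_speed_sweep(results: Sequence[SpeedResult], path: str | Path) -> None:
    rows = [
        {
            "speed_kmh": r.speed_kmh,
            "accuracy_pct": r.overall_accuracy_pct,
            "cross_phase_rate": r.cross_phase_rate,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def write_events(events: Sequence[PhaseEvent], path: str | Path) -> None:
    """Write an event log CSV: ``t,from_phase,to_phase,emitted_t``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["t", "from_phase", "to_phase", "emitted_t"])
        for e in events:
            writer.writerow([f"{e.t:.6f}", e.from_phase.name, e.to_phase.name, f"{e.emitted_t:.6f}"])
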