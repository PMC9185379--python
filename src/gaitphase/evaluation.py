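"""Evaluation protocol: stratified split, confusion matrix, per-class
metrics, k-sweep, speed-sweep and cross-phase-prediction analysis.

Terminology note: the per-class "accuracy (%)" column of the report is
per-class recall x 100 — the convention of the reference report format —
and the macro accuracy is the unweighted mean of those seven values.
Overall accuracy is trace(confusion) / total.  "Cross-phase prediction" is
the error mode of predicting the cycle-successor of the true phase (e.g.
foot flat misread as midstance): the classifier runs ahead of the gait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import knn
from .phases import (
    ALL_PHASES,
    JUNCTION_PHASES,
    N_PHASES,
    Phase,
    WALKING_PHASES,
    cycle_successor,
)
from .preprocess import FeatureVector, apply_calibration, fit_calibration
from .synthetic import (
    DEFAULT_NOISE_SD,
    GaitTemplate,
    REFERENCE_WEIGHT_KG,
    make_dataset,
    simulate_standing,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """7x7 count matrix, rows = true phase, columns = predicted phase."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_PHASES, N_PHASES):
            raise ValueError(f"confusion matrix must be {N_PHASES}x{N_PHASES}, got {c.shape}")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, phase: Phase) -> int:
        return int(self.counts[phase.value].sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    accuracy_pct: float  # recall x 100, the report-table convention


@dataclass(frozen=True)
class EvalReport:
    """Per-class and aggregate metrics derived from a confusion matrix."""

    confusion: ConfusionMatrix
    per_class: dict[Phase, ClassMetrics]
    macro_accuracy_pct: float
    overall_accuracy_pct: float
    cross_phase_rate: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "per_class": {
                p.name: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "accuracy_pct": m.accuracy_pct,
                }
                for p, m in self.per_class.items()
            },
            "macro_accuracy_pct": self.macro_accuracy_pct,
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "cross_phase_rate": self.cross_phase_rate,
        }

    def format_text(self) -> str:
        """Aligned table: precision/recall/F1 at 3 d.p., percentages at 2 d.p."""
        lines = [
            f"{'Gait Cycle':<12}{'Precision':>10}{'Recall':>8}{'F1-Score':>10}{'Accuracy (%)':>14}"
        ]
        for phase in ALL_PHASES:
            m = self.per_class[phase]
            lines.append(
                f"{phase.name.replace('_', ' ').title():<12}"
                f"{m.precision:>10.3f}{m.recall:>8.3f}{m.f1:>10.3f}{m.accuracy_pct:>14.2f}"
            )
        lines.append(f"{'Macro':<12}{'':>10}{'':>8}{'':>10}{self.macro_accuracy_pct:>14.2f}")
        lines.append(f"{'Overall':<12}{'':>10}{'':>8}{'':>10}{self.overall_accuracy_pct:>14.2f}")
        lines.append(f"Cross-phase rate among errors: {self.cross_phase_rate:.3f}")
        return "\n".join(lines)


def train_test_split(
    data: Sequence[FeatureVector], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Stratified split: per class, floor(fraction x n) to train, rest to test.

    Classes are shuffled independently with the seed; the two parts are
    disjoint and exhaustive.  With 100 frames per class and fraction 0.7
    this gives the 490/210 protocol split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if any(fv.label is None for fv in data):
        raise ValueError("all vectors must be labeled for a stratified split")
    rng = np.random.default_rng(seed)
    train: list[FeatureVector] = []
    test: list[FeatureVector] = []
    for phase in ALL_PHASES:
        idx = [i for i, fv in enumerate(data) if fv.label is phase]
        if not idx:
            continue
        if len(idx) < 2:
            raise ValueError(f"class {phase.name} has fewer than 2 members; cannot split")
        order = rng.permutation(len(idx))
        n_train = int(np.floor(train_fraction * len(idx)))
        train.extend(data[idx[i]] for i in order[:n_train])
        test.extend(data[idx[i]] for i in order[n_train:])
    return train, test


def confusion(true: Iterable[Phase], pred: Iterable[Phase]) -> ConfusionMatrix:
    """Count (true, predicted) phase pairs into a 7x7 matrix."""
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ValueError(f"label sequences differ in length: {len(true)} vs {len(pred)}")
    if not true:
        raise ValueError("cannot build a confusion matrix from empty label sequences")
    counts = np.zeros((N_PHASES, N_PHASES), dtype=np.int64)
    for t, p in zip(true, pred):
        counts[t.value, p.value] += 1
    return ConfusionMatrix(counts)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def macro_average_pct(accuracies_pct: Sequence[float]) -> float:
    """Unweighted mean of per-class accuracy percentages (macro accuracy)."""
    if len(accuracies_pct) == 0:
        raise ValueError("cannot average an empty sequence")
    return float(np.mean(accuracies_pct))


def per_class_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Derive the full report from a confusion matrix.

    Per class c: precision = cm[c,c]/colsum(c) (0 when the column is
    empty), recall = cm[c,c]/rowsum(c), F1 = 2PR/(P+R) (0 when P+R = 0),
    accuracy_pct = recall x 100.  Macro accuracy averages the seven
    accuracy_pct values unweighted; overall accuracy is trace/total.
    Values are kept unrounded; rounding happens only at display time.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    c = cm.counts
    per_class: dict[Phase, ClassMetrics] = {}
    for phase in ALL_PHASES:
        i = phase.value
        colsum = c[:, i].sum()
        rowsum = c[i, :].sum()
        precision = float(c[i, i] / colsum) if colsum > 0 else 0.0
        recall = float(c[i, i] / rowsum) if rowsum > 0 else 0.0
        per_class[phase] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1=f1_score(precision, recall),
            accuracy_pct=100.0 * recall,
        )
    macro = macro_average_pct([m.accuracy_pct for m in per_class.values()])
    overall = 100.0 * float(np.trace(c)) / cm.total
    return EvalReport(
        confusion=cm,
        per_class=per_class,
        macro_accuracy_pct=macro,
        overall_accuracy_pct=overall,
        cross_phase_rate=cross_phase_rate_from_cm(cm),
    )


def cross_phase_rate_from_cm(
    cm: ConfusionMatrix, true_phases: frozenset[Phase] | None = None
) -> float:
    """Fraction of misclassified walking-phase frames predicted one phase early.

    The denominator counts misclassified frames whose true phase lies in
    ``true_phases`` (default: all six walking phases; STAND is always
    excluded since it has no cycle successor); the numerator counts those
    whose prediction is the cycle-successor of the truth.  Returns 0.0
    when there are no such errors.
    """
    phases = WALKING_PHASES if true_phases is None else (true_phases & WALKING_PHASES)
    c = cm.counts
    errors = 0
    ahead = 0
    for phase in phases:
        i = phase.value
        row_errors = int(c[i].sum() - c[i, i])
        errors += row_errors
        ahead += int(c[i, cycle_successor(phase).value])
    return ahead / errors if errors else 0.0


def cross_phase_rate(
    true: Sequence[Phase], pred: Sequence[Phase],
    true_phases: frozenset[Phase] | None = None,
) -> float:
    """Cross-phase rate computed directly from label sequences."""
    return cross_phase_rate_from_cm(confusion(true, pred), true_phases=true_phases)


def evaluate(model: knn.KnnModel, test: Sequence[FeatureVector]) -> EvalReport:
    """Run the model over labelled raw frames and build the full report."""
    if any(fv.label is None for fv in test):
        raise ValueError("all test vectors must be labeled")
    preds = knn.predict(model, test)
    return per_class_metrics(confusion([fv.label for fv in test], preds))


def k_sweep(
    train: Sequence[FeatureVector],
    validation: Sequence[FeatureVector],
    k_candidates: Sequence[int] = knn.DEFAULT_K_GRID,
    weighting: str = knn.DISTANCE_WEIGHTED,
    scale: bool = True,
) -> tuple[int, list[tuple[int, float]]]:
    """Validation accuracy (%) per odd k; returns (best k, sweep table)."""
    best_k, accuracies = knn.select_k(
        train, validation, k_candidates=k_candidates, weighting=weighting, scale=scale
    )
    table = [(k, accuracies[k]) for k in k_candidates]
    return best_k, table


@dataclass(frozen=True)
class SpeedResult:
    speed_kmh: float
    overall_accuracy_pct: float
    cross_phase_rate: float
    confusion: ConfusionMatrix


def speed_sweep(
    template: GaitTemplate,
    speeds: Sequence[float],
    n_train_per_class: int = 70,
    n_test_per_class: int = 30,
    train_speed_kmh: float = 4.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    weight_kg: float = REFERENCE_WEIGHT_KG,
    k: int = 3,
    weighting: str = knn.DISTANCE_WEIGHTED,
    scale: bool = True,
    seed: int = 0,
    model: knn.KnnModel | None = None,
    profile=None,
) -> list[SpeedResult]:
    """Accuracy vs walking speed with a model trained at one reference speed.

    Trains once (at ``train_speed_kmh``, after standing calibration), then
    simulates a fresh labelled test set per speed and reports overall
    accuracy and the cross-phase rate.  Deterministic under ``seed``.  A
    pre-trained ``model``/``profile`` pair may be supplied to evaluate the
    same fixed model across sweeps.
    """
    rng = np.random.default_rng(seed)
    cal_seed, train_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    if profile is None:
        standing = simulate_standing(
            template, weight_kg=weight_kg, duration_s=10.0, noise_sd=noise_sd, seed=cal_seed
        )
        profile = fit_calibration(standing)
    if model is None:
        train_frames = make_dataset(
            template, n_per_class=n_train_per_class, speed_kmh=train_speed_kmh,
            noise_sd=noise_sd, seed=train_seed, weight_kg=weight_kg,
        )
        train_frames = [apply_calibration(fv, profile) for fv in train_frames]
        model = knn.fit(train_frames, k=k, weighting=weighting, scale=scale)
    results = []
    for speed in speeds:
        test_seed = int(rng.integers(0, 2**31 - 1))
        test_frames = make_dataset(
            template, n_per_class=n_test_per_class, speed_kmh=speed,
            noise_sd=noise_sd, seed=test_seed, weight_kg=weight_kg,
        )
        test_frames = [apply_calibration(fv, profile) for fv in test_frames]
        preds = knn.predict(model, test_frames)
        cm = confusion([fv.label for fv in test_frames], preds)
        results.append(
            SpeedResult(
                speed_kmh=float(speed),
                overall_accuracy_pct=100.0 * float(np.trace(cm.counts)) / cm.total,
                cross_phase_rate=cross_phase_rate_from_cm(cm),
                confusion=cm,
            )
        )
    return results


#: Primary walking phases (the junction phases' complement within the cycle).
PRIMARY_PHASES: frozenset[Phase] = WALKING_PHASES - JUNCTION_PHASES
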