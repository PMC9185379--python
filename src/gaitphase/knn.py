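"""From-scratch k-nearest-neighbor gait-phase classifier.

The classifier stores the entire (scaled) training set.  A query frame is
compared with every training frame by Euclidean distance

    Dist(p, q) = sqrt( sum_i (q_i - p_i)^2 ),  i = 1..5,

and the k nearest neighbors vote.  In *uniform* mode each neighbor casts a
unit vote; in *distance-weighted* mode each casts its Dudani weight

    w_i = (d_k - d_i) / (d_k - d_1)   if k != 1   (w_i = 1 if k = 1),

computed on distances sorted ascending, so the nearest neighbor carries
weight 1 and the k-th weight 0.  k is required to be odd.  Deterministic
tie rules (documented on each operation) make classification a pure
function of the model and the query.

Brute force over the full training set is the intended behaviour: training
sets here are a few hundred points, so no spatial index is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .phases import ALL_PHASES, N_SENSORS, Phase
from .preprocess import FeatureVector, ScalingParams, apply_scaling, fit_scaling

UNIFORM = "uniform"
DISTANCE_WEIGHTED = "distance_weighted"
WEIGHTING_MODES = (UNIFORM, DISTANCE_WEIGHTED)

#: Odd k values 1..15, the default model-selection grid.
DEFAULT_K_GRID: tuple[int, ...] = tuple(range(1, 16, 2))


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest training points of one query, sorted by distance.

    ``distances`` ascending; ``labels`` are phase codes; ``indices`` are
    positions in the training set (ties at the k-th distance are resolved
    by insertion order, earlier wins).
    """

    distances: np.ndarray
    labels: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if len(d) == 0:
            raise ValueError("a neighbor set cannot be empty")
        if np.any(np.diff(d) < 0):
            raise ValueError("neighbor distances must be sorted ascending")

    @property
    def k(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class KnnModel:
    """A fitted kNN gait-phase model: k, voting mode, scaling, training data.

    ``x`` holds the training vectors *after* attribute scaling (when
    ``scaling`` is not None); queries passed to :func:`classify` must be
    scaled the same way — :func:`predict` does this for raw frames.
    """

    k: int
    weighting: str
    x: np.ndarray
    y: np.ndarray
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=np.int64)
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")
        if x.ndim != 2 or x.shape[1] != N_SENSORS:
            raise ValueError(f"training matrix must be (n, {N_SENSORS}), got {x.shape}")
        if len(x) != len(y):
            raise ValueError("training matrix and labels must align")
        if len(x) == 0:
            raise ValueError("training set must be non-empty")
        if self.k > len(x):
            raise ValueError(f"k={self.k} exceeds training-set size {len(x)}")
        if self.weighting not in WEIGHTING_MODES:
            raise ValueError(f"weighting must be one of {WEIGHTING_MODES}, got {self.weighting!r}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_train(self) -> int:
        return len(self.x)


def fit(
    train: Sequence[FeatureVector],
    k: int = 3,
    weighting: str = DISTANCE_WEIGHTED,
    scale: bool = True,
) -> KnnModel:
    """Fit a model: store the training set, optionally min–max scaled.

    Scaling parameters are fitted on the training data only and kept in
    the model so queries are transformed identically at predict time.
    """
    if not train:
        raise ValueError("training set must be non-empty")
    if any(fv.label is None for fv in train):
        raise ValueError("all training vectors must be labeled")
    scaling = fit_scaling(train) if scale else None
    vectors = [apply_scaling(fv, scaling) if scaling else fv for fv in train]
    x = np.stack([fv.values for fv in vectors])
    y = np.array([fv.label.value for fv in train], dtype=np.int64)
    return KnnModel(k=k, weighting=weighting, x=x, y=y, scaling=scaling)


def euclidean_distance(p: FeatureVector | np.ndarray, q: FeatureVector | np.ndarray) -> float:
    """Euclidean distance between two five-sensor feature vectors."""
    pv = p.values if isinstance(p, FeatureVector) else np.asarray(p, dtype=float)
    qv = q.values if isinstance(q, FeatureVector) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"dimension mismatch: {pv.shape} vs {qv.shape}")
    return float(np.sqrt(np.sum((qv - pv) ** 2)))


def find_neighbors(model: KnnModel, x: FeatureVector | np.ndarray) -> NeighborSet:
    """The k training points nearest to a (scaled) query, sorted ascending.

    Exact distance ties at the k-th slot are broken by training-set
    insertion order (earlier wins), via a stable argsort.
    """
    xv = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if xv.shape != (N_SENSORS,):
        raise ValueError(f"query must have {N_SENSORS} values, got shape {xv.shape}")
    d = np.sqrt(np.sum((model.x - xv) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[: model.k]
    return NeighborSet(distances=d[order], labels=model.y[order], indices=order)


def dudani_weights(neighbors: NeighborSet | np.ndarray) -> np.ndarray:
    """Distance-based voting weights for a sorted neighbor set.

    w_1 = 1 and w_k = 0 whenever the distances are not all equal; if
    d_k = d_1 (all neighbors equidistant — the formula degenerates to 0/0)
    every weight is set to 1, reducing to uniform voting among
    indistinguishable neighbors.
    """
    d = neighbors.distances if isinstance(neighbors, NeighborSet) else np.asarray(neighbors, dtype=float)
    k = len(d)
    if k == 1:
        return np.ones(1)
    d1, dk = d[0], d[-1]
    if dk == d1:
        return np.ones(k)
    return (dk - d) / (dk - d1)


def classify(
    model: KnnModel, x: FeatureVector | np.ndarray
) -> tuple[Phase, dict[Phase, float]]:
    """Classify one scaled query; returns (phase, per-class score table).

    Uniform mode sums unit votes per class; distance-weighted mode sums
    Dudani weights.  Score ties are broken by (a) the smaller summed
    neighbor distance, then (b) phase enumeration order, so the result is
    fully deterministic.
    """
    neighbors = find_neighbors(model, x)
    if model.weighting == DISTANCE_WEIGHTED:
        votes = dudani_weights(neighbors)
    else:
        votes = np.ones(neighbors.k)
    scores = np.zeros(len(ALL_PHASES))
    dist_sums = np.full(len(ALL_PHASES), np.inf)
    for d, code, v in zip(neighbors.distances, neighbors.labels, votes):
        scores[code] += v
        if not np.isfinite(dist_sums[code]):
            dist_sums[code] = 0.0
        dist_sums[code] += d
    best = scores.max()
    candidates = [c for c in range(len(ALL_PHASES)) if scores[c] == best]
    winner = min(candidates, key=lambda c: (dist_sums[c], c))
    table = {phase: float(scores[phase.value]) for phase in ALL_PHASES}
    return Phase(winner), table


def predict(model: KnnModel, frames: Sequence[FeatureVector]) -> list[Phase]:
    """Scale raw frames with the model's scaling (if any) and classify each."""
    out = []
    for fv in frames:
        q = apply_scaling(fv, model.scaling) if model.scaling is not None else fv
        out.append(classify(model, q)[0])
    return out


def accuracy_pct(model: KnnModel, frames: Sequence[FeatureVector]) -> float:
    """Overall accuracy (%) of the model on labelled raw frames."""
    if not frames:
        raise ValueError("cannot score an empty collection")
    preds = predict(model, frames)
    hits = sum(1 for fv, p in zip(frames, preds) if fv.label is p)
    return 100.0 * hits / len(frames)


def select_k(
    train: Sequence[FeatureVector],
    validation: Sequence[FeatureVector],
    k_candidates: Sequence[int] = DEFAULT_K_GRID,
    weighting: str = DISTANCE_WEIGHTED,
    scale: bool = True,
) -> tuple[int, dict[int, float]]:
    """Pick the k with best validation accuracy; ties go to the smaller k.

    k candidates must be odd (an odd k avoids two-class vote ties); each
    candidate gets its own model fitted on ``train`` and scored on
    ``validation``.  Returns (best k, accuracy-% per candidate).
    """
    if not validation:
        raise ValueError("validation set must be non-empty")
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    for k in k_candidates:
        if k % 2 == 0 or k < 1:
            raise ValueError(f"k candidates must be odd positive integers, got {k}")
    accuracies: dict[int, float] = {}
    for k in k_candidates:
        model = fit(train, k=k, weighting=weighting, scale=scale)
        accuracies[k] = accuracy_pct(model, validation)
    best_k = None
    best_acc = -1.0
    for k in sorted(accuracies):
        if accuracies[k] > best_acc:
            best_k, best_acc = k, accuracies[k]
    return best_k, accuracies


def save_model(model: KnnModel, path: str | Path) -> None:
    """Serialise a model to JSON (lossless float round-trip via repr)."""
    payload = {
        "k": model.k,
        "weighting": model.weighting,
        "scaling": None
        if model.scaling is None
        else {"mins": model.scaling.mins.tolist(), "ranges": model.scaling.ranges.tolist()},
        "x": model.x.tolist(),
        "y": [Phase(int(c)).name for c in model.y],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> KnnModel:
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    scaling = None
    if payload.get("scaling") is not None:
        scaling = ScalingParams(
            mins=np.array(payload["scaling"]["mins"], dtype=float),
            ranges=np.array(payload["scaling"]["ranges"], dtype=float),
        )
    return KnnModel(
        k=int(payload["k"]),
        weighting=payload["weighting"],
        x=np.array(payload["x"], dtype=float),
        y=np.array([Phase[name].value for name in payload["y"]], dtype=np.int64),
        scaling=scaling,
    )
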