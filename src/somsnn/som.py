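"""Self-organizing map: unsupervised tonotopic feature map and spike encoding.

A rectangular Kohonen map is trained online on frame feature vectors.
Competition selects the best-matching unit (BMU, minimal Euclidean distance);
cooperation spreads the update over a Gaussian neighborhood on the grid, with
learning rate and neighborhood radius decaying exponentially over epochs.
After training, each sound frame is encoded as one spike per activated unit
(the top-K closest units), at a time given by the frame index times the frame
shift — the whole clip becomes a spatiotemporal spike pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .frontend import FeatureMatrix


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SOMConfig:
    rows: int = 8
    cols: int = 8
    epochs: int = 400
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: Optional[float] = None   # max(rows, cols)/2 if None
    radius_final: float = 1.0
    k_active: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 2:
            raise ValueError("SOM grid needs at least 2 units")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_initial >= self.lr_final > 0:
            raise ValueError("need lr_initial >= lr_final > 0")
        if self.radius_initial is not None and self.radius_initial < self.radius_final:
            raise ValueError("need radius_initial >= radius_final")
        if self.radius_final < 0:
            raise ValueError("radius_final must be >= 0")
        if self.k_active < 1:
            raise ValueError("k_active must be >= 1")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def initial_radius(self) -> float:
        if self.radius_initial is not None:
            return self.radius_initial
        return max(self.rows, self.cols) / 2.0


def grid_coordinates(rows: int, cols: int) -> np.ndarray:
    """Lattice points of the grid, row-major: unit u = r*cols + c -> (r, c)."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


@dataclass
class SOMModel:
    """A trained (or freshly initialized) map: weight vectors plus grid layout."""

    weights: np.ndarray          # n_units x n_features
    grid_coords: np.ndarray      # n_units x 2
    config: SOMConfig

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.grid_coords = np.asarray(self.grid_coords, dtype=np.int64)
        if self.weights.shape[0] != self.config.n_units:
            raise ValueError("weights row count must equal rows*cols")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("SOM weights must be finite")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


@dataclass
class SpikePattern:
    """Spatiotemporal spike pattern: (unit, time-ms) events sorted by time."""

    events: List[Tuple[int, float]]
    duration_ms: float
    n_units: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.events = [(int(u), float(t)) for u, t in self.events]
        times = [t for _, t in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("events must be sorted non-decreasing in time")
        for u, t in self.events:
            if not 0 <= u < self.n_units:
                raise ValueError(f"unit {u} out of range [0, {self.n_units})")
            if not 0.0 <= t <= self.duration_ms:
                raise ValueError(f"event time {t} outside [0, {self.duration_ms}]")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def unit_array(self) -> np.ndarray:
        return np.array([u for u, _ in self.events], dtype=np.int64)

    def time_array(self) -> np.ndarray:
        return np.array([t for _, t in self.events], dtype=np.float64)


# ---------------------------------------------------------------------------
# BMU queries
# ---------------------------------------------------------------------------

def _distances(model: SOMModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"feature vector of dim {x.shape} does not match "
            f"n_features={model.n_features}"
        )
    diff = model.weights - x[None, :]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def find_bmu(model: SOMModel, x: np.ndarray) -> int:
    """Index of the unit with minimal Euclidean distance to x (ties: lowest)."""
    return int(np.argmin(_distances(model, x)))


def top_k_units(model: SOMModel, x: np.ndarray, k: int) -> np.ndarray:
    """The k closest units, distance-ascending, ties broken by unit index."""
    if not 1 <= k <= model.n_units:
        raise ValueError(f"k={k} out of range [1, {model.n_units}]")
    d = _distances(model, x)
    # stable sort on distance gives index-order tie-breaking
    order = np.argsort(d, kind="stable")
    return order[:k]


def quantization_error(model: SOMModel, data: Iterable[np.ndarray]) -> float:
    """Mean Euclidean distance between each frame and its BMU weight vector."""
    frames = _stack_frames(data)
    if frames.shape[0] == 0:
        raise ValueError("quantization_error requires non-empty data")
    total = 0.0
    for x in frames:
        total += float(np.min(_distances(model, x)))
    return total / frames.shape[0]


def _stack_frames(data) -> np.ndarray:
    """Accept FeatureMatrix, iterable of FeatureMatrix, or raw 2-D arrays."""
    if isinstance(data, FeatureMatrix):
        return data.values
    if isinstance(data, np.ndarray):
        return np.atleast_2d(data)
    mats = []
    for item in data:
        mats.append(item.values if isinstance(item, FeatureMatrix) else np.atleast_2d(item))
    if not mats:
        return np.empty((0, 0))
    return np.vstack(mats)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_som(data, cfg: SOMConfig) -> SOMModel:
    """Online Kohonen training.

    Per presented frame x the BMU b is found and every unit u moves toward x
    by ``lr(t) * exp(-d_grid(u, b)^2 / (2 sigma(t)^2))``. Learning rate and
    radius decay exponentially from their initial to final values over the
    epochs; presentation order is reshuffled each epoch. Deterministic for a
    fixed seed. Weights are initialized uniformly within the per-feature
    min/max range of the data.
    """
    frames = _stack_frames(data)
    if frames.size == 0 or frames.shape[0] == 0:
        raise ValueError("train_som requires at least one frame")
    n_frames, n_features = frames.shape
    rng = np.random.default_rng(cfg.seed)

    lo = frames.min(axis=0)
    hi = frames.max(axis=0)
    weights = rng.uniform(lo, np.where(hi > lo, hi, lo + 1.0),
                          size=(cfg.n_units, n_features))

    coords = grid_coordinates(cfg.rows, cfg.cols).astype(np.float64)
    # pairwise squared grid distances, n_units x n_units
    diff = coords[:, None, :] - coords[None, :, :]
    grid_d2 = np.einsum("ijk,ijk->ij", diff, diff)

    r0 = max(cfg.initial_radius(), 1e-9)
    r1 = max(cfg.radius_final, 1e-9)
    for epoch in range(cfg.epochs):
        frac = epoch / max(cfg.epochs - 1, 1)
        lr = cfg.lr_initial * (cfg.lr_final / cfg.lr_initial) ** frac
        sigma = r0 * (r1 / r0) ** frac
        order = rng.permutation(n_frames)
        for i in order:
            x = frames[i]
            d2 = np.einsum("ij,ij->i", weights - x, weights - x)
            b = int(np.argmin(d2))
            h = np.exp(-grid_d2[b] / (2.0 * sigma * sigma))
            weights += (lr * h)[:, None] * (x - weights)

    return SOMModel(weights=weights,
                    grid_coords=grid_coordinates(cfg.rows, cfg.cols),
                    config=cfg)


# ---------------------------------------------------------------------------
# Spike encoding
# ---------------------------------------------------------------------------

def encode_features(model: SOMModel, feats: FeatureMatrix, k: int = 1) -> SpikePattern:
    """Encode a clip: for frame i the top-k units each emit one spike at
    ``i * frame_shift_ms`` (frame start, 0-based). Exactly ``k * n_frames``
    events; duration is ``n_frames * frame_shift_ms``."""
    if feats.n_frames == 0:
        raise ValueError("encode_features requires a non-empty FeatureMatrix")
    shift = feats.frame_shift_ms
    duration = feats.n_frames * shift
    events: List[Tuple[int, float]] = []
    for i in range(feats.n_frames):
        t = i * shift
        for u in top_k_units(model, feats.values[i], k):
            events.append((int(u), t))
    return SpikePattern(events=events, duration_ms=duration,
                        n_units=model.n_units, label=feats.label)


def encode_dataset(model: SOMModel, feats: Sequence[FeatureMatrix],
                   k: int = 1) -> List[SpikePattern]:
    return [encode_features(model, f, k) for f in feats]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(path, model: SOMModel) -> None:
    """Write the map as a self-describing JSON file (config + weights)."""
    payload = {
        "format": "somsnn-som-v1",
        "config": asdict(model.config),
        "n_units": model.n_units,
        "n_features": model.n_features,
        "weights": model.weights.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SOMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "somsnn-som-v1":
        raise ValueError(f"{path}: not a SOM model file")
    cfg = SOMConfig(**payload["config"])
    return SOMModel(weights=np.array(payload["weights"], dtype=np.float64),
                    grid_coords=grid_coordinates(cfg.rows, cfg.cols),
                    config=cfg)


def save_patterns(path, patterns: Sequence[SpikePattern]) -> None:
    """JSON-lines: one header record per pattern followed by its events."""
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(json.dumps({"n_units": p.n_units,
                                 "duration_ms": p.duration_ms,
                                 "label": p.label,
                                 "n_events": p.n_events}) + "\n")
            for u, t in p.events:
                fh.write(json.dumps({"unit": u, "t_ms": t}) + "\n")


def load_patterns(path) -> List[SpikePattern]:
    patterns: List[SpikePattern] = []
    with open(path) as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if "n_units" not in header:
            raise ValueError(f"{path}: malformed pattern stream at record {i}")
        n_ev = header["n_events"]
        events = [(rec["unit"], rec["t_ms"]) for rec in lines[i + 1: i + 1 + n_ev]]
        patterns.append(SpikePattern(events=events,
                                     duration_ms=header["duration_ms"],
                                     n_units=header["n_units"],
                                     label=header["label"]))
        i += 1 + n_ev
    return patterns
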