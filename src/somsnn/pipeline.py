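"""End-to-end orchestration: train the map and the spiking classifier on a
dataset (synthetic or WAV directory), then evaluate under clean, noisy,
early-decision and neuronal-noise conditions, writing CSV/JSON reports.

The three stages (front-end, map, classifier) are trained separately and
evaluated as one continuous pipeline. Every run records the configuration
hash and seeds, so reports are reproducible from (data, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import frontend, noise as noise_mod, snn, som, synthetic_data

logger = logging.getLogger("somsnn")


@dataclass
class SyntheticSpec:
    """Built-in dataset profile: C classes, n_train + n_test clips per class."""

    n_classes: int = 5
    n_train_per_class: int = 20
    n_test_per_class: int = 20
    sample_rate: int = 16000
    seed: int = 0


@dataclass
class ExperimentConfig:
    frontend_cfg: frontend.FrontendConfig = field(default_factory=frontend.FrontendConfig)
    som_cfg: som.SOMConfig = field(default_factory=lambda: som.SOMConfig(epochs=50))
    classifier_cfg: snn.ClassifierConfig = field(default_factory=snn.ClassifierConfig)
    noise_cfg: noise_mod.NoiseMixConfig = field(default_factory=noise_mod.NoiseMixConfig)
    synthetic: Optional[SyntheticSpec] = field(default_factory=SyntheticSpec)
    data_dir: Optional[str] = None        # WAV directory with labels.csv
    tau_m: float = 750.0
    tau_s: float = 187.5
    v_thr: float = 1.0
    margin: float = 0.5
    split_seed: int = 0
    multicondition: bool = False          # train on clean + noisy copies
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class EvaluationReport:
    mode: str
    accuracy: Dict[str, float]            # condition name -> accuracy [%]
    confusion: np.ndarray                 # rows: true class, cols: predicted
    decisions: pd.DataFrame               # per-sample decision records
    metadata: Dict[str, object]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.decisions.to_csv(out / f"decisions_{self.mode}.csv", index=False)
        with open(out / f"report_{self.mode}.json", "w") as fh:
            json.dump({"mode": self.mode,
                       "accuracy": self.accuracy,
                       "confusion": self.confusion.tolist(),
                       "metadata": _as_jsonable(self.metadata)}, fh, indent=2)


@dataclass
class PipelineModels:
    som_model: som.SOMModel
    neurons: List[snn.TempotronNeuron]
    epoch_errors: List[int]


# ---------------------------------------------------------------------------
# Data resolution
# ---------------------------------------------------------------------------

def load_wav_dataset(data_dir) -> List[frontend.AudioClip]:
    """WAV directory with a labels.csv (columns: filename, label)."""
    root = Path(data_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file: {labels_path}")
    table = pd.read_csv(labels_path)
    clips = []
    for _, row in table.iterrows():
        path = root / row["filename"]
        if not path.exists():
            raise FileNotFoundError(f"missing audio file: {path}")
        clips.append(frontend.read_wav(path, label=int(row["label"])))
    return clips


def resolve_datasets(cfg: ExperimentConfig,
                     ) -> Tuple[List[frontend.AudioClip], List[frontend.AudioClip]]:
    """Train/test clips: synthetic profile, or a stratified split of a WAV
    directory (disjoint, seeded)."""
    if cfg.data_dir is not None:
        clips = load_wav_dataset(cfg.data_dir)
        return stratified_split(clips, test_fraction=0.5, seed=cfg.split_seed)
    if cfg.synthetic is None:
        raise ValueError("config must provide either data_dir or synthetic spec")
    s = cfg.synthetic
    return synthetic_data.make_sound_fixture(
        n_classes=s.n_classes, n_train=s.n_train_per_class,
        n_test=s.n_test_per_class, sample_rate=s.sample_rate, seed=s.seed)


def stratified_split(clips: Sequence[frontend.AudioClip], test_fraction: float,
                     seed: int) -> Tuple[List[frontend.AudioClip], List[frontend.AudioClip]]:
    rng = np.random.default_rng(seed)
    by_label: Dict[int, List[frontend.AudioClip]] = {}
    for c in clips:
        by_label.setdefault(c.label, []).append(c)
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_test = int(round(test_fraction * len(group)))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test


def n_classes_of(clips: Sequence[frontend.AudioClip]) -> int:
    return int(max(c.label for c in clips)) + 1


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def encode_clips(clips: Sequence[frontend.AudioClip], cfg: ExperimentConfig,
                 model: som.SOMModel) -> List[som.SpikePattern]:
    feats = [frontend.extract_features(c, cfg.frontend_cfg) for c in clips]
    return som.encode_dataset(model, feats, k=cfg.som_cfg.k_active)


def _noise_clip_for(cfg: ExperimentConfig, duration_ms: float,
                    sample_rate: int) -> frontend.AudioClip:
    return synthetic_data.babble_noise(duration_ms, sample_rate,
                                       seed=cfg.noise_cfg.seed + 777)


def run_train(cfg: ExperimentConfig) -> PipelineModels:
    """Train map then classifier; write model files if out_dir is set."""
    train_clips, _ = resolve_datasets(cfg)
    if cfg.multicondition:
        noise_clip = _noise_clip_for(cfg, 10_000.0, train_clips[0].sample_rate)
        train_clips = noise_mod.build_multicondition_set(
            train_clips, noise_clip, cfg.noise_cfg)
    logger.info("extracting features from %d training clips", len(train_clips))
    feats = [frontend.extract_features(c, cfg.frontend_cfg) for c in train_clips]
    logger.info("training SOM (%dx%d, %d epochs)", cfg.som_cfg.rows,
                cfg.som_cfg.cols, cfg.som_cfg.epochs)
    model = som.train_som(feats, cfg.som_cfg)
    qe = som.quantization_error(model, feats)
    logger.info("final quantization error: %.4f", qe)
    patterns = som.encode_dataset(model, feats, k=cfg.som_cfg.k_active)
    kernel = snn.make_kernel(cfg.tau_m, cfg.tau_s)
    n_classes = n_classes_of(train_clips)
    logger.info("training SNN classifier (%d classes, %d epochs)",
                n_classes, cfg.classifier_cfg.epochs)
    neurons, epoch_errors = snn.train_one_vs_all(
        patterns, n_classes, cfg.classifier_cfg, kernel=kernel,
        v_thr=cfg.v_thr, margin=cfg.margin)
    logger.info("per-epoch training errors: %s", epoch_errors)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        som.save_model(out / "som_model.json", model)
        snn.save_classifier(out / "snn_classifier.json", neurons)
        with open(out / "experiment_config.json", "w") as fh:
            json.dump({"config": _as_jsonable(asdict(cfg)),
                       "config_hash": cfg.config_hash()}, fh, indent=2)
    return PipelineModels(som_model=model, neurons=neurons,
                          epoch_errors=epoch_errors)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

EVAL_MODES = ("clean", "mismatched", "multicondition", "early", "jitter",
              "deletion")


def _decisions_frame(patterns: Sequence[som.SpikePattern],
                     decisions: Sequence[snn.Decision],
                     condition: str) -> pd.DataFrame:
    return pd.DataFrame({
        "condition": condition,
        "label": [p.label for p in patterns],
        "prediction": [d.label for d in decisions],
        "decision_time_ms": [d.decision_time_ms for d in decisions],
        "duration_ms": [p.duration_ms for p in patterns],
        "fired": ["".join("1" if f else "0" for f in d.fired) for d in decisions],
    })


def _classify_all(neurons, patterns, dt) -> List[snn.Decision]:
    return [snn.classify(neurons, p, dt=dt) for p in patterns]


def _confusion(patterns, decisions, n_classes) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    for p, d in zip(patterns, decisions):
        m[p.label, d.label] += 1
    return m


def run_eval(cfg: ExperimentConfig, models: PipelineModels,
             mode: str = "clean") -> EvaluationReport:
    """Evaluate the trained pipeline on the test split under one condition.

    Modes: ``clean``; ``mismatched``/``multicondition`` (noise-mixed test
    clips per SNR level); ``early`` (truncated patterns at fractions
    0.1..1.0); ``jitter`` (spike-time jitter, sigma swept over 0.1-0.8 of the
    frame period); ``deletion`` (spike deletion at ratios 0.1-0.6).
    """
    if mode not in EVAL_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {EVAL_MODES}")
    _, test_clips = resolve_datasets(cfg)
    n_classes = n_classes_of(test_clips)
    dt = cfg.classifier_cfg.dt
    neurons = models.neurons
    model = models.som_model
    meta = {"config_hash": cfg.config_hash(), "mode": mode,
            "n_test": len(test_clips), "n_classes": n_classes}

    clean_patterns = encode_clips(test_clips, cfg, model)
    frames: List[pd.DataFrame] = []
    accuracy: Dict[str, float] = {}

    if mode == "clean":
        decisions = _classify_all(neurons, clean_patterns, dt)
        accuracy["clean"] = _acc(clean_patterns, decisions)
        confusion = _confusion(clean_patterns, decisions, n_classes)
        frames.append(_decisions_frame(clean_patterns, decisions, "clean"))
    elif mode in ("mismatched", "multicondition"):
        noise_clip = _noise_clip_for(cfg, 10_000.0, test_clips[0].sample_rate)
        rng = np.random.default_rng(cfg.noise_cfg.seed + 1)
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
        for snr in cfg.noise_cfg.snr_levels_db:
            mixed = [noise_mod.mix_at_snr(c, noise_clip, snr, rng=rng)
                     for c in test_clips]
            patterns = encode_clips(mixed, cfg, model)
            decisions = _classify_all(neurons, patterns, dt)
            accuracy[f"{snr:g}dB"] = _acc(patterns, decisions)
            confusion += _confusion(patterns, decisions, n_classes)
            frames.append(_decisions_frame(patterns, decisions, f"{snr:g}dB"))
        if cfg.noise_cfg.include_clean:
            decisions = _classify_all(neurons, clean_patterns, dt)
            accuracy["clean"] = _acc(clean_patterns, decisions)
            confusion += _confusion(clean_patterns, decisions, n_classes)
            frames.append(_decisions_frame(clean_patterns, decisions, "clean"))
    elif mode == "early":
        fractions = [round(0.1 * i, 1) for i in range(1, 11)]
        accs, ratios = snn.evaluate_early_decision(neurons, clean_patterns,
                                                   fractions, dt=dt)
        accuracy = {f"{f:g}": a for f, a in accs.items()}
        decisions = _classify_all(neurons, clean_patterns, dt)
        confusion = _confusion(clean_patterns, decisions, n_classes)
        df = _decisions_frame(clean_patterns, decisions, "full")
        df["decision_ratio"] = ratios
        frames.append(df)
        meta["mean_decision_ratio"] = float(np.mean(ratios))
    elif mode == "jitter":
        T = cfg.frontend_cfg.frame_shift_ms
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
        for frac in (0.0, 0.1, 0.2, 0.4, 0.6, 0.8):
            jittered = [noise_mod.jitter_spikes(p, frac * T,
                                                seed=cfg.noise_cfg.seed + 31 * i)
                        for i, p in enumerate(clean_patterns)]
            decisions = _classify_all(neurons, jittered, dt)
            accuracy[f"sigma={frac:g}T"] = _acc(jittered, decisions)
            confusion += _confusion(jittered, decisions, n_classes)
            frames.append(_decisions_frame(jittered, decisions, f"sigma={frac:g}T"))
    else:  # deletion
        confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
        for ratio in (0.0, 0.1, 0.2, 0.3, 0.4, 0.6):
            thinned = [noise_mod.delete_spikes(p, ratio,
                                               seed=cfg.noise_cfg.seed + 17 * i)
                       for i, p in enumerate(clean_patterns)]
            decisions = _classify_all(neurons, thinned, dt)
            accuracy[f"ratio={ratio:g}"] = _acc(thinned, decisions)
            confusion += _confusion(thinned, decisions, n_classes)
            frames.append(_decisions_frame(thinned, decisions, f"ratio={ratio:g}"))

    report = EvaluationReport(mode=mode, accuracy=accuracy,
                              confusion=confusion,
                              decisions=pd.concat(frames, ignore_index=True),
                              metadata=meta)
    if cfg.out_dir is not None:
        report.save(cfg.out_dir)
    for name, acc in accuracy.items():
        logger.info("%s / %s: %.2f%%", mode, name, acc)
    return report


def _acc(patterns, decisions) -> float:
    hits = sum(d.label == p.label for p, d in zip(patterns, decisions))
    return 100.0 * hits / len(patterns)
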