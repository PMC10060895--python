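"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
feature extraction -> balance/split/train -> confusion metrics.

Two feature sets are evaluated side by side, mirroring the ablation the
method is built around: the 30 time-domain features alone ("FBN") versus
time-domain plus the five PLV-network features ("FBN-PLV", 35-D).  The
repeated experiment keeps one detection + feature-extraction pass and
re-splits the balanced candidate set with fresh seeds each repeat, pooling
the resulting confusion matrices.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import (CandidateSpike, MatchConfig, kmeans_specific_templates,
                     match_specific, merge_candidates, scan_universal)
from .errors import SpikeFBNError
from .evaluate import Metrics, aggregate_runs, compute_metrics, label_candidates
from .graphs import FEATURE_ORDER, network_feature_vector
from .mlp import (LabeledDataset, MLPConfig, predict, split_train_test,
                  train_mlp, undersample_balance)
from .morphology import candidate_feature_block, feature_names
from .plv import PLVConfig, candidate_fbn
from .signal_io import Recording, bandpass, bp_neighbors, to_average_reference, to_bipolar
from .synth import AnnotationSet, SimulationConfig, simulate

logger = logging.getLogger(__name__)

ALL_FEATURE_NAMES: tuple[str, ...] = feature_names() + FEATURE_ORDER


@dataclass(frozen=True)
class RunConfig:
    """All stage configurations of one experiment."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    plv: PLVConfig = field(default_factory=PLVConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    n_repeats: int = 100
    match_tolerance_ms: float = 60.0
    test_frac: float = 0.2
    cv_folds: int = 5
    detect_channels: tuple[str, ...] | None = None  # None = all AV channels
    master_seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise SpikeFBNError("n_repeats must be >= 1")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-18s %.2fs", name, t1 - t0)
    return t1


def detect_candidates(av: Recording, config: MatchConfig,
                      channels: tuple[str, ...] | None = None
                      ) -> tuple[list[CandidateSpike], dict]:
    """Full candidate stage on an AV recording: universal scan, specific
    template derivation, re-matching, and interval merging."""
    channels = tuple(channels) if channels else av.labels
    universal: list[CandidateSpike] = []
    for label in channels:
        universal.extend(scan_universal(av.channel(label), av.fs, config,
                                        channel=label))
    counts = {"universal_candidates": len(universal)}
    if not universal:
        counts["specific_templates"] = 0
        counts["candidates"] = 0
        return [], counts

    templates = kmeans_specific_templates(universal, config)
    counts["specific_templates"] = len(templates)

    specific: list[CandidateSpike] = []
    for label in channels:
        specific.extend(match_specific(av.channel(label), templates, av.fs,
                                       config, channel=label))
    merged = [replace(c, bp_pair=bp_neighbors(c.av_channel))
              for c in merge_candidates(specific, config)]
    counts["candidates"] = len(merged)
    return merged, counts


def extract_features(candidates: list[CandidateSpike], av: Recording,
                     bp: Recording, plv_config: PLVConfig) -> pd.DataFrame:
    """The n x 35 feature table: 30 time-domain + (AD, ACC, CPL, GE, MD)."""
    rows = []
    for c in candidates:
        morph = candidate_feature_block(c, av, bp)
        fbn = candidate_fbn(av, c, plv_config)
        net = network_feature_vector(fbn).to_array()
        rows.append(np.concatenate([morph, net]))
    return pd.DataFrame(rows, columns=list(ALL_FEATURE_NAMES))


def candidates_to_frame(candidates: list[CandidateSpike]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.av_channel, c.apex_index, c.apex_index / c.fs, c.correlation,
          c.template_id) for c in candidates],
        columns=["channel", "apex_sample", "apex_seconds", "correlation",
                 "template_id"],
    )


def _prepare(run_config: RunConfig,
             recording: Recording | None = None,
             annotations: AnnotationSet | None = None):
    """Shared front half: simulate/load, filter, montages, detect, label,
    feature extraction."""
    t0 = time.perf_counter()
    if recording is None:
        recording, annotations = simulate(run_config.sim)
        t0 = _stage("simulate", t0)
    filtered = bandpass(recording)
    t0 = _stage("bandpass", t0)
    av = to_average_reference(filtered)
    bp = to_bipolar(filtered)
    t0 = _stage("montage", t0)
    candidates, counts = detect_candidates(av, run_config.match,
                                           run_config.detect_channels)
    t0 = _stage("detect", t0)
    labels = (label_candidates(candidates, annotations,
                               run_config.match_tolerance_ms)
              if annotations is not None else None)
    features = extract_features(candidates, av, bp, run_config.plv)
    _stage("features", t0)
    counts["annotations"] = len(annotations) if annotations is not None else 0
    if labels is not None:
        counts["true_candidates"] = int(labels.sum())
    return av, bp, candidates, labels, features, counts


def _train_and_score(features: np.ndarray, labels: np.ndarray,
                     run_config: RunConfig, seed: int) -> dict[str, Metrics]:
    """One balanced/split/train/score round for both feature sets."""
    balanced = undersample_balance(features, labels, seed=seed)
    out: dict[str, Metrics] = {}
    for name, dim in (("FBN", 30), ("FBN-PLV", features.shape[1])):
        ds = LabeledDataset(balanced.features[:, :dim], balanced.labels)
        train, test = split_train_test(ds, run_config.test_frac, seed=seed)
        cfg = replace(run_config.mlp, input_dim=dim, seed=seed)
        model, _ = train_mlp(train, cfg, cv_folds=run_config.cv_folds)
        _, pred = predict(model, test.features)
        out[name] = compute_metrics(test.labels, pred)
    return out


def run_pipeline(run_config: RunConfig,
                 recording: Recording | None = None,
                 annotations: AnnotationSet | None = None) -> dict:
    """One end-to-end pass (single split); returns a JSON-ready report with
    per-stage counts and Metrics for both feature sets."""
    if (recording is None) != (annotations is None):
        raise SpikeFBNError("provide both recording and annotations, or neither")
    av, bp, candidates, labels, features, counts = _prepare(
        run_config, recording, annotations
    )
    metrics = _train_and_score(features.to_numpy(), labels, run_config,
                               seed=run_config.master_seed)
    return {
        "master_seed": run_config.master_seed,
        "counts": counts,
        "metrics": {k: m.as_dict() for k, m in metrics.items()},
        "config": _config_dict(run_config),
    }


def run_experiment(run_config: RunConfig,
                   recording: Recording | None = None,
                   annotations: AnnotationSet | None = None) -> dict:
    """The repeated-split experiment: one detection/feature pass, then
    ``n_repeats`` fresh balance/split/train rounds whose confusion matrices
    are pooled per feature set."""
    av, bp, candidates, labels, features, counts = _prepare(
        run_config, recording, annotations
    )
    x = features.to_numpy()
    seeds = np.random.default_rng(run_config.master_seed).integers(
        2**31, size=run_config.n_repeats
    )
    per_run: dict[str, list[Metrics]] = {"FBN": [], "FBN-PLV": []}
    for seed in seeds:
        result = _train_and_score(x, labels, run_config, seed=int(seed))
        for name, m in result.items():
            per_run[name].append(m)

    report = {
        "master_seed": run_config.master_seed,
        "n_repeats": run_config.n_repeats,
        "counts": counts,
        "metrics": {},
        "per_run": {},
        "config": _config_dict(run_config),
    }
    for name, runs in per_run.items():
        pooled, table = aggregate_runs(runs)
        report["metrics"][name] = pooled.as_dict()
        report["per_run"][name] = table.to_dict(orient="list")
    return report


def _config_dict(run_config: RunConfig) -> dict:
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x

    return clean(asdict(run_config))
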