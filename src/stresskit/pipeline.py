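"""End-to-end orchestration used by both the CLI and the test harness.

Composes the module operations: simulate or load sessions, extract and
baseline-normalize minute-block features, train/evaluate the linear
stress model, and produce signal-detection reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import classifier as clf
from . import detection, pulse
from .config import PipelineConfig
from .pulse import FeatureVector, MinuteBlock
from .session import Channel, Phase, Session, read_schedule_csv, read_trace_csv, resample_trace
from .simulate import GroundTruth, simulate_cohort

logger = logging.getLogger("stresskit")

__all__ = [
    "extract_session_features",
    "cohort_feature_table",
    "train_from_table",
    "evaluate_model",
    "load_session_csv",
]


def load_session_csv(
    participant_id: str,
    ppg_path: str | Path,
    eda_path: str | Path,
    schedule_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> Session:
    """Read one participant's trace/schedule CSVs and resample to analysis rates."""
    ppg = read_trace_csv(ppg_path, Channel.PPG)
    eda = read_trace_csv(eda_path, Channel.EDA)
    schedule = read_schedule_csv(schedule_path)
    ppg = resample_trace(ppg, config.ppg_hz)
    eda = resample_trace(eda, config.eda_hz)
    return Session(participant_id, ppg, eda, schedule)


def extract_session_features(
    session: Session, config: PipelineConfig = PipelineConfig()
) -> tuple[list[MinuteBlock], list[FeatureVector]]:
    """Minute blocks for all phases plus baseline-normalized features.

    Raises ``ValueError`` when the participant has no valid baseline
    block (the exclusion contract).
    """
    blocks = pulse.session_blocks(
        session,
        min_valid_ibi=config.min_valid_ibi,
        min_bpm=config.min_bpm,
        max_bpm=config.max_bpm,
    )
    baseline_blocks = [b for b in blocks if b.phase is Phase.BASELINE]
    profile = pulse.compute_baseline(baseline_blocks)
    features = pulse.normalize_blocks(blocks, profile)
    n_discarded = sum(not b.hr_valid for b in blocks)
    logger.info(
        "participant %s: %d blocks, %d HR-discarded, %d feature vectors",
        session.participant_id,
        len(blocks),
        n_discarded,
        len(features),
    )
    return blocks, features


def cohort_feature_table(
    sessions: Sequence[Session], config: PipelineConfig = PipelineConfig()
) -> tuple[pd.DataFrame, list[str]]:
    """Feature table over a cohort; returns (table, skipped participant ids)."""
    all_blocks: list[MinuteBlock] = []
    all_features: list[FeatureVector] = []
    skipped: list[str] = []
    for session in sessions:
        try:
            blocks, features = extract_session_features(session, config)
        except ValueError as exc:
            logger.warning("skipping participant %s: %s", session.participant_id, exc)
            skipped.append(session.participant_id)
            continue
        all_blocks.extend(blocks)
        all_features.extend(features)
    return pulse.feature_table(all_blocks, all_features), skipped


def train_from_table(
    frame: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> tuple[clf.LinearStressModel, dict]:
    """75:25 split, SGD fit on the train portion, accuracy summary."""
    features = pulse.features_from_frame(frame)
    samples = clf.label_blocks(features, include_tsst_a=False)
    spec = clf.SplitSpec(config.train_fraction, config.n_folds, config.seed)
    train, test = clf.split_dataset(samples, spec)
    model = clf.train_sgd(
        train, seed=config.seed, epochs=config.epochs, l2=config.l2, loss=config.loss
    )
    summary = {
        "n_train": len(train),
        "n_test": len(test),
        "train": _evaluation_dict(model, train),
    }
    if test:
        summary["test"] = _evaluation_dict(model, test)
    return model, summary


def _evaluation_dict(model: clf.LinearStressModel, samples: Sequence[clf.LabeledSample]) -> dict:
    truth = [s.label for s in samples]
    predicted = clf.predict_samples(model, samples)
    counts = detection.count_outcomes(truth, predicted)
    metrics = detection.compute_metrics(counts)
    return {
        "counts": asdict(counts),
        "metrics": {
            "accuracy": metrics.accuracy,
            "hit_rate": metrics.hit_rate,
            "false_alarm_rate": metrics.false_alarm_rate,
        },
    }


def evaluate_model(
    model: clf.LinearStressModel,
    frame: pd.DataFrame,
    include_tsst_a: bool = True,
) -> dict:
    """Block-level signal-detection report, pooled and per participant."""
    features = pulse.features_from_frame(frame)
    samples = clf.label_blocks(features, include_tsst_a=include_tsst_a)
    if not samples:
        raise ValueError("no labeled samples to evaluate")
    report = _evaluation_dict(model, samples)
    pids = sorted({s.participant_id for s in samples})
    per_participant = []
    for pid in pids:
        subset = [s for s in samples if s.participant_id == pid]
        entry = {"participant_id": pid, "n_blocks": len(subset)}
        entry.update(_evaluation_dict(model, subset))
        per_participant.append(entry)
    report["n_participants"] = len(pids)
    report["per_participant"] = per_participant
    return report
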