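"""Beat detection, inter-beat intervals, and minute-block features.

The detector locates pulse upstrokes on the first derivative of the PPG
signal: candidates are local maxima of the central-difference derivative
exceeding an adaptive threshold (half the rolling 90th percentile of the
positive derivative over a 10-s window), thinned by a 0.25-s refractory
period. Inter-beat intervals outside 40-180 bpm are flagged invalid;
minute blocks with fewer than 40 valid intervals are discarded for the
heart-rate feature. Features are baseline-normalized per participant by
subtracting the mean over the seated-baseline minutes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .session import Channel, Phase, Session, SignalTrace, slice_phase

__all__ = [
    "BeatSeries",
    "IBISeries",
    "MinuteBlock",
    "BaselineProfile",
    "FeatureVector",
    "detect_beats",
    "ibi_from_beats",
    "validate_ibi",
    "hr_from_mean_ibi",
    "block_features",
    "session_blocks",
    "compute_baseline",
    "normalize_blocks",
    "feature_table",
    "write_feature_csv",
    "read_feature_csv",
]

#: Default physiological validity bounds on instantaneous heart rate (bpm).
MIN_VALID_BPM = 40.0
MAX_VALID_BPM = 180.0

#: Minimum number of valid IBIs for a minute block's HR to be kept.
MIN_VALID_IBI_PER_BLOCK = 40

BLOCK_SECONDS = 60.0


@dataclass(frozen=True)
class BeatSeries:
    """Pulse upstroke times in seconds on the session clock."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.beat_times, dtype=float)
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError("beat times must be strictly increasing")
        arr.setflags(write=False)
        object.__setattr__(self, "beat_times", arr)

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass(frozen=True)
class IBISeries:
    """Consecutive-beat intervals with physiological validity flags."""

    onsets: np.ndarray
    durations: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets, float)
        du = np.asarray(self.durations, float)
        va = np.asarray(self.valid, bool)
        if not (on.size == du.size == va.size):
            raise ValueError("onsets, durations and valid must have equal length")
        if np.any(du <= 0):
            raise ValueError("IBI durations must be positive")
        if on.size > 1 and not np.all(np.diff(on) > 0):
            raise ValueError("onsets must be strictly increasing")
        for name, arr in (("onsets", on), ("durations", du), ("valid", va)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class MinuteBlock:
    """One non-overlapping 60-s window's features for a participant."""

    participant_id: str
    phase: Phase
    minute_index: int
    mean_hr: float | None
    mean_eda: float | None
    hr_valid: bool
    n_valid_ibi: int

    def __post_init__(self) -> None:
        if self.hr_valid and self.mean_hr is None:
            raise ValueError("hr_valid block must define mean_hr")
        if not self.hr_valid and self.mean_hr is not None:
            raise ValueError("discarded block must not define mean_hr")


@dataclass(frozen=True)
class BaselineProfile:
    """Per-participant 5-min baseline means used for normalization."""

    participant_id: str
    baseline_hr: float
    baseline_eda: float


@dataclass(frozen=True)
class FeatureVector:
    """Baseline-normalized features of one valid minute block."""

    participant_id: str
    phase: Phase
    minute_index: int
    dhr: float
    deda: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dhr) and math.isfinite(self.deda)):
            raise ValueError("feature values must be finite")


def detect_beats(
    ppg: SignalTrace,
    *,
    window_s: float = 10.0,
    percentile: float = 90.0,
    threshold_fraction: float = 0.5,
    refractory_s: float = 0.25,
) -> BeatSeries:
    """Locate pulse upstrokes in a PPG trace.

    Raises ``ValueError`` for a non-PPG channel, a rate below 32 Hz, or a
    trace shorter than 2 s.
    """
    if ppg.channel is not Channel.PPG:
        raise ValueError(f"detect_beats requires a PPG trace, got {ppg.channel.value}")
    if ppg.sampling_rate < 32:
        raise ValueError(f"PPG rate must be >= 32 Hz, got {ppg.sampling_rate}")
    if ppg.duration < 2.0:
        raise ValueError(f"PPG trace too short ({ppg.duration:.3g} s < 2 s)")

    fs = ppg.sampling_rate
    deriv = np.gradient(ppg.samples) * fs  # central differences, one-sided at edges

    positive = pd.Series(np.where(deriv > 0, deriv, np.nan))
    win = max(int(round(window_s * fs)), 1)
    threshold = threshold_fraction * positive.rolling(
        win, center=True, min_periods=1
    ).quantile(percentile / 100.0).to_numpy()

    peaks, _ = find_peaks(deriv)
    ok = np.isfinite(threshold[peaks]) & (deriv[peaks] > threshold[peaks])
    candidates = peaks[ok]

    kept: list[int] = []
    last_t = -np.inf
    for idx in candidates:
        t = idx / fs
        if t - last_t >= refractory_s:
            kept.append(int(idx))
            last_t = t
    return BeatSeries(ppg.start_offset + np.asarray(kept, float) / fs)


def validate_ibi(
    duration_s: float,
    min_bpm: float = MIN_VALID_BPM,
    max_bpm: float = MAX_VALID_BPM,
) -> bool:
    """True when the interval's rate lies in ``[min_bpm, max_bpm]``.

    The exclusion is strict (<min or >max excluded), so exact-boundary
    intervals are kept.
    """
    if duration_s <= 0:
        raise ValueError(f"IBI duration must be positive, got {duration_s}")
    bpm = 60.0 / duration_s
    return min_bpm <= bpm <= max_bpm


def ibi_from_beats(
    beats: BeatSeries,
    min_bpm: float = MIN_VALID_BPM,
    max_bpm: float = MAX_VALID_BPM,
) -> IBISeries:
    """Intervals between consecutive beats, flagged for validity."""
    times = beats.beat_times
    if times.size < 2:
        raise ValueError(f"need at least 2 beats to form intervals, got {times.size}")
    durations = np.diff(times)
    onsets = times[:-1]
    bpm = 60.0 / durations
    valid = (bpm >= min_bpm) & (bpm <= max_bpm)
    return IBISeries(onsets, durations, valid)


def hr_from_mean_ibi(mean_ibi_s: float) -> float:
    """Heart rate in bpm from a mean inter-beat interval in seconds."""
    if mean_ibi_s <= 0:
        raise ValueError(f"mean IBI must be positive, got {mean_ibi_s}")
    return 60.0 / mean_ibi_s


def block_features(
    session: Session,
    phase: Phase,
    *,
    ibis: IBISeries | None = None,
    min_valid_ibi: int = MIN_VALID_IBI_PER_BLOCK,
    min_bpm: float = MIN_VALID_BPM,
    max_bpm: float = MAX_VALID_BPM,
) -> list[MinuteBlock]:
    """Per-minute features for one phase of a session.

    The phase is partitioned into consecutive ``[k*60, (k+1)*60)``
    windows with the trailing partial window dropped. Per window the HR
    feature is 60 / mean(valid IBI durations with onset in the window),
    kept only when at least ``min_valid_ibi`` valid intervals fall in the
    window; the EDA feature is the arithmetic mean of the window's raw
    samples. A phase shorter than one minute yields an empty list.

    ``ibis`` may be supplied to reuse a precomputed interval series
    (session clock); otherwise beats are detected on the phase slice.
    """
    interval = session.schedule.interval(phase)
    n_minutes = int(interval.duration // BLOCK_SECONDS)
    if n_minutes == 0:
        return []

    eda_phase = slice_phase(session.eda, session.schedule, phase)

    if ibis is None:
        ppg_phase = slice_phase(session.ppg, session.schedule, phase)
        ibis = _phase_ibis(ppg_phase, min_bpm, max_bpm)

    blocks: list[MinuteBlock] = []
    eda_times = eda_phase.timestamps()
    for k in range(n_minutes):
        w0 = interval.start_s + k * BLOCK_SECONDS
        w1 = w0 + BLOCK_SECONDS
        in_win = (ibis.onsets >= w0) & (ibis.onsets < w1)
        valid_durs = ibis.durations[in_win & ibis.valid]
        n_valid = int(valid_durs.size)
        if n_valid >= min_valid_ibi:
            mean_hr: float | None = hr_from_mean_ibi(float(valid_durs.mean()))
            hr_valid = True
        else:
            mean_hr, hr_valid = None, False
        eda_mask = (eda_times >= w0 - 1e-9) & (eda_times < w1 - 1e-9)
        mean_eda = float(eda_phase.samples[eda_mask].mean()) if eda_mask.any() else None
        blocks.append(
            MinuteBlock(
                participant_id=session.participant_id,
                phase=phase,
                minute_index=k,
                mean_hr=mean_hr,
                mean_eda=mean_eda,
                hr_valid=hr_valid,
                n_valid_ibi=n_valid,
            )
        )
    return blocks


def _phase_ibis(ppg_phase: SignalTrace, min_bpm: float, max_bpm: float) -> IBISeries:
    try:
        beats = detect_beats(ppg_phase)
    except ValueError:
        return IBISeries(np.array([]), np.array([]), np.array([], bool))
    if len(beats) < 2:
        return IBISeries(np.array([]), np.array([]), np.array([], bool))
    return ibi_from_beats(beats, min_bpm, max_bpm)


def session_blocks(
    session: Session,
    *,
    min_valid_ibi: int = MIN_VALID_IBI_PER_BLOCK,
    min_bpm: float = MIN_VALID_BPM,
    max_bpm: float = MAX_VALID_BPM,
) -> list[MinuteBlock]:
    """Minute blocks for every scheduled phase, in schedule order."""
    out: list[MinuteBlock] = []
    for iv in session.schedule:
        out.extend(
            block_features(
                session,
                iv.phase,
                min_valid_ibi=min_valid_ibi,
                min_bpm=min_bpm,
                max_bpm=max_bpm,
            )
        )
    return out


def compute_baseline(blocks: Sequence[MinuteBlock]) -> BaselineProfile:
    """Baseline means over the valid baseline minute blocks.

    Raises ``ValueError`` when no baseline block has a valid HR (the
    participant-exclusion signal) or when blocks are mixed-phase.
    """
    if not blocks:
        raise ValueError("no baseline blocks supplied")
    pids = {b.participant_id for b in blocks}
    if len(pids) != 1:
        raise ValueError(f"blocks from multiple participants: {sorted(pids)}")
    if any(b.phase is not Phase.BASELINE for b in blocks):
        raise ValueError("compute_baseline expects BASELINE blocks only")
    hr_values = [b.mean_hr for b in blocks if b.hr_valid]
    eda_values = [b.mean_eda for b in blocks if b.mean_eda is not None]
    if not hr_values:
        raise ValueError(
            f"participant {blocks[0].participant_id}: no valid baseline HR block "
            "(participant excluded)"
        )
    if not eda_values:
        raise ValueError(
            f"participant {blocks[0].participant_id}: no baseline EDA block"
        )
    return BaselineProfile(
        participant_id=blocks[0].participant_id,
        baseline_hr=float(np.mean(hr_values)),
        baseline_eda=float(np.mean(eda_values)),
    )


def normalize_blocks(
    blocks: Iterable[MinuteBlock], profile: BaselineProfile
) -> list[FeatureVector]:
    """Subtract the baseline profile; invalid blocks are skipped."""
    out: list[FeatureVector] = []
    for b in blocks:
        if b.participant_id != profile.participant_id:
            raise ValueError(
                f"participant mismatch: block {b.participant_id!r} vs "
                f"profile {profile.participant_id!r}"
            )
        if not b.hr_valid or b.mean_eda is None:
            continue
        out.append(
            FeatureVector(
                participant_id=b.participant_id,
                phase=b.phase,
                minute_index=b.minute_index,
                dhr=b.mean_hr - profile.baseline_hr,
                deda=b.mean_eda - profile.baseline_eda,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature table (CSV contract)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "participant_id",
    "phase",
    "minute_index",
    "mean_hr",
    "mean_eda",
    "dhr",
    "deda",
    "hr_valid",
    "n_valid_ibi",
]


def feature_table(
    blocks: Sequence[MinuteBlock], features: Sequence[FeatureVector]
) -> pd.DataFrame:
    """Join raw blocks with their normalized features into one table."""
    fmap = {(f.participant_id, f.phase, f.minute_index): f for f in features}
    rows = []
    for b in blocks:
        f = fmap.get((b.participant_id, b.phase, b.minute_index))
        rows.append(
            {
                "participant_id": b.participant_id,
                "phase": b.phase.value,
                "minute_index": b.minute_index,
                "mean_hr": b.mean_hr,
                "mean_eda": b.mean_eda,
                "dhr": f.dhr if f is not None else None,
                "deda": f.deda if f is not None else None,
                "hr_valid": b.hr_valid,
                "n_valid_ibi": b.n_valid_ibi,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    return frame


def features_from_frame(frame: pd.DataFrame) -> list[FeatureVector]:
    """Normalized feature vectors from a feature table (valid rows only)."""
    out = []
    for row in frame.itertuples(index=False):
        if pd.isna(row.dhr) or pd.isna(row.deda):
            continue
        out.append(
            FeatureVector(
                participant_id=str(row.participant_id),
                phase=Phase[row.phase],
                minute_index=int(row.minute_index),
                dhr=float(row.dhr),
                deda=float(row.deda),
            )
        )
    return out
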