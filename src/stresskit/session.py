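"""Domain types for physiological sessions and plain-text I/O.

A session bundles one participant's photoplethysmography (PPG) and
electrodermal activity (EDA) traces with a phase schedule marking the
seated baseline and the three Trier-Social-Stress-Test task phases.
Time is expressed in seconds from session start; intervals are half-open
``[start, end)`` so that consecutive minute windows partition a phase
exactly.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "Channel",
    "Phase",
    "SignalTrace",
    "PhaseInterval",
    "PhaseSchedule",
    "Session",
    "TraceFormatError",
    "ScheduleError",
    "read_trace_csv",
    "write_trace_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "resample_trace",
    "slice_phase",
]


class Channel(enum.Enum):
    """Physiological channel identity of a trace."""

    PPG = "PPG"
    EDA = "EDA"


class Phase(enum.Enum):
    """Session phase labels; the three TSST_* phases are task phases."""

    BASELINE = "BASELINE"
    TSST_P = "TSST_P"
    TSST_S = "TSST_S"
    TSST_A = "TSST_A"


class TraceFormatError(ValueError):
    """Malformed trace file (non-numeric rows, bad timestamps, rate mismatch)."""


class ScheduleError(ValueError):
    """Malformed phase schedule (unknown phase, overlap, inverted interval)."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled physiological channel.

    Parameters
    ----------
    channel
        Which physiological quantity the samples represent.
    sampling_rate
        Samples per second; must be positive.
    samples
        Amplitudes (PPG in arbitrary units, EDA in microsiemens). All
        values must be finite; non-finite input is a hard error rather
        than being silently imputed.
    start_offset
        Time of the first sample, in seconds from session start.
    """

    channel: Channel
    sampling_rate: float
    samples: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.start_offset < 0:
            raise ValueError(f"start_offset must be non-negative, got {self.start_offset}")
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span of the trace in seconds (``len / rate``)."""
        return self.samples.size / self.sampling_rate

    @property
    def end_offset(self) -> float:
        return self.start_offset + self.duration

    def timestamps(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return self.start_offset + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True, order=True)
class PhaseInterval:
    """One labeled half-open interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    phase: Phase

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ScheduleError(
                f"interval end must exceed start: {self.phase.value} "
                f"[{self.start_s}, {self.end_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSchedule:
    """Sorted, non-overlapping phase intervals; each phase at most once."""

    intervals: tuple[PhaseInterval, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals))
        seen: set[Phase] = set()
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s:
                raise ScheduleError(
                    f"overlapping intervals: {a.phase.value} "
                    f"[{a.start_s}, {a.end_s}) and {b.phase.value} "
                    f"[{b.start_s}, {b.end_s})"
                )
        for iv in ordered:
            if iv.phase in seen:
                raise ScheduleError(f"phase {iv.phase.value} appears more than once")
            seen.add(iv.phase)
        object.__setattr__(self, "intervals", ordered)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def phases(self) -> tuple[Phase, ...]:
        return tuple(iv.phase for iv in self.intervals)

    def interval(self, phase: Phase) -> PhaseInterval:
        for iv in self.intervals:
            if iv.phase is phase:
                return iv
        raise KeyError(f"phase {phase.value} not in schedule")

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0].start_s, self.intervals[-1].end_s


@dataclass(frozen=True)
class Session:
    """One participant's recording: both traces plus the phase schedule."""

    participant_id: str
    ppg: SignalTrace
    eda: SignalTrace
    schedule: PhaseSchedule

    def __post_init__(self) -> None:
        if self.ppg.channel is not Channel.PPG:
            raise ValueError("ppg trace must have channel PPG")
        if self.eda.channel is not Channel.EDA:
            raise ValueError("eda trace must have channel EDA")
        tol = 1e-9
        for trace, name in ((self.ppg, "PPG"), (self.eda, "EDA")):
            for iv in self.schedule:
                if iv.start_s < trace.start_offset - tol or iv.end_s > trace.end_offset + tol:
                    raise ValueError(
                        f"{name} trace [{trace.start_offset}, {trace.end_offset}) does not "
                        f"cover scheduled interval {iv.phase.value} [{iv.start_s}, {iv.end_s})"
                    )


# ---------------------------------------------------------------------------
# Plain-text I/O
#
# Two trace dialects: single-column (`value` header) and timestamped
# (`time_s,value` header). Timestamps must be uniform within 1e-6 s and,
# when a rate is declared, agree with it within 0.1%.
# ---------------------------------------------------------------------------

_TIME_UNIFORMITY_TOL = 1e-6
_RATE_MATCH_RTOL = 1e-3


def _parse_float(text: str, row: int, path: Path) -> float:
    try:
        value = float(text)
    except ValueError:
        raise TraceFormatError(f"{path}: non-numeric value {text!r} at row {row}") from None
    if not math.isfinite(value):
        raise TraceFormatError(f"{path}: non-finite value {text!r} at row {row}")
    return value


def read_trace_csv(
    path: str | Path,
    channel: Channel,
    sampling_rate: float | None = None,
) -> SignalTrace:
    """Read a trace from CSV.

    ``sampling_rate`` is required for the single-column dialect; for the
    timestamped dialect it may be omitted (the rate is then inferred from
    the timestamps) or given, in which case it must agree with the
    inferred rate within 0.1%.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(cell.strip() for cell in r)]
    if not rows:
        raise TraceFormatError(f"{path}: empty trace file")

    header = [c.strip().lower() for c in rows[0]]
    if header == ["time_s", "value"]:
        timestamped, data_rows, first_row = True, rows[1:], 2
    elif header == ["value"]:
        timestamped, data_rows, first_row = False, rows[1:], 2
    else:
        # headerless single-column file of bare numbers
        timestamped, data_rows, first_row = False, rows, 1
    if not data_rows:
        raise TraceFormatError(f"{path}: no data rows")

    if timestamped:
        times = np.empty(len(data_rows))
        values = np.empty(len(data_rows))
        for i, row in enumerate(data_rows):
            if len(row) != 2:
                raise TraceFormatError(
                    f"{path}: expected 2 columns at row {first_row + i}, got {len(row)}"
                )
            times[i] = _parse_float(row[0], first_row + i, path)
            values[i] = _parse_float(row[1], first_row + i, path)
        if len(times) < 2:
            if sampling_rate is None:
                raise TraceFormatError(f"{path}: cannot infer rate from a single row")
            rate = float(sampling_rate)
        else:
            dts = np.diff(times)
            spread = np.abs(dts - dts.mean())
            if np.any(spread > _TIME_UNIFORMITY_TOL):
                bad = int(np.argmax(spread))
                raise TraceFormatError(
                    f"{path}: non-uniform timestamp at row {first_row + bad + 1} "
                    f"(dt={dts[bad]:.9g} s vs mean {dts.mean():.9g} s)"
                )
            inferred = 1.0 / dts.mean()
            if sampling_rate is not None:
                if abs(inferred - sampling_rate) > _RATE_MATCH_RTOL * sampling_rate:
                    raise TraceFormatError(
                        f"{path}: declared rate {sampling_rate} Hz does not match "
                        f"inferred rate {inferred:.6g} Hz"
                    )
                rate = float(sampling_rate)
            else:
                rate = inferred
        return SignalTrace(channel, rate, values, start_offset=float(times[0]))

    if sampling_rate is None:
        raise TraceFormatError(f"{path}: single-column dialect requires an explicit rate")
    values = np.empty(len(data_rows))
    for i, row in enumerate(data_rows):
        if len(row) != 1:
            raise TraceFormatError(
                f"{path}: expected 1 column at row {first_row + i}, got {len(row)}"
            )
        values[i] = _parse_float(row[0], first_row + i, path)
    return SignalTrace(channel, float(sampling_rate), values)


def write_trace_csv(trace: SignalTrace, path: str | Path) -> None:
    """Write the timestamped dialect (`time_s,value`) at full precision."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    times = trace.timestamps()
    with path.open("w", newline="") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(times, trace.samples):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_schedule_csv(path: str | Path) -> PhaseSchedule:
    """Read a `phase,start_s,end_s` schedule; returns it sorted and validated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"schedule file not found: {path}")
    intervals = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader, start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if i == 1 and [c.strip().lower() for c in row] == ["phase", "start_s", "end_s"]:
                continue
            if len(row) != 3:
                raise ScheduleError(f"{path}: expected 3 columns at row {i}, got {len(row)}")
            label = row[0].strip()
            try:
                phase = Phase[label]
            except KeyError:
                raise ScheduleError(f"{path}: unknown phase label {label!r} at row {i}") from None
            start = _parse_float(row[1], i, path)
            end = _parse_float(row[2], i, path)
            intervals.append(PhaseInterval(start, end, phase))
    if not intervals:
        raise ScheduleError(f"{path}: schedule has no intervals")
    return PhaseSchedule(tuple(intervals))


def write_schedule_csv(schedule: PhaseSchedule, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write("phase,start_s,end_s\n")
        for iv in schedule:
            fh.write(f"{iv.phase.value},{float(iv.start_s)!r},{float(iv.end_s)!r}\n")


# ---------------------------------------------------------------------------
# Rate conversion and slicing
# ---------------------------------------------------------------------------


def resample_trace(trace: SignalTrace, target_rate: float) -> SignalTrace:
    """Anti-aliased rational resampling to ``target_rate``.

    Uses polyphase filtering (Kaiser-windowed low-pass) on the rational
    rate ratio; output length is ``round(n * target / source)``. A no-op
    when the rates already match within 1e-9.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if len(trace) == 0:
        raise ValueError("cannot resample an empty trace")
    if abs(target_rate - trace.sampling_rate) <= 1e-9:
        return trace
    ratio = (
        Fraction(target_rate).limit_denominator(10**6)
        / Fraction(trace.sampling_rate).limit_denominator(10**6)
    )
    up, down = ratio.numerator, ratio.denominator
    # resample about the mean with 'line' padding: the DC component passes
    # through exactly instead of picking up filter passband ripple
    mean = trace.samples.mean()
    out = resample_poly(trace.samples - mean, up, down, padtype="line") + mean
    n_out = int(round(len(trace) * target_rate / trace.sampling_rate))
    if len(out) > n_out:
        out = out[:n_out]
    elif len(out) < n_out:
        out = np.concatenate([out, np.full(n_out - len(out), out[-1])])
    return SignalTrace(trace.channel, float(target_rate), out, trace.start_offset)


def slice_phase(trace: SignalTrace, schedule: PhaseSchedule, phase: Phase) -> SignalTrace:
    """Samples whose timestamps fall in the phase's ``[start, end)`` window."""
    iv = schedule.interval(phase)  # KeyError if absent
    rate = trace.sampling_rate
    i0 = max(0, int(math.ceil((iv.start_s - trace.start_offset) * rate - 1e-9)))
    i1 = min(len(trace), int(math.ceil((iv.end_s - trace.start_offset) * rate - 1e-9)))
    if i1 <= i0:
        raise ValueError(f"phase {phase.value} contains no samples of the trace")
    return SignalTrace(trace.channel, rate, trace.samples[i0:i1], start_offset=iv.start_s)
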