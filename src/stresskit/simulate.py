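"""Seeded generator of TSST-structured physiological sessions.

The study's own recordings were never deposited, so the simulator stands
in for them: each synthetic session has a 5-min seated baseline followed
by three 5-min task phases (anticipation, speech, arithmetic). Stress
phases raise mean heart rate and skin conductance relative to baseline,
with between-subject variability in both baseline level and reactivity;
the anticipation phase receives a configurable fraction of the stress
delta and is left unlabeled downstream.

PPG is rendered as a stereotyped pulse waveform (fast upstroke, slower
exponential decay) at each beat; EDA as a piecewise-linear tonic level
plus phasic skin-conductance responses at Poisson event times. All
randomness flows from explicit seeds, and every session carries its
ground truth (true beat times, per-minute mean HR, programmed deltas).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .session import (
    Channel,
    Phase,
    PhaseInterval,
    PhaseSchedule,
    Session,
    SignalTrace,
)

__all__ = [
    "ReactivityConfig",
    "GroundTruth",
    "simulate_ppg",
    "simulate_eda",
    "simulate_session",
    "simulate_cohort",
    "default_schedule",
    "PULSE_RISE_S",
]

PHASE_SECONDS = 300.0
PHASE_ORDER = (Phase.BASELINE, Phase.TSST_P, Phase.TSST_S, Phase.TSST_A)

# Pulse waveform shape: half-cosine-squared rise then exponential decay.
PULSE_RISE_S = 0.125
PULSE_DECAY_TAU_S = 0.25
#: Offset of the steepest upstroke slope from pulse onset (the ground-truth
#: beat time reported for each rendered pulse).
UPSTROKE_OFFSET_S = PULSE_RISE_S / 2

# Skin-conductance response kernel time constants.
SCR_RISE_TAU_S = 0.75
SCR_DECAY_TAU_S = 4.0


@dataclass(frozen=True)
class ReactivityConfig:
    """Population parameters of the simulated cohort.

    Means/SDs parameterize between-subject draws; deltas are the stress
    effect applied in full during task-stress phases and scaled by
    ``anticipation_fraction`` during the anticipation phase.
    """

    baseline_hr_mean: float = 70.0
    baseline_hr_sd_between: float = 8.0
    hr_delta_stress_mean: float = 15.0
    hr_delta_stress_sd: float = 5.0
    ibi_jitter_cv: float = 0.04
    hr_minute_wander_sd: float = 1.0
    baseline_eda_mean: float = 4.0
    baseline_eda_sd_between: float = 1.5
    eda_delta_stress_mean: float = 2.0
    eda_delta_stress_sd: float = 0.7
    scr_rate_baseline: float = 2.0
    scr_rate_stress: float = 6.0
    scr_amp_mean: float = 0.3
    measurement_noise_sd: float = 0.02
    anticipation_fraction: float = 0.5
    ppg_hz: float = 64.0
    eda_hz: float = 4.0
    motion_artifact_rate: float = 0.0
    motion_artifact_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_hr_sd_between",
            "hr_delta_stress_sd",
            "ibi_jitter_cv",
            "hr_minute_wander_sd",
            "baseline_eda_sd_between",
            "eda_delta_stress_sd",
            "scr_rate_baseline",
            "scr_rate_stress",
            "scr_amp_mean",
            "measurement_noise_sd",
            "motion_artifact_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.anticipation_fraction <= 1:
            raise ValueError("anticipation_fraction must be in [0, 1]")
        if self.ppg_hz < 32 or self.eda_hz <= 0:
            raise ValueError("invalid simulator sampling rates")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually generated, for oracle-style checks."""

    participant_id: str
    beat_times: np.ndarray
    hr_per_minute: np.ndarray
    eda_tonic_per_minute: np.ndarray
    baseline_hr: float
    hr_delta: float
    baseline_eda: float
    eda_delta: float


def default_schedule() -> PhaseSchedule:
    """Baseline then three task phases, 5 min each, back to back."""
    intervals = []
    for k, phase in enumerate(PHASE_ORDER):
        intervals.append(PhaseInterval(k * PHASE_SECONDS, (k + 1) * PHASE_SECONDS, phase))
    return PhaseSchedule(tuple(intervals))


def _pulse(dt: np.ndarray) -> np.ndarray:
    """Stereotyped pulse waveform evaluated at times since pulse onset."""
    out = np.zeros_like(dt)
    rising = (dt >= 0) & (dt < PULSE_RISE_S)
    out[rising] = np.sin(np.pi * dt[rising] / (2 * PULSE_RISE_S)) ** 2
    decaying = dt >= PULSE_RISE_S
    out[decaying] = np.exp(-(dt[decaying] - PULSE_RISE_S) / PULSE_DECAY_TAU_S)
    return out


def simulate_ppg(
    hr_per_minute: Sequence[float],
    jitter_cv: float,
    rate: float = 64.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[SignalTrace, np.ndarray]:
    """Render a PPG trace from a per-minute heart-rate trajectory.

    Beats are placed sequentially with IBI = (60 / HR) * (1 + N(0,
    jitter_cv)), truncated to the physiologic 40-180 bpm range; each
    beat contributes one pulse waveform. Returns the trace and the true
    upstroke times (seconds from trace start).
    """
    hr = np.asarray(hr_per_minute, dtype=float)
    if hr.size == 0:
        raise ValueError("hr_per_minute must be non-empty")
    if np.any((hr <= 40.0) | (hr >= 180.0)):
        raise ValueError("hr trajectory must lie strictly within (40, 180) bpm")
    if rate < 32:
        raise ValueError(f"PPG rate must be >= 32 Hz, got {rate}")
    rng = np.random.default_rng(seed)
    duration = 60.0 * hr.size
    onsets = []
    t = 0.0
    while t < duration:
        minute = min(int(t // 60.0), hr.size - 1)
        ibi = (60.0 / hr[minute]) * (1.0 + rng.normal(0.0, jitter_cv))
        ibi = float(np.clip(ibi, 60.0 / 180.0, 60.0 / 40.0))
        onsets.append(t)
        t += ibi
    onsets = np.asarray(onsets)

    n = int(round(duration * rate))
    samples = np.zeros(n)
    support = int(np.ceil((PULSE_RISE_S + 6 * PULSE_DECAY_TAU_S) * rate))
    for onset in onsets:
        i0 = max(0, int(np.ceil(onset * rate)))
        i1 = min(n, i0 + support)
        idx = np.arange(i0, i1)
        samples[idx] += _pulse(idx / rate - onset)
    trace = SignalTrace(Channel.PPG, float(rate), samples)
    return trace, onsets + UPSTROKE_OFFSET_S


def _scr_kernel(dt: np.ndarray) -> np.ndarray:
    out = np.zeros_like(dt)
    pos = dt >= 0
    out[pos] = np.exp(-dt[pos] / SCR_DECAY_TAU_S) - np.exp(-dt[pos] / SCR_RISE_TAU_S)
    return out


def simulate_eda(
    tonic_per_minute: Sequence[float],
    scr_rate_per_minute: Sequence[float],
    config: ReactivityConfig,
    rate: float = 4.0,
    seed: int | np.random.SeedSequence = 0,
) -> SignalTrace:
    """Render an EDA trace: tonic level + phasic responses + noise.

    The tonic level interpolates linearly between minute midpoints;
    skin-conductance responses occur at Poisson times with per-minute
    rates and exponentially distributed amplitudes; Gaussian measurement
    noise is added and the result clipped at zero.
    """
    tonic = np.asarray(tonic_per_minute, dtype=float)
    rates = np.asarray(scr_rate_per_minute, dtype=float)
    if tonic.size == 0 or tonic.size != rates.size:
        raise ValueError("tonic and SCR-rate trajectories must be non-empty and equal length")
    if np.any(tonic < 0):
        raise ValueError("tonic level must be non-negative")
    if np.any(rates < 0):
        raise ValueError("SCR rates must be non-negative")
    rng = np.random.default_rng(seed)
    duration = 60.0 * tonic.size
    n = int(round(duration * rate))
    times = np.arange(n) / rate

    midpoints = 30.0 + 60.0 * np.arange(tonic.size)
    samples = np.interp(times, midpoints, tonic)

    support = int(np.ceil(8 * SCR_DECAY_TAU_S * rate))
    for minute in range(tonic.size):
        n_events = rng.poisson(rates[minute])
        event_times = np.sort(rng.uniform(60.0 * minute, 60.0 * (minute + 1), n_events))
        amps = rng.exponential(config.scr_amp_mean, n_events)
        for et, amp in zip(event_times, amps):
            i0 = max(0, int(np.ceil(et * rate)))
            i1 = min(n, i0 + support)
            idx = np.arange(i0, i1)
            samples[idx] += amp * _scr_kernel(idx / rate - et)

    if config.measurement_noise_sd > 0:
        samples = samples + rng.normal(0.0, config.measurement_noise_sd, n)
    return SignalTrace(Channel.EDA, float(rate), np.clip(samples, 0.0, None))


def _inject_motion_artifacts(
    ppg: SignalTrace, config: ReactivityConfig, seed: np.random.SeedSequence
) -> SignalTrace:
    """Additive triangular transients at Poisson times (default off)."""
    rng = np.random.default_rng(seed)
    n = len(ppg)
    rate = ppg.sampling_rate
    duration_min = ppg.duration / 60.0
    n_events = rng.poisson(config.motion_artifact_rate * duration_min)
    samples = ppg.samples.copy()
    half = max(1, int(round(0.3 * rate)))  # ~0.6 s transient
    shape = 1.0 - np.abs(np.arange(-half, half + 1)) / half
    for _ in range(n_events):
        center = rng.integers(0, n)
        amp = config.motion_artifact_amp * rng.choice((-1.0, 1.0))
        i0, i1 = max(0, center - half), min(n, center + half + 1)
        samples[i0:i1] += amp * shape[i0 - (center - half) : i1 - (center - half)]
    return SignalTrace(ppg.channel, rate, samples, ppg.start_offset)


def _phase_multipliers(config: ReactivityConfig) -> dict[Phase, float]:
    return {
        Phase.BASELINE: 0.0,
        Phase.TSST_P: config.anticipation_fraction,
        Phase.TSST_S: 1.0,
        Phase.TSST_A: 1.0,
    }


def simulate_session(
    participant_id: str,
    config: ReactivityConfig = ReactivityConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Session, GroundTruth]:
    """One synthetic participant: traces, schedule, and ground truth.

    Participant-level baseline and stress deltas are drawn from the
    between-subject distributions; stress phases get the full delta and
    the anticipation phase ``anticipation_fraction`` of it.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    draw_ss, ppg_ss, eda_ss = ss.spawn(3)
    rng = np.random.default_rng(draw_ss)

    baseline_hr = float(rng.normal(config.baseline_hr_mean, config.baseline_hr_sd_between))
    baseline_hr = float(np.clip(baseline_hr, 45.0, 110.0))
    hr_delta = float(rng.normal(config.hr_delta_stress_mean, config.hr_delta_stress_sd))
    baseline_eda = float(rng.normal(config.baseline_eda_mean, config.baseline_eda_sd_between))
    baseline_eda = max(baseline_eda, 0.5)
    eda_delta = float(rng.normal(config.eda_delta_stress_mean, config.eda_delta_stress_sd))

    schedule = default_schedule()
    mult = _phase_multipliers(config)
    minutes_per_phase = int(PHASE_SECONDS // 60)

    hr_per_minute = []
    tonic_per_minute = []
    scr_rate_per_minute = []
    for iv in schedule:
        m = mult[iv.phase]
        for _ in range(minutes_per_phase):
            wander = float(rng.normal(0.0, config.hr_minute_wander_sd))
            hr_per_minute.append(
                float(np.clip(baseline_hr + m * hr_delta + wander, 42.0, 178.0))
            )
            tonic_per_minute.append(max(baseline_eda + m * eda_delta, 0.0))
            scr_rate_per_minute.append(
                config.scr_rate_baseline
                + m * (config.scr_rate_stress - config.scr_rate_baseline)
            )
    hr_per_minute = np.asarray(hr_per_minute)
    tonic_per_minute = np.asarray(tonic_per_minute)

    ppg, beat_times = simulate_ppg(hr_per_minute, config.ibi_jitter_cv, config.ppg_hz, ppg_ss)
    eda = simulate_eda(tonic_per_minute, scr_rate_per_minute, config, config.eda_hz, eda_ss)

    if config.motion_artifact_rate > 0 and config.motion_artifact_amp > 0:
        (artifact_ss,) = ss.spawn(1)
        ppg = _inject_motion_artifacts(ppg, config, artifact_ss)

    session = Session(participant_id, ppg, eda, schedule)
    truth = GroundTruth(
        participant_id=participant_id,
        beat_times=beat_times,
        hr_per_minute=hr_per_minute,
        eda_tonic_per_minute=tonic_per_minute,
        baseline_hr=baseline_hr,
        hr_delta=hr_delta,
        baseline_eda=baseline_eda,
        eda_delta=eda_delta,
    )
    return session, truth


def simulate_cohort(
    n: int,
    config: ReactivityConfig = ReactivityConfig(),
    master_seed: int = 0,
) -> list[tuple[Session, GroundTruth]]:
    """n sessions with per-participant seeds derived from ``master_seed``."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [
        simulate_session(f"P{i + 1:02d}", config, child)
        for i, child in enumerate(children)
    ]
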