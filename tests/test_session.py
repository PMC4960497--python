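import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresskit.session import (
    Channel,
    Phase,
    PhaseInterval,
    PhaseSchedule,
    ScheduleError,
    Session,
    SignalTrace,
    TraceFormatError,
    read_schedule_csv,
    read_trace_csv,
    resample_trace,
    slice_phase,
    write_schedule_csv,
    write_trace_csv,
)


def make_schedule():
    return PhaseSchedule(
        (
            PhaseInterval(0, 300, Phase.BASELINE),
            PhaseInterval(300, 600, Phase.TSST_P),
            PhaseInterval(600, 900, Phase.TSST_S),
            PhaseInterval(900, 1200, Phase.TSST_A),
        )
    )


class TestSignalTrace:
    def test_duration_and_timestamps(self):
        t = SignalTrace(Channel.EDA, 4.0, [1.0, 2.0, 3.0])
        assert t.duration == pytest.approx(0.75)
        assert np.allclose(t.timestamps(), [0.0, 0.25, 0.5])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            SignalTrace(Channel.PPG, 64.0, [1.0, np.nan, 2.0])

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError, match="sampling_rate"):
            SignalTrace(Channel.PPG, 0.0, [1.0])

    def test_samples_are_immutable(self):
        t = SignalTrace(Channel.EDA, 4.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            t.samples[0] = 9.0


class TestTraceCSV:
    def test_single_column_dialect(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("value\n1.0\n2.0\n3.0\n")
        t = read_trace_csv(p, Channel.EDA, sampling_rate=4.0)
        assert len(t) == 3
        assert t.duration == pytest.approx(0.75)
        assert np.allclose(t.samples, [1.0, 2.0, 3.0])

    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        t = SignalTrace(Channel.PPG, 64.0, rng.normal(size=500), start_offset=1.25)
        p = tmp_path / "t.csv"
        write_trace_csv(t, p)
        back = read_trace_csv(p, Channel.PPG, sampling_rate=64.0)
        assert np.array_equal(back.samples, t.samples)
        assert back.sampling_rate == t.sampling_rate
        assert back.start_offset == t.start_offset

    def test_non_numeric_row_names_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("value\n1.0\nabc\n3.0\n")
        with pytest.raises(TraceFormatError, match="row 3"):
            read_trace_csv(p, Channel.EDA, sampling_rate=4.0)

    def test_non_uniform_timestamps(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value\n0.0,1\n0.25,2\n0.8,3\n")
        with pytest.raises(TraceFormatError, match="non-uniform"):
            read_trace_csv(p, Channel.EDA)

    def test_rate_mismatch(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value\n0.0,1\n0.25,2\n0.5,3\n")
        with pytest.raises(TraceFormatError, match="does not match"):
            read_trace_csv(p, Channel.EDA, sampling_rate=10.0)

    def test_rate_inferred_from_timestamps(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value\n0.0,1\n0.25,2\n0.5,3\n")
        t = read_trace_csv(p, Channel.EDA)
        assert t.sampling_rate == pytest.approx(4.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_trace_csv(tmp_path / "nope.csv", Channel.PPG, 64.0)

    def test_write_rows(self, tmp_path):
        t = SignalTrace(Channel.EDA, 1.0, [3.5, 4.5])
        p = tmp_path / "t.csv"
        write_trace_csv(t, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "time_s,value"
        assert [float(x) for x in lines[1].split(",")] == [0.0, 3.5]
        assert [float(x) for x in lines[2].split(",")] == [1.0, 4.5]

    def test_write_empty_trace_errors(self, tmp_path):
        t = SignalTrace(Channel.EDA, 1.0, [])
        with pytest.raises(ValueError, match="empty"):
            write_trace_csv(t, tmp_path / "t.csv")

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=50,
        ),
        rate=st.sampled_from([1.0, 4.0, 64.0]),
    )
    def test_roundtrip_property(self, tmp_path_factory, values, rate):
        t = SignalTrace(Channel.EDA, rate, values)
        p = tmp_path_factory.mktemp("rt") / "t.csv"
        write_trace_csv(t, p)
        back = read_trace_csv(p, Channel.EDA, sampling_rate=rate)
        assert np.allclose(back.samples, t.samples, rtol=1e-9, atol=0)


class TestScheduleCSV:
    def test_four_interval_schedule(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "phase,start_s,end_s\n"
            "BASELINE,0,300\nTSST_P,300,600\nTSST_S,600,900\nTSST_A,900,1200\n"
        )
        s = read_schedule_csv(p)
        assert len(s) == 4
        assert s.phases() == (Phase.BASELINE, Phase.TSST_P, Phase.TSST_S, Phase.TSST_A)
        assert s.span == (0.0, 1200.0)

    def test_rows_out_of_order_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("phase,start_s,end_s\nTSST_S,600,900\nBASELINE,0,300\n")
        s = read_schedule_csv(p)
        assert s.phases() == (Phase.BASELINE, Phase.TSST_S)

    def test_overlap_error_names_both(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("phase,start_s,end_s\nBASELINE,0,300\nTSST_P,200,600\n")
        with pytest.raises(ScheduleError, match="BASELINE.*TSST_P"):
            read_schedule_csv(p)

    def test_unknown_phase(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("phase,start_s,end_s\nWARMUP,0,300\n")
        with pytest.raises(ScheduleError, match="WARMUP"):
            read_schedule_csv(p)

    def test_inverted_interval(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("phase,start_s,end_s\nBASELINE,300,100\n")
        with pytest.raises(ScheduleError, match="exceed"):
            read_schedule_csv(p)

    def test_duplicate_phase_rejected(self):
        with pytest.raises(ScheduleError, match="more than once"):
            PhaseSchedule(
                (PhaseInterval(0, 10, Phase.BASELINE), PhaseInterval(10, 20, Phase.BASELINE))
            )

    def test_write_read_roundtrip(self, tmp_path):
        s = make_schedule()
        p = tmp_path / "s.csv"
        write_schedule_csv(s, p)
        assert read_schedule_csv(p) == s


class TestResample:
    def test_dc_invariance(self):
        t = SignalTrace(Channel.PPG, 1000.0, np.full(5000, 5.0))
        out = resample_trace(t, 64.0)
        assert out.sampling_rate == 64.0
        assert len(out) == round(5000 * 64 / 1000)
        assert np.max(np.abs(out.samples - 5.0)) < 1e-6

    def test_sinusoid_matches_analytic(self):
        # 1 Hz tone sampled at 1000 Hz for 30 s, resampled to 64 Hz
        src_rate, dst_rate, dur = 1000.0, 64.0, 30.0
        t_src = np.arange(int(src_rate * dur)) / src_rate
        t = SignalTrace(Channel.PPG, src_rate, np.sin(2 * np.pi * t_src))
        out = resample_trace(t, dst_rate)
        t_dst = np.arange(len(out)) / dst_rate
        expected = np.sin(2 * np.pi * t_dst)
        interior = slice(int(dst_rate), -int(dst_rate))  # exclude 1 s at each edge
        assert np.max(np.abs(out.samples[interior] - expected[interior])) < 0.01

    def test_identity_at_own_rate(self):
        t = SignalTrace(Channel.EDA, 4.0, [1.0, 2.0, 3.0])
        out = resample_trace(t, 4.0)
        assert np.array_equal(out.samples, t.samples)

    def test_nonpositive_rate(self):
        t = SignalTrace(Channel.EDA, 4.0, [1.0])
        with pytest.raises(ValueError):
            resample_trace(t, 0.0)

    def test_preserves_channel_and_offset(self):
        t = SignalTrace(Channel.EDA, 1000.0, np.full(2000, 1.0), start_offset=3.0)
        out = resample_trace(t, 4.0)
        assert out.channel is Channel.EDA
        assert out.start_offset == 3.0

    def test_bandlimited_mean_preserved(self):
        rng = np.random.default_rng(5)
        src = 1000.0
        t_src = np.arange(int(src * 20)) / src
        # content below 0.4 * 4 Hz target
        x = 2.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t_src) + 0.2 * np.cos(2 * np.pi * 0.8 * t_src)
        out = resample_trace(SignalTrace(Channel.EDA, src, x), 4.0)
        assert abs(out.samples.mean() - x.mean()) < 0.01 * abs(x.mean())


class TestSlicePhase:
    def test_exact_sample_count(self):
        t = SignalTrace(Channel.EDA, 4.0, np.arange(4800.0))
        out = slice_phase(t, make_schedule(), Phase.BASELINE)
        assert len(out) == 1200
        assert out.start_offset == 0.0

    def test_endpoint_excluded(self):
        # sample at exactly t=2.0 must not be in [0, 2)
        t = SignalTrace(Channel.EDA, 1.0, [0.0, 1.0, 2.0, 3.0])
        sched = PhaseSchedule((PhaseInterval(0, 2, Phase.BASELINE), PhaseInterval(2, 4, Phase.TSST_S)))
        out = slice_phase(t, sched, Phase.BASELINE)
        assert np.array_equal(out.samples, [0.0, 1.0])

    def test_absent_phase(self):
        t = SignalTrace(Channel.EDA, 4.0, np.arange(4800.0))
        sched = PhaseSchedule((PhaseInterval(0, 300, Phase.BASELINE),))
        with pytest.raises(KeyError):
            slice_phase(t, sched, Phase.TSST_S)

    def test_partition_reconstructs_count(self):
        t = SignalTrace(Channel.EDA, 4.0, np.arange(4800.0))
        sched = make_schedule()
        total = sum(len(slice_phase(t, sched, iv.phase)) for iv in sched)
        assert total == len(t)


class TestSession:
    def test_schedule_must_fit_traces(self):
        ppg = SignalTrace(Channel.PPG, 64.0, np.zeros(64 * 100))
        eda = SignalTrace(Channel.EDA, 4.0, np.zeros(4 * 100))
        with pytest.raises(ValueError, match="does not cover"):
            Session("X", ppg, eda, make_schedule())

    def test_channel_mismatch(self):
        eda = SignalTrace(Channel.EDA, 4.0, np.zeros(4800))
        with pytest.raises(ValueError, match="PPG"):
            Session("X", eda, eda, make_schedule())
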