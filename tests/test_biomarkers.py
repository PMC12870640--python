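from datetime import datetime

import numpy as np
import pytest

from neuroloop.biomarkers import (
    DoseLog,
    DoseRecord,
    PKParams,
    SleepStageSeries,
    alpha_delta_ratio,
    asm_load,
    phase_synchrony,
    sleep_events,
    sleep_report,
    smooth_hypnogram,
)
from neuroloop.core import EEGRecording, ValidationError


def stages(seq):
    return SleepStageSeries(stages=list(seq), epoch_start_times=np.arange(len(seq)) * 30.0)


class TestHypnogram:
    def test_lone_epoch_absorbed_by_surrounding_run(self):
        series = stages(["N2"] * 10 + ["N1"] + ["N2"] * 10)
        out = smooth_hypnogram(series)
        assert out.stages[10] == "N2"

    def test_constant_series_unchanged(self):
        series = stages(["N2"] * 30)
        assert smooth_hypnogram(series).stages == series.stages

    def test_smoothing_is_stable_on_long_runs(self):
        series = stages(["wake"] * 20 + ["N2"] * 25 + ["N3"] * 20)
        once = smooth_hypnogram(series)
        twice = smooth_hypnogram(once)
        assert once.stages == twice.stages

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth_hypnogram(stages(["N2"] * 20), window=4)


class TestSleepEvents:
    def test_four_minute_bout_discarded(self):
        series = stages(["wake"] * 5 + ["N2"] * 8 + ["wake"] * 5)  # 8 epochs = 4 min
        assert sleep_events(series) == []

    def test_short_wake_gap_bridged(self):
        seq = ["wake"] * 4 + ["N2"] * 6 + ["wake"] * 2 + ["N3"] * 6 + ["wake"] * 4
        events = sleep_events(stages(seq))  # 60-s gap <= 90 s, merged 7 min
        assert len(events) == 1
        assert events[0].duration >= 300.0

    def test_all_wake_gives_empty(self):
        assert sleep_events(stages(["wake"] * 40)) == []

    def test_events_never_shorter_than_min_duration(self):
        rng = np.random.default_rng(0)
        seq = [("wake", "N1", "N2", "N3", "REM")[i] for i in rng.integers(0, 5, 200)]
        events = sleep_events(smooth_hypnogram(stages(seq)))
        assert all(e.duration >= 300.0 for e in events)


class TestSleepReport:
    start = datetime(2024, 3, 1, 19, 0, 0)

    def test_full_n2_overnight_period(self):
        series = stages(["N2"] * (12 * 120))  # 12 h of 30-s epochs
        rep = sleep_report(series, self.start, "19:00-07:00")
        assert rep["minutes"]["N2"] == pytest.approx(720.0)
        assert rep["fractions"]["N2"] == pytest.approx(1.0)

    def test_half_wake_half_n3(self):
        series = stages(["wake"] * 720 + ["N3"] * 720)
        rep = sleep_report(series, self.start, "19:00-07:00")
        assert rep["minutes"]["wake"] == pytest.approx(360.0)
        assert rep["minutes"]["N3"] == pytest.approx(360.0)
        assert rep["fractions"]["N3"] == pytest.approx(0.5)

    def test_partial_coverage_reported(self):
        series = stages(["N2"] * 720)  # only 6 h recorded
        rep = sleep_report(series, self.start, "19:00-07:00")
        assert rep["coverage"] == pytest.approx(0.5)
        assert rep["fractions"]["N2"] == pytest.approx(1.0)


def tone_recording(freq, fs=200.0, seconds=120.0, n_channels=3):
    t = np.arange(int(fs * seconds)) / fs
    data = np.tile(20.0 * np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return EEGRecording(data, [f"ch{i}" for i in range(n_channels)], fs=fs)


class TestAlphaDeltaRatio:
    def test_delta_tone_gives_near_zero_ratio(self):
        _, ratios = alpha_delta_ratio(tone_recording(2.0))
        assert (ratios < 0.05).all()

    def test_alpha_tone_gives_large_ratio(self):
        _, ratios = alpha_delta_ratio(tone_recording(10.0))
        assert (ratios > 20).all()

    def test_white_noise_ratio_near_one(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.normal(size=(3, 200 * 300)), ["a", "b", "c"], fs=200.0)
        _, ratios = alpha_delta_ratio(rec)
        assert abs(ratios.mean() - 1.0) < 0.2

    def test_trailing_partial_window_dropped(self):
        starts, ratios = alpha_delta_ratio(tone_recording(10.0, seconds=90.0))
        assert len(ratios) == 1


class TestPhaseSynchrony:
    def test_identical_channels_fully_synchronous(self):
        _, idx = phase_synchrony(tone_recording(6.0))
        np.testing.assert_allclose(idx, 1.0, atol=1e-9)

    def test_antiphase_pair_zero_synchrony(self):
        fs, seconds = 200.0, 120.0
        t = np.arange(int(fs * seconds)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)
        rec = EEGRecording(np.stack([x, -x]), ["a", "b"], fs=fs)
        _, idx = phase_synchrony(rec)
        np.testing.assert_allclose(idx, 0.0, atol=1e-9)

    def test_random_phases_match_expected_resultant(self):
        # E[R] for C i.i.d. uniform phases is ~ sqrt(pi)/(2 sqrt(C))
        rng = np.random.default_rng(0)
        C, n = 16, 50_000
        phases = rng.uniform(0, 2 * np.pi, size=(C, n))
        r = np.abs(np.exp(1j * phases).mean(axis=0))
        expected = np.sqrt(np.pi) / (2 * np.sqrt(C))
        se = r.std() / np.sqrt(n)
        assert abs(r.mean() - expected) < 3 * se + 1e-3

    def test_invariance_to_common_rescaling(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 200 * 120))
        rec = EEGRecording(data, list("abcd"), fs=200.0)
        _, idx1 = phase_synchrony(rec)
        rec2 = EEGRecording(5.0 * data, list("abcd"), fs=200.0)
        _, idx2 = phase_synchrony(rec2)
        np.testing.assert_allclose(idx1, idx2, atol=1e-12)

    def test_single_channel_rejected(self):
        rec = EEGRecording(np.zeros((1, 1000)), ["a"], fs=100.0)
        with pytest.raises(ValidationError):
            phase_synchrony(rec)


class TestAsmLoad:
    def test_concentration_halves_after_one_half_life(self):
        log = DoseLog(records=[DoseRecord("lev", 500.0, 0.0)])
        params = {"lev": PKParams(half_life_h=7.0)}
        t, load = asm_load(log, params, duration_h=14.0, normalize=False)
        peak = load[0]
        at_half_life = load[np.searchsorted(t, 7.0)]
        assert at_half_life == pytest.approx(0.5 * peak, rel=1e-9)

    def test_superposition_of_equal_doses(self):
        params = {"lev": PKParams(half_life_h=7.0)}
        single = DoseLog(records=[DoseRecord("lev", 500.0, 0.0)])
        double = DoseLog(records=[DoseRecord("lev", 500.0, 0.0),
                                  DoseRecord("lev", 500.0, 7.0)])
        t, c1 = asm_load(single, params, duration_h=14.0, normalize=False)
        _, c2 = asm_load(double, params, duration_h=14.0, normalize=False)
        i = np.searchsorted(t, 7.0)
        assert c2[i] == pytest.approx(1.5 * c1[0], rel=1e-9)

    def test_empty_log_gives_zero_series(self):
        _, load = asm_load(DoseLog(records=[]), {}, duration_h=5.0)
        assert not load.any()

    def test_linearity_in_dose_and_additivity_across_drugs(self):
        p = {"a": PKParams(3.0), "b": PKParams(9.0)}
        log_a = DoseLog(records=[DoseRecord("a", 100.0, 0.0)])
        log_2a = DoseLog(records=[DoseRecord("a", 200.0, 0.0)])
        log_b = DoseLog(records=[DoseRecord("b", 50.0, 2.0)])
        log_ab = DoseLog(records=[DoseRecord("a", 100.0, 0.0),
                                  DoseRecord("b", 50.0, 2.0)])
        _, ca = asm_load(log_a, p, 12.0, normalize=False)
        _, c2a = asm_load(log_2a, p, 12.0, normalize=False)
        _, cb = asm_load(log_b, p, 12.0, normalize=False)
        _, cab = asm_load(log_ab, p, 12.0, normalize=False)
        np.testing.assert_allclose(c2a, 2 * ca, atol=1e-9)
        np.testing.assert_allclose(cab, ca + cb, atol=1e-9)

    def test_unknown_drug_rejected_by_name(self):
        log = DoseLog(records=[DoseRecord("mystery", 10.0, 0.0)])
        with pytest.raises(ValidationError, match="mystery"):
            asm_load(log, {}, duration_h=2.0)
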