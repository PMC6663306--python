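"""Referencing, artifact screening, and epoch extraction."""

import numpy as np
import pytest

from stimnet.errors import (
    InsufficientDataError,
    ReferencingError,
    ScheduleError,
)
from stimnet.preproc import (
    Recording,
    common_average_reference,
    extract_epochs,
    screen_artifact_electrodes,
    window_samples,
)
from stimnet.schedule import SessionSchedule, StimTrial


def _schedule(n_trials=4, duration=0.5, start=31.0, gap=3.0, pair=("c0", "c1")):
    trials = []
    t = start
    for _ in range(n_trials):
        trials.append(
            StimTrial(
                onset=t,
                duration=duration,
                amplitude=1.0,
                pulse_frequency=50.0,
                stim_pair=pair,
                isi=gap,
            )
        )
        t += duration + gap
    return SessionSchedule(baseline_span=(0.0, 30.0), trials=trials)


def _recording(n_channels=4, seconds=60.0, fs=500.0, rng=None, labels=None):
    rng = rng or np.random.default_rng(0)
    labels = labels or [f"c{i}" for i in range(n_channels)]
    return Recording(
        signal=rng.standard_normal((n_channels, int(seconds * fs))),
        fs=fs,
        labels=labels,
    )


class TestCommonAverageReference:
    def test_two_channel_closed_form(self):
        rec = Recording(
            signal=np.array([[3.0], [1.0]]), fs=500, labels=["a", "b"]
        )
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.signal[:, 0], [1.0, -1.0])

    def test_column_means_vanish(self, rng):
        rec = _recording(rng=rng)
        out = common_average_reference(rec)
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-10
        assert out.reference == "common_average"

    def test_matches_brute_force_loop(self, rng):
        rec = _recording(n_channels=8, seconds=1.0, rng=rng)
        out = common_average_reference(rec)
        expected = np.empty_like(rec.signal)
        for s in range(rec.n_samples):
            m = sum(rec.signal[c, s] for c in range(8)) / 8
            for c in range(8):
                expected[c, s] = rec.signal[c, s] - m
        np.testing.assert_allclose(out.signal, expected, atol=1e-12)

    def test_single_channel_and_rereference_rejected(self):
        rec = Recording(signal=np.zeros((1, 10)), fs=500, labels=["a"])
        with pytest.raises(ReferencingError):
            common_average_reference(rec)
        rec2 = _recording()
        out = common_average_reference(rec2)
        with pytest.raises(ReferencingError):
            common_average_reference(out)


class TestArtifactScreening:
    def test_unchanged_channel_kept_with_p_one(self):
        sched = _schedule()
        rec = _recording(rng=np.random.default_rng(1))
        # channel 2: make every pre window identical to its post window
        fs = rec.fs
        for t in sched.trials:
            onset = int(round(t.onset * fs))
            post = int(round(t.offset * fs)) + 50
            rec.signal[2, post : post + 500] = np.tile(
                rec.signal[2, onset - 250 : onset], 2
            )
        kept, discarded, pvals = screen_artifact_electrodes(rec, sched)
        assert "c2" in kept
        assert pvals["c2"] == 1.0

    def test_planted_post_offset_discarded(self):
        sched = _schedule(n_trials=50, start=31.0, gap=3.0)
        rec = _recording(seconds=230.0, rng=np.random.default_rng(2))
        fs = rec.fs
        for t in sched.trials:
            post = int(round(t.offset * fs)) + 50
            rec.signal[3, post : post + 500] += 50.0
        kept, discarded, _ = screen_artifact_electrodes(rec, sched)
        assert "c3" in discarded

    def test_suppressed_channel_kept(self):
        # one-sided rule: significantly *lower* post amplitude is retained
        sched = _schedule(n_trials=50, start=31.0)
        rec = _recording(seconds=230.0, rng=np.random.default_rng(3))
        fs = rec.fs
        for t in sched.trials:
            post = int(round(t.offset * fs)) + 50
            rec.signal[3, post : post + 500] *= 0.2
        kept, discarded, pvals = screen_artifact_electrodes(rec, sched)
        assert "c3" in kept
        assert pvals["c3"] < 0.05

    def test_stimulated_pair_exempt(self):
        sched = _schedule(n_trials=50, start=31.0)
        rec = _recording(seconds=230.0, rng=np.random.default_rng(4))
        fs = rec.fs
        for t in sched.trials:
            post = int(round(t.offset * fs)) + 50
            rec.signal[0, post : post + 500] += 100.0
        kept, _, pvals = screen_artifact_electrodes(rec, sched)
        assert "c0" in kept and "c0" not in pvals

    def test_too_few_trials(self):
        sched = _schedule(n_trials=1)
        rec = _recording()
        with pytest.raises(InsufficientDataError):
            screen_artifact_electrodes(rec, sched)


class TestExtractEpochs:
    def test_thirty_second_baseline_tiles_into_sixty_windows(self):
        sched = _schedule()
        rec = _recording()
        wins = extract_epochs(rec, sched)
        assert sum(w.role == "baseline" for w in wins) == 60

    def test_post100_span_arithmetic(self):
        # onset 10.0 s puts the trial inside a shifted baseline; use a
        # direct schedule instead: trial at 10.0 s, 0.5 s duration, fs 500
        trial = StimTrial(
            onset=10.0, duration=0.5, amplitude=1, pulse_frequency=50,
            stim_pair=("c0", "c1"), isi=3.0,
        )
        sched = SessionSchedule(baseline_span=(0.0, 9.0), trials=[trial])
        rec = _recording(seconds=15.0)
        wins = extract_epochs(rec, sched)
        post100 = [w for w in wins if w.role == "post100"][0]
        assert (post100.start, post100.stop) == (5300, 5550)
        pre = [w for w in wins if w.role == "pre"][0]
        assert (pre.start, pre.stop) == (4750, 5000)
        post600 = [w for w in wins if w.role == "post600"][0]
        assert (post600.start, post600.stop) == (5550, 5800)

    def test_empty_trial_list_returns_only_baseline(self):
        sched = SessionSchedule(baseline_span=(0.0, 30.0), trials=[])
        wins = extract_epochs(_recording(), sched)
        assert {w.role for w in wins} == {"baseline"}

    def test_trial_past_recording_end_dropped_with_warning(self, caplog):
        sched = _schedule(n_trials=3, start=31.0)
        rec = _recording(seconds=36.0)  # last trial's post600 won't fit
        with caplog.at_level("WARNING"):
            wins = extract_epochs(rec, sched)
        trials_present = {w.trial_index for w in wins if w.trial_index is not None}
        assert trials_present == {0}
        assert "dropped" in caplog.text

    @pytest.mark.parametrize("fs", [500, 512, 1000, 1024, 2000])
    def test_window_sample_counts_across_clinical_rates(self, fs):
        sched = _schedule()
        rec = _recording(fs=fs, seconds=60.0)
        wins = extract_epochs(rec, sched)
        expected = int(round(0.5 * fs))
        assert window_samples(fs) == expected
        assert all(w.n_samples == expected for w in wins)

    def test_no_window_overlaps_stimulation_or_buffer(self):
        for seed in range(5):
            from stimnet.schedule import draw_trial_schedule

            sched = draw_trial_schedule(n_trials=20, seed=seed)
            fs = 500.0
            rec = _recording(seconds=sched.end_time + 3.0, fs=fs)
            wins = extract_epochs(rec, sched)
            forbidden = []
            for t in sched.trials:
                a = int(round(t.onset * fs))
                b = int(round(t.offset * fs)) + int(round(0.1 * fs))
                forbidden.append((a, b))
            for w in wins:
                for a, b in forbidden:
                    assert w.stop <= a or w.start >= b

    def test_pre_window_before_recording_start_raises(self):
        trial = StimTrial(
            onset=0.2, duration=0.5, amplitude=1, pulse_frequency=50,
            stim_pair=("c0", "c1"), isi=0.1,
        )
        sched = SessionSchedule(baseline_span=(0.0, 0.1), trials=[trial])
        with pytest.raises(ScheduleError):
            extract_epochs(_recording(seconds=10.0), sched)
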