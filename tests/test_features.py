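"""Feature quantification: onset density, tempo, pitch, harmony, Z-scoring."""

import warnings

import numpy as np
import pytest

from tensionlab import features as feat
from tensionlab.timebase import OnsetTable, SampledSeries
from .conftest import make_series


def onsets_at(times, voice="melody", pitches=None, beats=None):
    pitches = pitches if pitches is not None else [60] * len(times)
    beats = beats if beats is not None else [True] * len(times)
    rows = [(t, k // 3, (k % 3) / 3, voice, p, b)
            for k, (t, p, b) in enumerate(zip(times, pitches, beats))]
    return OnsetTable.from_rows(rows)


class TestOnsetFrequency:
    def test_longest_event_scores_zero_and_subtraction(self):
        # durations 3.51 and 0.5 with the observed maximum as reference
        t = onsets_at([0.0, 3.51, 4.01, 5.0])
        f = feat.onset_frequency(t)
        # first event (duration 3.51) -> 0; second (0.5) -> 3.01
        assert f.values[0] == pytest.approx(0.0)
        idx = int(round((3.6 - 0.0) / 0.1))
        assert f.values[idx] == pytest.approx(3.51 - 0.5)

    def test_isochronous_constant(self):
        f = feat.onset_frequency(onsets_at([0.0, 0.5, 1.0, 1.5, 2.0]))
        assert np.allclose(f.values, f.values[0])

    def test_duration_exceeding_max_errors(self):
        with pytest.raises(ValueError):
            feat.onset_frequency(onsets_at([0.0, 1.0, 5.0]), max_duration=2.0)

    def test_translation_invariance(self):
        times = [0.0, 0.7, 1.1, 2.0, 2.2, 3.0]
        a = feat.onset_frequency(onsets_at(times))
        b = feat.onset_frequency(onsets_at([t + 11.3 for t in times]))
        assert np.allclose(a.values, b.values)

    def test_coincident_onsets_merge(self):
        # two voices hitting within 30 ms count as one event
        rows = [(0.0, 0, 0.0, "melody", 60, True),
                (0.01, 0, 0.0, "bass", 40, False),
                (1.0, 0, 1 / 3, "melody", 62, True),
                (2.0, 0, 2 / 3, "melody", 64, True)]
        f = feat.onset_frequency(OnsetTable(onsets_at([0, 1, 2]).frame.iloc[0:0].pipe(
            lambda _: __import__("pandas").DataFrame(
                rows, columns=list(OnsetTable.REQUIRED)))))
        assert np.allclose(f.values, f.values[0])  # isochronous after merging


class TestTempoSeries:
    def test_isochronous_60bpm(self):
        f = feat.tempo_series(onsets_at([0.0, 1.0, 2.0, 3.0]))
        assert np.allclose(f.values, 60.0)

    def test_missing_beat_interpolated(self):
        # beats flagged at 0 and 2 s; the middle beat is unmarked but its tick
        # is recovered by interpolation -> constant 60 BPM
        rows = [(0.0, 0, 0.0, "melody", 60, True),
                (2.0, 0, 2 / 3, "melody", 62, True),
                (3.0, 1, 0.0, "melody", 64, True)]
        f = feat.tempo_series(OnsetTable.from_rows(rows))
        assert np.allclose(f.values, 60.0)

    def test_tempo_change_by_hand(self):
        # inter-beat intervals 0.5 s then 1.0 s -> 120 BPM then 60 BPM
        f = feat.tempo_series(onsets_at([0.0, 0.5, 1.5]))
        assert f.values[0] == pytest.approx(120.0)
        assert f.values[-1] == pytest.approx(60.0)

    def test_fewer_than_two_beats_errors(self):
        with pytest.raises(ValueError):
            feat.tempo_series(onsets_at([0.0, 1.0], beats=[True, False]))

    def test_faster_tempo_means_larger_onset_frequency(self):
        slow = onsets_at([0.0, 1.0, 2.0, 3.0])
        fast = onsets_at([0.0, 0.5, 1.0, 1.5])
        of_slow = feat.onset_frequency(slow, max_duration=2.0)
        of_fast = feat.onset_frequency(fast, max_duration=2.0)
        assert of_fast.values[0] > of_slow.values[0]


class TestPitchHeight:
    def test_held_note_constant(self):
        f = feat.pitch_height(onsets_at([0.0, 3.0], pitches=[60, 60]), "melody")
        assert np.allclose(f.values[~np.isnan(f.values)], 60.0)

    def test_ascending_staircase(self):
        f = feat.pitch_height(
            onsets_at([0.0, 1.0, 2.0, 3.0], pitches=[60, 62, 64, 65]), "melody")
        vals = f.values[~np.isnan(f.values)]
        assert np.all(np.diff(vals) >= 0)
        assert set(np.unique(vals)) == {60, 62, 64, 65}

    def test_inactive_voice_missing_outside_span(self):
        rows = [(0.0, 0, 0.0, "melody", 60, True),
                (4.0, 1, 1 / 3, "inner", 55, False),
                (5.0, 1, 2 / 3, "inner", 57, False),
                (10.0, 3, 1 / 3, "melody", 62, True)]
        f = feat.pitch_height(OnsetTable.from_rows(rows), "inner")
        t = f.series.times
        assert np.all(np.isnan(f.values[t < 4.0 - 1e-9]))
        assert np.all(np.isnan(f.values[t > 5.0 + 1e-9]))
        assert not np.any(np.isnan(f.values[(t >= 4.0) & (t <= 5.0)]))

    def test_empty_voice_warns_all_missing(self):
        with pytest.warns(UserWarning):
            f = feat.pitch_height(onsets_at([0.0, 1.0]), "bass")
        assert np.all(np.isnan(f.values))


class TestHarmonicTension:
    def _chords(self, rows):
        import pandas as pd
        return feat.ChordTable(pd.DataFrame(
            rows, columns=["chord_index", "reduction_onset_s", "performance_onset_s"]))

    def test_sampled_two_seconds_after_onset(self):
        red = make_series(np.arange(200) * 1.0)  # value = 10 * time
        chords = self._chords([(1, 10.0, 0.0), (2, 15.0, 3.0)])
        f = feat.harmonic_tension(red, chords, lag=2.0)
        assert f.values[0] == pytest.approx(120.0)  # reduction value at 12 s
        assert f.values[-1] == pytest.approx(170.0)  # at 17 s

    def test_zero_lag_samples_at_onset(self):
        red = make_series(np.arange(200) * 1.0)
        f = feat.harmonic_tension(red, self._chords([(1, 10.0, 0.0), (2, 15.0, 3.0)]),
                                  lag=0.0)
        assert f.values[0] == pytest.approx(100.0)

    def test_lag_past_series_end_clamps_with_warning(self):
        red = make_series(np.arange(50) * 1.0)  # ends at 4.9 s
        with pytest.warns(UserWarning):
            f = feat.harmonic_tension(red, self._chords([(1, 0.0, 0.0), (2, 4.5, 3.0)]),
                                      lag=2.0)
        assert f.values[-1] == pytest.approx(49.0)

    def test_repeated_chord_reuses_predecessor(self):
        red = make_series(np.arange(200) * 1.0)
        chords = self._chords([(1, 10.0, 0.0), (2, np.nan, 2.0), (3, 15.0, 4.0)])
        f = feat.harmonic_tension(red, chords, lag=2.0)
        idx = int(round(2.5 / 0.1))
        assert f.values[idx] == pytest.approx(120.0)  # chord 2 reuses chord 1


class TestNormalize:
    def test_two_point_series(self):
        # (0, 2): mean 1, sample std (n-1 denominator) sqrt(2)
        f = feat.FeatureSeries("loudness", make_series([0.0, 2.0]))
        out = feat.normalize([f])["loudness"]
        assert out.values == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert out.normalization == pytest.approx((1.0, np.sqrt(2)))

    def test_pooled_pitch_moments_match_bruteforce(self):
        mel = feat.FeatureSeries("pitch_melody", make_series([72.0] * 10))
        bass = feat.FeatureSeries("pitch_bass", make_series([48.0] * 10))
        inner = feat.FeatureSeries("pitch_inner", make_series([60.0] * 10))
        out = feat.normalize([mel, bass, inner])
        pooled = np.concatenate([[72.0] * 10, [48.0] * 10, [60.0] * 10])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        assert mu == pytest.approx(60.0)
        assert np.allclose(out["pitch_melody"].values, (72 - mu) / sd)
        assert np.allclose(out["pitch_bass"].values, (48 - mu) / sd)
        assert out["pitch_melody"].values[0] == pytest.approx(-out["pitch_bass"].values[0])
        assert np.allclose(out["pitch_inner"].values, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        f = feat.FeatureSeries("tempo", make_series(rng.uniform(40, 120, 50)))
        once = feat.normalize([f])["tempo"]
        twice = feat.normalize([once])["tempo"]
        assert np.allclose(once.values, twice.values, atol=1e-9)
        assert abs(once.values.mean()) < 1e-9
        assert once.values.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_pooled_normalization_preserves_pitch_differences(self):
        rng = np.random.default_rng(1)
        mel = feat.FeatureSeries("pitch_melody", make_series(rng.uniform(60, 80, 30)))
        bass = feat.FeatureSeries("pitch_bass", make_series(rng.uniform(40, 60, 30)))
        out = feat.normalize([mel, bass])
        diff_raw = mel.values - bass.values
        diff_norm = out["pitch_melody"].values - out["pitch_bass"].values
        ratio = diff_norm / diff_raw
        assert np.allclose(ratio, ratio[0])

    def test_zero_variance_errors_naming_feature(self):
        f = feat.FeatureSeries("harmony", make_series([5.0] * 10))
        with pytest.raises(ValueError, match="harmony"):
            feat.normalize([f])
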