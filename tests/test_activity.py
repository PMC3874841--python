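"""Activity analysis: change events, activity levels, coordination, shuffles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tensionlab import activity as act
from tensionlab.activity import (
    ChangePointProcess, activity_levels, activity_rate, alternation_score,
    change_point_process, circular_shift, collection_summary, coordination_score,
    local_coordination, processes_from_collection,
)


def proc(events, direction="increase", rater="r"):
    return ChangePointProcess(rater=rater, events=np.asarray(events, dtype=np.uint8),
                              direction=direction)


class TestChangePointProcess:
    def test_unit_ramp_fires_every_sample(self):
        p = change_point_process(np.arange(0, 20, 1.0), "increase")
        assert np.all(p.events == 1)

    def test_accumulation_fires_every_third_sample(self):
        # rises of 0.4/sample: 0.4, 0.8, 1.2 -> event, reset; repeat
        p = change_point_process(np.arange(0, 8, 0.4), "increase")
        expected = np.zeros(19, dtype=np.uint8)
        expected[2::3] = 1
        assert np.array_equal(p.events, expected)

    def test_pure_decrease_yields_no_increase_events(self):
        p = change_point_process(np.arange(50, 0, -1.0), "increase")
        assert p.n_events == 0

    def test_reversal_resets_accumulation(self):
        # up 0.6, down 5, up 0.6: the two rises never accumulate to 1.0
        rating = np.array([50.0, 50.6, 45.6, 46.2])
        p = change_point_process(rating, "increase")
        assert p.n_events == 0
        # but the decrease process sees the 5-unit fall
        assert change_point_process(rating, "decrease").n_events == 1

    def test_constant_series_all_zero(self):
        assert change_point_process(np.full(30, 42.0), "increase").n_events == 0


class TestActivityLevels:
    def test_proportion_denominator_is_n_responses(self):
        # 10 of 25 raters active in the single frame -> level 0.40
        procs = [proc(np.concatenate([[1], np.zeros(9, int)]) if i < 10
                      else np.zeros(10, int)) for i in range(25)]
        lv = activity_levels(procs, frame_s=1.0)
        assert lv.levels[0] == pytest.approx(0.40)
        assert lv.n_responses == 25

    def test_all_zero_and_all_ones(self):
        zero = [proc(np.zeros(40, int)) for _ in range(5)]
        ones = [proc(np.ones(40, int)) for _ in range(5)]
        assert np.all(activity_levels(zero, 1.0).levels == 0.0)
        assert np.all(activity_levels(ones, 1.0).levels == 1.0)

    def test_rate_of_alternating_frames(self):
        ev = np.zeros(200, int)
        ev[::20] = 1  # one event in every other 1 s frame
        procs = [proc(ev) for _ in range(4)]
        assert activity_rate(procs, 1.0) == pytest.approx(0.5)

    def test_frame_shorter_than_sample_errors(self):
        with pytest.raises(ValueError):
            activity_levels([proc(np.zeros(20, int))], frame_s=0.05)


class TestCoordinationScore:
    def test_concentrated_events_score_significant(self):
        # 25 identical raters, events only in odd frames
        ev = np.zeros(400, int)
        for f in range(1, 40, 2):
            ev[f * 10 + 3] = 1
        procs = [proc(ev) for _ in range(25)]
        res = coordination_score(procs, 1.0)
        assert res.score >= 2.0

    def test_score_never_exceeds_cap(self):
        ev = np.zeros(2000, int)
        ev[5::20] = 1
        procs = [proc(ev) for _ in range(25)]
        assert coordination_score(procs, 1.0).score <= 16.0

    def test_independent_raters_typically_below_two(self):
        rng = np.random.default_rng(21)
        low = 0
        for _ in range(10):
            procs = [proc((rng.random(2000) < 0.022).astype(int)) for _ in range(25)]
            low += coordination_score(procs, 1.0).score < 2.0
        assert low >= 9

    def test_chi_square_matches_direct_histogram_oracle(self):
        # 10-frame toy, one slicing; oracle computes the Poisson-binomial
        # expected histogram and Pearson statistic from first principles
        rng = np.random.default_rng(22)
        procs = [proc((rng.random(100) < 0.3).astype(int)) for _ in range(4)]
        res = coordination_score(procs, 1.0)
        ev = np.vstack([p.events for p in procs])
        for off in range(10):
            active = ev[:, off:off + (100 - off) // 10 * 10] \
                .reshape(4, -1, 10).max(axis=2)
            n_frames = active.shape[1]
            rates = active.mean(axis=1)
            pmf = np.array([1.0])
            for pr in rates:
                pmf = np.convolve(pmf, [1 - pr, pr])
            observed = np.bincount(active.sum(axis=0), minlength=5).astype(float)
            expected = pmf * n_frames
            # greedy left-to-right merge at >= 5 expected
            ob, eb, oa, ea = [], [], 0.0, 0.0
            for o, e in zip(observed, expected):
                oa += o; ea += e
                if ea >= 5:
                    ob.append(oa); eb.append(ea); oa = ea = 0.0
            if ea > 0 and eb:
                ob[-1] += oa; eb[-1] += ea
            elif ea > 0:
                ob, eb = [oa], [ea]
            if len(ob) < 2:
                p_expected = 1.0
            else:
                chi2 = sum((o - e) ** 2 / e for o, e in zip(ob, eb))
                p_expected = stats.chi2.sf(chi2, len(ob) - 1)
            assert res.p_per_slicing[off] == pytest.approx(p_expected, abs=1e-9)

    def test_invariant_under_rater_relabeling_and_joint_rotation(self):
        rng = np.random.default_rng(23)
        evs = [(rng.random(600) < 0.1).astype(int) for _ in range(8)]
        procs = [proc(e) for e in evs]
        base = coordination_score(procs, 1.0).score
        shuffled = [proc(evs[i]) for i in rng.permutation(8)]
        assert coordination_score(shuffled, 1.0).score == pytest.approx(base)
        # joint rotation: exact for the frame-aligned slicing, approximate
        # overall (partial trailing frames are trimmed per slicing)
        rotated = [proc(np.roll(e, 170)) for e in evs]
        res_rot = coordination_score(rotated, 1.0)
        assert res_rot.p_per_slicing[0] == pytest.approx(
            coordination_score(procs, 1.0).p_per_slicing[0])
        assert res_rot.score == pytest.approx(base, abs=0.15)

    def test_no_events_warns_score_zero(self):
        procs = [proc(np.zeros(200, int)) for _ in range(5)]
        with pytest.warns(UserWarning):
            assert coordination_score(procs, 1.0).score == 0.0


class TestAlternationScore:
    def test_strict_alternation_scores_high(self):
        inc_ev = np.zeros(600, int)
        dec_ev = np.zeros(600, int)
        for f in range(0, 60, 2):
            inc_ev[f * 10 + 4] = 1
            if f + 1 < 60:
                dec_ev[(f + 1) * 10 + 4] = 1
        inc = [proc(inc_ev, "increase") for _ in range(12)]
        dec = [proc(dec_ev, "decrease") for _ in range(12)]
        assert alternation_score(inc, dec, 1.0).score >= 2.0

    def test_independent_processes_typically_low(self):
        rng = np.random.default_rng(24)
        low = 0
        for _ in range(10):
            inc = [proc((rng.random(1200) < 0.02).astype(int), "increase")
                   for _ in range(12)]
            dec = [proc((rng.random(1200) < 0.02).astype(int), "decrease")
                   for _ in range(12)]
            low += alternation_score(inc, dec, 1.0).score < 2.0
        assert low >= 8

    def test_all_zero_direction_degenerate(self):
        inc = [proc(np.ones(300, int), "increase") for _ in range(4)]
        dec = [proc(np.zeros(300, int), "decrease") for _ in range(4)]
        with pytest.warns(UserWarning):
            assert alternation_score(inc, dec, 1.0).score == 0.0


class TestLocalCoordination:
    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=200, deadline=None)
    def test_circular_shift_conserves_event_counts(self, seed):
        rng = np.random.default_rng(seed)
        p = proc((rng.random(100) < rng.uniform(0.02, 0.4)).astype(int))
        shift = int(rng.integers(-80, 80))
        assert circular_shift(p, shift).n_events == p.n_events

    def test_synchronized_burst_flagged_remote_frames_not(self):
        rng = np.random.default_rng(25)
        n = 1200
        procs = []
        for _ in range(25):
            ev = (rng.random(n) < 0.015).astype(int)
            ev[600:605] = 1  # shared burst at 60 s
            procs.append(proc(ev))
        frames = [(59.8, 1.0), (20.0, 1.0), (90.0, 1.0)]
        res = local_coordination(procs, frames, n_shuffles=500, seed=1)
        assert res.flagged[0]
        assert not res.flagged[1] and not res.flagged[2]

    def test_single_rater_all_p_one(self):
        p = proc((np.random.default_rng(3).random(500) < 0.1).astype(int))
        res = local_coordination([p], [(2.0, 1.0), (10.0, 1.0)], n_shuffles=200,
                                 seed=0)
        assert np.all(res.p == 1.0)
        assert not res.flagged.any()

    def test_small_shuffle_count_warns(self):
        procs = [proc(np.zeros(200, int)) for _ in range(3)]
        with pytest.warns(UserWarning):
            local_coordination(procs, [(0.0, 1.0)], n_shuffles=50, seed=0)


class TestCollectionSummary:
    def test_common_shape_plus_offsets_closed_form(self):
        rng = np.random.default_rng(26)
        shape = np.cumsum(rng.standard_normal(400)) * 0.5 + 50
        offsets = np.array([-6.0, -2.0, 0.0, 3.0, 5.0])
        ratings = shape[None, :] + offsets[:, None]
        s = collection_summary(ratings)
        assert s["tension_std"] == pytest.approx(np.std(shape, ddof=1))
        assert s["std_ratio"] == pytest.approx(
            np.std(shape, ddof=1) / np.std(offsets, ddof=1))

    def test_identical_raters_undefined_ratio(self):
        ratings = np.tile(np.linspace(0, 80, 200), (4, 1))
        with pytest.warns(UserWarning):
            s = collection_summary(ratings)
        assert np.isnan(s["std_ratio"])

    def test_flat_shape_independent_noise_ratio_near_zero(self):
        rng = np.random.default_rng(27)
        ratings = 50 + rng.standard_normal((25, 3000)) * 5
        s = collection_summary(ratings)
        assert s["std_ratio"] < 0.35

    def test_binarization_round_trip_from_collection(self):
        # ratings built from known events recover exactly those events
        rng = np.random.default_rng(28)
        ev = (rng.random(300) < 0.08).astype(np.uint8)
        rating = 50.0 + np.concatenate([[0], np.cumsum(ev * 1.1)])
        p = processes_from_collection(rating[None, :], "increase")[0]
        assert np.array_equal(p.events, ev)
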