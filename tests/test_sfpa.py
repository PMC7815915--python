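"""Event downsampling, Fisher CIs, peak windows and the two SFPA models."""

import numpy as np
import pandas as pd
import pytest

from sfpa import (
    CorrelationSFPA,
    DataError,
    EventTable,
    PeakSFPA,
    StateTimecourses,
    SubjectTimeseries,
    default_roiset,
    event_downsample,
    fisher_ci,
    peak_event_windows,
    sliding_isfc,
    zscore_isfc,
)
from sfpa.sfpa import network_average_window, network_peak_summary
from sfpa.isfc import ISFCSeries, upper_pairs


def _series(z, valid_start=7, window_len=15, roi_labels=("a", "b"), subject_z=None):
    n_pairs = z.shape[0]
    return ISFCSeries(
        z=z,
        pairs=upper_pairs(len(roi_labels)),
        roi_labels=list(roi_labels),
        valid_trs=np.arange(valid_start, valid_start + z.shape[1]),
        window_len=window_len,
        subject_ids=["s0", "s1"] if subject_z is not None else ["s0"],
        subject_z=subject_z,
    )


class TestFisherCI:
    @pytest.mark.parametrize(
        "r, n, expected",
        [
            (0.44, 49, (0.18, 0.64)),
            (0.03, 49, (-0.25, 0.31)),
            (-0.08, 49, (-0.35, 0.21)),
            (0.92, 36, (0.85, 0.96)),
        ],
    )
    def test_reproduces_published_intervals(self, r, n, expected):
        lo, hi = fisher_ci(r, n)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_r_interval_symmetric(self):
        lo, hi = fisher_ci(0.0, 30)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_degenerate_r_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = fisher_ci(1.0, 30)
        assert lo == hi == 1.0


class TestEventDownsample:
    def test_boundary_events_discarded(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 86))   # T=100, window 15 -> valid 7..92
        series = _series(z)
        events = EventTable.from_onsets(["early", "mid", "late"],
                                        [3.0, 50.0, 96.0], 1.0)
        ev = event_downsample(series, events)
        assert ev.retained_event_ids == ["mid"]

    def test_all_valid_retained_in_order(self):
        rng = np.random.default_rng(1)
        series = _series(rng.standard_normal((3, 86)))
        events = EventTable.from_onsets(["a", "b", "c"], [10.0, 40.0, 80.0], 1.0)
        ev = event_downsample(series, events)
        assert ev.retained_event_ids == ["a", "b", "c"]
        np.testing.assert_array_equal(
            ev.values, series.z[:, [3, 33, 73]]
        )

    def test_no_retained_events_errors(self):
        rng = np.random.default_rng(2)
        series = _series(rng.standard_normal((3, 86)))
        events = EventTable.from_onsets(["a"], [2.0], 1.0)
        with pytest.raises(DataError):
            event_downsample(series, events)

    def test_sherlock_sized_run_retains_49(self, ):
        rng = np.random.default_rng(3)
        subs = [
            SubjectTimeseries.from_raw(f"s{k}", rng.standard_normal((2, 946)),
                                       1.5, ["a", "b"])
            for k in range(2)
        ]
        series = sliding_isfc(subs, keep_subject_layers=False)
        onsets = np.linspace(12.0, (946 - 9) * 1.5, 49)
        events = EventTable.from_onsets([f"e{k}" for k in range(49)], onsets, 1.5)
        ev = event_downsample(series, events)
        assert ev.n_retained == 49


class TestZScoreISFC:
    def test_moments_after_zscoring(self):
        rng = np.random.default_rng(4)
        series = _series(rng.standard_normal((3, 50)))
        zed = zscore_isfc(series)
        np.testing.assert_allclose(zed.z.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(zed.z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 40))
        zed = zscore_isfc(_series(x))
        oracle = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                            keepdims=True)
        np.testing.assert_allclose(zed.z, oracle, atol=1e-12)

    def test_linear_ramp_symmetric(self):
        zed = zscore_isfc(_series(np.arange(10.0)[None, :].repeat(3, axis=0)))
        np.testing.assert_allclose(zed.z[0], -zed.z[0][::-1], atol=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DataError):
            zscore_isfc(_series(np.ones((3, 20))))


class TestPeakEventWindows:
    def test_window_is_29_bins_and_centered(self):
        rng = np.random.default_rng(6)
        series = _series(rng.standard_normal((3, 86)))
        events = EventTable.from_onsets(["a"], [50.0], 1.0)
        w = peak_event_windows(series, events, ["a"])
        assert w.per_event.shape[-1] == 29
        assert w.offsets[w.half] == 0
        # center bin equals the series value at the onset TR
        np.testing.assert_allclose(
            w.per_event[0, :, w.half], series.z[:, 50 - 7], atol=1e-12
        )

    def test_single_event_window_is_series_slice(self):
        rng = np.random.default_rng(7)
        series = _series(rng.standard_normal((3, 86)))
        events = EventTable.from_onsets(["a"], [40.0], 1.0)
        w = peak_event_windows(series, events, ["a"])
        np.testing.assert_allclose(
            w.per_event[0], series.z[:, 40 - 7 - 14 : 40 - 7 + 15], atol=1e-12
        )

    def test_edge_event_bins_marked_missing(self):
        rng = np.random.default_rng(8)
        series = _series(rng.standard_normal((3, 86)))
        events = EventTable.from_onsets(["a"], [10.0], 1.0)
        with pytest.warns(UserWarning, match="missing"):
            w = peak_event_windows(series, events, ["a"])
        assert np.isnan(w.per_event[0, :, 0]).all()     # bin -14 out of range
        assert np.isfinite(w.per_event[0, :, -1]).all()


class TestNetworkPeakSummary:
    def _window_with_subjects(self, n_sub):
        rng = np.random.default_rng(9)
        roiset = default_roiset()
        labels = roiset.table["roi_label"].tolist()
        subject_z = rng.standard_normal((n_sub, len(upper_pairs(len(labels))), 60))
        series = ISFCSeries(
            z=subject_z.mean(axis=0),
            pairs=upper_pairs(len(labels)),
            roi_labels=labels,
            valid_trs=np.arange(7, 67),
            window_len=15,
            subject_ids=[f"s{k}" for k in range(n_sub)],
            subject_z=subject_z,
        )
        events = EventTable.from_onsets(["a"], [40.0], 1.0)
        return peak_event_windows(series, events, ["a"]), roiset

    def test_three_subject_mean_sem_match_hand_computation(self):
        window, roiset = self._window_with_subjects(3)
        out = network_peak_summary(window, roiset, ["DMN"])
        _, per_sub = network_average_window(window, roiset, "DMN")
        vals = per_sub[:, window.half]
        assert out["onset_mean"].iloc[0] == pytest.approx(vals.mean())
        assert out["onset_sem"].iloc[0] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(3)
        )

    def test_single_subject_sem_missing(self):
        window, roiset = self._window_with_subjects(1)
        out = network_peak_summary(window, roiset, ["DMN"])
        assert np.isnan(out["onset_sem"].iloc[0])

    def test_identical_subjects_sem_zero(self):
        window, roiset = self._window_with_subjects(3)
        same = window.per_event_subject.copy()
        same[:] = same[:1]
        window = type(window)(
            per_event=window.per_event, offsets=window.offsets,
            event_ids=window.event_ids, pairs=window.pairs,
            roi_labels=window.roi_labels, per_event_subject=same,
            subject_ids=window.subject_ids,
        )
        out = network_peak_summary(window, roiset, ["DMN"])
        assert out["onset_sem"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestCorrelationSFPAModel:
    def _model(self, n_events=20, n_pairs_rois=3, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"r{k}" for k in range(n_pairs_rois)]
        z = rng.standard_normal((len(upper_pairs(n_pairs_rois)), 100))
        series = ISFCSeries(
            z=z, pairs=upper_pairs(n_pairs_rois), roi_labels=labels,
            valid_trs=np.arange(7, 107), window_len=15, subject_ids=["s0"],
        )
        onsets = np.linspace(10.0, 100.0, n_events)
        events = EventTable.from_onsets(
            [f"e{k}" for k in range(n_events)], onsets, 1.0
        )
        ev = event_downsample(series, events)
        states = StateTimecourses(
            {"surprise": rng.standard_normal(ev.n_retained)},
            {"surprise": np.ones(ev.n_retained, int)},
            ev.retained_event_ids,
        )
        return ev, states

    def test_perfect_correlation_recovered(self):
        ev, _ = self._model()
        states = StateTimecourses(
            {"surprise": ev.values[0].copy()},
            {"surprise": np.ones(ev.n_retained, int)},
            ev.retained_event_ids,
        )
        res = CorrelationSFPA(ev, states).fit(n_iter=200, seed=1)
        row = res.table.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p_perm"] <= 5 / 201

    def test_event_order_invariance(self):
        ev, states = self._model()
        res1 = CorrelationSFPA(ev, states).fit(n_iter=100, seed=2)
        # common reordering of events in both inputs leaves r unchanged
        perm = np.random.default_rng(0).permutation(ev.n_retained)
        ev2 = type(ev)(
            values=ev.values[:, perm], pairs=ev.pairs, roi_labels=ev.roi_labels,
            retained_event_ids=[ev.retained_event_ids[i] for i in perm],
            retained_onset_trs=ev.retained_onset_trs[perm],
        )
        states2 = StateTimecourses(
            {"surprise": states.states["surprise"][perm]},
            {"surprise": np.ones(ev.n_retained, int)},
            ev2.retained_event_ids,
        )
        res2 = CorrelationSFPA(ev2, states2).fit(n_iter=100, seed=2)
        np.testing.assert_allclose(
            res1.table["r"].to_numpy(), res2.table["r"].to_numpy(), atol=1e-12
        )

    def test_null_r_centered_at_zero_across_pairs(self):
        ev, states = self._model(n_events=40, n_pairs_rois=8, seed=3)
        res = CorrelationSFPA(ev, states).fit(n_iter=50, seed=4)
        rs = res.table["r"].to_numpy()
        assert abs(rs.mean()) < 3 * rs.std() / np.sqrt(len(rs))

    def test_seed_reproducibility(self):
        ev, states = self._model()
        r1 = CorrelationSFPA(ev, states).fit(n_iter=150, seed=7)
        r2 = CorrelationSFPA(ev, states).fit(n_iter=150, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_summary_mentions_measures(self):
        ev, states = self._model()
        res = CorrelationSFPA(ev, states).fit(n_iter=50, seed=5)
        assert "surprise" in res.summary()


class TestPeakSFPAModel:
    def test_end_to_end_on_small_dataset(self, small_dataset):
        (subjects, events, ratings, features, truth), cfg = small_dataset
        from sfpa import aggregate_states, zscore_ratings

        with pytest.warns(UserWarning):
            states = aggregate_states(zscore_ratings(ratings), events)
        series = sliding_isfc(subjects)
        model = PeakSFPA(series, events, states, default_roiset())
        res = model.fit(n_iter=100, seed=0)
        curve = res.curve("DMN", "surprise")
        assert len(curve["mean"]) == 29
        assert len(res.onset_summary) == 3 * len(states.measures)
        assert set(res.pair_tests["measure"]) == {"surprise"}
        # per-pair q values present and within [0, 1]
        assert res.pair_tests["q"].between(0, 1).all()
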