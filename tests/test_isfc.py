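"""ISFC engine: leave-one-out averaging, sliding/full correlations,
phase surrogates and the max-statistic null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfpa import (
    DataError,
    SubjectTimeseries,
    full_isfc,
    loo_average,
    max_null_isfc,
    phase_randomize,
    sliding_isfc,
)
from sfpa.isfc import fisher_z, fisher_z_inv


def _subjects_from_arrays(arrays, tr=1.5, labels=None):
    labels = labels or [f"r{i}" for i in range(arrays[0].shape[0])]
    return [
        SubjectTimeseries.from_raw(f"s{k}", a, tr, labels)
        for k, a in enumerate(arrays)
    ]


def brute_force_sliding_isfc(subjects, window_len=15):
    """Independent oracle: per-window np.corrcoef loops, Fisher-averaged."""
    T = subjects[0].n_trs
    R = len(subjects[0].roi_labels)
    half = window_len // 2
    centers = range(half, T - half)
    out = {}
    for i in range(R):
        for j in range(i, R):
            zs = []
            for t in centers:
                sl = slice(t - half, t + half + 1)
                z_t = []
                for k, s in enumerate(subjects):
                    others = [x for m, x in enumerate(subjects) if m != k]
                    L = np.mean([x.data for x in others], axis=0)
                    r_ij = np.corrcoef(s.data[i, sl], L[j, sl])[0, 1]
                    r_ji = np.corrcoef(s.data[j, sl], L[i, sl])[0, 1]
                    z_t.append(0.5 * (fisher_z(r_ij) + fisher_z(r_ji)))
                zs.append(np.mean(z_t))
            out[(i, j)] = np.array(zs)
    return out


class TestLooAverage:
    def test_two_subjects_returns_the_other(self, toy_subjects):
        out = loo_average(toy_subjects[:2], exclude="s0")
        np.testing.assert_array_equal(out, toy_subjects[1].data)

    def test_identical_subjects_average_to_self(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((2, 20))
        subs = _subjects_from_arrays([base.copy() for _ in range(4)])
        out = loo_average(subs, exclude="s2")
        np.testing.assert_allclose(out, subs[0].data, atol=1e-12)

    def test_hand_computed_mean(self):
        # ROI signals are z-scored at load, so plant the target values
        # in otherwise-identical noise and check the cell mean directly
        rng = np.random.default_rng(2)
        base = rng.standard_normal((1, 12))
        arrays = [base + c for c in (0.0, 0.0, 0.0)]
        subs = _subjects_from_arrays(arrays)
        excl = loo_average(subs, exclude="s0")
        np.testing.assert_allclose(
            excl, (subs[1].data + subs[2].data) / 2, atol=1e-12
        )

    def test_single_subject_errors(self, toy_subjects):
        with pytest.raises(DataError):
            loo_average(toy_subjects[:1], exclude="s0")


class TestSlidingISFC:
    def test_matches_brute_force_oracle(self, toy_subjects):
        series = sliding_isfc(toy_subjects, window_len=15)
        oracle = brute_force_sliding_isfc(toy_subjects, window_len=15)
        for p, (i, j) in enumerate(series.pairs):
            np.testing.assert_allclose(
                series.z[p], oracle[(i, j)], atol=1e-12,
                err_msg=f"pair ({i},{j})",
            )

    def test_shared_identical_signal_gives_unit_isfc(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal(60)
        subs = _subjects_from_arrays([np.vstack([sig, sig]) for _ in range(3)])
        series = sliding_isfc(subs)
        np.testing.assert_allclose(series.r, 1.0, atol=1e-5)

    def test_independent_noise_isfc_near_zero(self):
        rng = np.random.default_rng(4)
        subs = _subjects_from_arrays([rng.standard_normal((4, 400)) for _ in range(6)])
        series = sliding_isfc(subs, keep_subject_layers=False)
        off_diag = series.z[~series.is_diagonal()]
        # overlapping windows are correlated, so allow a generous margin
        assert abs(off_diag.mean()) < 0.01

    def test_valid_tr_count_946(self):
        rng = np.random.default_rng(5)
        subs = _subjects_from_arrays([rng.standard_normal((1, 946)) for _ in range(2)])
        series = sliding_isfc(subs, keep_subject_layers=False)
        assert series.n_valid == 932

    def test_symmetric_under_pair_swap(self, toy_subjects):
        series = sliding_isfc(toy_subjects)
        np.testing.assert_array_equal(
            series.pair_series("roiA", "roiB"), series.pair_series("roiB", "roiA")
        )

    def test_correlations_bounded_and_finite(self, toy_subjects):
        series = sliding_isfc(toy_subjects)
        assert np.all(np.isfinite(series.z))
        assert np.all(np.abs(series.r) <= 1)

    def test_noise_subject_attenuates_group_isfc(self):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal((2, 300))
        coherent = [sig + 0.3 * rng.standard_normal(sig.shape) for _ in range(5)]
        subs = _subjects_from_arrays(coherent)
        base = sliding_isfc(subs, keep_subject_layers=False)
        noisy = _subjects_from_arrays(
            [a for a in [s.data for s in subs]] + [rng.standard_normal((2, 300))]
        )
        attenuated = sliding_isfc(noisy, keep_subject_layers=False)
        assert attenuated.z.mean() < base.z.mean()


class TestFullISFC:
    def test_identical_shared_signal_near_one(self):
        rng = np.random.default_rng(7)
        sig = rng.standard_normal(100)
        subs = _subjects_from_arrays([np.vstack([sig, sig]) for _ in range(3)])
        out = full_isfc(subs)
        assert np.all(out["r"] > 0.999)

    def test_anticorrelated_signals_near_minus_one(self):
        rng = np.random.default_rng(8)
        sig = rng.standard_normal(100)
        subs = _subjects_from_arrays([np.vstack([sig, -sig]) for _ in range(3)])
        out = full_isfc(subs)
        off = out[(out["roi_i"] == "r0") & (out["roi_j"] == "r1")]
        assert float(off["r"].iloc[0]) < -0.999

    def test_equals_sliding_with_full_window(self, toy_subjects):
        T = toy_subjects[0].n_trs
        full = full_isfc(toy_subjects)
        slid = sliding_isfc(toy_subjects, window_len=T, keep_subject_layers=False)
        assert slid.n_valid == 1
        np.testing.assert_allclose(full["z"].to_numpy(), slid.z[:, 0], atol=1e-12)


class TestPhaseRandomize:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([64, 101, 200]))
    def test_amplitude_spectrum_preserved(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        surr = phase_randomize(x, rng)
        a0, a1 = np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(surr))
        np.testing.assert_allclose(a1, a0, rtol=1e-8, atol=1e-10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(128) + 3.7
        surr = phase_randomize(x, rng)
        assert surr.mean() == pytest.approx(x.mean(), abs=1e-10)

    def test_autocorrelation_distribution_preserved(self):
        # lag-1 autocorrelation of an AR(1) signal survives surrogate creation
        rng = np.random.default_rng(10)
        x = np.empty(400)
        x[0] = rng.standard_normal()
        for t in range(1, 400):
            x[t] = 0.6 * x[t - 1] + 0.8 * rng.standard_normal()
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]
        acs = [lag1(phase_randomize(x, rng)) for _ in range(200)]
        assert abs(np.mean(acs) - lag1(x)) < 0.05

    def test_permute_mode_preserves_spectrum(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100)
        surr = phase_randomize(x, rng, mode="permute")
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(surr)), np.abs(np.fft.rfft(x)), rtol=1e-8, atol=1e-10
        )

    def test_complex_input_rejected(self):
        with pytest.raises(DataError):
            phase_randomize(np.ones(8) + 1j, np.random.default_rng(0))

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            phase_randomize(np.ones(3), np.random.default_rng(0))


class TestMaxNullISFC:
    def test_null_length_and_positive_threshold(self, toy_subjects):
        threshold, null = max_null_isfc(toy_subjects, spec_n_iter=100, seed=0)
        assert null.n_iter == 100 and len(null.values) == 100
        assert threshold > 0

    def test_reproducible_given_seed(self, toy_subjects):
        t1, n1 = max_null_isfc(toy_subjects, spec_n_iter=50, seed=5)
        t2, n2 = max_null_isfc(toy_subjects, spec_n_iter=50, seed=5)
        assert t1 == t2
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_white_noise_familywise_control(self):
        # on null data the observed full ISFC should rarely beat the threshold
        rng = np.random.default_rng(12)
        exceed = 0
        runs = 20
        for _ in range(runs):
            subs = _subjects_from_arrays(
                [rng.standard_normal((2, 120)) for _ in range(4)]
            )
            threshold, _ = max_null_isfc(
                subs, spec_n_iter=100, seed=int(rng.integers(2**31))
            )
            obs = full_isfc(subs)
            # per-subject max |r| is what the null bounds; compare group-level
            if np.max(np.abs(obs["r"])) > threshold:
                exceed += 1
        assert exceed <= 3  # ~5% familywise rate, generous binomial slack
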