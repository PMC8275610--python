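"""Preprocessing chain contracts: resampling, filtering, alignment, epoching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitscope import preprocessing as pp
from gaitscope.synthetic import Recording, SubjectProfile, generate_gait_recording


def _rec(a, fs=50.0, t=None):
    a = np.asarray(a, dtype=float)
    if t is None:
        t = np.arange(len(a)) / fs
    return Recording("s", "t0", "HC", fs, t, a)


class TestResample:
    def test_already_50hz_is_identity(self):
        rec = _rec(np.random.default_rng(0).normal(size=(200, 3)))
        assert pp.resample_to_50hz(rec) is rec

    def test_sinusoid_resampled_close_to_analytic(self):
        """Oracle: dense analytic evaluation of the 1 Hz sinusoid."""
        fs_in = 20.0
        t = np.arange(0, 10, 1 / fs_in)
        a = np.stack([np.sin(2 * np.pi * t)] * 3, axis=1)
        out = pp.resample_to_50hz(_rec(a, fs=fs_in, t=t))
        assert abs(out.fs_hz - 50.0) < 1e-9
        analytic = np.sin(2 * np.pi * out.t)
        assert np.max(np.abs(out.a_xyz[:, 0] - analytic)) < 0.01

    def test_constant_stays_constant(self):
        t = np.arange(0, 5, 0.04)  # 25 Hz
        a = np.full((len(t), 3), 0.7)
        out = pp.resample_to_50hz(_rec(a, fs=25.0, t=t))
        assert np.allclose(out.a_xyz, 0.7)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            pp.resample_to_50hz(_rec(np.zeros((3, 3)), fs=25.0))


class TestLowpass:
    def test_dc_unchanged(self):
        rec = _rec(np.full((500, 3), 0.42))
        out = pp.lowpass_filter(rec)
        assert np.allclose(out.a_xyz, 0.42, atol=1e-9)

    @pytest.mark.parametrize("freq,expected,tol", [(17.0, 0.5, 0.02),
                                                   (2.0, 1.0, 0.01)])
    def test_gain_matches_analytic_butterworth_response(self, freq, expected, tol):
        """Two zero-phase passes of a 4th-order Butterworth: |H|^2 = 0.5 at
        the 17 Hz cutoff, ~1 at 2 Hz."""
        t = np.arange(0, 40, 0.02)
        s = np.sin(2 * np.pi * freq * t)
        out = pp.lowpass_filter(_rec(np.stack([s] * 3, 1), t=t)).a_xyz[:, 0]
        core = slice(200, -200)  # avoid edge transients
        gain = np.sqrt(np.mean(out[core] ** 2) / np.mean(s[core] ** 2))
        assert gain == pytest.approx(expected, abs=tol)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            pp.lowpass_filter(_rec(np.zeros((10, 3))))


class TestAlignment:
    def test_gravity_on_y_is_identity(self):
        a = np.tile([0.0, 1.0, 0.0], (100, 1))
        out = pp.align_to_global_frame(_rec(a))
        np.testing.assert_allclose(out.a_xyz, a, atol=1e-12)

    def test_gravity_on_x_rotated_to_y(self):
        a = np.tile([1.0, 0.0, 0.0], (100, 1))
        out = pp.align_to_global_frame(_rec(a))
        np.testing.assert_allclose(out.a_xyz.mean(0), [0, 1, 0], atol=1e-6)

    def test_magnitude_invariant_under_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.2, 0.5, size=(300, 3)) + [0.6, 0.4, 0.3]
        out = pp.align_to_global_frame(_rec(a))
        np.testing.assert_allclose(np.linalg.norm(out.a_xyz, axis=1),
                                   np.linalg.norm(a, axis=1), atol=1e-9)

    def test_near_zero_gravity_skips_with_warning(self):
        a = np.random.default_rng(0).normal(0, 0.01, size=(100, 3))
        with pytest.warns(UserWarning, match="skipping"):
            out = pp.align_to_global_frame(_rec(a))
        np.testing.assert_array_equal(out.a_xyz, a)


class TestDetrendNormalise:
    def test_channels_zero_mean_unit_sd(self):
        rec = generate_gait_recording(SubjectProfile("s", "HC"), 10, 50,
                                      np.random.default_rng(0))
        x = pp.detrend_normalise(rec)
        assert x.shape == (4, rec.n_samples)
        np.testing.assert_allclose(x.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(x.std(axis=1), 1, atol=1e-9)

    def test_magnitude_computed_before_normalisation(self):
        # a single 3-4-5 sample: magnitude 0.5 g pre-normalisation
        a = np.tile([0.3, 0.4, 0.0], (100, 1))
        mag = np.linalg.norm(a, axis=1)
        assert np.allclose(mag, 0.5)

    def test_linear_ramp_detrends_to_zero(self):
        t = np.arange(200) / 50
        a = np.stack([0.1 * t + 1.0] * 3, axis=1)
        with pytest.warns(UserWarning, match="zero-variance"):
            x = pp.detrend_normalise(_rec(a, t=t))
        assert np.allclose(x, 0.0, atol=1e-9)


class TestEpoching:
    def test_window_geometry(self):
        assert pp.EPOCH_SAMPLES == 128 and pp.EPOCH_STEP == 64

    @pytest.mark.parametrize("n,expected_starts", [
        (128, [0]),
        (320, [0, 64, 128, 192]),
        (127, []),
        (191, [0]),
    ])
    def test_epoch_starts_match_enumeration(self, n, expected_starts):
        x = np.random.default_rng(0).normal(size=(4, n))
        rec = _rec(np.zeros((n, 3)))
        if n < 128:
            with pytest.warns(UserWarning):
                epochs = pp.epoch_signal(x, rec)
        else:
            epochs = pp.epoch_signal(x, rec)
        assert [e.start_index for e in epochs] == expected_starts

    @given(n=st.integers(min_value=128, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_epoch_count_formula_equals_start_enumeration(self, n):
        brute = len([s for s in range(0, n) if s % 64 == 0 and s + 128 <= n])
        assert pp.epoch_count(n) == brute == (n - 128) // 64 + 1

    def test_epochs_slice_the_processed_signal_exactly(self):
        x = np.random.default_rng(3).normal(size=(4, 300))
        epochs = pp.epoch_signal(x, _rec(np.zeros((300, 3))))
        for e in epochs:
            np.testing.assert_array_equal(
                e.x, x[:, e.start_index:e.start_index + 128])


class TestDatasetStages:
    def _dataset(self, tests_per_subject=3, n_subj=2):
        rng = np.random.default_rng(0)
        epochs = []
        for g in ("HC", "PwMSmod"):
            for s in range(n_subj):
                for t in range(tests_per_subject):
                    for start in (0, 64):
                        epochs.append(pp.Epoch(
                            rng.normal(size=(4, 128)), f"{g}s{s}",
                            f"{g}s{s}t{t}", start, g))
        return pp.EpochDataset.from_epochs(epochs)

    def test_resample_tests_draws_m_per_subject(self):
        ds = self._dataset()
        out = pp.resample_tests_per_subject(ds, m=10, rng=0)
        df = out.manifest()
        per_subject = df.groupby("subject_id")["draw"].nunique()
        assert (per_subject == 10).all()

    def test_single_test_subject_repeats_that_test(self):
        ds = self._dataset(tests_per_subject=1, n_subj=1)
        out = pp.resample_tests_per_subject(ds, m=10, rng=0)
        # 2 subjects x 10 draws x 2 epochs of each subject's single test
        assert len(out) == 2 * 10 * 2
        assert set(out.test_ids) == set(ds.test_ids)

    def test_resampling_deterministic_for_seed(self):
        ds = self._dataset()
        a = pp.resample_tests_per_subject(ds, m=5, rng=42)
        b = pp.resample_tests_per_subject(ds, m=5, rng=42)
        assert np.array_equal(a.test_ids, b.test_ids)
        assert np.array_equal(a.X, b.X)

    def test_balance_equalises_counts(self):
        ds = self._dataset()
        drop = np.ones(len(ds), dtype=bool)
        drop[np.flatnonzero(ds.labels == "PwMSmod")[:7]] = False
        unbalanced = ds.subset(drop)
        out = pp.balance_classes(unbalanced, rng=0)
        _, counts = np.unique(out.labels, return_counts=True)
        assert len(set(counts)) == 1

    def test_balanced_input_unchanged(self):
        ds = self._dataset()
        out = pp.balance_classes(ds, rng=0)
        assert len(out) == len(ds)

    def test_pipeline_produces_finite_epochs(self):
        rec = generate_gait_recording(SubjectProfile("s", "HC"), 10, 50,
                                      np.random.default_rng(0))
        epochs = pp.preprocess_recording(rec)
        assert len(epochs) == pp.epoch_count(rec.n_samples)
        assert all(np.all(np.isfinite(e.x)) for e in epochs)
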