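"""Generator contracts: spectra, determinism, cohort bookkeeping."""

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram

from gaitscope import synthetic as syn


def _profile(**kw):
    base = dict(subject_id="s", group="HC")
    base.update(kw)
    return syn.SubjectProfile(**base)


def _moderate_profile():
    return _profile(group="PwMSmod", cadence_hz=1.5, step_jitter_s=0.035,
                    step_amp_g=0.35, perturb_amp_g=0.3, perturb_freq_hz=8.5,
                    noise_sd_g=0.045)


class TestGaitRecording:
    def test_clean_cadence_gives_dominant_fourier_peak_at_cadence(self):
        p = _profile(cadence_hz=2.0, step_jitter_s=0.0, noise_sd_g=0.0,
                     perturb_amp_g=0.0, harmonic_gain=0.0)
        rec = syn.generate_gait_recording(p, 30, 50, np.random.default_rng(0))
        f, P = periodogram(rec.a_xyz[:, 1] - 1.0, fs=50)
        assert abs(f[np.argmax(P)] - 2.0) <= f[1] - f[0] + 1e-12

    def test_no_steps_no_noise_gives_constant_gravity(self):
        p = _profile(step_amp_g=0.0, noise_sd_g=0.0)
        rec = syn.generate_gait_recording(p, 10, 50, np.random.default_rng(0))
        assert np.allclose(rec.a_xyz[:, 1], 1.0)
        assert np.allclose(rec.a_xyz[:, [0, 2]], 0.0)

    def test_moderate_profile_shifts_energy_above_gait_band(self):
        """Periodogram band-integration oracle: 5-15 Hz vs 0.5-3 Hz energy
        ratio is higher for the moderate-MS profile than for HC."""
        def ratio(profile, seed):
            rec = syn.generate_gait_recording(profile, 60, 50,
                                              np.random.default_rng(seed))
            f, P = periodogram(rec.a_xyz[:, 1] - 1.0, fs=50)
            return (P[(f >= 5) & (f <= 15)].sum()
                    / P[(f >= 0.5) & (f <= 3)].sum())
        for seed in range(3):
            assert ratio(_moderate_profile(), seed) > ratio(_profile(), seed)

    def test_gait_band_energy_ordering_hc_above_moderate(self):
        """With default group profiles, mean 0.5-3 Hz energy over >= 20 seeded
        subjects is larger for HC than for moderate MS."""
        dists = syn.default_group_distributions()

        def band(group, n=20):
            vals = []
            for i in range(n):
                sid = f"{group}_x{i}"
                rng = syn.subject_rng(123, sid)
                prof = syn._draw_profile(sid, group, dists[group], rng)
                rec = syn.generate_gait_recording(prof, 30, 50, rng)
                f, P = periodogram(rec.a_xyz[:, 1] - 1.0, fs=50)
                vals.append(P[(f >= 0.5) & (f <= 3)].sum())
            return np.mean(vals)

        assert band("HC") > band("PwMSmod")

    def test_perturbation_bursts_are_step_locked(self):
        # exact construction check: a burst starts at its step time, never before
        t = np.arange(0, 10, 0.02)
        steps = np.array([2.0, 5.0, 8.0])  # well separated vs the decay
        pert = syn._perturbation_train(t, steps, amp=0.3, freq_hz=8.5)
        for t_k in steps:
            before = pert[(t >= t_k - 0.5) & (t < t_k)]
            after = pert[(t >= t_k) & (t < t_k + 0.3)]
            assert np.allclose(before, 0.0)
            assert np.max(np.abs(after)) > 0.1

    def test_burst_envelope_xcorr_peaks_at_the_step(self):
        """Cohort-level step-locking: the cross-correlation between the step
        impulse train and the Hilbert envelope of the perturbation signal
        peaks at the step onset, within the envelope estimator's quarter-
        carrier-cycle smearing (<= 2 samples at 50 Hz)."""
        rec = syn.generate_gait_recording(_moderate_profile(), 30, 50,
                                          np.random.default_rng(3))
        steps = rec.ground_truth["step_times"]
        pert = rec.ground_truth["perturbation"]
        imp = np.zeros(rec.n_samples)
        imp[np.clip((steps * 50).round().astype(int), 0, rec.n_samples - 1)] = 1
        env = np.abs(hilbert(pert))
        xc = np.correlate(env - env.mean(), imp - imp.mean(), "full")
        lag = np.argmax(xc) - (rec.n_samples - 1)
        assert 0 <= lag <= 2

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_gait_recording(_profile(), duration_s=2.0)
        with pytest.raises(ValueError):
            syn.generate_gait_recording(_profile(), duration_s=10, fs_hz=0)
        with pytest.raises(ValueError):
            _profile(cadence_hz=-1.0)
        with pytest.raises(ValueError):
            _profile(cadence_hz=2.0, step_jitter_s=0.6)


class TestHarRecording:
    def test_sitting_without_noise_is_constant(self):
        rec = syn.generate_har_recording("sitting", 10, 50,
                                         np.random.default_rng(0),
                                         noise_sd_g=0.0)
        assert np.allclose(rec.a_xyz.var(axis=0), 0.0)

    def test_jogging_cadence_peak_above_walking(self):
        def peak(act, seed):
            rec = syn.generate_har_recording(act, 20, 50,
                                             np.random.default_rng(seed))
            f, P = periodogram(rec.a_xyz[:, 1] - 1.0, fs=50)
            m = (f > 0.5) & (f < 5)
            return f[m][np.argmax(P[m])]
        for seed in range(3):
            assert peak("jogging", seed) > peak("walking", seed)

    def test_laying_and_standing_gravity_orthogonal(self):
        lay = syn.generate_har_recording("laying", 5, 50, noise_sd_g=0.0)
        std = syn.generate_har_recording("standing", 5, 50, noise_sd_g=0.0)
        cosang = (lay.a_xyz.mean(0) @ std.a_xyz.mean(0)
                  / np.linalg.norm(lay.a_xyz.mean(0))
                  / np.linalg.norm(std.a_xyz.mean(0)))
        assert abs(np.degrees(np.arccos(np.clip(cosang, -1, 1))) - 90) < 1e-9

    def test_unknown_activity_rejected(self):
        with pytest.raises(ValueError, match="unknown activity"):
            syn.generate_har_recording("swimming", 10, 50)


class TestCohort:
    def test_manifest_counts(self):
        cfg = syn.SyntheticConfig(
            n_subjects={g: 2 for g in syn.GROUPS}, tests_per_subject=4,
            duration_s=6.0, rng_seed=0)
        recs, manifest = syn.generate_cohort(cfg)
        assert len(recs) == len(manifest) == 3 * 2 * 4
        assert manifest.groupby("group").size().to_dict() == {
            "HC": 8, "PwMSmild": 8, "PwMSmod": 8}

    def test_default_cohort_sizes_match_study_groups(self):
        cfg = syn.SyntheticConfig()
        assert cfg.n_subjects == {"HC": 24, "PwMSmild": 52, "PwMSmod": 21}
        assert cfg.duration_s == 120.0 and cfg.fs_hz == 50.0

    def test_same_seed_bytes_identical(self):
        cfg = syn.SyntheticConfig(n_subjects={"HC": 2, "PwMSmod": 2},
                                  tests_per_subject=2, duration_s=6.0,
                                  rng_seed=11)
        a, _ = syn.generate_cohort(cfg)
        b, _ = syn.generate_cohort(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.a_xyz, rb.a_xyz)

    def test_extending_cohort_keeps_existing_subjects(self):
        small = syn.SyntheticConfig(n_subjects={"HC": 2}, tests_per_subject=1,
                                    duration_s=6.0, rng_seed=5)
        big = syn.SyntheticConfig(n_subjects={"HC": 4}, tests_per_subject=1,
                                  duration_s=6.0, rng_seed=5)
        a, _ = syn.generate_cohort(small)
        b, _ = syn.generate_cohort(big)
        for ra, rb in zip(a, b[:2]):
            assert np.array_equal(ra.a_xyz, rb.a_xyz)

    def test_roundtrip_through_csv(self, tmp_path):
        cfg = syn.SyntheticConfig(n_subjects={"HC": 1, "PwMSmild": 1},
                                  tests_per_subject=2, duration_s=6.0,
                                  rng_seed=3)
        recs, manifest = syn.generate_cohort(cfg)
        path = syn.write_cohort(recs, manifest, tmp_path)
        loaded, mf = syn.read_cohort(path)
        assert len(loaded) == len(recs)
        for ra, rb in zip(recs, loaded):
            assert ra.test_id == rb.test_id and ra.group == rb.group
            np.testing.assert_allclose(ra.a_xyz, rb.a_xyz, atol=1e-9)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = syn.SyntheticConfig(n_subjects={"HC": 3, "PwMSmod": 2},
                                  tests_per_subject=1, duration_s=8.0,
                                  rng_seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        cfg2 = syn.SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert cfg2 == cfg
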