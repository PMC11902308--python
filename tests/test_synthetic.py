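"""Simulator contracts: determinism, acquisition rates, phase structure,
subject separability, segmentation arithmetic, and lossless cohort I/O."""

import numpy as np
import pytest

from metagait.errors import ConfigurationError, DomainError
from metagait.synthetic import (CohortDataset, GeneratorConfig, emg_envelope,
                                joint_angles, make_cohort, make_subject,
                                segment_clips, simulate_trial, speed_class)


# ----------------------------------------------------------------- profiles
def test_make_subject_deterministic_and_seed_sensitive(gen_config):
    p0a = make_subject(0, gen_config)
    p0b = make_subject(0, gen_config)
    p1 = make_subject(1, gen_config)
    assert np.array_equal(p0a.baseline_offsets, p0b.baseline_offsets)
    assert np.array_equal(p0a.fourier_amps, p0b.fourier_amps)
    assert p0a.cadence_scale == p0b.cadence_scale
    differs = (not np.array_equal(p0a.baseline_offsets, p1.baseline_offsets)
               or not np.array_equal(p0a.fourier_amps, p1.fourier_amps)
               or p0a.cadence_scale != p1.cadence_scale)
    assert differs


def test_zero_width_ranges_pin_profile_to_midpoints():
    cfg = GeneratorConfig(offset_halfwidth_deg=0.0, amp_scale_range=(1.0, 1.0),
                          phase_jitter_rad=0.0, cadence_scale_range=(1.0, 1.0),
                          emg_gain_range=(1.0, 1.0))
    p = make_subject(7, cfg)
    assert p.cadence_scale == 1.0
    assert np.all(p.emg_gain == 1.0)
    # left/right offsets equal the per-joint templates
    assert np.array_equal(p.baseline_offsets[:3], p.baseline_offsets[3:])


def test_invalid_config_range_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(amp_scale_range=(1.3, 0.7))


def test_profile_invariants_hold(gen_config):
    for seed in range(5):
        p = make_subject(seed, gen_config)
        assert np.all(np.isfinite(p.fourier_amps)) and np.all(p.fourier_amps >= 0)
        assert p.cadence_scale > 0
        assert all(v >= 0 for v in p.noise_levels.values())


# -------------------------------------------------------------------- trials
def test_trial_sample_counts_match_acquisition_rates(trial60):
    """60 s at the hardware rates: 1800 / 66667 / 12000 / 6000 samples."""
    n = {m: trial60.streams[m].n_samples for m in trial60.streams}
    assert n == {"image": 1800, "emg": 66667, "vio": 12000, "angles": 6000}


def test_trial_channel_dims_and_quaternion_norm(trial60):
    assert trial60.streams["emg"].samples.shape[1] == 6
    assert trial60.streams["angles"].samples.shape[1] == 6
    vio = trial60.streams["vio"].samples
    assert vio.shape[1] == 7
    assert np.abs(np.linalg.norm(vio[:, 3:], axis=1) - 1.0).max() < 1e-6
    img = trial60.streams["image"].samples
    assert img.shape[1:] == (64, 64, 3) and img.dtype == np.uint8


def test_trial_seeded_determinism(subject0, gen_config):
    a = simulate_trial(subject0, 6.0, 12.0, "cw", seed=5, config=gen_config)
    b = simulate_trial(subject0, 6.0, 12.0, "cw", seed=5, config=gen_config)
    for m in a.streams:
        assert np.array_equal(a.streams[m].samples, b.streams[m].samples)


def test_noiseless_angles_are_exact_fourier_model(gen_config):
    cfg = GeneratorConfig(image_noise_sd=0, emg_noise_sd=0,
                          vio_pos_noise_m=0, vio_rot_noise_rad=0)
    p = make_subject(3, cfg)
    t1 = simulate_trial(p, 4.5, 15.0, "ccw", seed=1, config=cfg)
    t2 = simulate_trial(p, 4.5, 15.0, "ccw", seed=99, config=cfg)
    # angle ground truth is a deterministic function of (profile, speed, t)
    assert np.array_equal(t1.streams["angles"].samples, t2.streams["angles"].samples)
    f0 = cfg.stride_freq(4.5, p.cadence_scale)
    t = np.arange(1500) / 100.0
    assert np.allclose(t1.streams["angles"].samples, joint_angles(p, f0, t))


def test_emg_envelope_is_exactly_stride_periodic(subject0, gen_config):
    f0 = gen_config.stride_freq(4.5, subject0.cadence_scale)
    t = np.linspace(0, 2.0, 1000)
    e1 = emg_envelope(subject0, f0, t)
    e2 = emg_envelope(subject0, f0, t + 1.0 / f0)
    assert np.abs(e1 - e2).max() < 1e-9


def test_invalid_trial_arguments_rejected(subject0, gen_config):
    with pytest.raises(DomainError):
        simulate_trial(subject0, -1.0, 10.0, "ccw", 0, gen_config)
    with pytest.raises(DomainError):
        simulate_trial(subject0, 4.5, 0.0, "ccw", 0, gen_config)
    with pytest.raises(DomainError):
        simulate_trial(subject0, 4.5, 10.0, "sideways", 0, gen_config)


# -------------------------------------------------------------- phase & speed
def test_stance_fraction_in_band_and_decreasing_with_speed(gen_config):
    p = make_subject(1, gen_config)
    fracs = []
    for speed in (3.5, 4.5, 6.0):
        trial = simulate_trial(p, speed, 30.0, "ccw", seed=2, config=gen_config)
        frac = trial.phase_stance.mean()
        lo, hi = gen_config.stance_band
        assert lo - 0.02 <= frac <= hi + 0.02
        fracs.append(frac)
    assert fracs[0] > fracs[1] > fracs[2]


def test_phase_mask_one_stance_one_swing_interval_per_cycle(trial60):
    mask = trial60.phase_stance
    flips = np.count_nonzero(mask[1:] != mask[:-1])
    expected = 2 * trial60.meta.stride_freq * trial60.meta.duration_s
    assert abs(flips - expected) <= 2


def test_subject_separability_of_angle_trajectories(gen_config):
    """Inter-subject distance between angle trajectories exceeds intra-subject
    distance across trials — the premise of few-shot adaptation."""
    trials = {}
    for seed in (0, 1, 2):
        p = make_subject(seed, gen_config)
        trials[seed] = [
            simulate_trial(p, 4.5, 10.0, "ccw", seed=k, config=gen_config)
            .streams["angles"].samples
            for k in (0, 1)
        ]
    intra = np.mean([np.sqrt(((trials[s][0] - trials[s][1]) ** 2).mean())
                     for s in trials])
    inter = np.mean([
        np.sqrt(((trials[a][0] - trials[b][0]) ** 2).mean())
        for a in trials for b in trials if a < b
    ])
    assert inter > intra


def test_speed_class_maps_to_nearest_protocol_speed():
    assert speed_class(3.5) == "slow"
    assert speed_class(4.4) == "moderate"
    assert speed_class(6.2) == "fast"


# ---------------------------------------------------------------- segmentation
def test_sixty_second_trial_yields_six_ten_second_clips(trial60):
    clips = segment_clips(trial60)
    assert len(clips) == 6
    for clip in clips:
        assert clip.streams["emg"].n_samples == 11111
        assert clip.streams["image"].n_samples == 300
        assert clip.streams["vio"].n_samples == 2000
        assert clip.angles.shape == (1000, 6)
        assert clip.phase_stance.shape == (1000,)


def test_short_trial_produces_no_clips_with_warning(subject0, gen_config):
    trial = simulate_trial(subject0, 4.5, 9.5, "ccw", seed=0, config=gen_config)
    with pytest.warns(UserWarning):
        clips = segment_clips(trial, clip_s=10.0)
    assert clips == []


def test_twelve_trials_per_subject_yield_72_clips(gen_config):
    ds = make_cohort(1, 4, seed=3, config=gen_config, duration_s=60.0)
    assert len(ds) == 12
    assert len(ds.clips()) == 72


def test_one_trial_per_speed_cohort(gen_config):
    ds = make_cohort(1, 1, seed=0)
    assert len(ds) == 3
    speeds = sorted(m.speed_kmh for m in ds.trial_metas)
    assert speeds == [3.5, 4.5, 6.0]


# ------------------------------------------------------------------------ I/O
def test_cohort_hdf5_round_trip_is_lossless(tmp_path, gen_config):
    mem = make_cohort(2, 1, seed=9, duration_s=20.0)
    disk = make_cohort(2, 1, seed=9, duration_s=20.0, path=tmp_path / "c.h5")
    reopened = CohortDataset.open(tmp_path / "c.h5")
    assert len(reopened) == len(mem)
    for i in range(len(mem)):
        a, b = mem.load_trial(i), reopened.load_trial(i)
        for m in a.streams:
            assert np.array_equal(a.streams[m].samples, b.streams[m].samples), m
        assert np.array_equal(a.phase_stance, b.phase_stance)
    assert reopened.config.to_yaml() == mem.config.to_yaml()


def test_cohort_determinism_across_builds():
    a = make_cohort(2, 1, seed=5, duration_s=15.0)
    b = make_cohort(2, 1, seed=5, duration_s=15.0)
    for i in range(len(a)):
        for m in a.load_trial(i).streams:
            assert np.array_equal(a.load_trial(i).streams[m].samples,
                                  b.load_trial(i).streams[m].samples)


def test_angles_csv_export_is_tidy(tmp_path):
    import pandas as pd
    ds = make_cohort(1, 1, seed=2, duration_s=10.0)
    ds.export_angles_csv(tmp_path / "angles.csv")
    df = pd.read_csv(tmp_path / "angles.csv")
    assert set(df.columns) >= {"time_s", "joint", "side", "angle_deg"}
    assert set(df["joint"]) == {"hip", "knee", "ankle"}
    assert set(df["side"]) == {"L", "R"}
    assert len(df) == 3 * 1000 * 6


def test_invalid_cohort_arguments():
    with pytest.raises(DomainError):
        make_cohort(0, 1, seed=0)
    with pytest.raises(DomainError):
        make_cohort(1, 0, seed=0)
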