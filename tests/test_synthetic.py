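"""Synthetic-cohort generator: MET formula, protocol, orientations, signals."""

import dataclasses
import io

import numpy as np
import pytest

import pockethar as ph
from pockethar.synthetic import make_profile, read_recording_csv, write_cohort_csv


class TestMet:
    @pytest.mark.parametrize(
        "rate, weight, expected",
        [(245.0, 70.0, 1.0), (735.0, 70.0, 3.0), (0.0, 70.0, 0.0)],
    )
    def test_oxygen_rate_over_resting_rate(self, rate, weight, expected):
        assert ph.compute_met(rate, weight) == pytest.approx(expected)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            ph.compute_met(245.0, 0.0)


class TestProtocol:
    def test_nine_trials_totalling_65_minutes(self):
        prot = ph.make_protocol()
        assert len(prot.trials) == 9
        assert prot.total_minutes == 65
        assert [t.rank for t in prot.trials] == list(range(1, 10))

    def test_first_trial_is_five_minutes_lying(self):
        first = ph.make_protocol().trials[0]
        assert (first.activity, first.duration_min) == ("lying", 5)

    def test_durations_follow_schedule(self):
        assert [t.duration_min for t in ph.make_protocol().trials] == [
            5, 5, 10, 5, 10, 5, 10, 5, 10,
        ]

    def test_covers_all_six_activities(self):
        assert {t.activity for t in ph.make_protocol().trials} == set(ph.ACTIVITIES)


class TestOrientation:
    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_proper_rotation(self, seed):
        R = ph.sample_orientation(seed)
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
        assert abs(np.linalg.det(R) - 1.0) < 1e-10

    def test_deterministic_under_seed(self):
        assert np.array_equal(ph.sample_orientation(9), ph.sample_orientation(9))


@pytest.fixture
def quiet_profile():
    return make_profile(1, seed=11, noise_sd=0.0)


class TestSimulateTrial:
    def test_lying_without_noise_is_pure_gravity(self, quiet_profile):
        rec = ph.simulate_trial("lying", 1.0, quiet_profile, seed=3)
        norms = np.linalg.norm(rec.accel, axis=1)
        assert np.abs(norms - ph.GRAVITY).max() < 1e-9

    def test_intensity_orders_norm_variance(self):
        prof = make_profile(1, seed=11)
        walk = ph.simulate_trial("walking", 2.0, prof, seed=5)
        run7 = ph.simulate_trial("run7MET", 2.0, prof, seed=5)
        var = lambda r: np.var(np.linalg.norm(r.accel, axis=1))
        assert var(run7) > var(walk)

    def test_sample_count_matches_duration_times_rate(self, quiet_profile):
        rec = ph.simulate_trial("walking", 5.0, quiet_profile, seed=5)
        assert abs(len(rec) - 3600) < 360  # 300 s at a mean of 12 Hz, +-10%

    def test_timestamps_strictly_increasing(self, quiet_profile):
        rec = ph.simulate_trial("sitting", 1.0, quiet_profile, seed=5)
        assert np.all(np.diff(rec.timestamps) > 0)

    def test_unknown_activity_rejected(self, quiet_profile):
        with pytest.raises(ValueError):
            ph.simulate_trial("jumping", 1.0, quiet_profile, seed=0)

    def test_orientation_enters_as_exact_rotation(self, quiet_profile):
        """Same seed, different orientation -> the exactly rotated stream."""
        R = ph.sample_orientation(77)
        upright = dataclasses.replace(quiet_profile, orientation=np.eye(3))
        rotated = dataclasses.replace(quiet_profile, orientation=R)
        a = ph.simulate_trial("run5MET", 0.5, upright, seed=21)
        b = ph.simulate_trial("run5MET", 0.5, rotated, seed=21)
        assert np.allclose(b.accel, a.accel @ R.T, atol=1e-12)


class TestInjectMissing:
    def test_zero_fraction_is_identity(self, quiet_profile):
        rec = ph.simulate_trial("walking", 1.0, quiet_profile, seed=2)
        out = ph.inject_missing(rec, 0.0, seed=4)
        assert np.array_equal(out.accel, rec.accel)

    def test_fraction_controls_missing_count(self, quiet_profile):
        rec = ph.simulate_trial("walking", 5.0, quiet_profile, seed=2)
        rec = ph.RawRecording(rec.participant_id, rec.timestamps[:1000],
                              rec.accel[:1000], rec.labels[:1000])
        out = ph.inject_missing(rec, 0.1, seed=4)
        n_missing = int(np.isnan(out.accel).any(axis=1).sum())
        assert 70 <= n_missing <= 130

    def test_same_seed_same_mask(self, quiet_profile):
        rec = ph.simulate_trial("walking", 1.0, quiet_profile, seed=2)
        a = ph.inject_missing(rec, 0.2, seed=9)
        b = ph.inject_missing(rec, 0.2, seed=9)
        assert np.array_equal(np.isnan(a.accel), np.isnan(b.accel))

    def test_labels_and_timestamps_untouched(self, quiet_profile):
        rec = ph.simulate_trial("walking", 1.0, quiet_profile, seed=2)
        out = ph.inject_missing(rec, 0.3, seed=9)
        assert np.array_equal(out.timestamps, rec.timestamps)
        assert np.array_equal(out.labels, rec.labels)

    def test_fraction_one_rejected(self, quiet_profile):
        rec = ph.simulate_trial("walking", 0.5, quiet_profile, seed=2)
        with pytest.raises(ValueError):
            ph.inject_missing(rec, 1.0, seed=0)


class TestCohort:
    def test_one_recording_per_participant(self, micro_cohort):
        assert len(micro_cohort) == 3
        assert [r.participant_id for r in micro_cohort] == [1, 2, 3]

    def test_each_recording_contains_all_activities(self, micro_cohort):
        for rec in micro_cohort:
            assert set(np.unique(rec.labels)) == set(ph.ACTIVITIES)

    def test_participants_get_distinct_orientations(self):
        c1 = ph.simulate_cohort(2, seed=3, duration_scale=0.005, missing_fraction=0.0)
        # orientations differ -> the raw streams cannot be equal
        assert not np.allclose(c1[0].accel[:100], c1[1].accel[:100])

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            ph.simulate_cohort(1, seed=0)

    def test_label_counts_track_protocol_durations(self, micro_cohort):
        # lying totals 15 of 65 minutes; walking 10 of 65
        rec = micro_cohort[0]
        frac_lying = np.mean(rec.labels == "lying")
        assert abs(frac_lying - 15 / 65) < 0.08

    def test_csv_roundtrip_is_byte_identical_and_lossless(self, tmp_path, micro_cohort):
        p1 = write_cohort_csv(micro_cohort, tmp_path / "a")[0]
        p2 = write_cohort_csv(micro_cohort, tmp_path / "b")[0]
        assert p1.read_bytes() == p2.read_bytes()
        back = read_recording_csv(p1)[0]
        assert np.array_equal(back.timestamps, micro_cohort[0].timestamps)
        assert np.array_equal(
            np.isnan(back.accel), np.isnan(micro_cohort[0].accel)
        )
        assert np.allclose(back.accel, micro_cohort[0].accel, atol=1e-6, equal_nan=True)
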