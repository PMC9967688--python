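"""Channel-to-ROI reduction, filtering, windowing and exclusion rules."""

import numpy as np
import pytest

from emodecode import (
    DEFAULT_BANDS,
    DEFAULT_MONTAGE,
    MontageMap,
    StudyDesign,
    average_channels_to_rois,
    bandpass,
    build_observation_set,
    extract_windows,
    generate_cohort,
    null_spec,
    rereference,
)
from emodecode.preprocess import BROADBAND, BandDefinition

RATE = 500.0


class TestMontage:
    def test_default_montage_covers_ten_rois_without_overlap(self):
        assert sorted(DEFAULT_MONTAGE.rois) == list(range(1, 11))
        all_members = [ch for m in DEFAULT_MONTAGE.rois.values() for ch in m]
        assert len(all_members) == len(set(all_members))
        assert not set(DEFAULT_MONTAGE.reference) & set(all_members)

    def test_rejects_electrode_in_two_rois(self):
        with pytest.raises(ValueError, match="two ROIs"):
            MontageMap(rois={1: ("F3",), 2: ("F3",)})

    def test_rejects_reference_inside_roi(self):
        with pytest.raises(ValueError, match="reference"):
            MontageMap(rois={1: ("T7",)})


class TestRoiAveraging:
    def test_roi_is_mean_of_members(self):
        montage = MontageMap(rois={1: ("F3", "F7")})
        x = np.vstack([np.full(10, 2.0), np.full(10, 4.0)])
        roi, missing = average_channels_to_rois(x, ["F3", "F7"], montage)
        assert np.allclose(roi[0], 3.0)
        assert not missing.any()

    def test_single_member_roi_is_identity(self):
        montage = MontageMap(rois={1: ("F3",), 2: ("F4",)})
        x = np.random.default_rng(0).standard_normal((2, 50))
        roi, _ = average_channels_to_rois(x, ["F3", "F4"], montage)
        assert np.array_equal(roi[0], x[0])

    def test_roi_with_no_available_member_flagged_missing(self):
        montage = MontageMap(rois={1: ("F3",), 7: ("O1", "PO3")})
        x = np.zeros((3, 20))
        roi, missing = average_channels_to_rois(
            x, ["F3", "O1", "PO3"], montage, available={"F3"}
        )
        assert missing.tolist() == [False, True]
        assert np.isnan(roi[1]).all()

    def test_nothing_resolvable_is_hard_error(self):
        montage = MontageMap(rois={1: ("F3",)})
        with pytest.raises(ValueError, match="no montage channel"):
            average_channels_to_rois(np.zeros((1, 10)), ["Cz"], montage)


class TestRereference:
    def test_zero_reference_leaves_input_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 100))
        names = ["F3", "F4", "T7", "T8"]
        x[2] = x[3] = 0.0
        assert np.allclose(rereference(x, names), x)

    def test_channels_equal_to_reference_become_zero(self):
        x = np.tile(np.sin(np.linspace(0, 5, 80)), (4, 1))
        assert np.allclose(rereference(x, ["F3", "F4", "T7", "T8"]), 0.0)

    def test_rereferencing_is_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 200))
        names = ["F3", "F4", "Cz", "T7", "T8"]
        once = rereference(x, names)
        assert np.allclose(rereference(once, names), once, atol=1e-12)

    def test_missing_reference_channel_named_in_error(self):
        with pytest.raises(ValueError, match="T8"):
            rereference(np.zeros((2, 10)), ["F3", "T7"])


class TestBandpass:
    @pytest.mark.parametrize(
        "tone_hz,band,expect_pass",
        [
            (10.0, ("alpha", 8, 12), True),
            (10.0, ("gamma", 30, 45), False),
            (20.0, ("beta", 12, 30), True),
            (2.0, ("delta", 1, 4), True),
            (16.0, ("alpha", 8, 12), False),  # one octave above the 8 Hz edge
        ],
    )
    def test_tone_amplitude_through_band(self, tone_hz, band, expect_pass):
        t = np.arange(int(10 * RATE)) / RATE
        x = np.sin(2 * np.pi * tone_hz * t)[None, :]
        y = bandpass(x, band[1], band[2], RATE)
        # measure amplitude away from the edges
        amp = np.abs(y[0, 1000:-1000]).max()
        if expect_pass:
            assert amp >= 0.95
        else:
            assert amp <= 0.05

    def test_zero_signal_stays_zero(self):
        assert np.allclose(bandpass(np.zeros((2, 4000)), 8, 12, RATE), 0.0)

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((1, 1000)), 12, 8, RATE)
        with pytest.raises(ValueError):
            bandpass(np.zeros((1, 1000)), 10, 300, RATE)

    def test_subbands_partition_broadband_white_noise(self):
        """The five sub-band signals must reconstruct the broadband content
        (relative RMS error < 15% on white noise)."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, int(30 * RATE)))
        transition = min(2.0, min(b.low for b in DEFAULT_BANDS))
        broad = bandpass(x, BROADBAND.low, BROADBAND.high, RATE)
        total = sum(bandpass(broad, b.low, b.high, RATE, transition) for b in DEFAULT_BANDS)
        core = slice(2000, -2000)  # ignore edge transients
        err = np.sqrt(np.mean((total[0, core] - broad[0, core]) ** 2))
        rms = np.sqrt(np.mean(broad[0, core] ** 2))
        assert err / rms < 0.15


class TestExtractWindows:
    def test_default_shape_and_first_window_start(self):
        x = np.arange(int(30 * RATE), dtype=float)
        w = extract_windows(np.tile(x, (10, 1)), RATE)
        assert w.shape == (10, 8, 1500)
        assert w[0, 0, 0] == 1500  # window 0 starts at sample 3 s * 500 Hz

    def test_ramp_window_starts_at_expected_seconds(self):
        t = np.arange(int(30 * RATE)) / RATE
        w = extract_windows(t[None, :], RATE)
        for k in range(8):
            assert w[0, k, 0] == pytest.approx(3 + 3 * k, abs=1e-9)

    def test_exact_27s_accepted_and_shorter_rejected(self):
        ok = np.zeros((2, int(27 * RATE)))
        assert extract_windows(ok, RATE).shape == (2, 8, 1500)
        with pytest.raises(ValueError, match="too short"):
            extract_windows(np.zeros((2, int(26.9 * RATE))), RATE)


@pytest.fixture(scope="module")
def cohort():
    design = StudyDesign(n_participants=1, n_sessions=1, trials_per_session=5)
    return generate_cohort(design, null_spec(), seed=5)


class TestBuildObservationSet:

    def test_rows_aligned_and_counted(self, cohort):
        obs = build_observation_set(cohort)
        assert obs.n_obs == 5
        for band in ["broadband"] + [b.name for b in DEFAULT_BANDS]:
            assert obs.emotional[band].shape == obs.baseline[band].shape == (5, 10, 8, 1500)
        assert list(obs.metadata["condition"]) == [t.condition for t in cohort]

    def test_missing_roi_trial_excluded_everywhere(self, cohort):
        import copy

        bad = copy.deepcopy(cohort[2])
        bad.emotional_signal = bad.emotional_signal.copy()
        bad.emotional_signal[1] = np.nan  # kill ROI 2
        trials = cohort[:2] + [bad] + cohort[3:]
        obs = build_observation_set(trials)
        assert obs.n_obs == 4
        assert len(obs.exclusions) == 1
        assert "ROI(s) 2" in obs.exclusions.iloc[0]["reason"]

    def test_exclusion_does_not_disturb_retained_rows(self, cohort):
        import copy

        obs_clean = build_observation_set(list(cohort))
        bad = copy.deepcopy(cohort[0])
        bad.baseline_signal = bad.baseline_signal.copy()
        bad.baseline_signal[:] = np.nan
        obs_mixed = build_observation_set(list(cohort) + [bad])
        assert obs_mixed.n_obs == obs_clean.n_obs
        assert np.array_equal(
            obs_mixed.emotional["alpha"], obs_clean.emotional["alpha"]
        )

    def test_all_trials_excluded_is_error(self, cohort):
        import copy

        bad = copy.deepcopy(cohort[0])
        bad.emotional_signal = np.full_like(bad.emotional_signal, np.nan)
        with pytest.raises(ValueError, match="all trials excluded"):
            build_observation_set([bad])

    def test_band_definitions_match_convention(self):
        edges = {(b.name, b.low, b.high) for b in DEFAULT_BANDS}
        assert edges == {
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 12.0),
            ("beta", 12.0, 30.0),
            ("gamma", 30.0, 45.0),
        }

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 12.0, 8.0)
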