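"""Synthetic-data generator: determinism, amplitude surface, planted truth."""

import numpy as np
import pandas as pd
import pytest

from corticomap.mep import peak_to_peak
from corticomap.synth import (
    SimulationConfig,
    TrackingParams,
    _mep_epoch,
    _session_sites,
    amplitude_surface,
    gen_cohort,
    gen_outcome_table,
    gen_subjects,
    gen_tms_session,
    gen_tracking_trial,
    substream,
)
from corticomap.tracking import tracking_error


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_per_group": 1}, "n_per_group"),
            ({"missing_rate": 1.0}, "missing_rate"),
            ({"noise_sd_uv": -1.0}, "noise_sd_uv"),
            ({"amplitude_spatial_sd_mm": 0.0}, "amplitude_spatial_sd_mm"),
            ({"scalp_radius_mm": -5.0}, "scalp_radius_mm"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SimulationConfig(**kwargs).validate()

    def test_negative_tracking_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SimulationConfig(tracking=TrackingParams(duration_s=-1.0)).validate()


class TestAmplitudeSurface:
    def test_peak_at_true_cog_and_epoch_roundtrip(self):
        cfg = SimulationConfig(noise_sd_uv=0.0)
        cog = cfg.true_cog_for("longissimus_L5", "control")
        amp = amplitude_surface(cfg, "longissimus_L5", cog)
        assert amp[0] == pytest.approx(cfg.amplitude_peak_uv, abs=1e-9)
        epoch = _mep_epoch(amp[0], cfg.emg_sampling_rate, 0.0, substream(0, "x"))
        assert peak_to_peak(epoch) == pytest.approx(cfg.amplitude_peak_uv, abs=1e-9)

    def test_closed_form_gaussian_falloff(self):
        cfg = SimulationConfig(amplitude_peak_uv=400.0, amplitude_spatial_sd_mm=10.0)
        cog = cfg.true_cog_for("longissimus_L3", "control")
        site = cog + np.array([10.0, 0.0, 0.0])
        amp = amplitude_surface(cfg, "longissimus_L3", site)
        assert amp[0] == pytest.approx(400.0 * np.exp(-0.5), abs=1e-9)
        assert amp[0] == pytest.approx(242.6, abs=0.1)

    def test_surface_matches_formula_everywhere_noiseless(self):
        cfg = SimulationConfig(noise_sd_uv=0.0, n_stims=50)
        sites = _session_sites(cfg, "S")
        cog = cfg.true_cog_for("obliquus_externus", "control")
        d = np.linalg.norm(sites - cog, axis=1)
        expected = cfg.amplitude_peak_uv * np.exp(-(d**2) / (2 * cfg.amplitude_spatial_sd_mm**2))
        assert np.allclose(amplitude_surface(cfg, "obliquus_externus", sites), expected, atol=1e-9)

    def test_subthreshold_sites_stay_subthreshold_noiseless(self):
        cfg = SimulationConfig(noise_sd_uv=0.0, n_stims=60, seed=5)
        events = gen_tms_session(cfg, "S01", "longissimus_L3")
        sites = np.array([e.coords for e in events])
        amps = amplitude_surface(cfg, "longissimus_L3", sites)
        for e, a in zip(events, amps):
            if a <= 50.0:
                assert peak_to_peak(e.epoch) <= 50.0


class TestDeterminism:
    def test_same_seed_identical_sessions(self):
        cfg = SimulationConfig(n_stims=20, seed=42)
        a = gen_tms_session(cfg, "S01", "longissimus_L5")
        b = gen_tms_session(cfg, "S01", "longissimus_L5")
        assert len(a) == len(b) == 20
        for ea, eb in zip(a, b):
            assert ea.coords == eb.coords
            assert np.array_equal(ea.epoch.samples, eb.epoch.samples)

    def test_same_seed_identical_trials_and_outcomes(self):
        cfg = SimulationConfig(
            n_per_group=3, n_stims=10, seed=9, tracking=TrackingParams(duration_s=5.0)
        )
        t1 = gen_tracking_trial(cfg, "S01")
        t2 = gen_tracking_trial(cfg, "S01")
        assert np.array_equal(t1.actual_x, t2.actual_x)
        c1 = gen_cohort(cfg, raw=False)
        c2 = gen_cohort(cfg, raw=False)
        pd.testing.assert_frame_equal(c1.outcomes, c2.outcomes)

    def test_adding_subjects_does_not_reshuffle_existing(self):
        cfg_small = SimulationConfig(n_per_group=2, n_stims=10, seed=3)
        cfg_big = SimulationConfig(n_per_group=4, n_stims=10, seed=3)
        a = gen_tms_session(cfg_small, "P01", "longissimus_L3")
        b = gen_tms_session(cfg_big, "P01", "longissimus_L3")
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.epoch.samples, eb.epoch.samples)


class TestTracking:
    def test_no_lag_no_noise_equals_target(self):
        cfg = SimulationConfig(
            tracking=TrackingParams(duration_s=10.0, lag_tau_s=0.0, noise_sd_deg=0.0)
        )
        trial = gen_tracking_trial(cfg, "S01")
        assert np.allclose(trial.actual_x, trial.target_x)
        assert np.allclose(trial.actual_y, trial.target_y)

    def test_isotropic_noise_gives_rayleigh_mean_error(self):
        cfg = SimulationConfig(
            tracking=TrackingParams(
                duration_s=20.0, sampling_rate=50.0, lag_tau_s=0.0, noise_sd_deg=0.5
            )
        )
        trial = gen_tracking_trial(cfg, "S01")
        mean_err = float(np.mean(tracking_error(trial)))
        # Rayleigh mean = sigma * sqrt(pi/2) ~ 0.627 deg at sigma = 0.5
        assert 0.3 <= mean_err <= 1.0

    def test_lag_produces_trailing_cursor(self):
        cfg = SimulationConfig(
            tracking=TrackingParams(duration_s=20.0, lag_tau_s=0.5, noise_sd_deg=0.0)
        )
        trial = gen_tracking_trial(cfg, "S01")
        assert np.mean(tracking_error(trial)) > 0.05


class TestCohort:
    def test_balanced_groups_and_matching(self):
        cfg = SimulationConfig(n_per_group=6)
        subjects = gen_subjects(cfg)
        assert (subjects["group"].value_counts() == 6).all()
        paired = subjects.assign(pair=subjects["subject"].str[1:]).pivot(
            index="pair", columns="group", values="age"
        )
        assert (paired["LBP"] == paired["control"]).all()

    def test_full_cohort_has_200_outcome_slots(self):
        cfg = SimulationConfig(n_per_group=25, missing_rate=0.0)
        cohort = gen_cohort(cfg, raw=False)
        slot_cols = [c for c in cohort.outcomes.columns if c.startswith("area:")]
        assert len(cohort.outcomes) * len(slot_cols) == 200
        assert cohort.outcomes[slot_cols].notna().all().all()

    def test_missingness_binomial_mean(self):
        rates = []
        for seed in range(40):
            cfg = SimulationConfig(n_per_group=25, missing_rate=0.065, seed=seed)
            cohort = gen_cohort(cfg, raw=False)
            area_cols = [c for c in cohort.outcomes.columns if c.startswith("area:")]
            rates.append(cohort.outcomes[area_cols].isna().sum().sum() / 200)
        # binomial mean 13/200; MC tolerance over 40 cohorts (SE ~ 0.0028)
        assert np.mean(rates) == pytest.approx(0.065, abs=0.012)

    def test_zero_variance_zero_effects_makes_groups_identical(self):
        from corticomap.synth import TestParams

        cfg = SimulationConfig(n_per_group=4, missing_rate=0.0)
        cfg.group_effects = {}
        cfg.test_params = {k: TestParams(v.mean, 0.0, 0.0) for k, v in cfg.test_params.items()}
        out = gen_cohort(cfg, raw=False).outcomes
        values = out.drop(columns=["subject", "group"])
        by_group = values.groupby(out["group"]).mean()
        pd.testing.assert_frame_equal(
            by_group.loc[["LBP"]].reset_index(drop=True),
            by_group.loc[["control"]].reset_index(drop=True),
        )

    def test_group_means_recover_planted_effects(self):
        diffs = []
        for seed in range(60):
            cfg = SimulationConfig(n_per_group=25, missing_rate=0.0, seed=seed)
            out = gen_cohort(cfg, raw=False).outcomes
            g = out.groupby("group")["temporal_summation"].mean()
            diffs.append(g["LBP"] - g["control"])
        # planted 0.992; SE of the mean difference over 60 cohorts ~ 0.044
        assert np.mean(diffs) == pytest.approx(0.992, abs=0.15)

    def test_missing_slots_become_unresponsive_sessions(self):
        cfg = SimulationConfig(
            n_per_group=3, n_stims=15, missing_rate=0.4, seed=2,
            tracking=TrackingParams(duration_s=2.0),
        )
        cohort = gen_cohort(cfg, raw=True)
        out = cohort.outcomes.set_index("subject")
        for sid, by_muscle in cohort.tms_sessions.items():
            for muscle, events in by_muscle.items():
                missing = np.isnan(out.loc[sid, f"area:{muscle}"])
                max_p2p = max(peak_to_peak(e.epoch) for e in events)
                if missing:
                    assert max_p2p <= 50.0
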