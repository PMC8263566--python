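"""Generator contracts: determinism, stated sensing rates, depression effect
direction, heterogeneity knob, and the EMA/truth round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobisense.ema_scoring import score_participants
from mobisense.feature_extraction import extract_participant_features, haversine_m
from mobisense.synthetic_data import (CohortConfig,
                                      LifestyleProfile, simulate_cohort,
                                      simulate_ema, simulate_steps,
                                      simulate_trajectory)


def _fast_cfg(**kw):
    base = dict(n_participants=30, seed=5, records_per_day_mean=40.0,
                records_per_day_sd=10.0)
    base.update(kw)
    return CohortConfig(**base)


def _single_anchor_profile(transition_rate=0.05, activity=5000.0, **kw):
    sched = np.ones((24, 1))
    defaults = dict(participant_id="solo", rng_key=0,
                    anchors=[(40.0, -100.0, "home")], daily_schedule=sched,
                    transition_rate=transition_rate, activity_level=activity,
                    depressed=False, severity=0.1)
    defaults.update(kw)
    return LifestyleProfile(**defaults)


def _nearest_anchor_changes(t_s, lat, lon, profile, max_m=150.0):
    """Daily location changes measured by nearest-anchor assignment."""
    alat = np.array([a[0] for a in profile.anchors])
    alon = np.array([a[1] for a in profile.anchors])
    d = haversine_m(lat[:, None], lon[:, None], alat[None, :], alon[None, :])
    lab = d.argmin(axis=1)
    lab[d.min(axis=1) > max_m] = -1
    keep = lab >= 0
    seq = lab[keep]
    day = (t_s[keep] // 86400).astype(int)
    changes = (seq[1:] != seq[:-1]) & (day[1:] == day[:-1])
    return changes.sum() / max(1, len(np.unique(day)))


def _cohort_anchor_changes(cohort):
    """Per-participant daily location changes from the cohort's own GPS."""
    profiles = {p.participant_id: p for p in cohort.profiles}
    out = []
    for pid, g in cohort.gps.groupby("participant_id"):
        t = g["timestamp"].astype("int64").to_numpy() / 1e9
        out.append(_nearest_anchor_changes(
            t, g["lat"].to_numpy(), g["lon"].to_numpy(), profiles[pid]))
    return np.array(out)


class TestSimulateCohort:
    def test_identical_config_and_seed_is_bit_identical(self):
        a = simulate_cohort(_fast_cfg(n_participants=8))
        b = simulate_cohort(_fast_cfg(n_participants=8))
        pd.testing.assert_frame_equal(a.gps, b.gps)
        pd.testing.assert_frame_equal(a.steps, b.steps)
        pd.testing.assert_frame_equal(a.ema, b.ema)
        pd.testing.assert_frame_equal(a.demographics, b.demographics)

    def test_zero_prevalence_all_labels_false(self):
        c = simulate_cohort(_fast_cfg(prevalence=0.0, n_participants=15))
        assert not c.truth_labels.any()

    def test_empty_cohort_is_legal(self):
        c = simulate_cohort(_fast_cfg(n_participants=0))
        assert len(c.profiles) == 0
        assert len(c.gps) == 0 and len(c.ema) == 0 and len(c.steps) == 0

    def test_label_fraction_within_exact_binomial_band(self):
        # 99% central binomial interval for n=1000, p=0.5, computed from the
        # exact distribution (independent of the generator)
        n = 1000
        lo = stats.binom.ppf(0.005, n, 0.5) / n
        hi = stats.binom.ppf(0.995, n, 0.5) / n
        cfg = _fast_cfg(n_participants=n, prevalence=0.5, n_days=1,
                        records_per_day_mean=3.0, records_per_day_sd=1.0)
        c = simulate_cohort(cfg)
        assert lo <= c.truth_labels.mean() <= hi

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortConfig(n_participants=5, prevalence=1.5).validate()
        with pytest.raises(ValueError, match="gps_noise_m"):
            CohortConfig(n_participants=5, gps_noise_m=-1.0).validate()
        with pytest.raises(ValueError, match="records_per_day_mean"):
            CohortConfig(n_participants=5,
                         records_per_day_mean=float("nan")).validate()

    def test_every_participant_in_all_collections(self, small_cohort):
        ids = {p.participant_id for p in small_cohort.profiles}
        assert set(small_cohort.demographics["participant_id"]) == ids
        assert set(small_cohort.gps["participant_id"].unique()) <= ids
        assert set(small_cohort.truth_labels.index) == ids
        for p in small_cohort.profiles:
            assert small_cohort.truth_labels[p.participant_id] == p.depressed


class TestTrajectory:
    def test_immobile_participant_stays_at_home(self):
        cfg = _fast_cfg(n_participants=1, dropout_prob=0.0)
        prof = _single_anchor_profile(transition_rate=1e-6)
        traj = simulate_trajectory(prof, cfg)
        d = haversine_m(traj["lat"], traj["lon"], 40.0, -100.0)
        assert np.all(d <= 5 * cfg.gps_noise_m)

    def test_timestamps_strictly_increasing_and_wgs84(self, small_cohort):
        for pid, g in small_cohort.gps.groupby("participant_id"):
            t = g["timestamp"].to_numpy()
            assert (t[1:] > t[:-1]).all()
        assert small_cohort.gps["lat"].between(-90, 90).all()
        assert small_cohort.gps["lon"].between(-180, 180).all()

    def test_default_sensing_rate_near_stated_mean(self):
        """Mean records per tracked day within 10% of 403.57 (defaults)."""
        cfg = CohortConfig(n_participants=100, seed=21)
        c = simulate_cohort(cfg)
        day = (c.gps["timestamp"].astype("int64") // (86400 * 10 ** 9))
        per_day = c.gps.groupby(["participant_id", day]).size()
        assert abs(per_day.mean() - 403.57) / 403.57 < 0.10

    def test_depressed_group_moves_less(self):
        """Only the depressed flag differs: fewer daily location changes."""
        rates = {}
        for prev in (0.0, 1.0):
            cfg = CohortConfig(n_participants=500, prevalence=prev, seed=17,
                               effect_size=1.0, heterogeneity_sd=0.3,
                               records_per_day_mean=72.0, records_per_day_sd=18.0)
            rates[prev] = _cohort_anchor_changes(simulate_cohort(cfg)).mean()
        assert rates[1.0] < rates[0.0]

    def test_effect_size_monotonically_separates_groups(self):
        """Larger effect size never shrinks the standardized group gap."""
        seps = []
        for eff in (0.0, 0.75, 1.5):
            groups = {}
            for prev in (0.0, 1.0):
                cfg = CohortConfig(n_participants=120, prevalence=prev, seed=29,
                                   effect_size=eff, heterogeneity_sd=0.3,
                                   records_per_day_mean=72.0,
                                   records_per_day_sd=18.0)
                groups[prev] = _cohort_anchor_changes(simulate_cohort(cfg))
            pooled = np.sqrt((groups[0.0].var(ddof=1) + groups[1.0].var(ddof=1)) / 2)
            seps.append((groups[0.0].mean() - groups[1.0].mean()) / pooled)
        assert seps[0] <= seps[1] + 1e-9 and seps[1] <= seps[2] + 1e-9

    def test_heterogeneity_increases_feature_variance(self):
        """Between-person variance of entropy and total distance grows."""
        var = {}
        for het in (0.0, 1.0):
            cfg = CohortConfig(n_participants=60, prevalence=0.0, seed=31,
                               heterogeneity_sd=het, records_per_day_mean=40.0,
                               records_per_day_sd=10.0)
            cohort = simulate_cohort(cfg)
            ent, dist = [], []
            for pid, g in cohort.gps.groupby("participant_id"):
                t = g["timestamp"].astype("int64").to_numpy() / 1e9
                row, _ = extract_participant_features(
                    t, g["lat"].to_numpy(), g["lon"].to_numpy())
                ent.append(row["entropy_14d"])
                dist.append(row["total_distance_14d_m"])
            var[het] = (np.nanvar(ent), np.nanvar(dist))
        assert var[1.0][0] > var[0.0][0]
        assert var[1.0][1] > var[0.0][1]


class TestSteps:
    def test_zero_activity_yields_zero_steps(self):
        cfg = _fast_cfg(n_participants=1)
        st = simulate_steps(_single_anchor_profile(activity=0.0), cfg)
        assert (st["steps"] == 0).all()

    def test_one_record_per_day(self):
        cfg = _fast_cfg(n_participants=1, n_days=14)
        st = simulate_steps(_single_anchor_profile(transition_rate=3.0), cfg)
        assert len(st) == 14
        assert (st["steps"] >= 0).all()

    def test_steps_track_daily_distance(self, small_cohort):
        cfg = small_cohort.config
        dists, steps = [], []
        for p in small_cohort.profiles:
            from mobisense.synthetic_data import _simulate_movement
            _, dd = _simulate_movement(p, cfg)
            st = simulate_steps(p, cfg)
            dists.extend(dd)
            steps.extend(st["steps"])
        r = stats.pearsonr(dists, steps)[0]
        assert r > 0


class TestEma:
    def test_zero_severity_zero_noise_scores_negative(self):
        cfg = _fast_cfg(n_participants=1, ema_slope=0.0)
        prof = _single_anchor_profile(severity=0.0)
        em = simulate_ema(prof, cfg)
        assert not em["endorsed"].any()
        em["participant_id"] = "solo"
        lab = score_participants(em)
        assert not lab["label"].iloc[0]

    def test_max_severity_zero_noise_scores_positive(self):
        cfg = _fast_cfg(n_participants=1, ema_slope=0.0)
        prof = _single_anchor_profile(severity=1.0)
        em = simulate_ema(prof, cfg)
        assert em["endorsed"].all()
        em["participant_id"] = "solo"
        lab = score_participants(em)
        assert lab["label"].iloc[0]

    def test_burden_present_iff_endorsed(self, small_cohort):
        em = small_cohort.ema
        assert em.loc[em["endorsed"], "burden"].between(1, 4).all()
        assert em.loc[~em["endorsed"], "burden"].isna().all()

    def test_truth_label_agreement_at_calibration_defaults(self):
        """ICD-10 scored label agrees with the latent truth >= 90%."""
        cfg = CohortConfig(n_participants=500, prevalence=0.5, seed=41,
                           n_days=14, records_per_day_mean=3.0,
                           records_per_day_sd=1.0)
        c = simulate_cohort(cfg)
        lab = score_participants(c.ema).set_index("participant_id")
        agree = (lab["label"] == c.truth_labels.loc[lab.index]).mean()
        assert agree >= 0.90
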