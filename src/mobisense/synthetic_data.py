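"""Synthetic cohort generator for GPS-mobility depression studies.

Emulates the data a mood self-tracking app would collect: event-based GPS
sampling (defaults: 403.57 records/day with SD 250.72, 24.92 m spatial
noise), daily step counts, and up-to-three-times-daily symptom surveys over
a 14-day window, together with a six-attribute demographics table.

The movement model is semi-Markov anchor-hopping: each participant owns a
small set of significant places (home, work, others), dwells at one anchor,
and jumps to the next according to an hourly occupancy schedule, with
straight-line interpolated waypoints during the jump.  Depression shifts a
participant's transition rate, anchor diversity, daytime home occupancy, and
activity level downward/homeward by ``effect_size`` in units of a reference
population SD; ``heterogeneity_sd`` scales the between-person (lognormal)
variance of all lifestyle parameters, so a cohort can be dialled from fully
homogeneous (every non-depressed participant shares one lifestyle) to
heavily heterogeneous.

Everything is deterministic given (config, seed): each participant draws
from substreams derived from ``(seed, participant index, stream tag)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from mobisense.feature_extraction import haversine_m

#: local-time origin of every simulated window (a Monday).
WINDOW_START = pd.Timestamp("2021-03-01 00:00:00")

# Reference (heterogeneity-independent) lifestyle population: used both as
# the base profile and to define the SD unit in which effect_size operates.
BASE_TRANSITION_RATE = 8.0     # expected location changes / day
BASE_EXTRA_ANCHORS = 4         # significant places beyond home and work
BASE_ACTIVITY = 7000.0         # expected steps / day
BASE_HOME_DAY_WEIGHT = 0.35    # daytime home-occupancy probability
REF_REL_SD = 0.25              # reference relative SD of lifestyle params

#: exponent coupling a participant's movement level to their record volume
#: (event-based sampling: more movement events, more records).
RECORD_MOVEMENT_EXPONENT = 0.3

TRANSIT_DURATION_S = 600.0     # anchor-to-anchor jump duration
WAYPOINTS_PER_JUMP = 3

M_PER_DEG_LAT = 111_320.0

DEMOGRAPHIC_ATTRIBUTES = (
    "gender", "age", "education", "urbanicity", "sexual_orientation", "ethnicity",
)

#: default categorical distributions, loosely shaped like a U.S.-wide
#: self-selected app cohort.
DEFAULT_DEMOGRAPHIC_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "gender": {"female": 0.66, "male": 0.29, "non_binary": 0.05},
    "age": {"16-25": 0.58, "26-35": 0.28, "36-45": 0.09, "46+": 0.05},
    "education": {"less_than_hs": 0.09, "high_school": 0.20,
                  "some_college": 0.36, "bachelor": 0.19, "graduate": 0.16},
    "urbanicity": {"urban": 0.74, "rural": 0.26},
    "sexual_orientation": {"heterosexual": 0.51, "bisexual": 0.31,
                           "homosexual": 0.07, "other": 0.11},
    "ethnicity": {"white": 0.64, "hispanic": 0.13, "black": 0.12,
                  "asian": 0.04, "other": 0.07},
}

DEMOGRAPHIC_LEVELS = {a: tuple(d) for a, d in DEFAULT_DEMOGRAPHIC_DISTRIBUTIONS.items()}

# ---------------------------------------------------------------------------
# 17-item depressive-symptom pool mapped onto the 10 ICD-10 symptoms
# (3 core, 7 additional).  The intercept is the severity at which the item
# flips from unlikely to likely endorsement.
# item_id, symptom_key, is_core, intercept
SYMPTOM_ITEMS: tuple[tuple[int, str, bool, float], ...] = (
    (1, "depressed_mood", True, 0.35),
    (2, "depressed_mood", True, 0.38),
    (3, "loss_of_interest", True, 0.40),
    (4, "loss_of_interest", True, 0.43),
    (5, "fatigue", True, 0.45),
    (6, "fatigue", True, 0.47),
    (7, "concentration", False, 0.48),
    (8, "concentration", False, 0.51),
    (9, "self_esteem", False, 0.50),
    (10, "self_esteem", False, 0.54),
    (11, "guilt", False, 0.58),
    (12, "pessimism", False, 0.52),
    (13, "pessimism", False, 0.56),
    (14, "self_harm", False, 0.68),
    (15, "sleep", False, 0.49),
    (16, "sleep", False, 0.53),
    (17, "appetite", False, 0.55),
)
assert len(SYMPTOM_ITEMS) == 17
assert sum(c for _, _, c, _ in SYMPTOM_ITEMS) == 6

ITEM_IDS = np.array([i for i, _, _, _ in SYMPTOM_ITEMS])
ITEM_CORE = np.array([c for _, _, c, _ in SYMPTOM_ITEMS])
ITEM_INTERCEPTS = np.array([b for _, _, _, b in SYMPTOM_ITEMS])
ITEMS_PER_SESSION = 6


def _require(cond: bool, name: str, value) -> None:
    if not cond:
        raise ValueError(f"invalid CohortConfig field {name}={value!r}")


@dataclass
class CohortConfig:
    """Scenario definition for one simulated cohort.

    ``effect_size`` is the standardized downward shift of mobility-linked
    lifestyle parameters under depression (units: the reference population
    SD, i.e. ``REF_REL_SD`` × the base value).  ``heterogeneity_sd`` is the
    log-scale SD of the between-person lifestyle multipliers.
    """

    n_participants: int
    prevalence: float = 0.35
    n_days: int = 14
    effect_size: float = 1.0
    heterogeneity_sd: float = 0.5
    geo_spread_km: float = 50.0
    records_per_day_mean: float = 403.57
    records_per_day_sd: float = 250.72
    gps_noise_m: float = 24.92
    seed: int = 0
    center_lat: float = 39.5
    center_lon: float = -98.35
    timezone_offset: float = 0.0
    dropout_prob: float = 0.05
    ema_slope: float = 0.07
    severity_threshold: float = 0.55
    demographic_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(d) for a, d in
                                 DEFAULT_DEMOGRAPHIC_DISTRIBUTIONS.items()})
    demographic_coupling: dict[str, dict[str, dict[str, float]]] | None = None

    def validate(self) -> None:
        _require(isinstance(self.n_participants, (int, np.integer))
                 and self.n_participants >= 0, "n_participants", self.n_participants)
        for name in ("prevalence", "effect_size", "heterogeneity_sd", "geo_spread_km",
                     "records_per_day_mean", "records_per_day_sd", "gps_noise_m",
                     "center_lat", "center_lon", "timezone_offset", "dropout_prob",
                     "ema_slope", "severity_threshold"):
            v = getattr(self, name)
            _require(isinstance(v, (int, float)) and math.isfinite(v), name, v)
        _require(0.0 <= self.prevalence <= 1.0, "prevalence", self.prevalence)
        _require(self.n_days >= 1, "n_days", self.n_days)
        _require(self.heterogeneity_sd >= 0, "heterogeneity_sd", self.heterogeneity_sd)
        _require(self.records_per_day_sd >= 0, "records_per_day_sd", self.records_per_day_sd)
        _require(self.records_per_day_mean > 0, "records_per_day_mean", self.records_per_day_mean)
        _require(self.gps_noise_m >= 0, "gps_noise_m", self.gps_noise_m)
        _require(self.geo_spread_km >= 0, "geo_spread_km", self.geo_spread_km)
        _require(0.0 <= self.dropout_prob < 1.0, "dropout_prob", self.dropout_prob)
        _require(self.ema_slope >= 0, "ema_slope", self.ema_slope)
        for attr, dist in self.demographic_distributions.items():
            _require(attr in DEMOGRAPHIC_ATTRIBUTES, "demographic_distributions", attr)
            tot = sum(dist.values())
            _require(abs(tot - 1.0) < 1e-6, f"demographic_distributions[{attr}]", tot)


@dataclass
class LifestyleProfile:
    """Latent per-participant generative parameters."""

    participant_id: str
    rng_key: int
    anchors: list[tuple[float, float, str]]           # (lat, lon, role)
    daily_schedule: np.ndarray                        # 24 x n_anchors occupancy
    transition_rate: float
    activity_level: float
    depressed: bool
    severity: float
    timezone_offset: float = 0.0

    def validate(self) -> None:
        if not any(role == "home" for _, _, role in self.anchors):
            raise ValueError("profile must have a home anchor")
        if self.transition_rate <= 0:
            raise ValueError("transition_rate must be > 0")
        sums = self.daily_schedule.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("hourly occupancy probabilities must sum to 1")


@dataclass
class SyntheticCohort:
    """All simulated tables for one cohort, keyed by participant_id."""

    config: CohortConfig
    profiles: list[LifestyleProfile]
    demographics: pd.DataFrame
    gps: pd.DataFrame
    steps: pd.DataFrame
    ema: pd.DataFrame
    truth_labels: pd.Series


def _rng(cfg_seed: int, key: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed & 0x7FFFFFFF, key, stream])


def _offset_latlon(lat0: float, lon0: float, east_m: float, north_m: float
                   ) -> tuple[float, float]:
    lat = lat0 + north_m / M_PER_DEG_LAT
    lon = lon0 + east_m / (M_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return lat, lon


def _sample_demographics(cfg: CohortConfig, rng: np.random.Generator) -> dict[str, str]:
    row = {}
    for attr in DEMOGRAPHIC_ATTRIBUTES:
        dist = cfg.demographic_distributions.get(
            attr, DEFAULT_DEMOGRAPHIC_DISTRIBUTIONS[attr])
        levels = list(dist)
        probs = np.array([dist[l] for l in levels], dtype=float)
        row[attr] = levels[rng.choice(len(levels), p=probs / probs.sum())]
    return row


def _build_profile(i: int, cfg: CohortConfig, demo: dict[str, str]) -> LifestyleProfile:
    rng = _rng(cfg.seed, i, 0)
    depressed = bool(rng.random() < cfg.prevalence)
    severity = float(0.60 + 0.35 * rng.random()) if depressed \
        else float(0.35 * rng.random())

    het = cfg.heterogeneity_sd
    z = rng.normal(size=4)
    mult = np.exp(het * z - 0.5 * het * het)
    dep_shift = cfg.effect_size * REF_REL_SD if depressed else 0.0
    dep_factor = max(0.05, 1.0 - dep_shift)

    transition_rate = max(0.05, BASE_TRANSITION_RATE * mult[0] * dep_factor)
    n_extra = max(1, int(round(BASE_EXTRA_ANCHORS * mult[1] * dep_factor)))
    activity = max(0.0, BASE_ACTIVITY * mult[2] * dep_factor)
    home_day_w = float(np.clip(BASE_HOME_DAY_WEIGHT * mult[3] * (1.0 + dep_shift),
                               0.05, 0.90))

    if cfg.demographic_coupling:
        for attr, levels in cfg.demographic_coupling.items():
            mults = levels.get(demo.get(attr, ""), {})
            transition_rate = max(0.05, transition_rate * mults.get("transition_rate", 1.0))
            activity = max(0.0, activity * mults.get("activity_level", 1.0))
            home_day_w = float(np.clip(home_day_w * mults.get("home_day_weight", 1.0),
                                       0.05, 0.95))
            n_extra = max(1, int(round(n_extra * mults.get("n_extra_anchors", 1.0))))

    # geography: home anchor inside a disk of radius geo_spread_km, other
    # anchors within commuting distance of home
    theta = rng.uniform(0, 2 * math.pi)
    r = cfg.geo_spread_km * 1000.0 * math.sqrt(rng.random())
    home = _offset_latlon(cfg.center_lat, cfg.center_lon,
                          r * math.cos(theta), r * math.sin(theta))
    anchors: list[tuple[float, float, str]] = [(home[0], home[1], "home")]
    for k in range(1 + n_extra):  # work + others
        th = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(500.0, 4000.0)
        la, lo = _offset_latlon(home[0], home[1], d * math.cos(th), d * math.sin(th))
        anchors.append((la, lo, "work" if k == 0 else "other"))

    n_anchor = len(anchors)
    sched = np.zeros((24, n_anchor))
    for h in range(24):
        if h >= 22 or h < 6:
            w = np.full(n_anchor, 0.03 / max(1, n_anchor - 1))
            w[0] = 0.97
        else:
            w = np.empty(n_anchor)
            w[0] = home_day_w
            rest = 1.0 - home_day_w
            work_share = 0.55 if 9 <= h < 18 else 0.15
            w[1] = rest * work_share
            if n_anchor > 2:
                w[2:] = rest * (1.0 - work_share) / (n_anchor - 2)
            else:
                w[1] = rest
        sched[h] = w / w.sum()

    prof = LifestyleProfile(
        participant_id=f"p{i:05d}", rng_key=i, anchors=anchors,
        daily_schedule=sched, transition_rate=transition_rate,
        activity_level=activity, depressed=depressed, severity=severity,
        timezone_offset=cfg.timezone_offset)
    prof.validate()
    return prof


def _simulate_movement(profile: LifestyleProfile, cfg: CohortConfig):
    """Deterministic dwell/jump trace shared by the GPS and step simulators.

    Returns per-day lists of segments ``(t_start_s, t_end_s, anchor_idx)``
    and the per-day travelled anchor-to-anchor distance in meters.
    """
    rng = _rng(cfg.seed, profile.rng_key, 1)
    alat = np.array([a[0] for a in profile.anchors])
    alon = np.array([a[1] for a in profile.anchors])
    n_anchor = len(profile.anchors)
    days = []
    day_dist = np.zeros(cfg.n_days)
    for d in range(cfg.n_days):
        day0 = d * 86400.0
        n_trans = int(rng.poisson(profile.transition_rate))
        times = np.sort(rng.uniform(7 * 3600.0, 22 * 3600.0, size=n_trans))
        cur = 0  # midnight: at home
        segs = []
        t_prev = 0.0
        dist = 0.0
        for tt in times:
            hour = int(tt // 3600) % 24
            w = profile.daily_schedule[hour].copy()
            if n_anchor > 1:
                w[cur] = 0.0
                if w.sum() <= 0:
                    w = np.ones(n_anchor)
                    w[cur] = 0.0
                nxt = int(rng.choice(n_anchor, p=w / w.sum()))
            else:
                nxt = cur
            segs.append((day0 + t_prev, day0 + tt, cur))
            if nxt != cur:
                dist += float(haversine_m(alat[cur], alon[cur], alat[nxt], alon[nxt]))
            cur = nxt
            t_prev = tt
        segs.append((day0 + t_prev, day0 + 86400.0, cur))
        days.append(segs)
        day_dist[d] = dist
    return days, day_dist


def simulate_trajectory(profile: LifestyleProfile, config: CohortConfig
                        ) -> pd.DataFrame:
    """Event-sampled GPS records for one participant's window.

    Columns: t_local_s (strictly increasing local epoch-offset seconds),
    lat, lon, accuracy_m.  Record volume scales with the participant's
    movement level; positions carry Gaussian jitter with radial SD
    ``gps_noise_m``.
    """
    profile.validate()
    config.validate()
    rng = _rng(config.seed, profile.rng_key, 2)
    days, _ = _simulate_movement(profile, config)
    alat = np.array([a[0] for a in profile.anchors])
    alon = np.array([a[1] for a in profile.anchors])

    move_factor = (profile.transition_rate / BASE_TRANSITION_RATE) ** RECORD_MOVEMENT_EXPONENT
    mu = config.records_per_day_mean * move_factor
    sd = config.records_per_day_sd * move_factor

    ts, la, lo = [], [], []
    for d, segs in enumerate(days):
        if rng.random() < config.dropout_prob:
            continue
        n_rec = max(1, int(round(rng.normal(mu, sd))))
        jumps = [(segs[k][1], segs[k][2], segs[k + 1][2])
                 for k in range(len(segs) - 1) if segs[k][2] != segs[k + 1][2]]
        n_way = WAYPOINTS_PER_JUMP * len(jumps)
        for t_jump, a_from, a_to in jumps:
            fr = (np.arange(WAYPOINTS_PER_JUMP) + 1) / (WAYPOINTS_PER_JUMP + 1)
            ts.append(t_jump + fr * TRANSIT_DURATION_S)
            la.append(alat[a_from] + fr * (alat[a_to] - alat[a_from]))
            lo.append(alon[a_from] + fr * (alon[a_to] - alon[a_from]))
        n_dwell = max(0, n_rec - n_way)
        if n_dwell:
            dur = np.array([e - s for s, e, _ in segs])
            alloc = rng.multinomial(n_dwell, dur / dur.sum())
            for (s, e, a), m in zip(segs, alloc):
                if m == 0:
                    continue
                ts.append(rng.uniform(s, e, size=m))
                la.append(np.full(m, alat[a]))
                lo.append(np.full(m, alon[a]))
    if not ts:
        return pd.DataFrame(columns=["t_local_s", "lat", "lon", "accuracy_m"])
    t = np.concatenate(ts)
    lat = np.concatenate(la)
    lon = np.concatenate(lo)
    axis_sd = config.gps_noise_m / math.sqrt(2.0)
    lat = lat + rng.normal(0, axis_sd, lat.size) / M_PER_DEG_LAT
    lon = lon + rng.normal(0, axis_sd, lon.size) / (
        M_PER_DEG_LAT * math.cos(math.radians(config.center_lat)))
    order = np.argsort(t, kind="stable")
    t = t[order] + np.arange(t.size) * 1e-6  # enforce strictly increasing
    acc = np.abs(rng.normal(config.gps_noise_m, config.gps_noise_m / 3.0, t.size))
    return pd.DataFrame({"t_local_s": t, "lat": lat[order], "lon": lon[order],
                         "accuracy_m": acc})


def simulate_steps(profile: LifestyleProfile, config: CohortConfig) -> pd.DataFrame:
    """One non-negative daily step count per simulated day.

    Counts are positively coupled to the day's travelled distance and scale
    with the participant's activity level.
    """
    profile.validate()
    config.validate()
    rng = _rng(config.seed, profile.rng_key, 3)
    _, day_dist = _simulate_movement(profile, config)
    ref = day_dist.mean() if day_dist.mean() > 0 else 1.0
    noise = np.exp(rng.normal(0.0, 0.08, size=config.n_days))
    raw = profile.activity_level * (0.4 + 0.6 * day_dist / ref) * noise
    steps = np.maximum(0, np.round(raw)).astype(int)
    dates = pd.date_range(WINDOW_START, periods=config.n_days, freq="D").date
    return pd.DataFrame({"date": dates, "steps": steps})


def simulate_ema(profile: LifestyleProfile, config: CohortConfig) -> pd.DataFrame:
    """Repeated symptom-survey responses (up to 3 sessions/day).

    Each session administers a random subset of the 17 depressive-symptom
    items; endorsement follows a per-item logistic response in the latent
    severity (a step function when ``ema_slope`` = 0); endorsed items carry
    a 1–4 burden rating.
    """
    profile.validate()
    config.validate()
    rng = _rng(config.seed, profile.rng_key, 4)
    sev = profile.severity
    rows_t, rows_item = [], []
    for d in range(config.n_days):
        n_sessions = int(rng.choice([1, 2, 3], p=[0.15, 0.35, 0.50]))
        times = np.sort(rng.uniform(8 * 3600.0, 22 * 3600.0, size=n_sessions))
        for t in times:
            items = rng.choice(17, size=ITEMS_PER_SESSION, replace=False)
            for ix in np.sort(items):
                rows_t.append(d * 86400.0 + t)
                rows_item.append(ix)
    if not rows_t:
        return pd.DataFrame(columns=["t_local_s", "item_id", "symptom_key",
                                     "is_core", "endorsed", "burden"])
    item_ix = np.array(rows_item)
    b = ITEM_INTERCEPTS[item_ix]
    if config.ema_slope > 0:
        p = 1.0 / (1.0 + np.exp(-(sev - b) / config.ema_slope))
        endorsed = rng.random(item_ix.size) < p
    else:
        endorsed = sev > b
    burden = np.clip(np.round(1.0 + 3.0 * sev + rng.normal(0, 0.5, item_ix.size)),
                     1, 4).astype(int)
    symptom_keys = np.array([s for _, s, _, _ in SYMPTOM_ITEMS])
    df = pd.DataFrame({
        "t_local_s": np.array(rows_t),
        "item_id": ITEM_IDS[item_ix],
        "symptom_key": symptom_keys[item_ix],
        "is_core": ITEM_CORE[item_ix],
        "endorsed": endorsed,
        "burden": np.where(endorsed, burden, np.int64(0)),
    })
    df["burden"] = df["burden"].where(df["endorsed"], other=pd.NA)
    return df


def _to_utc(t_local_s: np.ndarray, tz_offset_hours: float) -> pd.DatetimeIndex:
    ns = (WINDOW_START.value + ((t_local_s - tz_offset_hours * 3600.0) * 1e9)
          .astype(np.int64))
    return pd.DatetimeIndex(ns.astype("datetime64[ns]"))


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (profiles + 4 data tables)."""
    config.validate()
    profiles: list[LifestyleProfile] = []
    demo_rows = []
    gps_parts, step_parts, ema_parts = [], [], []
    truth = {}
    for i in range(config.n_participants):
        demo = _sample_demographics(config, _rng(config.seed, i, 5))
        prof = _build_profile(i, config, demo)
        profiles.append(prof)
        pid = prof.participant_id
        demo_rows.append({"participant_id": pid, **demo})
        truth[pid] = prof.depressed

        traj = simulate_trajectory(prof, config)
        if len(traj):
            gps_parts.append(pd.DataFrame({
                "participant_id": pid,
                "timestamp": _to_utc(traj["t_local_s"].to_numpy(), config.timezone_offset),
                "lat": traj["lat"].to_numpy(),
                "lon": traj["lon"].to_numpy(),
                "accuracy_m": traj["accuracy_m"].to_numpy(),
            }))
        st = simulate_steps(prof, config)
        st.insert(0, "participant_id", pid)
        step_parts.append(st)
        em = simulate_ema(prof, config)
        if len(em):
            em.insert(0, "participant_id", pid)
            em["timestamp"] = _to_utc(em["t_local_s"].to_numpy(), config.timezone_offset)
            ema_parts.append(em.drop(columns=["t_local_s"]))

    gps = pd.concat(gps_parts, ignore_index=True) if gps_parts else pd.DataFrame(
        columns=["participant_id", "timestamp", "lat", "lon", "accuracy_m"])
    steps = pd.concat(step_parts, ignore_index=True) if step_parts else pd.DataFrame(
        columns=["participant_id", "date", "steps"])
    ema = pd.concat(ema_parts, ignore_index=True) if ema_parts else pd.DataFrame(
        columns=["participant_id", "item_id", "symptom_key", "is_core",
                 "endorsed", "burden", "timestamp"])
    demographics = pd.DataFrame(
        demo_rows, columns=["participant_id", *DEMOGRAPHIC_ATTRIBUTES])
    truth_s = pd.Series(truth, dtype=bool, name="depressed")
    truth_s.index.name = "participant_id"
    return SyntheticCohort(config=config, profiles=profiles,
                           demographics=demographics, gps=gps, steps=steps,
                           ema=ema, truth_labels=truth_s)


# ---------------------------------------------------------------------------
# writers / scenario IO


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write gps.csv, steps.csv, ema.csv, demographics.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gps = cohort.gps.copy()
    if len(gps):
        gps["timestamp"] = gps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    paths["gps"] = outdir / "gps.csv"
    gps.to_csv(paths["gps"], index=False)
    paths["steps"] = outdir / "steps.csv"
    cohort.steps.to_csv(paths["steps"], index=False)
    ema = cohort.ema.copy()
    if len(ema):
        ema["timestamp"] = ema["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
        ema = ema[["participant_id", "timestamp", "item_id", "is_core",
                   "endorsed", "burden", "symptom_key"]]
    paths["ema"] = outdir / "ema.csv"
    ema.to_csv(paths["ema"], index=False)
    paths["demographics"] = outdir / "demographics.csv"
    cohort.demographics.to_csv(paths["demographics"], index=False)
    return paths


def cohort_config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg


def cohort_config_to_yaml(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
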