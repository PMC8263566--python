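"""Mobility feature extraction from raw GPS trajectories.

The mobility representation follows the digital-phenotyping convention:
significant locations are DBSCAN clusters (haversine metric, eps = 30 m,
minPts = 3) of a participant's GPS records; the home location is the cluster
holding the most records between 22:00 and 06:00 local time.  From the
clustered trajectory, 33 features are computed per local day and aggregated
over the 14-day window with mean / min / max / sd (= 132 values), and 38
features are computed once over the whole window, giving 170 GPS features
per participant.  Six further features summarize daily step counts.

All distances are great-circle (haversine, Earth radius 6,371,000 m).
"Time spent" proportions use record counts as the time proxy: sampling is
event-based, so the record stream itself is movement-weighted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from sklearn.cluster import DBSCAN

EARTH_RADIUS_M = 6_371_000.0
NOISE = -1
LOG_EPS = 1e-10

#: speed below which a record pair is considered stationary (jitter-level
#: motion at ~25 m accuracy and multi-minute gaps sits well under this).
STATIONARY_SPEED_MPS = 0.15

#: minimum inter-record gap (s) used when converting displacement to speed.
MIN_SPEED_DT_S = 1.0

DAILY_STATS = ("mean", "min", "max", "sd")

DAILY_FEATURES = (
    "num_records",
    "num_clusters_visited",
    "num_location_changes",
    "proportion_noise_records",
    "total_distance_m",
    "max_displacement_m",
    "radius_of_gyration_m",
    "max_distance_from_home_m",
    "mean_distance_from_home_m",
    "entropy",
    "normalized_entropy",
    "location_variance",
    "proportion_time_home",
    "proportion_time_top_cluster",
    "mean_dwell_min",
    "max_dwell_min",
    "num_transitions_night",
    "proportion_records_night",
    "proportion_records_day",
    "proportion_records_evening",
    "first_movement_hour",
    "last_movement_hour",
    "tracked_span_hours",
    "mean_speed_mps",
    "max_speed_mps",
    "proportion_stationary_records",
    "num_unique_clusters_night",
    "distance_home_sd_m",
    "displacement_sd_m",
    "inter_record_gap_mean_s",
    "inter_record_gap_max_s",
    "bounding_box_diagonal_m",
    "cluster_visit_gini",
)

PERIOD_FEATURES = (
    "num_significant_locations",
    "entropy_14d",
    "normalized_entropy_14d",
    "location_variance_14d",
    "radius_of_gyration_14d_m",
    "max_distance_from_home_14d_m",
    "mean_distance_from_home_14d_m",
    "sd_distance_from_home_14d_m",
    "total_distance_14d_m",
    "proportion_time_home_14d",
    "proportion_time_top_cluster_14d",
    "proportion_noise_records_14d",
    "total_records",
    "mean_records_per_day",
    "days_tracked",
    "days_with_gt100_records",
    "circadian_movement",
    "routine_index",
    "mean_dwell_min_14d",
    "max_dwell_min_14d",
    "num_location_changes_14d",
    "location_changes_per_day_14d",
    "weekday_weekend_diff_distance_m",
    "weekday_weekend_diff_home_time",
    "weekday_weekend_diff_entropy",
    "weekday_weekend_diff_location_changes",
    "weekday_weekend_diff_records",
    "proportion_home_night_14d",
    "proportion_home_day_14d",
    "distance_night_14d_m",
    "distance_day_14d_m",
    "proportion_records_night_14d",
    "proportion_records_weekend_14d",
    "bounding_box_diagonal_14d_m",
    "max_displacement_14d_m",
    "mean_speed_14d_mps",
    "max_speed_14d_mps",
    "cluster_visit_gini_14d",
)

STEP_FEATURES = (
    "steps__mean",
    "steps__min",
    "steps__max",
    "steps__sd",
    "steps__sum",
    "steps__weekday_weekend_diff",
)

assert len(DAILY_FEATURES) == 33
assert len(PERIOD_FEATURES) == 38
assert len(STEP_FEATURES) == 6


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters for significant-location extraction."""

    eps_m: float = 30.0
    min_pts: int = 3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps_m) and self.eps_m > 0):
            raise ValueError(f"eps_m must be positive, got {self.eps_m}")
        if self.min_pts < 1:
            raise ValueError(f"min_pts must be >= 1, got {self.min_pts}")


@dataclass
class ClusterAssignment:
    """Per-record significant-location labels (-1 = noise) plus centroids."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]]
    home_cluster_id: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if not (np.all(np.isfinite(lat1)) and np.all(np.isfinite(lon1))
            and np.all(np.isfinite(lat2)) and np.all(np.isfinite(lon2))):
        raise ValueError("haversine_m requires finite coordinates")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def cluster_locations(lat: np.ndarray, lon: np.ndarray,
                      params: ClusterParams = ClusterParams()) -> ClusterAssignment:
    """DBSCAN significant locations over the haversine metric.

    Labels are renumbered canonically: cluster 0 is the one whose first
    member occurs earliest in the (time-sorted) record stream, so the
    labelling is invariant to record-order permutation up to this renumber.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return ClusterAssignment(labels=np.empty(0, dtype=int), centroids={})
    X = np.radians(np.column_stack([lat, lon]))
    raw = DBSCAN(eps=params.eps_m / EARTH_RADIUS_M, min_samples=params.min_pts,
                 metric="haversine", algorithm="ball_tree").fit_predict(X)
    labels = np.full(raw.shape, NOISE, dtype=int)
    centroids: dict[int, tuple[float, float]] = {}
    next_id = 0
    for i in range(raw.size):
        r = raw[i]
        if r == NOISE or labels[i] != NOISE:
            continue
        members = raw == r
        labels[members] = next_id
        centroids[next_id] = (float(lat[members].mean()), float(lon[members].mean()))
        next_id += 1
    return ClusterAssignment(labels=labels, centroids=centroids)


def detect_home(assignment: ClusterAssignment, local_hour: np.ndarray) -> int | None:
    """Home = cluster with most records in the 22:00–06:00 local window.

    Ties break by larger total record count, then lower cluster id.  If no
    records fall in the night window, falls back to the overall
    most-populated cluster.  Returns None when there are no clusters.
    """
    labels = assignment.labels
    if assignment.n_clusters == 0:
        return None
    local_hour = np.asarray(local_hour, dtype=float)
    night = (local_hour >= 22.0) | (local_hour < 6.0)
    nonnoise = labels != NOISE
    ids = np.array(sorted(assignment.centroids))
    total = np.array([(labels == c).sum() for c in ids])
    night_ct = np.array([((labels == c) & night).sum() for c in ids])
    if night_ct.sum() == 0:
        order = np.lexsort((ids, -total))
    else:
        order = np.lexsort((ids, -total, -night_ct))
    del nonnoise
    return int(ids[order[0]])


def shannon_entropy(proportions: Sequence[float], normalized: bool = False) -> float:
    """−Σ p ln p over an occupancy distribution (0·ln 0 = 0), in nats.

    With ``normalized=True`` divides by ln K (0 for K = 1).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("proportions must be non-negative")
    if p.size and abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum()) if p.size else 0.0
    if normalized:
        k = len(proportions)
        return h / np.log(k) if k > 1 else 0.0
    return h


def _ls_band_energy(t_hours: np.ndarray, y: np.ndarray,
                    period_min_h: float, period_max_h: float,
                    n_periods: int = 32) -> float:
    """Summed Lomb–Scargle periodogram power in a period band."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    if np.allclose(yc, 0.0):
        return 0.0
    periods = np.linspace(period_min_h, period_max_h, n_periods)
    omega = 2.0 * np.pi / periods
    pgram = lombscargle(np.asarray(t_hours, dtype=float), yc, omega)
    return float(pgram.sum())


def circadian_movement(t_hours: np.ndarray, lat: np.ndarray, lon: np.ndarray) -> float:
    """log spectral energy of the location series near the 24 h period.

    Lomb–Scargle energy of latitude and longitude in the 23.5–24.5 h band,
    combined as log(E_lat + E_lon + 1e-10); a constant trajectory returns the
    log-epsilon floor.
    """
    e = (_ls_band_energy(t_hours, lat, 23.5, 24.5)
         + _ls_band_energy(t_hours, lon, 23.5, 24.5))
    return float(np.log(e + LOG_EPS))


def routine_index(day_distributions: Sequence[Mapping[int, float]]) -> float:
    """Mean histogram intersection of day-pair cluster-occupancy distributions.

    1.0 = identical routine every day; 0.0 = disjoint places on every pair of
    days; NaN with fewer than two days.
    """
    days = [d for d in day_distributions if d]
    if len(days) < 2:
        return float("nan")
    sims = []
    for i in range(len(days)):
        for j in range(i + 1, len(days)):
            keys = set(days[i]) | set(days[j])
            sims.append(sum(min(days[i].get(k, 0.0), days[j].get(k, 0.0)) for k in keys))
    return float(np.mean(sims))


def _gini(counts: np.ndarray) -> float:
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size <= 1:
        return 0.0
    c = np.sort(c)
    n = c.size
    idx = np.arange(1, n + 1)
    return float((2.0 * (idx * c).sum() - (n + 1) * c.sum()) / (n * c.sum()))


def _occupancy(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(cluster ids, record counts) over non-noise records."""
    nn = labels[labels != NOISE]
    if nn.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    ids, counts = np.unique(nn, return_counts=True)
    return ids, counts.astype(float)


def _location_changes(labels: np.ndarray) -> np.ndarray:
    """Indices (into the non-noise subsequence positions of the original
    array) where consecutive non-noise records change cluster.

    Noise records are transparent: they neither create nor mask a change.
    Returns the original-array index of the record *after* each change.
    """
    pos = np.flatnonzero(labels != NOISE)
    if pos.size < 2:
        return np.empty(0, dtype=int)
    seq = labels[pos]
    chg = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    return pos[chg]


def _dwell_minutes(labels: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Durations (min) of maximal same-cluster runs over non-noise records."""
    pos = np.flatnonzero(labels != NOISE)
    if pos.size == 0:
        return np.empty(0)
    seq = labels[pos]
    breaks = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [seq.size]])
    return (t_s[pos[ends - 1]] - t_s[pos[starts]]) / 60.0


def compute_daily_features(t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                           labels: np.ndarray,
                           home: tuple[float, float] | None,
                           home_id: int | None = None) -> dict[str, float]:
    """The 33-feature daily registry for one local day's records.

    ``t_s`` are local-time epoch seconds, sorted.  A zero-record day should
    not be passed; upstream code emits an all-missing row instead.
    """
    n = t_s.size
    out: dict[str, float] = {k: np.nan for k in DAILY_FEATURES}
    if n == 0:
        return out
    hour = (t_s % 86400.0) / 3600.0
    night = (hour >= 22.0) | (hour < 6.0)
    day_w = (hour >= 6.0) & (hour < 18.0)
    eve = (hour >= 18.0) & (hour < 22.0)

    out["num_records"] = float(n)
    ids, counts = _occupancy(labels)
    out["num_clusters_visited"] = float(ids.size)
    changes = _location_changes(labels)
    out["num_location_changes"] = float(changes.size)
    out["proportion_noise_records"] = float((labels == NOISE).mean())

    if n >= 2:
        disp = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = np.diff(t_s)
        out["total_distance_m"] = float(disp.sum())
        out["max_displacement_m"] = float(disp.max())
        out["displacement_sd_m"] = float(np.std(disp, ddof=1)) if disp.size >= 2 else np.nan
        speed = disp / np.maximum(dt, MIN_SPEED_DT_S)
        out["mean_speed_mps"] = float(speed.mean())
        out["max_speed_mps"] = float(speed.max())
        out["proportion_stationary_records"] = float((speed < STATIONARY_SPEED_MPS).mean())
        out["inter_record_gap_mean_s"] = float(dt.mean())
        out["inter_record_gap_max_s"] = float(dt.max())
    else:
        out["total_distance_m"] = 0.0
        out["max_displacement_m"] = 0.0

    clat, clon = float(lat.mean()), float(lon.mean())
    out["radius_of_gyration_m"] = float(np.sqrt((haversine_m(lat, lon, clat, clon) ** 2).mean()))
    if home is not None:
        dh = haversine_m(lat, lon, home[0], home[1])
        out["max_distance_from_home_m"] = float(dh.max())
        out["mean_distance_from_home_m"] = float(dh.mean())
        out["distance_home_sd_m"] = float(np.std(dh, ddof=1)) if n >= 2 else np.nan

    if counts.size:
        p = counts / counts.sum()
        out["entropy"] = shannon_entropy(p)
        out["normalized_entropy"] = shannon_entropy(p, normalized=True)
        out["proportion_time_top_cluster"] = float(counts.max() / counts.sum())
        if home_id is not None:
            out["proportion_time_home"] = float((labels == home_id).sum() / counts.sum())
    out["location_variance"] = float(np.log(lat.var() + lon.var() + LOG_EPS))
    out["cluster_visit_gini"] = _gini(counts)

    dwell = _dwell_minutes(labels, t_s)
    if dwell.size:
        out["mean_dwell_min"] = float(dwell.mean())
        out["max_dwell_min"] = float(dwell.max())

    out["num_transitions_night"] = float(night[changes].sum()) if changes.size else 0.0
    out["proportion_records_night"] = float(night.mean())
    out["proportion_records_day"] = float(day_w.mean())
    out["proportion_records_evening"] = float(eve.mean())
    if changes.size:
        out["first_movement_hour"] = float(hour[changes[0]])
        out["last_movement_hour"] = float(hour[changes[-1]])
    out["tracked_span_hours"] = float((t_s[-1] - t_s[0]) / 3600.0)
    out["num_unique_clusters_night"] = float(np.unique(labels[night & (labels != NOISE)]).size)
    out["bounding_box_diagonal_m"] = float(
        haversine_m(lat.min(), lon.min(), lat.max(), lon.max()))
    return out


def compute_period_features(t_s: np.ndarray, lat: np.ndarray, lon: np.ndarray,
                            labels: np.ndarray, assignment: ClusterAssignment,
                            home: tuple[float, float] | None,
                            daily_rows: pd.DataFrame,
                            day_index: np.ndarray,
                            record_day_threshold: int = 100) -> dict[str, float]:
    """The 38-feature period registry over the full 14-day window."""
    out: dict[str, float] = {k: np.nan for k in PERIOD_FEATURES}
    n = t_s.size
    if n == 0:
        return out
    hour = (t_s % 86400.0) / 3600.0
    night = (hour >= 22.0) | (hour < 6.0)
    day_w = ~night
    wd = (np.floor_divide(t_s.astype(np.int64), 86400) + 3) % 7  # epoch Thu -> Mon=0
    weekend = wd >= 5

    out["num_significant_locations"] = float(assignment.n_clusters)
    ids, counts = _occupancy(labels)
    if counts.size:
        p = counts / counts.sum()
        out["entropy_14d"] = shannon_entropy(p)
        out["normalized_entropy_14d"] = shannon_entropy(p, normalized=True)
        out["proportion_time_top_cluster_14d"] = float(counts.max() / counts.sum())
    out["location_variance_14d"] = float(np.log(lat.var() + lon.var() + LOG_EPS))
    clat, clon = float(lat.mean()), float(lon.mean())
    out["radius_of_gyration_14d_m"] = float(
        np.sqrt((haversine_m(lat, lon, clat, clon) ** 2).mean()))
    if home is not None:
        dh = haversine_m(lat, lon, home[0], home[1])
        out["max_distance_from_home_14d_m"] = float(dh.max())
        out["mean_distance_from_home_14d_m"] = float(dh.mean())
        out["sd_distance_from_home_14d_m"] = float(np.std(dh, ddof=1)) if n >= 2 else np.nan
        home_id = assignment.home_cluster_id
        nn = labels != NOISE
        if nn.sum():
            out["proportion_time_home_14d"] = float((labels == home_id).sum() / nn.sum())
        nnight = nn & night
        nday = nn & day_w
        if nnight.sum():
            out["proportion_home_night_14d"] = float(
                (labels[nnight] == home_id).mean())
        if nday.sum():
            out["proportion_home_day_14d"] = float((labels[nday] == home_id).mean())
    out["proportion_noise_records_14d"] = float((labels == NOISE).mean())
    out["total_records"] = float(n)

    day_counts = daily_rows["num_records"]
    out["days_tracked"] = float((day_counts > 0).sum())
    out["mean_records_per_day"] = float(day_counts[day_counts > 0].mean()) if (day_counts > 0).any() else np.nan
    out["days_with_gt100_records"] = float((day_counts > record_day_threshold).sum())

    t_h = (t_s - t_s[0]) / 3600.0
    uniq_days = np.unique(np.floor_divide(t_s.astype(np.int64), 86400))
    if uniq_days.size >= 2:
        out["circadian_movement"] = circadian_movement(t_h, lat, lon)
        dists = []
        for d in uniq_days:
            m = np.floor_divide(t_s.astype(np.int64), 86400) == d
            di, dc = _occupancy(labels[m])
            tot = dc.sum()
            dists.append({int(i): c / tot for i, c in zip(di, dc)} if tot else {})
        out["routine_index"] = routine_index(dists)

    dwell = _dwell_minutes(labels, t_s)
    if dwell.size:
        out["mean_dwell_min_14d"] = float(dwell.mean())
        out["max_dwell_min_14d"] = float(dwell.max())
    changes = _location_changes(labels)
    out["num_location_changes_14d"] = float(changes.size)
    if out["days_tracked"] > 0:
        out["location_changes_per_day_14d"] = float(changes.size / out["days_tracked"])

    if n >= 2:
        disp = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = np.diff(t_s)
        same_day = np.floor_divide(t_s.astype(np.int64)[:-1], 86400) == \
            np.floor_divide(t_s.astype(np.int64)[1:], 86400)
        out["total_distance_14d_m"] = float(disp[same_day].sum())
        out["max_displacement_14d_m"] = float(disp[same_day].max()) if same_day.any() else 0.0
        speed = disp[same_day] / np.maximum(dt[same_day], MIN_SPEED_DT_S)
        if speed.size:
            out["mean_speed_14d_mps"] = float(speed.mean())
            out["max_speed_14d_mps"] = float(speed.max())
        both_night = night[:-1] & night[1:] & same_day
        out["distance_night_14d_m"] = float(disp[both_night].sum())
        out["distance_day_14d_m"] = float(disp[day_w[:-1] & day_w[1:] & same_day].sum())

    def _contrast(col: str) -> float:
        wk = daily_rows.loc[~daily_rows["is_weekend"], col].dropna()
        we = daily_rows.loc[daily_rows["is_weekend"], col].dropna()
        if wk.empty or we.empty:
            return np.nan
        return float(wk.mean() - we.mean())

    out["weekday_weekend_diff_distance_m"] = _contrast("total_distance_m")
    out["weekday_weekend_diff_home_time"] = _contrast("proportion_time_home")
    out["weekday_weekend_diff_entropy"] = _contrast("entropy")
    out["weekday_weekend_diff_location_changes"] = _contrast("num_location_changes")
    out["weekday_weekend_diff_records"] = _contrast("num_records")

    out["proportion_records_night_14d"] = float(night.mean())
    out["proportion_records_weekend_14d"] = float(weekend.mean())
    out["bounding_box_diagonal_14d_m"] = float(
        haversine_m(lat.min(), lon.min(), lat.max(), lon.max()))
    out["cluster_visit_gini_14d"] = _gini(counts)
    del day_index
    return out


def aggregate_daily_rows(rows: pd.DataFrame) -> dict[str, float]:
    """mean/min/max/sd over tracked days for each of the 33 daily features.

    Returns 132 values named ``<feature>__<stat>``; the SD is the sample
    (n−1) standard deviation and is missing for a single tracked day.
    """
    out: dict[str, float] = {}
    for f in DAILY_FEATURES:
        v = rows[f].dropna().to_numpy(dtype=float) if f in rows else np.empty(0)
        out[f"{f}__mean"] = float(v.mean()) if v.size else np.nan
        out[f"{f}__min"] = float(v.min()) if v.size else np.nan
        out[f"{f}__max"] = float(v.max()) if v.size else np.nan
        out[f"{f}__sd"] = float(np.std(v, ddof=1)) if v.size >= 2 else np.nan
    return out


def compute_step_features(dates: Sequence, steps: Sequence[float]) -> dict[str, float]:
    """Six summaries of daily step counts over the window.

    mean, min, max, sample SD, sum, and mean(Mon–Fri) − mean(Sat–Sun); the
    weekday–weekend difference is missing if either side has no days.
    """
    s = np.asarray(steps, dtype=float)
    out = {k: np.nan for k in STEP_FEATURES}
    if s.size == 0:
        return out
    out["steps__mean"] = float(s.mean())
    out["steps__min"] = float(s.min())
    out["steps__max"] = float(s.max())
    out["steps__sd"] = float(np.std(s, ddof=1)) if s.size >= 2 else np.nan
    out["steps__sum"] = float(s.sum())
    wd = pd.to_datetime(pd.Series(list(dates))).dt.dayofweek.to_numpy()
    wk, we = s[wd < 5], s[wd >= 5]
    if wk.size and we.size:
        out["steps__weekday_weekend_diff"] = float(wk.mean() - we.mean())
    return out


def gps_feature_columns() -> list[str]:
    """Stable order of the 170 GPS feature columns."""
    cols = list(PERIOD_FEATURES)
    for f in DAILY_FEATURES:
        cols.extend(f"{f}__{s}" for s in DAILY_STATS)
    return cols


def assemble_features(daily_aggregates: Mapping[str, float],
                      period: Mapping[str, float],
                      steps: Mapping[str, float],
                      demographics: Mapping[str, float]) -> dict[str, float]:
    """Concatenate the blocks into one row with a validated, stable order."""
    if len(period) != 38:
        raise ValueError(f"period block must have 38 features, got {len(period)}")
    if len(daily_aggregates) != 132:
        raise ValueError(
            f"daily aggregate block must have 132 features, got {len(daily_aggregates)}")
    if len(steps) != 6:
        raise ValueError(f"step block must have 6 features, got {len(steps)}")
    row: dict[str, float] = {}
    for c in PERIOD_FEATURES:
        row[c] = float(period[c])
    for f in DAILY_FEATURES:
        for s in DAILY_STATS:
            row[f"{f}__{s}"] = float(daily_aggregates[f"{f}__{s}"])
    for c in STEP_FEATURES:
        row[c] = float(steps[c])
    for c, v in demographics.items():
        row[c] = float(v)
    return row


def encode_demographics(demographics: pd.DataFrame,
                        levels: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """One-hot encode the categorical demographic attributes.

    ``levels`` fixes the category sets (and hence the column schema); when
    omitted, the sorted observed levels per attribute are used.
    """
    demo = demographics.set_index("participant_id") if "participant_id" in demographics \
        else demographics
    blocks = []
    for attr in sorted(demo.columns):
        lv = list(levels[attr]) if levels and attr in levels else sorted(demo[attr].dropna().unique())
        cat = pd.Categorical(demo[attr], categories=lv)
        oh = pd.get_dummies(cat, prefix=f"demo_{attr}", dtype=float)
        oh.index = demo.index
        blocks.append(oh)
    return pd.concat(blocks, axis=1)


def extract_participant_features(t_local_s: np.ndarray, lat: np.ndarray,
                                 lon: np.ndarray,
                                 params: ClusterParams = ClusterParams()
                                 ) -> tuple[dict[str, float], ClusterAssignment]:
    """Full GPS feature block (170 values) for one participant's window."""
    order = np.argsort(t_local_s, kind="stable")
    t_local_s = np.asarray(t_local_s, dtype=float)[order]
    lat = np.asarray(lat, dtype=float)[order]
    lon = np.asarray(lon, dtype=float)[order]

    assignment = cluster_locations(lat, lon, params)
    hour = (t_local_s % 86400.0) / 3600.0
    home_id = detect_home(assignment, hour)
    assignment.home_cluster_id = home_id
    home = assignment.centroids.get(home_id) if home_id is not None else None

    day_idx = np.floor_divide(t_local_s.astype(np.int64), 86400)
    rows = []
    if t_local_s.size:
        for d in np.unique(day_idx):
            m = day_idx == d
            r = compute_daily_features(t_local_s[m], lat[m], lon[m],
                                       assignment.labels[m], home, home_id)
            r["day_index"] = int(d)
            r["is_weekend"] = bool((d + 3) % 7 >= 5)
            rows.append(r)
    daily_rows = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=list(DAILY_FEATURES) + ["day_index", "is_weekend", "num_records"])
    period = compute_period_features(t_local_s, lat, lon, assignment.labels,
                                     assignment, home, daily_rows, day_idx)
    daily_agg = aggregate_daily_rows(daily_rows)
    gps_row: dict[str, float] = {}
    for c in PERIOD_FEATURES:
        gps_row[c] = period[c]
    for f in DAILY_FEATURES:
        for s in DAILY_STATS:
            gps_row[f"{f}__{s}"] = daily_agg[f"{f}__{s}"]
    return gps_row, assignment


def extract_features(gps: pd.DataFrame, steps: pd.DataFrame,
                     demographics: pd.DataFrame,
                     params: ClusterParams = ClusterParams(),
                     tz_offset_hours: float = 0.0,
                     demographic_levels: Mapping[str, Sequence[str]] | None = None
                     ) -> pd.DataFrame:
    """Per-participant feature matrix: 170 GPS + 6 step + demographic one-hots.

    ``gps`` columns: participant_id, timestamp (UTC datetime64), lat, lon.
    ``steps`` columns: participant_id, date, steps.  Participants present in
    demographics but with no GPS/steps get all-missing sensing blocks.
    """
    demo_oh = encode_demographics(demographics, demographic_levels)
    pids = list(demo_oh.index)

    gps = gps.sort_values(["participant_id", "timestamp"], kind="stable")
    t_utc = gps["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    t_loc = t_utc + tz_offset_hours * 3600.0
    lat_all = gps["lat"].to_numpy(dtype=float)
    lon_all = gps["lon"].to_numpy(dtype=float)
    gidx = gps.groupby("participant_id", sort=False).indices

    sidx = steps.groupby("participant_id", sort=False).indices if len(steps) else {}

    rows = {}
    nan_gps = {c: np.nan for c in gps_feature_columns()}
    for pid in pids:
        if pid in gidx:
            ii = gidx[pid]
            gps_row, _ = extract_participant_features(t_loc[ii], lat_all[ii],
                                                      lon_all[ii], params)
        else:
            gps_row = dict(nan_gps)
        if pid in sidx:
            sub = steps.iloc[sidx[pid]]
            step_row = compute_step_features(sub["date"], sub["steps"])
        else:
            step_row = {k: np.nan for k in STEP_FEATURES}
        rows[pid] = {**gps_row, **step_row}
    feat = pd.DataFrame.from_dict(rows, orient="index")
    feat = feat.reindex(columns=gps_feature_columns() + list(STEP_FEATURES))
    out = feat.join(demo_oh.loc[pids])
    out.index.name = "participant_id"
    return out


def feature_registry() -> dict[str, str]:
    """Human-readable definition of every feature column."""
    reg: dict[str, str] = {}
    daily_desc = {
        "num_records": "number of GPS records on the day",
        "num_clusters_visited": "distinct significant locations visited",
        "num_location_changes": "cluster changes between consecutive non-noise records",
        "proportion_noise_records": "fraction of records labeled DBSCAN noise",
        "total_distance_m": "summed consecutive-record haversine distance (m)",
        "max_displacement_m": "largest single inter-record displacement (m)",
        "radius_of_gyration_m": "RMS distance of records from the day centroid (m)",
        "max_distance_from_home_m": "max distance from home centroid (m)",
        "mean_distance_from_home_m": "mean distance from home centroid (m)",
        "entropy": "Shannon entropy (nats) of cluster occupancy",
        "normalized_entropy": "entropy / ln(clusters visited)",
        "location_variance": "log(var(lat)+var(lon)+1e-10), degrees^2",
        "proportion_time_home": "record share in home cluster (non-noise denominator)",
        "proportion_time_top_cluster": "record share of the most-visited cluster",
        "mean_dwell_min": "mean duration of same-cluster record runs (min)",
        "max_dwell_min": "max duration of same-cluster record runs (min)",
        "num_transitions_night": "location changes in the 22:00-06:00 window",
        "proportion_records_night": "record share 22:00-06:00",
        "proportion_records_day": "record share 06:00-18:00",
        "proportion_records_evening": "record share 18:00-22:00",
        "first_movement_hour": "local hour of first location change",
        "last_movement_hour": "local hour of last location change",
        "tracked_span_hours": "hours between first and last record",
        "mean_speed_mps": "mean consecutive-record speed (m/s, dt floor 1 s)",
        "max_speed_mps": "max consecutive-record speed (m/s)",
        "proportion_stationary_records": f"record-pair share with speed < {STATIONARY_SPEED_MPS} m/s",
        "num_unique_clusters_night": "distinct clusters among night records",
        "distance_home_sd_m": "sample SD of distance from home (m)",
        "displacement_sd_m": "sample SD of inter-record displacement (m)",
        "inter_record_gap_mean_s": "mean inter-record time gap (s)",
        "inter_record_gap_max_s": "max inter-record time gap (s)",
        "bounding_box_diagonal_m": "haversine diagonal of the lat/lon bounding box (m)",
        "cluster_visit_gini": "Gini coefficient of per-cluster record counts",
    }
    for f, d in daily_desc.items():
        for s in DAILY_STATS:
            reg[f"{f}__{s}"] = f"{s} over tracked days of: {d}"
    for c in PERIOD_FEATURES:
        reg[c] = f"14-day window feature: {c.replace('_', ' ')}"
    for c in STEP_FEATURES:
        reg[c] = f"daily step count summary: {c.split('__')[1]}"
    return reg


def write_feature_registry(path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_registry(), fh, indent=1)
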