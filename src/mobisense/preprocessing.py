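"""Raw-table parsing, 14-day windowing, day segmentation and cohort filters.

Participant-level inclusion mirrors the study design this pipeline targets:
a participant is kept when their home region passes a pluggable predicate,
they contribute at least 1000 GPS records ("less than 1000" removed — the
boundary participant with exactly 1000 is kept), and their survey data
yields a scoreable depression assessment.  Removal reasons are mutually
exclusive and applied in the fixed order region -> GPS count -> survey, so
the per-reason counts are reproducible.

Day boundaries are local midnight using the cohort timezone offset; the
14-day window is anchored at the local midnight of each participant's first
record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400.0

REASON_REGION = "region"
REASON_LOW_GPS = "low_gps"
REASON_NO_SURVEY = "no_survey"


@dataclass
class FilterReport:
    """Auditable account of participant-level filtering."""

    n_input: int = 0
    n_removed_region: int = 0
    n_removed_low_gps: int = 0
    n_removed_no_survey: int = 0
    n_retained: int = 0
    removal_reasons: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        total = (self.n_retained + self.n_removed_region
                 + self.n_removed_low_gps + self.n_removed_no_survey)
        if total != self.n_input:
            raise ValueError("filter report counts do not partition the input")

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump({
                "n_input": self.n_input,
                "n_removed_region": self.n_removed_region,
                "n_removed_low_gps": self.n_removed_low_gps,
                "n_removed_no_survey": self.n_removed_no_survey,
                "n_retained": self.n_retained,
                "removal_reasons": self.removal_reasons,
            }, fh, indent=1)


def parse_gps_table(source, tz_offset_hours: float = 0.0) -> pd.DataFrame:
    """Read and validate a delimited GPS table.

    ``source`` is a path/buffer (CSV with header participant_id, timestamp,
    lat, lon[, accuracy_m]) or an already-loaded DataFrame.  Rows are
    validated (WGS84 ranges, finite timestamps), sorted by (participant,
    timestamp), and exact duplicate (participant, timestamp, lat, lon) rows
    are dropped.  Adds ``t_local_s`` (local epoch seconds) and
    ``local_day`` columns.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    required = {"participant_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GPS table missing columns: {sorted(missing)}")
    if len(df) == 0:
        df["t_local_s"] = pd.Series(dtype=float)
        df["local_day"] = pd.Series(dtype=np.int64)
        return df
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                        format="ISO8601").dt.tz_localize(None)
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"malformed timestamp at line {line}")
    df["timestamp"] = ts
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    invalid = (lat.isna() | lon.isna() | (lat < -90) | (lat > 90)
               | (lon < -180) | (lon > 180))
    if invalid.any():
        line = int(np.flatnonzero(invalid.to_numpy())[0]) + 2
        raise ValueError(f"latitude/longitude out of range at line {line}")
    df["lat"], df["lon"] = lat, lon
    n0 = len(df)
    df = df.drop_duplicates(subset=["participant_id", "timestamp", "lat", "lon"])
    df.attrs["n_duplicates_dropped"] = n0 - len(df)
    df = df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)
    t_utc = df["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64) / 1e9
    df["t_local_s"] = t_utc + tz_offset_hours * 3600.0
    df["local_day"] = np.floor_divide(df["t_local_s"].to_numpy().astype(np.int64),
                                      int(SECONDS_PER_DAY))
    return df


def restrict_window(gps: pd.DataFrame, n_days: int = 14) -> pd.DataFrame:
    """Keep each participant's records within [first local midnight, +n_days).

    The window anchor is the local midnight of the participant's first
    record, so a participant starting mid-afternoon still spans at most
    ``n_days`` local calendar days.
    """
    if len(gps) == 0:
        return gps
    first_day = gps.groupby("participant_id")["local_day"].transform("min")
    keep = gps["local_day"] < first_day + n_days
    return gps.loc[keep].reset_index(drop=True)


def segment_days(gps: pd.DataFrame) -> dict:
    """Map local calendar day -> records, for a single participant's window."""
    if len(gps) == 0:
        return {}
    return {int(d): g for d, g in gps.groupby("local_day", sort=True)}


def days_with_min_records(gps: pd.DataFrame, threshold: int = 100) -> int:
    """Number of local days with strictly more than ``threshold`` records."""
    if len(gps) == 0:
        return 0
    counts = gps.groupby("local_day").size()
    return int((counts > threshold).sum())


def _home_proxy(gps: pd.DataFrame) -> tuple[float, float]:
    """Median coordinates, preferring night (22:00-06:00) records."""
    hour = (gps["t_local_s"].to_numpy() % SECONDS_PER_DAY) / 3600.0
    night = (hour >= 22.0) | (hour < 6.0)
    sub = gps.loc[night] if night.any() else gps
    return float(sub["lat"].median()), float(sub["lon"].median())


def apply_cohort_filters(gps: pd.DataFrame, labels: pd.DataFrame,
                         min_gps_records: int = 1000,
                         region_predicate: Callable[[float, float], bool] | None = None,
                         require_scoreable_label: bool = True,
                         all_participants: list[str] | None = None
                         ) -> tuple[list[str], FilterReport]:
    """Apply the participant inclusion rules; return (retained ids, report).

    Rules, in order: home centroid passes ``region_predicate``; at least
    ``min_gps_records`` GPS records (strictly fewer removed); a scoreable
    depression assessment in ``labels`` (frame from
    :func:`mobisense.ema_scoring.score_participants`).
    """
    counts = gps.groupby("participant_id").size() if len(gps) else pd.Series(dtype=int)
    scoreable = set()
    if len(labels):
        scoreable = set(labels.loc[labels["scoreable"], "participant_id"].astype(str))
    pids = all_participants
    if pids is None:
        pids = sorted(set(counts.index.astype(str))
                      | set(labels["participant_id"].astype(str)) if len(labels)
                      else set(counts.index.astype(str)))
    report = FilterReport(n_input=len(pids))
    gidx = gps.groupby("participant_id").indices if len(gps) else {}
    retained = []
    for pid in pids:
        if region_predicate is not None:
            sub = gps.iloc[gidx[pid]] if pid in gidx else gps.iloc[:0]
            if len(sub) == 0 or not region_predicate(*_home_proxy(sub)):
                report.n_removed_region += 1
                report.removal_reasons[pid] = REASON_REGION
                continue
        if int(counts.get(pid, 0)) < min_gps_records:
            report.n_removed_low_gps += 1
            report.removal_reasons[pid] = REASON_LOW_GPS
            continue
        if require_scoreable_label and pid not in scoreable:
            report.n_removed_no_survey += 1
            report.removal_reasons[pid] = REASON_NO_SURVEY
            continue
        retained.append(pid)
    report.n_retained = len(retained)
    report.validate()
    return retained, report


def bounding_box_predicate(lat_min: float, lat_max: float,
                           lon_min: float, lon_max: float
                           ) -> Callable[[float, float], bool]:
    """Region predicate factory: home centroid inside a lat/lon box."""
    def pred(lat: float, lon: float) -> bool:
        return lat_min <= lat <= lat_max and lon_min <= lon <= lon_max
    return pred


def parse_steps_table(source) -> pd.DataFrame:
    """Read and validate the daily step-count table."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"participant_id", "date", "steps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"steps table missing columns: {sorted(missing)}")
    if len(df):
        steps = pd.to_numeric(df["steps"], errors="coerce")
        if steps.isna().any() or (steps < 0).any():
            raise ValueError("steps must be non-negative numbers")
        df["steps"] = steps.astype(int)
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def parse_ema_table(source) -> pd.DataFrame:
    """Read the survey-response table (one row per item administration)."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"participant_id", "item_id", "endorsed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ema table missing columns: {sorted(missing)}")
    if len(df):
        if df["endorsed"].dtype != bool:
            df["endorsed"] = df["endorsed"].astype(str).str.lower().isin(
                ("true", "1", "yes"))
        if "symptom_key" not in df.columns:
            from mobisense.synthetic_data import SYMPTOM_ITEMS
            key = {i: s for i, s, _, _ in SYMPTOM_ITEMS}
            df["symptom_key"] = df["item_id"].map(key)
    return df
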