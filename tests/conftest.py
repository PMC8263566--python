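"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mobisense.feature_extraction import haversine_m
from mobisense.synthetic_data import CohortConfig, simulate_cohort


def dbscan_oracle(lat: np.ndarray, lon: np.ndarray, eps_m: float,
                  min_pts: int) -> np.ndarray:
    """Brute-force neighborhood-expansion DBSCAN (the independent oracle).

    Pairwise haversine distances, core points with >= min_pts neighbors
    (self included) inside eps, BFS cluster growth in index order.
    """
    n = len(lat)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    D = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    nbr = [np.flatnonzero(D[i] <= eps_m) for i in range(n)]
    core = np.array([len(nbr[i]) >= min_pts for i in range(n)])
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            q = queue.pop(0)
            if not core[q]:
                continue
            for j in nbr[q]:
                if labels[j] == -1:
                    labels[j] = cid
                    queue.append(j)
        cid += 1
    return labels


def canonical_renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by first occurrence so labelings are comparable."""
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, l in enumerate(labels):
        if l == -1:
            continue
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out


def random_blob_trajectory(rng: np.random.Generator, max_points: int = 200
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Random well-separated location blobs plus scattered noise points."""
    n_blobs = int(rng.integers(1, 6))
    lat0, lon0 = 40.0, -100.0
    pts = []
    for b in range(n_blobs):
        # blob centers >= 500 m apart on a coarse grid; spread ~10 m
        cy = lat0 + (b // 3) * 0.01
        cx = lon0 + (b % 3) * 0.01
        m = int(rng.integers(1, max(2, max_points // n_blobs)))
        pts.append(np.column_stack([
            cy + rng.normal(0, 10 / 111_320.0, m),
            cx + rng.normal(0, 10 / 111_320.0, m)]))
    n_noise = int(rng.integers(0, 10))
    if n_noise:
        pts.append(np.column_stack([
            lat0 + rng.uniform(0.1, 0.5, n_noise),
            lon0 + rng.uniform(0.1, 0.5, n_noise)]))
    xy = np.vstack(pts)[:max_points]
    perm = rng.permutation(len(xy))
    return xy[perm, 0], xy[perm, 1]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant cohort at a reduced sensing rate."""
    cfg = CohortConfig(n_participants=40, prevalence=0.4, seed=11,
                       heterogeneity_sd=0.4, geo_spread_km=20.0,
                       records_per_day_mean=60.0, records_per_day_sd=20.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    from mobisense.pipeline_cli import build_dataset
    return build_dataset(small_cohort, min_gps_records=150)
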