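"""Shared fixtures: small grids, scenarios and independently written oracles."""

import math

import numpy as np
import pytest

from ecoclim.io import GridGeometry
from ecoclim.synthetic import SyntheticScenario


@pytest.fixture
def small_geom():
    """10x10 grid of ~1 km cells near 45 N."""
    return GridGeometry(n_rows=10, n_cols=10, origin_lon=6.0, origin_lat=45.0,
                        dlon=0.0127, dlat=0.009)


@pytest.fixture
def small_scenario():
    """A fast scenario for unit tests (not the default study conditions)."""
    return SyntheticScenario(n_rows=60, n_cols=60, conifer_patch_count=6,
                             conifer_patch_radius_km=5.0, n_presence=400,
                             rng_seed=7)


def slow_haversine(lon1, lat1, lon2, lat2, radius=6371.0088):
    """Independent great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, c)))


def brute_force_thin(lons, lats, radius_km):
    """Reference greedy thinning: quadratic scan, scalar distances."""
    kept = []
    for i in range(len(lons)):
        if all(slow_haversine(lons[i], lats[i], lons[j], lats[j]) > radius_km
               for j in kept):
            kept.append(i)
    return kept


def brute_force_auc(labels, scores):
    """Pairwise-comparison probability, ties counting one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_monthly_climate(rng, n=1):
    """Randomised but physically ordered monthly climate for n cells."""
    tavg = rng.uniform(-15, 35, size=(n, 12))
    spread_lo = rng.uniform(0.5, 8, size=(n, 12))
    spread_hi = rng.uniform(0.5, 8, size=(n, 12))
    return {
        "tavg": tavg,
        "tmin": tavg - spread_lo,
        "tmax": tavg + spread_hi,
        "precip": rng.uniform(0, 300, size=(n, 12)),
        "rh": rng.uniform(0, 100, size=(n, 12)),
    }
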