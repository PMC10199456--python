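"""Seeded synthetic study systems: climate grids, land cover, DEM, occurrences.

The generator emulates the structure of a temperate-European study region
on a regular lon/lat grid: mean temperature falls with latitude and with
elevation (a fixed lapse rate), the seasonal cycle peaks in July,
precipitation / humidity / radiation follow stated monthly profiles plus
cell-level noise, coniferous/mixed forest occurs in random circular
patches, the DEM is a smooth random field, and presence records are drawn
from a logistic occurrence model on standardised predictor layers (by
default: close to conifer cells, warm springs, low elevation) with
within-cell jitter.  Every generator is a pure function of
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigError, DataError
from .features import PredictorStack, distance_to_conifer
from .io import GridGeometry
from .occurrence import make_occurrence_set

KM_PER_DEG_LAT = 111.195  # R * pi / 180 at R = 6371.0088 km

__all__ = ["SyntheticScenario", "coarse_scenario", "strong_recovery_scenario",
           "null_scenario", "scenario_geometry", "generate_climate",
           "generate_landcover_dem", "generate_stack", "generate_occurrences"]

MONTH_AXIS = np.arange(1, 13)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the synthetic study region.

    Climate: ``base_tavg`` is the annual-mean temperature at the southern
    edge at sea level (degC); ``lat_gradient`` its decline per degree of
    latitude northwards (degC/deg); ``lapse_rate`` the decline per km of
    elevation (degC/km); ``seasonal_amplitude`` the half-range of the
    annual cycle, which peaks in July; ``noise_sd`` the sd of independent
    cell-and-month noise.  ``tmin_offset``/``tmax_offset`` set the daily
    spread of the monthly min/max around the mean.

    Occurrence model: per-cell presence intensity is
    ``logistic(occ_intercept + sum_j occ_slopes[j] * x_j)`` where ``x_j``
    are predictor layers in their natural units, so slopes read as logits
    per km of conifer distance, per degC, per m of elevation;
    ``n_presence`` points are drawn proportionally and jittered within
    their cell.  ``urban_bias_weight`` > 0 multiplies the
    intensity near randomly placed "urban" disks, emulating
    human-observation bias (off by default).
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_km: float = 1.0
    origin_lon: float = 6.0
    origin_lat: float = 44.0

    base_tavg: float = 16.0
    lat_gradient: float = 0.8
    lapse_rate: float = 6.5
    seasonal_amplitude: float = 9.0
    noise_sd: float = 0.5
    tmin_offset: float = 4.0
    tmax_offset: float = 5.0

    precip_profile: tuple = (60, 50, 55, 60, 70, 65, 60, 70, 75, 80, 75, 70)
    precip_noise_sd: float = 6.0
    rh_profile: tuple = (86, 82, 78, 74, 72, 70, 68, 70, 75, 80, 84, 86)
    rh_noise_sd: float = 2.0
    radiation_profile: tuple = (40, 65, 100, 140, 180, 200, 195, 165, 120, 75, 45, 35)
    radiation_noise_sd: float = 8.0

    conifer_patch_count: int = 25
    conifer_patch_radius_km: float = 6.0
    dem_min: float = 0.0
    dem_max: float = 1200.0
    dem_smooth_cells: float = 10.0

    occ_intercept: float = -6.0
    occ_slopes: dict = field(default_factory=lambda: {"Di": -0.6, "tx3": 0.9, "DEM": -0.006})
    n_presence: int = 5000
    urban_bias_weight: float = 0.0
    urban_patch_count: int = 8
    urban_patch_radius_km: float = 4.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.cell_km <= 0:
            raise ConfigError("grid shape and cell size must be positive")
        if self.noise_sd < 0 or self.precip_noise_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        if self.n_presence < 1:
            raise ConfigError("n_presence must be >= 1")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def strong_recovery_scenario(**overrides) -> SyntheticScenario:
    """A scenario whose occurrences are generated from distance-to-conifer
    and one spring-temperature layer only, with slopes steep enough that a
    correctly built classifier should recover both drivers and discriminate
    presences from background almost perfectly.  Raw presences are dense
    enough that most suitable cells hold a record, so pseudo-absences
    rarely fall on suitable habitat."""
    base = SyntheticScenario(
        n_rows=300, n_cols=300,
        conifer_patch_count=40, conifer_patch_radius_km=10.0,
        occ_slopes={"Di": -2.0, "tx3": 2.0}, occ_intercept=-25.3,
        n_presence=30000)
    return base.with_(**overrides) if overrides else base


def null_scenario(**overrides) -> SyntheticScenario:
    """Occurrences independent of every predictor (all slopes zero):
    presences fall uniformly, so any fitted classifier should sit at
    chance level."""
    base = SyntheticScenario(occ_slopes={}, occ_intercept=0.0)
    return base.with_(**overrides) if overrides else base


def coarse_scenario(**overrides) -> SyntheticScenario:
    """An 18 km-cell scenario spanning a wide latitude band, sized for the
    ecoclimatic-index grid rather than the 1 km predictor grid."""
    base = SyntheticScenario(
        n_rows=40, n_cols=40, cell_km=18.0, origin_lat=42.0,
        base_tavg=15.0, conifer_patch_count=12, conifer_patch_radius_km=40.0,
        n_presence=400)
    return base.with_(**overrides) if overrides else base


def scenario_geometry(s: SyntheticScenario) -> GridGeometry:
    dlat = s.cell_km / KM_PER_DEG_LAT
    mid_lat = s.origin_lat + 0.5 * s.n_rows * dlat
    dlon = s.cell_km / (KM_PER_DEG_LAT * np.cos(np.radians(mid_lat)))
    return GridGeometry(n_rows=s.n_rows, n_cols=s.n_cols,
                        origin_lon=s.origin_lon, origin_lat=s.origin_lat,
                        dlon=dlon, dlat=dlat)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def generate_landcover_dem(s: SyntheticScenario, seed: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray, GridGeometry]:
    """Conifer mask (bool) and DEM (m a.s.l.) rasters.

    Conifer cover is the union of ``conifer_patch_count`` random disks; the
    DEM is Gaussian-smoothed white noise rescaled to [dem_min, dem_max] and
    clipped to the plausible terrestrial range [-226, 5111] m.
    """
    seed = s.rng_seed if seed is None else seed
    geom = scenario_geometry(s)
    rng = _rng(seed, 1)
    mask = np.zeros(geom.shape, dtype=bool)
    rows = np.arange(s.n_rows)[:, None]
    cols = np.arange(s.n_cols)[None, :]
    for _ in range(s.conifer_patch_count):
        r0 = rng.uniform(0, s.n_rows)
        c0 = rng.uniform(0, s.n_cols)
        d_km = np.hypot((rows + 0.5 - r0), (cols + 0.5 - c0)) * s.cell_km
        mask |= d_km <= s.conifer_patch_radius_km

    noise = rng.standard_normal(geom.shape)
    smooth = gaussian_filter(noise, sigma=s.dem_smooth_cells, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi > lo:
        dem = s.dem_min + (smooth - lo) / (hi - lo) * (s.dem_max - s.dem_min)
    else:
        dem = np.full(geom.shape, s.dem_min)
    dem = np.clip(dem, -226.0, 5111.0)
    return mask, dem, geom


def generate_climate(s: SyntheticScenario, seed: int | None = None,
                     dem: np.ndarray | None = None
                     ) -> tuple[dict[str, np.ndarray], GridGeometry]:
    """Monthly climate rasters, shape (12, n_rows, n_cols) per variable.

    Variables: ``tavg``, ``tmin``, ``tmax`` (degC), ``precip`` (mm/month),
    ``rh`` (%), ``radiation`` (W m-2).  The mean temperature field is
    ``base_tavg - lat_gradient*(lat - southern edge) - lapse_rate*dem_km``
    plus a July-peaking cosine annual cycle and white noise.
    """
    seed = s.rng_seed if seed is None else seed
    geom = scenario_geometry(s)
    if dem is None:
        _, dem, _ = generate_landcover_dem(s, seed)
    rng = _rng(seed, 2)
    _, lat = geom.cell_centers()
    annual_mean = (s.base_tavg
                   - s.lat_gradient * (lat - s.origin_lat)
                   - s.lapse_rate * np.asarray(dem) / 1000.0)
    season = s.seasonal_amplitude * np.cos(2.0 * np.pi * (MONTH_AXIS - 7) / 12.0)
    tavg = (annual_mean[None, :, :] + season[:, None, None]
            + rng.normal(0.0, s.noise_sd, size=(12, *geom.shape)))
    tmin = tavg - s.tmin_offset
    tmax = tavg + s.tmax_offset

    def profile_field(profile, sd, stream, lo=None, hi=None):
        r = _rng(seed, stream)
        arr = (np.asarray(profile, dtype=float)[:, None, None]
               + r.normal(0.0, sd, size=(12, *geom.shape)))
        return np.clip(arr, lo, hi)

    precip = profile_field(s.precip_profile, s.precip_noise_sd, 3, lo=0.0)
    rh = profile_field(s.rh_profile, s.rh_noise_sd, 4, lo=0.0, hi=100.0)
    radiation = profile_field(s.radiation_profile, s.radiation_noise_sd, 5, lo=0.0)
    climate = {"tavg": tavg, "tmin": tmin, "tmax": tmax,
               "precip": precip, "rh": rh, "radiation": radiation}
    return climate, geom


def generate_stack(s: SyntheticScenario, seed: int | None = None
                   ) -> tuple[PredictorStack, dict[str, np.ndarray], np.ndarray]:
    """Predictor stack with the standard layer names.

    Monthly slices follow the tx/tn/rr/qq/hu naming (variable code + month
    number); DEM and distance-to-conifer (Di, km) complete the stack.
    Returns (stack, monthly climate dict, conifer mask).
    """
    seed = s.rng_seed if seed is None else seed
    conifer, dem, geom = generate_landcover_dem(s, seed)
    climate, _ = generate_climate(s, seed, dem=dem)
    if not conifer.any():
        raise DataError("scenario produced no conifer cells; distance layer undefined")
    stack = PredictorStack(geom)
    slices = {
        "tx3": ("tmax", 3), "tx5": ("tmax", 5),
        "tn8": ("tmin", 8), "tn12": ("tmin", 12),
        "rr4": ("precip", 4), "rr5": ("precip", 5), "rr8": ("precip", 8),
        "rr9": ("precip", 9), "rr10": ("precip", 10),
        "qq5": ("radiation", 5), "qq12": ("radiation", 12),
        "hu4": ("rh", 4), "hu12": ("rh", 12),
    }
    for name, (var, month) in slices.items():
        stack.add(name, climate[var][month - 1])
    stack.add("DEM", dem)
    stack.add("Di", distance_to_conifer(conifer, geom))
    return stack, climate, conifer


def generate_occurrences(s: SyntheticScenario, stack: PredictorStack,
                         seed: int | None = None) -> pd.DataFrame:
    """Presence records from the logistic occurrence model.

    Cell intensity = logistic(intercept + sum slope_j * x_j) over the
    layers named in ``occ_slopes``, in their natural units; ``n_presence``
    cells are sampled with probability proportional to intensity and each
    record is jittered uniformly within its cell.
    """
    seed = s.rng_seed if seed is None else seed
    geom = stack.geom
    logit = np.full(geom.shape, float(s.occ_intercept))
    for name, slope in s.occ_slopes.items():
        if name not in stack.layers:
            raise DataError(f"occurrence model references missing layer {name!r}")
        logit = logit + slope * np.asarray(stack.layers[name], dtype=float)
    intensity = expit(logit)
    intensity = np.where(np.isnan(intensity), 0.0, intensity)
    total = intensity.sum()
    if total <= 0:
        raise DataError("occurrence intensity is zero everywhere")

    if s.urban_bias_weight > 0:
        rng_u = _rng(seed, 6)
        rows = np.arange(s.n_rows)[:, None]
        cols = np.arange(s.n_cols)[None, :]
        urban = np.zeros(geom.shape, dtype=bool)
        for _ in range(s.urban_patch_count):
            r0 = rng_u.uniform(0, s.n_rows)
            c0 = rng_u.uniform(0, s.n_cols)
            d_km = np.hypot(rows + 0.5 - r0, cols + 0.5 - c0) * s.cell_km
            urban |= d_km <= s.urban_patch_radius_km
        intensity = intensity * np.where(urban, 1.0 + s.urban_bias_weight, 1.0)
        total = intensity.sum()

    rng = _rng(seed, 7)
    p = (intensity / total).ravel()
    cells = rng.choice(len(p), size=s.n_presence, replace=True, p=p)
    r, c = np.unravel_index(cells, geom.shape)
    jitter_lon = rng.uniform(-0.5, 0.5, size=s.n_presence) * geom.dlon
    jitter_lat = rng.uniform(-0.5, 0.5, size=s.n_presence) * geom.dlat
    lon = geom.lon_center(c) + jitter_lon
    lat = geom.lat_center(r) + jitter_lat
    return make_occurrence_set(lon, lat, label=1)
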