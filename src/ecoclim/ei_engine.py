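"""Ecoclimatic Index (EI) engine.

Implements an open, fully documented variant of the CLIMEX-style annual
suitability calculation for a poikilotherm pest.  Weekly climate is derived
from monthly inputs by piecewise-linear interpolation; a weekly Growth Index
GI_w = TI_w x MI_w combines a temperature trapezoid (DV0..DV3) with a soil
moisture trapezoid (SM0..SM3) driven by a single-bucket hydrology; four
stresses (cold, heat, dry, wet) accumulate linearly above/below their
thresholds and discount survival multiplicatively; and

    EI = GI_A x SI,   GI_A = 100 x mean_w(GI_w),   SI = prod(1 - S/100)

optionally gated to zero when the annual degree-day total above DV0 falls
short of PDD, the heat sum needed to complete one generation.

All functions are vectorised: a scalar cell and an (n,)-vector of cells go
through the same code path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .io import GridGeometry

__all__ = [
    "SpeciesParams",
    "SoilMoistureConfig",
    "WCSB_PARAMS",
    "EIResult",
    "interpolate_monthly_to_weekly",
    "temperature_index",
    "moisture_index",
    "update_soil_moisture",
    "run_soil_moisture",
    "weekly_growth_index",
    "annual_degree_days",
    "accumulate_stress",
    "stress_index",
    "ecoclimatic_index",
    "categorize_ei",
    "compute_ei",
    "ei_map",
    "CATEGORIES",
]

CATEGORIES = ("unsuitable", "marginal", "suitable", "optimal")

DAYS_PER_YEAR = 365.0
WEEKS = 52
MONTHS = 12


@dataclass(frozen=True)
class SpeciesParams:
    """Species response parameters.

    Temperature trapezoid DV0 < DV1 <= DV2 < DV3 (deg C); PDD is the annual
    degree-day sum above DV0 required to complete one generation.  Soil
    moisture trapezoid SM0 < SM1 <= SM2 < SM3 (fraction of bucket capacity).
    Each stress has a threshold and a weekly accumulation rate; cold/dry
    rates are non-positive, heat/wet rates non-negative (sign encodes the
    direction of the exceedance, magnitude the accumulation speed).
    """

    dv0: float
    dv1: float
    dv2: float
    dv3: float
    pdd: float
    sm0: float
    sm1: float
    sm2: float
    sm3: float
    ttcs: float
    thcs: float
    tths: float
    thhs: float
    smds: float
    hds: float
    smws: float
    hws: float

    def __post_init__(self) -> None:
        if not (self.dv0 < self.dv1 <= self.dv2 < self.dv3):
            raise ConfigError(f"temperature thresholds must satisfy dv0 < dv1 <= dv2 < dv3, got "
                              f"{self.dv0}, {self.dv1}, {self.dv2}, {self.dv3}")
        if not (self.sm0 < self.sm1 <= self.sm2 < self.sm3):
            raise ConfigError(f"moisture thresholds must satisfy sm0 < sm1 <= sm2 < sm3, got "
                              f"{self.sm0}, {self.sm1}, {self.sm2}, {self.sm3}")
        if self.pdd < 0:
            raise ConfigError(f"pdd must be non-negative, got {self.pdd}")
        if self.thcs > 0 or self.hds > 0:
            raise ConfigError("cold/dry stress rates must be <= 0")
        if self.thhs < 0 or self.hws < 0:
            raise ConfigError("heat/wet stress rates must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesParams":
        """Load from a flat key-value file (``key: value`` or ``key = value``)."""
        text = Path(path).read_text()
        values: dict[str, float] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            m = re.match(r"^([A-Za-z_][A-Za-z0-9_]*)\s*[:=]\s*(\S+)$", line)
            if not m:
                raise ConfigError(f"unparseable parameter line: {line!r}")
            try:
                values[m.group(1).lower()] = float(m.group(2))
            except ValueError as exc:
                raise ConfigError(f"non-numeric value for {m.group(1)}: {m.group(2)!r}") from exc
        fields = set(cls.__dataclass_fields__)
        missing = fields - set(values)
        extra = set(values) - fields
        if missing:
            raise ConfigError(f"missing species parameters: {sorted(missing)}")
        if extra:
            raise ConfigError(f"unknown species parameters: {sorted(extra)}")
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")


#: Parameter set for the western conifer seed bug (Leptoglossus occidentalis).
WCSB_PARAMS = SpeciesParams(
    dv0=13.4, dv1=21.0, dv2=28.0, dv3=31.0, pdd=500.0,
    sm0=0.05, sm1=0.1, sm2=0.8, sm3=1.4,
    ttcs=-10.0, thcs=-0.0005,
    tths=31.0, thhs=0.0015,
    smds=0.05, hds=-0.005,
    smws=1.4, hws=0.001,
)


@dataclass(frozen=True)
class SoilMoistureConfig:
    """Single-bucket weekly hydrology.

    capacity_mm: bucket size defining the soil-moisture unit (sm = storage /
    capacity); k_e: evaporation per positive degree of weekly mean
    temperature (mm/week/degC); sm_max: overflow ceiling in capacity units
    (> 1 allows transient waterlogging, which is what the wet-stress
    threshold responds to); sm_init: spin-up start; n_cycles: annual cycles
    run before the reported year (the last cycle is returned).
    """

    capacity_mm: float = 100.0
    k_e: float = 1.5
    sm_max: float = 2.5
    sm_init: float = 0.5
    n_cycles: int = 2


@dataclass
class EIResult:
    """Annual result for one cell (or arrays of cells)."""

    gi_a: np.ndarray | float
    cs: np.ndarray | float
    hs: np.ndarray | float
    ds: np.ndarray | float
    ws: np.ndarray | float
    si: np.ndarray | float
    dd_total: np.ndarray | float
    ei: np.ndarray | float
    category: np.ndarray | str
    pdd_satisfied: np.ndarray | bool


def _week_month_weights() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolation stencil: for each of 52 week midpoints, the two
    bracketing month midpoints (with Dec<->Jan wrap-around) and the weight
    of the earlier one."""
    t_month = (np.arange(MONTHS) + 0.5) * DAYS_PER_YEAR / MONTHS
    t_week = (np.arange(WEEKS) + 0.5) * DAYS_PER_YEAR / WEEKS
    # periodic extension: December shifted a year back, January a year forward
    t_ext = np.concatenate([[t_month[-1] - DAYS_PER_YEAR], t_month, [t_month[0] + DAYS_PER_YEAR]])
    idx_ext = np.concatenate([[MONTHS - 1], np.arange(MONTHS), [0]])
    j = np.searchsorted(t_ext, t_week, side="right") - 1
    w_hi = (t_week - t_ext[j]) / (t_ext[j + 1] - t_ext[j])
    return idx_ext[j], idx_ext[j + 1], 1.0 - w_hi


_I_LO, _I_HI, _W_LO = _week_month_weights()


def interpolate_monthly_to_weekly(monthly: np.ndarray, kind: str = "instant") -> np.ndarray:
    """Interpolate 12 monthly values to 52 weekly values.

    Piecewise linear between month midpoints with December-January
    wrap-around.  ``kind="instant"`` treats values as point samples
    (temperatures, humidities); ``kind="total"`` treats them as monthly
    totals (precipitation) and rescales so that a constant monthly total T
    yields the constant weekly total 12 T / 52, conserving the annual sum.

    ``monthly`` has shape (..., 12); the result has shape (..., 52).
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[-1] != MONTHS:
        raise DataError(f"expected 12 monthly values on the last axis, got shape {monthly.shape}")
    if not np.all(np.isfinite(monthly)):
        raise DataError("monthly climate contains non-finite values")
    weekly = _W_LO * monthly[..., _I_LO] + (1.0 - _W_LO) * monthly[..., _I_HI]
    if kind == "total":
        weekly = weekly * (MONTHS / WEEKS)
    elif kind != "instant":
        raise ConfigError(f"unknown interpolation kind {kind!r}")
    return weekly


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    x = np.asarray(x, dtype=float)
    up = (x - lo) / (opt_lo - lo)
    down = (hi - x) / (hi - opt_hi)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def temperature_index(tavg, p: SpeciesParams):
    """Weekly Temperature Index: 0 outside (DV0, DV3), 1 on [DV1, DV2],
    linear ramps between."""
    return _trapezoid(tavg, p.dv0, p.dv1, p.dv2, p.dv3)


def moisture_index(sm, p: SpeciesParams):
    """Weekly Moisture Index: trapezoid over (SM0, SM1, SM2, SM3)."""
    return _trapezoid(sm, p.sm0, p.sm1, p.sm2, p.sm3)


def update_soil_moisture(prev_sm, precip, tavg, config: SoilMoistureConfig = SoilMoistureConfig()):
    """One weekly step of the bucket: sm' = clip(sm + (P - E)/capacity, 0, sm_max)
    with E = k_e * max(0, tavg) mm/week."""
    precip = np.asarray(precip, dtype=float)
    if np.any(precip < 0):
        raise DataError("negative precipitation")
    evap = config.k_e * np.maximum(0.0, np.asarray(tavg, dtype=float))
    return np.clip(np.asarray(prev_sm, dtype=float) + (precip - evap) / config.capacity_mm,
                   0.0, config.sm_max)


def run_soil_moisture(weekly_precip: np.ndarray, weekly_tavg: np.ndarray,
                      config: SoilMoistureConfig = SoilMoistureConfig()) -> np.ndarray:
    """Run the bucket over repeated annual cycles and return the last cycle.

    The state carries over week 52 -> week 1, so after spin-up the series is
    (near) periodic and independent of the initial condition.
    Input shape (..., 52); output the same.
    """
    weekly_precip = np.asarray(weekly_precip, dtype=float)
    weekly_tavg = np.asarray(weekly_tavg, dtype=float)
    if weekly_precip.shape[-1] != WEEKS or weekly_tavg.shape[-1] != WEEKS:
        raise DataError("weekly series must have 52 entries on the last axis")
    sm = np.full(weekly_precip.shape[:-1], config.sm_init, dtype=float)
    out = np.empty_like(weekly_precip)
    for cycle in range(config.n_cycles):
        for w in range(WEEKS):
            sm = update_soil_moisture(sm, weekly_precip[..., w], weekly_tavg[..., w], config)
            if cycle == config.n_cycles - 1:
                out[..., w] = sm
    return out


def weekly_growth_index(ti, mi):
    """GI_w = TI x MI."""
    return np.asarray(ti, dtype=float) * np.asarray(mi, dtype=float)


def annual_degree_days(weekly_tavg: np.ndarray, dv0: float):
    """Degree-days above dv0: sum over weeks of 7 x max(0, tavg - dv0)."""
    weekly_tavg = np.asarray(weekly_tavg, dtype=float)
    return 7.0 * np.maximum(0.0, weekly_tavg - dv0).sum(axis=-1)


def accumulate_stress(weekly_driver: np.ndarray, threshold: float, rate: float,
                      direction: str):
    """Linear annual stress accumulation, capped at 100.

    S = min(100, 100 x |rate| x 7 x sum_w exceed_w), with
    exceed_w = max(0, threshold - x_w) for ``direction="below"`` (cold, dry)
    and max(0, x_w - threshold) for ``direction="above"`` (heat, wet).
    """
    x = np.asarray(weekly_driver, dtype=float)
    if direction == "below":
        exceed = np.maximum(0.0, threshold - x)
    elif direction == "above":
        exceed = np.maximum(0.0, x - threshold)
    else:
        raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")
    return np.minimum(100.0, 100.0 * abs(rate) * 7.0 * exceed.sum(axis=-1))


def stress_index(cs, hs, ds, ws):
    """SI = prod over stresses of (1 - S/100)."""
    return ((1.0 - np.asarray(cs) / 100.0) * (1.0 - np.asarray(hs) / 100.0)
            * (1.0 - np.asarray(ds) / 100.0) * (1.0 - np.asarray(ws) / 100.0))


def categorize_ei(ei):
    """Suitability category: 0 unsuitable; (0,10) marginal; [10,30) suitable;
    [30,100] optimal.  Vector input returns an array of strings."""
    ei_arr = np.asarray(ei, dtype=float)
    codes = categorize_ei_codes(ei_arr)
    if ei_arr.ndim == 0:
        return CATEGORIES[int(codes)]
    return np.array(CATEGORIES, dtype=object)[codes]


def categorize_ei_codes(ei) -> np.ndarray:
    """Integer codes 0..3 for unsuitable/marginal/suitable/optimal."""
    ei = np.asarray(ei, dtype=float)
    codes = np.zeros(ei.shape, dtype=np.uint8)
    codes[ei > 0] = 1
    codes[ei >= 10] = 2
    codes[ei >= 30] = 3
    return codes


def ecoclimatic_index(gi_a, si, dd_total, p: SpeciesParams, use_pdd: bool) -> EIResult:
    """Combine annual growth, stress and the degree-day gate into the EI.

    ``gi_a`` on [0,100], ``si`` on [0,1].  With ``use_pdd`` every cell whose
    degree-day total falls below PDD is forced to EI = 0 (one generation
    cannot complete), regardless of growth and stress.
    """
    gi_a = np.asarray(gi_a, dtype=float)
    si = np.asarray(si, dtype=float)
    dd_total = np.asarray(dd_total, dtype=float)
    ei = np.clip(gi_a * si, 0.0, 100.0)
    satisfied = dd_total >= p.pdd
    if use_pdd:
        ei = np.where(satisfied, ei, 0.0)
    scalar = ei.ndim == 0
    cat = categorize_ei(ei)
    return EIResult(
        gi_a=float(gi_a) if scalar else gi_a,
        cs=np.nan, hs=np.nan, ds=np.nan, ws=np.nan,
        si=float(si) if scalar else si,
        dd_total=float(dd_total) if scalar else dd_total,
        ei=float(ei) if scalar else ei,
        category=cat,
        pdd_satisfied=bool(satisfied) if scalar else satisfied,
    )


def compute_ei(monthly: dict[str, np.ndarray], p: SpeciesParams, use_pdd: bool,
               sm_config: SoilMoistureConfig = SoilMoistureConfig()) -> EIResult:
    """Full annual pipeline for one cell or a batch of cells.

    ``monthly`` maps variable names (``tavg``, ``tmin``, ``tmax``,
    ``precip``; ``rh`` accepted and ignored by the index math) to arrays of
    shape (..., 12).
    """
    for key in ("tavg", "tmin", "tmax", "precip"):
        if key not in monthly:
            raise DataError(f"missing climate variable {key!r}")
    tavg = interpolate_monthly_to_weekly(monthly["tavg"])
    tmin = interpolate_monthly_to_weekly(monthly["tmin"])
    tmax = interpolate_monthly_to_weekly(monthly["tmax"])
    precip = interpolate_monthly_to_weekly(monthly["precip"], kind="total")

    sm = run_soil_moisture(precip, tavg, sm_config)
    ti = temperature_index(tavg, p)
    mi = moisture_index(sm, p)
    gi_w = weekly_growth_index(ti, mi)
    gi_a = 100.0 * gi_w.mean(axis=-1)

    cs = accumulate_stress(tmin, p.ttcs, p.thcs, "below")
    hs = accumulate_stress(tmax, p.tths, p.thhs, "above")
    ds = accumulate_stress(sm, p.smds, p.hds, "below")
    ws = accumulate_stress(sm, p.smws, p.hws, "above")
    si = stress_index(cs, hs, ds, ws)
    dd = annual_degree_days(tavg, p.dv0)

    res = ecoclimatic_index(gi_a, si, dd, p, use_pdd)
    scalar = np.asarray(gi_a).ndim == 0
    res.cs = float(cs) if scalar else cs
    res.hs = float(hs) if scalar else hs
    res.ds = float(ds) if scalar else ds
    res.ws = float(ws) if scalar else ws
    return res


def ei_map(monthly_rasters: dict[str, np.ndarray], geom: GridGeometry,
           p: SpeciesParams, use_pdd: bool,
           sm_config: SoilMoistureConfig = SoilMoistureConfig()) -> dict[str, np.ndarray]:
    """Apply the annual pipeline to every valid cell of a climate grid.

    ``monthly_rasters`` maps variable names to arrays of shape
    (12, n_rows, n_cols).  A cell is no-data if any variable is NaN in any
    month; no-data propagates to every output layer.  Returns a dict with
    keys ``ei``, ``category`` (uint8 codes, 255 = no-data), ``gi_a``,
    ``cs``, ``hs``, ``ds``, ``ws``, ``si``, ``dd_total``, ``pdd_satisfied``.
    """
    needed = ("tavg", "tmin", "tmax", "precip")
    for key in needed:
        if key not in monthly_rasters:
            raise DataError(f"missing climate variable {key!r}")
        arr = np.asarray(monthly_rasters[key])
        if arr.shape != (MONTHS, *geom.shape):
            raise DataError(
                f"climate layer {key!r} has shape {arr.shape}, expected {(MONTHS, *geom.shape)}")
    stack = {k: np.asarray(monthly_rasters[k], dtype=float) for k in needed}
    valid = np.ones(geom.shape, dtype=bool)
    for arr in stack.values():
        valid &= np.isfinite(arr).all(axis=0)

    out = {k: np.full(geom.shape, np.nan) for k in
           ("ei", "gi_a", "cs", "hs", "ds", "ws", "si", "dd_total")}
    out["category"] = np.full(geom.shape, 255, dtype=np.uint8)
    out["pdd_satisfied"] = np.zeros(geom.shape, dtype=bool)
    if valid.any():
        batch = {k: np.moveaxis(stack[k][:, valid], 0, -1) for k in needed}
        res = compute_ei(batch, p, use_pdd, sm_config)
        out["ei"][valid] = res.ei
        out["gi_a"][valid] = res.gi_a
        out["cs"][valid] = res.cs
        out["hs"][valid] = res.hs
        out["ds"][valid] = res.ds
        out["ws"][valid] = res.ws
        out["si"][valid] = res.si
        out["dd_total"][valid] = res.dd_total
        out["category"][valid] = categorize_ei_codes(res.ei)
        out["pdd_satisfied"][valid] = res.pdd_satisfied
    return out
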