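"""Synthetic settlement landscapes and seasonal rainfall series.

The spatial simulator runs on a network of mosquito populations, one per
human settlement, whose larval carrying capacity tracks local water
availability: daily rainfall plus permanent groundwater (rivers, lake
edges, small permanent pools).  This module generates synthetic landscapes
and rainfall with the statistical features that matter for drive dynamics
in the West-African Sahel/savannah setting — clustered vs sparse
settlement patterns, and a strong north–south gradient in wet-season
length — and reads/writes both as plain CSV.

Coordinates are planar kilometres; at the 12-km dispersal scale projection
distortion is irrelevant and synthetic landscapes need no geodesy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Site",
    "Landscape",
    "RainfallSeries",
    "SeasonProfile",
    "generate_landscape",
    "generate_rainfall",
    "neighbor_weights",
    "read_landscape",
    "write_landscape",
    "read_rainfall",
    "write_rainfall",
    "SchemaError",
]

LANDSCAPE_COLUMNS = ["id", "x_km", "y_km", "permanent_water", "river_lake"]
RAINFALL_COLUMNS = ["day", "site_id", "rain_mm"]


class SchemaError(ValueError):
    """A delimited-text input is missing columns or fails validation."""


@dataclass(frozen=True)
class Site:
    id: int
    x: float
    y: float
    permanent_water: float = 0.0
    river_lake: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("site coordinates must be finite")
        if self.permanent_water < 0 or self.river_lake < 0:
            raise ValueError("water scores must be non-negative")


@dataclass
class Landscape:
    sites: List[Site]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def ids(self) -> np.ndarray:
        return np.array([s.id for s in self.sites])

    @property
    def coords(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.sites])

    @property
    def permanent_water(self) -> np.ndarray:
        return np.array([s.permanent_water for s in self.sites])

    @property
    def river_lake(self) -> np.ndarray:
        return np.array([s.river_lake for s in self.sites])

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        """Bounding box (xmin, xmax, ymin, ymax) in km."""
        c = self.coords
        return float(c[:, 0].min()), float(c[:, 0].max()), float(c[:, 1].min()), float(c[:, 1].max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x_km": self.coords[:, 0],
                "y_km": self.coords[:, 1],
                "permanent_water": self.permanent_water,
                "river_lake": self.river_lake,
            }
        )


@dataclass
class RainfallSeries:
    """Daily rainfall (mm/day) per site: array shape (n_days, n_sites)."""

    rain: np.ndarray
    site_ids: np.ndarray

    def __post_init__(self) -> None:
        self.rain = np.asarray(self.rain, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        if self.rain.ndim != 2 or self.rain.shape[1] != len(self.site_ids):
            raise ValueError("rain must be (n_days, n_sites)")
        if (self.rain < 0).any():
            raise SchemaError("rainfall contains negative values")

    @property
    def n_days(self) -> int:
        return self.rain.shape[0]

    def to_frame(self) -> pd.DataFrame:
        days = np.repeat(np.arange(self.n_days), len(self.site_ids))
        sites = np.tile(self.site_ids, self.n_days)
        return pd.DataFrame({"day": days, "site_id": sites, "rain_mm": self.rain.ravel()})


@dataclass(frozen=True)
class SeasonProfile:
    """Parameters of the synthetic seasonal rainfall regime.

    A single wet season per year: a raised-cosine envelope of length
    ``wet_season_length`` days centred on ``wet_season_midpoint``, scaled
    so a site's expected annual total is ``annual_total`` mm.  Year-to-year
    totals vary with coefficient of variation ``interannual_cv``.
    ``latitudinal_gradient`` shortens the wet season by that many days per
    km northward (larger y), producing the Sahel-like north–south
    seasonality gradient.
    """

    wet_season_midpoint: int = 227  # mid-August
    wet_season_length: float = 150.0
    annual_total: float = 800.0
    interannual_cv: float = 0.15
    latitudinal_gradient: float = 0.0
    daily_shape: float = 1.0  # gamma shape of daily wet-season rain

    def __post_init__(self) -> None:
        if not 0 < self.wet_season_length <= 365:
            raise ValueError("wet_season_length must be in (0, 365]")
        if self.annual_total < 0:
            raise ValueError("annual_total must be non-negative")


def generate_landscape(
    n_sites: int,
    extent: Tuple[float, float] = (100.0, 100.0),
    clustering: float = 0.0,
    seed: int = 0,
    cluster_sigma_km: float = 2.0,
    river_fraction: float = 0.1,
    permanent_water_mean: float = 0.05,
) -> Landscape:
    """Generate a synthetic settlement pattern.

    ``clustering=0`` gives a homogeneous (binomial/Poisson) point pattern
    over the ``extent`` box; larger values give a Thomas-process-like
    pattern with an expected ``1 + clustering`` settlements per cluster,
    scattered with standard deviation ``cluster_sigma_km`` around cluster
    centres.  A fraction ``river_fraction`` of sites receives a positive
    river/lake groundwater score; every site gets a small positive
    permanent-water score (lognormal around ``permanent_water_mean``).
    Pure function of its arguments and ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = extent
    if clustering <= 0:
        xy = rng.uniform([0, 0], [w, h], size=(n_sites, 2))
    else:
        n_parents = max(1, int(round(n_sites / (1.0 + clustering))))
        parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
        assignment = rng.integers(0, n_parents, size=n_sites)
        xy = parents[assignment] + rng.normal(0.0, cluster_sigma_km, size=(n_sites, 2))
        xy[:, 0] = np.clip(xy[:, 0], 0, w)
        xy[:, 1] = np.clip(xy[:, 1], 0, h)
    perm = permanent_water_mean * rng.lognormal(0.0, 0.5, size=n_sites)
    river = np.where(
        rng.uniform(size=n_sites) < river_fraction,
        rng.lognormal(0.0, 0.5, size=n_sites),
        0.0,
    )
    sites = [
        Site(i, float(xy[i, 0]), float(xy[i, 1]), float(perm[i]), float(river[i]))
        for i in range(n_sites)
    ]
    return Landscape(sites)


def _wet_lengths(landscape: Landscape, profile: SeasonProfile) -> np.ndarray:
    y = landscape.coords[:, 1]
    lengths = profile.wet_season_length - profile.latitudinal_gradient * (y - y.min())
    return np.clip(lengths, 5.0, 365.0)


def generate_rainfall(
    landscape: Landscape,
    profile: SeasonProfile = SeasonProfile(),
    years: int = 1,
    seed: int = 0,
) -> RainfallSeries:
    """Generate daily rainfall for every site over ``years`` years.

    Daily wet-season rain is gamma-distributed around the site's seasonal
    envelope; dry-season days are dry.  Expected per-site annual totals
    equal ``profile.annual_total`` scaled by a lognormal year factor with
    the configured interannual CV.  Pure function of its arguments.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(landscape)
    lengths = _wet_lengths(landscape, profile)  # (n,)
    doy = np.arange(365)
    # raised-cosine envelope per site, normalised to unit annual sum
    phase = (doy[None, :] - profile.wet_season_midpoint) / lengths[:, None]  # (n, 365)
    in_season = np.abs(phase) <= 0.5
    envelope = np.where(in_season, 1.0 + np.cos(2.0 * np.pi * phase), 0.0)
    sums = envelope.sum(axis=1, keepdims=True)
    envelope = np.divide(envelope, sums, out=np.zeros_like(envelope), where=sums > 0)
    rain = np.zeros((years * 365, n))
    if profile.annual_total > 0:
        sigma = np.sqrt(np.log1p(profile.interannual_cv**2))
        for yr in range(years):
            factor = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
            mean_daily = profile.annual_total * factor[:, None] * envelope  # (n, 365)
            k = profile.daily_shape
            wet = mean_daily > 0
            draw = np.zeros_like(mean_daily)
            draw[wet] = rng.gamma(k, mean_daily[wet] / k)
            rain[yr * 365:(yr + 1) * 365, :] = draw.T
    return RainfallSeries(rain, landscape.ids)


def neighbor_weights(
    landscape: Landscape,
    radius: float = 12.0,
    kernel_scale: float = 4.0,
) -> Dict[int, List[Tuple[int, float]]]:
    """Dispersal destinations and probabilities for each site.

    For each focal site, all other sites within ``radius`` km receive a
    weight proportional to ``exp(-distance / kernel_scale)``, normalised to
    sum to 1.  Sites with no neighbour in range map to an empty list.
    Keys and neighbour references are site ids.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = landscape.coords
    ids = landscape.ids
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    out: Dict[int, List[Tuple[int, float]]] = {int(i): [] for i in ids}
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        w = np.exp(-d / kernel_scale)
        for (i, j), dist, wt in zip(pairs, d, w):
            if dist == 0.0:
                continue  # co-located sites are excluded (distance must be > 0)
            out[int(ids[i])].append((int(ids[j]), float(wt)))
            out[int(ids[j])].append((int(ids[i]), float(wt)))
    for sid, lst in out.items():
        total = sum(wt for _, wt in lst)
        out[sid] = [(nid, wt / total) for nid, wt in lst] if total > 0 else []
    return out


# ---------------------------------------------------------------------------
# delimited-text IO


def write_landscape(landscape: Landscape, path) -> None:
    """Write the settlement table as CSV: id,x_km,y_km,permanent_water,river_lake."""
    landscape.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_landscape(path) -> Landscape:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LANDSCAPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"landscape file {path} missing columns: {missing}")
    sites = [
        Site(int(r.id), float(r.x_km), float(r.y_km), float(r.permanent_water), float(r.river_lake))
        for r in df.itertuples()
    ]
    return Landscape(sites)


def write_rainfall(series: RainfallSeries, path) -> None:
    """Write rainfall as long-format CSV: day,site_id,rain_mm."""
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_rainfall(path) -> RainfallSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RAINFALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"rainfall file {path} missing columns: {missing}")
    if (df["rain_mm"] < 0).any():
        raise SchemaError(f"rainfall file {path} contains negative values")
    wide = df.pivot(index="day", columns="site_id", values="rain_mm").sort_index()
    if wide.isna().any().any():
        raise SchemaError(f"rainfall file {path} has missing day x site entries")
    return RainfallSeries(wide.to_numpy(), wide.columns.to_numpy())
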