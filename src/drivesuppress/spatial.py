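"""Stochastic spatial metapopulation simulator of drive releases.

Daily-timestep, individual-count simulation of mosquito populations at a
network of settlements.  Each site holds stage-structured counts: juvenile
cohorts (fixed 10-day development, sex and genotype assigned at the egg
stage), adult males by genotype, and adult females by genotype x
parental-deposition class, mating status and (if mated) mate genotype.
Larval survival is density dependent with a carrying capacity driven by
recent rainfall and permanent groundwater, which produces the strong
seasonal population cycles of the Sahel.  Adults disperse to nearby
settlements; optional dry-season mechanisms (aestivation of adult
females, or wind-borne long-distance redistribution) can replace the
default assumption of small permanent water bodies at every site.

The order of events within a day is fixed and documented:

1. density-dependent juvenile survival, ageing, eclosion of day-10 cohort
2. adult survival (aestivating females at reduced mortality)
3. aestivation entry/exit (if enabled)
4. short-range dispersal of adults
5. long-distance redistribution of adult females (if enabled)
6. mating of females that eclosed on an earlier day, if males are present
7. oviposition by mated, non-aestivating females (Poisson egg numbers,
   offspring drawn from the cross distribution), then eclosed adults from
   step 1 join the adult pools

All stochasticity comes from a single demographic RNG stream seeded from
``SimConfig.seed``, so runs are bit-reproducible; paired reference and
release runs should share landscape and rainfall but use different
demographic seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .deterministic import GrowthParams
from .genetics import Allele, DriveParams, ModelTables, WD, WW
from .landscape import Landscape, RainfallSeries, neighbor_weights

__all__ = [
    "SimConfig",
    "AestivationParams",
    "LongDistanceParams",
    "SimState",
    "SiteState",
    "Recorder",
    "ReleaseEvent",
    "carrying_capacity",
    "density_dependent_juvenile_survival",
    "step_day",
    "release_males",
    "run_simulation",
]

DRY_SEASON_MODES = ("permanent_water", "long_distance", "aestivation")


@dataclass(frozen=True)
class AestivationParams:
    """Dormancy of mated adult females through the dry season.

    On ``entry_day`` (day of year) a fraction ``entry_fraction`` of mated
    females at sites whose trailing rainfall is below ``dry_threshold_mm``
    enter dormancy: they stop laying eggs and their daily mortality is
    multiplied by ``mortality_multiplier``.  All dormant females wake on
    ``exit_day``.
    """

    entry_fraction: float = 0.5
    mortality_multiplier: float = 0.2
    entry_day: int = 335
    exit_day: int = 160
    dry_threshold_mm: float = 1.0


@dataclass(frozen=True)
class LongDistanceParams:
    """Wind-borne redistribution of adult females, once per year.

    On ``event_day`` a fraction of adult females at every site is
    displaced by the prevailing-wind vector ``wind_km`` plus isotropic
    Gaussian noise and lands at the nearest settlement.
    """

    fraction: float = 0.1
    wind_km: Tuple[float, float] = (30.0, 0.0)
    noise_km: float = 15.0
    event_day: int = 160


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the spatial simulation."""

    life_history: GrowthParams = GrowthParams()
    drive: DriveParams = DriveParams()
    dispersal_rate: float = 0.005  # inter-village movements per mosquito-day
    dispersal_radius: float = 12.0  # km
    kernel_scale: float = 4.0  # km, exponential kernel decay length
    dry_season_mode: str = "permanent_water"
    aestivation: AestivationParams = AestivationParams()
    long_distance: LongDistanceParams = LongDistanceParams()
    density_alpha0: float = 10_000.0  # baseline larval capacity scale
    rain_coef: float = 0.25  # capacity per mm/day of trailing mean rain
    rain_window: int = 14  # days of trailing rainfall averaged
    burnin_years: int = 2
    init_adults_per_alpha: float = 0.02  # initial adults of each sex / alpha
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dispersal_rate <= 1.0:
            raise ValueError("dispersal_rate must be in [0, 1]")
        if self.dry_season_mode not in DRY_SEASON_MODES:
            raise ValueError(
                f"dry_season_mode must be one of {DRY_SEASON_MODES}"
            )

    @property
    def adult_daily_survival(self) -> float:
        return 1.0 - 1.0 / self.life_history.adult_female_life_expectancy

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReleaseEvent:
    day: int  # day index relative to the end of burn-in
    site_id: int
    n_males: int
    genotype: object = WD


def carrying_capacity(
    permanent_water: float,
    river_lake: float,
    rainfall_window: Sequence[float],
    config: SimConfig,
) -> float:
    """Larval carrying capacity alpha of one site on one day.

    ``alpha = density_alpha0 * (permanent + river_lake + rain_coef * mean(recent rain))``
    where the permanent-water component only contributes in
    ``permanent_water`` dry-season mode (the other modes assume no
    settlement has year-round breeding pools unless it sits by a river or
    lake).
    """
    rain = np.asarray(rainfall_window, dtype=float)
    if (rain < 0).any():
        raise ValueError("rainfall must be non-negative")
    perm = permanent_water if config.dry_season_mode == "permanent_water" else 0.0
    trailing = float(rain.mean()) if rain.size else 0.0
    return config.density_alpha0 * (perm + river_lake + config.rain_coef * trailing)


def density_dependent_juvenile_survival(
    total_juveniles: float, alpha: float, base: float = 0.95
) -> float:
    """Beverton–Holt daily larval survival: ``base / (1 + J / alpha)``."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0.0:
        return 0.0
    return base / (1.0 + total_juveniles / alpha)


class SimState:
    """Full metapopulation state: dense count arrays over all sites.

    Axes: S sites, 10 juvenile ages (0 = laid today), G genotypes, 4
    deposition classes; mated females also carry the mate genotype axis.
    """

    def __init__(self, n_sites: int, tables: ModelTables):
        G = tables.n_genotypes
        self.tables = tables
        self.juv_m = np.zeros((n_sites, 10, G), dtype=np.int64)
        self.juv_f = np.zeros((n_sites, 10, G, 4), dtype=np.int64)
        self.males = np.zeros((n_sites, G), dtype=np.int64)
        self.unmated = np.zeros((n_sites, G, 4), dtype=np.int64)
        self.mated = np.zeros((n_sites, G, 4, G), dtype=np.int64)
        self.aest = np.zeros((n_sites, G, 4, G), dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.males.shape[0]

    def total_juveniles(self) -> np.ndarray:
        return self.juv_m.sum(axis=(1, 2)) + self.juv_f.sum(axis=(1, 2, 3))

    def total_females(self) -> np.ndarray:
        return (
            self.unmated.sum(axis=(1, 2))
            + self.mated.sum(axis=(1, 2, 3))
            + self.aest.sum(axis=(1, 2, 3))
        )

    def total_adults(self) -> np.ndarray:
        return self.males.sum(axis=1) + self.total_females()

    def females_by_genotype(self) -> np.ndarray:
        return (
            self.unmated.sum(axis=2)
            + self.mated.sum(axis=(2, 3))
            + self.aest.sum(axis=(2, 3))
        )

    def phenotypic_females(self) -> np.ndarray:
        """Biting females per site (excludes dsx-null genotypes)."""
        return (self.females_by_genotype() * self.tables.phenotypic).sum(axis=1)

    def adult_allele_counts(self) -> np.ndarray:
        """Allele copy counts among adults, shape (S, 4)."""
        by_g = self.females_by_genotype() + self.males
        return by_g @ self.tables.allele_dosage

    def assert_valid(self) -> None:
        for arr in (self.juv_m, self.juv_f, self.males, self.unmated, self.mated, self.aest):
            if (arr < 0).any():
                raise AssertionError("negative count in state")


@dataclass
class SiteState:
    """Read-only per-settlement view of the metapopulation state."""

    juveniles_male: np.ndarray  # (10, G)
    juveniles_female: np.ndarray  # (10, G, 4)
    adult_males: np.ndarray  # (G,)
    unmated_females: np.ndarray  # (G, 4)
    mated_females: np.ndarray  # (G, 4, G)
    aestivating_females: np.ndarray  # (G, 4, G)


def site_state(state: SimState, s: int) -> SiteState:
    return SiteState(
        state.juv_m[s].copy(),
        state.juv_f[s].copy(),
        state.males[s].copy(),
        state.unmated[s].copy(),
        state.mated[s].copy(),
        state.aest[s].copy(),
    )


@dataclass
class Recorder:
    """Daily per-site series written by :func:`run_simulation`.

    Day 0 is the first day after burn-in; negative-free arrays with shape
    (n_days, n_sites) (allele counts have a trailing allele axis).
    """

    days: np.ndarray
    site_ids: np.ndarray
    phenotypic_females: np.ndarray
    total_females: np.ndarray
    total_adults: np.ndarray
    allele_counts: np.ndarray  # (n_days, n_sites, 4)
    seed: int = 0
    config_hash: str = ""

    def totals(self) -> Dict[str, np.ndarray]:
        return {
            "phenotypic_females": self.phenotypic_females.sum(axis=1),
            "total_females": self.total_females.sum(axis=1),
            "total_adults": self.total_adults.sum(axis=1),
            "allele_counts": self.allele_counts.sum(axis=1),
        }

    def allele_frequency(self, allele: Allele = Allele.D) -> np.ndarray:
        """Study-area-wide adult allele frequency per day (NaN if no adults)."""
        counts = self.allele_counts.sum(axis=1)
        tot = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, counts[:, allele] / tot, np.nan)


class _Env:
    """Precomputed environment shared by all days of a run."""

    def __init__(self, config: SimConfig, landscape: Landscape, rainfall: RainfallSeries):
        self.landscape = landscape
        n = len(landscape)
        ids = landscape.ids
        self.id_to_idx = {int(i): k for k, i in enumerate(ids)}
        nb = neighbor_weights(landscape, config.dispersal_radius, config.kernel_scale)
        self.nb_idx: List[np.ndarray] = []
        self.nb_w: List[np.ndarray] = []
        for i in ids:
            lst = nb[int(i)]
            self.nb_idx.append(np.array([self.id_to_idx[j] for j, _ in lst], dtype=np.int64))
            self.nb_w.append(np.array([w for _, w in lst]))
        # trailing mean rainfall, (n_days, n_sites)
        rain = rainfall.rain
        win = config.rain_window
        cs = np.cumsum(np.vstack([np.zeros((1, n)), rain]), axis=0)
        lo = np.maximum(np.arange(rain.shape[0]) - win + 1, 0)
        width = (np.arange(rain.shape[0]) - lo + 1).astype(float)
        self.trailing_rain = (cs[np.arange(rain.shape[0]) + 1] - cs[lo]) / width[:, None]
        perm = landscape.permanent_water
        if config.dry_season_mode != "permanent_water":
            perm = np.zeros_like(perm)
        self.alpha = config.density_alpha0 * (
            perm[None, :]
            + landscape.river_lake[None, :]
            + config.rain_coef * self.trailing_rain
        )
        self.tree = cKDTree(landscape.coords)


def _cross_tables(tables: ModelTables):
    """Offspring pvals over (female genotypes, male genotypes) = 2G outcomes."""
    G = tables.n_genotypes
    pvals = np.zeros((G, G, 2 * G))
    pvals[:, :, :G] = tables.offspring * (1.0 - tables.p_male)[None, :, None]
    pvals[:, :, G:] = tables.offspring * tables.p_male[None, :, None]
    return pvals


def release_males(state: SimState, site_idx: int, n: int, genotype=WD) -> None:
    """Add ``n`` adult males of ``genotype`` at site index ``site_idx``."""
    if n < 0:
        raise ValueError("release size must be non-negative")
    state.males[site_idx, state.tables.index(genotype)] += n


def _binom(rng: np.random.Generator, n: np.ndarray, p) -> np.ndarray:
    return rng.binomial(n, p)


def step_day(
    state: SimState,
    config: SimConfig,
    env: _Env,
    day: int,
    rng: np.random.Generator,
    cross_pvals: Optional[np.ndarray] = None,
) -> None:
    """Advance the whole metapopulation by one day, in place.

    ``day`` indexes the rainfall series (absolute day including burn-in).
    """
    t = state.tables
    G = t.n_genotypes
    S = state.n_sites
    if cross_pvals is None:
        cross_pvals = _cross_tables(t)
    doy = day % 365
    alpha = env.alpha[day]
    surv_a = config.adult_daily_survival

    # (1) juvenile survival, ageing, eclosion -------------------------------
    juv_tot = state.total_juveniles().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_juv = np.where(
            alpha > 0,
            config.life_history.juvenile_daily_survival / (1.0 + juv_tot / np.where(alpha > 0, alpha, 1.0)),
            0.0,
        )
    surv_m = _binom(rng, state.juv_m, p_juv[:, None, None])
    surv_f = _binom(rng, state.juv_f, p_juv[:, None, None, None])
    eclose_m = surv_m[:, 9, :]
    eclose_f = surv_f[:, 9, :, :]
    state.juv_m[:, 1:, :] = surv_m[:, :9, :]
    state.juv_m[:, 0, :] = 0
    state.juv_f[:, 1:, :, :] = surv_f[:, :9, :, :]
    state.juv_f[:, 0, :, :] = 0

    # (2) adult survival ----------------------------------------------------
    state.males = _binom(rng, state.males, surv_a)
    state.unmated = _binom(rng, state.unmated, surv_a)
    state.mated = _binom(rng, state.mated, surv_a)
    if state.aest.any():
        surv_dormant = 1.0 - (1.0 - surv_a) * config.aestivation.mortality_multiplier
        state.aest = _binom(rng, state.aest, surv_dormant)

    # (3) aestivation entry / exit ------------------------------------------
    if config.dry_season_mode == "aestivation":
        ap = config.aestivation
        if doy == ap.entry_day:
            dry = env.trailing_rain[day] < ap.dry_threshold_mm
            entering = _binom(rng, state.mated, ap.entry_fraction * dry[:, None, None, None])
            state.mated -= entering
            state.aest += entering
        if doy == ap.exit_day:
            state.mated += state.aest
            state.aest[:] = 0

    # (4) short-range dispersal ---------------------------------------------
    if config.dispersal_rate > 0.0:
        pools = (state.males, state.unmated, state.mated)
        flat_sizes = [p[0].size for p in pools]
        movers = [
            _binom(rng, p, config.dispersal_rate) for p in pools
        ]
        counts = np.concatenate(
            [mv.reshape(S, -1) for mv in movers], axis=1
        )  # (S, sum flat)
        incoming = np.zeros_like(counts)
        active = np.nonzero(counts.sum(axis=1))[0]
        for s in active:
            idx = env.nb_idx[s]
            if idx.size == 0:
                continue  # isolated site: would-be movers stay
            alloc = rng.multinomial(counts[s], env.nb_w[s])  # (flat, n_nb)
            np.add.at(incoming, idx, alloc.T)
            # departures only happen when there is somewhere to go
            for pool, mv in zip(pools, movers):
                pool[s] -= mv[s]
        off = 0
        for pool, sz in zip(pools, flat_sizes):
            pool += incoming[:, off:off + sz].reshape(pool.shape)
            off += sz

    # (5) long-distance wind redistribution ---------------------------------
    if config.dry_season_mode == "long_distance" and doy == config.long_distance.event_day:
        ld = config.long_distance
        for pool in (state.unmated, state.mated):
            movers = _binom(rng, pool, ld.fraction)
            pool -= movers
            flat = movers.reshape(S, -1)
            arrivals = np.zeros_like(flat)
            for s in np.nonzero(flat.sum(axis=1))[0]:
                classes = np.repeat(np.arange(flat.shape[1]), flat[s])
                disp = env.landscape.coords[s] + np.asarray(ld.wind_km) + rng.normal(
                    0.0, ld.noise_km, size=(classes.size, 2)
                )
                _, dest = env.tree.query(disp)
                np.add.at(arrivals, (dest, classes), 1)
            pool += arrivals.reshape(pool.shape)

    # (6) mating -------------------------------------------------------------
    males_tot = state.males.sum(axis=1)
    can_mate = np.nonzero((males_tot > 0) & (state.unmated.sum(axis=(1, 2)) > 0))[0]
    if can_mate.size:
        pv = state.males[can_mate] / males_tot[can_mate, None]
        draws = rng.multinomial(
            state.unmated[can_mate], pv[:, None, None, :]
        )  # (k, G, 4, G)
        state.mated[can_mate] += draws
        state.unmated[can_mate] = 0

    # (7) oviposition --------------------------------------------------------
    lam = state.mated * (config.life_history.eggs_per_female_per_day * t.fertility[None, :, :, None])
    eggs = rng.poisson(lam)
    nz = np.nonzero(eggs)
    if nz[0].size:
        s_i, mg_i, dc_i, fg_i = nz
        alloc = rng.multinomial(eggs[nz], cross_pvals[mg_i, fg_i])  # (k, 2G)
        dep_off = t.dep_index[mg_i, fg_i]
        for g in range(G):
            np.add.at(state.juv_f, (s_i, 0, g, dep_off), alloc[:, g])
            np.add.at(state.juv_m[:, 0, :], (s_i, g), alloc[:, G + g])

    # eclosed adults join the pools (mate from tomorrow) ---------------------
    state.males += eclose_m
    state.unmated += eclose_f


def _initialise(state: SimState, env: _Env, config: SimConfig) -> None:
    t = state.tables
    iww = t.index(WW)
    n0 = np.maximum(np.round(config.init_adults_per_alpha * env.alpha[0]), 0).astype(np.int64)
    state.males[:, iww] = n0
    state.mated[:, iww, 0, iww] = n0


def run_simulation(
    config: SimConfig,
    landscape: Landscape,
    rainfall: RainfallSeries,
    release_schedule: Optional[Sequence[ReleaseEvent]] = None,
    years: int = 1,
) -> Recorder:
    """Burn in to seasonal quasi-equilibrium, then simulate releases.

    ``release_schedule`` days are relative to the end of burn-in (day 0 is
    the first recorded day); the recorder covers ``years * 365`` days.
    """
    n_days = years * 365
    burnin = config.burnin_years * 365
    if rainfall.n_days < burnin + n_days:
        raise ValueError("rainfall series shorter than burn-in + simulated years")
    tables = ModelTables.build(config.drive)
    env = _Env(config, landscape, rainfall)
    state = SimState(len(landscape), tables)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2718281]))
    _initialise(state, env, config)
    cross_pvals = _cross_tables(tables)

    schedule: Dict[int, List[ReleaseEvent]] = {}
    for ev in release_schedule or []:
        schedule.setdefault(ev.day, []).append(ev)

    rec_phen = np.zeros((n_days, len(landscape)), dtype=np.int64)
    rec_fem = np.zeros_like(rec_phen)
    rec_adults = np.zeros_like(rec_phen)
    rec_alleles = np.zeros((n_days, len(landscape), 4), dtype=np.int64)

    for day in range(burnin + n_days):
        rel_day = day - burnin
        for ev in schedule.get(rel_day, []):
            release_males(state, env.id_to_idx[ev.site_id], ev.n_males, ev.genotype)
        step_day(state, config, env, day, rng, cross_pvals)
        if rel_day >= 0:
            rec_phen[rel_day] = state.phenotypic_females()
            rec_fem[rel_day] = state.total_females()
            rec_adults[rel_day] = state.total_adults()
            rec_alleles[rel_day] = state.adult_allele_counts()

    return Recorder(
        days=np.arange(n_days),
        site_ids=landscape.ids,
        phenotypic_females=rec_phen,
        total_females=rec_fem,
        total_adults=rec_adults,
        allele_counts=rec_alleles,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
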