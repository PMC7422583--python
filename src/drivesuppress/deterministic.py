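"""Deterministic non-spatial dynamics of the female-sterility drive.

Discrete, non-overlapping generations in an effectively infinite, randomly
mating population.  The state is the frequency distribution of female
classes (genotype x parental-deposition class) and of male genotypes, each
normalised within its sex.  Iterating the cross recursion to a fixed point
yields the equilibrium allele frequencies and the genetic load

    L = 1 - sum_i f_i F*_i

where ``f_i`` is the relative fertility of female class ``i`` and ``F*_i``
its equilibrium frequency.  A population is predicted to go extinct when
the load meets the critical load ``L_c = 1 - 1/R_m``, with ``R_m`` the
intrinsic (density-independent) per-generation growth rate computed from
the life-history parameters shared with the spatial simulator.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .genetics import (
    Allele,
    DepositionClass,
    DEPOSITION_CLASSES,
    DriveParams,
    FemaleClass,
    Genotype,
    ModelTables,
    WD,
    WR1,
    WW,
)

__all__ = [
    "GrowthParams",
    "PopulationFrequencies",
    "EquilibriumResult",
    "DegeneratePopulationError",
    "NoCrossingError",
    "step_generation",
    "equilibrate",
    "genetic_load",
    "intrinsic_growth_rate",
    "critical_load",
    "find_cost_threshold",
    "simulate_r1_invasion",
    "run_trajectory",
    "small_introduction",
]


class DegeneratePopulationError(RuntimeError):
    """Raised when total female reproductive output is zero (all sterile)."""


class NoCrossingError(RuntimeError):
    """Raised when a threshold scan finds no load/critical-load crossing."""


@dataclass(frozen=True)
class GrowthParams:
    """Life-history parameters determining the intrinsic growth rate.

    Defaults describe *Anopheles gambiae*: 95%/day juvenile survival over a
    fixed 10-day larval development, 87.5% survival of the first adult day
    (to become a mated female), 9 eggs per female per day, an 8-day adult
    female life expectancy, and an even primary sex ratio.
    """

    juvenile_daily_survival: float = 0.95
    juvenile_duration: int = 10
    pre_mating_survival: float = 0.875
    eggs_per_female_per_day: float = 9.0
    adult_female_life_expectancy: float = 8.0
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"GrowthParams.{name} must be non-negative")


def intrinsic_growth_rate(gp: GrowthParams = GrowthParams()) -> float:
    """Expected lifetime female offspring of a female at low density (R_m)."""
    return (
        gp.juvenile_daily_survival**gp.juvenile_duration
        * gp.pre_mating_survival
        * gp.eggs_per_female_per_day
        * gp.adult_female_life_expectancy
        * gp.female_fraction
    )


def critical_load(rm: float) -> float:
    """Genetic load above which deterministic extinction is predicted."""
    if rm < 1.0:
        raise ValueError("critical_load requires R_m >= 1")
    return 1.0 - 1.0 / rm


@dataclass
class PopulationFrequencies:
    """Per-sex frequency state of the deterministic model.

    ``female`` has shape (G, 4): genotype x deposition class, summing to 1.
    ``male`` has shape (G,), summing to 1.  ``female_fraction`` records the
    female share of the most recent zygote cohort (1/2 unless the drive
    biases the sex ratio).
    """

    female: np.ndarray
    male: np.ndarray
    params: DriveParams
    female_fraction: float = 0.5

    @property
    def tables(self) -> ModelTables:
        return ModelTables.build(self.params)

    def validate(self, tol: float = 1e-9) -> None:
        if (self.female < -tol).any() or (self.male < -tol).any():
            raise ValueError("negative frequencies")
        if abs(self.female.sum() - 1.0) > tol or abs(self.male.sum() - 1.0) > tol:
            raise ValueError("frequencies do not sum to 1")

    def allele_freqs(self) -> np.ndarray:
        """Allele frequencies pooled across sexes (equal weights), shape (4,)."""
        t = self.tables
        f = self.female.sum(axis=1) @ t.allele_dosage / 2.0
        m = self.male @ t.allele_dosage / 2.0
        return 0.5 * (f + m)

    def allele_freq_dict(self) -> Dict[Allele, float]:
        freqs = self.allele_freqs()
        return {a: float(freqs[a]) for a in Allele if freqs[a] > 0 or a != Allele.R1}

    @property
    def female_freqs(self) -> Dict[FemaleClass, float]:
        t = self.tables
        return {
            FemaleClass(g, d): float(self.female[i, d.index])
            for i, g in enumerate(t.space)
            for d in DEPOSITION_CLASSES
        }

    @property
    def male_freqs(self) -> Dict[Genotype, float]:
        t = self.tables
        return {g: float(self.male[i]) for i, g in enumerate(t.space)}


def small_introduction(
    params: DriveParams, male_het_fraction: float = 0.01
) -> PopulationFrequencies:
    """Standard release initial condition.

    All females wildtype; W/D heterozygous males at ``male_het_fraction``
    of the male pool (default 1%), the rest wildtype.
    """
    t = ModelTables.build(params)
    G = t.n_genotypes
    female = np.zeros((G, 4))
    female[t.index(WW), 0] = 1.0
    male = np.zeros(G)
    male[t.index(WD)] = male_het_fraction
    male[t.index(WW)] = 1.0 - male_het_fraction
    return PopulationFrequencies(female, male, params)


@functools.lru_cache(maxsize=64)
def _step_tensors(params: DriveParams):
    """Combined cross tensors: female (G,G,G,4) and male (G,G,G)."""
    t = ModelTables.build(params)
    G = t.n_genotypes
    kf = np.zeros((G, G, G, 4))
    for c in range(4):
        mask = (t.dep_index == c).astype(float)
        kf[:, :, :, c] = t.offspring * (mask * (1.0 - t.p_male)[None, :])[:, :, None]
    km = t.offspring * t.p_male[None, :, None]
    return t, kf, km


def step_generation(
    state: PopulationFrequencies, params: Optional[DriveParams] = None
) -> PopulationFrequencies:
    """Advance one generation of random mating with fertility selection.

    The zygote distribution is the fertility-weighted sum over all
    (mother class, father genotype) crosses of the offspring distribution;
    frequencies are renormalised within each sex.
    """
    params = params or state.params
    t, kf, km = _step_tensors(params)
    w_m = (state.female * t.fertility).sum(axis=1)  # fertility-weighted mothers
    if w_m.sum() <= 0.0:
        raise DegeneratePopulationError("all females are sterile")
    female = np.einsum("m,f,mfgc->gc", w_m, state.male, kf)
    male = np.einsum("m,f,mfg->g", w_m, state.male, km)
    tot_f, tot_m = female.sum(), male.sum()
    frac_f = tot_f / (tot_f + tot_m)
    if tot_f <= 0.0:
        raise DegeneratePopulationError("no female offspring produced")
    return PopulationFrequencies(female / tot_f, male / tot_m, params, frac_f)


def genetic_load(
    state: PopulationFrequencies, params: Optional[DriveParams] = None
) -> float:
    """One minus the fertility-weighted sum of female class frequencies."""
    params = params or state.params
    t = ModelTables.build(params)
    return float(1.0 - (state.female * t.fertility).sum())


@dataclass
class EquilibriumResult:
    state: PopulationFrequencies
    allele_freqs: Dict[Allele, float]
    load: float
    generations: int
    converged: bool


def equilibrate(
    params: DriveParams,
    init: Optional[PopulationFrequencies] = None,
    tol: float = 1e-10,
    max_gens: int = 100_000,
) -> EquilibriumResult:
    """Iterate to the genotype-frequency fixed point.

    Convergence is declared when the largest change in pooled allele
    frequency between successive generations falls below ``tol``.  If all
    females become sterile en route (possible only in corner cases), the
    degenerate all-sterile state is reported with load 1.
    """
    state = init if init is not None else small_introduction(params)
    freqs = state.allele_freqs()
    converged = False
    gen = 0
    for gen in range(1, max_gens + 1):
        try:
            state = step_generation(state, params)
        except DegeneratePopulationError:
            return EquilibriumResult(state, state.allele_freq_dict(), 1.0, gen, True)
        new = state.allele_freqs()
        if np.abs(new - freqs).max() < tol:
            freqs = new
            converged = True
            break
        freqs = new
    return EquilibriumResult(
        state, state.allele_freq_dict(), genetic_load(state, params), gen, converged
    )


_AXES = ("somatic", "deposition_equal", "deposition_paternal")


def _with_cost(base: DriveParams, axis: str, x: float) -> DriveParams:
    if axis == "somatic":
        return base.with_(s=x)
    if axis == "deposition_equal":
        return base.with_(d_m=x, d_p=x)
    if axis == "deposition_paternal":
        return base.with_(d_p=x)
    raise ValueError(f"unknown cost axis {axis!r}; expected one of {_AXES}")


def find_cost_threshold(
    base: DriveParams,
    axis: str,
    gp: GrowthParams = GrowthParams(),
    tol: float = 1e-3,
    equilibrate_tol: float = 1e-10,
    max_gens: int = 100_000,
) -> float:
    """Largest cost on ``axis`` for which the drive still predicts extinction.

    Bisects over the cost parameter in [0, 1], comparing the equilibrium
    load (reached from the standard small-introduction initial condition,
    so that in bistable deposition scenarios the discontinuous transition
    between the high- and low-load equilibria is what is detected) with the
    critical load ``L_c`` from the life-history parameters.
    """
    lc = critical_load(intrinsic_growth_rate(gp))

    def meets(x: float) -> bool:
        params = _with_cost(base, axis, x)
        res = equilibrate(params, tol=equilibrate_tol, max_gens=max_gens)
        return res.load >= lc

    if not meets(0.0):
        raise NoCrossingError("equilibrium load below critical load at zero cost")
    if meets(1.0):
        raise NoCrossingError("equilibrium load never falls below critical load")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if meets(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def run_trajectory(
    params: DriveParams,
    generations: int,
    init: Optional[PopulationFrequencies] = None,
) -> pd.DataFrame:
    """Per-generation pooled allele frequencies and load.

    Returns a DataFrame with columns
    ``generation, freq_W, freq_D, freq_R2, freq_R1, load``.
    """
    state = init if init is not None else small_introduction(params)
    rows = []
    for gen in range(generations + 1):
        freqs = state.allele_freqs()
        rows.append(
            {
                "generation": gen,
                "freq_W": freqs[Allele.W],
                "freq_D": freqs[Allele.D],
                "freq_R2": freqs[Allele.R2],
                "freq_R1": freqs[Allele.R1] if len(freqs) > 3 else 0.0,
                "load": genetic_load(state, params),
            }
        )
        if gen < generations:
            try:
                state = step_generation(state, params)
            except DegeneratePopulationError:
                break
    return pd.DataFrame(rows)


def simulate_r1_invasion(
    params: DriveParams,
    r1_init: Optional[float] = None,
    generations: int = 1000,
    male_het_fraction: float = 0.01,
) -> pd.DataFrame:
    """Trajectory of a drive release into a population seeding rare r1 alleles.

    Functional-resistant r1 alleles (fitness equal to wildtype, immune to
    homing) start at allele frequency ``r1_init`` in both sexes, carried by
    W/R1 heterozygotes.  ``r1_init=0`` reduces to the standard model run in
    the extended genotype space.
    """
    if r1_init is None:
        r1_init = params.r1_init_freq
    if not 0.0 <= r1_init < 1.0:
        raise ValueError("r1_init must be in [0, 1)")
    p = params.with_(r1_enabled=True)
    state = small_introduction(p, male_het_fraction)
    if r1_init > 0.0:
        t = state.tables
        iww, iwr1 = t.index(WW), t.index(WR1)
        het = 2.0 * r1_init  # W/R1 genotype frequency giving allele freq r1_init
        state.female[iww, 0] -= het
        state.female[iwr1, 0] += het
        state.male[iww] -= het  # r1 carriers drawn from the wildtype male pool
        state.male[iwr1] += het
    return run_trajectory(p, generations, init=state)
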