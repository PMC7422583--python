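"""Inheritance architecture of a female-sterility homing gene drive.

Four alleles can segregate at the target locus (the mosquito *doublesex*
gene): the wildtype allele ``W``, the homing (drive) allele ``D``, a
non-functional homing-resistant allele ``R2``, and — optionally — a
functional homing-resistant allele ``R1``.  Homing converts ``W`` to ``D``
in the germline of W/D heterozygotes of both sexes; failed homing events
can leave behind ``R2`` alleles (end-joining repair).  Females without at
least one functional allele (``W`` or ``R1``) are sterile.  The drive may
additionally carry fitness costs from somatic nuclease expression, from
parental deposition of nuclease protein into the zygote, and a paternally
expressed male bias in offspring sex ratio.

This module defines the allele/genotype types, the per-genotype gamete
distributions, the cross (offspring) distributions, and the female
fertility model shared by the deterministic and spatial simulators.  All
distributions are exact (no sampling happens here).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "Allele",
    "Sex",
    "Genotype",
    "DriveParams",
    "DepositionClass",
    "FemaleClass",
    "gamete_distribution",
    "offspring_distribution",
    "female_fertility",
    "is_phenotypic_female",
    "genotype_space",
    "ModelTables",
    "GENOTYPES",
    "GENOTYPES_R1",
    "WW",
    "WD",
    "WR2",
    "DD",
    "DR2",
    "R2R2",
]


class Allele(IntEnum):
    """Alleles at the *doublesex* locus."""

    W = 0  # wildtype (functional, homable)
    D = 1  # drive / homing allele
    R2 = 2  # non-functional, homing-resistant
    R1 = 3  # functional, homing-resistant (optional extension)


class Sex(IntEnum):
    FEMALE = 0
    MALE = 1


@dataclass(frozen=True, order=True)
class Genotype:
    """An unordered diploid genotype; the allele pair is kept sorted."""

    alleles: Tuple[Allele, Allele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a > b:
            object.__setattr__(self, "alleles", (b, a))

    def count(self, allele: Allele) -> int:
        return sum(1 for a in self.alleles if a == allele)

    @property
    def carries_drive(self) -> bool:
        return Allele.D in self.alleles

    @property
    def has_functional(self) -> bool:
        """Carries at least one allele producing functional dsx product."""
        return Allele.W in self.alleles or Allele.R1 in self.alleles

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "/".join(a.name for a in self.alleles)


def _g(a: Allele, b: Allele) -> Genotype:
    return Genotype((a, b))


WW = _g(Allele.W, Allele.W)
WD = _g(Allele.W, Allele.D)
WR2 = _g(Allele.W, Allele.R2)
DD = _g(Allele.D, Allele.D)
DR2 = _g(Allele.D, Allele.R2)
R2R2 = _g(Allele.R2, Allele.R2)
WR1 = _g(Allele.W, Allele.R1)
DR1 = _g(Allele.D, Allele.R1)
R1R2 = _g(Allele.R2, Allele.R1)
R1R1 = _g(Allele.R1, Allele.R1)

#: The 6 genotypes of the standard model (no functional resistance).
GENOTYPES: List[Genotype] = [WW, WD, WR2, DD, DR2, R2R2]

#: The 10 genotypes of the r1 extension.
GENOTYPES_R1: List[Genotype] = GENOTYPES + [WR1, DR1, R1R2, R1R1]


def genotype_space(r1_enabled: bool = False) -> List[Genotype]:
    """Genotype list for the model variant (6 without r1, 10 with)."""
    return GENOTYPES_R1 if r1_enabled else GENOTYPES


@dataclass(frozen=True)
class DriveParams:
    """Transgene parameters.

    Parameters
    ----------
    e
        Homing probability per wildtype allele in a W/D germline (both
        sexes).  Default 0.95.
    rho
        Fraction of non-homed (cleaved, end-joining repaired) alleles that
        become non-functional resistant (r2) alleles.  Default 0.5.
    s
        Somatic-expression fertility cost to W/D heterozygous females.
    d_m, d_p
        Maternal / paternal deposition fertility costs: the fractional
        fertility loss of any female whose mother / inseminating father
        carried a drive allele, independent of her own genotype.
    m
        Paternal male-bias extent: offspring of drive-carrying fathers are
        male with probability (1 + m) / 2, so m=0 is an even sex ratio and
        m=1 gives all-male progeny.
    r1_enabled
        Include the functional-resistant r1 allele in the genotype space.
    r1_init_freq
        Standing allele frequency at which rare r1 alleles are seeded when
        the extension is active.
    """

    e: float = 0.95
    rho: float = 0.5
    s: float = 0.0
    d_m: float = 0.0
    d_p: float = 0.0
    m: float = 0.0
    r1_enabled: bool = False
    r1_init_freq: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("e", "rho", "s", "d_m", "d_p", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"DriveParams.{name}={v!r} outside [0, 1]")
        if not 0.0 <= self.r1_init_freq < 1.0:
            raise ValueError("r1_init_freq must be in [0, 1)")

    # flat serialisation block used by scenario configs
    _KEYS = {
        "homing": "e",
        "r2_fraction": "rho",
        "somatic_cost": "s",
        "maternal_deposition": "d_m",
        "paternal_deposition": "d_p",
        "male_bias": "m",
        "r1_enabled": "r1_enabled",
        "r1_init_freq": "r1_init_freq",
    }

    def to_dict(self) -> Dict[str, float]:
        return {k: getattr(self, attr) for k, attr in self._KEYS.items()}

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "DriveParams":
        kwargs = {attr: d[k] for k, attr in cls._KEYS.items() if k in d}
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown drive parameter keys: {sorted(unknown)}")
        return cls(**kwargs)

    def with_(self, **kwargs) -> "DriveParams":
        return replace(self, **kwargs)


@dataclass(frozen=True, order=True)
class DepositionClass:
    """Parental drive exposure, fixed at conception.

    ``maternal_exposed`` / ``paternal_exposed`` record whether the mother /
    father carried at least one drive allele (and hence may have deposited
    nuclease protein in the egg or sperm).
    """

    maternal_exposed: bool = False
    paternal_exposed: bool = False

    @property
    def index(self) -> int:
        return int(self.maternal_exposed) + 2 * int(self.paternal_exposed)

    @classmethod
    def from_index(cls, i: int) -> "DepositionClass":
        return cls(bool(i & 1), bool(i & 2))


#: All four deposition classes, ordered by :attr:`DepositionClass.index`.
DEPOSITION_CLASSES = [DepositionClass.from_index(i) for i in range(4)]


@dataclass(frozen=True, order=True)
class FemaleClass:
    """Adult female state relevant to fertility: genotype x parental exposure."""

    genotype: Genotype
    deposition: DepositionClass = field(default_factory=DepositionClass)


def gamete_distribution(g: Genotype, params: DriveParams) -> Dict[Allele, float]:
    """Gamete allele distribution of genotype ``g``.

    Homing occurs only in W/D germlines (of either sex): prior to meiosis
    each wildtype allele is converted to drive with probability ``e``;
    failed conversions become r2 with probability ``rho`` and remain
    wildtype otherwise, giving gamete fractions
    ``D:(1+e)/2, W:(1-e)(1-rho)/2, R2:(1-e)rho/2``.  Every other genotype
    segregates 50:50 (r1 and r2 alleles cannot be cut).
    """
    if g == WD:
        e, rho = params.e, params.rho
        dist = {
            Allele.D: (1.0 + e) / 2.0,
            Allele.W: (1.0 - e) * (1.0 - rho) / 2.0,
            Allele.R2: (1.0 - e) * rho / 2.0,
        }
        return {a: p for a, p in dist.items() if p > 0.0}
    a, b = g.alleles
    if a == b:
        return {a: 1.0}
    return {a: 0.5, b: 0.5}


def female_fertility(fc: FemaleClass, params: DriveParams) -> float:
    """Relative fertility (eggs laid per day vs wildtype) of a female class.

    Females lacking any functional allele are completely sterile.  W/D
    heterozygotes pay the somatic-expression cost ``s`` (D/R1 females do
    not: the r1 allele is resistant to cleavage, so somatic nuclease
    activity leaves their functional copy intact).  Deposition costs
    multiply in: ``(1-d_m)`` if the mother carried the drive and
    ``(1-d_p)`` if the father did, independently.
    """
    g = fc.genotype
    if not g.has_functional:
        return 0.0
    base = 1.0 - params.s if g == WD else 1.0
    if fc.deposition.maternal_exposed:
        base *= 1.0 - params.d_m
    if fc.deposition.paternal_exposed:
        base *= 1.0 - params.d_p
    return min(max(base, 0.0), 1.0)


def is_phenotypic_female(g: Genotype) -> bool:
    """Whether an adult female of genotype ``g`` is a biting female.

    Females with no functional dsx product from either a wildtype or an r1
    allele develop an intersex phenotype; drive homozygotes and drive/r2
    heterozygotes are excluded from suppression metrics.  r2/r2 females
    (vanishingly rare) are counted.
    """
    return g not in (DD, DR2)


def _pair_index(space: List[Genotype]) -> Dict[Tuple[Allele, Allele], int]:
    idx = {}
    for i, g in enumerate(space):
        a, b = g.alleles
        idx[(a, b)] = i
        idx[(b, a)] = i
    return idx


@dataclass(frozen=True)
class ModelTables:
    """Dense numeric tables for fast iteration/simulation.

    Shapes use ``G`` genotypes (6, or 10 with r1) and 4 deposition classes
    indexed by :attr:`DepositionClass.index`.
    """

    space: Tuple[Genotype, ...]
    gametes: np.ndarray  # (G, 4) gamete allele fractions
    offspring: np.ndarray  # (G, G, G): mother, father -> offspring genotype
    p_male: np.ndarray  # (G,) offspring male probability by father genotype
    dep_index: np.ndarray  # (G, G) deposition class of offspring by parents
    fertility: np.ndarray  # (G, 4) female fertility by genotype x class
    phenotypic: np.ndarray  # (G,) bool, biting-female genotypes
    carries_d: np.ndarray  # (G,) bool
    allele_dosage: np.ndarray  # (G, 4) allele copies per genotype

    @classmethod
    @functools.lru_cache(maxsize=64)
    def build(cls, params: DriveParams) -> "ModelTables":
        space = tuple(genotype_space(params.r1_enabled))
        G = len(space)
        gam = np.zeros((G, 4))
        for i, g in enumerate(space):
            for a, p in gamete_distribution(g, params).items():
                gam[i, a] = p
        pair = _pair_index(list(space))
        off = np.zeros((G, G, G))
        for i in range(G):
            for j in range(G):
                for a in Allele:
                    if gam[i, a] == 0.0:
                        continue
                    for b in Allele:
                        if gam[j, b] == 0.0:
                            continue
                        off[i, j, pair[(a, b)]] += gam[i, a] * gam[j, b]
        carries_d = np.array([g.carries_drive for g in space])
        p_male = np.where(carries_d, (1.0 + params.m) / 2.0, 0.5)
        dep = (carries_d[:, None].astype(int)
               + 2 * carries_d[None, :].astype(int))
        fert = np.array(
            [
                [female_fertility(FemaleClass(g, d), params) for d in DEPOSITION_CLASSES]
                for g in space
            ]
        )
        phen = np.array([is_phenotypic_female(g) for g in space])
        dosage = np.zeros((G, 4))
        for i, g in enumerate(space):
            for a in g.alleles:
                dosage[i, a] += 1.0
        return cls(space, gam, off, p_male, dep, fert, phen, carries_d, dosage)

    @property
    def n_genotypes(self) -> int:
        return len(self.space)

    def index(self, g: Genotype) -> int:
        return self.space.index(g)


def offspring_distribution(
    mother: Genotype, father: Genotype, params: DriveParams
) -> Dict[Tuple[Genotype, Sex, DepositionClass], float]:
    """Joint offspring distribution over (genotype, sex, deposition class).

    The genotype marginal is the product of the parental gamete
    distributions; sex is male with probability ``(1+m)/2`` when the father
    carries a drive allele (else 1/2); the deposition class is the same for
    every offspring of a cross, set by which parents carry the drive.
    """
    gm = gamete_distribution(mother, params)
    gf = gamete_distribution(father, params)
    p_male = (1.0 + params.m) / 2.0 if father.carries_drive else 0.5
    dep = DepositionClass(mother.carries_drive, father.carries_drive)
    out: Dict[Tuple[Genotype, Sex, DepositionClass], float] = {}
    for a, pa in gm.items():
        for b, pb in gf.items():
            g = Genotype((a, b))
            for sex, ps in ((Sex.FEMALE, 1.0 - p_male), (Sex.MALE, p_male)):
                if ps == 0.0:
                    continue
                key = (g, sex, dep)
                out[key] = out.get(key, 0.0) + pa * pb * ps
    return out
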