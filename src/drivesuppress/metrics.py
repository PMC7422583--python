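"""Release strategies and suppression metrics.

Suppression at a date is one minus the ratio of phenotypic (biting)
females in a release run to the corresponding count in a paired
no-release reference run that shares the same landscape and rainfall.
Because both series cycle seasonally, headline numbers ("suppression
after N years") use trailing one-year means of both series to damp
seasonal phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .genetics import Genotype, WD
from .landscape import Landscape
from .spatial import Recorder, ReleaseEvent

__all__ = [
    "select_release_sites",
    "annual_release_schedule",
    "suppression_series",
    "suppression_after",
    "seasonality_index",
    "connectivity",
]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def select_release_sites(
    landscape: Landscape,
    fraction: float,
    strategy: str = "random",
    year: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Choose release sites for one year.

    ``random`` draws a fresh uniform sample of ``round(fraction * n)``
    sites each year (half-away-from-zero rounding); ``grid`` picks the
    sites nearest to the nodes of a regular lattice spanning the landscape
    extent, the same set every year.  Returns site ids.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(landscape)
    k = min(max(_round_half_away(fraction * n), 1), n)
    ids = landscape.ids
    if strategy == "random":
        if rng is None:
            raise ValueError("random strategy requires an rng")
        return np.sort(rng.choice(ids, size=k, replace=False))
    if strategy == "grid":
        xmin, xmax, ymin, ymax = landscape.extent
        w, h = max(xmax - xmin, 1e-9), max(ymax - ymin, 1e-9)
        nx = max(1, _round_half_away(np.sqrt(k * w / h)))
        ny = int(np.ceil(k / nx))
        gx = xmin + (np.arange(nx) + 0.5) * w / nx
        gy = ymin + (np.arange(ny) + 0.5) * h / ny
        nodes = np.array([[x, y] for y in gy for x in gx])[:k]
        tree = cKDTree(landscape.coords)
        chosen: List[int] = []
        taken = set()
        for node in nodes:
            # nearest site not already chosen
            for kk in range(1, n + 1):
                _, idx = tree.query(node, k=kk)
                cand = int(np.atleast_1d(idx)[-1])
                if cand not in taken:
                    taken.add(cand)
                    chosen.append(cand)
                    break
        return np.sort(ids[np.array(chosen, dtype=int)])
    raise ValueError(f"unknown strategy {strategy!r}")


def annual_release_schedule(
    landscape: Landscape,
    years: int,
    fraction: float = 0.01,
    n_males: int = 5000,
    strategy: str = "random",
    seed: int = 0,
    day_of_year: int = 180,
    genotype: Genotype = WD,
) -> List[ReleaseEvent]:
    """Yearly releases of drive-heterozygous males.

    Defaults follow the study design: 5000 males at 1% of sites per year,
    sites drawn independently each year (or fixed on a grid), released
    mid wet season.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    events: List[ReleaseEvent] = []
    for year in range(years):
        sites = select_release_sites(landscape, fraction, strategy, year, rng)
        day = year * 365 + day_of_year
        events.extend(ReleaseEvent(day, int(s), n_males, genotype) for s in sites)
    return events


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    cs = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x], axis=0), axis=0)
    n = x.shape[0]
    lo = np.maximum(np.arange(n) - window + 1, 0)
    width = (np.arange(n) - lo + 1).astype(float)
    return (cs[np.arange(n) + 1] - cs[lo]) / width.reshape((-1,) + (1,) * (x.ndim - 1))


def suppression_series(
    treatment: Recorder,
    reference: Recorder,
    scope: str = "all",
    trailing_window: int = 365,
) -> np.ndarray:
    """Per-day suppression of phenotypic females vs the paired reference.

    ``scope='all'`` pools all sites (returns shape ``(n_days,)``);
    ``scope='per_site'`` divides site-wise (shape ``(n_days, n_sites)``).
    Both series are smoothed with a trailing mean over ``trailing_window``
    days (1 disables smoothing).  Days (or site-days) where the reference
    is zero are NaN — undefined, never fabricated.
    """
    if treatment.phenotypic_females.shape != reference.phenotypic_females.shape:
        raise ValueError("recorders cover different days/sites")
    if not np.array_equal(treatment.site_ids, reference.site_ids):
        raise ValueError("recorders cover different sites")
    if scope == "all":
        t = treatment.phenotypic_females.sum(axis=1).astype(float)
        r = reference.phenotypic_females.sum(axis=1).astype(float)
    elif scope == "per_site":
        t = treatment.phenotypic_females.astype(float)
        r = reference.phenotypic_females.astype(float)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if trailing_window > 1:
        t = _trailing_mean(t, trailing_window)
        r = _trailing_mean(r, trailing_window)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(r > 0, 1.0 - t / r, np.nan)


def suppression_after(
    treatment: Recorder, reference: Recorder, years: float
) -> float:
    """Suppression at ``years`` after releases begin (trailing 1-year mean)."""
    day = min(int(round(years * 365)) - 1, treatment.phenotypic_females.shape[0] - 1)
    return float(suppression_series(treatment, reference)[day])


def seasonality_index(reference: Recorder) -> pd.DataFrame:
    """Per-site seasonality: mean yearly minimum population in the reference.

    Lower values mean stronger seasonal bottlenecks.  Returns a frame with
    columns ``site_id, index, tertile`` where tertile 0 groups the most
    seasonal third of sites (lowest yearly minima) and 2 the least.
    """
    n_days = reference.total_adults.shape[0]
    n_years = n_days // 365
    if n_years < 1:
        raise ValueError("reference must span at least one full year")
    pop = reference.total_adults[: n_years * 365].reshape(n_years, 365, -1)
    idx = pop.min(axis=1).mean(axis=0)
    order = np.argsort(np.argsort(idx, kind="stable"), kind="stable")
    tertile = (order * 3) // len(idx)
    return pd.DataFrame(
        {"site_id": reference.site_ids, "index": idx, "tertile": tertile}
    )


def connectivity(landscape: Landscape, radius: float = 12.0) -> pd.DataFrame:
    """Number of neighbouring settlements within ``radius`` km of each site."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(landscape.coords)
    counts = np.array(
        [len(tree.query_ball_point(c, radius)) - 1 for c in landscape.coords]
    )
    return pd.DataFrame({"site_id": landscape.ids, "n_neighbors": counts})
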