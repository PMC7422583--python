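"""Tests of the stochastic spatial simulator."""

import numpy as np
import pytest
from scipy import stats

from drivesuppress.deterministic import GrowthParams
from drivesuppress.genetics import Allele, DriveParams, ModelTables, WD, WW
from drivesuppress.landscape import Landscape, RainfallSeries, Site
from drivesuppress.spatial import (
    AestivationParams,
    ReleaseEvent,
    SimConfig,
    SimState,
    _Env,
    carrying_capacity,
    density_dependent_juvenile_survival,
    release_males,
    run_simulation,
    site_state,
    step_day,
)


def one_site_env(config, permanent_water=1.0, days=365 * 4, river=0.0):
    ls = Landscape([Site(0, 0.0, 0.0, permanent_water, river)])
    rain = RainfallSeries(np.zeros((days, 1)), ls.ids)
    return ls, rain, _Env(config, ls, rain)


def test_carrying_capacity():
    cfg = SimConfig(density_alpha0=100.0, rain_coef=0.5)
    assert carrying_capacity(0.0, 0.0, [0.0] * 14, cfg) == 0.0
    a1 = carrying_capacity(1.0, 0.5, [4.0] * 14, cfg)
    a2 = carrying_capacity(1.0, 0.5, [4.0] * 14, SimConfig(density_alpha0=200.0, rain_coef=0.5))
    assert a2 == pytest.approx(2 * a1)
    # permanent-water-only site: capacity is constant over a rainless window
    vals = {carrying_capacity(1.0, 0.0, [0.0] * w, cfg) for w in (1, 7, 14)}
    assert vals == {100.0}
    # permanent water is discounted outside permanent_water dry-season mode
    aest_cfg = SimConfig(density_alpha0=100.0, rain_coef=0.5, dry_season_mode="aestivation")
    assert carrying_capacity(1.0, 0.0, [0.0] * 14, aest_cfg) == 0.0
    with pytest.raises(ValueError):
        carrying_capacity(1.0, 0.0, [-1.0], cfg)


def test_density_dependent_survival():
    assert density_dependent_juvenile_survival(0, 100.0) == pytest.approx(0.95)
    assert density_dependent_juvenile_survival(100, 100.0) == pytest.approx(0.95 / 2)
    assert density_dependent_juvenile_survival(50, 0.0) == 0.0
    js = [density_dependent_juvenile_survival(j, 100.0) for j in (0, 10, 100, 1000)]
    assert all(a > b for a, b in zip(js, js[1:]))


def test_empty_site_stays_empty():
    cfg = SimConfig(seed=0)
    _, _, env = one_site_env(cfg)
    state = SimState(1, ModelTables.build(cfg.drive))
    rng = np.random.default_rng(0)
    for day in range(30):
        step_day(state, cfg, env, day, rng)
    assert state.total_adults()[0] == 0
    assert state.total_juveniles()[0] == 0


def test_release_males():
    cfg = SimConfig()
    state = SimState(1, ModelTables.build(cfg.drive))
    release_males(state, 0, 0)
    assert state.males.sum() == 0
    release_males(state, 0, 5000)
    assert state.males[0, state.tables.index(WD)] == 5000
    with pytest.raises(ValueError):
        release_males(state, 0, -1)
    view = site_state(state, 0)
    assert view.adult_males.sum() == 5000


def test_first_generation_offspring_match_cross_distribution():
    """Eggs of WW mothers mated to W/D fathers follow the analytic cross
    distribution over (genotype, sex) — checked with a chi-square test."""
    from drivesuppress.genetics import offspring_distribution, Sex

    cfg = SimConfig(seed=0, density_alpha0=1e7)
    _, _, env = one_site_env(cfg)
    t = ModelTables.build(cfg.drive)
    state = SimState(1, t)
    iww, iwd = t.index(WW), t.index(WD)
    state.mated[0, iww, 0, iwd] = 5000
    state.males[0, iwd] = 100  # mates only; composition fixed already
    rng = np.random.default_rng(42)
    step_day(state, cfg, env, 0, rng)
    counts = []
    expected_probs = []
    dist = offspring_distribution(WW, WD, cfg.drive)
    for (g, sex, dep), p in sorted(dist.items()):
        gi = t.index(g)
        if sex == Sex.FEMALE:
            counts.append(state.juv_f[0, 0, gi, dep.index])
        else:
            counts.append(state.juv_m[0, 0, gi])
        expected_probs.append(p)
    counts = np.array(counts, dtype=float)
    total = counts.sum()
    assert total > 10_000  # ~9 eggs x ~0.875 x 5000 mothers
    res = stats.chisquare(counts, total * np.array(expected_probs))
    assert res.pvalue > 1e-3


def test_no_dispersal_keeps_sites_independent():
    ls = Landscape([Site(0, 0.0, 0.0, 1.0), Site(1, 5.0, 0.0, 1.0)])
    rain = RainfallSeries(np.zeros((365 * 3, 2)), ls.ids)
    cfg = SimConfig(seed=1, dispersal_rate=0.0, burnin_years=1)
    rec = run_simulation(cfg, ls, rain, [ReleaseEvent(0, 0, 500)], years=2)
    # drive alleles never appear at the unreleased site
    assert rec.allele_counts[:, 1, Allele.D].sum() == 0
    assert rec.allele_counts[:, 0, Allele.D].sum() > 0


def test_dispersal_spreads_the_drive():
    ls = Landscape([Site(0, 0.0, 0.0, 1.0), Site(1, 5.0, 0.0, 1.0)])
    rain = RainfallSeries(np.zeros((365 * 3, 2)), ls.ids)
    cfg = SimConfig(seed=1, dispersal_rate=0.01, burnin_years=1)
    rec = run_simulation(cfg, ls, rain, [ReleaseEvent(0, 0, 500)], years=2)
    assert rec.allele_counts[:, 1, Allele.D].sum() > 0


def test_runs_are_bit_reproducible():
    ls = Landscape([Site(0, 0.0, 0.0, 0.5), Site(1, 3.0, 0.0, 0.5)])
    rain = RainfallSeries(np.full((365 * 2, 2), 0.0), ls.ids)
    cfg = SimConfig(seed=7, burnin_years=1)
    rel = [ReleaseEvent(10, 0, 200)]
    a = run_simulation(cfg, ls, rain, rel, years=1)
    b = run_simulation(cfg, ls, rain, rel, years=1)
    np.testing.assert_array_equal(a.phenotypic_females, b.phenotypic_females)
    np.testing.assert_array_equal(a.allele_counts, b.allele_counts)
    c = run_simulation(SimConfig(seed=8, burnin_years=1), ls, rain, rel, years=1)
    assert (a.total_adults != c.total_adults).any()


def test_isolated_wildtype_site_persists_two_years():
    """Default capacity keeps an isolated settlement from stochastic
    extinction: none of 20 replicate two-year runs dies out."""
    extinct = 0
    for seed in range(20):
        cfg = SimConfig(seed=seed, burnin_years=1)
        ls, rain, _ = one_site_env(cfg, days=365 * 3)
        rec = run_simulation(cfg, ls, rain, None, years=2)
        if (rec.total_adults[:, 0] == 0).any():
            extinct += 1
    assert extinct == 0


def test_equilibrium_population_scales_with_capacity():
    means = []
    alphas = [2000.0, 4000.0, 8000.0]
    for a0 in alphas:
        cfg = SimConfig(seed=3, burnin_years=1, density_alpha0=a0)
        ls, rain, _ = one_site_env(cfg, days=365 * 2)
        rec = run_simulation(cfg, ls, rain, None, years=1)
        means.append(rec.total_adults[:, 0].mean())
    r1 = means[1] / means[0]
    r2 = means[2] / means[1]
    assert r1 == pytest.approx(2.0, rel=0.15)
    assert r2 == pytest.approx(2.0, rel=0.15)


def test_aestivating_females_lay_no_eggs_and_skip_mortality():
    cfg = SimConfig(
        seed=0,
        dry_season_mode="aestivation",
        aestivation=AestivationParams(
            entry_fraction=1.0, mortality_multiplier=0.0, entry_day=0, exit_day=200
        ),
    )
    _, _, env = one_site_env(cfg, permanent_water=0.0, river=1.0)
    t = ModelTables.build(cfg.drive)
    state = SimState(1, t)
    iww = t.index(WW)
    state.aest[0, iww, 0, iww] = 500
    rng = np.random.default_rng(1)
    for day in range(5, 25):  # dry-season days, no entry/exit crossing
        step_day(state, cfg, env, day, rng)
    assert state.aest[0, iww, 0, iww] == 500  # zero dormant mortality
    assert state.total_juveniles()[0] == 0  # no eggs laid while dormant
    # wake-up: dormant females return to the mated pool and resume laying
    step_day(state, cfg, env, 200, rng)
    assert state.aest.sum() == 0
    assert state.mated.sum() > 0


def test_aestivation_entry_requires_dry_conditions():
    cfg = SimConfig(
        seed=0,
        dry_season_mode="aestivation",
        aestivation=AestivationParams(entry_fraction=1.0, entry_day=3, exit_day=200,
                                      dry_threshold_mm=1.0),
    )
    ls = Landscape([Site(0, 0.0, 0.0, 0.0, 1.0)])
    rain = RainfallSeries(np.full((30, 1), 5.0), ls.ids)  # wet: above threshold
    env = _Env(cfg, ls, rain)
    t = ModelTables.build(cfg.drive)
    state = SimState(1, t)
    state.mated[0, t.index(WW), 0, t.index(WW)] = 1000
    rng = np.random.default_rng(2)
    step_day(state, cfg, env, 3, rng)
    assert state.aest.sum() == 0  # site is wet on entry day: nobody dorms


def test_counts_stay_nonnegative_through_a_seasonal_run():
    ls = Landscape([Site(0, 0.0, 0.0, 0.1), Site(1, 4.0, 2.0, 0.1)])
    rain_year = np.concatenate([np.zeros(180), np.full(120, 8.0), np.zeros(65)])
    rain = RainfallSeries(np.tile(rain_year[:, None], (3, 2)), ls.ids)
    cfg = SimConfig(seed=5, burnin_years=1)
    rec = run_simulation(cfg, ls, rain, [ReleaseEvent(0, 0, 1000)], years=2)
    assert (rec.phenotypic_females >= 0).all()
    assert (rec.total_adults >= 0).all()
    assert (rec.phenotypic_females <= rec.total_females).all()
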