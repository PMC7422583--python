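# Methods

## Inheritance architecture

Drive conversion is modelled as occurring in the germline before meiosis:
in a W/D individual each wildtype allele is homed with probability `e`;
a non-homed allele becomes a non-functional resistant allele (r2) with
probability `ρ` and stays wildtype otherwise. Gamete fractions from W/D
parents are therefore `(1+e)/2 : (1−e)(1−ρ)/2 : (1−e)ρ/2` for D : W : R2.
A consequence of this parameterisation is that `ρ` still converts
wildtype alleles in W/D germlines when `e = 0`; a fully inert drive needs
`e = 0, ρ = 0`. All other genotypes segregate 50:50 — both resistant
alleles are immune to cleavage, so D/R2 and D/R1 germlines do not home.

Female fertility is multiplicative over three factors:

- genotype: 0 without a functional allele (W or R1); `1 − s` for W/D
  (somatic nuclease expression damages the one functional, cleavable
  copy); 1 otherwise. D/R1 females pay no somatic cost because their
  functional allele is cleavage-resistant.
- maternal deposition: `× (1 − d_m)` if the mother carried the drive;
- paternal deposition: `× (1 − d_p)` if the father carried the drive.

When both parents carry the drive the two deposition costs combine
multiplicatively — the minimal independence assumption; the printed
equal-cost transition at 0.813 is reproduced under it. Deposition and
male bias are triggered by *carrying* at least one drive allele; dosage
(het vs hom parent) is not distinguished. Offspring of drive-carrying
fathers are male with probability `(1+m)/2`, so `m` spans "no bias" (0)
to "all-male progeny" (1); a reported 93% male bias corresponds to
`m = 0.86`.

Phenotypic ("biting") females exclude the dsx-null genotypes D/D and
D/R2. R2/R2 females are counted as phenotypic: they are vanishingly rare
at equilibrium and the suppression metric excludes only the two drive
genotypes.

## Deterministic model

State: frequencies of female classes (genotype × parental-exposure
class) and of male genotypes, each normalised within its sex; discrete
non-overlapping generations; random mating with male mating success
independent of genotype. The zygote distribution is the
fertility-weighted sum over all crosses of the exact offspring
distribution. Equilibria are found by iteration from the standard
introduction — W/D males at 1% of the male pool, all females wildtype —
until the pooled allele-frequency change falls below 1e−10 (cap 100,000
generations; the cap is never reached in the scanned regimes, although
runs near the deposition transition need tens of thousands of
generations because convergence slows critically there).

Genetic load is `L = 1 − Σ f_i F*_i`. The intrinsic growth rate uses the
shared life history (juvenile survival 0.95/day over 10 days, 0.875
survival to mated female, 9 eggs/day, 8-day adult life expectancy, even
sex ratio), giving `R_m ≈ 18.9` and critical load `L_c = 0.947`.
Extinction-cost thresholds are located by bisection (resolution 1e−3) of
the indicator `equilibrium load ≥ L_c` over the cost axis, always
equilibrating from the standard small introduction so that in the
deposition regime the detected transition is the one reached from a
release. Near the equal-deposition transition (0.8136 at this
resolution) the system is genuinely bistable slightly *above* the
small-introduction threshold: a drive-dominated initial condition still
reaches the high-load branch up to ≈ 0.83.

The r1 extension adds a functional, cleavage-immune allele with wildtype
fitness, seeded as W/R1 heterozygotes at a configurable allele frequency
(default 1e−8). Because the model is deterministic, a weakly suppressing
drive is never *lost*, only driven to arbitrarily low frequency, so the
terminal population always retains some wildtype alongside r1; stochastic
loss of the drive before r1 fixation is a finite-population effect
outside this model's scope.

## Synthetic landscape and rainfall

Settlements are placed either uniformly (clustering 0) or by a
Thomas-like cluster process (expected `1 + clustering` settlements per
cluster, Gaussian scatter, default 2 km). Every site receives a small
lognormal permanent-water score (mean 0.05) and a random tenth of sites
a river/lake score of order 1. Rainfall is a raised-cosine wet-season
envelope (default mid-point day 227, length 150 days, 800 mm/yr —
Sudano-Sahelian values), with gamma-distributed daily rain in season,
lognormal interannual variation (CV 0.15), and a latitudinal gradient
that shortens northern wet seasons (0.5 day/km in the bundled seasonal
test landscape, spanning near-year-round to strongly seasonal regimes
over 100 km). The generators are pure functions of their parameters and
seed, and both files round-trip exactly through CSV (`%.17g` on write,
round-trip float parsing on read).

What the synthetic environment does *not* emulate: real settlement-size
distributions, spatially correlated rainfall anomalies, and the empirical
rainfall-to-larval-habitat transfer function, which is why the spatial
tests assert structural properties (ordering, colonisation–extinction,
conservation laws) rather than the full-scale headline suppression
percentages, which depend on the real 42,360-site geography.

## Spatial simulator

Daily event order (fixed, pinned by tests): (1) density-dependent
juvenile survival `0.95/(1 + J/α)` (Beverton–Holt; `α` from permanent
water + river/lake + 0.25 × trailing 14-day mean rainfall, all scaled by
`density_alpha0 = 10⁴`), ageing, eclosion of the day-10 cohort; (2)
adult survival at 0.875/day; (3) aestivation entry/exit; (4) dispersal
(0.005 movements/mosquito/day, exponential kernel with 4 km scale among
sites within 12 km; would-be movers at isolated sites stay); (5)
long-distance wind redistribution; (6) mating — females that eclosed on
an earlier day mate once, mate drawn proportional to current male
counts; (7) oviposition — each mated, non-dormant female lays
Poisson(9 × fertility) eggs whose genotype/sex follow the exact cross
distribution, with sex and parental-exposure class fixed at the egg
stage. Eclosing adults join the pools after mating, so a female's first
possible mating falls on her second adult day, matching the 0.875
"survival to mated female" factor in `R_m`.

With `density_alpha0 = 10⁴` a permanent-water-only site equilibrates
around ~260 adults; an isolated such site survives two simulated years
in 20/20 replicates, while dry-season bottlenecks on the seasonal
landscape still reach the tens of adults where drift disrupts the drive.
Site populations scale linearly with `α`.

Dry-season mechanisms: in `permanent_water` mode every site keeps its
permanent score year-round. In `aestivation` mode permanent scores are
zeroed and a configurable fraction (default 0.5) of mated females at
sites below 1 mm/day trailing rain become dormant on day 335, lay no
eggs, die at mortality × 0.2, and wake on day 160. In `long_distance`
mode a fraction (default 0.1) of adult females is displaced once a year
(day 160) by a wind vector (default 30 km east) plus 15 km isotropic
noise, landing at the nearest settlement.

One demographic RNG stream derives from the config seed; landscape and
rainfall carry their own seeds, so paired release/reference runs share
the environment but not demographic noise. Runs are bit-reproducible.

## Suppression metrics

Suppression at a date is `1 − treatment/reference` phenotypic-female
counts, by default smoothed with trailing one-year means of both series
(the averaging convention is a package choice; it is configurable and
window 1 disables it). Reference zeros give NaN. Annual releases default
to 5000 W/D males at 1% of sites (round-half-away-from-zero, giving 424
sites for a 42,360-site landscape), drawn fresh each year or fixed on a
regular lattice; releases happen mid wet season (day 180), when
recipient populations are large. Seasonality is indexed by the mean
yearly minimum of a site's reference population (tertile 0 = most
seasonal); connectivity is the number of neighbours within 12 km.

## Numerical choices and limitations

- Deterministic engine: dense per-cross tensors (≤10 genotypes × 4
  exposure classes), single einsum per sex per generation; degenerate
  all-sterile states raise rather than silently renormalising.
- Threshold bisection reports the midpoint of a 1e−3 bracket; printed
  comparisons should not be read beyond that resolution.
- The spatial tests run at reduced scale (500 sites, 4 release years,
  single replicates per scenario; chosen as the smallest landscape that
  still exhibits the seasonality gradient and colonisation–extinction
  regime). Quantitative full-scale suppression levels are out of scope.
- Mating is unlimited for males (no harmonic-mean saturation); dsx-null
  females do mate, which is inert under male-unlimited mating.
- Whether dispersal differs by sex is unknown; both sexes disperse at
  the same rate here.
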