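# Methods

## The model

fraxkit reconstructs the epidemiological core of a country-specific
FRAX-style model: the population-average probability of a first hip (or
major osteoporotic) fracture over a fixed horizon, under the competing
risk of death. Two hazards drive everything — an annual fracture hazard
h_f(a) and an annual death hazard h_d(a), both functions of age a. With
both taken piecewise-constant on one-year age intervals, the probability
of fracturing before dying within the horizon decomposes exactly over
intervals:

    P = Σ_k S_k · h_f/(h_f+h_d) · (1 − e^{−(h_f+h_d)}),
    S_k = Π_{j<k} e^{−(h_f+h_d)_j}

The closed within-interval form means the only discretization is the
one-year hazard grid itself; there is no step-size error to tune away. A
degenerate interval with h_f + h_d = 0 contributes zero. "Lifetime" is
the horizon from the starting age to the terminal age of the table.
Swapping the roles of the two hazards gives the probability of dying
fracture-free, and the three-way identity
P(fracture) + P(death first) + P(event-free) = 1 holds to machine
precision — the main internal consistency check.

Assumptions worth stating: the modeled event is the *first* fracture (no
refracture); the population is homogeneous within age × sex (no clinical
risk factors or bone-density adjustment — those belong to the proprietary
layer of risk-score engines, not to the country incidence/mortality core
built here); and the fracture hazard estimated from all persons, not
fracture-free survivors, is used, which at hip-fracture incidence levels
differs negligibly.

## Estimating the hazards

**Incidence.** Cases per sex × 5-year band come from a deduplicated
admission line list; denominators are person-years, summed mid-year head
counts (one person-year per person per calendar year — the convention
chosen here; averaged-population denominators would differ only by the
growth factor). Rates carry exact (Garwood) Poisson intervals because
registry tables for small countries routinely contain cells with 0–10
events, where normal approximations misbehave. The exact interval is
conservative: its true coverage at means of 1–20 events sits at 95.7–99%,
never below the nominal 95%.

**Smoothing.** The per-age hip hazard is a Poisson GLM of band counts on
band-midpoint age (log link, log person-years offset), quadratic in age
by default: hip incidence is near-exponential in age, so the log-linear
term carries the signal and the quadratic term absorbs mild curvature
without overfitting nine bands. Age is centered at 65 and scaled by 10
for conditioning. The fitted curve is evaluated at single years 40–90 and
held constant to the terminal age; the open "80+" band is anchored at a
nominal midpoint of 85. These two choices (flat tail, midpoint 85) are
this package's documented convention for the open band — how production
risk tools distribute "80+" incidence internally is not public.

**MOF imputation.** Where direct spine/forearm/humerus incidence is
missing, the MOF hazard is imputed from hip via age- and sex-specific
other-MOF:hip ratios: mof(a) = hip(a)·(1+r(a)). Ratio tables are user
inputs (the widely used Swedish ratios are not redistributed here; tests
use a clearly labeled synthetic illustrative table with the same shape —
ratios falling from ~6 to ~1.5 in women with age). A person sustaining
multiple fracture types is not modeled; the additive form slightly
overstates MOF hazard at ages where co-occurrence is common.

**Mortality.** q → m via m = −ln(1−q); central rates pass through
unchanged. Abridged tables expand constant-within-band; beyond the last
band the hazard follows a log-linear (Gompertz) extrapolation through the
last two band midpoints up to the terminal age. On Gompertz-generated
tables this tail is exact to within the banding error (<5% in tests).

## The synthetic registry

The generator emulates the data-generating process the estimation stack
assumes: a three-year national admission extract over two nationality
strata. Its defaults are the study conditions, fixed once:

| parameter | default | meaning |
|---|---|---|
| years | 2017–2019 | three calendar years, non-leap |
| pop_size | ~28.9k national, ~65.7k expatriate per sex | head counts 40+, thinning with age; expatriates younger and more numerous |
| growth | 1.0 | per-year projection factor from the first year |
| frac_hazard_scale a | 2.0·10⁻⁷ /yr | Gompertz fracture hazard h_f = a·e^{b·age} |
| frac_hazard_slope b | 0.13 /yr of age | incidence doubling every ~5.3 years, the log-linear age gradient registry tables show |
| sex_multiplier | 1.25 | female:male fracture-hazard ratio |
| expat_rate_multiplier | 1.4 | expatriate:national fracture-hazard ratio |
| dup_prob | 0.15 | chance a fracture produces a second admission 1–90 days later |
| decoy_fraction | 0.10 | non-hip (S82.1/S52.5/S42.2) records appended per index case |
| mort_makeham | m: (6·10⁻⁴, 4·10⁻⁵, 0.090); f: (4·10⁻⁴, 2.5·10⁻⁵, 0.095) | Gompertz–Makeham death hazard α+β·e^{c·age} |

These produce ≈150 national and ≈500 total hip fractures over the three
years — the sparse-count regime that motivates exact intervals. Stratum
counts are Poisson with mean = head count × h_f(band midpoint): the
band-midpoint discretization has second-order error in the band width.
Within-band case ages are uniform, except the open 80+ band, where ages
80–100 are drawn with survival weights e^{−∫h_d} (a stationary-population
profile, since only the band total is observable). One RNG stream per
run, keyed by the seed, consumed in fixed order — including draws for
duplicates that are then discarded — so identical seeds give
byte-identical output and the deduplicated case count is exactly
invariant to `dup_prob`.

What the generator does *not* emulate: secular trends, seasonality,
within-band age misreporting, in-hospital mortality after fracture,
fracture recurrence beyond the duplicate-admission window, and coding
error beyond clean non-hip decoys. Passing tests therefore demonstrate
that the estimation stack recovers the truth *when its structural
assumptions hold*, not that those assumptions hold in any particular
hospital system.

## Numerical and design choices

* Dedup window 365 days, blind to the hip subcode (readmissions are often
  recoded); the earliest admission fixes the case's age and year.
* Age bands half-open [40,45)…[75,80) plus [80,∞); age = completed years
  at admission.
* Standardized-rate intervals by the Fay–Feuer gamma method; two-sample
  comparison by a z-test on log rates with delta-method errors. Both are
  standard for sparse direct standardization; an exact alternative is
  suggested by the error message when a rate is zero.
* Rounding to one decimal per 100,000 happens only in the reporting
  layer (`format_incidence`); all internal values are full precision.
* Terminal age 105 (closed-table convention), configurable.
* Probability curves by default at ages 50–90 in 5-year steps with a
  10-year horizon; lifetime probabilities reported from age 50.

## Problem sizes in the test suite and acceptance script

Parameter-recovery checks use a 20× scaled registry (≈3.5 million
national person-years, ≈10,000 cases) — enough that smoothing error, not
Monte-Carlo noise, dominates the ≤10% recovery tolerance at ages 60–80.
Interval-coverage checks pool 72 strata from two registries. The
discrete-event oracle uses 100,000 subjects per profile (binomial SE
≈0.1–0.15 percentage points), and 10⁶ subjects for the single
closed-form self-consistency check. The whole suite runs in well under a
minute; the acceptance script in a few seconds.

## Known limitations

* Absolute probabilities from a real registry inherit every bias of the
  admission extract: case ascertainment, coding quality, and the match
  between numerator catchment and denominator population. None of these
  are correctable inside this package.
* The MOF layer is only as good as the supplied ratio table; validation
  of ratio portability across countries is an empirical question outside
  the package's scope.
* The comparison z-test is asymptotic; with very few events per stratum
  its p-values are approximate even though the rate intervals are exact.
* Clinical-risk-factor adjustment, bone-density integration, and
  reproduction of any specific country's published absolute curves are
  out of scope: those require unpublished calibration inputs.
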