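# Methods

## Model and assumptions

The package models individual health histories as a discrete-time Markov
chain on seven states: six morbidity states obtained by aggregating the
nine CRG health statuses (the cross-walk is 1→1, 2→2, 3→3, 4→3, 5→4,
6→4, 7→5, 9→5, 8→6, exposed as a configurable table), plus death as an
absorbing state. Time advances in one-year cycles; the state next year
depends only on sex, current age and current state (first-order Markov),
and transition probabilities are stationary — estimated once from a
single pair of consecutive years and assumed constant over the whole
simulated lifetime. These are strong assumptions: they ignore calendar
trends in mortality and morbidity, cohort effects, and within-person
heterogeneity (frailty).

The estimation → interpolation → simulation design addresses the
sparse-data problem directly: transition probabilities are estimated per
sex and ten broad age groups (so every [sex × group × state] cell keeps
a workable number of observations), attributed to the group midpoint
ages, and only then expanded to single years of age by smooth
interpolation.

## Pipeline stages and their parameters

**Estimation** (`estimate_group_matrices`). The count-ratio MLE
`p̂_ij = s_ij / s_i` per (sex, age group), with the age group assigned
from the *baseline* age — consistent with conditioning on the earlier
year's state. Deaths during the follow-up year count as transitions to
death regardless of within-year timing (annual-cycle model). Parameters:

- `min_cell` (default 30 persons): exposure below this is flagged in the
  diagnostics; nothing is pooled automatically.
- `zero_exposure_policy` (default `borrow_nearest`): a row with zero
  exposure cannot be estimated; it is copied from the nearest age group
  with exposure for the same sex and state (ties toward the younger
  group), or set to identity-with-zero-mortality under the `identity`
  policy. Every filled row is flagged. Borrowing keeps the downstream
  splines defined by complete data rather than manufactured zeros.

**Interpolation** (`interpolate_yearly`). Each entry is a natural cubic
spline (second derivative zero at the boundary knots) through the nine
non-infant group matrices at midpoints 8, 20, 30, 40, 50, 60, 70, 80,
90 years, evaluated at integer ages 1..`max_age` (default 90). Age 0
takes the infant-group matrix verbatim: infant dynamics (birth
conditions, perinatal mortality) do not lie on the adult age gradient.
The open-ended 85+ group is pinned at midpoint 90 so the yearly set
terminates at the ≥90 index. Numerical repairs: interpolated values are
clipped to [0, 1] and each living row renormalized to sum 1 — the
minimal restoration of row-stochasticity; a log message records any row
whose pre-repair sum deviates by more than 1e-3. Ages beyond the last
midpoint evaluate the spline at the last midpoint (constant tail).
This flat tail understates very-old-age mortality and therefore
overstates LE at the highest ages (the package's comparison tables show
the effect at age ≥90); `tail_mortality_inflation` optionally compounds
the death probability beyond the pivot for a steeper closure, off by
default.

**Simulation** (`simulate_trajectories`). 10,000 trajectories per sex
by default, starting at age 0 in a state drawn from the empirical
under-1 composition, advancing by inverse-CDF draws over the (sex, age)
row with states ordered 1..7 and ties at cumulative boundaries resolved
upward. One stream per sex (seeds `seed` and `seed+1`); each trajectory
consumes one initial uniform plus one uniform per potential year, so
samples are bit-reproducible. Lifetimes still running at
`max_attained_age` (default 110; ages past the matrix set reuse its
last matrix) are censored, flagged, and contribute observed person-years
only; a warning fires if more than 1% of trajectories are censored.

**Person-year convention.** A person alive at exact age x who dies
during the cycle is credited the full year in the state occupied at x
(years lived = age at death + 1). Discrete annual cycles make this the
natural accounting, but it sits roughly half a year above the mid-year
(a_x = 0.5) convention of standard life tables. The Sullivan module
exposes `ax` so either convention can be matched; the consistency check
uses a_x = 1 deliberately.

**Expectancies.** `l_x` is the number of trajectories alive during
age-year x; `e_{x,j}` follows the demographic formula by reverse
cumulation of person-years. The state partition Σ_j e_{x,j} = e_x holds
exactly by construction. `expectancy_standard_errors` gives per-cell
Monte Carlo standard errors (sample SD of remaining state-years among
survivors at x, divided by √l_x), which also serve as a replicate-level
variability report.

**Sullivan comparator.** Standard period life table
(l, L, T, e columns; terminal open group closed by `l/m`), Sullivan
HLE by reverse cumulation of `π_y L_y`, and the conventional
binomial-prevalence SE propagation. The module also ships transcriptions
of the published 2017 Catalan Sullivan HLE series and official LE tables
as reference fixtures for the comparison reports; they are never inputs
to estimation.

## The synthetic population generator

The generator emulates the kind of data the estimator expects: a
general-population two-year panel (~87,850 people at scale 1) with a
plausible southern-European age pyramid, female share rising with age,
healthy prevalence falling from 95% (infants) to 10% (85+), and annual
mortality rising steeply after 75 with a severity gradient across states
(crude death rate ≈ 0.9%, ~758 deaths/year at scale 1). Ages are uniform
within each group — a fixture simplification. All numbers are documented
package choices, not estimates of any real registry; the generator's
purpose is parameter recovery (known truth in, estimates out), so
passing tests demonstrates correctness of the machinery, not realism of
any particular population. Within each (sex, group) block the seeded
stream is consumed in vectorized field-wise passes (ages, baseline
states, follow-up states), which keeps multi-million-row panels cheap
while remaining bit-reproducible.

## Statistical yardsticks in the test suite

The Monte Carlo engine is validated against the analytic
absorbing-chain propagation with a 3-standard-error yardstick per
(sex, age, state) cell, restricted to cells with at least 100 survivors
(below that the SE estimate itself is unstable). Because a validation
run compares ~800 cells simultaneously, a perfect engine still shows
~2 chance excursions beyond 3 SE per run; the suite therefore asserts
the family-wise reading of the same yardstick — headline expectancies at
birth within 3 SE each, the count of >3-SE cells within the binomial
null bound, and no cell beyond the family-wise 3-SE equivalent (z < 5
at ~800 cells). Verified empirically: across independent simulation
seeds the >3-SE cells wander among unrelated cells, the signature of
noise rather than bias.

Problem sizes used by the default test and acceptance runs: full
pipeline at scale 1 (~88k records) with 10,000 trajectories per sex;
oracle comparisons on randomized stationary chains over a 60-year
horizon; parameter recovery at 50,000 observations per
(sex, group, state) cell (6M records). Everything runs in about a
minute on one CPU.

## Known limitations

- Stationarity: period rates from one year-pair projected over a whole
  synthetic lifetime; no mortality improvement or cohort effects.
- The constant spline tail overstates LE at ages ≥90 (see above).
- No parametric old-age mortality law (Gompertz–Makeham) and no
  monotonicity-constrained splines; entries can need clipping where the
  spline overshoots near sharp gradients.
- Point estimates only for the multistate path: no bootstrap over the
  source individuals; the Monte Carlo SEs capture simulation noise, not
  estimation noise in p̂_ij.
- Whole-year death crediting makes LE ≈ 0.5 years higher than mid-year
  conventions; comparisons with standard life tables must match `ax`.
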