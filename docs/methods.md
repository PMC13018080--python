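# Methods

## Model structure

The cohort (default n = 100) is partitioned once, at admission, by whether a
new cerebral infarction occurs during the initial hospitalization (base
proportion 0.35). Each stratum then follows an independent three-state
trajectory — functionally independent (mRS 0–2), functionally dependent
(mRS 3–5), dead — on the evaluation grid {3 months, 1, 2, 3, 5 years}, then
annually to 30 years. The 3-month distribution seeds the trajectory;
per-interval row-stochastic matrices move it to year 5; after year 5 only
annual mortality acts, so the independent:dependent split of survivors is
frozen (functional transitions plateau). Dead is absorbing, so the dead
fraction is non-decreasing by construction.

Nursing-home occupancy is a second track, seeded at 3 months from band-level
utilization (u·mRS-mix), thinned by the retention schedule: 70% of 3-month
residents remain at 1 year, 61% and 36% of 1-year residents remain at 2 and
5 years. The 3-year retention is not separately specified; it is interpolated
geometrically between the 2- and 5-year anchors (the smooth monotone choice
consistent with both). After year 5 two readings of the continuation rule
conflict — "no further discharges expected" versus a "13% annual rate of
continuing" — so both are implemented as `post5y_mode`: `retain_all`
(default; occupancy frozen at its 5-year level, thinned only by deaths) and
`retain_13pct` (occupancy multiplied by 0.13 each year). Occupancy is always
capped at the alive fraction.

## Costs and QALYs

Per patient, cumulative cost at a horizon is:

* **acute admission** (all patients, deaths included): \$122,200.96 with
  infarction, \$89,997.00 without (USD 2025, NIS-derived);
* **year-1 disability care**: the 1-year state mix billed at \$14,293.80
  (independent) / \$15,633.30 (dependent) per alive patient-year;
* **year-1 nursing home**: the 3-month-seeded occupancy × \$114,665/yr
  × 0.85 (the first-year factor absorbs discharges between 3 months and
  1 year);
* **years 2–5 block**: annual disability + nursing-home cost evaluated at
  the 2-, 3- and 5-year state mixes, summed and expanded by 1.33 to a
  4-year cost (3 × 1.33 ≈ 4 sparse evaluations stand in for 4 annual ones);
* **after year 5**: annual costs run unchanged against survivors to the
  horizon.

QALYs are **cross-sectional**: cohort utility at the horizon time point is
n × (f_independent × 0.74 + f_dependent × 0.38), never integrated over the
elapsed years. This is why 30-year cohort QALYs (18.3) are *lower* than
1-year QALYs (56.9): they measure the surviving cohort's utility at year 30,
not accumulated life-years. No discounting is applied by default
(`discount_rate: 0`); a rate hook exists but the shipped aggregates are
consistent with none.

## Anchor mode and mechanistic mode

The engine evaluates scenarios two ways.

**Anchor mode** (default) reproduces published aggregates exactly. The
per-patient stratum values at each horizon are back-solved from stratum
anchors (e.g. 1-year infarction stratum: \$5,982,964 / 35 patients =
\$170,941.83); 1-year cohort totals are the affine mixture
n·[p·c_ci + (1−p)·c_no_ci]. The 30-year stratum cost anchors are
years-5-to-30 *increments*: only that reading satisfies the identity
5-year cohort total (\$21,833,504.20) + \$10,112,038 + \$28,969,455 =
\$60,914,997.20 against the published 30-year total (\$60,914,997, residual
\$0.20; `calibrate` rejects anchor sets violating it by more than \$5). The
stratum total is treated as authoritative where it conflicts with a printed
per-patient value (119,922.71 vs the printed 119,922.40 — a rounding slip in
the source). The 5- and 30-year totals for the counterfactual proportions
(0.30/0.25/0.20) are **not** affine in p and their generative detail is not
recoverable from the published aggregates, so those six cells are stored
verbatim in the config and returned as-is; any other proportion falls back
to the affine mixture.

**Mechanistic mode** regenerates totals from the transition schedule and
unit costs. The shipped schedule is itself a calibration product (labelled
so in the config): 3-month mixes and a death-fraction path are assumed
(infarction stratum: dead 0.24 → 0.32 → 0.38 at 3 months/1 y/5 y;
no-infarction: 0.08 → 0.09 → 0.105 — chosen once as clinically plausible
shapes), the 1- and 5-year state mixes are then *solved* from the stratum
QALY anchors, post-5-year mortality is uniform across alive bands and solved
from the 30-year QALY anchor, and nursing-home seeds are solved from the
1-year cost anchors (band utilizations from the two strata jointly:
≈ 0.78 of dependent and ≈ 0.024 of independent patients at 3 months).
Consequently mechanistic QALYs match the anchors to machine precision at
all three horizons and mechanistic 1-year costs match exactly; 5-year costs
carry a residual (−0.2% infarction stratum, +5% no-infarction) and 30-year
costs a larger one (−5% / −26%), because the sparse published aggregates
under-determine the long-run cost composition. `economics.residual_report`
quantifies this; the mechanistic 5/30-year scenario cells are not asserted
against published tables.

## Cost-utility analytics

ICER = (n·C − S)/G; a zero QALY gain raises an explicit undefined-ICER error
rather than emitting ±inf. WTP classification uses strict `<` against
ordered tiers; positive gain with negative ICER is "dominant" and the raw
negative ratio is retained in tables. In anchor mode the grid rounds QALY
gains to one decimal first, matching the published table convention. The
source tables were evidently computed at higher internal precision: from the
printed one-decimal inputs, all twelve 5-year ICER cells reproduce within
\$2, but several 1-year and 30-year cells deviate by up to ~\$15k (e.g.
244,904/1.3 = 188,388 against a printed 189,848 = 244,904/1.29). Tests
therefore pin the 5-year column and treat the other columns' ICERs as
derived outputs. One narrative claim in the source conflicts with its own
table: the 5-year, 5%-reduction, \$5,000 cell prints \$53,840/QALY, which
clears the <\$100k tier but not the <\$50k tier it is verbally assigned to;
the engine (and its tests) follow the table.

## Sensitivity analysis

One-way sweeps rescale a single input and report the ICER change from the
anchor ICER. The anchor scenario is not stated in the source; it is inferred
as (5-year horizon, 15% reduction, \$5,000/patient) because only that anchor
reproduces the published deltas exactly: QALY ±10% → +\$20,991 / −\$25,656
(closed form A(1/m − 1)); intervention ±20% → ±\$30,303
(= 0.2 × 100 × 5,000 / 3.3). `qaly_gain` and `intervention_cost` sweeps act
directly on the anchor-mode ICER arithmetic. `nh_cost` and
`longterm_cost_mrs02` change how savings are composed, so they rerun the
mechanistic model with the scaled unit cost (the calibrated schedule held
fixed); their deltas are taken against the mechanistic anchor ICER
(−\$146,576, versus −\$230,905 in anchor mode — the gap reflects the
mechanistic 5-year residual above). The mechanistic nursing-home ±20% sweep
spans ≈ ±\$42k here, smaller than the ≈ ±\$100k the source narrative reports;
the source's internal cost composition is not recoverable, so the package
asserts only the qualitative finding that the nursing-home sweep dominates
the tornado, which holds. Tornado ordering is span-descending with
alphabetical tie-break.

## Drug costing

Fixed-schedule regimens cost unit × units/day × days in exact `Decimal`
cents (half-up), reproducing the published two-decimal rows bit-exactly.
Albumin dispenses whole bags: ceil(1.25 g/kg × 80 kg / 12.5 g) = 8 bags per
dose at \$55.87/bag. Combination rows are component-wise sums; the "per
dosing unit" column of a combination adds heterogeneous units (tablet + bag)
and is retained purely as a display convention. Clazosentan is a lump-sum
course price (\$15,332.03 in 2023 → \$16,280.15 in 2025; the implied ratio
is the shipped inflation-factor example — no FX modelling). Elsewhere the
engine uses floats, because calibrated per-patient anchors are
non-terminating decimals; display rounding is half-up via `money.round_half_up`.

## Fixtures

`sahcue fixtures` writes the default config (every constant with a
provenance comment; calibrated values labelled as such) plus seeded
perturbed variants: unit costs scaled by U(0.8, 1.2) and utilities jittered
within their ordering bounds. Perturbed configs exercise the invariant
(non-golden) test surface: conservation, monotone mortality, occupancy
bounds, ICER homogeneity, classification monotonicity. What passing these
shows about real data is limited: the generator perturbs *parameters*
around one published operating point; it does not emulate patient-level
heterogeneity, correlated cost/outcome errors, or non-US price structures.

## Numerical choices and limitations

* State-distribution validation tolerates 1e-9 on the sum; simulated
  trajectories conserve mass to <1e-12 and agree with explicit
  matrix-product evolution to <1e-10 (tested on 50 random schedules).
* Horizon 4 is off the evaluation grid; its state is linearly interpolated
  between years 3 and 5 and it is never a billing point.
* Money comparisons in tests use absolute tolerances at the printed
  precision (\$1–\$3); QALYs at one decimal.
* The model inherits the source framework's assumptions: infarction's
  effect on outcome is unconfounded; functional status and annual costs
  plateau after year 5; indirect costs, caregiver costs and
  monitoring/imaging surveillance are excluded; CPI adjustment may not
  track healthcare-specific inflation. The calibrated transition schedule
  is a reconstruction consistent with published aggregates, not a
  literature parameter set, and should be replaced by empirical transition
  estimates when modelling a real trial population.
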