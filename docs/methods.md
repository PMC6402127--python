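# Methods

`chwcea` implements a trial-based cost-effectiveness analysis (CEA) of a
community health worker (CHW) home-visiting diabetes intervention
against standard care, from the societal perspective, over a 2-year
horizon (one pre-enrollment year of utilization, one intervention
year), with all costs in 2012 USD. This note documents the model, its
assumptions, the tunable parameters, and the design choices made where
the published record left the design open.

## Pipeline

`DiabetesCEA.fit()` composes five stages:

1. **Hospital micro-costing** (`chwcea.costing`). The facility ledger
   lists overhead and activity cost centers. Overhead pools are
   *step-allocated*: centers are processed in a declared order; each
   pool (direct cost plus overhead already received) is split over the
   not-yet-allocated centers proportionally to its allocation driver
   (staff count for administration, floor space for plant upkeep and
   laundry, patient count for patient-service management,
   inpatient-equivalent days for clinical support such as the lab).
   Unit costs are then (direct + allocated) / output volume per
   activity center, aggregated to service categories by volume-weighted
   mean — equivalently total category cost over total category volume,
   so multiplying back by category-level utilization reproduces the sum
   over centers. Conservation (allocations sum to the pools) and
   reconciliation (unit cost x volume sums to total spending) hold to
   1e-9 relative and are enforced by property tests.

   Step-down results depend on the order. The order is configuration
   (default: descending direct cost), and
   `allocation_order_report` enumerates all permutations of up to four
   overhead centers so that the order dependence is documented rather
   than hidden.

2. **Program costing** (`intervention_cost_per_participant`). Variable
   costs: each quarter's consumables divided by that quarter's visits
   gives a variable cost per visit, applied to the mean per-participant
   visits of that quarter. Fixed costs — annual staffing share,
   straight-line depreciation of startup capital over a 5-year useful
   life, donated-space opportunity cost, other overhead — are converted
   to a monthly rate and divided by the visit count of the *busiest
   month*, costing the program at full capacity as an ongoing service
   would run; the per-visit rate is multiplied by mean visits per
   participant. The busiest-month arithmetic is one coherent reading of
   "divide by the visits in the busiest month" for annual figures; an
   `annual_average` rule (annual fixed cost over total annual visits)
   is available as a config switch. Note the intended scale behavior:
   scaling all monies by k scales every per-participant cost by k, and
   doubling participants, visits and consumables leaves the variable
   component unchanged while *halving* the fixed components (the same
   fixed base spreads over a busier busiest month) — economies of
   scale, not an error.

3. **Utilization difference-in-differences** (`chwcea.did`). For each
   service category,
   `DiD = [sum_chw(post) − sum_chw(pre)] / py_chw − [sum_ctrl(post) − sum_ctrl(pre)] / py_ctrl`,
   with pre = the 12 months before enrollment, post = the 12 months
   after, and person-year denominators either supplied (the study's
   100 CHW / 163 control follow-up person-years) or approximated from
   retention flags (retained = 1 year, lost = half a year; dropout
   dates are not recorded). Analysis is intent-to-treat: no
   per-protocol filtering. Maternity-ward and Ob-Gyn utilization is
   excluded by configuration before aggregation, since pregnancy care
   is unrelated to glycemic control in an older T2DM cohort. Cost DiD
   per category = utilization DiD x unit cost; hospitalization is
   assembled ward by ward, which is what lets a small increase in
   expensive ICU days (+0.06/patient-year) outweigh a net reduction in
   total inpatient days (−0.14) and produce a positive hospitalization
   cost DiD. Statistical inference on the DiD (clustered standard
   errors, bootstrap) is out of scope; the analysis reports point
   estimates.

4. **Patient-time (indirect) costs** (`chwcea.timevalue`). Time is
   valued at a policy wage ($4.76/h, the 2009 minimum wage of the
   territory's largest employment sector) with time-and-a-half beyond
   8 h *per continuous episode*. The premium is per episode because
   summing short visits into "overtime" would be absurd — and the
   published intervention-time value (602 min ≈ 10.03 h valued at
   $47.76 ≈ flat wage) confirms short home visits were not
   overtime-valued. Outpatient contacts (ED, ambulatory, surgery) use a
   30-minute convention; an inpatient day is a single 24-hour episode
   (value $152.32).

5. **Effectiveness, ICERs, decisions** (`chwcea.qaly`, `chwcea.cea`).
   The HbA1c arm effect is either computed from the patient table
   (unadjusted arm difference of mean 1-year change) or supplied as the
   externally estimated covariate-adjusted effect (the base case
   consumes −0.53 points this way; estimating the adjusted effect is
   outside this package's scope). Utility is assumed linear in HbA1c
   with decrement d = 0.17 per percentage point (cross-sectional EQ-5D
   evidence with US preference weights); with HbA1c changing linearly
   over the follow-up year, the incremental utility at time t is
   `d·r·t`, and the QALY gain is the triangle area `d·r/2` = 0.04505
   for r = 0.53. A trapezoid-rule integrator serves as an independent
   oracle (agreement to 1e-6 is a test invariant). Horizons beyond one
   year hold the year-1 gain constant; they are exploratory only and no
   discounting is applied. ICERs are classified (interior / dominant /
   dominated / undefined) before division — no silent division by
   zero — and compared against six willingness-to-pay thresholds
   ($39 000 = 3x local GDP per capita of $13 000; $50 000 conventional;
   $66 351 and $111 134 study-derived; $102 902 and $154 353 = 2x and
   3x US GDP per capita), with ICER = λ counting as cost-effective.
   One-way sensitivity re-runs the entire pipeline varying one
   parameter at a time (`hba1c_reduction`, `utility_decrement`, and an
   exploratory cost multiplier); a singleton grid at base values
   reproduces the base case exactly.

## The synthetic generator

`chwcea.simulate` produces data with the structure the analysis
assumes, for parameter-recovery testing and exploration. Defaults are
the study conditions: 104 CHW / 164 control participants, baseline
HbA1c 9.8 ± 2.3%, treatment effect −0.53 points, 91% retention,
100/163 follow-up person-years.

- **Cohort**: whole clusters (villages) are assigned to one arm, with
  cluster counts split in proportion to arm sizes. The trial reports
  neither cluster count nor intra-cluster correlation, so both are
  parameters; the defaults (10 clusters, between-cluster baseline SD
  0.3 HbA1c points) are plausible for village-level clustering and are
  the package's choice. Baseline HbA1c is truncated-normal on [3, 20];
  follow-up adds a secular drift (default 0 — the control arm's 1-year
  drift is not reported), the treatment effect in the CHW arm, and
  independent noise (default SD 1.5 points, typical 1-year
  within-person HbA1c variability). Follow-up is missing exactly for
  patients lost to follow-up. Age/sex marginals follow the baseline
  table; joint covariate structure is not modeled.
- **Encounters**: per patient-period Poisson counts at category base
  rates (defaults per person-year: ED 1.5, ambulatory 6.0, medical
  ward 0.5, surgical ward 0.3, ICU 0.05, surgery 0.2 — a
  high-comorbidity T2DM cohort); the CHW post-period rate is shifted by
  the injected DiD target, so the DiD estimator recovers each target
  within Monte-Carlo error (a 3-SE recovery test at n = 1000 per arm is
  part of the suite).
- **Finance ledger**: constructed by *inverting* the costing engine —
  unit costs and volumes are chosen, the step-down allocation is
  computed with the real engine, and direct costs are set to
  (unit cost x volume − allocation). The engine therefore recovers the
  chosen unit costs to machine precision, which is the ledger's
  internal-consistency guarantee.

What the generator does **not** emulate: correlated utilization across
categories within a patient, seasonality, overdispersion beyond
Poisson, informative dropout, or free-text records. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to real-world messiness.

## The calibrated dataset

`chwcea.datasets.study_fixture()` is a deterministic bundle whose
pipeline outputs reproduce the published per-patient results. The
published values are rounded aggregates, not raw records, so the
fixture encodes them at the aggregate level:

- Utilization DiDs are encoded as arm-level totals (a reduction of x
  per person-year over 100 CHW person-years appears as a pre-period
  quantity of 100x), with balanced control-arm background utilization.
- Unit costs are back-computed ratios of published aggregates (ED
  83.77/0.61 ≈ $137.33 per visit; ambulatory 38.38/0.18 ≈ $213.22;
  surgery 12.92/0.10 = $129.20). Ward-level inpatient unit costs are
  synthetic calibrations (medical $350, surgical $358.875, ICU $1500)
  constrained to the two published facts: +0.06 ICU days and a net
  hospitalization cost DiD of +$19.29.
- The intervention ledger is inverted from the published component
  costs (staffing $439.18, equipment $124.24, space $52.94) under the
  busiest-month rule, with consumables as the published-total residual
  ($61.07 = 677.43 − 439.18 − 124.24 − 52.94). The components are
  calibration targets, not derivable from first principles here.
- **Medical indirect time** is the one place where the published table
  is not internally reproducible: −3.74 h / −$15.15 per patient-year
  cannot be obtained from the rounded utilization DiDs under any flat
  or per-episode valuation (flat gives −$17.80; the package's
  per-episode rule gives −3.805 h / −$23.44). The fixture therefore
  carries this row as a calibrated aggregate (hours −3.74; cost
  −15.1387, the residual of the published total against the other
  full-precision components), supplied through the
  `medical_indirect_*_override` config slots. The package's own
  valuation is always computed and exposed as
  `CEAResults.own_medical_indirect`; on data without overrides it is
  what enters the total.

With this calibration the full pipeline yields an incremental cost of
$594.27 per patient per year, ICERs of $1 121.26 per HbA1c point and
≈$13 191.3 per QALY, cost-effective at all six thresholds; the
conservative utility decrement 0.03 (back-derived from the published
sensitivity maximum) yields ≈$74 750.9 per QALY — above the $39 000 and
$50 000 thresholds, below 2x and 3x US GDP per capita.

## Numerical conventions

- All computation at full float64 precision; rounding (money and
  utilization to 2 decimals, QALYs to 5) happens only in display code.
  Components in the printed report may disagree with the printed total
  by one cent for this reason; totals are never forced to match
  rounded component sums.
- Degenerate inputs raise typed errors rather than producing NaNs: a
  zero-driver allocation pool, a zero-volume activity center, zero
  busiest-month visits with positive fixed costs, empty threshold sets
  and empty sensitivity grids are all refused; a zero incremental
  effect yields an `undefined` ICER flag, never a division.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds carried in the parameter objects; the fixture uses no RNG at
  all; fitted results carry content hashes of the inputs and config.

## Problem sizes

Tests and the acceptance script run at desk scale by design: the
calibrated dataset has 268 patients and a ~15-center ledger; recovery
tests use 1000–1500 patients per arm, which makes 3-SE Monte-Carlo
bands tight enough to detect estimator bias while the whole suite
completes in a few seconds.

## Known limitations

- The 2-year horizon stops at observed data; lifetime extrapolation
  (UKPDS-style), mortality and complication modeling are deliberately
  out of scope.
- Linear HbA1c-utility is an extrapolation beyond the source sample's
  HbA1c range; the decrement is a config slot precisely because it is
  the most fragile assumption (the sensitivity analysis varies it).
- No probabilistic sensitivity analysis (CEAC) and no uncertainty on
  the DiD point estimates.
- Step-down allocation is order-dependent by construction; reciprocal
  (simultaneous-equation) allocation is not implemented.
- The time-valuation discrepancy for medical indirect costs described
  above: on the calibrated dataset the published aggregate is used; on
  any other data the package's per-episode rule applies.
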