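# Methods

## Model structure

The analysis compares two strategies for morbidly obese (BMI > 32.5 kg/m²)
type-2 diabetes patients: bariatric surgery and conventional medical
management. Year 1 is modelled as a deterministic decision tree: the whole
cohort is distributed over five outcome states (remission, improved,
persistent, uncontrolled, dead) according to each arm's year-1 outcome
probabilities. From year 2 an annual-cycle Markov cohort model applies a
row-stochastic 5×5 transition matrix per arm; the dead state is absorbing.
The simulation is an expected-value cohort trace — no microsimulation and
no random numbers in the engine.

Accrual is end-of-cycle: the accrual of cycle *t* (costs `v_t·c`, QALYs
`v_t·u`, life-years = alive mass) is discounted by `(1+r)^-t`, so the
year-1 outputs — including the one-time surgery fee — carry exponent 1.
A half-cycle correction (mean of cycle start/end occupancy for cycles
2..T) is implemented but **off by default**, as the original analysis
never mentions one. Costs and effects use the same 3 % rate by default but
are separately configurable.

## Parameters

All parameters live in one JSON configuration; the bundled
`thailand_baseline.json` carries the published values (2017 THB):

* **Year-1 outcome probabilities** — surgery arm 0.8356 / 0.0411 / 0.0099 /
  0.1233 / 0.0001 (the printed vector sums to 1.0100 and is renormalized at
  load with a logged warning; vectors off by more than ±0.015 are
  rejected); no-surgery arm 0.0001 / 0.23 / 0.17 / 0.5998 / 0.0001.
* **Costs** — surgery 150,000 THB one-time; annual drug prices metformin
  538.6, sulfonylurea 162, thiazolidinedione 12,840, α-glucosidase
  inhibitor 1,155.6, insulin 3,480; supplementation 396; complication
  management 15,326.4 THB/yr. State costs are composed at load: remission
  = supplementation; improved = metformin; persistent = metformin + a
  second agent; uncontrolled = a multi-drug regimen + complication
  management; dead = 0.
* **Utilities** — 0.83 / 0.80 / 0.78 / 0.75 / 0.
* **Discounting & horizon** — 3 %/yr, 50 annual cycles.
* **WTP band** — 150,000–200,000 THB/QALY (1–3× Thai GDP per capita);
  a ratio exactly on a boundary counts as cost-effective.

Two cost-bundle compositions were genuinely open and are fixed here as
package defaults (both configurable): the persistent-state second agent is
**sulfonylurea**, and the uncontrolled regimen is **metformin +
sulfonylurea + insulin** — first-, second- and third-line agents in Thai
practice and the cheapest clinically sensible triple. Both choices are
conservative for the surgery arm, since they minimise the medical-arm
costs that surgery avoids.

## Years-2+ transition dynamics (assumption, not data)

The long-run transition probabilities behind the original analysis were
taken from literature and never printed. The engine therefore accepts any
row-stochastic matrix from the configuration; the bundled default keeps
every alive state where it is except

* a **remission → improved relapse probability of 0.05/yr** — a flat-hazard
  stand-in for published long-term relapse series (roughly 25–40 %
  cumulative relapse 5–10 years after surgery), applied to both arms; and
* a **flat death probability of 0.0001/yr** from every alive state,
  matching the year-1 death entries.

Consequences to keep in mind: with equal flat mortality the two arms gain
essentially no differential life-years, so the QALY gain comes from
utility differences alone; and because surgery moves the cohort into
low-cost states, the baseline run makes surgery **dominant** over 50 years
(ΔC ≈ −89,000 THB, ΔQALY ≈ +1.0) rather than costlier-but-worth-it. The
time-horizon threshold analysis puts the crossing at year 9 (200,000
THB/QALY) or 11 (150,000). An analysis with literature-calibrated relapse,
differential mortality and richer state costs can legitimately put the
crossing earlier and lifetime ΔC above zero; these outputs are reported,
not asserted, and the relapse probability is exposed to the DSA (range
0–0.10).

## Sensitivity and threshold analysis

The one-way DSA perturbs each named parameter to the ends of its range
with everything else at baseline and reruns the full two-arm model; the
baseline is evaluated once and reused for range ends equal to it. Varying
one entry of a year-1 probability vector rescales the remaining entries
proportionally so the vector stays stochastic. Default ranges: published
cost ranges verbatim; ±10 % truncated to [0, 1] for probabilities and
utilities (no ranges were published; output metadata should be read with
that in mind); 0–6 %/yr for the discount rate (the conventional HTA
span). Dominant ends are recorded without a ratio, count as below any
threshold, and enter the tornado swing as ratio 0; dominated ends never
count as below threshold and are excluded from swing. Ties in the tornado
order break alphabetically. The whole DSA is deterministic.

The threshold analysis scans horizons h = 1..T ascending and reports the
first h whose cumulative discounted ΔC / ΔQALY is at or below the WTP with
ΔQALY > 0, so the returned year is minimal by construction.

## Synthetic cohorts

The generator emulates the published surgical series (n = 73, 58.9 %
female, age 41.8 ± 12.2, baseline BMI 50.1 ± 10.3 and HbA1C 7.6 ± 1.9,
year-1 BMI 36.9 ± 8.9 and HbA1C 5.8 ± 1.4) with truncated-Gaussian draws:
baseline BMI resampled above the 32.5 kg/m² inclusion floor, HbA1C floored
at 4.0 %. Outcome states are drawn from the published year-1 distribution
(renormalized), and each record's year-1 HbA1C and medication list are
drawn conditional on its state — < 6.5 % for remission/improved, ≥ 6.5 %
otherwise, with the state's defining regimen — so classification recovers
the assigned state exactly. This round-trip contract is what the pipeline
tests rely on; the price is that marginal year-1 HbA1C moments deviate
slightly from the published table, and the truncation floor biases the
baseline BMI mean upward by ≈ 1 kg/m². `exact_count_cohort` fixes state
counts exactly for reproducing printed proportions (note 0.0099 of 73 is
not an integer count; exact-count fixtures use 0 or 1 persistent
patients). What these cohorts cannot show: real covariance between
endpoints, surgery-type strata, lipid/blood-pressure structure, or any
long-term follow-up — passing tests demonstrate the pipeline's
correctness, not clinical fidelity.

## Numerical conventions and degenerate inputs

* Occupancy vectors must sum to 1 within 1e-9 at every cycle; transition
  rows within 1e-9 at load.
* Classification is a total function: combinations outside the four
  published definitions (HbA1C ≥ 6.5 % with ≤ 1 agent; two-class regimens
  without metformin) fall back to **persistent** — the conservative
  assignment — and every fallback is logged. Duplicate drug labels count
  once; the HbA1C boundary is strict (< 6.5).
* Paired summaries use sample SD (n−1) and a two-sided paired t-test;
  all-zero differences give p = NaN (documented), a nonzero constant
  shift p = 0.
* Reporting precision: probabilities 4 dp, percentages 1 dp, THB 2 dp.
* Dominance is always reported as a label, never a signed ratio; the
  cheaper-and-less-effective quadrant keeps a (positive) ratio whose
  reading is savings per QALY forgone.

## Problem sizes

The test suite and acceptance script run the 50-cycle, two-arm model, the
16-parameter DSA (33 model evaluations) and cohorts of up to 10,000
synthetic patients; the full suite completes in a few seconds on one CPU.

## Known limitations

No age/sex-specific background mortality, tunnel states, probabilistic
sensitivity analysis, or net-monetary-benefit curves; CPI adjustment
accepts an index table but does not construct one; currency conversion is
out of scope.
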