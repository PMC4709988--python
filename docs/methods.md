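# Methods

## Model

`cadcost` is a decision-analytic cost-minimization model. Three diagnostic
work-up strategies for suspected coronary artery disease are represented
as decision trees over one year of follow-up and ranked by expected
per-patient cost from a third-payer (reimbursement tariff) perspective.
The central assumption is **equal outcomes**: ischemia testing by
stress-perfusion CMR and by FFR are taken to identify the same fraction of
patients needing revascularization, and the same complication rates apply
to every arm. Under that assumption the downstream revascularization,
drug, complication and follow-up cost terms of the CMR-guided and CXA+FFR
arms are identical (the implementation computes them once and shares them
bit-for-bit), and strategies differ only in their diagnostic cascades —
plus, for the anatomy-guided CXA-only arm, in revascularizing every ≥50%
stenosis rather than only ischemic patients.

Expected cost is the probability-weighted sum of unit tariffs over tree
branches. Consequences the model deliberately prices at zero: death (no
cost attached in any mode), drugs for risk-factor management (identical
across strategies), and any event beyond the one-year horizon. With a
12-month horizon no discounting is applied.

Conditional probabilities with a zero denominator are represented as
*undefined* (`None`), and cost evaluation refuses to price a tree with an
undefined branch rather than silently treating it as zero. This surfaces,
for example, an attempt to cost the invasive arms before the FFR-eligible
fraction has been derived.

## Branch probabilities

From a patient-level cohort table the package derives, by exact counting:
ischemia prevalence; revascularization rates conditional on the CMR
result; the PCI-only / CABG-only / both type mix among revascularized
patients; and marginal one-year event rates (all-cause death as the
*union* of overlapping death flags, with cause-specific sub-tallies, so
complication rates never double-count a death). The marginal
revascularization rate recombined from the conditional branches equals
the direct count ratio exactly — a counting identity the tests enforce at
1e-12.

The FFR-positive rate of the hypothetical invasive arm defaults to the
observed revascularization rate (the equal-outcome coupling). Subgroup
analyses re-derive all probabilities within the subgroup rather than
scaling the whole-cohort tree.

## Stenosis–FFR extrapolation

The fraction of patients *eligible* for FFR testing (those with a ≥50%
diameter stenosis on angiography) exceeds the fraction with a *positive*
FFR (≤ 0.80), because many intermediate stenoses are not
flow-limiting. The package models the relationship as a monotone curve
through the origin defined by calibration anchors, with two
interpolants: piecewise-linear (default — exactly invertible, no
overshoot) and a monotone PCHIP spline (opt-in; inverted by Brent root
finding to 1e-12). The shipped default is a single-anchor calibration —
a 6.2% FFR-positive rate corresponding to ~35% stenosis prevalence —
extended linearly beyond the anchor with the anchor slope, capped at 1.
The curve refuses to extrapolate beyond its calibrated FFR-rate range;
analyses of high-prevalence subgroups may therefore require recalibration
with additional anchors, which is intentional: a single-anchor line has
no authority far from its anchor. Users with a published stenosis-FFR
regression should calibrate the curve to it and record the source in
`provenance_note`; the 30–55% sweep in the sensitivity module is the
model's robustness answer to curve uncertainty.

## Tariff schedules and options

A `UnitCostSchedule` carries one health system's tariffs: CMR, CXA, the
*incremental* FFR add-on, PCI, CABG, both-procedures (default: sum),
non-fatal MI management, stroke, aborted sudden cardiac death, one year of
dual antiplatelet therapy, and two optional items — post-MI
rehabilitation and a post-revascularization cardiologist visit — that
`AnalysisOptions` toggles (both included by default, matching systems that
reimburse them). Complication costing defaults to `death_and_mi_only`
(death free, MI priced); `all_mace` additionally prices stroke and
aborted SCD. Two further documented toggles: CMR-negative patients who
are nevertheless revascularized are charged one CXA (a revascularization
presupposes an angiogram; default on), and the CXA-only arm's
revascularized fraction receives dual antiplatelet therapy (default on,
mirroring the other arms).

The shipped `examples/systems.yaml` schedules are **illustrative**
round numbers with realistic relative magnitudes (invasive angiography
above CMR, CABG several-fold above PCI, larger absolute tariffs in the
Swiss- and US-style systems). They are not authoritative tariffs for any
payer, and absolute cost levels computed from them carry no evidential
weight; the structure of the comparison (which strategy is cheapest, how
reductions respond to parameters) is what the package reproduces.

## Sensitivity and break-even analyses

One-way deterministic sensitivity analysis scales exactly one tariff by
(1 + relative change), re-evaluates all three strategies, and reports
cost and percent-reduction deltas. Revascularization-procedure tariffs
are excluded by default — under equal outcomes the procedures are
identical across arms — with an explicit override for exploratory use.
Re-running with a relative change of zero reproduces the baseline
bit-identically (no hidden state).

The FFR-eligible-fraction sweep walks an inclusive grid (default 30–55%
in 5-point steps; the upper endpoint is always included even when the
step does not divide the range). By default the swept fraction drives
both the CXA+FFR arm's FFR count and the CXA-only arm's revascularized
fraction, since both trees share the ≥50%-stenosis quantity; a toggle
decouples them.

Expected costs are affine in any single tariff, so the break-even
multiplier equalizing two strategies is the intersection of two lines,
computed in closed form from two model evaluations (tariff zeroed and at
baseline) and verified by a full re-evaluation at the solution
(tolerance 1e-9 relative). Parallel lines (equal coefficients) are
reported as unsolvable rather than infinite, as is an intersection at a
negative multiplier.

## Synthetic cohorts and the microsimulation oracle

The registry data the analysis emulates are not publicly deposited, so
the generator produces cohorts with the published statistical structure:
n = 3,647; 49.0% atypical chest pain, 16.0% typical angina, the rest
unlabeled; whole-cohort ischemia prevalence 20.9% with 17.4% of positives
and 3.3% of negatives revascularized (34.9%/23.2%/7.4% in typical
angina); type mix and event counts per the published treatment and
outcome tables. Each patient is sampled independently: subgroup ~
categorical, CMR result ~ Bernoulli(subgroup prevalence),
revascularization ~ Bernoulli conditional on the result, type ~
categorical, events ~ independent Bernoullis at subgroup marginal rates.
One explicit seeded generator per call; no global RNG state.

Quantities the registry does not print are synthetic and solved for
consistency: the atypical subgroup's prevalence (set to 17%) and
negative-conditional rate (2.5%) chosen below the cohort totals, and the
remainder subgroup's parameters solved so the mixture reproduces the
published subgroup revascularization rates and whole-cohort marginals.
One consequence of honoring the printed treatment *counts* (226 = 179 +
41 + 6) is that the mixture's whole-cohort conditional rates come out
near 16.6%/3.4% rather than the printed 17.4%/3.3% — the printed
percentages imply ~228 revascularizations and are internally inconsistent
with the counts at rounding level. Death causes are distributed among the
dead (cardiac / unknown / other) so the union reproduces the all-cause
rate.

What the generator does *not* emulate: event timing, competing risks,
covariate-dependent risks (age and sex are generated for realism but
drive nothing), center effects, or missing follow-up. Passing tests
therefore demonstrate the *arithmetic* of the cost model and the
self-consistency of the pipeline on data with the assumed structure —
not the clinical validity of the equal-outcome assumption on real
patients.

`simulate_strategy_costs` is the package's central oracle: it walks each
patient through a strategy's tree accruing tariffs under the same rules
as the analytic model. The CMR-guided walk involves no assignment
randomness, so its mean equals the analytic cost *exactly* when the
probabilities are derived from the same cohort (a plug-in identity the
tests assert at 1e-12). The invasive arms assign FFR eligibility by
Bernoulli draw and the CXA-only arm samples procedure types from the
empirical mix, so their means converge at the Monte-Carlo rate; the
acceptance suite checks agreement within three standard errors at
n = 100,000.

## Problem sizes and numerical choices

The test suite uses cohorts of 3,647 (the registry size) for structural
checks, 50 replicate seeds at n = 3,647 for parameter-recovery coverage
(each generating proportion must lie in its 3-SE binomial interval in
≥ 95% of replicates), and a single n = 100,000 cohort for
microsimulation agreement. The acceptance script measures cohort rates
on one n = 100,000 cohort so reported values carry negligible
Monte-Carlo error while the generating parameters remain the registry
defaults. Money is computed at full float precision throughout; rounding
(whole currency units, one-decimal percentages) happens only in the
rendering layer. Component breakdowns must sum to totals within 1e-9
relative, enforced at construction.

## Known limitations

- The equal-outcome assumption is structural; the package offers no way
  to model outcome differences between strategies (by design — that would
  be cost-effectiveness, not cost-minimization).
- The default stenosis-FFR curve is a single-anchor line; conclusions
  sensitive to its shape should be re-run with a literature-calibrated
  curve and the FFR-fraction sweep.
- No probabilistic sensitivity analysis (distributions over tariffs);
  robustness is assessed by deterministic one-way variation, the fraction
  sweep, and break-even solving only.
- No QALY or ICER computation, no discounting, no currency conversion.
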