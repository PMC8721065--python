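# Methods

## Model and procedure

`rankagree` analyses agreement between two ordinal classifications of the
same subjects. The data model is a long-format table of rating records
(subject, rater, occasion, item, integer score) validated against an
`OrdinalScale` (ordered items with level ranges, plus named sum-score
groups). A *comparison* fixes two assessment coordinates — one rater at two
occasions (intra-rater) or the subject's two paired raters at one occasion
(inter-rater) — and a *unit* (a single item or a sum group). Each comparison
reduces to a C×C contingency table `n_ij`, on which all statistics operate.

The statistics are rank-invariant: they use only the ordering of
categories, never arithmetic on the codes, so they are unchanged by any
monotone relabelling of the scale. Disagreement is decomposed into:

* a systematic shift in position, **RP** — the difference between the
  probabilities that an independent draw from the second assessment's
  marginal exceeds / falls below one from the first;
* a systematic difference in concentration, **RC** — the probability that a
  second-assessment value falls strictly between two independent
  first-assessment values, minus the converse;
* random (individual) variability, **RV** — the normalised sum of squared
  differences between each cell's augmented mean ranks under the two
  orderings (`6 Σ n_ij (R1_ij − R2_ij)² / n³`).

All three are zero for a purely diagonal table; RP and RC change sign under
transposition while PA and RV are invariant; RP and RC (and the ROC-style
cumulative-marginal curve) depend on the table only through its marginals.
These laws, and exact agreement of every closed form with exhaustive
pair/triple/subject-rank enumeration on random small tables, are enforced
by the test suite — the enumeration oracles, not the formulas, are the
correctness authority here.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| tolerance set `k` | {1, 2} | accepted point differences for sum-score PA rows |
| PA threshold | 70% | satisfactory agreement; also the target of the minimum-tolerance search |
| negligibility band | ±0.1 | below it, RP/RC (and RV) are clinically negligible |
| floor/ceiling threshold | 15% | strict `>` rule on subjects at the scale extremes |
| bootstrap `B` | 2000 | percentile-bootstrap resamples |
| confidence level | 0.95 | two-sided percentile interval |

Display convention: estimates with absolute value ≤ 0.01 print as `0`,
everything else with two decimals; machine-readable JSON always carries
full precision.

## Inference

Confidence intervals use a nonparametric percentile bootstrap over
subjects. Because every statistic is a function of the contingency table
alone, resampling n subject pairs with replacement is implemented as one
multinomial redraw over the table's nonempty cells, making B = 2000
replicates cheap even on 35-category sum-score tables. Intervals are
deterministic given a seed; the pipeline derives one child seed per
(comparison, unit, statistic) from the master seed in a fixed order, so a
whole report is reproducible byte-for-byte (`report.json` deliberately
contains no timestamp for this reason).

Classification combines the band and the interval: `significant`
(|estimate| ≥ 0.1, CI excludes 0), `tendency` (|estimate| ≥ 0.1, CI includes
0), `negligible_significant` (|estimate| < 0.1, CI excludes 0), else
`none`. The "tendency" notion is operationalised purely as a non-negligible
point estimate whose CI still includes zero; no separate asymmetry test is
applied. RV, being nonnegative, inherits the same rule; its percentile CI
can never extend below zero.

On simulated null studies (no systematic shift, default rater noise, n = 60,
total-score unit) the measured rate of 95% intervals excluding the true
RP = 0 is ≈4–5% and coverage ≈95–96% (500 replicates; recomputed by
`scripts/acceptance.py` and the test suite).

## The synthetic study generator

`generate_study` emulates a pairwise reliability design: subjects are
assigned round-robin over all unordered pairs of the rater pool (a 3-rater
pool with 60 subjects gives each rater 40 subjects), each pair scores every
subject independently at two occasions. Two mechanisms with known
parameters drive disagreement:

* **shift_prob (δ)** — between occasions a subject's latent item level
  increments by one with probability δ, capped at the item maximum. This
  models genuine change (e.g. spontaneous recovery between consecutive days
  early after stroke) and surfaces as positive intra-rater RP.
* **noise_prob (ε)** — each recorded rating independently deviates ±1 from
  the latent level with probability ε (symmetric direction, reflected at
  the bounds). This models rater variability and surfaces as RV > 0 with
  RP ≈ 0, because the perturbation is symmetric.

Defaults were chosen once as a realistic inpatient scenario: item marginals
(0.10, 0.20, 0.70) per 3-level item (a mildly-to-moderately impaired cohort,
expected total ≈ 27/34), δ = 0.1, ε = 0.05 (experienced, jointly trained
raters deviating one level on about one rating in twenty).
`induced_marginals` propagates δ and ε to the exact per-occasion category
distributions, giving closed-form expectations for parameter-recovery tests
(the empirical intra-rater RP converges to the RP of the induced marginals).

What the generator does **not** model: item difficulty hierarchies (each
item is drawn independently from the same family of marginals, whereas real
FMA-LE items form a near-Guttman hierarchy), rater-specific bias or skill,
correlated errors across items within an assessment, and multi-step
changes. Consequently, passing tests demonstrate the statistical machinery
and its calibration under a faithful *design*, not the numerical values any
particular clinical cohort would produce; exact agreement on the 35-category
total score is lower in this simulation than in real cohorts because
independent item noise compounds multiplicatively.

## Numerical and design choices

* **RC normalisation.** The convention `ν = 2` (unordered extreme pair) is
  used, under which the attainable extreme is ±0.5 — reached when one
  assessment is entirely central and the other splits evenly over the two
  extremes. The ±0.1 negligibility band is the functional contract and is
  unaffected by this choice. Any 2-category table has RC = 0 exactly (no
  category lies strictly between two others).
* **RV range.** With the `6/n³` normalisation RV is ≈1 for independent
  assessments on a fine scale, but ties depress it on coarse scales (the
  independence limit with uniform marginals is `(1−1/C)²(C²−1)/C²`, e.g.
  0.61 at C = 3..5), and adversarial rank-reversal tables can exceed 1. The
  implementation reports the statistic as defined; interpretation uses the
  <0.1 negligibility convention.
* **Orientation.** Rows are the first-listed assessment (occasion 1 for
  intra; the first rater of the subject's pair — the occasion-1 test leader
  — for inter), so RP > 0 always reads "higher categories at the second
  listed assessment".
* **Sum-score tables** span the full theoretical range (35 categories for a
  0–34 total) even when levels are unobserved; empty categories contribute
  nothing to the statistics but keep the point-tolerance metric honest.
* **Missing data.** Assessments missing any item of a group are excluded
  from that group's sums, and subjects missing either side of a comparison
  are dropped, both with logged warnings; subjects are the unit of
  exclusion and of resampling throughout. A comparison with zero usable
  subjects is reported as empty rather than failing the whole run.
* **Floor/ceiling** is screened on the whole-scale sum group at the first
  occasion, one total per subject taken from the first-listed (test-leader)
  rater, with the strict >15% rule — 9 of 60 at the maximum is *not* a
  ceiling effect, 10 of 60 is.
* **Degenerate inputs.** A single-category table returns PA = 100 and
  RP = RC = RV = 0 rather than erroring; a tolerance search always
  terminates because PA at k = C−1 is 100 by construction.
* **Problem sizes.** Replicated-study checks use 200 replicates per shift
  level for parameter recovery and 500 replicates for null calibration at
  n = 60 subjects with B = 2000 bootstrap resamples — enough for Monte-Carlo
  error of roughly ±1 percentage point on a 5% rate.

## Known limitations

* Bootstrap percentile intervals on very small samples (n ≲ 20) of coarse
  items are discrete and can be conservative; the calibration figures above
  are for n = 60 at sum-score resolution.
* The "tendency" flag depends on the negligibility band and the CI only; it
  is not a formal test of CI asymmetry.
* Inter-rater comparisons assume exactly two raters per subject (the
  pairwise design); designs with three simultaneous raters per subject are
  rejected at validation.
* No multiple-comparison adjustment is applied across items — flags are
  per-unit descriptions, not family-wise hypothesis tests.
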