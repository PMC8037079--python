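# Methods

## Problem and scope

Severely injured geriatric patients (≥ 65 years) have distinctly higher
trauma mortality than younger patients, and the established prediction
models are either built for general trauma populations or require many
variables that are impractical at the bedside. The package implements an
additive five-item score for in-hospital mortality (one point per present
finding: age ≥ 80, maximum AIS ≥ 4, pre-ICU red-cell transfusion, ASA ≥ 3,
GCS ≤ 13), the screening procedure that selects such criteria from
registry data, and an evaluation layer (mortality by score level, ROC/AUC
comparison against GTOS, maximum AIS, ISS and age). Richer comparators that
need coefficients not available here (RISC-II, EMAT/qEMAT, frailty indices)
are out of scope.

## Cohort model and inclusion filter

A record carries demographics, a six-region AIS profile (head/neck, face,
chest, abdomen, extremities including pelvis, external — the ISS
convention, needed so ISS and maximum AIS are defined consistently), GCS,
ASA, systolic blood pressure, a pre-ICU transfusion flag, ICU admission,
mechanism, transfer status, hospital region and the outcome. The inclusion
filter keeps patients aged ≥ 65, primarily admitted to a European hospital,
with known transfusion status, who are either relevantly injured
(max AIS ≥ 3) or mildly injured but ICU-treated. Each removed record is
logged with the *first* matching reason in a fixed precedence order
(under-65, non-European, transfer, missing transfusion data, minor trauma
without ICU), which makes the exclusion log deterministic when several
rules fire; counts are always conserved and the filter is idempotent.

Missing transfusion status excludes a record (a score component and a GTOS
input would otherwise be undefined in an analysis of transfusion effects),
while missing GCS or ASA does not: registry screens routinely tolerate
per-variable missingness, which is why per-candidate evaluable counts are
reported in the screening output. At scoring time the caller chooses the
policy: `zero_points` (default — unknown criteria contribute nothing, so a
bedside score remains computable with partial data) or `propagate_missing`
(complete-case analyses).

## Score development

1. **Dichotomization.** Continuous candidates are dichotomized by searching
   a small grid — age ∈ {65, 70, 75, 80, 85} (≥), GCS upper bound
   ∈ {8, 12, 13} (≤), max AIS ∈ {3, 4, 5} (≥), ASA ∈ {2, 3} (≥) — for the
   least extreme cut-off whose exposed-group mortality reaches the target
   (default 0.30; ties go to the cut-off exposing more patients). The grids
   are a design choice: they contain the clinically conventional break
   points for these instruments. Sex, penetrating mechanism, transfusion
   and SBP ≤ 90 mmHg enter with their natural dichotomies.
2. **Univariable screen.** For each dichotomy a 2×2 table against death is
   formed; the odds ratio is the crude cross-product (a·d)/(b·c) with a 95%
   Wald CI, exp(ln OR ± 1.96·SE), SE = √(1/a + 1/b + 1/c + 1/d). No
   continuity correction by default; Haldane–Anscombe k = 0.5 is available
   for zero cells, which are otherwise flagged (OR 0/∞, CI undefined) and
   never silently dropped.
3. **Optional multivariable mode.** A joint logistic model over all
   dichotomized candidates (complete cases) is fit by iteratively
   reweighted least squares (convergence max |Δβ| < 1e-8, at most 100
   iterations, divergence guard |β| > 30 raising a separation error), and
   adjusted ORs exp(β_j) with Wald CIs replace the crude ones. Both modes
   are exposed because screening practice varies; the default is
   univariable, which matches how such screens are usually tabulated.
4. **Selection.** Candidates with OR > 2.0 (configurable) become one-point
   criteria, emitted in a fixed canonical variable order regardless of
   input order.

The development target mortality is a parameter (default 0.30) because the
two natural conventions — "at least 25%" and "roughly 30% or more" — differ;
either can be set.

## Evaluation

AUC is computed in the Mann–Whitney form with midrank tie handling —
essential for a score taking only six values — and the ROC polygon is built
from thresholds at each distinct score value; the trapezoidal area under
that polygon equals the Mann–Whitney statistic exactly, an identity the
test suite asserts at 1e-12 against a brute-force pairwise oracle.
Confidence intervals use DeLong's asymptotic variance by default (a seeded
stratified bootstrap is available for small samples); a no-signal
simulation checks 93–97% coverage of AUC = 0.5. Higher score means higher
predicted mortality; anti-discriminating scores report AUC < 0.5 and are
not auto-flipped. Score comparisons are computed on the intersection of
records where every requested score is evaluable, so all AUCs refer to the
same patients. Mortality-by-score tables report one row per level 0–5 with
exact (Clopper–Pearson) binomial 95% CIs and count records whose score is
missing under the chosen policy.

## Synthetic registry generator

The generator emulates the marginal structure of a large geriatric trauma
registry so every pipeline stage is testable without restricted data:

* **Age**: truncated normal (mean 77, SD 7.6, floor 65), reweighted across
  the 80-year boundary so P(age ≥ 80) = 0.38 exactly; realized mean ≈ 77.4.
* **Component prevalences** (defaults): max AIS ≥ 4: 0.45, transfusion:
  0.08, ASA ≥ 3: 0.41, GCS ≤ 13: 0.41, male sex: 0.578; mechanism mix
  traffic 0.351 / low fall 0.450 / high fall 0.136 / penetrating 0.026 /
  other 0.037.
* **Dependence**: the five risk components share a Gaussian copula on
  latent severity with exchangeable correlation (default 0.2, the matrix is
  positive definite for ρ ∈ (−0.25, 1)), reflecting that severe anatomy,
  depressed consciousness and transfusion co-occur. Only marginals are
  empirically anchored; the joint distribution is a modelling choice.
* **AIS profiles**: a primary injured region carries the maximum AIS
  (head/neck weighted 0.54 so severe head injury lands near 46%), other
  regions receive minor (AIS 1–2) injuries with probability 0.35 each, so
  ISS, maximum AIS and the head-injury share are internally consistent.
* **Mortality**: logit p = β₀ + Σ β_j x_j on the five indicators. Default
  slopes are logs of odds ratios typical of univariable registry screens
  (2.27, 6.25, 2.99, 2.09, 7.61) used as conditional effects — a stated
  approximation, not a claim about any real registry. The intercept is
  calibrated by bracketed root finding so mean predicted mortality equals
  the target (default 0.223) on the drawn covariates.
* **Missingness**: MCAR after outcome draw — ASA 16%, GCS 5%, SBP 5%,
  transfusion 0% by default, mirroring that per-variable evaluable counts
  differ in real screens.
* **Reproducibility**: all draws flow from one seeded generator; identical
  config + seed gives byte-identical CSV.

Consequences worth knowing: because the components are positively
dependent, crude univariable odds ratios on generated cohorts sit *above*
the conditional exp(β_j) (the transfusion OR lands near 3.8–4.7 against a
conditional 2.99); the joint logistic fit recovers the β_j without bias,
and the test suite checks exactly that. The generator does not emulate
hospital-level clustering, length-of-stay dynamics, non-MCAR missingness,
or the full feature set of multivariable comparators, so passing tests
demonstrate correctness of the pipeline's arithmetic and its qualitative
behaviour (monotone risk in the score, sensible AUC ordering), not
real-world predictive performance.

## Numerical choices

* Wald z = 1.959963984540054 throughout; odds ratios use exact float
  arithmetic on counts.
* IRLS solves the weighted normal equations directly (p ≤ 10 here);
  linear-algebra failure or divergence raises, never returns silently.
* Exact binomial CIs per score level; empty levels report n = 0 with NaN
  rates rather than being dropped.
* Cohort sizes in tests: shared 50,000-record simulated cohorts (seed
  20210325) for distributional checks; 58,055 records for the mortality
  calibration check; small enumerated fixtures everywhere else.

## Limitations

* The score is developed and evaluated here on synthetic cohorts; published
  registry AUCs and score-level mortality rates are not reproducible
  without the restricted source data, and no external validation is
  attempted.
* GTOS is implemented up to the score value; its mapping to a mortality
  probability belongs to the original GTOS logistic model, whose
  coefficients are not part of this package.
* The univariable/multivariable duality in screening is surfaced as a mode
  rather than resolved: crude and adjusted ORs answer different questions,
  and either can drive selection.
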