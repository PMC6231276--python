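# Methods

## Setting and scope

The package analyses direct medical asthma costs from the perspective of a
third-party payer, using administrative claims only: enrollment spans,
billed medical events with ICD-10 codes, and medication fills. Indirect
costs, out-of-pocket spending, multi-year dynamics and clinical severity
measures are out of scope. The default calibration emulates a 2015
Colombian subsidized-regime insurance cohort (20,410 patients, four
severity strata, costs in 2015 International Dollars at 1203.9 COP/I\$).

## Severity grading

Severity is a total, deterministic function of three annual counts —
SABA fills, OCS fills, exacerbations (ED visits + hospitalizations in the
analysis year) — combined as the maximum of a medication grade and an
exacerbation grade so that severity is never under-assessed. The published
medication grid needed two repairs to be total and monotone:

* the severe rule "zero to six SABA fills and three or more … fills" can
  only refer to OCS fills (any other reading contradicts the milder rules);
  it is implemented as `ocs >= 3` at any SABA count;
* the cell (SABA ≤ 3, OCS = 2) is covered by no printed rule; it is
  assigned *moderate persistent*, the smallest completion that keeps the
  grid monotone (it sits between mild persistent at OCS = 1 and severe at
  OCS = 3, and moderate already covers OCS = 2 at SABA 4–6).

Both repairs, and the max-combination, are audited by an exhaustive scan
(SABA 0–12 × OCS 0–6 × exacerbations 0–6): totality, monotonicity in each
argument, and agreement with every explicitly printed rule.

## Cohort selection

A patient enters the cohort on (1) at least one medical event in the
2004–2014 identification window carrying a code equal to or prefixed by
J45/J46 (prefix matching covers sub-codes; non-string codes are logged and
skipped), and (2) day-level gap-free enrollment over the whole 2015
analysis year, with adjacent spans merged. "At least 12 months of
uninterrupted coverage during the cost-analysis period" is read as
calendar-year coverage, the only reading consistent with a
January-to-December analysis window. The manual chart review used in
practice to discard non-asthma procedures is represented by a configurable
code-prefix allow-list. Counts at each funnel step are logged — with
claims data the funnel is the only audit trail. A same-day ED visit
followed by hospitalization counts as two exacerbation events (simplest
rule on billing records; billing chains are not resolved).

## Cost aggregation

Costs accumulate in COP and are converted once at reporting time, avoiding
compounded rounding. Stratified tables report mean/SD/median/IQR on two
bases: all stratum members (zero-utilization patients stay in the
denominator) and users only. ED/hospitalization cells for mild
intermittent patients are *structural* zeros (the grading forbids
exacerbations there) and carry a marker distinct from numeric 0. Printed
precision is a rendering concern; full precision is retained internally.
Weighted-mean identities (Σ nᵢ·meanᵢ = N·mean, component shares of the
total, stratum contributions) are exposed as standalone routines and hold
on any cohort by construction.

## Synthetic claims generator

The generator is the package's stand-in for a proprietary billing
database. What it emulates, per patient:

1. a severity category from the configured mixture (default: the exact
   stratum shares 14191/3680/1408/1131 of 20,410);
2. a (SABA, OCS, exacerbation) triple drawn **uniformly from the severity
   category's rule region** on the capped grid (SABA ≤ 12, OCS ≤ 6,
   exacerbations ≤ 6), so classification round-trips exactly;
   exacerbations are split ED-vs-hospitalization by a per-stratum fraction;
3. demographics (age band, sex, SISBEN level, urban residency) and five
   comorbidity flags from per-stratum margins; a small fraction of records
   lose the sex field, as in real extracts;
4. utilization of the remaining services/medication classes as
   Bernoulli(p) with count 1 + Poisson(0.5) among users;
5. event-level gamma costs (ISO dates inside the analysis year), with a
   configurable fraction of patients made ineligible (coverage gap or no
   identification-window event) so that selection filters something.

**Cost calibration.** The configured cost cells are annual per-patient
(mean, SD) pairs per (stratum × component). Per-event gamma parameters are
solved by method of moments from the cell and the analytic count moments:
per-event mean = cell mean / E[count]; per-event variance from
cell variance − count-driven variance, floored at CV 0.2 when counts alone
exceed the cell variance. Patient-year component totals therefore match
the cells in mean, and in SD where the count process allows. Medication
component cells do not sum to the published any-medication margin; the gap
is carried by the theophylline class (whose own cost cell is unpublished),
so component means sum exactly to the stratum totals (67, 482, 1061,
2235 I\$) and conservation identities hold.

**Effect structure.** A multiplicative covariate effect r(x) (sex, SISBEN
level 1, urban residency, five comorbidities; cost ratios from the
reference adjusted model) scales every cost of a patient, normalised by
its within-stratum expectation E[r|s] so stratum means are preserved. A
purely multiplicative gamma process cannot reproduce simultaneously all
four unadjusted stratum means *and* the published adjusted severity ratios
under the observed covariate distribution — real data are not exactly
multiplicative. The generator resolves this by taking the adjusted
severity ratios (1, 6.63, 13.59, 28.84) as ground truth of the
positive-cost conditional mean, anchoring the severe stratum's all-members
mean at its unadjusted value (2235 I\$), and letting the other three
stratum means follow (they land 4–16% below their unadjusted table values;
only mild intermittent has a positive probability of a zero-cost year,
which the anchoring accounts for analytically). `Calibration` exposes the
per-stratum scale factors, E[r|s], and positive-cost probabilities so
tests can check convergence against the *effective* configuration.

**What the generator does not emulate:** within-year seasonality,
correlated utilization across components (components are conditionally
independent given severity), covariate-dependent utilization, billing-code
noise, re-enrollment identity problems, and the real selection funnel's
attrition counts. Consequently, passing recovery tests shows the pipeline
is correct and well-calibrated under a known data-generating process — not
that real claims satisfy that process. Rule-region sampling is uniform, so
medication-utilization *marginals* (e.g. the share of mild-intermittent
patients with a SABA fill) deliberately differ from the reference
utilization table; cost cells, stratum shares and the effect structure are
the calibrated quantities.

## Statistical procedures

* **Pearson chi-square** for proportions (own closed form; cross-checked
  against an independent implementation and a margin-fixed permutation
  null — the asymptotic tail is compared with the permutation *mid-p*,
  which it approximates on a discrete 2×2 null).
* **Cochran-Armitage trend** with equally spaced scores 1..k by default;
  two-sided normal p; sign gives the direction. Cross-checked against a
  10⁵-permutation null.
* **Welch ANOVA** (heteroscedastic F with Welch–Satterthwaite denominator
  df) and **Games-Howell** post hocs
  (q = |Δ|/√((v₁/n₁+v₂/n₂)/2), studentized-range reference with pairwise
  Welch df). Both match pingouin to ~1e-8; the k = 2 reductions to Welch's
  t are verified algebraically. Games-Howell p-values are exact by
  default; a "tabulated" mode interpolates the classical tables
  (~3-decimal agreement, orders of magnitude faster) for simulation loops,
  and CI critical values always use the tabulated inverse.
* **Gamma log-link GLM** with sandwich covariances, via statsmodels IRLS
  (HC1 by default, matching common practice for "robust" errors).
  Cost-ratio CIs use exp(b ± 1.96·SE). Records with non-positive outcomes
  (outside the gamma support) or missing covariates are excluded with
  logged reasons; terms constant in the included rows are dropped with a
  flagged report rather than failing. The univariate screen forces age,
  sex and socio-economic level into the model and admits any candidate
  with a joint robust-Wald p < 0.1.
* Shapiro-Wilk and Levene diagnostics are reported descriptively only;
  they justify the heteroscedastic choices and gate nothing.

## Numerical and design choices

* Severity dummies are coded against mild intermittent; SISBEN is entered
  as a level-1 indicator versus levels 2–3/other.
* Gamma draws use shape = (mean/SD)², scale = SD²/mean; SD = 0 yields a
  degenerate constant; mean 0 with SD > 0 is a configuration error.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical config + seed gives byte-identical
  claims tables and manifests.
* Simulation sizes used in the test suite: cohort-scale checks run at
  n = 20,000 with 10 replicates for CI-coverage of the severity ratio;
  type-I calibration of Welch/Games-Howell uses 500 replicates of four
  gamma groups (n = 500/400/300/250, shapes 5/3/2/1, common mean 100) —
  sizes at which the asymptotic tests operate in their nominal regime;
  permutation oracles use 10⁵ permutations.

## Known limitations

* The generator's conditional independence of components understates the
  variance of patient totals relative to real claims (where hospital stays
  and prescriptions co-occur); stratum-total SDs are nevertheless within
  ~10–25% of the reference values because the count processes contribute
  most of the spread.
* The anchored effect structure means unadjusted stratum means other than
  the severe anchor sit a few percent below the reference table; both
  quantities cannot hold exactly at once (see above).
* "One fill" is one dispensation record; pack sizes and days-supply are
  not modelled.
* The GLM is a one-part model: zero-cost patient-years are excluded, not
  modelled; no hurdle/two-part extension is provided.
* Welch/Games-Howell size is only guaranteed in the moderate-to-large
  sample regime; with very small, very skewed groups the omnibus test is
  known to be liberal.
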