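# Methods

## Scope and data model

One record per woman scheduled for surgery for a pelvic mass: menopausal
status, CA125 (U/mL), HE4 (pmol/L, optional), the ten IOTA simple-rules
feature flags plus colour score, the five RMI ultrasound feature flags, an
optional expert-ultrasound call, and the histology reference standard
(benign / borderline / malignant) with an ovarian/non-ovarian flag, site
(cancer centre vs general unit) and optional FIGO stage. The evaluation
truth is *malignant iff histology is borderline or malignant*: borderline
tumours count as disease. Feature flags are recorded directly (as they are
at the scan); no morphology is derived from images, and no menopause rule
is imputed from age.

Validation is total and non-throwing (`validate_record` returns named
violations); strict CSV reads raise on the first violation, lenient reads
drop and log. Flags are encoded 0/1, missing optional values as empty
cells, so cohorts round-trip losslessly through CSV.

## Classification rules

* IOTA: malignant iff ≥1 M-feature and no B-feature; benign iff ≥1
  B-feature and no M-feature; otherwise inconclusive. Colour score 1 *is*
  the no-flow B-feature and score 4 the strong-flow M-feature; scores 2–3
  contribute to neither. Size boundaries live in the flag definitions
  exactly as published (≥100 mm malignant flag, <100 mm benign flag,
  <7 mm solid-component flag), so a 100 mm smooth multilocular mass
  carries neither size flag — the printed strict/non-strict inequalities
  are followed rather than inventing rounding.
* ROMA: the menopause-specific logistic predictive index on
  (ln HE4, ln CA125); the score is compared **unrounded** against the
  published cut-offs, inclusive at the boundary (≥ 7.4 pre, ≥ 25.3 post).
  A non-positive or missing marker makes ROMA *unavailable* for that
  record (logarithm undefined) rather than clamped to a floor.
* RMI: variant I conventions — U ∈ {0,1,3} from the count of the five
  features, M ∈ {1,3} — because the source formula `RMI = U × M × CA125`
  presumes them; the mapping and the ≥ 200 cut-off are configurable
  through `Thresholds`.
* Strategies: IOTA-first strategies adopt the conclusive IOTA call and
  delegate only inconclusive masses to the fallback. A record missing a
  needed component (HE4, or the expert call on an inconclusive mass) is
  excluded from that strategy and counted, never imputed. `IOTA_ONLY` is
  exposed as a conclusive-stratum pseudo-strategy so the conclusive-only
  tables can be produced directly.

## Diagnostic metrics

Sensitivity = tp/(tp+fn) over histology-malignant records, specificity =
tn/(tn+fp) over benign, accuracy = (tp+tn)/n over all analysed records.
CIs are Clopper–Pearson (beta quantiles) by default; Wilson is available
because the CI method behind published tables of this kind is often
unstated — point estimates, not interval bounds, are the reproducible
surface. Zero-denominator metrics are flagged undefined instead of NaN.

McNemar comparisons condition on the right subset per metric (diseased for
sensitivity, non-diseased for specificity, everyone for accuracy), on the
intersection of the two strategies' evaluable records. Both the exact
two-sided binomial p (2·P(X ≤ min(b,c)) at p = ½, capped at 1; p = 1 when
b+c = 0) and the continuity-corrected (|b−c|−1)²/(b+c) chi-square p are
always computed; the exact value is the headline for small discordance.
No multiplicity adjustment is applied; p-values are reported raw.

Display rounding is half-up to one decimal of a percent and never feeds
back into any comparison or test.

## Non-inferiority of correlated accuracies

For paired correctness indicators with discordant probabilities p10
(reference only correct) and p01 (comparator only correct), non-inferiority
at margin d tests H0: p01 − p10 ≤ −d one-sided. The statistic is the
restricted-MLE score statistic: the constrained MLE of p01 under
p01 − p10 = −d solves a quadratic (the concentrated multinomial
likelihood), giving Z = (x01 − x10 + n·d) / √(n(2·p̃01 + d(1−d)))
evaluated at δ0 = −d. Power is estimated by multinomial simulation of the
four cells, built from the two marginal accuracies and a phi-correlation
between correctness indicators, with an explicit feasibility check that
names the admissible correlation interval. Simulated type-I error at the
boundary null is ≈ 0.047–0.050 for n ≥ 160 at α = 0.05.

The worked design in `examples/power_calculation.py` reads the published
sizing narrative (160 paired women, reference accuracy ~85%, "actual
difference 5%", 5% margin, 90% power) as: reference 0.80, comparator 0.85,
margin 0.05, correlation 0.4 — a true difference of −5% would sit exactly
on the margin and cannot yield 90% power, so the difference must favour
the comparator; correlation 0.4 is a moderate, plausible agreement level
that reproduces the claimed power (~91%).

## Synthetic cohort generator

The generator emulates the *statistical structure* of a surgical
pelvic-mass cohort, not any individual patient data:

* site (cancer centre with probability 0.494), then truth class: overall
  prevalence 0.206 of truth-malignant masses, split by site through
  relative risks (≈1.60 / 0.42) normalised so the mixture reproduces the
  configured prevalence exactly; 36/179 of truth-malignant masses are
  borderline;
* menopausal status premenopausal with probability 0.693, independent of
  class (a simplification; in real cohorts malignancy and menopause are
  associated);
* colour score from a class-conditional 4-category distribution, flow
  flags derived from it; remaining feature flags conditionally independent
  Bernoulli given class, ascites drawn once and shared between the
  M-feature and RMI sets;
* CA125 and HE4 log-normal given (class, menopause) — the standard
  positive-skew model for these markers; borderline tumours get
  attenuated feature and marker separation;
* expert call = truth flipped with probability 1−0.81 (malignant) or
  1−0.717 (benign); by default the expert is recorded only for
  inconclusive-IOTA women, as in practice;
* FIGO stage for invasive malignant records from (0.447, 0.132, 0.219,
  0.105, 0.096) over I/II/III/IV/unstaged; borderline tumours are left
  unstaged so stage-restricted tables cover invasive cancers only;
  7.5% of masses are non-ovarian.

Default feature/marker parameters were fixed once by closed-form
calibration so that the implied operating points are realistic: IOTA on
its conclusive stratum ≈ 81% sensitive / 98% specific, ROMA alone ≈ 79% /
83%, RMI alone ≈ 62% / 96%, inconclusive rate ≈ 27% (within the 20–30%
band typical of simple-rules cohorts), expert fallback 81% / 71.7%.

`analytic_operating_points` computes every strategy's exact
sensitivity/specificity under the model: feature patterns are enumerated
exhaustively (the ascites coupling between IOTA and RMI is handled by
enumerating their joint), and marker thresholds reduce to normal tail
probabilities on the log scale (ROMA's decision boundary is linear in
(ln HE4, ln CA125), hence Gaussian under the model). This closed form is
the oracle for the pipeline's parameter-recovery tests: on a
50,000-record cohort every strategy's empirical operating point must fall
within 3 binomial standard errors of it.

Reproducibility: one seeded NumPy generator per cohort; draws occur field
by field in a fixed documented order, so adding fields appends draws
without shifting existing ones; cohorts are bit-identical under a fixed
seed and parameter digest.

### What passing tests do and do not show

The generator's conditional-independence and log-normality assumptions
are chosen for analytic tractability. Passing parameter recovery shows the
*pipeline* is correct — classification, composition, bookkeeping and
intervals — not that real tumours behave this way. In particular: markers
are not stage-dependent (real stage-I cancers have lower CA125, which is
why RMI is weak on early disease — the stage-I table here is structural,
not a calibrated reproduction); feature correlations beyond the ascites
and colour-score couplings are absent; menopause is independent of class;
and the expert model is a fixed error rate, not a model of expert
reasoning.

## Problem sizes and numerical conventions

Default analyses run at the study scale (n = 690); validation uses
50,000-record cohorts for parameter recovery, 20,000 Monte-Carlo
replicates for test calibration, and 2,000 replicates per grid point for
Clopper–Pearson coverage at n = 50. Thresholds are inclusive at their
printed boundary; the logistic transform is evaluated on its stable
branch so extreme predictive indices cannot overflow; degenerate CI
boundaries (x = 0 or x = n) are returned exactly as 0 or 1; degenerate
marker scales (σ = 0) give step-function operating points.

## Known limitations

* The ovarian/non-ovarian flag is carried as data; whole-population
  analyses filter on it directly.
* Newer continuous models (logistic-regression risk models, simple-rules
  risk, ADNEX) are out of scope, as are assay calibration, cost
  effectiveness, and any image handling.
* The expert call is a recorded binary label; availability of expertise
  is a data property (`expert_coverage`), not a modelled process.
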