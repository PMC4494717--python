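# Methods

## Scope and data model

The package analyses cohorts of infants assessed for bronchiolitis on two
ordinal severity scales — a four-item clinical score (items 0–3, total
0–12) and a four-component lung-ultrasound score (items 0–2, total 0–8) —
together with an oxygen-requirement outcome and RSV status. The unit of
analysis is one infant (`CohortRecord`), carrying pre-coded item values
for the clinician and for two sonographers, so the package consumes
already-interpreted findings; image acquisition and B-line detection are
out of scope, as are alternative published bronchiolitis scores.

## Banding rules and rubric gaps

The published rubric leaves three codings ambiguous; the package resolves
them explicitly and exposes each as a `ScoringConfig` field:

* **Respiratory rate exactly 70/min** falls between the "61–69" and ">70"
  bands. Default: item 3 (`rr_boundary_70=3`) — clinical severity scores
  conventionally round up.
* **Extension bands share endpoints** ("0–6", "6–12", ">12" intercostal
  spaces). Default `extension_band_rule="lower"`: 0–6 → 0, 7–12 → 1,
  ≥13 → 2 (the lower band wins at a shared endpoint); `"upper"` moves 6
  into the middle band.
* **LUS total exactly 3** is unassigned by the oxygen rule, which defines
  only ">3 → oxygen" and "<3 → no oxygen". Default: negative, so the
  positive class matches the literal ">3" definition
  (`oxygen_threshold=3`, strict inequality).

A consolidation of exactly 1 cm codes 2 ("1 cm or more" is inclusive).
Dyspnea, accessory-muscle and auscultation items are accepted only
pre-coded: their rubric descriptors are multi-sign clinical judgments
with no mechanical encoding.

## Agreement statistics

Kappa is **unweighted**: the grades are ordinal, but the source analysis
used plain Cohen's kappa, and weighted or multi-rater variants are out of
scope. The significance test uses the H₀ (κ = 0) standard error

    se0 = sqrt(Pe + Pe² − Σᵢ pᵢ· p·ᵢ (pᵢ· + p·ᵢ)) / ((1 − Pe) · sqrt(n))

which depends only on the marginals — this is the denominator of the
standard large-sample kappa test and reproduces the published standard
errors (0.0765 and 0.0711) exactly. The p-value is the one-sided
upper-tail normal probability; `KappaResult.display_p()` truncates to
three decimals ("0.000" below 0.0005), mirroring the source's reporting.
Categories are fixed to the four-level grade set even when a level has
zero counts (the clinician assigned no "normal" among 106 cases), so
marginal vectors keep length 4. Degenerate tables (both raters confined
to one category, Pe = 1) raise, except for the perfect-agreement corner
Po = Pe = 1, reported as κ = 1 with NaN test statistics.

## Diagnostic accuracy and comparisons

The source never names its confidence-interval method. Both common ones
are implemented: **Wilson score** (the default — it reproduces the
published specificity interval 93 %–99.8 % exactly) and exact
**Clopper–Pearson** (which reproduces the published sensitivity lower
bound 82.2 %). The published sensitivity interval mixes the two methods
between its ends; no single method reproduces both, so reproduction
checks use Wilson for the specificity interval and Clopper–Pearson for
the sensitivity lower bound only. Wilson endpoints are clamped to exact
0/1 at x = 0 / x = n, where they are analytically exact.

χ² tests are Pearson's on 2×2 tables **without continuity correction**,
verified against the published statistics (e.g. 44.3, 24.9, 41.7, 24.4,
21.5, 9.21), computed via `scipy.stats.chi2_contingency` and
property-tested against the shortcut form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).
Expected cells below 5 emit a warning but do not block computation — the
source ran χ² on such tables. Fisher's exact test, odds ratios and ROC
analysis are out of scope (no per-threshold data exist).

## Fixtures and known inconsistencies

`study_fixtures()` packages every printed count: the two rater-pair
marginal sets, the oxygen 2×2 (TP=28, FP=1, FN=1, TN=76 — the unique
non-negative integer table with n = 106, 29 condition-positives and the
printed 96.6 %/98.7 % metrics), and all 28 group-comparison rows. Two
published values are inconsistent with their own printed inputs and are
flagged rather than matched: z = 10.19 for the first rater pair (its own
K = 0.80 and se = 0.0765 give 10.49), and χ² = 26.4 for "consolidation
≥1 cm, mild vs moderate-severe" (its own counts 3/76 vs 13/30 give 26.0).
The severity marginals follow the source's Results (76/27/3), which
reproduce the published expected agreement of 52.3 %, rather than its
abstract (74/30/2). Reproduction tolerance is 1 % or one unit of the last
printed decimal, whichever is looser, because the source truncates rather
than rounds (its printed "44.3" is a computed 44.39).

## Synthetic-cohort generator

No patient-level data were released, so the generator emulates the cohort
from its printed margins. Factorisation: clinical items and LUS findings
are **conditionally independent given a latent severity grade** — the
simplest structure consistent with the published marginals and agreement
levels, since only marginals and 2×2 slices were printed; any joint
matching those is admissible.

Defaults (the study's conditions):

| parameter | default | source of the value |
|---|---|---|
| cases / controls | 106 / 25 | cohort sizes |
| severity probs (mild, mod, sev) | 76/106, 27/106, 3/106 | clinical grade counts |
| RSV prevalence (cases) | 73/106 | rapid-test positives |
| extension given severity | mild (.82,.18,0), mod-sev-pooled split | printed mild vs moderate-severe frequencies |
| consolidation given severity | mild (.70,.27,.03), moderate (.15,.42,.43) | printed frequencies |
| anterolateral / posterior-interstitial given severity | monotone-in-severity tables | unpublished per-severity; chosen so the severity mixture reproduces the published overall frequencies |
| rater-2 stay probability | 0.90 | matches the 89.6 % inter-sonographer agreement; disagreements move to adjacent grades only, mirroring the observed normal↔mild confusions |
| P(oxygen \| LUS total 0–8) | (.005,.005,.005,.04,.86,.95,.96,.97,.97) | monotone step calibrated once so prevalence ≈ 29/106 and the >3 rule attains ≈97 %/97 % sens/spec |

Clinical items are drawn uniformly from the 4-tuples whose total lies in
the drawn grade's band; the second sonographer's exam is copied when the
grade is kept and redrawn uniformly within the new grade's band when it
moves. Controls score 0 on both scales, never require oxygen, and carry an
isolated B-line (coded 0) with probability 0.2. Demographics (age, sex,
delivery, feeding, prematurity) follow the printed cohort description and
feed no analysis. One `numpy.random.default_rng(seed)` stream per cohort;
no global RNG state.

**What the generator does not emulate:** within-severity correlation
between LUS components (real B-line extension and consolidation co-occur
beyond what severity explains), viral dynamics, treatment effects, and
longitudinal resolution beyond a constant resolved-at-discharge flag.
Passing calibration tests therefore shows the pipeline recovers the
generator's structure at the study's margins — not that the scores would
perform identically on real infants. Under the defaults the population
agreement between clinical and LUS grading is κ ≈ 0.65 (the published
cohort's 0.80 lies above it; the independence factorisation spreads LUS
totals slightly more than the real joint did), and calibration tests
assert the bounds κ > 0.6 and sensitivity/specificity > 0.85 at n = 5000.

## Problem sizes and determinism

Calibration and parameter-recovery checks use 5 000-case cohorts
(binomial 3-SE bands are then tight enough to detect miscalibration) and
one 10 000-case draw for the oxygen-prevalence check; the full test suite
and the acceptance script each run in well under a minute on one CPU.
Reports are deterministic: identical cohort, config and seed give
byte-identical JSON (`AnalysisReport.to_json` sorts keys and stores no
timestamps), with full-precision values stored and truncation applied
only in display helpers.
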