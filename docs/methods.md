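# Methods

## Classification model

Each risk-factor entry is normalized (NFKC, lowercase, whitespace collapse,
dash/apostrophe standardization, trailing sentence punctuation stripped; the
map is idempotent) and split into sentences at `.`/`;` boundaries that are
not inside decimal numbers. Three phrase dictionaries (past-use, denial,
family-attribution) are matched case-insensitively on word boundaries; a
quantity grammar recognizes `<number> [unit] <period>` with numeric words up
to twenty, ranges resolved to their midpoint, and per-day/per-month
quantities converted to weekly equivalents (× 7 and × 7/30).

Decision precedence inside one note is **past keywords > quantity band >
denial > unknown**:

* a sentence containing a family marker ("father", "family history", ...)
  is attributed to a relative and contributes nothing;
* a denial phrase voids any quantity in the same sentence (simple
  sentence-window negation — "denies alcohol, maybe 2/wk" is a denial,
  while "no more than 2/wk" parses as a quantity because "no more than" is
  not a denial phrase);
* when several quantities survive, the largest weekly equivalent is used
  (risk-conservative);
* bands are sex-agnostic by default: light (0, 3), moderate [3, 15], heavy
  (15, ∞) drinks/week, an explicit 0 mapping to non-drinker. A
  `sex_specific_bands` option (off by default) substitutes the guideline
  heavy thresholds (> 15 male / > 10 female); the primary analysis the
  package reproduces uses the sex-agnostic bands.

Patients with several notes are resolved to the **most recent** note inside
the study window (ties on date break to the heavier-risk label;
`heaviest` and `first` policies are selectable). The published pipeline
reports one category per patient without stating its resolution rule;
recency was chosen because the clinical question is current status.

The shipped dictionaries are seeded from the four published past-use
phrases and the category names; the original study's full keyword appendix
is not public, so dictionaries are plain-text files that can be replaced
wholesale without touching code.

## Cohort construction

Eligibility: age ≥ 18 with ≥ 1 encounter in the half-open window
[2015-01-01, 2018-01-01). The right endpoint is treated as exclusive; age
is computed at the patient's last in-window encounter (the source analysis
does not anchor age, and the last contact is when the note is plausibly
current). Visit frequency is the median of per-calendar-year encounter
counts over the window years (zero-count years included), dichotomized at
> 3. Urban means CMA population ≥ 100,000 (inclusive); the synthetic
extract carries the population directly since a postal-code lookup is out
of scope. Age is dichotomized at the observed cohort mean by default; fixed
cuts (e.g. the published 50.7 / 49.6 years) are configuration options.
Patients whose note could not be categorized count as documented (they have
a record) but are excluded from the heightened-risk denominator; a
configuration flag reverses the first half of that rule.

Missing covariates are excluded listwise per model with logged counts.

## Regression models

Both models are marginal logistic regressions estimated by GEE with
patients clustered on provider, exchangeable working correlation
(independence selectable) and robust sandwich standard errors — choices
made because the source analysis states only "generalized estimating
equations" with provider repetition. 95% CIs are Wald intervals on the log
scale. "Unadjusted" odds ratios are single-term clustered fits, matching
how adjusted/unadjusted columns are usually produced in this literature;
the crude cross-product OR with a Woolf CI (Haldane–Anscombe 0.5 correction
on zero cells, flagged) is kept as an independent oracle, not as the
reported unadjusted estimate. Degenerate inputs are refused explicitly:
constant outcomes, single-cluster data, non-finite coefficients.

No multiple-testing correction is applied (none is applied in the source
analysis); the report footer says so.

One naming wrinkle is surfaced rather than resolved: the source text says
"osteoarthritis" in its covariate section but "osteoporosis" in its model
tables. The package models a single bone/joint condition flag named
`osteoarthritis`.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
clinical realism:

* independent per-patient covariates — sex (P(male) = 0.4292), age
  truncated-normal(50.7, 17.5) on [18, 100], urban 0.8453, eight condition
  flags at the reference cohort's pooled prevalences;
* providers with sex ~ Bernoulli(0.5), age truncated-normal(49.6, 11),
  99.4% family physicians; patients assigned to providers with mildly
  unequal Dirichlet weights (`provider_concentration` = 50) so clusters are
  near-uniform around n_patients/n_providers;
* encounter counts per calendar year negative-binomial with mean 4.9 and
  dispersion 0.85 (variance ≈ 33, matching the reported SD ≈ 5.6–5.9);
  every patient is guaranteed one in-window encounter so the generated and
  eligible populations coincide; birth dates are back-computed so that age
  at last encounter equals the drawn age;
* documentation ~ Bernoulli(expit(β₀ + xᵀβ)) with β defaulting to the
  published adjusted log-ORs and β₀ solved by root-finding on the realized
  linear predictors so the marginal rate equals `p_document_base` (0.406);
* conditional on documentation, a note is unclassifiable with probability
  0.0492 (the published unclassified share) independent of covariates;
  among classifiable notes, heightened risk follows a second calibrated
  logistic model (age entering per-year), heavy vs past and
  none/light/moderate are split in the published proportions, and band
  categories receive integer weekly quantities inside their band
  (light {1, 2}, moderate 3–15, heavy 16–40);
* notes are rendered from templates that the default classifier provably
  round-trips; `text_noise_rate` (default 0) replaces a note with an
  ambiguous fragment — ambiguity at the published rate is already carried
  by the unknown mix share, so extra noise is a knob, not a default.

The provider random-intercept SD defaults to 0, so the fitted marginal
model is exactly well specified and the generator's log-odds are the
estimands; a nonzero value induces real intra-cluster correlation but
attenuates marginal effects relative to the conditional inputs. Because
covariates are independent, the generator cannot reproduce confounding
patterns of real EMR data (e.g. the published crude-vs-adjusted diabetes
reversal arises there from covariate correlation); passing parameter
recovery here demonstrates correctness of the estimation machinery, not
robustness to real-world confounding, measurement error or informative
documentation.

## Numerical and reporting conventions

* Intercept calibration by Brent root-finding on [-35, 35], xtol 1e-12;
  degenerate targets 0/1 short-circuit to ∓∞.
* Percents are rounded half-up to one decimal, odds ratios to two decimals
  (the precision of the reference tables); `round_half_up` uses decimal
  arithmetic, not banker's rounding.
* Determinism: one `numpy` Generator seeded from the config; the pipeline
  fans a global seed out to stages through
  `SeedSequence([global_seed, stage_index])`, keeping derived seeds below
  2³¹.
* Tie-breaks: equal-date notes resolve to the heavier-risk label under the
  severity order UNKNOWN < NONE < LIGHT < MODERATE < PAST < HEAVY.

## Problem sizes used in the test suite

Unit and property tests run on a 4,000-patient extract (25 providers).
Parameter-recovery checks use 20 replicates of 200,000 patients across 200
providers, covering the focal terms (male documentation OR 1.09; male,
depression and rural heightened-risk ORs 3.27, 2.01, 1.35); the acceptance
script averages three such replicates. These sizes give CI half-widths
comfortably narrower than the effects being recovered while keeping a full
run in minutes on one CPU.

## Known limitations

* Note templates are an invention of this package; the distribution of
  real documentation styles (structured field vs narrative) is unknown, and
  round-trip accuracy on templates says nothing about recall on real notes.
* The classifier does no spelling correction, no ML, and no formal
  screening-instrument (e.g. AUDIT-C) scoring — documentation is not
  screening.
* No real postal-code→CMA mapping; the urban rule consumes a population
  field directly.
* Chronic-condition flags are consumed as given; the validated case
  definitions that produce them are upstream of this package.
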