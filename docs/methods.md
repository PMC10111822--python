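# Methods

This note documents the models and conventions behind the package: what
each estimator assumes, where the published analysis left a choice open and
what this implementation chose, and what the synthetic generators do and do
not emulate.

## Screen enrichment scoring

The screen statistic is the ratio of relative hairpin abundances,
R_h = (c¹⁴ₕ/T¹⁴)/(c⁰ₕ/T⁰), with the totals T taken over *all* hairpins in
the file before any filtering. A gene is called a hit when at least
`min_enriched` (default 2) of its hairpins exceed the fold threshold
(default 2) **strictly** — "more than twofold" is read as a strict
inequality on the raw ratio, not on log2.

Choices where the published analysis is silent:

* **Pseudocount** — default 0, which reproduces the ratio formula exactly.
  A hairpin absent at day 0 but present at day 14 gets a `+inf` ratio and a
  `low_confidence` flag rather than an exception; a hairpin absent at both
  timepoints gets `NaN`, which never counts as enriched (treating 0/0 as
  infinitely enriched would plant spurious hits).
* **Day-0 floor** — hairpins with fewer than 10 day-0 reads are flagged
  `low_confidence` but still scored; they are excluded from the enriched
  count only when `exclude_low_confidence` is requested (default off).
* **Single-hairpin genes** are flagged `insufficient_hairpins` and can
  never be hits under a two-hairpin rule.
* Ranked outputs break ties by descending ratio, then gene symbol, for
  deterministic files. The two library presets (kinome 903 genes, polarity
  1526 genes) are analysed as independent screens; no cross-library
  normalisation is applied.

## IHC scoring and association

Core score = intensity (0–3) × stained area (0–100%); a tumour's category
is the **maximum** over its duplicate cores. The five-category binning is
not specified numerically in the source analysis; the package default is an
H-score quartering with an explicit negative class — 0 | (0,50] | (50,100]
| (100,200] | (200,300] — and the edges are a parameter everywhere they are
used. Binning is monotone in the raw score by construction.

Associations use plain Pearson chi-square on the full level × category
table: no Yates correction, no category merging, expected counts
E_ij = nᵢ₊n₊ⱼ/N, p from the upper chi-square tail (the regularized upper
incomplete gamma Q(df/2, χ²/2), via `scipy.special.chdtrc`). When more
than 20% of expected counts fall below 5 the result carries a
`small_expected_warning`, and `montecarlo_pvalue` provides a margins-fixed
Monte-Carlo null (Patefield sampling via `scipy.stats.random_table`,
equivalent to shuffling category labels against levels) as a finite-sample
check. Tumours with a missing level are dropped per block, which is why the
packaged blocks have different totals. Row percentages are rounded half-up
to one decimal, matching the display convention of the printed table.

Recomputing plain Pearson on the packaged printed counts reproduces the
printed p-values closely for most blocks (grade 5.80E-02 vs recomputed
5.799E-02; histological type 5.50E-02 vs 5.454E-02; prognostic subgroups
4.40E-02 vs 4.370E-02; ER−/HER2 5.40E-05 vs 5.362E-05). Two do not match
exactly and are documented rather than forced: the tubule block prints
3.0E-04 where plain Pearson gives 3.47E-04, and the mitotic block prints
5.80E-02 — identical to the grade block's value — where plain Pearson gives
2.40E-02, which looks like a printing duplication. Printed p-values are
therefore treated as documentation; printed counts and percentages are the
reconstruction targets.

Two schema conventions: "Ki67-low" means staining in ≤ 20% of tumour cells
(the luminal-A-like definition); and because the cohort schema carries no
basal cytokeratin marker, the triple-negative basal-like/non-basal split in
the prognostic-subgroup parameter is proxied by the same Ki67 cut (basal-
like = TN with Ki67 > 20%). The packaged fixture is unaffected — its counts
are used as printed. The printed ER/HER2 parameter consists of two
separately totalled, separately tested strata (ER− and ER+), so the fixture
carries nine tables covering eight parameters.

## Survival

Kaplan–Meier with standard tie handling: deaths at a tied time are
processed together; subjects censored at an event time remain at risk for
it. Greenwood standard errors are attached to the curve. Median survival is
the smallest event time with Ŝ ≤ 0.5 and is reported as undefined (NaN)
when the curve never reaches 0.5 — common in arms with few events.

The two-group comparison is the logrank test (df = 1) with the
observed/expected hazard ratio HR = (O_A/E_A)/(O_B/E_B) and CI
exp(ln HR ± 1.96 √(1/E_A + 1/E_B)), chosen over Cox regression to match
the "hazard ratio (logrank)" convention of the validation experiments; the
numerator group is the caller's first group, and the inverse is exposed to
avoid orientation ambiguity. A known property of this estimator: it
approaches the true hazard ratio under incomplete follow-up (heavy
censoring, as in both the human cohort and the mouse arms), but is
attenuated toward 1 when every subject's event is observed. The parameter-
recovery test therefore censors administratively at one control-arm mean
lifetime (~43% of events observed), where the median recovered HR at a
planted HR of 0.3 is ≈ 0.30; with complete follow-up it would be ≈ 0.37.

Caliper tumour area = B × S, the product of the largest and smallest
two-dimensional measurements; arguments are canonicalized so the function
is symmetric.

## Synthetic data

**Screen generator.** Day-0 hairpin proportions are Dirichlet with
symmetric concentration 1/`representation_dispersion` (default 0.1, a
moderate, roughly ten-fold representation skew typical of pooled plasmid
libraries; 0 means perfectly even). Sequencing is multinomial at
`sequencing_depth` (default 500× the hairpin count, a standard coverage
target). Outgrowth draws each hairpin's clone size multinomially from
1.5 × 10⁶ cells, applies a binomial bottleneck (`bottleneck_survival`,
default 0.1 — 3D outgrowth is strongly selective), multiplies clones by
2^e_g for planted gene effects, renormalizes and resamples at depth. Single
integration per cell is assumed (the low-MOI design). The generator does
not emulate PCR amplification bias, sequencing error or multi-integration;
passing recovery tests therefore demonstrate statistical power under
sampling and bottleneck noise, not robustness to those artefacts.

**Cohort generator.** Receptor subtypes default to the study cohort's
frequencies (320/27/29/77); the IHC category is drawn per subtype from the
printed category-by-subtype breakdown; grade, mitotic and tubule scores,
stage, histological type and age at diagnosis are drawn independently from
the printed marginals, with per-parameter missingness matching each
printed block's total. Core-level intensity/area pairs invert the category
bins (scores are drawn from the bin interior, so binning round-trips
exactly), and the second core's category is ≤ the first's, preserving the
max rule. Survival arms are COMMD3-positive (category ≥ 1) vs negative
(category 0), with default planted 10-year survival 0.83 and 0.73 —
the luminal-A-like contrast — exponential event times with
λ = −ln(S₁₀)/10 (a Weibull shape parameter is exposed, default 1),
administrative censoring at 20 years and a 10% uniform early-censoring
fraction (the real cohort's follow-up averages ~17 years in survivors).
Covariates are drawn independently of each other, so the generator
reproduces each printed margin but not the real cohort's correlation
structure (e.g. grade–mitotic dependence); association tests on simulated
data are calibration checks, not effect-size reproductions. The
`luminal_a_arms` preset restricts to ER+/HER2−, Ki67-low patients with
fixed arm sizes for survival-recovery experiments.

All randomness flows from one `numpy.random.Generator` seeded by the
mandatory config seed; identical configs give byte-identical output files.

## Numerical conventions

* Tables are tab-separated, UTF-8, `.` decimal, `inf`/`nan` literals;
  reals are written with 12 significant digits (round-trip relative error
  ≤ 5e-12); integers round-trip exactly.
* Percentages round half-up (not banker's) to one decimal.
* Chi-square Monte-Carlo p uses the add-one estimator (B+1 denominator).
* Validation errors raise typed exceptions; the CLI maps them to non-zero
  exit codes.

## Problem sizes in the checks

The recovery and calibration checks run at desk scale chosen once: screen
recovery uses 100-gene libraries at 500× coverage over 50 replicates
(null calibration: 200 replicates at 10⁷ reads); chi-square Monte-Carlo
nulls use 10,000 draws; logrank calibration uses 1,000 replicates at 50 per
arm; cohort survival recovery uses 1,000 patients per arm over 10 seeds.

## Known limitations

* The screen pipeline implements the ratio rule only; it is not a
  significance model (no rank aggregation or count-model test), matching
  the analysis it reproduces.
* Asymptotic chi-square p-values are unreliable on blocks with many small
  expected counts; the Monte-Carlo null is the fallback.
* The O/E hazard ratio is attenuated under complete follow-up (above).
* The cohort simulator draws covariates independently; it cannot be used
  to study confounding between clinicopathological parameters.
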