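# Methods

This note documents the models, conventions and design choices behind
`taavet`, and what the synthetic-data generators do and do not emulate.

## Candidate selection cascade

The cascade vets candidate antigens in three ordered stages.

**Stage 1 — antigen-class exclusion.**  Only self-antigens proceed.
Neoantigens are patient-specific (not broadly applicable as engineered-TCR
targets) and EOC has no oncogenic-virus association, so virus-associated
antigens are likewise removed.  Both are recorded under the single
exclusion reason `neoantigen`, the label of the stage's dominant class.

**Stage 2 — healthy-tissue tiering.**  A gene's healthy-tissue profile is
one median expression value (TPM) per tissue.  "Below the cutoff in all
tissues" is equivalent to the per-gene maximum being below the cutoff, so
tiering is implemented on the max with strict `<`: *low* when
max < 40 TPM, *medium* when max < 400 TPM, *excluded* otherwise.  Boundary
values land in the next (more expressed) tier, following the strict
inequality.  Which GTEx summary statistic feeds the profile is the
caller's choice; median per tissue is the intended default.  Both cutoffs
are configurable (`--low-tpm`, `--medium-tpm`).

**Stage 3 — tumor-expression gate.**  Per tier, a candidate is retained
iff its tumor-cohort `median FPKM > median_min` **or**
`mean FPKM > mean_min`, with defaults 0.5/1 (low tier) and 5/10 (medium
tier); strict `>` on both clauses.  The medium tier's raised cutoffs
reflect the higher on-target/off-tumor risk of genes with some healthy
expression: robust tumor expression is required to justify pursuing them.
The OR-of-strict-`>` structure mirrors the low-tier detection rule with
raised thresholds; because the direction of the medium-tier rule could
also be read as an AND, the cutoffs and the gate are configurable.
A candidate missing from the tumor table is excluded softly with reason
`no_tumor_data`; a candidate missing from the healthy table is a hard
error, because tiering cannot proceed without healthy-tissue evidence.

Every stage emits `n_in`, `n_excluded`, `n_out` and one exclusion reason
per removed candidate; the report validator asserts
`n_in = n_excluded + n_out` per stage and `n_out → n_in` chaining.

## Scoring rubric

The default rubric is a seven-criterion weighted scheme (a Cheever-style
prioritization modified for TCR therapy: the clinical-efficacy and
cellular-location criteria are removed, and the weights renormalized so
the criterion maxima sum to exactly 10.00 points).  The shipped point
values are canonical constants; `normalize_rubric` exists for
user-supplied rubrics and rescales every subcriterion by
`target / sum-of-maxima`, rounding to 2 decimals half-away-from-zero
(idempotent up to that rounding; post-round drift beyond ±0.05 warns).

Scoring selects one subcriterion per criterion.  Two sentinel selections
score 0 without invalidating the candidate: `not applicable` (the
criterion genuinely does not apply) and `unknown` (no literature evidence
found).  A candidate whose evidence is insufficient altogether is flagged
`insufficient_data`, carries no total, and is listed unranked after the
ranked candidates.  Totals are summed in decimal arithmetic and reported
to 2 decimals, so the tabulated constants produce exact totals (e.g. the
worked profiles 8.34 / 8.07 / 7.70).  Ranking is competition-style
(ties share a rank, the next rank skips) with ascending candidate id as
the deterministic display order within a tie.

## IHC quantification

Each tissue-microarray core carries two independent rater intensities
(0 negative, 1 weak, 2 moderate, 3 strong), a consensus intensity and an
integer percent of positively stained tumor cells.  The data model does
not average raters — averaging would create non-integer intensities
outside the 0–3 scale; instead, discordant cores are counted and the
consensus field (required in the input when raters differ) is used for
all downstream statistics.  Unassessable cores carry an explicit flag,
are excluded from every summary count and reported separately.

Q-Score = intensity × percent, an integer in [0, 300], binned
0 / 1–149 / ≥ 150.  The bins partition the range; Q ≥ 150 implies
intensity ≥ 2 and percent ≥ 50 (the converse does not hold: 2 × 50 =
100 < 150).  Intensity dichotomization (0–1 low vs 2–3 high) provides the
second grouping used in the clinical battery.

## Statistical toolkit

* **Fisher's exact test (2×2, two-sided).**  Point-probability
  convention: with margins fixed, p is the sum of hypergeometric
  probabilities of all tables whose point probability is ≤ that of the
  observed table, with a 1 + 1e-7 relative tolerance guarding
  floating-point ties.  A zero margin carries no information → p = 1.
  The implementation enumerates the support with log-gamma weights; tests
  verify it against an exact integer-weight enumeration oracle on every
  table with grand total ≤ 40 and against `scipy.stats.fisher_exact`.
* **Pearson chi-squared** via `scipy.stats.chi2_contingency` without
  continuity correction; df = (r−1)(c−1); a zero expected cell raises
  with advice to use the exact test.
* **Spearman's ρ** is the Pearson correlation of tie-averaged ranks.
  p is exact by full permutation for n ≤ 8 and uses the t-approximation
  for larger n.  Constant input has no defined rank correlation and is
  reported as not computable.
* **Kaplan–Meier** via lifelines; the median is the smallest *event* time
  at which the estimate falls to ≤ 0.5 (undefined if never reached).
  Censored observations shrink the risk set without steps.
* **Log-rank** (two groups, 1 df) via lifelines; with zero events in both
  groups the test is uninformative and returns (0, 1) with a warning.
* **Kruskal–Wallis** uses the tie-corrected H; the asymptotic p comes
  from χ²(k−1) and an exact partition-enumeration p is available for
  total n ≤ 10.  Tests cross-check H and p against `scipy.stats.kruskal`.
* **Dunn–Bonferroni post-hoc.**  Pairwise z from pooled mean ranks with
  tie-corrected variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`; two-sided
  normal p; adjusted p = min(1, m·p) over all m = k(k−1)/2 pairs (full
  pairwise correction, the conservative reading when only a subset of
  contrasts is of interest).
* The association battery applies Fisher to 2×2 tables and chi-squared
  otherwise (policy configurable) across the binary clinical covariates
  for both groupings, plus a log-rank test on PFS.  No multiple-testing
  correction is applied by default — the battery is exploratory — and a
  Bonferroni column is available on request.

## Subtype analysis

The loader accepts any pre-normalized probe × sample intensity matrix
(model-based expression values from invariant-set normalization are the
intended provenance; normalization itself is out of scope) together with
sample → cluster labels restricted to c1/c2/c4/c5 — the expression-derived
ovarian-cancer clusters representing true malignant neoplasia — and a
probe → gene map.  For a gene with several probe sets, the probe with the
highest average expression across all samples is used (ties break to the
lexicographically smallest probe id).  Genes are screened with
Kruskal–Wallis across clusters; genes passing the omnibus α (default
0.05) get Dunn–Bonferroni pairwise rows.

## Synthetic-data generators

The generators emulate the *structure* of the study inputs, not their
biology; distributional forms are modeling choices.

* **Healthy profiles**: per gene, a maximum tissue value drawn
  log-uniformly strictly inside the tier band; other tissues are the max
  scaled down by half-normal log-factors (`noise_sd`, default 0.5
  log-units).  The planted max is exact by construction, so tier recovery
  is noise-independent — which is why tier-recovery tests demonstrate
  correctness of the tiering rule, not robustness to mis-measured maxima.
  Default tier counts 60/47/60 mirror the study's marginal split of 167
  self-antigens.
* **Tumor cohorts**: per gene, log-normal FPKM across samples (default
  n = 373), rescaled so planted-retained genes have sample median at 4×
  the tier's median cutoff and planted-omitted genes sit at half of both
  cutoffs; planted-missing genes are dropped from the matrix.  Defaults
  plant 21 + 17 retained and 3 missing, the study's marginals.
* **Annotations**: uniformly random valid selections per criterion with
  expected totals summed independently of the scoring path;
  `worked_example_annotations()` returns the three canonical profiles.
* **TMA cohorts** (default n = 58, 5 unassessable optional): categorical
  intensity (probabilities 0.30/0.20/0.30/0.20), percent ≈ 30 × intensity
  plus Gaussian noise (σ = 12, clipped to [1, 100]; 0 when negative),
  exponential PFS with the high-intensity group's hazard =
  HR × the low group's (low-group median 28 months), independent
  exponential censoring tuned to the requested censored fraction,
  platinum sensitivity with baseline odds 1.5 multiplied by the planted
  odds ratio for Q ≥ 150 cores, and clinical covariates drawn to a
  serous, ~90 % grade-3, mostly stage-III cohort (median age ≈ 60.5).
  Real TMA data has correlated covariates, non-exponential hazards and
  informative censoring; passing recovery tests therefore shows the
  statistics detect the planted effects under the model, not that the
  clinical conclusions transfer.
* **Subtype matrices**: Gaussian intensities (mean 100, SD 20, clipped at
  0) exchangeable across clusters; planted genes shifted by
  `shift × SD` in one named cluster; optional multi-probe genes with one
  dominant probe (secondaries at half signal), including explicitly named
  probe ids for structural reproduction of probe selection.

Determinism: every generator takes an explicit integer seed feeding a
dedicated `numpy` Generator; one seed fixes every output byte, and all
written artifacts (JSON/TSV, no timestamps) are reproducible
byte-for-byte from the run manifest.

## Problem sizes and runtime choices

Tests and the acceptance suite run the cascade at the study's full roster
scale (237 candidates × 373 tumor samples), the TMA at n = 58–100, power
and type-I simulations at 100 replicates of n = 100 per arm, and the
subtype screen at 51 genes × 80 samples — sizes chosen so each planted
effect is comfortably detectable while the whole suite stays fast.
Fisher's oracle sweep covers all 135,751 2×2 tables with grand total ≤ 40
via a vectorized common-denominator enumeration.

## Known limitations

* Curated literature evidence enters as annotation files; no literature
  mining, epitope-database querying or expression-portal access is
  performed.
* The exclusion-reason vocabulary collapses viral antigens into the
  `neoantigen` stage-1 reason.
* The medium-tier gate direction (OR of strict `>`) is a documented
  reading of an ambiguous rule; both cutoffs and the rule's inputs are
  configurable so the AND reading can be emulated by adjusting cutoffs.
* Dunn's test uses the large-sample normal approximation; no exact small-
  sample post-hoc option is provided.
* No Cox regression or multivariable modeling; the clinical battery is
  exploratory by design.
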