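# Methods

This note records the statistical model behind `methpanel`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions taken where the design was open.

## Data model and preprocessing

Beta values (methylated intensity fraction, in [0, 1]) are stored with an
explicit missingness mask; sentinel values are never used because the
quality filters count missing entries. Genomic coordinates are 1-based
inclusive internally (array-manifest convention) and converted to 0-based
half-open only on BED export. The genome build is carried as metadata
only; no liftover is performed.

Preprocessing runs in a fixed order: clamp betas to [0, 1]
(values < 0 → 0, > 1 → 1), remove samples with *strictly more than* 25%
missing probes (the boundary sample is retained), remove probes carrying
any exclusion flag (control, sex-chromosome, SNP-overlapping, multi-hit)
and then any probe still containing a missing value, and finally collapse
repeated samples to one per (patient, tissue) by keeping the
lexicographically smallest sample id. Each probe removal is attributed to
exactly one reason with a fixed precedence (control, sex_chromosome, snp,
multihit, missingness) so the report is deterministic. The keep-first
deduplication deliberately replaces a mixed-model treatment of repeated
barcodes: it keeps every per-probe test a plain two-sample comparison and
makes reruns reproducible. The sample→probe filter order is a fixed
convention of this package.

## Differential methylation

The per-probe statistic is the fold change of group mean betas,
formalized as `log2((mean_A + ε)/(mean_B + ε))` with ε = 10⁻³ floored to
both means for stability near zero. The base-2 logarithm and ε are
config-exposed (`DmpThresholds`). The test is Welch's two-sided t on beta
values — asymptotically it ranks probes like a moderated linear model but
carries no extra dependencies. p-values are BH step-up adjusted (own
implementation, oracle-tested against a brute-force reference). A probe
is a DMP iff |log2 FC| ≥ 2 and adjusted p ≤ 0.01 (both inclusive).

A consequence of the log-ratio form worth knowing: with the factor-4
threshold, hypermethylation events are detectable only from low baselines
(β̄_normal ≤ (β̄_tumor)/4), and hypomethylation from β ≈ 0.9 can
essentially never pass (0.9 → 0.22 would be needed). This asymmetry is a
property of the statistic, not of the implementation; it is why the
region/block scanner applies no fold-change threshold.

### Bump hunting (DMRs and DMBs)

A from-scratch smooth → threshold → assemble → permute scan:

1. order probes by position within each chromosome (open-sea probes only
   for blocks);
2. smooth the per-probe mean difference with a centered running mean
   (window 3 probes for DMRs, 25 for DMBs; edge windows shrink);
3. threshold |smoothed| at a genome-wide quantile — 0.99 for DMRs, 0.95
   for DMBs. Blocks need the lower quantile: by definition they cover a
   non-trivial fraction of the open-sea track, and a 0.99 cutoff cannot
   retain a ≥ 20-probe run once blocks exceed 1% of scanned probes;
4. assemble maximal same-sign runs with inter-probe gaps ≤ 1 kb (DMR) /
   100 kb (DMB); keep runs with width ≥ 50 / 500 bp and ≥ 5 / 20 probes;
5. permutation p-value: shuffle group labels (default 100 permutations,
   seeded), rebuild runs at the *original* cutoff, and compare each
   observed region's area (sum of |smoothed|) against the best
   same-length-or-longer run per permutation. The add-one estimator
   avoids zero p-values, so min p = 1/(1+B).

Probe-count minima, gaps, windows and the permutation count are declared
package defaults — minimum widths are the only externally fixed values.

## Pan-cancer panel search

Candidates are probes that pass the full DMP criteria (including
|log2 FC| ≥ 2) in *every* cancer type's tumor-vs-normal contrast; the
direction-concordance (all-hyper) flag is reported, and restricting
candidates to concordant probes is available as an option rather than
imposed — in practice the surviving intersection is hypermethylated
anyway, because of the fold-change asymmetry above.

The exhaustive 1..4-probe search is two-staged for tractability at
24,157 combinations on one CPU: a batched Newton-IRLS logistic screen
(ridge 10⁻⁶, coefficient cap ±60 against separation) scores *every*
combination by apparent AUC and AIC; the leading combinations (default
50) then get the full treatment — maximum-likelihood fit (statsmodels),
Wald-tested covariates (age and centered stage, dropped at p > 0.05),
stratified 10-fold cross-validated AUC, and stratified-bootstrap SDs of
AUC and misclassification (default B = 100). The final model is the
lexicographic winner on (max CV AUC, min misclassification, min bootstrap
SD(AUC), min AIC, probe-id order). AIC is *minimized* as a late
tie-break, following standard model-selection convention; ranking by AUC
first makes the choice insensitive to that convention in practice.
Perfect separation flags the model and falls back to an L2-ridge fit
(penalty 10⁻⁴). The classification cutoff defaults to probability 0.5; a
Youden-optimal cutoff is available.

**Stage handling.** Normal samples have no tumor stage. In the
stage-adjusted regression and the methylation × stage likelihood-ratio
test, tumors contribute a centered numeric stage score (stage − mean
stage) and normals sit at the 0 reference. Coding normals as their own
categorical stratum would let the stage dummies perfectly separate tissue
type (stage ≥ I ⇔ tumor) and the ML fit would diverge. The joint LRT
compares (methylation + stage + methylation:stage) against
(methylation + stage), χ² with one df per interaction term; single-df
per-probe LRTs are reported alongside. Note the usual finite-sample
caveat: when the methylation effect is strong enough to near-separate the
classes, the LRT null distribution inflates; the calibration tests
therefore run in a moderate-effect regime.

Stage-stratified performance recomputes AUC/sensitivity/specificity on
each stratum (tumors of one stage + all normals) at the discovery-set
cutoff.

## Type-specific cascade

1. **One-vs-all DMPs** among pooled tumors: a probe is specific to type t
   iff it passes the DMP criteria in t's one-vs-rest contrast and in no
   other type's contrast (exclusive "Venn" membership).
2. **ReliefF** (own implementation, oracle-tested against an O(n²)
   reference): all instances, k = 10 neighbors (truncated with a warning
   when a class is smaller), Manhattan distance on range-scaled features,
   prior-weighted miss/hit mean differences, deterministic index
   tie-breaks. The relevance filter keeps the top ⌈fraction·n⌉ features
   (default 3%), ties broken by feature id.
3. **K-means redundancy filter**: features are the clustered points
   (standardized profiles across samples), k-means++ with 10 restarts and
   a fixed seed. Each cluster contributes its centroid-closest member and
   its top-Relief member (next-best Relief if they coincide); singleton
   clusters contribute one feature, so the output is ≤ 2·k and exactly
   2·k when every cluster has ≥ 2 members with distinct picks.
4. **PLS-DA**: PLS2 regression (NIPALS via scikit-learn, tolerance 1e-10)
   of the one-hot class indicator on centered/scaled predictors;
   prediction is the argmax class score and the continuous per-class
   scores feed one-vs-rest ROC. The iteration cap is 5000: at tolerance
   1e-10 the inner power iteration converges linearly with the gap
   between leading latent directions and can legitimately need > 500
   iterations (~1.5% of random small panels). The combination search caps
   components at panel_size − 1 (full-rank PLS2 is NIPALS-degenerate) and
   at classes − 1; the integrated model should be fit with ~classes − 1
   components — a 6-class problem is not separable in 3 latent
   dimensions, and the CLI does this automatically.
5. **Search and integration**: every C(candidates, panel_size) subset is
   scored by stratified k-fold CV; per class the subset maximizing that
   class's one-vs-rest AUC wins (ties: smaller mean candidate index). The
   exact combination count is always computed even when a subsample of
   combinations is evaluated (`--subsample-combos`). The final model is
   one PLS-DA fit on the deduplicated union of per-type winners, reported
   with per-type CV AUC and hard-assignment sensitivity/specificity.

Per-type "best" uses CV AUC only; sensitivity/specificity are reported
but not used for ranking.

## Evaluation machinery

AUC is the tie-corrected Mann–Whitney rank statistic; the ROC curve is
kept for export and equals the trapezoidal integral of its points to
machine precision (tested to 1e-12). Binary metrics use "score ≥ cutoff"
as positive. Stratified k-fold assignment is seeded and class-balanced
within ±1; the fold count is reduced (with a warning) to the smallest
class size when needed. Bootstrap resampling is stratified within class.

## Synthetic cohorts: what they emulate, and what they don't

Per-probe normal-tissue baselines are a two-component mixture (low mode
U(0.10, 0.20), high mode U(0.80, 0.90), equal weight). Planted effects:

* **pan-cancer probes** — hypermethylated (+effect) in tumors of every
  type, planted at unmethylated-promoter-like baselines U(0.03, 0.08):
  biologically this mirrors CpG-island promoters that are unmethylated in
  normal tissue, and statistically it is the only regime in which a
  β-shift of ~0.3 clears the 4-fold mean-ratio filter;
* **type-specific probes** — same construction, shifted in one type only;
* **regions** — runs of ~12 densely spaced probes (internal gaps ≤ 900 bp,
  CpG-island-like) at intermediate baselines U(0.25, 0.45), shifted up in
  all tumors;
* **blocks** — runs of ~25 consecutive open-sea probes at high baselines
  U(0.75, 0.92), shifted *down* in tumors (the canonical large-scale
  open-sea hypomethylation of cancer genomes).

Tumor stages I–IV are uniform and scale every planted shift by
(0.8, 1.0, 1.1, 1.2) — stage I weakest, reproducing the qualitative
"stage I hardest to classify" pattern without asserting real-data values.
Noise is i.i.d. Gaussian on the beta scale (default SD 0.08, a realistic
within-group dispersion for array betas), clamped to [0, 1]; the clamp
introduces a small mean bias near the boundaries, which is real behavior
for bounded data but means harsh noise regimes (SD ≥ 0.2) push
low-baseline group means up and can legitimately defeat the 4-fold
filter. Missingness is i.i.d. at a configurable rate (default 0, since
the probe filter removes any probe with missing values). The external
cohort re-derives the same baselines and effects deterministically from
the config, draws fresh samples, and adds a uniform batch shift before
clamping. The default tumor:normal ratio is 80:10 per type (~8:1, typical
of public tumor archives); tests and the acceptance script override
sample sizes per experiment.

Not emulated: co-methylation correlation beyond the planted contiguous
runs, heteroscedastic (intensity-dependent) noise, cell-type composition
and purity effects, copy-number confounding, probe cross-reactivity
beyond a generic flag, and realistic batch structure beyond a uniform
shift. Passing tests on these cohorts therefore demonstrates the
*algorithms* recover what was planted under the stated noise model — not
that the pipeline is robust to every artifact of real array data.

## Problem sizes and operating points

Chosen once as the package's standard experiment sizes:

* DMP recovery / FDR and type-I control: 2,000 probes, 50 tumors vs 50
  normals per type, 3 types, effect 0.3, noise SD 0.08, 5 seeds.
* Bump hunting: 1,500–2,000 probes, 50/50, noise SD 0.05, 100
  permutations; null calibration over 20 seeds.
* Pan-cancer search: 28 candidates (4 informative), 200/200 samples,
  effect 0.3, noise SD 0.2 — that noise level sets the single-probe AUC
  to ≈ 0.84–0.86 (Φ(0.3/0.2√2)), the regime in which panel selection is
  a genuine discrimination problem rather than a saturated one; 10 seeds.
* Type-specific cascade: 6 types × 40 tumors, 3 specific probes per
  type, effect 0.35, noise SD 0.1; panels of 3 from the ~18 nonredundant
  predictors (C(18,3) = 816 combinations per seed), 5 seeds. The
  full-scale 6-of-20 search (38,760 combinations × 10-fold CV) is
  supported and its count always reported exactly, but routine runs
  evaluate scaled-down versions.
* Stage stratification: 1 type, 200 tumors / 100 normals, noise SD 0.25
  (lower per-stage AUCs widen the stage I↔IV gap), 20 seeds.

## Known limitations

* The Welch t replaces a moderated/mixed-model test; with very few
  samples per group its ranking is noisier than an empirical-Bayes test.
* The two-stage panel search assumes the apparent-AUC screen does not
  exclude the CV-optimal panel from the top set; with strongly correlated
  candidates and a small `top_n` this is not guaranteed.
* Permutation p-values for overlapping candidate regions are computed
  against the same permutation ensemble and are therefore dependent
  across regions.
* The LRT for methylation × stage inherits logistic-regression
  small-sample behavior near separation (anticonservative); interpret
  with the usual caution in saturated regimes.
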