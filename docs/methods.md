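# Methods

This note documents the statistical model behind each pipeline stage,
the parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer would want to know.

## The analysis problem

In a proximity-labeling experiment a promiscuous biotin ligase (TurboID)
is fused to a bait protein; proteins within ~10–30 nm are biotinylated
in living cells, captured on streptavidin, and quantified by LFQ-MS.
"Interactor" here therefore means *proximal protein* — stable, transient
and indirect neighbours alike. Two confounders dominate the analysis:

* **bait-expression differences** between lines inflate or deflate every
  AP intensity in a sample — handled by bait-abundance normalization;
* **whole-cell proteome shifts** caused by transduction/over-expression
  masquerade as AP enrichment — handled by subtracting bulk-proteome
  DEPs from the AP DEP list (`ap_specific`).

## Preprocessing model

**Missingness.** LFQ missingness is treated as left-censored (MNAR):
low-abundance proteins preferentially drop out. A protein is retained if
quantified in ≥ `min_valid_fraction` (default 0.5) of the replicates of
at least one (group, assay) cohort — a protein absent everywhere except
one cohort is exactly the AP-enrichment signal the experiment looks for,
so filtering must be cohort-wise, not row-wise.

**Imputation** is column-wise (per sample): missing cells in sample *j*
are drawn from `N(μ_j − shift·σ_j, (width·σ_j)²)` with defaults
`shift = 1.8`, `width = 0.3` (the Perseus convention; the multipliers
are in units of the per-sample sd of observed log2 intensities).
Observed cells are never modified — this is asserted bitwise in tests.
The model is only appropriate when missingness is truly left-censored;
see "known limitations" for what happens when it is not.

**Bait normalization** (AP, bait-expressing groups only):
`x′_ij = x_ij − b_j + mean(b)` with `b_j` the bait's log2 intensity in
sample *j*. Recentering by `mean(b)` keeps the matrix on the original
log2 scale so fold changes against the control remain interpretable.
Control (bait-free) AP samples are untouched — they contain no bait to
normalize to — so the TurboID-vs-control contrast mixes a normalized and
an unnormalized scale; the recentering step mitigates this and the
mixing is logged. The pipeline refuses to run if the bait is unquantified
in any bait-bearing AP sample *before* imputation: an imputed (far-left-
tail) bait value would silently shift that entire column by several log2
units. Order of AP operations: flag filter → log2 → missingness filter →
impute → bait-normalize; imputing first makes bait observability an
explicit, checkable precondition rather than an accident of missingness.

**Quantile normalization** (bulk): each column's sorted vector is
replaced by the row-wise mean of all sorted columns; tied values within
a column share the mean of the reference values over their rank range.
It requires a complete (imputed) matrix. With the tie rule, sorted
column vectors are exactly equal only when tie patterns agree across
columns; on continuous LFQ data ties do not occur and equality is exact.
The operation is idempotent.

## Differential enrichment

Welch's unequal-variance t-test with Satterthwaite degrees of freedom,
two-sided, per protein; BH adjustment across all proteins of a contrast.
Welch is the robust default at n = 3 with no variance moderation;
moderated/empirical-Bayes tests are deliberately out of scope. Calls use
the raw p-value (`p < 0.05`) and a *strict* fold-change cut
(`log2FC > 2`, i.e. > 4-fold; a protein at exactly 4-fold is excluded),
with `adj_p` reported for transparency. Degenerate rows: both cohorts
zero-variance with equal means → t = 0, p = 1; zero-variance with
unequal means → p = 0, flagged in the log. PCA (full SVD of the
protein-centered samples × proteins matrix) is provided for QC; on
simulated data PC1 separates pull-downs of TurboID lines from control
pull-downs.

## Interactor nomination

All set operations key on uppercased gene symbols, because annotation
lists and cross-species (human/mouse) comparisons are symbol-level;
proteins lacking a symbol are excluded with a logged count, and
multi-gene protein groups collapse to their first (razor) symbol.
Named sets and their algebra:

| set | definition |
|---|---|
| `ap_interactors` | enriched, pooled TurboID AP vs control AP |
| `bulk_deps_up/down` | bulk TurboID vs control, both directions |
| `ap_specific` | `ap_interactors ∖ (bulk_up ∪ bulk_down)` |
| `unique_N / unique_C / shared_NC` | partition of the per-terminus DEP sets |
| `enriched_direct_N/C` | direct N-term vs C-term contrast |
| `combined_N/C` | `unique ∪ enriched_direct` |
| `pdz_lost / pdz_gained` | C-term vs C-termΔPDZ, enriched in A / in B |

Every set carries a provenance record (contrast, thresholds, operation)
sufficient to regenerate it, and is exported as a TSV plus a
`venn_counts.json`.

## Over-representation analysis

Hypergeometric upper tail `P(X ≥ k)` for a query of size n against a
term restricted to the background (size K of N); one-sided enrichment
only, BH across the terms of one collection, significance at adjusted
p < 0.05. The background is the quantified post-filter proteome, not
the genome: a genome-wide universe would overstate enrichment of
anything abundant enough to be detected by MS at all. The
implementation is verified against exhaustive combinatorial enumeration
for every configuration with N ≤ 12.

## Synthetic data: what it emulates, and what it does not

One protein is the bait ("TURBOID"); the remaining proteins divide into
planted classes (shared, N-only, C-only and PDZ-dependent interactors),
background, endogenously biotinylated proteins, and flagged
contaminant/decoy rows. Log2 intensity of protein *i* in sample *j* is

```
x_ij = base_i + effect_i(class, group, assay) + ε,  ε ~ N(0, noise_sd²)
```

with `base_i ~ N(25, 2²)` (typical LFQ log2 range), `noise_sd = 0.4`
(replicate CV ~30%, ordinary for AP-MS), planted effects uniform on
log2 [2, 8] (4- to 256-fold), a bait boost of +8 in transduced lines,
and a +3 AP boost for endogenously biotinylated proteins *in every
group including control* — they are captured by streptavidin but are
not differential, exercising specificity. The ΔPDZ construct still
carries the C terminus, so PDZ-independent C-interactors are enriched
in both C-terminal lines, PDZ-lost interactors only in the full
C-terminus, PDZ-gained only in the deletion line. The bait is
structurally absent (intensity 0) from the non-transduced control and
never randomly dropped in transduced lines, where the over-expressed
fusion dominates the eluate.

A cell is censored (written as `0`, the MaxQuant dialect) with
probability `logistic(−slope·(x − midpoint))`, `midpoint = 23`,
`slope = 2.5`, OR-ed with a uniform 2% (MCAR) dropout. The slope gives
a 10–90% detection band of ~1.8 log2 units — a sharp detection limit
consistent with empirical LFQ missingness curves and with the
left-censoring assumption of the imputation model — and yields ~20%
missingness in control AP columns, a plausible figure for this design.

Deliberately **not** emulated: peptide-level evidence, match-between-run
artifacts, ratio compression, shared-peptide ambiguity beyond the
first-symbol collapse, batch effects, and correlated noise across
proteins. Passing recovery tests on this generator therefore shows the
*statistical logic* is sound under the stated noise model, not that the
pipeline is robust to every pathology of real MS data.

**A documented bias worth knowing about:** the default 2% uniform MCAR
dropout occasionally removes a high-abundance value; the left-censored
imputation then fills it several log2 units too low, which can destroy
a 3-replicate cohort mean and cost a true positive (or, in a
between-construct contrast, create an asymmetry). This is a faithful
reproduction of what down-shifted-normal imputation does to any
missingness that is not actually left-censored, and it is the main
reason demo recovery rates sit a few points below the MNAR-only ones.

## Problem sizes and determinism

Default simulations use 2,000 proteins × 24 samples — large enough for
stable recovery statistics (planted classes of 16–160 proteins) while
keeping the full pipeline under a few seconds. All randomness flows
from one integer seed, fanned out to per-stage child seeds via
`seed·1000003 + counter (mod 2³¹)`; generator output is byte-identical
under a fixed seed, and two pipeline runs with the same config and seed
produce byte-identical output trees (manifests record file basenames,
a config digest and counts — never timestamps or absolute paths).

## Numerical choices

* Sample sd uses ddof = 1 throughout (imputation moments, Welch).
* Bait normalization makes the bait row bit-exactly constant; within-
  sample differences are preserved to 1-ulp scale (~4e-16 relative) —
  an additive float shift cannot preserve them bit-exactly.
* Quantile-normalization ties: mean over the full rank range (computed
  by grouping equal values), not the mean of the range endpoints.
* ORA p-values come from the hypergeometric survival function
  `sf(k−1, N, K, n)`; `k = 0` gives p = 1 exactly.
* BH adjustment is the step-up procedure with enforced monotonicity,
  capped at 1; for a single test it is the identity.
* PCA uses the full (deterministic) SVD solver.

## Scoring recovery (which truth set for which list)

The pooled TurboID-vs-control contrast dilutes terminus-restricted
effects threefold (a N-only interactor is enriched in 3 of 9 pooled
replicates), so `ap_specific` sensitivity is scored against the planted
*shared* class, while its false-discovery proportion counts any planted
interactor (or the bait) as a true positive. `combined_N` is scored
against the N-only class; `combined_C` against C-only plus PDZ-lost
(both are genuinely C-preferential); `pdz_lost`/`pdz_gained` against
the corresponding PDZ-dependent subtypes.

## Known limitations

* No variance moderation: at n = 3, Welch p-values are noisy; the
  strict fold-change cut carries most of the specificity.
* The control AP samples are never bait-normalized (nothing to
  normalize to), so the TurboID-vs-control fold change mixes scales.
* Symbol-keyed set logic silently merges isoforms sharing a symbol and
  drops symbol-less protein groups (both logged).
* The ORA background default differs by construction from genome-wide
  universes used by popular web services; numbers are not comparable
  across backgrounds.
* Quantile normalization assumes bulk samples share a common intensity
  distribution; it erases genuine global shifts if present.
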