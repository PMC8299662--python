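# Methods

This note records the statistical conventions, the synthetic-data model,
and the design decisions behind `cernet`, in the spirit of a methods
appendix.

## Data model

All expression enters the pipeline as log2-scale feature-by-sample
matrices (`log2_transform(x) = log2(x + offset)`, default pseudo-count
offset 1 for count-like data; `already_log=True` is a bit-identical
no-op). Missing values are explicit NaN, never silent zeros; features
missing in more than 20% of samples (configurable) are dropped before
differential expression, and remaining gaps are handled
pairwise-complete per feature. Duplicate probes mapping to one canonical
id are collapsed by keeping the probe with the highest mean expression
("max-mean", the common microarray convention), with per-column
averaging available via `collapse="mean"`. Gene symbols are uppercased
on GMT ingest to avoid case mismatches against expression tables.

## Differential expression

Per feature, `log2FC = mean(log2 tumor) − mean(log2 normal)` and a
two-sample t-test: Welch by default, pooled-variance Student on request,
and the paired t-test whenever complete tumor/normal pairing is
available (the pipeline auto-selects paired for matched cohorts). Calls
use strict thresholds — `p < 0.05` and `|log2FC| > 1` — on the raw
p-value; Benjamini–Hochberg adjusted p is always reported and can be
used for calling via `use_adjusted_p`. Features with zero variance in
both groups are assigned p = 0 when the means differ and p = 1 when
equal, with a logged warning; this keeps obviously shifted but noiseless
features callable instead of propagating NaNs. No moderated-variance
(limma-style) shrinkage is implemented: at the cohort sizes involved the
plain t-test is the transparent reference analysis, and a moderated
option would change no admission rule downstream.

DE-list overlap between two cohorts is scored with the one-sided Fisher
exact test: `p = P(X ≥ k)` including the observed overlap, `X ~
Hypergeom(N, |A|, |B|)`. The universe is caller-supplied and defaults to
the features measured in both cohorts. The odds ratio uses a 0.5 Haldane
substitute in all four cells when any cell is zero. The "consensus"
circRNA list passed to the network stage consists of features DE in both
cohorts with concordant direction.

## ceRNA network assembly

The sponge hypothesis fixes the admissible direction pattern of a
triplet: circRNA and mRNA concordant, miRNA opposite, all three DE. The
default `sign_rule` mode enforces exactly this on the DE calls, because
the typical design measures circRNAs and miRNA/mRNA in *different*
cohorts (small arrays vs large sequencing collections), where
sample-level correlation across partners is undefined; direction
concordance is the implementable reading of the required
positive/negative correlations. When both partners are measured on the
same samples, `correlation` mode instead retains pairs whose Spearman ρ
has the required sign and magnitude (≥ 5 shared samples; undefined ρ
from constant expression drops the pair with a warning).

Triplets are kept in canonical lexicographic order, so outputs are
byte-reproducible and any network equals the brute-force cross-product
enumeration (property-tested up to 50 features per kind). Composition
percentages (network members over DE totals) are reported to two
decimals.

## Enrichment

One-sided over-representation only: `P(X ≥ k)` for the overlap of the
query with each set, both intersected with the universe first. The
universe defaults to the genes measured in the mRNA matrix, not the
genome — enrichment against an unmeasurable background inflates
significance. BH adjustment is applied within each collection; results
sort by p then set name, and `top_terms` applies the strict `p < 0.05`
filter before taking the first k. No GO-graph ancestor propagation: set
membership is whatever the GMT states.

## Survival screening

Cohorts are dichotomized at each gene's median expression with ties
assigned to LOW, so "high" always means strictly above the median; a
constant gene is a degenerate split and is reported with a skip reason
rather than a p-value. Curves are Kaplan–Meier product-limit estimates
(via lifelines) stepping only at event times, and groups are compared
with the standard two-group log-rank test (hypergeometric variance, no
stratification), chi-square with 1 df. Genes at log-rank `p < 0.05` are
flagged prognostic. Times are days internally. No Cox modelling or
multivariate adjustment — the screen is deliberately univariate.

## Drug–gene association

Spearman rank correlation (average-rank ties) between gene expression
and IC50 across cell lines, pairwise-complete over missing IC50 entries,
minimum 3 complete pairs. The p-value is the exact two-sided permutation
p for n ≤ 10 (full n! enumeration on the rank cross-sum, which is
monotone in ρ for fixed margins) and the t-approximation `t = ρ√((n−2)/
(1−ρ²))` otherwise. BH is applied over the whole gene×drug screen by
default (`per_gene` grouping available); FDR < 0.05 strict flags a pair,
with ρ < 0 labelled sensitizing. Constant vectors are explicit
"degenerate" rows excluded from BH.

## Synthetic-data generator

The generator emulates the full study design with planted, manifest-
recorded truth:

- **Cohort shapes** (defaults): two paired circRNA cohorts of 4 and 5
  tumor/normal pairs, a 6-pair mRNA array cohort, unpaired miRNA and
  mRNA sequencing cohorts of 45 normal / 450 tumor, a 30-line cell
  panel, 20 drugs. Feature counts default to 300 circRNAs, 200 miRNAs,
  1000 mRNAs — large enough for stable FDR behavior, small enough that
  the full suite runs in seconds.
- **Expression**: per-feature baseline uniform on [4, 12] log2 units,
  Gaussian within-group noise (sd 0.5), planted DE features (10% of each
  kind, alternating directions) shifted ±2.0 in tumor. The two circRNA
  cohorts share one true DE set, as do the two mRNA cohorts, so
  cross-cohort overlap is real signal. A >2-fold shift at sd 0.5 makes
  the paired 4–5-pair designs well powered, mirroring how real
  microarray screens at such tiny n can still yield hundreds of calls.
- **Interactions**: pairs realizing each planted triplet, plus decoy
  candidate triplets each violating exactly one admission condition
  (non-DE miRNA / non-DE circRNA / non-DE gene / sign-rule breach),
  drawn from pools disjoint from the planted members so decoys cannot
  recombine into valid triplets, plus background miRNA–circRNA bulk with
  no mRNA partner.
- **Survival**: event times exponential with hazard
  `h0 · HR^{1[expr > median]}` per planted prognostic gene (default one
  gene at HR 3 among 20 designated nulls; `h0 = ln2/730` days, median
  OS ≈ 2 years). Censoring uses an independent exponential clock whose
  rate is solved numerically so the expected censored fraction equals
  the configured rate (default 0.6, i.e. ~40% observed events); because
  min(T, C) is independent of which clock fired, the censored subset is
  drawn with a fixed count (weighted by each sample's censoring
  probability), pinning the realized rate while keeping observed times
  exactly distributed.
- **Drugs**: planted pairs follow `ln IC50 = a + b·z(expr) + ε` with
  |b|/sd(ε) = 1 and alternating sign; everything else is independent
  noise with a 5% missingness mask.
- **Gene sets**: random background sets plus one set seeded with the
  planted triplet genes, so enrichment has a known right answer.

All randomness flows through named substreams of a single seed
(`SeedSequence([seed, stream_code])`), so outputs are bit-reproducible
and adding a generator never perturbs the others.

What the generator does **not** emulate: probe-level microarray
chemistry, sequencing depth/count noise (noise is Gaussian on the log2
scale, matching the post-transform analysis), batch effects, correlated
co-expression structure, or informative missingness. Passing tests
therefore demonstrate the correctness of the statistical machinery and
the admission logic under the stated model, not robustness to every
artifact of real GEO/TCGA/GDSC data.

## Validation studies and problem sizes

The operating-characteristic studies (module `evaluation`, exercised by
the acceptance tests and `scripts/acceptance.py`) use: 20 seeds for DE
sensitivity/FPR, network recovery, the prognostic screen (400 clinical
samples) and drug-sign recovery; 50 seeds for the drug null (50 genes ×
20 drugs × 30 lines); 1000 simulations for log-rank null calibration;
and enumeration sweeps over all hypergeometric configurations with
universes ≤ 25 exhaustively plus vectorized tails up to 60. These sizes
give stable averages while keeping the whole suite around a minute.

## Known limitations

- Direction concordance is a coarse surrogate for expression
  correlation; with same-cohort data the correlation mode is preferable.
- The exact Spearman permutation p is quadratic-factorial in n and
  capped at n ≤ 10 by design.
- The host-gene overlap utility treats host-gene annotation as given;
  no coordinate-based assignment is attempted.
- The run report is deterministic by construction (no timestamps), so
  wall-clock provenance must come from the surrounding workflow.
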