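# Methods

This note records the statistical conventions the package implements, the
choices made where several defensible conventions exist, what the
synthetic generators emulate, and the package's known limitations.

## Two-group comparison from summaries

Cohorts arrive as per-arm (n, mean, SD) summaries. Both t variants are
implemented; **Welch is the default** because the unequal-variance
statistic is the one that reproduces the published per-cohort values where
arm variances differ strongly (the RNA-seq cohort's printed t = −6.274 is a
Welch value; the pooled statistic gives −3.87 there). The pooled variant is
kept because one small published cohort (10 vs 6) reproduces only under it.
SDs use the n−1 denominator throughout. Three published rows (two GEO
cohorts and the paired qRT-PCR cohort) reproduce under neither unpaired
variant — consistent with a paired test on per-pair values that were never
published — and are therefore not used as exact checks.

The differential-expression screen is deliberately simple: linear fold
change case/control (or 2^Δmean on log2 data) with strict bounds
(fc < 0.5 or fc > 2) and p < 0.05. No moderated/empirical-Bayes statistics:
the screen is the published rule, not a reimplementation of limma.

ROC analysis uses the Mann–Whitney AUC with midrank ties. Because the
marker is *down*-regulated, the raw AUC is below ½; the result is oriented
to ≥ ½ with the direction recorded (`case_low`). The standard error is the
DeLong placement-variance form, chosen over the binormal model because it
is distribution-free and matches the behavior of the common clinical ROC
software. The 95% CI is clipped to [0, 1].

## Meta-analysis conventions

Per cohort, the effect is Hedges' g = J·d with d = (m₁−m₂)/s_p, s_p the
(n−1)-weighted pooled SD, and J = 1 − 3/(4(n₁+n₂−2)−1). The sampling
variance is the **Hedges–Olkin large-sample form**

    var(g) = J² · ( (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2)) ).

Several near-equivalent variances circulate (denominators 2N, 2(N−2),
2(N−3.94), with or without the J² factor); they differ by O(1/N) and are
indistinguishable at large n. The Hedges–Olkin form was adopted because,
applied to the packaged cohort table, it reproduces the published pooled
estimates, confidence intervals and heterogeneity percentages most closely
of the candidates (e.g. I² of 76%/79% for the two panels exactly as
printed, against 74%/77% under the 2(N−3.94) variant).

Pooling is inverse-variance; the random-effects model uses the
DerSimonian–Laird moment estimator tau² = max(0, (Q−df)/C),
C = Σw − Σw²/Σw with fixed-effect weights — not REML or Paule–Mandel —
because DL is what the mainstream meta-analysis GUIs compute. CIs use the
normal quantile 1.96 rather than a t quantile, same rationale. Model choice
follows the stated rule: random effects when p_Q < 0.05 **or** I² > 50%,
else fixed; the chosen model is recorded in the result.

Egger's test is the classic form — OLS of the standardized effect g/se on
precision 1/se, two-sided t on the intercept with K−2 df. Begg's test is
the rank correlation between variance-standardized deviations from the
fixed-effect pooled value and the sampling variances, with the
continuity-corrected normal approximation. Both conventions are recorded
here because published reports rarely state them; exact p-values are
convention-sensitive (an exact-permutation Kendall p differs from the
normal approximation by ~0.1 at K = 11), so only the qualitative
no-bias conclusion is treated as reproducible. A leave-one-out sensitivity
table is emitted; it has no published reference values.

## Hypergeometric tails (co-citation and enrichment)

Both the literature co-citation score and pathway enrichment are the same
upper-tail probability P(X ≥ k) for X ~ Hypergeom(N, n, m), evaluated as
exp(logsumexp(log-pmf)) over the support [k, min(n, m)] and clamped to
[0, 1]. The log-space route is required at corpus scale (N ~ 10⁷ overflows
the factorial form) and agrees with an exact integer coefficient-sum oracle
to 1e−12; the test grid is exhaustive for N ≤ 25 plus a dense seeded sample
up to N = 200 (full enumeration to N = 200 is ~10⁸ tail evaluations and
adds no coverage the sample lacks). Counting is document-level: an article
contributes at most once to each of n, m, k. Gene-mention tagging is out of
scope; the module ingests pre-tagged mention lists (normalized through a
case-insensitive alias map, unknown mentions passed through flagged) or
ready count tables. Ranking ties break by descending k then symbol so
output is byte-reproducible. Raw per-gene p is the default (matching how
such gene lists are published); Benjamini–Hochberg q-values are available
behind a flag.

The enrichment background defaults to the union of pathway members and can
be overridden by an explicit background set (validated to contain every
pathway) or an integer genome size. Published enrichment p-values are not
reproducible without knowing the original background, which is why none are
used as reference values.

## Consensus voting and integration

Platform nominations are binary; the consensus rule accepts a gene at ≥ 4
nominations (threshold configurable, validated against the platform
count). Symbols are upper-cased and alias-normalized before tallying —
without a shared namespace the "≥ 4 platforms" rule is ill-defined. Set
integration is plain intersection over normalized symbols.

## Connectivity z-test and networks

The hub connectivity statistic standardizes each gene's degree by the
**sample mean and n−1 SD of the candidate hub population's degrees** (the
20-gene population for the packaged network) and reports the one-sided
upper normal tail. This exact convention — population restricted to the
supplied hub list, n−1 denominator, one-sided tail — reproduces all seven
distinct published tail probabilities to 5+ decimal places; plausible
alternatives (population = all network nodes, n denominator) do not. The
degree population is approximately treated as normal; with 20 genes this
is a coarse approximation, which is inherited from the published analysis
rather than improved upon. How the original study chose its 20 hub genes
from the 251 predicted targets is not derivable (the hub table includes
genes outside the 104-gene overlap), so the hub list is an explicit input,
with the published 20 as the packaged default.

Networks are undirected and unweighted with per-edge source tags
(pathway_relation | ppi | literature); merging keeps an edge once and
unions its tags, drops self-loops (counted), and skips malformed rows
(counted). SIF and GraphML exports round-trip node sets, edge sets and
tags. One published-text quirk is worth flagging: the results prose once
names a different microRNA ("miR-132") where the context implies the
study's microRNA; the packaged data treat it as a typo.

## Synthetic generators

The generators produce inputs with exactly the structure each stage
assumes, and are bit-reproducible given (spec, seed):

* **Cohorts**: Gaussian per arm at specified n/mean/SD. Real expression
  data are heavier-tailed and often log-transformed upstream; passing
  recovery tests shows correctness of the statistics, not robustness to
  non-normality.
* **Meta panels**: per-study latent effect θᵢ ~ N(true_smd, tau²), unit
  SD arms, empirical summaries from actual draws so sampling error enters
  naturally. Recovery conditions used by the validation suite: 500 panels
  of K = 30 studies, 50 per arm, true SMD −0.5, tau 0.3 — the DL mean
  estimate lands within 0.05 of truth with CI coverage in [90%, 98%].
* **Corpora**: m uniform on a range (default 50–500), k hypergeometric
  under the null, then shifted by (factor−1)·E[k] and capped at min(n, m);
  factor 1 is the exact null (null calibration: ≤ 7% flagged at α = 0.05
  over 2000 genes — conservative because the statistic is discrete),
  factor 5 plants a top-ranking association.
* **Predictions**: planted targets get ≥ threshold votes, decoys fewer, so
  consensus recovery is exact by construction.
* **Pathways**: one planted set drawing 80% of members from the query.
* **Networks**: a prescribed degree sequence is realized *exactly* by a
  deterministic Havel–Hakimi pairing (seeded shuffle only breaks ties among
  equal degrees); non-graphical plans (odd sum, Erdős–Gállai violations)
  raise immediately. This is why the published degree sequence reproduces
  its connectivity table exactly from a generated network.

## Pipeline

All stage seeds derive from one config seed via SHA-256 (stable across
platforms, < 2³¹). Stage TSVs are byte-identical across reruns of the same
config+seed; wall-clock timestamps appear only in the run manifest, next to
the package version and a config hash. Stages for which the published raw
inputs are external (corpus, predictions, pathways) run on synthetic data
sized to mirror the published analysis (2000-gene corpus, 251 planted
targets, 104-gene overlap, 1800-gene literature list).

## Limitations

* Everything downstream of the cohort table treats the printed 4-decimal
  summaries as exact; reproduction tolerances (±0.02 SMD, ±2 I² points)
  absorb that input rounding.
* The ROC analyses of the original cohorts require sample-level values that
  were never published; the package demonstrates ROC on synthetic cohorts
  matched to the printed summary statistics instead.
* Published co-citation and enrichment p-values depend on unpublished
  corpus constants and background choices and are treated as data, not as
  reproducible computations.
* No directed-network statistics, no trim-and-fill or meta-regression, no
  gene-mention NER — all outside the analysis chain implemented here.
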