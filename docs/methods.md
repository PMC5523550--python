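# Methods

## The D1 statistic

With one pooled array per strain × condition there are no replicate columns,
so differential expression cannot be assessed by variance-based tests.  The
pipeline ranks genes by a J5-family global-difference statistic: for a
contrast with per-gene difference `d_g = x_treated,g − x_untreated,g`,

    d1_g = d_g / ( (1/N) Σ_j |d_j| ),

where the denominator runs over all N background genes of the contrast (the
post-revision-filter gene set, never only the responsive genes).  Two exact
properties follow and are asserted in the test suite: `d1` is invariant
under global positive rescaling of intensities, and the mean of `|d1|` over
the background is exactly 1.  Calls are made at an inclusive threshold of 3
(`up` iff `d1 ≥ 3`, `down` iff `d1 ≤ −3`); the boundary convention is a
package decision, recorded in output metadata together with the formula.

**Scale.**  `d1` is computed on linear signal intensities by default (the
J5 convention) with a `log2` option.  The linear scale is structurally
asymmetric: a downregulated gene's difference is bounded below by
`−SI_untreated`, so when a realistic fraction of genes carries strong
upregulation, the genome-wide mean absolute difference is dominated by the
up genes and downregulated genes cannot reach `|d1| = 3` no matter how
complete their repression.  On the log2 scale the statistic is symmetric in
direction and, at zero noise, equals `log2fc / mean|log2fc|` independent of
a gene's baseline — which makes recovery of planted truth closed-form
predictable.  Round-trip tests therefore run on `scale="log2"`; a heuristic
(all intensities < 25) warns when the input already looks log-scaled but
never switches silently.

## Regulon classification

All categories are pure set logic on the per-gene call table (genes ×
(strain, stress)):

* **coregulated** — same non-`none` call under all three stresses within a
  strain; "unidirectional" is enforced strictly, so (up, up, down) is
  excluded.
* **uniquely regulated** — responsive (either direction) under exactly one
  stress; the per-stress sets are disjoint by construction.
* **AtfA-dependent** (per stress and direction) — `up` in the control with
  mutant call in {`none`, `down`} (mirror case for `down`).  No intensity
  magnitudes are compared between strains; only the calls matter.
* **Venn partitions** — the seven disjoint regions of the three per-stress
  responsive sets, computed per strain and direction; their counts always
  sum to the union size.
* **transitions** — a gene's signature is its set of (stress, direction)
  responses.  Genes with differing control/mutant signatures receive one
  primary category with the declared precedence lost_responsiveness >
  gained_responsiveness > gained_dependence > other_shift, plus all
  applicable secondary tags (including lost/gained coregulation).
  `gained_dependence(A→B)` requires the gene to be responsive to A only in
  the control and responsive to B in the mutant; the "to" direction is
  unconstrained by default, with a `strict_direction` flag for the
  same-direction variant.  Counts are reported both with precedence
  (primary) and without (tag counts), because a single gene can satisfy
  several descriptions.

## Enrichment

Gene groups are built three ways: GO terms with transitive annotation
propagation over `is_a` and `part_of` (a gene annotated to a term belongs to
every ancestor; set semantics prevent double counting through diamond
paths; a cycle over these relations is a hard error), flat FunCat
categories without propagation, and curated ID lists from configuration.
Every group is intersected with the analysis background — exactly the
post-revision chip gene list — and empty groups are flagged untestable.

The test is the one-sided over-representation hypergeometric upper tail
`P(X ≥ k)`, the quantity computed by the standard GO term-finder tools.
Raw and Benjamini–Hochberg-adjusted p-values are both reported; the
significance flag uses raw p < 0.05 by default (`significance_on=
"adjusted"` switches), matching how such screens are usually filtered.
A dedicated oracle test verifies the closed-form tail against exhaustive
enumeration of all C(N, n) draws on instances up to 10⁶ combinations, and a
Monte-Carlo null check confirms the raw-p significance rate stays at or
below α (the hypergeometric is discrete, hence conservative).

## qPCR and physiology statistics

ΔΔCP is `(CP_ref,treated − CP_gene,treated) − (CP_ref,untreated −
CP_gene,untreated)` with *actA* (AN6542) as the default reference; one PCR
cycle per two-fold change makes ΔΔCP a log2 fold-change estimate with
induction positive.  Replicates are paired by index within (strain,
condition); with unequal counts the summary falls back to the difference of
per-condition means with a delta-method SD.  ΔΔCP is invariant to adding a
per-replicate plate offset to all CP values.

One-sample (`t = mean / (sd/√n)`, df = n−1) and two-sample
(pooled-variance, df = n1+n2−2; Welch optional) Student t-tests accept
either raw replicate values or printed mean ± SD summaries (sample SD,
n−1 denominator, is assumed for printed ± values).  Degenerate inputs are
defined explicitly: sd = 0 with nonzero mean reports p = 0 (significant),
sd = 0 with zero mean reports t = 0, p = 1.

**Published-panel concordance.**  The packaged panels carry published
significance flags whose underlying tests' sidedness is not documented.
Recomputation classifies each cell as *concordant* (two-sided verdict
matches the flag), *borderline* (only the one-sided verdict matches — e.g.
ΔΔCP 1.4 ± 0.9, n = 4: two-sided p ≈ 0.053, one-sided ≈ 0.026), or
*discordant* (neither convention reproduces the flag; these are consistent
with printed-rounding of the SDs, and one such star is contradicted by the
panel's own accompanying narrative).  Concordant cells are asserted; the
borderline and discordant lists are reported and frozen, not absorbed.
Group counts on the panel always use the published flags as the
authoritative input, with recomputation as a cross-check.

## Synthetic data

The generator emulates the pooled-array design: two strains × (untreated +
three stressors), exactly one column each.  Choices and defaults:

* **Intensities** — log-normal baseline `2^N(10, 2)` with multiplicative
  log2-Gaussian noise (default sd 0.15), the standard error model for
  normalized positive one-color intensities; no replicate, probe-level or
  spatial artifacts are simulated, and normalization is assumed done.
* **Planted regulation** — 5% up + 5% down per stress by default, effect
  `|log2fc| ~ |N(3, 0.75)|` signed by direction.  Cross-stress overlap is
  assigned hierarchically (triple-overlap core, then pairwise extras, then
  stress-unique genes), with targets expressed as fractions of the smallest
  per-stress responsive set and explicit infeasibility errors naming the
  violated constraint.
* **AtfA dependence** — each control-responsive (gene, stress) pair is made
  dependent with probability 0.5 by default: its mutant effect is erased,
  or sign-flipped with probability 0.1.  This is the "absent or reversed in
  the mutant" definition planted as ground truth; the simulator does not
  plant mutant-only (gained) responses except through reversal.
* **qPCR tables** — CP of a planted gene under treatment is its untreated
  CP minus the planted log2fc; the reference gene is condition-independent.
  At zero CP noise the recomputed ΔΔCP equals the planted log2fc exactly.

What passing the synthetic round trips does *not* show: robustness to
probe-level noise structure, array spatial artifacts, normalization error,
or genuinely asymmetric mutant regulons — real-data behaviour on those axes
is outside what the generator emulates.

## Problem sizes and numerical choices

Round-trip checks run at 3 000 genes with constant effect size 3 and 10%
responsive genes per stress, where the log2-scale closed form puts every
planted gene at `|d1| = 10`, comfortably beyond threshold — perfect
recovery is then a correctness requirement, not luck.  The t-test
calibration uses 5 000 null replicates of n = 4 and checks the rejection
rate against the binomial 99% interval around 0.05.  Duplicate probe rows
are collapsed by per-gene median (order-independent and robust;
mean/max configurable) and the collapse rule is recorded in output
metadata.  TSV outputs carry 6 significant digits (12 for expression
matrices, giving write/read round trips lossless to declared precision);
JSON summaries keep full precision.  All generators take explicit integer
seeds; fixed seed implies bit-identical outputs.

## Known limitations

* The exact D1 variant used for the original chip evaluation (linear vs
  log scale, denominator trimming) is not documented anywhere we could rely
  on; the implemented formula is recorded in run metadata and swappable, but
  exact reproduction of historical counts from the deposited matrices may
  require matching those undocumented choices and the same genome-revision
  snapshot.
* Enrichment reproduces the file-based computation, not any web tool's
  server-side defaults.
* The curated groups shipped with the package are the qPCR validation
  panel; chip-wide curated groups must be supplied by the user.
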