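# Methods

`consensusde` implements a whole-blood RNA-seq biomarker analysis for
attention-deficit/hyperactivity disorder (ADHD) built on two cohort designs —
an unpaired case–control comparison and monozygotic twin pairs discordant for
ADHD severity — and on the idea that no single differential-expression (DE)
statistic should be trusted alone. This note documents the models, the
parameters that matter, the synthetic-data generator, and the numerical
choices; it is the package's own account of its science.

## Count model and the DE battery

Counts are modeled at transcript (isoform) resolution as negative binomial
(NB) with the standard quadratic mean–variance law

    Var(Y) = mu + phi * mu^2,

where `phi` is the overdispersion. Aggregating isoforms to genes can mask
changes confined to an alternatively spliced transcript, so counts are never
collapsed; gene symbols exist only for cross-cohort matching.

The battery comprises six statistics spanning five families of analysis; the
consensus layer is method-agnostic, so the number of methods M is
configuration, not a constant:

| method id     | normalization        | test                                  |
|---------------|----------------------|---------------------------------------|
| `exact-tmm`   | TMM                  | conditional NB exact test             |
| `glm-lrt-tmm` | TMM                  | NB GLM likelihood-ratio test (1 df)   |
| `exact-deges` | DEGES (iterated TMM) | conditional NB exact test             |
| `wald-mor`    | median of ratios     | NB GLM Wald test                      |
| `mod-t`       | log-CPM              | trend-weighted moderated t            |
| `clr-mc`      | CLR                  | Dirichlet Monte-Carlo Welch t         |

An empirical-Bayes posterior-probability method (baySeq-style) is not
implemented; it emits no p-value and is left as an extension.

### Dispersion

All NB tests share one dispersion model, estimated by a Cox–Reid adjusted
profile likelihood: the common `phi` maximizes the adjusted likelihood pooled
over transcripts (grid over `phi in {0} ∪ [1e-3, 6]` with parabolic refinement
on the log scale); tagwise estimates are per-transcript maximizers shrunk
toward the common value with weight `prior_df` (default 10) against the
residual degrees of freedom. Fitted means come from a vectorized IRLS fit at a
provisional dispersion and are refined once. For the twin cohort the design
used for fitted means and the Cox–Reid term includes the pair indicators, so
between-pair variance is not misattributed to `phi`. On simulated data the
common estimate recovers `phi` in {0, 0.2, 0.4} to within ±0.005 at 2,000
transcripts (the acceptance suite asserts ±0.1).

### Exact test

Group sums at equalized effective library sizes (counts rescaled to the
geometric-mean depth) are compared conditionally on their total: under the
null, each group sum is NB with dispersion `phi / n_g`, and the two-sided p
sums the conditional probability of every split no more probable than the one
observed. Totals up to 20,000 are enumerated exactly; above that the
conditional law is normal-approximated (mean/variance from the two NB
components, continuity-corrected) — at such depths the approximation error is
far below any decision threshold.

### GLM tests

A log-link NB GLM with fixed tagwise dispersion is fitted by IRLS, vectorized
across transcripts (batched p×p solves; convergence when the relative deviance
change is < 1e-8, at most 50 iterations; linear predictors clipped to ±30;
non-converged transcripts are flagged and conservatively assigned p = 1).
Unpaired design: intercept + group. Paired design: one indicator per pair
(pair-specific intercepts) + group. The LRT drops the group column and refers
the deviance difference to chi-square(1); the Wald test divides the group
coefficient by its standard error from the observed information.

### Moderated t

Counts become log2-CPM with a library-size-scaled pseudocount (0.5 at the
average depth). The scaling matters: with a constant pseudocount, a zero count
maps to a depth-dependent value, so whenever the two groups differ in
sequencing depth by chance, every near-zero transcript inherits a coherent
spurious group effect — on spiked simulations this alone pushed the empirical
FDR of the method above 0.3. Effective library sizes are TMM-corrected for the
same reason (composition bias from one-sided DE otherwise shifts all null
transcripts). A lowess trend of sqrt-residual-sd against average log-count
yields per-observation precision weights (trend^-4); per-transcript weighted
least squares is followed by empirical-Bayes variance moderation,

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d),

with `(d0, s0^2)` fitted by moment-matching a scaled F distribution to the
observed variances on the log scale (digamma/trigamma inversion). Paired
cohorts are analyzed as one-sample tests on within-pair log-CPM differences,
with pair weights combined harmonically from the two members. `prior_df=0`
recovers the ordinary pooled t-test exactly; all-equal transcripts report
p = 1.

### Compositional Monte-Carlo test

Per instance, per-sample compositions are drawn from Dirichlet(counts + 0.5),
centered-log-ratio transformed, and compared by a Welch t per transcript; the
reported p is the mean over instances (default 128), which is conservative by
construction, and the effect is the expected CLR difference in log2 units. The
instance stream is seeded, so results are reproducible.

### Multiple testing

Benjamini–Hochberg step-up adjustment (delegated to statsmodels behind the
`bh_adjust` surface; an independently coded textbook step-up serves as the
test oracle).

## Normalization

* **TMM** — weighted trimmed mean of M-values against a reference sample
  (chosen by the 75th-percentile rule), trimming 30% of M-values and 5% of
  A-values on each side, delta-method precision weights, factors rescaled to
  geometric mean 1.
* **Median of ratios** — per-sample median of count ratios to per-transcript
  geometric means over transcripts nonzero in every sample; factors are
  absolute size factors.
* **DEGES** — iterate (default 3×): TMM-normalize, run the exact test, drop
  the top 30% of transcripts by raw p, recompute TMM on the remainder. The
  subset factors are rescaled by the subset-to-full library-size ratio so they
  apply to the full matrix — this step is what lets DEGES undo the bias that
  a large one-sided DE fraction induces in single-pass TMM.

A note on tolerances: factor-recovery checks ("TMM within 5%", "DEGES equals
TMM within 2% without DE") are run on near-Poisson simulations (dispersion
0.02–0.05). At `phi = 0.2` the sampling noise of a trimmed weighted mean of
M-values (whose spread is then dominated by biological dispersion) exceeds
those bands at desk-scale transcript counts, regardless of estimator; the
checks measure depth recovery, not biological noise.

## Expression metrics and filters

RPKM is count / (length/10^3) / (informative reads/10^6), with "informative
reads" the column sum of the supplied matrix. The prevalence filter keeps a
transcript when RPKM strictly exceeds `tau = 0.01` in at least a fraction
`phi = 0.70` of the samples of one diagnostic group; the fraction comparison
uses exact rational arithmetic (`Fraction(k, n) >= Fraction("0.7")`) so
boundary cases like 7/10 never depend on floating-point representation. The
`>= phi` reading of "70%" is a configurable choice.

Fold changes use a pseudocount (default 0.25 on the mean scale) on both group
means; per-pair fold changes are log2 ratios of the affected over the
unaffected twin with the same pseudocount. The triple filter combines
prevalence, |ratio| > 1.5 (either direction), and an uncorrected t-test
p < 0.01 on log2(RPKM + pseudocount) — Welch for unpaired cohorts, paired t on
within-pair differences for twins. The t-statistic choice is logged in the run
report; the filtering thresholds are named config keys with these defaults.

## Consensus and cross-cohort comparison

Each method contributes its top K = 100 transcripts ranked by adjusted p (ties
broken by raw p, then transcript id — top-100 cutoffs will hit ties, so the
tie-break is part of the contract). The consensus statistic is the appearance
count across method lists; the table sorts by count, best adjusted p, then id.
Pairwise method concordance is a Jaccard matrix over the top-K sets.

Cohorts are intersected at gene-symbol level (the most significant passing
isoform defines a symbol's direction); symbols with opposite directions are
excluded. Overlap significance is the one-sided hypergeometric upper tail
P(X >= k) — the enrichment tail of the 2×2 exact test — over an explicitly
supplied universe; the universe is never silently defaulted, because the
overlap p is meaningless without it.

## Twin discordance

Eligibility: a pair is discordant when any criterion fires — raw-score
separation >= 3 with the lower twin below the diagnostic threshold (default
12 on the 0–27 ADHD-RS raw total), T-score difference >= 10, or a
diagnosis/treatment asymmetry. The quantitative discrepancy score is the
absolute within-pair difference of ADHD-RS raw subscale scores (inattention,
hyperactivity–impulsivity, total; each 0–27). Pairs are ranked with rank 1 =
most discrepant, ties sharing the average rank. A clinician consensus ranking
cannot be computed from data and is only accepted as an input column.

Per-transcript within-pair fold changes are correlated with the rank (Pearson
by default because the fold change is interval-scaled; Spearman available
since ranks are ordinal). Negative r — larger expression change in more
discordant pairs — is the biomarker-consistent direction; transcripts with
r <= -0.4 are flagged, and positive-r transcripts are reported too, since an
inverse severity relationship is also informative. Constant fold-change
vectors yield a missing r, never zero.

## Synthetic cohorts

The generator emulates the two cohort designs so every stage is testable
without patient data:

* transcript baselines log-uniform over 18 log2 units (2^-5 to 2^13 expected
  counts), emulating the very wide dynamic range of ribo-depleted whole-blood
  sequencing; transcript ids, symbols and lengths (log-uniform 200 bp – 20 kb)
  are deterministic in the transcript index, so cohorts share an annotation;
* NB counts at dispersion `phi` (default 0.2, a typical bulk-tissue value
  chosen for testability); library sizes log-uniform
  over 0.5×–2× to exercise normalization;
* group sizes 23 affected / 21 unaffected (case–control) and 16 discordant
  pairs (twins);
* a spiked DE fraction (default 10%) with log2 fold-change magnitudes uniform
  in [0.585, 3.0] (1.5× to 8×, bracketing the changes the design targets),
  random or fixed sign; spiked baselines can be floored (`de_min_mean`);
* twins: an independent log-normal effect per (pair, transcript), shared by
  both twins (sd 0.2 on the natural-log scale, a modest heritable/shared-
  environment component on top of `phi`). A single scalar per pair would be
  indistinguishable from a library-size factor and removed by normalization,
  leaving paired tests nothing to exploit, so the effect is per-transcript;
* ADHD-RS raw scores drawn as integers on the instrument's 0–27 range with
  the affected twin scoring higher; T-scores at clinically typical group
  means (62 ± 9 affected, 47 ± 6.8 unaffected);
* a coupling set (default 5 transcripts at correlation 0.8, amplitude 1.5
  log2 units) whose per-pair fold change tracks the pair's total-score
  discrepancy. Coupled transcripts are drawn from DE transcripts with
  baseline >= 50 expected counts: a severity-tracking biomarker is by
  construction above the detection floor, and at 16 pairs the count noise of
  weakly expressed transcripts would attenuate the correlation below
  recoverability.

What the generator does **not** emulate: sequencing-read artifacts, ribosomal
depletion efficiency, alignment ambiguity, batch effects, correlated
transcript modules, isoform-sharing between symbols, or any real covariance
between clinical scores and genome-wide expression. Passing tests therefore
demonstrate statistical correctness of the pipeline under its stated model,
not fidelity to any particular dataset.

## Determinism and problem sizes

Every stochastic component takes a seed; sub-streams are derived with
`SeedSequence` (kept below 2^31). A fixed config + seed reproduces every
output file byte for byte, and a resumed run on the emitted matrices
reproduces the analysis outputs. The test and acceptance runs use desk-scale
problem sizes — 2,000-transcript cohorts for calibration (10 seeds),
5,000 transcripts for consensus recovery, 150–200 seeds for the 16-pair
coupling recovery — chosen so the whole suite completes in a few minutes while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The six statistics are in-house implementations spanning the families of
  the established packages, not numerical replicas of edgeR/DESeq2/voom/ALDEx2
  internals; no quasi-likelihood F-tests, independent filtering, or fold-
  change shrinkage.
* The exact test ignores pairing; on twin data its inference is valid but
  leaves paired power on the table (the GLM and moderated t use the pairing).
* The conditional exact test's large-total branch is a normal approximation.
* Simulated cohorts draw independent DE truths, so the cross-cohort overlap
  of a default simulated run is at chance level by design.
* The hypergeometric overlap p treats the two hit lists as independent draws
  from the universe, which ignores the correlation structure of transcripts.
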