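# Methods

This note documents the statistical procedures implemented in `clutchsig`,
their assumptions, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Data model

The input is a probes × samples matrix of log2 single-channel intensities
from individual unfertilized eggs, each sample assigned to the mother it was
squeezed from. Mother and clutch are confounded by design: a "clutch effect"
cannot be separated from a "mother effect", and all conclusions are phrased
at the clutch level. One probe targets one transcript (3'-end design);
several transcripts, hence probes, may map to one gene. Every downstream
gene-level statistic runs on post-normalization values of the gene's
representative probe (highest across-sample mean intensity).

## Preprocessing

Order: extreme genes → suspect probes → quantile normalization.

- **Extreme genes.** A gene is dropped when exactly one sample sits at least
  `log2(fc_threshold)` (default threshold 3,000-fold, ≈ 11.55 log2 units)
  above the maximum of its other samples. The rule deliberately leaves
  genes with two or more high samples alone: a single isolated extreme is
  a measurement artifact, a repeated one may be biology.
- **Suspect probes.** Intensities are centered on each array's mean; an
  array's scaling factor is its mean minus the grand mean. Probes whose
  centered intensities correlate at or below `corr_cut` (default −0.8) with
  the scaling factors *and* whose centered sd is at or above `sd_cut`
  (default: 90th percentile of centered sds) are removed — they behave like
  transcripts carrying native long poly(A) tails, which a
  polyadenylation-based labeling protocol cannot scale with the rest of the
  array. Both cuts are exposed on the CLI; no principled universal values
  exist, so they are tunable diagnostics, not constants.
- **Quantile normalization.** Each column's sorted values are replaced by
  the across-column mean of sorted values; ties receive the mean of their
  tied quantile values (implemented by interpolating the reference
  distribution at average ranks). The transform is idempotent to numerical
  precision and removes any per-array multiplicative scaling exactly.

## Expressed-gene calling

Assumption: expressed probes vary across eggs (biologically and
technically), background probes do not, so the per-probe log variance of
log2 intensity over the experiment is bimodal. The procedure is run on
*raw* (filtered, unnormalized) data, since per-array scaling contributes
variance to every probe equally and the posterior step is per-array anyway.

1. **Log variance.** Natural log of the unbiased across-sample variance.
   Zero-variance probes map to (minimum finite value − 1) so they fall in
   the low class instead of producing −∞.
2. **Valley.** A binned Gaussian KDE (Silverman bandwidth, 512-point grid)
   of the log variances; modes are local maxima with prominence ≥ 5% of the
   density maximum; the valley is the density minimum strictly between the
   two highest modes. A 200-bin histogram fallback (peak prominence also
   ≥ 4·√max-count, the Poisson noise scale) is tried before declaring the
   distribution unimodal, which is an error — never a silent threshold.
3. **Split.** Probes at or above the valley are high-variance (boundary
   convention: the valley itself is high).
4. **Posterior.** Per array, the class-conditional intensity densities
   f_low and f_high are estimated from that array's low-class and
   high-class probe intensities (binned Gaussian KDE on a 2048-point grid;
   a two-Gaussian fit is available via `density="gaussian"`, and pooling
   across arrays via `per_array=False`). Priors are the experiment-wide
   class proportions. Posterior = π_h f_h / (π_h f_h + π_l f_l). Where both
   densities vanish the posterior is assigned by the nearer class support;
   an empty class yields the constant degenerate posterior.
5. **Calls.** Probe expressed on an array iff posterior > 0.95 (stringent
   against false positives); transcript expressed iff its probe passes on
   ≥ 4 arrays; gene expressed iff any transcript is. Raising the posterior
   threshold can only shrink the expressed set.

## Fold-change variability

On log2 data the maximum fold change (mFC) of a gene is max − min over the
samples considered; the within-clutch mFC is the largest per-clutch range.
Within-clutch mFC ≤ experiment mFC always. Threshold summaries use ≤ on
the log2 bound (a gene at exactly twofold counts as "within twofold").

## Mother-specific signatures

Per expressed gene, the per-clutch interval [min, max] of the
representative probe's normalized values. Clutches are merged by
transitive *closed*-interval overlap (a shared endpoint is overlap, so
"absolutely distinct" requires a strict gap); the connected components are
the unique finest partition of clutches into groups with pairwise disjoint
hulls — verified in the test suite against exhaustive set-partition search.
If more than one group remains, the gene carries a signature with n_levels
= number of groups; groups are ranked by hull midpoint (ties by group
minimum), highest = level 1, and the profile code assigns each mother the
digit of its group. Genes sharing a code form a signature cluster; for
two-level codes the inverse code swaps 1 ↔ 2. Detection is deterministic
on the ranges; no per-gene significance is attached.

## Differential expression

Per-gene one-way fixed-effects ANOVA with clutch as the single factor
(df: k−1, n−k). No variance moderation or shrinkage: with ≥ 4 eggs per
clutch the per-gene error estimate is used as-is. Zero within-group
variance with non-zero between yields the smallest positive double with a
flag rather than p = 0. FDR control uses Storey q-values: π₀(λ) =
#{p > λ}/(m(1−λ)) on λ = 0.05…0.95 (step 0.05), extrapolated to λ → 1 with
a cubic polynomial smoother, clipped to [1/m, 1]; q of the i-th ranked p is
min over j ≥ i of π₀ m p₍ⱼ₎ / j. With π₀ = 1 this reduces exactly to
Benjamini–Hochberg, which is exposed as `method="bh"`.

## Enrichment

- **Motif scoring.** IUPAC patterns over the RNA alphabet expand to
  position weights 1/|allowed| against a uniform 0.25 background; the
  per-sequence score is the mean over same-strand windows of the per-column
  odds product, with exact-match counts reported alongside. Ambiguous
  sequence letters are odds-neutral for scoring and non-matching for exact
  counts. The builtin set: AAUAAA, AUUAAA, UUUUAU, UUUUAMU, UGUA(N)AUA, and
  each poly-U run length 11–20 as a separate motif in the correction
  family.
- **Rank-sum test.** One-sided (foreground greater) Wilcoxon rank-sum on
  the scores, Bonferroni-corrected across the motif set. Consensus-motif
  scores on short UTRs take only a few distinct values (essentially hit
  counts), where the asymptotic normal approximation is anti-conservative;
  the p-value is therefore computed exactly — the permutation distribution
  of the foreground mid-rank sum over the tie classes is a multivariate
  hypergeometric and is enumerated whenever the enumeration stays below
  10⁵ combinations, with the tie-corrected asymptotic test as fallback for
  near-continuous scores. All-tied scores give p = 1.
- **Overrepresentation.** Upper-tail hypergeometric p of the overlap
  between a set of interest and an annotation set inside an explicit
  universe (equivalent to one-sided Fisher); overlap 0 gives p = 1.
  External gene-set collections are consumed as plain two-column tables;
  no term database is bundled.
- **Chromosome distribution.** Clusters × chromosomes matrix of gene
  fractions (rows sum to 1, unmapped genes in an "unplaced" column),
  clustered with Euclidean distance and Ward linkage. Rows are sorted by
  label before linkage so the tree is invariant to input order; the row
  pairs that merge as original leaves are reported — the clusterogram
  analogue of inverse-profile clusters pairing up.

## Synthetic data

`generate_dataset` emulates the experiment the analysis assumes: 24 eggs in
5 clutches (sizes 5,5,5,4,5), a fraction of genes expressed, the rest
background. Expressed probe intensity = gene baseline (uniform on
`expr_mean_range`) + clutch offset + egg noise + probe affinity + per-array
scale; background probes = N(bg_mean, bg_sd) + affinity + scale. Signature
genes (a fraction of expressed genes) take clutch offsets from a planted
profile code with consecutive levels `level_separation` apart (two-level
codes by default, mirroring the dominant observed structure; more via
`max_levels`); other expressed genes get N(0, clutch_sd) jitter per mother,
so subtle mother effects touch every expressed gene, as observed in real
clutch data. All randomness flows from one seed through spawned
`SeedSequence` streams. Optionally `n_suspect_probes` expressed probes skip
the array scale, emulating natively polyadenylated transcripts for QC
tests.

Default calibration, chosen once from the structure the analysis assumes
and the magnitudes the source experiment reports, not from test outcomes:

- `egg_sd = 0.24`: Monte-Carlo of the max-over-clutches range of
  N(0, σ) noise puts ~88% of genes within a twofold within-clutch range at
  σ = 0.24 — the observed tight within-clutch regulation.
- `bg_sd = 0.05`, `array_scale_sd = 0.1`: total raw background sd ≈ 0.11,
  so the background log-variance mode sits clearly below the valley, the
  regime in which a valley near ln(var) ≈ −3.7 separates the classes. The
  generator must satisfy the caller's own assumption (clean bimodality) or
  recovery tests would measure the generator, not the method.
- `clutch_sd = 0.1`: non-signature mother jitter, small relative to level
  separations but detectable by ANOVA on most genes — the "virtually all
  genes are mother-differential" regime.
- `expr_mean_range = (6, 10)` vs `bg_mean = 4`: 4 log2 units between class
  intensity means; recovery studies at 3 log2 units tighten this via
  `expr_mean_range=(5.5, 8.5)`.
- `probe_affinity_sd = 0.25`: probe-level offsets so probes of one gene
  agree in profile but not in absolute intensity.

`generate_utrs` produces uniform-random ACGU sequences with exact
consensus occurrences of chosen motifs planted at random positions in
chosen genes; background occurrence rates follow the closed form
(L−k+1)/4ᵏ per fixed k-mer.

**What the generator does not emulate:** scanner physics, dye or spatial
artifacts, probe-sequence hybridization thermodynamics, correlated egg
noise across probes of a gene, non-Gaussian heavy-tailed intensity noise,
and realistic 3'UTR base composition. Passing recovery tests therefore
demonstrates correctness of the inference under the stated statistical
model, not performance on any real array.

## Problem sizes and numerics

Recovery studies run at 10,000 genes × 2 probes × 24 samples; oracle
equivalence checks use 1,000 random interval instances, 500 mFC instances
and universes ≤ 20 for exact hypergeometric enumeration; motif null
calibration uses 500 resampled splits of 400 sequences. Density grids:
512 points (valley), 2048 (posterior). Quantile-normalization and linkage
determinism are asserted at 1e-9; the exact rank-sum enumeration is capped
at 10⁵ tie-class combinations. Ties and boundaries are fixed by convention
and tested: valley boundary → high class, representative-probe ties →
lexicographically smallest probe id, level-rank ties → higher group
minimum first, shared interval endpoints → overlap.

## Known limitations

- The valley finder requires genuine bimodality and refuses otherwise;
  arrays with few expressed probes will not be callable.
- Storey π₀ via a cubic polynomial smoother can differ slightly from
  spline-based implementations; the BH mode is exact.
- The exact rank-sum enumeration grows with the number of distinct score
  values; for rich scores the asymptotic fallback reintroduces the usual
  large-sample approximation.
- Mother and clutch are confounded; the ANOVA factor is "clutch" and no
  egg-level random effect is modeled.
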