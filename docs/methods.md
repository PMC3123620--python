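# Methods

`mirsig` implements a complete analysis chain for paired tumor /
adjacent-normal qPCR-array data on the cycle-threshold (Ct) scale:
quantile normalization, paired differential-expression testing with FDR
control, signature selection, hierarchical-clustering classification,
cross-validated generalization testing with a permuted-label null, and
PCA-based subgroup discovery.  This note records the statistical model,
the defaults and why they were chosen, and the numerical decisions made
where the design was genuinely open.

## The Ct scale and the sign convention

qPCR reports, per miRNA and sample, the cycle number at which amplified
signal crosses a threshold.  Abundance and Ct are inversely related: one
fewer cycle ≈ a doubling of starting template.  The single sign convention
the whole package relies on is fixed in the generator and the direction
caller: **up-regulated expression = decreased Ct**.  A feature's paired
effect is reported as the mean ΔCt = Ct(malignant) − Ct(normal); a
negative mean ΔCt yields a `+` (up in tumor) direction call.

## Synthetic data generator

Each well is drawn as

    Ct = baseline(feature) + case(pair) + offset(sample array)
         + DE shift (malignant wells of planted features)
         + Gleason shift (malignant wells of subgroup features)
         + ε,   ε ~ N(0, noise_sd²)

with wells above the detection ceiling `ct_max` recorded as missing
("Undetermined"), never clamped, and additional wells removed completely
at random at `missing_rate`.

Defaults mirror a ~19-case, 667-miRNA paired cohort: `n_cases=19`,
`n_features=667`, `n_de=9`, `effect_ct=2.0` cycles, baselines uniform on
20–35 cycles, `ct_max=40` (a standard 40-cycle protocol).  Quantities no
study reports had to be fixed once as realistic values: between-case SD
1.0 cycle (biological heterogeneity shared by both tissues of a pair),
per-array additive offset SD 0.5 cycles (loading/efficiency differences —
exactly the nuisance quantile normalization removes, which gives
normalization a falsifiable job in the test suite), and a 2% random
missing-well rate.

What the generator deliberately does **not** emulate: TaqMan chemistry and
pre-amplification bias, card A/B panel structure, replicate wells,
informative missingness (dropout correlated with high Ct beyond the hard
ceiling), and heavy-tailed well noise.  Tests passing on this generator
therefore demonstrate that the pipeline's statistics behave correctly
under the paired-Gaussian-with-offsets model, not that any particular
biological dataset will separate.

The Gleason variant assigns each case one of the configured scores
(round-robin) and adds a score-specific shift on a dedicated 16-feature
block disjoint from the DE block.  In strong-separation test scenarios the
shifts are centered around zero (e.g. −6/−2/+2/+6 cycles) and baselines
kept ≤ 28 cycles so the largest shift cannot cross the 40-cycle ceiling;
otherwise censoring turns planted wells into missing values and removes
those features from downstream complete-case analyses.

## Quantile normalization

Samples are forced onto a common reference distribution — the mean of
order statistics across arrays — preserving within-sample ranks.  On
complete data this is the classical exact algorithm: every sample's sorted
value vector becomes identical, and a pure per-sample additive offset is
removed exactly.  With missing wells, each sample's observed quantile
function is linearly interpolated onto a common grid of length
`n_features` when building the reference, and an observed value of
(average) rank *r* among *m* non-missing wells is replaced by the
reference quantile at position (r−1)/(m−1).  This reduces to the exact
algorithm when m = n and gives tied wells the mean of the reference values
at their tied ranks.  Missing wells are never imputed.  Normalization is
applied to Ct directly, not to ΔCt or 2^−Ct.

## Paired differential expression

Per feature, pairs with a missing well in either member are dropped; the
remaining differences d feed a paired Student's t-test
(t = mean(d)/(sd(d)/√n), two-sided p on n−1 df, vectorized across
features) and, for comparison, a two-sided Wilcoxon signed-rank test
(zeros dropped; exact null for n ≤ 25, normal approximation with
continuity correction above).  Degenerate inputs are flagged rather than
propagated as NaN: all differences identical but nonzero → t = ±∞, p = 0,
flag `degenerate`; all differences exactly zero, or fewer than two usable
pairs → flag `untestable`, p missing.

Benjamini–Hochberg adjustment is applied over all testable features (m ≈
667), with untestable features excluded from m.  Signatures are the
features with t-test p **strictly below** the threshold, ordered by
ascending p with a lexicographic feature-ID tie-break so reports are
byte-reproducible.  The two conventional thresholds are 1e-4 and 1e-5;
by construction the stringent signature is nested in the permissive one.

## Clustering as a classifier

Samples are compared by Euclidean distance over the signature features.
When signature wells are missing, a pair's distance uses the mutually
non-missing features rescaled by √(n_total/n_used) to remain comparable;
a pair sharing no features is an error (and, inside cross-validation,
marks the repeat as failed).  Agglomeration is UPGMA — the distance
between clusters is the unweighted mean of all cross-pair distances — and
a k-cluster partition is obtained by undoing the last k−1 merges.  Full
cohorts are cut at k = 2 (tumor vs normal); held-out sets in
cross-validation at k = 3, which tolerates a single outlier cluster.

Scoring is by majority vote: each cluster is labeled with its most
frequent tissue class and minority members count as misplaced.  A tied
cluster is scored conservatively against the cohort-wide majority class
and the tie recorded.  No leaf-order seriation is performed; partitions
depend only on merges and cuts.

## Cross-validation and the permutation null

Each of 15 repetitions samples 14 of the 19 case pairs (pairs kept
intact), re-runs the paired t-test and signature selection at p < 1e-4 on
the 28 training samples only, then clusters the 10 held-out samples
(5 normal + 5 malignant) on that signature and counts misplacements.
Selection happens strictly inside the loop, so held-out error is an
honest generalization estimate; a dedicated test verifies that perturbing
only held-out samples cannot change a repeat's signature.  Repeats whose
signature is empty (or unusable on the held-out samples) are recorded as
failed with a reason and excluded from the error average.  One global seed
spawns per-repeat seeds, making any repeat reproducible in isolation.

The null control permutes tissue-class labels before each repeat by
swapping normal↔malignant within each case with probability ½ — the
label permutation that preserves the paired design, keeping the paired
t-test well defined (an unrestricted shuffle is available behind a flag).
On data with real signal this collapses the per-repeat signatures toward
the ~667·α false positives expected by chance, and most repeats fail
empty.

The aggregate error rate is mean(misplaced / held-out size) over
successful repeats, reported as a percentage; the per-repeat histogram is
reported alongside, and the two are consistent by construction.

## PCA and subgroup discovery

Features are centered and scaled to unit variance before PCA
(zero-variance features are dropped with a warning); loading signs are
fixed so each component's largest-magnitude loading is positive.  The
subgroup sweep operates on malignant samples: per feature, a one-way
F-test across the levels of the grouping variable (Gleason score); then,
for each threshold in a descending sweep (default 40 log-spaced points
from 0.05 to 1e-4), the sub-threshold complete features are projected
with PCA and the top-2 scores partitioned by k-means (g = number of
levels, 50 restarts, seeded).  Concordance is majority-vote misplacement
against the known levels.  The sweep returns the most permissive
threshold attaining the minimal misplacement, with the full trace, so the
minimal feature set achieving the same concordance can be read off the
trace or from the F-test ranking.  The sweep statistic is pluggable; the
F-test is the default reading of "decrease a p-value threshold until
groups emerge".

## Problem sizes and determinism

All simulation-backed tests run at the study's own scale (667 features ×
38 samples), which the vectorized t-test handles in milliseconds; seed
batteries use 100 generator seeds for recovery/type-I checks and 5 seeds
for the subgroup sweep.  Every stochastic component — generator, CV
repeat sampling, label permutation, k-means — is driven by explicit
`numpy.random.default_rng` seeds; equal (config, seed) reproduce
bit-identical outputs, and the pipeline writes its resolved configuration
next to its artifacts.

## Known limitations

- The quantile-normalization behavior under missing data is one of
  several defensible interpolation schemes; alternatives differ slightly
  in how unequal detection across arrays is projected onto the reference.
- The paired t-test assumes approximately normal Ct differences; the
  signed-rank test is computed alongside for exactly this reason, and the
  package reports their concordance rather than arbitrating.
- Majority-vote scoring of a k=3 cut is a coarse classifier; it cannot
  express confidence and treats an outlier singleton cluster as its own
  majority.
- The subgroup sweep's k-means step depends on its seed when groups
  overlap; with 50 restarts this matters only in genuinely ambiguous
  configurations.
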