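# Methods

## Overview

`selandscape` implements the cis-regulatory analysis workflow used to map
superenhancer (SE) landscapes in breast-cancer H3K27Ac ChIP-seq cohorts and
to nominate tumor-specific, dependency-linked oncogenes:

1. **Per-sample SE calling** (`rose.py`). Peaks within 12.5 kb of each
   other are stitched into candidate regions; regions are scored by
   depth-adjusted (reads-per-million) ChIP signal minus matched input,
   floored at 0; regions are ranked ascending by signal and the SE cutoff
   is the inflection point of the ranked curve. With ranks and signals
   min-max scaled to x, y ∈ [0, 1], the cutoff rank is argmax(x − y): the
   point where a slope-1 line is tangent to the curve, which is the exact,
   deterministic form of the usual graphical definition. Ties in signal are
   broken by genomic position, so the ranking is order-invariant. TSS
   exclusion is implemented but defaults to 0 (off).
2. **Consensus maps** (`consensus.py`). Per-sample SE calls are
   consolidated across samples by transitive merging of intervals sharing
   ≥ 5000 bp; typical-enhancer (peak-level) calls merge at ≥ 10 bp.
   "Minimum overlap" is read as required shared bases (bedtools merge with
   negative `-d`), and a test cross-checks the boundary against bedtools
   itself. Enhancer-class elements overlapping a TSS by ≥ 1 bp are removed
   whole; SEs keep TSS overlaps. Consensus SEs are split into 20 kb bins;
   the final short bin is kept so binning conserves territory.
3. **Scoring and presence** (`scoring.py`). Every sample is scored against
   the consensus map as input-subtracted RPKM
   max(0, RPKM_ChIP − RPKM_input); a sample is SE-positive for an element
   when log2(score + 1) ≥ 6 (inclusive). Length normalization uses full
   RPKM (not bare per-million counts) because the score feeds a fixed
   cross-element threshold. "SE size" per sample is the sum of the
   element's bin scores — genomic width is fixed by the consensus, so
   signal mass is the only sample-varying notion of size.
4. **Clustering** (`cluster.py`). The top 10% of SEs by variance of SE
   size (ceiling count; ties by element id) feed a sample × sample Pearson
   matrix of log2(size + 1); variance is taken on the raw sizes, the
   correlation on log values (log compresses the dynamic range the same way
   the presence threshold does). Average-linkage (UPGMA) clustering on
   distance 1 − r is cut at k = 10; clusters with < 3 samples dissolve to
   "unassigned". k is a configuration parameter — elbow and silhouette
   diagnostics are reported but never override it. Group-defining SEs are
   those where, for some set S of clusters, every in-group mean minus
   sample SD strictly exceeds every out-group mean; valid S are always
   top runs of the clusters ordered by mean, so only prefixes are tested
   and the maximal one is reported (singleton S = cluster-specific,
   larger proper S = shared).
5. **SE→gene mapping** (`genemap.py`). Candidates are all genes whose span
   lies within 10 Mb (inclusive, nearest-edge distance) of the SE.
   Association: Pearson r of log2(size + 1) vs log2(RPKM + 1) across tumor
   cell lines (primaries excluded by default — they lack matched culture
   conditions), keep r ≥ 0.6, always add the 2 best-correlated genes
   ("mandatory"). Zero-variance vectors get r defined as 0 so batch runs
   never crash; such genes stay eligible for mandatory slots only.
6. **Tumor-specific SEs** (`tumor.py`). *Acquired*: present in ≥ 4 tumor
   cell lines and ≥ 1 primary, absent from every normal. *Enlarged*: same
   tumor presence, present in normals, and mean tumor score ≥ 2× mean
   normal score (inclusive). The fold uses the depth-normalized
   input-subtracted score rather than raw read totals, which are
   depth-confounded. Acquired takes precedence when both hold.
7. **Screen analysis** (`screen.py`). Guide LFC = log2((CPM_late + 0.5) /
   (CPM_t0 + 0.5)); gene LFC = mean of the 3 most-depleted guides (the
   standard dropout convention for "top"); normalization is the affine map
   sending the essential-gene mean to −1.0 and the NTC mean to 0.0; hits at
   norm LFC ≤ −0.5 (inclusive). Cell lines are "dependent" at CERES-like
   score ≤ −0.5. The dependency signature takes the `signature_size` most
   positively and most negatively point-biserial-correlated SEs and tests
   separation of per-line signature scores (positive-set sum minus
   negative-set sum) between dependency classes with a two-sided
   Mann-Whitney U test.

### The signature separation p-value is selection-biased

The signature is selected on the same dependency labels it is then tested
against, so the naive `separation_p` is anti-conservative: on pure noise it
is still ≈ 10⁻³. It is reported because it matches the workflow being
reproduced, but `permutation_separation_p` re-runs the whole
selection-plus-test procedure inside each label permutation and returns an
empirical p that is uniform under the null (verified by a KS test in the
suite). Use the calibrated p for inference.

## The synthetic study

`synth.py` generates a complete miniature cohort with planted ground truth
for every downstream stage. Defaults (all configurable):

| component | default | why |
|---|---|---|
| genome | 8 chromosomes × 2.5 Mb | the 10 Mb gene window spans a whole chromosome at desk scale; same-ownership-pattern SEs and their target genes are placed on different chromosomes so exact association recovery is well-defined |
| samples | 16 cell lines in 4 clusters, 2 outlier lines, 8 primaries in 2 clusters, 1 outlier primary, 4 normals (31 total) | mirrors a cohort with cell-line clusters, primary-tumor clusters, normals and a few unclassifiable samples |
| SE elements | 26 shared, 4 per cluster (one high-signal marker each), 8 tumor-specific (2 enlarged), 5 normal-only, 3 private per outlier; 18 kb spans of 4–6 peaks | every class the calling/cluster/tumor-specific stages must distinguish |
| signal levels | owner input-subtracted RPKM on an evenly spaced 150–1000 grid; cluster markers 2300–2500; typical enhancers 5–15 | grid spacing keeps the per-sample ranked curve strictly steeper than slope 1 beyond the typical/SE boundary, so the inflection cutoff falls exactly there; marker levels dominate the variance ranking so every cluster's identity survives top-10% selection |
| enlarged SEs | owned by all tumors at level L, normals at L/3 | exercises the 2× rule with margin on both sides of the presence threshold |
| background | Poisson, 0.5 reads/bp in 10 kb windows, ChIP and input independent | input subtraction then cancels background in expectation; residual noise ≈ 0.8 RPKM per element, far from the 63-RPKM presence boundary |
| expression | log2(RPKM+1) = 2 + log2(size+1) + N(0, σ), σ tuned from the cell-line size variance so realized r ≈ the target (target 1 ⇒ σ = 0) | the Monte-Carlo calibration test shows realized r ∈ [0.7, 0.99] in ≥ 95% of seeds at target 0.9 |
| screen | 8 guides/gene; NB counts (size 30, base mean 500); ~half the guides carry full effect, a quarter partial, a quarter none; essential effect −3 LFC | makes top-3 selection meaningful; planted dependencies deplete only in their dependent lines |

Shared and enlarged elements carry a deterministic alternating ±20 % / ±25 %
per-sample modulation. Because the alternation is balanced inside every
4-sample cluster block, these elements correlate exactly 0 with any cluster
indicator — they can never produce spurious gene associations — while still
having genuine per-sample variance (a flat vector would correlate with
noise unpredictably). Elements with zero variance across cell lines
(normal-only, primary-cluster, primary-outlier SEs) live on the last
chromosome, which carries no associated genes, for the same reason.

Outlier samples co-own two cluster markers from different clusters plus
private SEs, which makes them moderately similar to several clusters but
identical to none: cutting the UPGMA tree at k = 10 then isolates exactly
the 7 planted clusters plus 3 singletons, and the min-cluster-size rule
leaves the singletons unassigned — reproducing the cluster-plus-unassigned
structure the pipeline must handle.

What the generator does **not** emulate: fragment-level reads, GC and
mappability bias, copy-number confounding of ChIP or guide counts,
correlated backgrounds between ChIP and input, peak-caller false negatives,
and biological covariance between SEs beyond the planted ownership
patterns. Passing the planted-recovery suite therefore demonstrates that
the *computational* contract of each stage is honored (thresholds,
orderings, set operations, normalizations), not that the pipeline is robust
to every artifact of real ChIP-seq.

## Numerical choices and degenerate inputs

- Gap/overlap/threshold comparisons are inclusive exactly where the
  workflow prints a boundary ("within 12.5 kb", "= > 6", "0.6 or greater",
  "at or below −0.5", "at least 2 times", "less than or equal to −0.5").
- Input-subtracted signal floors at 0 before any log; log transforms are
  log2(x + 1).
- A flat ranked curve (all signals equal) yields zero SEs with a warning;
  fewer than two stitched regions is an error.
- Zero-variance samples are dropped from the correlation matrix with a
  warning; zero-variance expression/size vectors get r = 0; constant
  elements get dependency correlation 0.
- Mandatory-association ties break by distance then gene id; variance ties
  by element id; ranking ties by genomic position — all orderings are
  deterministic and order-invariant.
- The strict (">") reading of "mean minus SD does not overlap" is used and
  configurable to "≥"; clusters with < 2 members are skipped with a warning
  because the SD is undefined.
- Pseudocount 0.5 on CPM in guide LFCs; library sizes default to column
  totals.
- Seeds: every generator consumes a `numpy` `SeedSequence` derived from the
  study seed plus a stage-specific constant, so stages are independently
  reproducible and byte-identical across runs.

## Problem sizes

The shipped study (31 samples, 20 Mb genome, 332 elements, 62 genes,
~180-guide screens) runs end-to-end in well under a minute; oracle
equivalence tests use randomized instances up to 1000 elements. These sizes
were chosen so every planted effect has a decade of margin over its
threshold while the whole suite stays desk-scale.

## Known limitations

- Consolidation implements the transitive closure of the pairwise
  ≥-overlap relation; a sequential sweep (as some merge tools implement)
  can differ on long chains of partially overlapping intervals.
- The enhancer-class consensus is built from raw peak calls; peak-caller
  post-filters are available (`rose.filter_peaks`) but carry no default
  thresholds because they are dataset-specific.
- `separation_p` inherits the selection circularity discussed above; the
  permutation-calibrated variant is the inferentially valid one.
- RNA-based clustering reuses the same selection/correlation/linkage
  machinery on an expression matrix; no expression-specific normalization
  (e.g. variance stabilization) is applied.
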