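# Methods

This note documents the models, conventions and design choices behind
`cardiac_atlas`, in the order the pipeline runs.

## Synthetic study design

The generator (`cardiac_atlas.synthetic`) emulates the statistical structure
of a two-line iPSC → cardiomyocyte differentiation sampled by droplet
scRNA-seq on days 0/2/4/10. Its defaults are the study conditions, not tuning
knobs:

* **Cells per day** 11,281 / 6,466 / 8,650 / 5,968 (32,365 total), with
  50,000 ambient (empty) droplets per day.
* **Day-by-stage mixture** `emulate_printed_composition()` — the
  row-stochastic time × stage matrix whose entries reproduce the published
  composition of each stage (day 0 is pure stage I; day 10 apportions stages
  II–V as 23/87/4669/1187 out of 5,968). Each cell draws its latent stage
  from its day's row.
* **Counts** are negative binomial with a single shared dispersion
  (size r = 2, variance μ + μ²/2) around `stage profile × size factor`, the
  size factor lognormal(μ=0, σ=0.25) per cell. This is the simplest model
  with the overdispersion the hurdle marker test must tolerate.
* **Gene panel** (~1,200 genes, fixed independently of the dataset seed):
  one sex marker, 10 stage markers per stage (mean 10 UMI in their own
  stage, 0.1 elsewhere; *TNNT2* at 30 so stage-V positivity is near
  certain), 300 oncogenes, 500 TSGs, 349 flat housekeeping genes. Planted
  monotone trends mirror the published tallies: 15 continuously up and 13
  continuously down oncogenes (with *MALAT1* topping out at 576.07 UMI/cell
  in stage V), 7 continuously down and 25 continuously up TSGs. Non-trend
  cancer genes get shuffled non-monotone stage multipliers so their truth
  class is unambiguously `other`. The panel size keeps the pairwise
  correlation sweep (~1.4M ordered pairs) at seconds of runtime.
* **Cell line signal** — line-1 cells draw *RPS4Y1* as 1 + NB (always
  detected), line-2 cells are exactly 0, so line assignment has an exact
  truth. The same shifted-draw convention marks planted MYC-high cells
  (mean 30) and the TP53-*expressing* complement (mean 2) of the
  co-occurrence plant; TP53 *silencing* is a forced zero count, matching the
  reading that a silenced gene shows no UMI. Guaranteeing ≥ 1 UMI in the
  planted-on cells makes the planted fractions identifiable rather than
  confounded with NB dropout.
* **Co-occurrence plant** — each stage-V cell is MYC-high with probability
  0.149; a MYC-high cell is TP53-silent with probability 0.70. The flags are
  independent of *TNNT2* counts, so the double-positive fraction among
  TNNT2+ cells estimates 0.149 without bias.
* **Ambient droplets** draw a Poisson(10) total spread over the pooled
  expression profile (sex marker excluded). Expected ambient total ≈ 0.5% of
  the median real-cell total (~2,000 UMI), and the 1st percentile of real
  totals exceeds 10× the 99th percentile of ambient totals, so the m/10
  calling rule separates them exactly.

What the generator does **not** emulate: doublets, batch effects, ambient
contamination correlated with cell content, cell-cycle structure, per-day
depth differences, or the 20k+-gene transcriptome. Passing tests therefore
demonstrate correctness of the pipeline's rules and estimators under the
designed statistical structure, not robustness to every artifact of real
droplet data.

## Cell calling

`m` is the nearest-rank `percentile`-th (default 99th) value of the
descending-sorted top-N barcode totals; the threshold is `m/10`, and the
called set is `{total > m/10}` with strict inequality at ties. Nearest-rank
is chosen (no interpolation convention is standard here) so integer inputs
give exact, order-invariant results. `N` larger than the number of barcodes
clamps with a warning. An all-zero matrix raises "no candidate cells".

## Normalization

Each cell is scaled by `median(total)/total` after pooling the called cells
of all time points (a per-time-point switch exists in the pipeline config).
The operation is a positive per-cell scalar multiply: zero patterns and
within-cell gene ranks are preserved, and it is idempotent to floating
point. Cells with zero total raise with the offending barcodes listed.

## Staging

PCA runs on log1p of the median-normalized matrix with per-gene centering
(the log stabilizes NB variance and is the field default; M = 10 components
by default). For each candidate k (2…10), k-means runs with 10 seeded
restarts; the mean silhouette (estimated on a seeded 5,000-cell subsample
above that size) is the primary criterion and the SSE elbow (largest second
difference) breaks exact ties, then the smaller k. Clusters are ordered into
stages I, II, … by ascending mean collection-time rank (day 0 → 0 … day
10 → 3), ties by descending size — the package's replacement for pseudotime
ordering, justified by the clusters tracking collection time by
construction. Composition percentages round half-up to 2 decimals, matching
the printed-table convention.

## Marker detection

The likelihood-ratio test is a two-part (hurdle) model per (gene, stage),
stage vs rest: a binomial component on the detection fraction and a Gaussian
component on log1p-normalized expression among detected cells (separate
group means, shared variance), χ² with df = 2. When one group has no
detected cells the Gaussian part is dropped (df kept at 2; the detection
difference already carries the signal); zero within-group variance with
nonzero total variance is perfect separation (p = 0). Genes detected in
< 10% of cells in both groups are reported untested. BH adjustment spans the
full gene × stage family; only positive fold-change genes are flagged. The
two likelihood components live in one function (`hurdle_lrt`) so an NB-based
variant could be substituted without touching the scan.

## Cancer-gene trends and co-occurrence

Stage profiles are mean **raw** UMI per cell per ordered stage (UMI/cell).
A gene is `continuous_up`/`continuous_down` only when its five stage means
are strictly monotone — a tie breaks the trend, since "continuous" contrasts
with transient patterns. Tier membership is inclusive at the low bound
(any stage mean ≥ 1.00) and strict at the stage-V high tier (> 10.00); where
the two source conventions differ (">1.00" vs "≥1.00"), the inclusive form
is adopted. Positivity is raw UMI ≥ 1 — the only convention under which a
"silenced" gene is a zero count. Trend significance is a cell-level rank
trend test: Spearman correlation between per-cell expression and ordinal
stage index with the normal approximation z = ρ√(n−1); constant expression
returns p = 1 by convention. Co-occurrence restricts to one stage's cells,
counts TNNT2+/MYC+ double positives, and partitions them by TP53 positivity;
percentages round half-up to 1 decimal.

## Co-expression network

The universe is (marker genes ∪ catalog oncogenes ∪ catalog TSGs)
restricted to genes with a nonzero stage mean. Spearman ρ uses average ranks
over the five ordered stage means; constant profiles are excluded (logged)
rather than assigned ρ = 0. P-values use the t-approximation with |ρ| = 1
mapped to p = 0: an exact permutation p on five points is ≥ 1/120 and could
never survive BH at q < 0.01 over ~1.5M pairs, so the approximation is the
only convention under which the ρ > 0.99 ∧ q < 0.01 filter can retain
anything. On five untied points the attainable ρ values are spaced 0.1
apart, so retained edges are exactly the rank-concordant (ρ = 1) pairs, and
negative perfect correlations are excluded (the filter is one-sided
positive, configurable). Pair counting is reported ordered-with-self (n²,
the published convention: 1734² = 3,006,756) while tests and edges use
unordered non-self pairs; BH spans all unordered non-self pairs. Topology
(degree and shortest-path-length histograms within components) comes from
networkx on the simple undirected graph.

## Pipeline, seeding, reporting

All randomness derives from one top-level seed through
`numpy.random.SeedSequence` children (one stream per time point; the k-means
seed derives from the pipeline seed), so module-level calls and full runs
agree. `run_report.json` records thresholds, seed and SHA-256 checksums of
every output; identical config + seed reproduces identical checksums.
`--resume` reuses the (expensive) simulated dataset already present in the
run directory; downstream stages are cheap and deterministic and are always
recomputed, which leaves final checksums unchanged.

`consistency_report` recomputes the published derived quantities from
printed primary counts only, with conventions fixed to reproduce the printed
figures: percentages half-up at the printed decimal count, read depth
nearest integer, and the oncogene below-tier share truncated to a whole
percent (72.81% prints as 72%).

## Problem sizes and numerical choices

The default synthetic scale is the study scale (32,365 cells, 200k ambient
droplets, ~1,200 genes); the full pipeline runs in well under a minute on a
single CPU, and the test suite uses a scaled-down configuration
(400/250/300/250 cells) for most integration tests plus one full-scale
session fixture for the recovery checks. Silhouette subsampling (5,000
cells, seeded) bounds the O(n²) silhouette cost. Variance floors of 1e-12
guard the Gaussian LRT component; Spearman values within 1e-12 of ±1 snap
to exactly ±1 before p-value computation.

## Known limitations

* The hurdle LRT is one published reading of an under-specified "likelihood
  ratio test"; absolute marker counts depend on that choice even though the
  planted-marker recovery does not.
* Stage ordering by collection time cannot separate two sub-populations
  collected at identical times with identical time profiles.
* Dataset-level published counts (120 markers, 695 expressed oncogenes, 378
  edges, 219 network nodes) are properties of the undeposited real dataset
  and specific catalog versions; the package reproduces the rules and the
  in-paper arithmetic, not those counts.
* The published "189/695=18%" figure is arithmetically inconsistent
  (189/695 = 27.2%); the consistency report reproduces only the coherent
  (695−189)/695 = 72% companion figure.
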