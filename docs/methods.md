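# Methods

This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Normalization

Library scaling uses the trimmed mean of M-values.  For library *k*
against a reference *r*, each gene with nonzero counts in both libraries
contributes a log ratio M = log₂((y_k/N_k)/(y_r/N_r)), an average
abundance A = ½·log₂((y_k/N_k)(y_r/N_r)) and a delta-method precision
weight (N_k−y_k)/(N_k·y_k) + (N_r−y_r)/(N_r·y_r).  Genes are doubly
trimmed by rank — the most extreme 30% of M on each side and 5% of A —
and the factor is 2 to the weighted mean of the surviving M.  The
reference library is the one whose upper-quartile count fraction is
closest to the mean upper-quartile; factors are rescaled so their
geometric mean is exactly 1, making CPM comparable across runs.  The trim
fractions follow the canonical TMM formulation.  Note one subtlety the
test suite pins down: scaling a library by a constant is absorbed by its
library size *almost* exactly — the precision weights depend on depth, so
factors move at the percent level, not zero.

## Differential expression

The DE stage is a self-contained exact conditional test, not an edgeR
binding.  Counts are scaled to the geometric-mean effective library size
and summed within each contrast group; under a common per-replicate mean
the group pseudo-sums are negative binomial — NB(nμ, φ/n) for n
replicates at dispersion φ (variance convention m + φ·m²) — and the
treatment sum is tested against its conditional law given the two-group
total, with μ estimated as total/(n_A+n_B).  Two-sided p-values sum the
probability of every outcome at most as likely as the observed one.  At
φ = 0 and equal effective sizes this reduces exactly to
Binomial(total, n_A/(n_A+n_B)): 0 versus 10 counts in a 1-vs-1 design
gives p = 2·(½)¹⁰ = 0.001953125.  Totals above 10⁶ switch to a Gaussian
approximation of the conditional law (never reached at the problem sizes
used here).  Discreteness makes the test conservative; its empirical size
at nominal 0.05 is about 0.042 over 5000 null genes.

The common dispersion is a median-of-moments estimator: per gene, the
pooled within-group variance v and mean m of depth-scaled counts give
φ_g = max(0, (v−m)/m²), and φ is the median over genes with m > 0.
Because the median of a χ²-distributed variance estimate lies below its
mean, v is rescaled by df/median(χ²_df) (≈1.19 at 4 df) so the median is
approximately unbiased; without this the estimator lands near 0.33 for a
true 0.4 in a 3-vs-3 design.

Fold changes are prior-moderated log₂ ratios of group mean CPM
(prior 0.5, configurable).  BH correction is applied per contrast family
(one family per timepoint), and calls use strict inequalities:
up ⇔ log₂FC > 1.5 and q < 0.05.  A gene at exactly 1.5, or exactly
q = 0.05, is not significant.

## Secretome and KOG summaries

The secretion filter keeps called DEGs with signal-peptide score ≥ 0.5 —
the boundary is inclusive.  Genes without an annotation record count as
score 0 (with a logged warning at read time).  KOG radar counts tally
up/down events per focus category and timepoint; a gene significant at
several timepoints counts once per timepoint, and the eight default focus
categories are configurable because KOG nomenclature varies between
annotation dumps.  The heatmap matrix clips log₂FC to ±12.5 for display
but flags significance on the unclipped value.

## Consensus network

Three association measures propose edges independently: |Pearson r|,
|Spearman ρ|, and mutual information on 4 equal-frequency bins normalized
by the smaller marginal entropy (MI/min(H_i, H_j) ∈ [0, 1]).  Defaults:
r and ρ thresholds 0.70, normalized MI threshold 0.30, and an edge enters
the consensus when at least 2 of 3 measures propose it; its weight is the
mean over proposing measures and its support count is recorded.
Zero-variance genes propose no edges (a constant profile also has zero
entropy).  Requiring cross-measure agreement suppresses edges driven by a
single outlier sample or by one measure's binning artefacts — the
consensus principle of multi-algorithm network builders.  The network is
built on log₂-CPM of TMM-normalized counts by default; correlating raw
counts confounds co-expression with sequencing depth, but a `--raw` flag
preserves that literal behavior for comparison.  The threshold/support
defaults were fixed by a one-time calibration on the generator's default
conditions (they sit mid-plateau of a wide stable region) and are fully
exposed in the configuration.

## Clustering and target selection

Gene profiles (log-CPM) are z-scored per gene — clustering then groups
temporal *shapes* rather than expression magnitudes, the standard
co-expression practice — and projected onto the top 3 principal
components (column-centered SVD; each component's sign is fixed by making
its largest-magnitude loading positive).  Scores are standardized per
component so one DBSCAN radius applies to every axis.  DBSCAN is
implemented directly to guarantee a deterministic border rule: points are
processed in lexicographic gene-ID order, clusters are created in that
order, and a border point joins the first-created cluster that
density-reaches it.  Defaults eps = 0.6, min_samples = 5 (neighbors
within eps, self included).

Betweenness centrality is computed once on the full consensus network
(normalized by (n−1)(n−2)/2), and within every non-noise cluster the
most central member is the cluster's target; full-network centrality is
used because a target's interest lies in its hub-ness relative to the
whole transcriptome, not its cluster — a `subgraph=True` mode implements
the induced-subgraph alternative.  Ties, and clusters whose members all
score 0, resolve to the lexicographically smallest gene ID (the
degenerate case also logs a warning).  The max-degree gene of the whole
network is reported alongside.  With fixed inputs, configuration and
seed, the selected target list is byte-identical across reruns.

## Synthetic data

The generator emulates the two study designs at desk scale: the
time course (timepoints 6, 12, 15, 24, 36 h post inoculation ×
{treatment, control} × 3 replicates = 30 libraries) and the mutant
comparison (6 and 30 hpi; per timepoint 10 wild-type treatment, 4
wild-type control and 4 replicates of each of two mutant strains = 44
libraries).  Defaults: 300 genes, base means log-normal (median 200,
σ_log = 1), per-sample depth factors log-normal (σ_log = 0.15), NB
dispersion φ = 0.05 — a biological coefficient of variation of ~22%,
realistic for pooled replicates of a clonal fungal culture.

Planted structure:

* **Modules** (3 × 10 genes): all members share a module-specific latent
  curve over the timepoints, active under treatment only.  Curves are
  centered, mutually orthogonalized, and scaled to unit RMS — the peak is
  then ≥ 1, so with amplitude 2.8 every module crosses the DEG threshold
  at its peak timepoint by construction.  Three modules are the default
  because three orthogonal temporal directions are what a 3-component
  projection can represent without loss.
* **Bridge hubs**: each module additionally carries two per-sample
  co-regulation "state" factors (σ = 1.7 in log₂ units), one per half of
  the membership; members of the same half correlate strongly, opposite
  halves only through the shared curve.  The designated hub carries an
  equal mixture of both states, so it is the only gene strongly
  correlated with *every* member: in the network the two halves form
  cliques joined through the hub, whose betweenness advantage is
  structural rather than statistical — robust at 30 samples, where pure
  correlation-magnitude advantages drown in sampling noise.  Realized
  state vectors are orthogonalized against each other and the curve so
  finite-sample chance correlation cannot short-circuit the bridge.
* **DEGs**: 40 genes receive one (timepoint, log₂FC) effect each,
  |log₂FC| uniform in [3, 5], applied to treatment samples (or to one
  mutant strain in the mutant design).
* **Secretome**: module and DE genes are secreted by construction (they
  are what the clustering stage should see); scores are Beta-distributed
  with planted class separation strictly at the 0.5 boundary.

What the generator does **not** emulate: transcript-length effects, GC
bias, batch effects, composition bias from highly expressed genes,
gene-gene correlation outside planted modules, and realistic KOG
category frequencies (categories are assigned uniformly).  Passing
recovery tests therefore demonstrates that the pipeline's logic is
correct under its own model assumptions — not that the thresholds are
optimal for any particular real dataset.

## Problem sizes and determinism

Default analyses run at 300 genes × 30 samples; recovery experiments use
50 seeded replicates (planted-hub recall ≈ 0.97–0.99, planted-DEG recall
≈ 1.0 under default conditions), dispersion recovery uses 2000 genes, and
the null-size experiment 5000 genes — sizes chosen so the whole suite
runs in about a minute on one CPU while keeping Monte-Carlo noise well
inside the acceptance margins.  Every stochastic component takes a single
integer seed through `numpy.random.default_rng`; all tie-breaks
(clusters, targets, hubs, edge ordering) are lexicographic on gene IDs as
text, so results are independent of dict ordering, locale and BLAS
backend.

## Known limitations

* The exact test conditions on an estimated μ for φ > 0 (the conditional
  law is not parameter-free as in the Poisson case); this is the same
  approximation spirit as quantile-adjusted conditional testing, and
  directional agreement on strong effects — not numeric identity with
  edgeR — is the design contract.
* Pseudo-sums are rounded to integers before the conditional test;
  at very shallow depths this rounding can matter.
* The consensus scheme is a documented emulation of multi-algorithm
  network builders, not a reimplementation of any specific tool.
* Betweenness on near-clique clusters is flat; singleton-DEG clusters
  routinely select their lexicographically smallest member (warned).
  This mirrors the method's real behavior: betweenness only discriminates
  where the graph has bridge structure.
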