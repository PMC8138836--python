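# Methods

This note documents the models and procedures implemented in `sigmatch`,
the assumptions behind them, the defaults and why they were chosen, and
what the tests do and do not establish.

## 1. The effect cube

An *instance* is one treatment experiment, keyed by the 4-tuple
(drug, cell line, concentration, platform); concentrations are kept as
strings so keys survive text round-trips exactly. From per-instance
treated and control replicate matrices of log2 expression, `build_cube`
derives, per gene:

- `logfc` — difference of replicate means, i.e. the log2 ratio of treated
  over control expression. Log base is 2 throughout (microarray
  convention); "raw" values are `2^x` of the log2 values.
- `t`, `p`, `df` — Welch (unequal-variance) two-sample t-test of treated
  vs control, defined only when both sides have ≥ 2 replicates. Welch was
  chosen over the pooled test because replicate counts and variances of
  treated and control cultures have no reason to match.
- `z` — `logfc / sqrt(var_t/n_t + var_c/n_c)`, the standardized change.
  With this definition z is numerically the Welch t statistic; it is kept
  as its own layer because the container contract lists both, and because
  alternative z definitions (e.g. against a global variance model) could
  replace it without touching consumers.
- `variance` — pooled replicate variance across both sides (single-side
  variance when only one side has ≥ 2 replicates).
- `n_case`, `n_control` — replicate counts, always defined.

Missing statistics are NaN, never zero. If both sides have ≥ 2 replicates
but identical values (zero standard error), t/z/df are set missing rather
than ±inf: no variance estimate, no evidence scale.

Feature-vector representations derived per instance: `fc` (logfc),
`fc_times_abs` (logfc × log2 abundance; an implicit weight towards
expressed genes), `fc_div_abs` (logfc / abundance, relative change;
genes with |abundance| < 1e−6 are *dropped*, not clamped — a guarded
division would silently manufacture huge values), `raw_diff`
(`2^treated − 2^control`, de-logged difference) and `z`. The abundance
source (control or treated) is selectable; control is the default since
the baseline expression of the untreated culture is the natural
reference. Genes with any missing required layer are dropped and the
drop count is reported on the vector.

### Cube file layout

One HDF5 file: root attributes `format="sigmatch-cube"`, `version=1`;
datasets `genes` (UTF-8 strings), `instances/{drug_id,cell_line,
concentration,platform}` (parallel string arrays), and
`layers/<name>` — float64 genes × instances matrices for
`logfc, abund_control, abund_treated, variance, z, p, t, df` (NaN =
missing) and int64 for `n_case, n_control`. Any HDF5 reader can open it.

## 2. Scoring functions

All scores operate on the gene-intersection of two feature vectors.
Polarity is metadata: L1/L2/L∞ and the KS statistic are distances
(smaller = more similar), everything else a similarity. Distances are
not negated at computation time; ranking consumes the polarity, keeping
raw values interpretable.

- **Lp norms**: Σ|xi−yi|, √Σ(xi−yi)², max|xi−yi|. The maximum norm is
  implemented as the Chebyshev distance max|x−y| (the self-evident
  reading of a "maximum norm" on a difference).
- **Pearson / Spearman / cosine**: standard; Spearman uses mid-ranks for
  ties. Cosine accepts a `center` flag; mean-centered cosine is
  algebraically Pearson, an identity the tests exercise end-to-end on
  candidate rankings.
- **Biweight midcorrelation**: u = (v − median)/(9·MAD), weights
  (1−u²)² for |u| < 1 else 0; correlation of the weighted, median-centred
  values. MAD = 0 makes the score missing.
- **Gini correlation**: cov(x, rank(y)) / cov(x, rank(x)) and its mirror
  form with roles swapped. The two asymmetric forms differ in general;
  both are exposed (`form="xy" | "yx"`), default is their mean — a
  symmetric compromise chosen because the benchmark's symmetry
  expectations (and the random-baseline construction) assume symmetric
  scorers.
- **Kolmogorov–Smirnov**: two-sample D between the two value
  *distributions*; gene pairing is deliberately ignored (the score asks
  only whether the magnitudes of change are distributed alike, like
  comparing Q-Q plots).
- **Set overlaps**: a gene is "changed" when |value| exceeds a threshold
  (default 0.5 log2 units, i.e. a 1.4-fold change; configurable). The
  matched set is the intersection, optionally constrained to same- or
  opposite-direction changes. Jaccard divides by the union size and is
  *missing* when no gene passes the threshold anywhere — the classic
  division-by-zero failure of thresholded signatures, handled as a
  logged missing score that ranks last. SameGenes/SameDir are the
  unnormalised counts.
- **Kraskov k-NN mutual information** (KSG algorithm 1): joint max-norm
  k-th-neighbour distance ε_i; counts of points strictly inside the
  marginal ε_i-intervals; MI = ψ(k) + ψ(N) − ⟨ψ(nx+1) + ψ(ny+1)⟩, in
  nats. Default k = 6; small negative estimates are clipped to 0.
  Assumes continuous marginals (no tie-breaking noise is added, keeping
  the score deterministic).
- **MINE statistics** (MIC, MEV, GMIC): characteristic-matrix grid
  search with B(n) = max(⌊n^0.6⌋, 4) and clump factor c = 15. One axis
  is equipartitioned, the other optimised by dynamic programming over
  clump boundaries capped at c·nx superclumps; both orientations are
  evaluated and the better kept per cell; entries are normalised by
  log2 min(nx, ny). MIC is the maximum entry; MEV the maximum over
  one-dimensional grids (nx = 2 or ny = 2); GMIC the generalized power
  mean with exponent p = −1 of the cumulative maxima of the matrix over
  the admissible region {nx, ny ≥ 2, nx·ny ≤ B} (the exact averaging
  region of the original R implementation is not printed anywhere
  accessible; this definition follows the published generalized-mean
  construction and is fixed here). Constant input returns 0 for the
  whole family. Complexity is O(B²c²) per pair — orders of magnitude
  slower than a correlation, intended for reduced gene sets.

`score_all` scores one query against every other instance (the query is
excluded: a self-hit at rank 1 would be vacuous), restricting both
vectors to the gene set selected by the filter on the *query* instance.
Query-side filtering is deliberate: it mirrors the disease-signature use
case, where the gene set comes from the query side and candidates are
scored on it. A `pairwise_union` mode exists for comparison. Pairs whose
score cannot be computed yield missing results that rank strictly after
all finite scores, in stable input order.

## 3. Gene filters

- **Top-n filters** on abundance, |logfc|, |z| or p-value (ascending).
  Ties break by ascending gene id, so output is independent of memory
  layout or hash order; missing criterion values are excluded. Top-n
  sets are nested by construction.
- **Landmark filter**: static membership in a fixed gene list, cube
  order preserved; instance-independent by definition — the point of a
  landmark set is that it is *not* adapted to the individual experiment.
- **Focus filter** (network-driven reduction): a gene is kept iff
  |logfc| ≥ fc-threshold, OR |abundance change| ≥ expression-threshold,
  OR it touches an edge whose link score passes the link threshold.
  The abundance change is measured on the raw scale
  (`2^treated − 2^control`) so it is genuinely distinct from logfc.
  The default link score of edge (a,b) is |logfc_a + logfc_b| (joint
  displacement; coordinated changes of interacting genes score high),
  with |logfc_a · logfc_b| behind a switch. Thresholds use ≥ so
  zero thresholds keep everything.
- **Focus tuner**: one scale factor applied to all three thresholds,
  each expressed as scale × max|statistic|, so scale 0 keeps all genes
  and scale > 1 none, and the kept count is non-increasing in the scale.
  Bisection (≤ 60 iterations) returns the thresholds whose kept count is
  nearest the target; plateaus from ties produce a warning with the
  nearest achievable count rather than an error.

Network files: STRING dialect (`combined_score` integers 0–1000,
normalised by 1/1000, edges kept when strictly > 0.9) or plain dialect
(`weight` in [0, 1], all kept). Strictness at the boundary follows the
"score above 0.9" convention; a score of exactly 900 is excluded.
Networks store each undirected edge once with sorted endpoints;
self-loops and out-of-range weights are rejected.

## 4. Retrieval benchmark

Eligible queries are instances whose drug occurs in ≥ 2 instances.
Ranking defaults to the *worst-position* tie rule: every member of a
tied block gets the block's last position, which is pessimistic for the
method under test (an average rule is available). Missing scores rank
after all finite ones. Best/worst same-drug ranks per query feed
recovery curves in "any" and "all" modes; the summary table counts
recovered queries at a reference threshold (default 250, the
legend-sorting convention for curve figures) and is sorted best-first.

The candidate set deliberately spans all platforms, cell lines and
concentrations — cross-condition retrieval is the point. Synthetic
worlds can create two instances of one drug under near-identical
conditions; they count as matches.

**Random baseline.** Each repetition draws one Uniform(0,1) similarity
per *unordered* instance pair, i.e. the random scorer is symmetric like
every real scoring function in the catalogue. This matters: the two
queries of a drug pair share the score of their connecting pair, so
their best ranks are positively correlated; a per-ordered-pair random
scorer lacks that dependence and yields a band visibly narrower than
the pipeline's own null distribution. With the symmetric scorer, the
Pearson recovery curve of an effect-free synthetic cube sits inside the
100-rep band, and each query's match ranks are marginally uniform, so
P(best ≤ x) = 1 − C(N−m, x)/C(N, x) — verified empirically in the
tests. All baseline randomness flows from a named substream of the run
seed, so adding pipeline components never perturbs the draws.

## 5. Synthetic worlds

The generator states: each drug has a sparse signature (support =
round(sparsity × n_genes), effects ±|N(effect, effect/4)| log2 units);
each instance shows `baseline + scale × signature + context noise`,
with `scale ~ Uniform(0.5, 1.5)` (same mechanism, different dose/cell
line response), context noise N(0, sd) per instance, and replicate
noise N(0, sd) per replicate; controls are `baseline + replicate
noise`. Defaults: 40 drugs × 2 instances, 1000 genes, sparsity 0.05,
effect size 1.0 log2 units (a 2-fold change — a typical strong
microarray response), context and replicate SD 0.25 (technical
replicate scatter on log2 scale), 3 + 3 replicates, baseline
N(7, 2) log2 intensity. A heavy-tailed option (t with 3 df, rescaled to
the same SD) exercises scores dominated by extreme values.

What the generator does *not* emulate: probe-level effects,
batch/chip artefacts, correlated gene modules, cell-line-specific
signature rewiring (an optional perturbation flag exists but is off by
default), or realistic signature overlap between related drugs. A green
benchmark test therefore establishes that the machinery ranks, counts
and calibrates correctly — not that any score will attain its synthetic
performance on real Connectivity-Map data, where context effects are
far stronger and signatures overlap.

Networks are G(n, p) graphs with an optional hub tail (pairs touching a
hub get a boosted edge probability) and weights Uniform(0.9, 1), so
every edge survives a STRING-style cut. Landmark lists are sampled
without replacement, optionally enriched towards high mean abundance
(probability ∝ abundance rank) to mimic how landmark transcripts are
chosen among well-measured genes.

## 6. Numerical choices and degenerate inputs

- Missing values are NaN end to end; counts are exact integers.
- `fc_div_abs` drops genes with |abundance| < 1e−6 instead of clamping.
- Zero-variance vectors make correlation-type scores missing (logged),
  not zero: "no information" must not masquerade as "uncorrelated".
- All stochastic components take explicit integer seeds; the CLI routes
  one root seed to named substreams (simulation, baseline, landmarks).
- Every output file carries `# sigmatch key=value` provenance headers
  (version, config hash, seed); stripping them leaves byte-identical
  data across reruns with one seed.
- The determinism contract is exact (byte-level), not approximate:
  ranking uses stable sorts and id-based tie-breaks throughout.

## 7. Known limitations

- The MINE family and Kraskov estimator are validated against
  independently coded reimplementations of the same published
  algorithms and against distributional sanity checks (MIC = 1 for
  noiseless functions, KSG ≈ −½log(1−ρ²) for Gaussians, sklearn's KSG
  cross-check); no third-party MINE implementation was available to
  compare against, so minor normalisation differences from the original
  R packages are possible (expected ranking impact: none to small).
- `z` duplicates the Welch t under the implemented definition; consumers
  wanting a variance-moderated z (limma-style) would need a new layer.
- The null-calibration check compares one pipeline run against a
  100-rep min/max band; it is itself stochastic across world seeds and
  can fall marginally below the 95%-inside criterion for unlucky seeds.
- The focus tuner assumes the kept count is monotone in the common
  scale factor; exotic threshold combinations tuned per-criterion are
  out of scope.
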