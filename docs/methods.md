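# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `fersig` package: a pipeline that classifies bulk tumor
expression profiles into ferroptosis-associated clusters (FACs), derives
immune-activated and stromal-activated ferroptosis signatures, composes the
Fersig prognostic score, and projects the bulk classification onto single
cells.

## Data model

All bulk expression is assumed to be on a non-negative log scale
(log2(x+1) of counts or array intensities).  The pipeline never transforms
expression itself beyond an optional `log2p1` flag at load time; the scale
assumption is recorded in every output manifest.  Gene identifiers are
matched case-sensitively with no alias resolution — alias maps are
database-versioned and out of scope.  Duplicate gene rows are collapsed to
the row with the larger mean, the common probe-collapse heuristic.

## Consensus NMF subtyping

Factorization is the classic Brunet variant: multiplicative updates
minimizing the generalized Kullback–Leibler divergence D(X‖WH), the
standard choice for expression subtyping.  Defaults: `max_iter=2000`,
relative objective tolerance `1e-6`; the objective trace is recorded every
iteration and its monotone decrease can be asserted in debug mode.  After
convergence W columns are rescaled to sum to one (H absorbs the magnitude)
so that hard assignment by the dominant metagene is comparable across
restarts.

Two preprocessing rules precede consensus clustering.  Genes with zero sum
or zero variance are dropped (they carry no factorizable signal and the
multiplicative updates are undefined on all-zero rows).  Each gene's
minimum across samples is then subtracted (`row_shift`): log expression
carries a large shared per-gene baseline which otherwise absorbs most of
the divergence into a single flat factor and blurs the between-sample
structure the subtyping is after.  The shift keeps the matrix non-negative
and is invertible bookkeeping, not a normalization of the data the rest of
the pipeline sees.

Consensus clustering runs `n_runs=30` restarts per candidate rank (seeds
`seed + run`).  Restarts alternate between two initializations: uniform
draws scaled to the matrix mean, and a random-partition start in which H is
seeded with a random hard assignment of samples to components.  The mixture
matters: with uniform-only starts on well-separated data, every restart at
every rank falls into the same basin, the consensus matrix is trivially
0/1, and the rank survey is uninformative (a rank-2 merge of three true
clusters looks exactly as "stable" as the true rank).  Partition starts
sample the basin structure — at the true rank they converge to the planted
blocks, at a wrong rank they scatter across the competing merges or splits
— so the cophenetic coefficient genuinely discriminates ranks.

Rank selection maximizes the cophenetic correlation between the
consensus-derived distances (1 − C, condensed) and the cophenetic distances
of their average-linkage dendrogram; ties break toward the smaller rank.
Final labels cut the same dendrogram into exactly k groups by merge order
(deterministic under tied heights) and are renamed 1..k by descending
cluster size, so cluster 1 is always the largest.

## Signature scoring

**ssGSEA.**  Per sample, genes are ranked by expression (average ranks on
ties).  Walking the list in descending order, the score is the sum over all
positions of the difference between the weighted in-set ECDF (weights =
rank^α) and the uniform out-of-set ECDF.  Defaults α = 0.25 and
range-normalization of the whole score matrix by max − min, the dominant
convention.  The statistic depends only on ranks, hence is invariant to any
strictly monotone per-sample transform; the test suite checks exact
agreement with a brute-force running-sum enumeration.

**Module scores** (single-cell).  Genes are placed into `n_bins=24`
equal-occupancy bins by mean expression; for each signature gene,
`n_ctrl=100` control genes are drawn from its bin (without replacement when
possible, signature genes excluded from the pool), and the score is the
mean signature expression minus the mean control expression per cell.  The
control draw is seeded; the same seed is used for every signature in a
comparison so identical signatures receive identical scores and argmax ties
are real ties.  Sparse counts are log-normalized (log1p of counts per
10,000) before scoring.

**PC1 signature score.**  The gene-set submatrix is centered per gene (no
variance scaling) and projected on the leading right singular vector.  The
eigensolver's sign is arbitrary, so the score is oriented to correlate
positively with the mean expression of the set: a higher score always means
higher set expression.  Without this rule the sign of the Fersig score
would be arbitrary.  Loadings, centers and the orientation are stored so a
trained score can be applied to new cohorts without refitting.

## Differential expression and derived signatures

One-vs-rest contrasts per cluster use the Wilcoxon rank-sum test (normal
approximation with tie correction; Welch's t is available).  Fold changes
are reported on the natural-log scale — the matrices are log2, so lnFC =
Δ(mean log2) × ln 2 — matching the single-cell marker-tool convention the
thresholds come from: |lnFC| ≥ 0.25 for signature genes, ≥ 0.5 for the
marker sets used in bulk-to-cell mapping, both at BH q < 0.05.  The
moderated linear model used for bulk arrays in the original analyses is not
reproduced; a rank test is distribution-robust and keeps the dependency
surface small.

The immune-activated signature is the intersection of the immune cluster's
upregulated DEGs with the ferroptosis gene list; the stromal-activated
signature is derived identically from the stromal cluster.  Which cluster
is "immune" or "stromal" is decided automatically as the cluster with the
highest mean ssGSEA score of user-supplied immune / stromal reference
signatures (overridable in the parameters).

The phenotype-related DEG set defaults to the **union** of the three
one-vs-rest significant gene lists.  The three-way intersection is
available, but it is structurally biased against small clusters: a cluster
holding ~15% of samples dilutes its genes' fold change in the other two
contrasts to about 0.15·ln-units × (1/0.85) ≈ 0.17, below the 0.25
threshold, so no small-cluster gene can pass all three contrasts and the
stromal block would vanish from the signature.

Phenotype DEGs are filtered by univariate Cox regression on expression
(keep Wald p < 0.05), and the retained genes drive a second consensus NMF
that groups *patients* into three gene-clusters.  Independently, the DEGs
themselves are partitioned into groups A/B/C by average-linkage clustering
on correlation distance (1 − Pearson r across samples), cut into three; the
group whose mean expression correlates best with the stromal-activated
ssGSEA score is labeled A, the best immune tracker B, the remainder C.
Labeling by correlation, rather than ontology enrichment, keeps the
pipeline reproducible without curated term databases.

## The Fersig score

For the stromal-related genes (A) and immune-related genes (B) the PC1
signature scores are computed, each score gets a univariate Cox coefficient
on the training cohort, and the composition is

    Fersig = Σ PC1_i − Σ PC1_j

where class i collects signatures with β ≥ 0 and class j those with β < 0
(β exactly 0 goes to i; the boundary convention is logged).  Patients are
split at the median (ties to "low").  Stored loadings, orientations and
sign classes let the trained score be applied to cohorts without survival
data; applying to the training cohort reproduces the training scores
exactly.

A consequence worth knowing: when a signature has no real survival effect
(e.g. the immune axis in a cohort where only the stromal program carries
hazard), its Cox coefficient is noise around zero and its sign class is
effectively random.  The composition is still formula-faithful, but the
orientation of the composed score with respect to that axis is then
arbitrary.  The score's validity checks therefore run on the designed
validation cohort where both axes carry hazard of known sign
(β_stromal = 0.8, β_immune = −0.5).

## Survival statistics

Cox fits use the Efron approximation for ties (better than Breslow under
day-granularity data), Newton–Raphson to a step tolerance of 1e-9,
step-halving on likelihood decrease, and flag (rather than fail on)
monotone likelihoods.  Kaplan–Meier curves mark censoring times; optional
day-truncation is display-level only — tests run on full follow-up unless
explicitly truncated.  The k-group log-rank test uses the standard
observed-minus-expected statistic with hypergeometric variance.

## Tumor mutation burden

TMB is the raw count of non-silent mutation records per sample (the
non-silent vocabulary covers missense, nonsense, frameshifts, splice-site,
in-frame indels, translation-start and nonstop changes); an optional
per-megabase mode divides by a configurable capture size (default 38 Mb).
No significantly-mutated-gene discovery is attempted.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes, with ground
truth returned for recovery tests.  Defaults (the reference conditions):

* **Bulk**: 300 tumors × 2,000 genes.  Three latent programs (canonical /
  immune / stromal), 60 genes each, cluster mixing 50/35/15%.  Expression =
  per-gene Uniform(2,8) baseline + δ·(program indicator) + N(0,σ), clipped
  at zero, with δ = 1.0 log2-units and σ = 0.5 (δ/σ = 2).  An optional
  `activity_sd` blurs the indicator for soft-cluster scenarios; the default
  is 0 (crisp cluster membership).  Immune-cell marker blocks (T/B/myeloid)
  co-vary with the immune program and a stromal-cell marker block with the
  stromal program, emulating microenvironment infiltration visible in bulk.
* **Ferroptosis list**: 150 genes tagged driver/suppressor/marker
  (47/40/63, proportioned like the curated databases), 20 embedded in each
  program — a symmetric overlap, making the three clusters pairwise
  equidistant in the clustered feature space — and 90 outside any program.
* **Survival**: exponential with rate λ0·exp(β_cluster), λ0 = 1/1500
  events/day, default β = (0, 0, 0.8) so the stromal cluster has the worst
  outcome; uniform administrative censoring on [0, 6000] days (~25%
  censoring).  Exponential rather than Weibull keeps closed-form checks.
* **Clinical categories**: stage sampled with cluster-skewed probabilities
  (stage IV: 16% in the stromal cluster vs 4–8% elsewhere); MSI-high
  enriched in the immune cluster (40% vs ~10%).
* **Mutations**: Bernoulli per (sample, gene) over 120 mutation genes at
  rate 0.02, doubled in the immune cluster.
* **Single cell**: 2,000 cells × the same gene universe; five cell types
  (epithelial 40%, T 20%, myeloid 15%, stromal 15%, B 10%) with 40-gene
  marker blocks elevated 4-fold; negative-binomial counts (dispersion 2,
  log-normal library-size factors).  Epithelial cells split evenly between
  canonical-program and immune-program states; stromal cells over-express
  the stromal program (hence the stromal ferroptosis genes).
* **ICB cohort**: 150 patients with continuous N(0,1) program activities;
  response ~ Bernoulli(sigmoid(γ·(immune − stromal))) with γ = 2; the
  hazard of responders is multiplied by exp(−0.8).

Each output block (expression / survival / mutations / single cell / ICB)
draws from its own RNG stream spawned from the master seed, so generating
one block never perturbs another, and a fixed seed reproduces cohorts
bit-exactly.

What the generator does **not** model: single-cell dropout and ambient RNA,
batch effects, copy-number structure, overlapping or correlated programs,
and gene–gene correlation beyond the shared program factors.  Passing the
recovery tests therefore shows the pipeline is correct under its stated
assumptions, not that it is robust to the full messiness of real cohorts.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the reference conditions at
sizes chosen for quick iteration: the rank-recovery check uses 10 cohort
draws at the default 30 restarts; Fersig survival separation and ICB
stratification use 20 draws each; determinism is exercised on a reduced
cohort (100–120 samples, 800 genes).  Thresholds are never relaxed when
sizes are scaled.  The acceptance script executes one full pipeline run at
the default conditions plus a 400-sample validation cohort for the Fersig
checks.

## Known limitations

* The consensus rank survey discriminates ranks through restart diversity;
  on data where every rank is genuinely stable under both initializations
  the argmax rule still defaults to the smallest such rank.
* The one-vs-rest DE is unmoderated; very small clusters (< ~10 samples)
  will be underpowered compared to shrinkage-based methods.
* `prognostic_filter` fits one Cox model per gene serially; for much larger
  gene sets than the pipeline produces (~10^4) it would need batching.
* Median splits are cohort-relative: applying a trained Fersig score to a
  new cohort re-splits at that cohort's median, as in the original design.
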