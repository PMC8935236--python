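# fersig

Ferroptosis-associated molecular classification of colorectal tumors and
the Fersig prognostic score.

## What this is

Colorectal tumors differ sharply in how their microenvironment is
organized: some are immune-inflamed, some immune-deserted, and some
immune-excluded, with immune cells trapped in the surrounding stroma.
Ferroptosis — iron- and lipid-peroxidation-dependent cell death — is wired
into this organization: the expression of ferroptosis driver, suppressor
and marker genes co-varies with immune and stromal activity and with
outcome.  This package implements, as a tested and reusable pipeline, the
analysis that exploits that link:

1. **Subtyping** — consensus non-negative matrix factorization (Brunet
   KL-divergence NMF, random restarts) of bulk expression restricted to a
   ferroptosis gene list; the number of clusters is chosen by the
   cophenetic coefficient of the consensus matrix.
2. **Microenvironment scoring** — single-sample GSEA (ssGSEA) of arbitrary
   signatures per tumor, used both to characterize clusters and to identify
   the immune-inflamed and stromal-activated clusters automatically.
3. **Signature derivation** — one-vs-rest differential expression
   (natural-log fold-change thresholds 0.25 / 0.5, BH q < 0.05);
   intersection of cluster-upregulated genes with the ferroptosis list
   yields the immune-activated and stromal-activated signatures; the
   pooled phenotype-related DEGs are Cox-filtered and partitioned into
   stromal-related (A), immune-related (B) and other (C) gene groups.
4. **The Fersig score** — per-sample first-principal-component scores of
   gene groups A and B, composed by the sign of their univariate Cox
   coefficients:

       Fersig = Σ PC1_i − Σ PC1_j ,

   where i indexes signatures with Cox β ≥ 0 and j those with β < 0.  A
   high score marks a stromal-dominant, poor-prognosis, immunotherapy-
   refractory phenotype; patients are stratified at the median.
5. **Single-cell projection** — bulk cluster marker sets score individual
   tumor cells via binned-control module scores; each cell is assigned to
   the best-scoring subtype.

Because the original cohorts (TCGA, GEO, FerrDb, melanoma immunotherapy
trials) cannot be bundled, the package ships a first-class synthetic cohort
generator that reproduces the statistical structure the analysis assumes —
three latent transcriptional programs, a ferroptosis list straddling the
immune and stromal programs, stromal-driven hazard, immune-cluster
hypermutation, and a five-cell-type single-cell compartment — with ground
truth returned for recovery testing.  It is intended for computational
biologists who want to run this classification on their own cohorts or to
study the method's behavior under controlled conditions.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic cohorts (each accepts `--seed`, default 1):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_consensus_subtyping.py
python analysis/03_signatures_and_fersig.py
python analysis/04_single_cell_mapping.py
python analysis/05_icb_stratification.py
```

`02_consensus_subtyping.py` prints the rank survey and cluster recovery:

```
rank survey (cophenetic coefficient per rank):
      cophenetic  dispersion
rank
2         0.9961      0.9534
3         1.0000      0.9981
4         0.9958      0.8097
5         0.9955      0.7769
selected rank: 3
cluster sizes: {1: 140, 2: 115, 3: 45}
agreement with planted clusters: ARI = 1.000
survival differs across clusters: log-rank chi2=14.24 (df=2), p=0.00081
```

The cophenetic coefficient peaks at rank 3 (the planted number of
programs), the three clusters are recovered exactly (adjusted Rand index
1.0), and survival separates across them — the planted stromal cluster
(cluster 3, hazard ratio e^0.8) drives the log-rank signal.

`03_signatures_and_fersig.py` then derives the signatures and the score:

```
immune-inflamed cluster: 2; stromal-activated cluster: 3
immune-activated signature: 20 genes
stromal-activated signature: 20 genes
phenotype-related DEGs: 340; prognostic subset: 75
gene groups: {'A': 100, 'B': 180, 'C': 60}
  stromal_related: Cox beta=+0.064 (p=0.0002) -> class i
  immune_related: Cox beta=+0.003 (p=0.74) -> class i
corr(Fersig, planted stromal-immune activity) = -0.480
high vs low Fersig survival: log-rank chi2=4.89, p=0.027
```

Both activated signatures recover exactly the 20 ferroptosis genes planted
in each program, and the A/B/C grouping reproduces the planted partition
(100 stromal-related = 60 program genes + 40 stromal-cell markers, and so
on).  The stromal PC1 carries a positive Cox coefficient, so it enters the
i class and a high Fersig marks poor prognosis.  Note the immune
signature's coefficient: under the default design the immune program has no
survival effect (β_immune = 0), so its sign class — and hence the composed
score's orientation with respect to the immune axis — is noise (here both
signatures land in class i and the correlation with the stromal-minus-
immune axis is weak).  The correlation readout is only meaningful on a
validation design where both axes carry hazard of known sign, which is
what the acceptance checks use (see `docs/methods.md`).

`04_single_cell_mapping.py` and `05_icb_stratification.py` close the loop:

```
epithelial mapping accuracy vs planted programs: 99.2%
response rate by Fersig group:
high    28.0%
low     82.7%
```

Tumor cells carrying the canonical or immune program are assigned to the
matching bulk cluster with 99% accuracy, and in the simulated checkpoint-
blockade cohort the low-Fersig half responds about three times as often as
the high-Fersig half — the direction the score is built to predict.

## Layout

```
src/fersig/        the library: io, simulate, nmf, scoring, destats,
                   survival, pipeline
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    models, parameters, design choices, limitations
```
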