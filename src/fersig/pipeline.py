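"""End-to-end orchestration of the ferroptosis classification analysis.

The stages mirror the study design: consensus-NMF subtyping of tumors on the
ferroptosis gene list, identification of the immune-inflamed and
stromal-activated clusters from reference microenvironment signatures,
derivation of the immune-activated and stromal-activated ferroptosis
signatures from one-vs-rest differential expression, a phenotype-related DEG
signature with prognostic filtering and gene grouping, the PCA-based Fersig
score composed by Cox-coefficient sign, survival/clinical stratification,
and projection of the bulk subtypes onto single cells via binned-control
module scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cut_tree
from scipy.spatial.distance import squareform

from . import nmf
from .destats import DEResult, chi_square_test, cluster_markers, compute_tmb, \
    rank_location_test
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, \
    MutationTable, SingleCellMatrix, write_results
from .scoring import Pc1Score, ScoreMatrix, module_scores, pca_signature_score, \
    ssgsea_scores
from .survival import CoxFit, MedianSplit, cox_univariate, km_estimate, \
    logrank_test, median_split

__all__ = [
    "PipelineParams",
    "SignatureBundle",
    "FersigResult",
    "CellAssignment",
    "derive_activated_signatures",
    "phenotype_related_degs",
    "prognostic_filter",
    "group_signature_genes",
    "compute_fersig",
    "apply_fersig",
    "map_clusters_to_cells",
    "stratify_and_contrast",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable threshold of the pipeline, with its default."""

    ranks: tuple[int, ...] = (2, 3, 4, 5)
    n_runs: int = 30
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    gene_cluster_rank: int = 3
    de_min_lnfc: float = 0.25       # natural-log threshold for signature genes
    de_alpha_q: float = 0.05
    mapping_min_lnfc: float = 0.5   # natural-log threshold for mapping genes
    de_test: str = "wilcoxon"
    alpha_p: float = 0.05           # prognostic-filter Wald p cut-off
    overlap_mode: str = "union"
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    n_bins: int = 24
    n_ctrl: int = 100
    truncate_days: float | None = None
    immune_cluster: int | None = None   # override automatic identification
    stromal_cluster: int | None = None
    seed: int = 0

    def with_(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)


@dataclass
class SignatureBundle:
    """Gene sets derived along the pipeline."""

    ferroptosis: GeneSetCollection
    immune_cluster: int | None = None
    stromal_cluster: int | None = None
    immune_activated: list[str] = field(default_factory=list)
    stromal_activated: list[str] = field(default_factory=list)
    phenotype_degs: list[str] = field(default_factory=list)
    gene_groups: dict[str, list[str]] = field(default_factory=dict)
    fac_markers: dict[int, list[str]] = field(default_factory=dict)

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name, members in self.ferroptosis.sets.items():
            role = self.ferroptosis.roles.get(name, "other")
            counts[role] = counts.get(role, 0) + len(members)
        return counts


@dataclass
class FersigResult:
    """Per-sample Fersig score with everything needed to re-apply it."""

    pc1: dict[str, Pc1Score]
    cox: dict[str, CoxFit]
    sign_class: dict[str, str]       # signature -> "i" (beta >= 0) or "j"
    score: pd.Series
    split: MedianSplit

    def recompute(self) -> pd.Series:
        """Fersig = sum of i-class PC1 scores minus sum of j-class scores."""
        total = pd.Series(0.0, index=self.score.index)
        for name, pc in self.pc1.items():
            total = total + (pc.scores if self.sign_class[name] == "i"
                             else -pc.scores)
        return total

    def apply(self, X: ExpressionMatrix | pd.DataFrame) -> pd.Series:
        """Score new samples with the trained loadings; no survival needed."""
        total = None
        for name, pc in self.pc1.items():
            s = pc.apply(X)
            s = s if self.sign_class[name] == "i" else -s
            total = s if total is None else total + s
        total.name = "fersig"
        return total

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"fersig": self.score,
                            "group": self.split.labels})
        for name, pc in self.pc1.items():
            out[f"pc1_{name}"] = pc.scores
        return out


@dataclass
class CellAssignment:
    scores: pd.DataFrame         # cells x marker sets
    labels: pd.Series            # assigned set name per cell
    margin: pd.Series            # top minus runner-up score
    tied: pd.Series              # True where the top score was tied


# ---------------------------------------------------------------------------
# signature derivation
# ---------------------------------------------------------------------------


def derive_activated_signatures(
    de: DEResult,
    ferro: GeneSetCollection,
    immune_cluster,
    stromal_cluster,
) -> SignatureBundle:
    """Intersect per-cluster upregulated DEGs with the ferroptosis list.

    The immune-activated signature is (genes up in the immune cluster)
    intersected with the ferroptosis genes; the stromal-activated signature
    is derived identically from the stromal cluster.
    """
    ferro_genes = set(ferro.all_genes())
    bundle = SignatureBundle(ferroptosis=ferro,
                             immune_cluster=immune_cluster,
                             stromal_cluster=stromal_cluster)
    for attr, cluster in (("immune_activated", immune_cluster),
                          ("stromal_activated", stromal_cluster)):
        up = de.markers(cluster, direction="up")
        overlap = [g for g in up if g in ferro_genes]
        if not overlap:
            warnings.warn(f"no overlap between cluster {cluster} DEGs and the "
                          "ferroptosis list; signature left empty")
        setattr(bundle, attr, overlap)
    return bundle


def phenotype_related_degs(de: DEResult, mode: str = "intersection") -> list[str]:
    """Genes significant across the one-vs-rest contrasts (any direction).

    ``intersection``: significant in every contrast; ``union``: in at least
    one.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    clusters = de.clusters()
    if len(clusters) < 2:
        raise ValueError("phenotype DEGs need contrasts for every cluster")
    lists = []
    for c in clusters:
        t = de.table
        sel = (t["cluster"] == c) & t["significant"]
        lists.append(set(t.loc[sel, "gene"]))
    merged = set.intersection(*lists) if mode == "intersection" else set.union(*lists)
    order = {g: i for i, g in enumerate(de.table["gene"].unique())}
    return sorted(merged, key=order.get)


def prognostic_filter(
    genes: list[str],
    X: ExpressionMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    alpha_p: float = 0.05,
) -> tuple[list[str], dict[str, CoxFit]]:
    """Keep genes whose expression carries univariate prognostic signal.

    One univariate Cox fit per gene on the samples with complete survival;
    genes with Wald p < ``alpha_p`` are retained along with their fits.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    surv = clinical.survival()
    common = [s for s in df.columns if s in surv.index]
    if not common:
        raise ValueError("no samples shared between expression and survival")
    surv = surv.loc[common]
    kept: list[str] = []
    fits: dict[str, CoxFit] = {}
    for g in genes:
        if g not in df.index:
            continue
        x = df.loc[g, common].to_numpy()
        if np.ptp(x) == 0:
            continue
        fit = cox_univariate(x, surv["time"].to_numpy(), surv["event"].to_numpy())
        if fit.p < alpha_p:
            kept.append(g)
            fits[g] = fit
    if not kept:
        raise ValueError(
            f"no gene passed the prognostic filter at alpha_p={alpha_p}; "
            "consider a larger alpha_p"
        )
    return kept, fits


def group_signature_genes(
    phenotype_degs: list[str],
    X: ExpressionMatrix | pd.DataFrame,
    immune_score: pd.Series,
    stromal_score: pd.Series,
) -> dict[str, list[str]]:
    """Partition the phenotype DEGs into groups A (stromal), B (immune), C.

    Genes are clustered into three groups by average-linkage hierarchical
    clustering on correlation distance (1 - Pearson r across samples).  The
    group whose mean expression best tracks the stromal-activated signature
    score becomes A, the best immune tracker becomes B, the remainder C; if
    one group wins both, it keeps the stronger correlation and the runner-up
    takes the other label.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    genes = [g for g in phenotype_degs if g in df.index]
    if len(genes) < 3:
        raise ValueError("need >= 3 phenotype DEGs to form groups")
    sub = df.loc[genes].to_numpy()
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    d = squareform(1.0 - corr, checks=False)
    d = np.clip(d, 0.0, None)
    raw = cut_tree(average(d), n_clusters=3).ravel()
    group_means = {k: df.loc[np.asarray(genes)[raw == k]].mean(axis=0)
                   for k in range(3)}
    r_stromal = {k: _corr(group_means[k], stromal_score) for k in range(3)}
    r_immune = {k: _corr(group_means[k], immune_score) for k in range(3)}
    a = max(range(3), key=lambda k: r_stromal[k])
    b = max(range(3), key=lambda k: r_immune[k])
    if a == b:
        if r_stromal[a] >= r_immune[b]:
            b = max((k for k in range(3) if k != a), key=lambda k: r_immune[k])
        else:
            a = max((k for k in range(3) if k != b), key=lambda k: r_stromal[k])
    c = next(k for k in range(3) if k not in (a, b))
    arr = np.asarray(genes)
    return {
        "A": arr[raw == a].tolist(),
        "B": arr[raw == b].tolist(),
        "C": arr[raw == c].tolist(),
    }


def _corr(a: pd.Series, b: pd.Series) -> float:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("-inf")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Fersig score
# ---------------------------------------------------------------------------


def compute_fersig(
    X: ExpressionMatrix | pd.DataFrame,
    genes_a: list[str],
    genes_b: list[str],
    clinical: ClinicalTable,
) -> FersigResult:
    """PC1 scores for the stromal-related (A) and immune-related (B) genes,
    composed into the Fersig score by the sign of their Cox coefficients.

    Each signature contributes its PC1 score; signatures whose univariate
    Cox coefficient is >= 0 enter the positive sum (class i), the rest the
    negative sum (class j): Fersig = sum(PC1_i) - sum(PC1_j).  Samples are
    median-split into high/low Fersig groups.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    surv = clinical.survival()
    common = [s for s in df.columns if s in surv.index]
    if not common:
        raise ValueError("training the Fersig score requires survival data")
    surv = surv.loc[common]
    pc1: dict[str, Pc1Score] = {}
    cox: dict[str, CoxFit] = {}
    sign_class: dict[str, str] = {}
    for name, genes in (("stromal_related", genes_a), ("immune_related", genes_b)):
        pc = pca_signature_score(df, genes)
        fit = cox_univariate(pc.scores.loc[common].to_numpy(),
                             surv["time"].to_numpy(), surv["event"].to_numpy())
        pc1[name] = pc
        cox[name] = fit
        sign_class[name] = "i" if fit.beta >= 0 else "j"
    if len(set(sign_class.values())) == 1:
        warnings.warn("both signatures fall in the same Cox-sign class "
                      f"({set(sign_class.values()).pop()!r}); the composition "
                      "formula still applies")
    score = pd.Series(0.0, index=df.columns, name="fersig")
    for name, pc in pc1.items():
        score = score + (pc.scores if sign_class[name] == "i" else -pc.scores)
    score.name = "fersig"
    return FersigResult(pc1=pc1, cox=cox, sign_class=sign_class,
                        score=score, split=median_split(score))


def apply_fersig(result: FersigResult, X: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Project a trained Fersig score onto a new cohort (no survival needed)."""
    return result.apply(X)


# ---------------------------------------------------------------------------
# single-cell mapping
# ---------------------------------------------------------------------------


def map_clusters_to_cells(
    sc: SingleCellMatrix | pd.DataFrame,
    marker_sets: dict[str, list[str]] | dict[int, list[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellAssignment:
    """Assign each cell to the bulk cluster with the highest module score.

    One binned-control module score per marker set per cell; the label is
    the argmax, ties go to the first set (declaration order) and are
    flagged; the margin between the top two scores is reported.
    """
    df = sc.log_normalized() if isinstance(sc, SingleCellMatrix) else sc
    if not marker_sets:
        raise ValueError("no marker sets provided")
    cols = {}
    for name, genes in marker_sets.items():
        overlap = [g for g in genes if g in df.index]
        if not overlap:
            raise ValueError(f"marker set {name!r} has no overlap with the cells")
        # same seed for every set: identical marker sets score identically,
        # so the declared tie rule is exercised rather than masked by the
        # control draw
        cols[name] = module_scores(df, overlap, n_bins=n_bins, n_ctrl=n_ctrl,
                                   seed=seed)
    scores = pd.DataFrame(cols)
    arr = scores.to_numpy()
    top = np.argmax(arr, axis=1)
    sorted_desc = np.sort(arr, axis=1)[:, ::-1]
    margin = sorted_desc[:, 0] - sorted_desc[:, 1] if arr.shape[1] > 1 \
        else np.full(len(arr), np.inf)
    tied = np.isclose(margin, 0.0)
    names = list(scores.columns)
    labels = pd.Series([names[i] for i in top], index=scores.index, name="fac_like")
    return CellAssignment(
        scores=scores,
        labels=labels,
        margin=pd.Series(margin, index=scores.index, name="margin"),
        tied=pd.Series(tied, index=scores.index, name="tied"),
    )


# ---------------------------------------------------------------------------
# stratified contrasts
# ---------------------------------------------------------------------------


def stratify_and_contrast(
    groups: pd.Series,
    clinical: ClinicalTable | None = None,
    scores: ScoreMatrix | pd.DataFrame | None = None,
    tmb: pd.Series | None = None,
) -> dict:
    """Compare groups on survival, categorical and continuous variables.

    Continuous variables get a Wilcoxon (2 groups) or Kruskal-Wallis test,
    categorical ones a Pearson chi-square on the contingency table, and
    survival a log-rank test; a response-rate table is added when the
    clinical table carries a ``response`` column.
    """
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("every group must be non-empty and >= 2 groups required")
    report: dict = {"group_sizes": counts.to_dict()}

    continuous: dict[str, pd.Series] = {}
    if scores is not None:
        mat = scores.scores if isinstance(scores, ScoreMatrix) else scores
        for name in mat.index:
            continuous[name] = mat.loc[name]
    if tmb is not None:
        continuous["tmb"] = tmb
    rows = []
    for name, vals in continuous.items():
        joined = pd.concat([vals, groups], axis=1, join="inner").dropna()
        arrays = [joined.iloc[:, 0][joined.iloc[:, 1] == g].to_numpy()
                  for g in counts.index]
        stat, p = rank_location_test(arrays)
        rows.append((name, stat, p))
    if rows:
        report["continuous"] = pd.DataFrame(rows, columns=["variable", "stat", "p"])

    if clinical is not None:
        tab = clinical.table.set_index("sample_id")
        cat_rows = []
        for col in tab.columns:
            if col in ("time", "event", "missing_survival", "response"):
                continue
            if not (tab[col].dtype == object or isinstance(
                    tab[col].dtype, pd.CategoricalDtype)):
                continue
            joined = pd.concat([tab[col], groups], axis=1, join="inner").dropna()
            ct = pd.crosstab(joined.iloc[:, 0], joined.iloc[:, 1])
            if ct.shape[0] < 2 or ct.shape[1] < 2:
                continue
            stat, dof, p, _ = chi_square_test(ct.to_numpy())
            cat_rows.append((col, stat, dof, p))
        if cat_rows:
            report["categorical"] = pd.DataFrame(
                cat_rows, columns=["variable", "stat", "df", "p"])

        surv = clinical.survival()
        joined = pd.concat([surv[["time", "event"]], groups], axis=1,
                           join="inner").dropna()
        if len(joined) and joined.iloc[:, 2].nunique() >= 2 and \
                joined["event"].sum() > 0:
            stat, dof, p = logrank_test(joined["time"], joined["event"],
                                        joined.iloc[:, 2])
            report["logrank"] = {"stat": stat, "df": dof, "p": p}
            curves = {}
            for g in counts.index:
                sub = joined[joined.iloc[:, 2] == g]
                if len(sub):
                    curves[g] = km_estimate(sub["time"], sub["event"]).table()
            report["km_curves"] = curves

        if "response" in tab.columns:
            joined = pd.concat([tab["response"], groups], axis=1,
                               join="inner").dropna()
            rr = joined.groupby(joined.columns[1], observed=True)[
                joined.columns[0]].agg(["mean", "size"])
            rr.columns = ["response_rate", "n"]
            report["response_rates"] = rr
    return report


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------


def _identify_clusters(
    labels: pd.Series,
    immune_score: pd.Series,
    stromal_score: pd.Series,
    params: PipelineParams,
) -> tuple[int, int]:
    """Clusters with the highest mean immune / stromal reference scores."""
    if params.immune_cluster is not None and params.stromal_cluster is not None:
        return params.immune_cluster, params.stromal_cluster
    means_i = immune_score.groupby(labels).mean()
    means_s = stromal_score.groupby(labels).mean()
    imm = int(means_i.idxmax())
    stro = int(means_s.idxmax())
    if imm == stro:
        zi = (means_i - means_i.mean()) / means_i.std()
        zs = (means_s - means_s.mean()) / means_s.std()
        if zi[imm] >= zs[stro]:
            stro = int(means_s.drop(index=imm).idxmax())
        else:
            imm = int(means_i.drop(index=stro).idxmax())
    if params.immune_cluster is not None:
        imm = params.immune_cluster
    if params.stromal_cluster is not None:
        stro = params.stromal_cluster
    return imm, stro


def run_pipeline(
    expression: ExpressionMatrix,
    ferroptosis: GeneSetCollection,
    clinical: ClinicalTable,
    immune_reference: list[str],
    stromal_reference: list[str],
    mutations: MutationTable | None = None,
    single_cell: SingleCellMatrix | None = None,
    icb: tuple[ExpressionMatrix, ClinicalTable] | None = None,
    params: PipelineParams = PipelineParams(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the whole analysis and return (and optionally write) every stage.

    Stages: ferroptosis-gene consensus NMF -> reference ssGSEA ->
    immune/stromal cluster identification -> one-vs-rest DE -> activated
    signatures -> phenotype DEGs -> prognostic filter -> patient gene
    clusters -> gene groups A/B/C -> Fersig score -> stratified contrasts ->
    optional single-cell mapping and ICB application.
    """
    results: dict = {}
    provenance: dict = {"params": {k: getattr(params, k)
                                   for k in params.__dataclass_fields__}}

    # 1. consensus NMF on the ferroptosis genes
    ferro_expr = expression.subset_genes(ferroptosis.all_genes())
    consensus = nmf.consensus_cluster(
        ferro_expr, ranks=list(params.ranks), n_runs=params.n_runs,
        seed=params.seed, max_iter=params.nmf_max_iter, tol=params.nmf_tol,
    )
    rank = nmf.select_rank(consensus)
    fac_labels = nmf.assign_clusters(consensus, rank)
    results["rank_survey"] = consensus.rank_survey()
    results["selected_rank"] = rank
    results["fac_labels"] = fac_labels.to_frame()

    # 2. reference microenvironment ssGSEA + cluster identity
    ref_sets = {"immune_reference": immune_reference,
                "stromal_reference": stromal_reference}
    role_sets = dict(ferroptosis.sets)
    ref_scores = ssgsea_scores(expression, {**ref_sets, **role_sets},
                               alpha=params.ssgsea_alpha,
                               normalize=params.ssgsea_normalize)
    results["ssgsea_scores"] = ref_scores.scores
    immune_cluster, stromal_cluster = _identify_clusters(
        fac_labels, ref_scores.row("immune_reference"),
        ref_scores.row("stromal_reference"), params)
    provenance["immune_cluster"] = immune_cluster
    provenance["stromal_cluster"] = stromal_cluster

    # 3. one-vs-rest DE and derived signatures
    de = cluster_markers(expression, fac_labels, min_lnfc=params.de_min_lnfc,
                         alpha_q=params.de_alpha_q, test=params.de_test)
    results["de_table"] = de.table
    bundle = derive_activated_signatures(de, ferroptosis, immune_cluster,
                                         stromal_cluster)
    bundle.fac_markers = {
        int(c): de.markers(c, direction="up", min_lnfc=params.mapping_min_lnfc)
        for c in de.clusters()
    }
    bundle.phenotype_degs = phenotype_related_degs(de, mode=params.overlap_mode)

    # 4. prognostic filter and patient gene clusters
    prognostic, cox_fits = prognostic_filter(bundle.phenotype_degs, expression,
                                             clinical, alpha_p=params.alpha_p)
    results["prognostic_genes"] = pd.DataFrame({
        "gene": prognostic,
        "beta": [cox_fits[g].beta for g in prognostic],
        "p": [cox_fits[g].p for g in prognostic],
    }).set_index("gene")
    gc_consensus = nmf.consensus_cluster(
        expression.subset_genes(prognostic), ranks=[params.gene_cluster_rank],
        n_runs=params.n_runs, seed=params.seed + 1000,
        max_iter=params.nmf_max_iter, tol=params.nmf_tol,
    )
    gene_cluster_labels = nmf.assign_clusters(gc_consensus,
                                              params.gene_cluster_rank)
    results["gene_cluster_labels"] = gene_cluster_labels.rename(
        "gene_cluster").to_frame()

    # 5. gene groups A/B/C from the activated-signature ssGSEA scores
    act_scores = ssgsea_scores(
        expression,
        {"immune_activated": bundle.immune_activated,
         "stromal_activated": bundle.stromal_activated},
        alpha=params.ssgsea_alpha, normalize=params.ssgsea_normalize)
    bundle.gene_groups = group_signature_genes(
        bundle.phenotype_degs, expression,
        immune_score=act_scores.row("immune_activated"),
        stromal_score=act_scores.row("stromal_activated"))
    results["signatures"] = GeneSetCollection(sets={
        "immune_activated": bundle.immune_activated,
        "stromal_activated": bundle.stromal_activated,
        "phenotype_degs": bundle.phenotype_degs,
        "genes_A_stromal": bundle.gene_groups["A"],
        "genes_B_immune": bundle.gene_groups["B"],
        "genes_C_other": bundle.gene_groups["C"],
    })
    results["bundle"] = bundle

    # 6. Fersig score and stratified contrasts
    fersig = compute_fersig(expression, bundle.gene_groups["A"],
                            bundle.gene_groups["B"], clinical)
    results["fersig"] = fersig
    results["fersig_scores"] = fersig.to_frame()
    results["fersig_meta"] = {
        name: {"beta": fit.beta, "p": fit.p, "class": fersig.sign_class[name]}
        for name, fit in fersig.cox.items()
    }
    tmb = None
    if mutations is not None:
        tmb = compute_tmb(mutations, expression.sample_ids)
        results["tmb"] = tmb
    results["fersig_contrast"] = stratify_and_contrast(
        fersig.split.labels, clinical, scores=ref_scores, tmb=tmb)
    results["fac_contrast"] = stratify_and_contrast(
        fac_labels.astype(str), clinical, scores=ref_scores, tmb=tmb)

    # 7. optional single-cell mapping
    if single_cell is not None:
        marker_sets = {f"FAC{c}": genes for c, genes in
                       bundle.fac_markers.items() if genes}
        assignment = map_clusters_to_cells(single_cell, marker_sets,
                                           n_bins=params.n_bins,
                                           n_ctrl=params.n_ctrl,
                                           seed=params.seed)
        results["cell_assignment"] = assignment
        results["cell_labels"] = pd.concat(
            [assignment.labels, assignment.margin, assignment.tied], axis=1)
    else:
        provenance["single_cell"] = "skipped: no input"

    # 8. optional ICB cohort: apply the trained score, contrast response
    if icb is not None:
        icb_expr, icb_clinical = icb
        icb_score = fersig.apply(icb_expr)
        icb_split = median_split(icb_score)
        results["icb_scores"] = pd.DataFrame({"fersig": icb_score,
                                              "group": icb_split.labels})
        results["icb_contrast"] = stratify_and_contrast(
            icb_split.labels, icb_clinical)
    else:
        provenance["icb"] = "skipped: no input"

    results["provenance"] = provenance
    if out_dir is not None:
        writable = {
            k: v for k, v in results.items()
            if isinstance(v, (pd.DataFrame, pd.Series, GeneSetCollection))
        }
        writable["provenance"] = provenance
        writable["fersig_meta"] = results["fersig_meta"]
        writable["selected_rank"] = {"rank": rank}
        for key in ("fersig_contrast", "fac_contrast", "icb_contrast"):
            if key in results:
                writable[key] = _contrast_jsonable(results[key])
        results["manifest"] = write_results(writable, out_dir)
    return results


def _contrast_jsonable(report: dict) -> dict:
    def convert(v):
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="list") | (
                {"index": v.index.tolist()} if not isinstance(
                    v.index, pd.RangeIndex) else {})
        if isinstance(v, dict):
            return {str(k): convert(x) for k, x in v.items()}
        return v

    return {k: convert(v) for k, v in report.items()}
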