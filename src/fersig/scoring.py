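"""Per-sample and per-cell signature scoring.

Three scorers with different trade-offs:

* :func:`ssgsea_scores` — single-sample GSEA: a rank-based running-sum
  enrichment statistic, invariant to any strictly monotone per-sample
  transform of expression.
* :func:`module_scores` — mean set expression minus the mean of
  expression-bin-matched control genes; the standard per-cell score for
  sparse single-cell data.
* :func:`pca_signature_score` — projection on the first principal component
  of the gene-set submatrix, oriented so that a higher score means higher
  set expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, GeneSetCollection, SingleCellMatrix

__all__ = [
    "ScoreMatrix",
    "Pc1Score",
    "ssgsea_scores",
    "module_scores",
    "pca_signature_score",
    "pearson_correlation",
    "PearsonResult",
]


@dataclass
class ScoreMatrix:
    """Signatures x samples scores plus the parameters that produced them."""

    scores: pd.DataFrame
    method: str
    params: dict

    def row(self, name: str) -> pd.Series:
        return self.scores.loc[name]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.values
    if isinstance(X, SingleCellMatrix):
        return X.log_normalized()
    return X


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _ssgsea_sample(x: np.ndarray, in_mask_by_set: dict[str, np.ndarray],
                   alpha: float) -> dict[str, float]:
    n = x.size
    # rank values: largest expression -> rank n; ties get the average rank
    ranks = scipy.stats.rankdata(x, method="average")
    order = np.lexsort((np.arange(n), -x))  # descending expression, stable
    weights = ranks[order] ** alpha
    out: dict[str, float] = {}
    for name, mask in in_mask_by_set.items():
        m = mask[order]
        w_in = np.where(m, weights, 0.0)
        denom_in = w_in.sum()
        p_in = np.cumsum(w_in) / denom_in
        n_out = n - int(m.sum())
        p_out = np.cumsum(~m) / n_out
        out[name] = float(np.sum(p_in - p_out))
    return out


def ssgsea_scores(
    X: ExpressionMatrix | pd.DataFrame,
    sets: GeneSetCollection | dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Single-sample GSEA enrichment scores for every set and sample.

    Per sample, genes are ranked by expression (descending walk, average
    ranks on ties).  The statistic is the sum over all list positions of the
    difference between the weighted in-set ECDF (weights = rank^alpha) and
    the uniform out-of-set ECDF.  With ``normalize`` the whole score matrix
    is divided by its max - min range, the usual cross-sample normalization.
    """
    df = _as_frame(X)
    set_map = sets.sets if isinstance(sets, GeneSetCollection) else sets
    genes = df.index
    masks: dict[str, np.ndarray] = {}
    for name, members in set_map.items():
        mask = np.asarray(genes.isin(set(members)))
        k = int(mask.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; skipped")
            continue
        if k == len(genes):
            raise ValueError(f"gene set {name!r} covers every gene; ES undefined")
        masks[name] = mask
    if not masks:
        raise ValueError("no gene set overlaps the expression matrix")
    arr = df.to_numpy(dtype=float)
    rows = {name: np.empty(arr.shape[1]) for name in masks}
    for j in range(arr.shape[1]):
        es = _ssgsea_sample(arr[:, j], masks, alpha)
        for name, v in es.items():
            rows[name][j] = v
    scores = pd.DataFrame(rows, index=df.columns).T
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return ScoreMatrix(
        scores=scores,
        method="ssgsea",
        params={"alpha": alpha, "normalize": normalize},
    )


# ---------------------------------------------------------------------------
# binned-control module score
# ---------------------------------------------------------------------------


def module_scores(
    M: SingleCellMatrix | ExpressionMatrix | pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus mean expression of bin-matched controls.

    Genes are binned into ``n_bins`` equal-occupancy bins by average
    expression across cells.  For each set gene, ``n_ctrl`` control genes are
    sampled from its bin (without replacement when the bin is large enough,
    with replacement otherwise); set genes are excluded from the control
    pool.  Sparse single-cell input is log-normalized first.
    """
    df = _as_frame(M)
    set_genes = [g for g in dict.fromkeys(gene_set) if g in df.index]
    if not set_genes:
        raise ValueError("gene set has no overlap with the matrix")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    mean_expr = df.mean(axis=1)
    order = np.argsort(mean_expr.to_numpy(), kind="stable")
    bin_of = np.empty(len(df), dtype=int)
    bin_of[order] = (np.arange(len(df)) * n_bins) // len(df)
    bins = pd.Series(bin_of, index=df.index)
    in_set = df.index.isin(set_genes)
    control: list[str] = []
    for g in set_genes:
        b = bins[g]
        candidates = df.index[(bins == b).to_numpy() & ~in_set]
        if len(candidates) == 0:
            candidates = df.index[~in_set]
            warnings.warn(f"bin of gene {g!r} holds only set genes; "
                          "sampling controls from all other genes")
        replace = len(candidates) < n_ctrl
        control.extend(rng.choice(candidates, size=n_ctrl, replace=replace))
    score = df.loc[set_genes].mean(axis=0) - df.loc[control].mean(axis=0)
    score.name = "module_score"
    return score


# ---------------------------------------------------------------------------
# PCA signature score
# ---------------------------------------------------------------------------


@dataclass
class Pc1Score:
    """First-principal-component signature score with reusable loadings."""

    genes: list[str]
    center: pd.Series          # per-gene mean used for centering
    loadings: pd.Series        # unit-norm gene loadings (orientation applied)
    scores: pd.Series          # per-sample projection
    oriented: bool             # True when the eigensolver sign was flipped

    def apply(self, X: ExpressionMatrix | pd.DataFrame) -> pd.Series:
        """Project new samples with the stored center and loadings."""
        df = _as_frame(X)
        missing = [g for g in self.genes if g not in df.index]
        if missing:
            raise ValueError(f"genes missing from new matrix: {missing[:5]}")
        sub = df.loc[self.genes]
        centered = sub.sub(self.center, axis=0)
        return pd.Series(self.loadings.to_numpy() @ centered.to_numpy(),
                         index=df.columns, name="pc1")


def pca_signature_score(
    X: ExpressionMatrix | pd.DataFrame, gene_set: list[str]
) -> Pc1Score:
    """PC1 of the gene-set submatrix as a per-sample signature score.

    Genes are centered across samples but not variance-scaled.  The sign of
    PC1 is arbitrary in the eigendecomposition, so the score is oriented to
    correlate positively with the mean expression of the set: higher score
    always means higher set expression.
    """
    df = _as_frame(X)
    genes = [g for g in dict.fromkeys(gene_set) if g in df.index]
    if len(genes) < 2:
        raise ValueError("gene set must match >= 2 genes in the matrix")
    if df.shape[1] < 3:
        raise ValueError("need >= 3 samples for a PC1 score")
    sub = df.loc[genes]
    center = sub.mean(axis=1)
    Xc = sub.sub(center, axis=0).to_numpy()
    if not np.any(Xc):
        raise ValueError("zero-variance submatrix; PC1 undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = U[:, 0]
    scores = S[0] * Vt[0]
    set_mean = sub.mean(axis=0).to_numpy()
    r = np.corrcoef(scores, set_mean)[0, 1]
    flipped = bool(r < 0)
    if flipped:
        loadings = -loadings
        scores = -scores
    return Pc1Score(
        genes=genes,
        center=center,
        loadings=pd.Series(loadings, index=genes, name="loading"),
        scores=pd.Series(scores, index=df.columns, name="pc1"),
        oriented=flipped,
    )


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


class PearsonResult(NamedTuple):
    r: float
    n: int


def pearson_correlation(
    a: pd.Series, b: pd.Series | pd.DataFrame | ScoreMatrix
) -> PearsonResult | pd.DataFrame:
    """Pearson r of ``a`` against a vector or against every row of a matrix.

    Pairwise-complete over missing values; a zero-variance input yields a
    flagged NaN rather than an error.
    """
    if isinstance(b, ScoreMatrix):
        b = b.scores
    if isinstance(b, pd.DataFrame):
        rows = [pearson_correlation(a, b.loc[name]) for name in b.index]
        return pd.DataFrame(rows, index=b.index, columns=["r", "n"])
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(r=float("nan"), n=n)
    return PearsonResult(r=float(np.corrcoef(x, y)[0, 1]), n=n)
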