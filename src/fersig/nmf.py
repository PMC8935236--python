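"""Consensus non-negative matrix factorization for molecular subtyping.

The factorization uses the classic Brunet multiplicative-update NMF that
minimizes the generalized Kullback-Leibler divergence D(X || WH) — the
standard choice for expression subtyping.  Stability-based model selection
follows the usual consensus recipe: many random restarts, per-run hard
assignment of samples by the dominant metagene, a consensus matrix of
co-clustering frequencies, and the cophenetic correlation coefficient of that
matrix as the rank-selection statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, cut_tree
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "nmf_factorize",
    "consensus_cluster",
    "select_rank",
    "assign_clusters",
    "filter_degenerate_genes",
]

_EPS = np.finfo(float).tiny


@dataclass
class NMFFactorization:
    W: pd.DataFrame          # genes x r, non-negative
    H: pd.DataFrame          # r x samples, non-negative
    rank: int
    trace: np.ndarray        # KL divergence per iteration (non-increasing)
    seed: int
    n_iter: int
    converged: bool

    def sample_labels(self) -> pd.Series:
        """Hard assignment: dominant metagene per sample (ties -> lower index)."""
        idx = np.argmax(self.H.to_numpy(), axis=0)
        return pd.Series(idx, index=self.H.columns, name="component")


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]        # rank -> samples x samples
    cophenetic: dict[int, float]
    dispersion: dict[int, float]
    sample_ids: list[str]
    n_runs: int
    seed: int
    chosen_rank: int | None = None
    labels: pd.Series | None = None
    factorizations: dict[int, NMFFactorization] = field(default_factory=dict)

    def rank_survey(self) -> pd.DataFrame:
        ranks = sorted(self.consensus)
        return pd.DataFrame(
            {
                "rank": ranks,
                "cophenetic": [self.cophenetic[r] for r in ranks],
                "dispersion": [self.dispersion[r] for r in ranks],
            }
        ).set_index("rank")


def _kl_divergence(X: np.ndarray, WH: np.ndarray, x_logx_minus_x: float) -> float:
    # D(X||WH) = sum(x log x - x log wh - x + wh); x log x terms precomputed
    return float(x_logx_minus_x - np.sum(X * np.log(WH + _EPS)) + WH.sum())


def nmf_factorize(
    X: ExpressionMatrix | pd.DataFrame,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: str = "uniform",
    debug_assert: bool = False,
) -> NMFFactorization:
    """Brunet multiplicative-update NMF minimizing KL divergence D(X || WH).

    ``init`` selects the starting point: "uniform" draws W and H from
    Uniform(0,1) scaled so WH matches the mean of X; "partition" seeds H
    with a random hard assignment of samples to components (a clustering-
    style start that lands restarts in different local basins — useful for
    consensus surveys).  Iteration stops when the relative objective change
    drops below ``tol`` or at ``max_iter``.  With ``debug_assert`` the
    monotone decrease of the objective is asserted at every step.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    A = df.to_numpy(dtype=float)
    p, n = A.shape
    if (A < 0).any():
        raise ValueError("NMF input must be non-negative")
    if not 1 <= rank < min(p, n):
        raise ValueError(f"rank must satisfy 1 <= r < min(genes, samples)={min(p, n)}")
    row_zero = np.flatnonzero(A.sum(axis=1) == 0)
    col_zero = np.flatnonzero(A.sum(axis=0) == 0)
    if row_zero.size or col_zero.size:
        raise ValueError(
            "all-zero rows/columns present "
            f"(rows {row_zero[:3].tolist()}, cols {col_zero[:3].tolist()}); "
            "filter them before factorization (see filter_degenerate_genes)"
        )

    rng = np.random.default_rng(seed)
    if init == "uniform":
        scale = np.sqrt(4.0 * A.mean() / rank)
        W = rng.uniform(0.0, 1.0, size=(p, rank)) * scale
        H = rng.uniform(0.0, 1.0, size=(rank, n)) * scale
    elif init == "partition":
        scale = np.sqrt(A.mean())
        W = rng.uniform(0.0, 1.0, size=(p, rank)) * scale
        start = rng.integers(0, rank, size=n)
        H = np.full((rank, n), 0.01 * scale)
        H[start, np.arange(n)] = scale
    else:
        raise ValueError(f"unknown init {init!r}")

    pos = A > 0
    x_logx_minus_x = float(np.sum(A[pos] * np.log(A[pos])) - A.sum())
    trace = []
    WH = W @ H
    prev = _kl_divergence(A, WH, x_logx_minus_x)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # H update
        H *= (W.T @ (A / (WH + _EPS))) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H
        # W update
        W *= ((A / (WH + _EPS)) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        WH = W @ H
        obj = _kl_divergence(A, WH, x_logx_minus_x)
        trace.append(obj)
        if debug_assert:
            assert obj <= prev + 1e-8 * max(1.0, abs(prev)), "KL objective increased"
        if abs(prev - obj) <= tol * max(abs(prev), 1.0):
            converged = True
            prev = obj
            break
        prev = obj

    # resolve the W/H scale ambiguity: W columns sum to 1, H carries the
    # magnitude, so argmax over H rows is comparable across restarts
    col = W.sum(axis=0)
    W = W / (col[None, :] + _EPS)
    H = H * col[:, None]

    return NMFFactorization(
        W=pd.DataFrame(W, index=df.index, columns=range(rank)),
        H=pd.DataFrame(H, index=range(rank), columns=df.columns),
        rank=rank,
        trace=np.asarray(trace),
        seed=seed,
        n_iter=it,
        converged=converged,
    )


def filter_degenerate_genes(X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero sum or zero variance (unusable for factorization)."""
    df = X.values if isinstance(X, ExpressionMatrix) else X
    keep = (df.sum(axis=1) > 0) & (df.std(axis=1) > 0)
    return df.loc[keep]


def _cophenetic_coefficient(C: np.ndarray) -> float:
    """Pearson correlation between 1-C distances and their average-linkage
    cophenetic distances; 1.0 for a perfectly ultrametric (e.g. 0/1 block)
    consensus."""
    d = squareform(1.0 - C, checks=False)
    Z = average(d)
    coph = cophenet(Z)
    if np.std(d) == 0 or np.std(coph) == 0:
        return 1.0 if np.max(np.abs(d - coph)) < 1e-12 else 0.0
    return float(np.corrcoef(d, coph)[0, 1])


def consensus_cluster(
    X: ExpressionMatrix | pd.DataFrame,
    ranks: list[int],
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    row_shift: bool = True,
    keep_factorizations: bool = False,
) -> ConsensusResult:
    """Consensus matrices and cophenetic coefficients over a rank sweep.

    Restart ``run`` uses seed ``seed + run``; each restart hard-assigns
    samples by the dominant metagene and the connectivity matrices are
    averaged into the consensus matrix C.  Restarts alternate between the
    "uniform" and "partition" initializations so the consensus reflects the
    basin structure of the factorization rather than a single dominant
    basin: at the true rank every start converges to the planted blocks,
    while at a wrong rank partition starts scatter across the competing
    merges/splits and depress the cophenetic coefficient.

    ``row_shift`` subtracts each gene's minimum before factorization.  Log
    expression carries a large shared per-gene baseline that would otherwise
    absorb most of the divergence into a single flat factor; the shift keeps
    the matrix non-negative while letting the factors track between-sample
    structure.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    df = filter_degenerate_genes(df)
    if row_shift:
        df = df.sub(df.min(axis=1), axis=0)
        df = filter_degenerate_genes(df)
    if any(r < 2 for r in ranks):
        raise ValueError("all candidate ranks must be >= 2")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    samples = list(df.columns)
    n = len(samples)
    consensus: dict[int, pd.DataFrame] = {}
    rho: dict[int, float] = {}
    disp: dict[int, float] = {}
    facts: dict[int, NMFFactorization] = {}
    for r in ranks:
        acc = np.zeros((n, n))
        best = None
        for run in range(n_runs):
            fit = nmf_factorize(df, r, seed=seed + run, max_iter=max_iter,
                                tol=tol,
                                init="uniform" if run % 2 == 0 else "partition")
            labels = fit.sample_labels().to_numpy()
            acc += labels[:, None] == labels[None, :]
            if best is None or fit.trace[-1] < best.trace[-1]:
                best = fit
        C = acc / n_runs
        np.fill_diagonal(C, 1.0)
        consensus[r] = pd.DataFrame(C, index=samples, columns=samples)
        rho[r] = _cophenetic_coefficient(C)
        disp[r] = float(np.mean(4.0 * (C - 0.5) ** 2))
        if keep_factorizations:
            facts[r] = best
    return ConsensusResult(
        consensus=consensus,
        cophenetic=rho,
        dispersion=disp,
        sample_ids=samples,
        n_runs=n_runs,
        seed=seed,
        factorizations=facts,
    )


def select_rank(result: ConsensusResult, candidate_ranks: list[int] | None = None) -> int:
    """Rank with the largest cophenetic coefficient; ties -> smallest rank."""
    candidates = sorted(result.consensus.keys() if candidate_ranks is None
                        else candidate_ranks)
    if not candidates:
        raise ValueError("no candidate ranks")
    missing = [r for r in candidates if r not in result.cophenetic]
    if missing:
        raise ValueError(f"cophenetic coefficient missing for ranks {missing}")
    best = max(candidates, key=lambda r: (result.cophenetic[r], -r))
    result.chosen_rank = best
    return best


def assign_clusters(result: ConsensusResult, rank: int) -> pd.Series:
    """Cut the consensus-matrix dendrogram at ``rank`` clusters.

    Average-linkage hierarchical clustering of 1-C, cut into exactly ``rank``
    groups by merge order (deterministic under tied heights); labels are
    renamed 1..k by descending cluster size, ties broken by first occurrence.
    """
    if rank not in result.consensus:
        raise ValueError(f"no consensus matrix computed at rank {rank}")
    C = result.consensus[rank].to_numpy()
    d = squareform(1.0 - C, checks=False)
    if np.all(d < 1e-12):
        warnings.warn("degenerate consensus matrix: all samples co-cluster in "
                      "every run; requested cut is arbitrary")
    Z = average(d)
    raw = cut_tree(Z, n_clusters=rank).ravel()
    # canonical naming: cluster 1 = largest
    sizes = pd.Series(raw).value_counts()
    first_seen = {c: int(np.flatnonzero(raw == c)[0]) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first_seen[c]))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=result.sample_ids,
                       name="cluster")
    result.labels = labels
    return labels
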