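"""Differential expression, enrichment, contingency/rank tests and TMB.

Fold changes are reported on the natural-log scale: the pipeline's marker
thresholds (0.25 for signature genes, 0.5 for mapping genes) follow the
convention of the single-cell marker tools, where "expression difference on
a natural log scale" is the difference of within-group means of log
expression.  Input matrices are log2-scale, so lnFC = (mean_in - mean_out)
* ln(2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, MutationTable, NONSILENT_CLASSES

__all__ = [
    "DEResult",
    "cluster_markers",
    "bh_adjust",
    "hypergeometric_enrichment",
    "chi_square_test",
    "rank_location_test",
    "compute_tmb",
]

LN2 = math.log(2.0)


@dataclass
class DEResult:
    """One-vs-rest differential expression over all clusters."""

    table: pd.DataFrame  # cluster, gene, lnfc, stat, p, q, direction, significant
    min_lnfc: float
    alpha_q: float
    test: str

    def markers(self, cluster, direction: str = "up",
                min_lnfc: float | None = None) -> list[str]:
        """Significant marker genes of one cluster (default: upregulated)."""
        thr = self.min_lnfc if min_lnfc is None else min_lnfc
        t = self.table
        sel = (t["cluster"] == cluster) & (t["q"] < self.alpha_q) & \
              (t["lnfc"].abs() >= thr)
        if direction in ("up", "down"):
            sel &= t["direction"] == direction
        return t.loc[sel, "gene"].tolist()

    def clusters(self) -> list:
        return sorted(self.table["cluster"].unique())


def cluster_markers(
    X: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    min_lnfc: float = 0.25,
    alpha_q: float = 0.05,
    test: str = "wilcoxon",
) -> DEResult:
    """One-vs-rest differential expression for every cluster.

    ``test`` is "wilcoxon" (rank-sum, normal approximation with tie
    correction) or "welch_t".  A gene is a marker of a cluster when
    q < ``alpha_q`` and |lnFC| >= ``min_lnfc``; BH adjustment is applied per
    contrast across genes.
    """
    df = X.values if isinstance(X, ExpressionMatrix) else X
    labels = labels.reindex(df.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"cluster(s) below minimum size 3: {small.index.tolist()}")
    arr = df.to_numpy(dtype=float)
    frames = []
    for c in uniq:
        in_c = (labels == c).to_numpy()
        a, b = arr[:, in_c], arr[:, ~in_c]
        lnfc = (a.mean(axis=1) - b.mean(axis=1)) * LN2
        if test == "wilcoxon":
            with np.errstate(invalid="ignore"):
                res = scipy.stats.mannwhitneyu(
                    a, b, axis=1, alternative="two-sided", method="asymptotic"
                )
            stat, p = res.statistic, res.pvalue
        elif test == "welch_t":
            res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
            stat, p = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        p = np.nan_to_num(p, nan=1.0)
        q = bh_adjust(p)
        frames.append(pd.DataFrame({
            "cluster": c,
            "gene": df.index,
            "lnfc": lnfc,
            "stat": stat,
            "p": p,
            "q": q,
            "direction": np.where(lnfc >= 0, "up", "down"),
            "significant": (q < alpha_q) & (np.abs(lnfc) >= min_lnfc),
        }))
    return DEResult(
        table=pd.concat(frames, ignore_index=True),
        min_lnfc=min_lnfc,
        alpha_q=alpha_q,
        test=test,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: list[str],
    sets: GeneSetCollection | dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe first; p = P(X >= k) for overlap
    k out of a query of size n against a set of size K in a universe of N.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in uni_set]
    if outside:
        raise ValueError(f"query genes outside the universe: {outside[:5]}")
    set_map = sets.sets if isinstance(sets, GeneSetCollection) else sets
    N, n = len(uni), len(q)
    q_set = set(q)
    rows = []
    for name, members in set_map.items():
        member_set = set(members) & uni_set
        K = len(member_set)
        k = len(q_set & member_set)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def chi_square_test(table) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (statistic, df, p, expected); warns when any expected count is
    below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row/column")
    stat, p, dof, expected = scipy.stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count below 5; chi-square approximation may be poor")
    return float(stat), int(dof), float(p), expected


def rank_location_test(groups: list) -> tuple[float, float]:
    """Two groups: Wilcoxon rank-sum; more: Kruskal-Wallis H (tie-corrected).

    The two-group branch uses the exact null distribution on small untied
    samples and the tie-corrected normal approximation otherwise.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 observations")
    if len(arrays) == 2:
        res = scipy.stats.mannwhitneyu(arrays[0], arrays[1],
                                       alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    res = scipy.stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def compute_tmb(
    mut: MutationTable,
    samples: list[str],
    nonsilent_only: bool = True,
    per_mb: bool = False,
    capture_mb: float = 38.0,
    nonsilent_classes: frozenset[str] = NONSILENT_CLASSES,
) -> pd.Series:
    """Tumor mutation burden: mutation records per sample.

    By default the raw count of non-silent records; ``per_mb`` divides by a
    configurable capture size in megabases.  Samples without records get 0.
    """
    if not samples:
        raise ValueError("sample list is empty")
    t = mut.table
    if nonsilent_only:
        t = t[t["variant_classification"].isin(nonsilent_classes)]
    counts = t["sample_id"].value_counts()
    tmb = pd.Series(0.0, index=pd.Index(samples, name="sample_id"), name="tmb")
    common = counts.index.intersection(tmb.index)
    tmb.loc[common] = counts.loc[common].astype(float)
    if per_mb:
        tmb = tmb / capture_mb
    return tmb
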