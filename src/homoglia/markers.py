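"""One-vs-rest marker statistics, the genescore, gene-set scores and summaries.

The genescore condenses a marker row into a single enrichment-and-
specificity statistic:

    genescore = avg_logFC * pct1 / max(pct2, 0.001)

where ``avg_logFC`` is the natural-log average fold change between cells in
the cluster and all remaining cells, ``pct1`` the fraction of in-cluster
cells detecting the gene and ``pct2`` the same fraction outside the
cluster.  The 0.001 floor keeps scores of perfectly specific markers
finite (pct fields are conventionally reported at 3-decimal resolution,
making 0.001 the smallest distinguishable nonzero value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import NormalizedMatrix

__all__ = [
    "wilcoxon_rank_sum",
    "find_markers",
    "find_all_markers",
    "compute_genescores",
    "gene_set_score",
    "summarize_scores",
    "PCT_FLOOR",
]

#: Floor applied to pct2 in the genescore denominator.
PCT_FLOOR = 0.001

MARKER_COLUMNS = ["cluster", "gene", "avg_logFC", "pct1", "pct2", "p_value", "p_adjusted"]


#: Largest pooled sample size for which the exact permutation p is computed.
EXACT_RANK_SUM_MAX_N = 25


def _exact_rank_sum_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided permutation p for the rank-sum with midranks.

    Convolves the subset-sum distribution of the (doubled, hence integer)
    midranks by dynamic programming: ``count[j, s]`` = number of j-subsets
    of the pooled ranks with doubled rank sum s.  Two-sided p is the
    probability of a rank-sum deviating from its expectation at least as
    much as observed.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    n = len(r2)
    total_sum = int(r2.sum())
    count = np.zeros((n1 + 1, total_sum + 1), dtype=float)
    count[0, 0] = 1.0
    for r in r2:
        for j in range(min(n1, n), 0, -1):
            count[j, r:] += count[j - 1, : total_sum + 1 - r]
    dist = count[n1]
    expect2 = n1 * (n + 1)  # doubled expectation
    obs2 = abs(int(np.round(2 * ranks[:n1].sum())) - expect2)
    sums = np.arange(total_sum + 1)
    hits = dist[np.abs(sums - expect2) >= obs2 - 1e-9].sum()
    return float(hits / dist.sum())


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test with midranks.

    For pooled samples of up to 25 values the exact tie-aware permutation
    p is computed (by subset-sum convolution); beyond that the normal
    approximation with tie-corrected variance and continuity correction is
    used (its error against enumeration stays within ~0.02 only for larger
    groups, hence the exact small-sample branch).  Returns
    ``(U, p_two_sided)`` where U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    if x.size + y.size <= EXACT_RANK_SUM_MAX_N:
        ranks = stats.rankdata(np.concatenate([x, y]))
        return u, _exact_rank_sum_p(ranks, x.size)
    return u, float(res.pvalue)


def _log_mean_expm1(X: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(values)) + 1) per column — the average-fold-change scale."""
    return np.log(np.expm1(X).mean(axis=0) + 1.0)


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    cluster,
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker rows for ``cluster``.

    Genes are admitted when ``avg_logFC >= min_logfc`` and ``pct1 > min_pct``
    (strict); the rank-sum p-value is computed per admitted gene on the
    log-normalized values and Bonferroni-adjusted over all genes in the
    matrix.  Rows with ``p_adjusted`` above ``alpha`` are retained in the
    table (callers filter as needed); rows are sorted by ``avg_logFC``
    descending.
    """
    labels = pd.Series(labels).loc[norm.cell_ids]
    in_mask = (labels == cluster).to_numpy()
    if in_mask.sum() < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")
    X = norm.dense()
    Xin, Xout = X[in_mask], X[~in_mask]
    lfc = _log_mean_expm1(Xin) - _log_mean_expm1(Xout)
    pct1 = (Xin > 0).mean(axis=0)
    pct2 = (Xout > 0).mean(axis=0)
    admit = (lfc >= min_logfc) & (pct1 > min_pct)
    idx = np.where(admit)[0]
    if idx.size == 0:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    if norm.n_cells <= EXACT_RANK_SUM_MAX_N:
        pvals = np.array(
            [wilcoxon_rank_sum(Xin[:, j], Xout[:, j])[1] for j in idx]
        )
    else:
        res = stats.mannwhitneyu(
            Xin[:, idx], Xout[:, idx], alternative="two-sided",
            method="asymptotic", axis=0,
        )
        pvals = np.atleast_1d(res.pvalue)
    padj = np.minimum(pvals * norm.n_genes, 1.0)  # Bonferroni over all genes
    out = pd.DataFrame(
        {
            "cluster": cluster,
            "gene": norm.gene_ids[idx],
            "avg_logFC": lfc[idx],
            "pct1": np.round(pct1[idx], 10),
            "pct2": np.round(pct2[idx], 10),
            "p_value": pvals,
            "p_adjusted": padj,
        }
    )
    return out.sort_values("avg_logFC", ascending=False, kind="stable").reset_index(
        drop=True
    )


def find_all_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Concatenate :func:`find_markers` over every cluster with >= min_cells cells."""
    labels = pd.Series(labels).loc[norm.cell_ids]
    tables = []
    for cl, n in labels.value_counts().sort_index().items():
        if n >= min_cells:
            tables.append(find_markers(norm, labels, cl, min_logfc, min_pct))
    if not tables:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def compute_genescores(markers: pd.DataFrame, fc_scale: str = "log") -> pd.DataFrame:
    """Append the genescore column to a marker table.

    genescore = fold_change * pct1 / max(pct2, 0.001), where fold_change is
    ``avg_logFC`` for ``fc_scale='log'`` (default) or ``exp(avg_logFC)`` for
    ``fc_scale='linear'``.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    if fc_scale not in ("log", "linear"):
        raise ValueError("fc_scale must be 'log' or 'linear'")
    fc = markers["avg_logFC"].to_numpy()
    if fc_scale == "linear":
        fc = np.exp(fc)
    out = markers.copy()
    out["genescore"] = fc * out["pct1"].to_numpy() / np.maximum(
        out["pct2"].to_numpy(), PCT_FLOOR
    )
    return out


def gene_set_score(
    norm: NormalizedMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score for a gene set (e.g. S-phase or G2/M genes).

    Mean expression of the set genes minus the mean of control genes drawn,
    per set gene, from the same average-expression bin.  Deterministic
    given ``seed``.
    """
    present = [g for g in gene_set if g in set(norm.gene_ids)]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    X = norm.dense()
    avg = X.mean(axis=0)
    # Rank-based bins of average expression (equal-occupancy).
    ranks = pd.Series(avg).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(avg) / n_bins)).astype(int)
    rng = np.random.default_rng(seed)
    set_idx = norm.gene_ids.get_indexer(present)
    in_set = np.zeros(norm.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx: list[np.ndarray] = []
    for g in set_idx:
        pool = np.where((bins == bins[g]) & ~in_set)[0]
        if pool.size == 0:  # bin exhausted by the set itself
            pool = np.where(~in_set)[0]
        take = rng.choice(pool, size=min(n_ctrl, pool.size), replace=False)
        ctrl_idx.append(take)
    ctrl = np.unique(np.concatenate(ctrl_idx)) if ctrl_idx else np.array([], int)
    ctrl_term = X[:, ctrl].mean(axis=1) if ctrl.size else 0.0
    score = X[:, set_idx].mean(axis=1) - ctrl_term
    return pd.Series(score, index=norm.cell_ids, name="score")


def summarize_scores(scores: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group five-number summary with the Tukey 1.5 x IQR outlier rule.

    Quartiles use the linear-interpolation convention (type-7).  The
    whisker min/max exclude outliers, which are listed separately.
    """
    scores = pd.Series(scores)
    groups = pd.Series(groups).loc[scores.index]
    rows = []
    for g, vals in scores.groupby(groups):
        if len(vals) == 0:
            raise ValueError(f"group {g!r} is empty")
        v = vals.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # type-7 (linear)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inlier = v[(v >= lo) & (v <= hi)]
        outliers = vals[(v < lo) | (v > hi)]
        rows.append(
            {
                "group": g,
                "min": inlier.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": inlier.max(),
                "n": len(v),
                "outliers": list(outliers.index),
            }
        )
    return pd.DataFrame(rows).set_index("group")
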