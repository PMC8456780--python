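"""Cluster marker-gene statistics.

Each cluster is compared against all other cells with two tests per gene: a
two-sided Wilcoxon rank-sum test on log-normalized expression and Fisher's
exact test on the expressing-cell frequency (count > 0). The two p-values
are combined with Fisher's method (chi-square, 4 df) and BH-adjusted across
genes within the cluster. A gene is called a marker when
|log2FC| >= 1.5, adjusted p < 0.05 and in-cluster expressing frequency > 0.3
(all configurable). GSEA pre-ranking scores are log2FC * (-log10 adjusted p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .graph import ClusterAssignment
from .preprocess import NormalizedMatrix

P_FLOOR = 1e-300


@dataclass
class MarkerCutoffs:
    min_abs_log2fc: float = 1.5
    max_p_adj: float = 0.05
    min_freq_in: float = 0.3
    pseudocount: float = 1.0


def wilcoxon_rank_sum(a, b, method: str = "auto") -> float:
    """Two-sided rank-sum p-value for two samples.

    With ``method='auto'``: exact enumeration when both groups have n <= 8
    and there are no ties across the pooled data, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def fisher_exact_frequency(
    n_expr_in: int, n_in: int, n_expr_out: int, n_out: int
) -> float:
    """Two-sided Fisher's exact p on the expressing/non-expressing 2x2 table."""
    if n_expr_in > n_in or n_expr_out > n_out or min(n_expr_in, n_expr_out) < 0:
        raise ValueError("expressing counts must be within group sizes")
    table = [[n_expr_in, n_in - n_expr_in], [n_expr_out, n_out - n_expr_out]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def combine_fisher(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: X = -2(ln p1 + ln p2) ~ chi2(4).

    The upper tail has the closed form exp(-X/2) * (1 + X/2). Inputs of 0
    are floored at 1e-300.
    """
    p1 = max(float(p1), P_FLOOR)
    p2 = max(float(p2), P_FLOOR)
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(min(np.exp(-x / 2.0) * (1.0 + x / 2.0), 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --- vectorized per-gene test batteries -----------------------------------


def _rank_precompute(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mid-ranks and tie correction sum(t^3 - t), shared by clusters."""
    ranks = stats.rankdata(X, axis=0)
    n = X.shape[0]
    tie_term = np.empty(X.shape[1])
    Xs = np.sort(X, axis=0)
    boundary = np.vstack([np.ones((1, X.shape[1]), bool), np.diff(Xs, axis=0) != 0])
    for j in range(X.shape[1]):
        counts = np.diff(np.append(np.flatnonzero(boundary[:, j]), n)).astype(float)
        tie_term[j] = np.sum(counts**3 - counts)
    return ranks, tie_term


def _wilcoxon_vectorized(
    X: np.ndarray,
    in_mask: np.ndarray,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Two-sided normal-approximation rank-sum p per column (gene).

    Ranks are computed once per gene across all cells; the in-group rank sum
    yields U. Tie and continuity corrections match the standard asymptotic
    Mann-Whitney test.
    """
    n = X.shape[0]
    n1 = int(in_mask.sum())
    n2 = n - n1
    ranks, tie_term = precomputed if precomputed is not None else _rank_precompute(X)
    r1 = ranks[in_mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.where(sd > 0, sd, np.inf)
    z = np.maximum(z, 0.0)
    return np.minimum(2.0 * stats.norm.sf(z), 1.0)


def _fisher_vectorized(
    k_in: np.ndarray, n_in: int, k_out: np.ndarray, n_out: int
) -> np.ndarray:
    """Two-sided Fisher's exact p per gene via hypergeometric enumeration.

    For gene g the table margin is K = k_in + k_out successes in a population
    of M = n_in + n_out with n_in draws; the two-sided p sums P(X = x) over
    all x with P(X = x) <= P(X = k_in) * (1 + 1e-7) (the standard relative
    tolerance for floating-point table probabilities).
    """
    M = n_in + n_out
    K = (k_in + k_out).astype(int)
    lo = np.maximum(0, K - n_out)
    hi = np.minimum(K, n_in)
    width = int((hi - lo).max()) + 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xc = np.clip(x, lo[:, None], hi[:, None])

    def _logpmf(xv, Kv):
        return (
            gammaln(Kv + 1)
            - gammaln(xv + 1)
            - gammaln(Kv - xv + 1)
            + gammaln(M - Kv + 1)
            - gammaln(n_in - xv + 1)
            - gammaln(M - Kv - (n_in - xv) + 1)
            + gammaln(n_in + 1)
            + gammaln(n_out + 1)
            - gammaln(M + 1)
        )

    logp = _logpmf(xc.astype(float), K[:, None].astype(float))
    logp_obs = _logpmf(k_in.astype(float), K.astype(float))
    pmf = np.where(valid, np.exp(logp), 0.0)
    pobs = np.exp(logp_obs)
    p = np.where(pmf <= pobs[:, None] * (1 + 1e-7), pmf, 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def find_markers(
    norm: NormalizedMatrix,
    clusters: ClusterAssignment | np.ndarray,
    cutoffs: MarkerCutoffs | None = None,
    wilcoxon_method: str = "asymptotic",
) -> pd.DataFrame:
    """Per-cluster differential expression table (the MarkerTable).

    Every cluster is tested against all other cells. Columns: cluster, gene,
    log2fc, p_wilcoxon, p_fisher, p_combined, p_adj, freq_in, freq_out,
    rank_score, is_marker. log2FC uses de-logged normalized means with a
    pseudocount of 1. Clusters of size < 3 are skipped with a warning.
    """
    cutoffs = cutoffs or MarkerCutoffs()
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else np.asarray(clusters)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 clusters for marker detection")
    X = np.asarray(norm.values.todense(), dtype=float)
    expressing = X > 0
    expm1 = np.expm1(X)
    genes = norm.gene_ids.astype(str)
    rank_pre = _rank_precompute(X)
    frames = []
    for c in uniq:
        in_mask = labels == c
        n_in = int(in_mask.sum())
        n_out = X.shape[0] - n_in
        if n_in < 3:
            warnings.warn(f"cluster {c} has {n_in} < 3 cells; skipped", stacklevel=2)
            continue
        mean_in = expm1[in_mask].mean(axis=0)
        mean_out = expm1[~in_mask].mean(axis=0)
        log2fc = np.log2(
            (mean_in + cutoffs.pseudocount) / (mean_out + cutoffs.pseudocount)
        )
        k_in = expressing[in_mask].sum(axis=0)
        k_out = expressing[~in_mask].sum(axis=0)
        p_w = _wilcoxon_vectorized(X, in_mask, precomputed=rank_pre)
        if wilcoxon_method == "exact" and n_in <= 8 and n_out <= 8:
            p_w = np.array(
                [wilcoxon_rank_sum(X[in_mask, j], X[~in_mask, j]) for j in range(X.shape[1])]
            )
        p_f = _fisher_vectorized(k_in, n_in, k_out, n_out)
        x_stat = -2.0 * (
            np.log(np.maximum(p_w, P_FLOOR)) + np.log(np.maximum(p_f, P_FLOOR))
        )
        p_comb = np.minimum(stats.chi2.sf(x_stat, df=4), 1.0)
        p_adj = bh_adjust(p_comb)
        rank_score = log2fc * (-np.log10(np.maximum(p_adj, P_FLOOR)))
        freq_in = k_in / n_in
        freq_out = k_out / max(n_out, 1)
        is_marker = (
            (np.abs(log2fc) >= cutoffs.min_abs_log2fc)
            & (p_adj < cutoffs.max_p_adj)
            & (freq_in > cutoffs.min_freq_in)
        )
        frames.append(
            pd.DataFrame(
                {
                    "cluster": c,
                    "gene": genes,
                    "log2fc": log2fc,
                    "p_wilcoxon": p_w,
                    "p_fisher": p_f,
                    "p_combined": p_comb,
                    "p_adj": p_adj,
                    "freq_in": freq_in,
                    "freq_out": freq_out,
                    "rank_score": rank_score,
                    "is_marker": is_marker,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.sort_values(
        ["cluster", "p_adj", "log2fc"],
        ascending=[True, True, False],
        inplace=True,
        kind="stable",
    )
    return table.reset_index(drop=True)


def preranked_scores(table: pd.DataFrame, cluster) -> pd.Series:
    """Ranked gene scores for GSEA: log2FC * (-log10 p_adj), descending.

    Ties are broken lexicographically by gene symbol. Returns a Series
    indexed by gene symbol.
    """
    sub = table[table["cluster"] == cluster]
    if sub.empty:
        raise KeyError(f"cluster {cluster!r} not in marker table")
    sub = sub.sort_values(
        ["rank_score", "gene"], ascending=[False, True], kind="stable"
    )
    return pd.Series(sub["rank_score"].to_numpy(), index=sub["gene"].to_numpy())
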