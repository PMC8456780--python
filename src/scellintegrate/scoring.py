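"""Gene-set scoring of single cells and threshold-based lineage classification.

Two scores are provided per cell and gene set: a rank-AUC (AUCell-style)
score — the area under the set's recovery curve within the top fraction of
each cell's expression ranking, normalized to [0, 1] — and the arithmetic
mean of log-normalized expression over the set. Cells are assigned to the
highest-scoring lineage when that score clears a cutoff (default 0.15),
otherwise they stay unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection
from .markers import bh_adjust, wilcoxon_rank_sum
from .preprocess import NormalizedMatrix


@dataclass
class SignatureScores:
    auc: pd.DataFrame  # cells x sets
    mean_score: pd.DataFrame | None
    rank_fraction: float = 0.05


@dataclass
class LineageCall:
    labels: np.ndarray  # lineage name or "unclassified" per cell
    threshold: float
    tie_flag: np.ndarray = field(default=None)  # type: ignore[assignment]


def _rank_matrix(X: np.ndarray, seed: int) -> np.ndarray:
    """Per-cell 1-based expression ranks (1 = highest expression).

    Ties are broken by a single seeded global shuffle of gene order applied
    before a stable sort, so tied genes fall in a fixed random order that is
    identical for every cell in the run.
    """
    n_cells, n_genes = X.shape
    rng = np.random.Generator(np.random.Philox(seed))
    perm = rng.permutation(n_genes)
    order_s = np.argsort(-X[:, perm], axis=1, kind="stable")
    ranks = np.empty((n_cells, n_genes), dtype=np.int32)
    np.put_along_axis(
        ranks, perm[order_s], np.tile(np.arange(1, n_genes + 1, dtype=np.int32), (n_cells, 1)),
        axis=1,
    )
    return ranks


def aucell_score(
    norm: NormalizedMatrix,
    sets: GeneSetCollection,
    rank_fraction: float = 0.05,
    seed: int = 0,
) -> SignatureScores:
    """Rank-AUC score per cell and gene set.

    With N panel genes and threshold T = ceil(rank_fraction * N), the raw
    area is the sum over ranks r = 1..T of the number of set genes recovered
    at or before r; it is normalized by the maximal area achievable by a
    fully front-loaded set of the same (panel-intersected) size.
    """
    if not 0 < rank_fraction <= 0.5:
        raise ValueError("rank_fraction must lie in (0, 0.5]")
    X = np.asarray(norm.values.todense(), dtype=float)
    n_genes = X.shape[1]
    T = int(np.ceil(rank_fraction * n_genes))
    ranks = _rank_matrix(X, seed)
    gene_index = {g: i for i, g in enumerate(norm.gene_ids.astype(str))}
    auc = {}
    for name in sets.names:
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if not idx:
            warnings.warn(f"set {name!r} has no genes on the panel; scores set to 0",
                          stacklevel=2)
            auc[name] = np.zeros(X.shape[0])
            continue
        m = len(idx)
        m_eff = min(m, T)
        max_area = m_eff * (m_eff + 1) / 2.0 + (T - m_eff) * m_eff
        r = ranks[:, idx]
        raw = np.clip(T - r + 1, 0, None).sum(axis=1)
        auc[name] = raw / max_area
    auc_df = pd.DataFrame(auc, index=norm.cell_ids.astype(str))
    return SignatureScores(auc=auc_df, mean_score=None, rank_fraction=rank_fraction)


def mean_signature_score(
    norm: NormalizedMatrix, sets: GeneSetCollection
) -> SignatureScores:
    """Per-cell arithmetic mean of log-normalized expression over each set."""
    gene_index = {g: i for i, g in enumerate(norm.gene_ids.astype(str))}
    out = {}
    for name in sets.names:
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        if not idx:
            warnings.warn(f"set {name!r} has no genes on the panel; scores set to 0",
                          stacklevel=2)
            out[name] = np.zeros(norm.n_cells)
            continue
        out[name] = np.asarray(norm.values[:, idx].mean(axis=1)).ravel()
    df = pd.DataFrame(out, index=norm.cell_ids.astype(str))
    return SignatureScores(auc=df * np.nan, mean_score=df, rank_fraction=np.nan)


def classify_lineage(
    scores: SignatureScores,
    lineage_sets: list[str] | None = None,
    threshold: float = 0.15,
    multi_label: bool = False,
):
    """Assign each cell to its maximum-scoring lineage above the threshold.

    Cells with no score strictly above ``threshold`` are "unclassified";
    exact ties at the maximum are "unclassified" with the tie flag set.
    With ``multi_label=True`` returns a boolean cells x lineages frame of
    all passing labels instead.
    """
    auc = scores.auc if lineage_sets is None else scores.auc[list(lineage_sets)]
    names = np.asarray(auc.columns, dtype=object)
    M = auc.to_numpy(dtype=float)
    if multi_label:
        return pd.DataFrame(M > threshold, index=auc.index, columns=auc.columns)
    best = M.max(axis=1)
    passing = best > threshold
    n_at_max = (M == best[:, None]).sum(axis=1)
    tie = passing & (n_at_max > 1)
    labels = np.full(M.shape[0], "unclassified", dtype=object)
    winners = names[np.argmax(M, axis=1)]
    labels[passing & ~tie] = winners[passing & ~tie]
    return LineageCall(labels=labels, threshold=threshold, tie_flag=tie)


def composition_by_group(call: LineageCall, groups: np.ndarray) -> pd.DataFrame:
    """Counts and fractions of lineage calls per group (e.g. per batch)."""
    df = pd.DataFrame({"group": groups, "lineage": call.labels})
    counts = df.groupby(["group", "lineage"], sort=True).size().rename("n").reset_index()
    totals = counts.groupby("group")["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    return counts


def compare_group_scores(
    scores: SignatureScores, groups: np.ndarray, use: str = "auc"
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon tests of set scores between groups.

    BH adjustment across all (set, pair) comparisons; significance tiers at
    0.05 / 0.01 / 0.001. Groups of size < 3 are skipped.
    """
    mat = scores.auc if use == "auc" else scores.mean_score
    if mat is None:
        raise ValueError(f"scores do not carry a {use!r} matrix")
    groups = np.asarray(groups, dtype=object)
    uniq = [g for g in pd.unique(pd.Series(groups)) if int(np.sum(groups == g)) >= 3]
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups of size >= 3")
    rows = []
    for s in mat.columns:
        v = mat[s].to_numpy(dtype=float)
        for i, g1 in enumerate(uniq):
            for g2 in uniq[i + 1 :]:
                p = wilcoxon_rank_sum(v[groups == g1], v[groups == g2])
                rows.append({"set_name": s, "group1": g1, "group2": g2, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["tier"] = pd.cut(
        out["p_adj"],
        bins=[-np.inf, 0.001, 0.01, 0.05, np.inf],
        labels=["***", "**", "*", "ns"],
    ).astype(str)
    return out
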