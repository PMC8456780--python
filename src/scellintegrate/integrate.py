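"""GSEA-supervised cross-sample cluster matching and prior-aware batch correction.

The supervised integration proceeds in two phases. First, every sample is
clustered on its own and a gene-set database is built from each cluster's
top markers; preranked GSEA of every cluster's ranked gene list against
every cluster-derived set yields a square matrix of cluster-matching scores
(positive NES at significance, else 0). Hierarchical clustering of that
matrix groups per-sample clusters into meta-clusters — "common" when they
span several samples, "unique" otherwise — and each cell receives a prior
probability vector concentrated on its own meta-cluster. Second, a
diversity-penalized soft-clustering correction (Harmony-style) consumes the
prior: soft assignments to K = #meta-clusters centroids under cosine
distance are multiplied by a batch-diversity factor and by prior**w, and a
per-cluster ridge regression removes batch/covariate effects from the
embedding, iterating to convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import CountMatrix, Embedding, GeneSetCollection, IntegrityError, QCThresholds
from .graph import ClusterAssignment, build_snn_graph, louvain_communities
from .gsea import gsea_preranked
from .markers import MarkerCutoffs, find_markers, preranked_scores
from .preprocess import filter_cells, filter_genes, normalize, run_pca, select_hvg

SEP = "|"
MIN_MARKERS_PER_SET = 5
TOP_MARKERS_PER_SET = 100


@dataclass
class MetaClusterMap:
    """Assignment of (sample, cluster) units to meta-clusters."""

    assignment: dict[str, int]  # "sample|cluster" -> meta id
    status: dict[int, str]  # meta id -> "common" | "unique"

    @property
    def n_meta(self) -> int:
        return len(self.status)


@dataclass
class PriorMatrix:
    probs: np.ndarray  # cells x meta-clusters, rows sum to 1
    confidence: float

    def __post_init__(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise IntegrityError("prior rows must sum to 1")
        if self.probs.min() < 0:
            raise IntegrityError("prior entries must be >= 0")


@dataclass
class HarmonyParams:
    n_clusters: int | None = None  # K; None = min(100, n_cells // 30)
    sigma: float = 0.1
    theta: float = 2.0
    lam: float = 1.0
    max_iter: int = 20
    tol: float = 1e-4
    prior_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.lam <= 0 or self.theta < 0:
            raise ValueError("sigma and lambda must be > 0, theta >= 0")
        if not 0.0 <= self.prior_weight <= 1.0:
            raise ValueError("prior_weight must lie in [0, 1]")


def unit_name(sample: str, cluster) -> str:
    return f"{sample}{SEP}{cluster}"


def parse_unit(name: str) -> tuple[str, str]:
    sample, cluster = name.rsplit(SEP, 1)
    return sample, cluster


def build_cluster_geneset_db(
    per_sample_markers: dict[str, pd.DataFrame],
    min_markers: int = MIN_MARKERS_PER_SET,
    top_n: int = TOP_MARKERS_PER_SET,
) -> GeneSetCollection:
    """One gene set per (sample, cluster) from its significant positive markers.

    Sets take the top ``top_n`` markers by rank score (positive log2FC only);
    clusters with fewer than ``min_markers`` markers are excluded with a
    warning, and a sample with no usable cluster raises.
    """
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for sample, table in per_sample_markers.items():
        usable = 0
        for c in sorted(pd.unique(table["cluster"])):
            sub = table[
                (table["cluster"] == c) & table["is_marker"] & (table["log2fc"] > 0)
            ]
            if len(sub) < min_markers:
                warnings.warn(
                    f"cluster {unit_name(sample, c)} has {len(sub)} < {min_markers} "
                    "markers; excluded from the gene-set database",
                    stacklevel=2,
                )
                continue
            sub = sub.sort_values(
                ["rank_score", "gene"], ascending=[False, True], kind="stable"
            ).head(top_n)
            name = unit_name(sample, c)
            sets[name] = sub["gene"].tolist()
            provenance[name] = f"top markers of cluster {c} in sample {sample}"
            usable += 1
        if usable == 0:
            raise IntegrityError(
                f"sample {sample!r} has no cluster with >= {min_markers} markers"
            )
    return GeneSetCollection(sets=sets, provenance=provenance)


def compute_match_matrix(
    per_sample_markers: dict[str, pd.DataFrame],
    db: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    p_adj_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Cluster-matching score matrix: rows are (sample, cluster) units, columns
    the database sets; entries are positive NES where the GSEA adjusted p is
    below the cutoff, else 0. Sequential over samples and clusters."""
    rows = {}
    offset = 0
    for sample, table in per_sample_markers.items():
        for c in sorted(pd.unique(table["cluster"])):
            name = unit_name(sample, c)
            ranked = preranked_scores(table, c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = gsea_preranked(ranked, db, n_perm=n_perm, seed=seed + offset)
            row = {r.set_name: (r.nes if (r.nes > 0 and r.p_adj < p_adj_cutoff) else 0.0)
                   for r in results}
            rows[name] = row
            offset += 1
    mat = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=db.names)
    return mat.fillna(0.0)


def match_clusters(match: pd.DataFrame) -> MetaClusterMap:
    """Group per-sample clusters into meta-clusters from their score profiles.

    Average-linkage hierarchical clustering on correlation distance between
    rows; the tree is cut at the k in [max per-sample cluster count,
    n_units - 1] that maximizes the mean silhouette. Meta-clusters spanning
    >= 2 samples are "common", single-member or single-sample ones "unique".
    """
    names = list(match.index)
    X = match.to_numpy(dtype=float)
    n = len(names)
    samples = [parse_unit(u)[0] for u in names]
    per_sample_counts = pd.Series(samples).value_counts()
    k_min = int(per_sample_counts.max())
    if np.allclose(X, 0.0):
        warnings.warn("all-zero match matrix; every cluster is unique", stacklevel=2)
        assignment = {u: i for i, u in enumerate(names)}
        status = {i: "unique" for i in range(n)}
        return MetaClusterMap(assignment=assignment, status=status)

    # correlation distance with a guard for zero-variance rows
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    safe = sd > 0
    corr = np.zeros((n, n))
    if safe.any():
        Z = Xc[safe] / sd[safe, None]
        corr[np.ix_(safe, safe)] = Z @ Z.T
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)

    condensed = sch.distance.squareform(dist, checks=False)
    tree = sch.linkage(condensed, method="average")
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in range(max(2, k_min), n):
        labels = sch.fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil > best_sil + 1e-12:
            best_k, best_sil, best_labels = k, sil, labels
    if best_labels is None:  # n too small to search: a single meta-cluster
        best_labels = np.ones(n, dtype=int)
    _, meta_ids = np.unique(best_labels, return_inverse=True)
    assignment = {u: int(m) for u, m in zip(names, meta_ids)}
    status = {}
    for m in np.unique(meta_ids):
        members = [names[i] for i in np.flatnonzero(meta_ids == m)]
        n_samples = len({parse_unit(u)[0] for u in members})
        status[int(m)] = "common" if n_samples >= 2 else "unique"
    return MetaClusterMap(assignment=assignment, status=status)


def build_prior_matrix(
    meta: MetaClusterMap, unit_of_cell: np.ndarray, confidence: float = 0.9
) -> PriorMatrix:
    """Per-cell prior over meta-clusters: probability w on the cell's own
    meta-cluster and (1 - w) / (M - 1) on each of the others."""
    M = meta.n_meta
    if M == 1:
        probs = np.ones((len(unit_of_cell), 1))
        return PriorMatrix(probs=probs, confidence=confidence)
    off = (1.0 - confidence) / (M - 1)
    probs = np.full((len(unit_of_cell), M), off)
    for i, u in enumerate(unit_of_cell):
        if u not in meta.assignment:
            raise IntegrityError(f"cell {i} belongs to unmapped cluster {u!r}")
        probs[i, meta.assignment[u]] = confidence
    return PriorMatrix(probs=probs, confidence=confidence)


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(pd.Series(labels)))
    mat = np.zeros((len(labels), len(levels)))
    for j, lv in enumerate(levels):
        mat[labels == lv, j] = 1.0
    return mat, levels


def harmony_correct(
    embedding: Embedding,
    batch: np.ndarray,
    covariates: np.ndarray | None = None,
    prior: PriorMatrix | None = None,
    params: HarmonyParams | None = None,
) -> Embedding:
    """Diversity-penalized soft-clustering batch correction with optional priors.

    Each round: (1) soft-assign cells to K centroids by cosine distance with
    entropy temperature sigma, multiply by the batch-diversity factor
    ((E+1)/(O+1))**theta and, when supplied, by prior**w, then row-normalize;
    (2) per cluster, ridge-regularized regression (lambda) removes the
    centered batch/covariate design from the embedding. Rounds repeat until
    the mean absolute change in assignments drops below tol. Deterministic
    for a fixed seed; a single batch level leaves the embedding unchanged.
    """
    params = params or HarmonyParams()
    Z = embedding.coords.copy()
    n, d = Z.shape
    if not np.all(np.isfinite(Z)):
        raise ValueError("embedding contains non-finite values")
    batch = np.asarray(batch, dtype=object)
    B, batch_levels = _one_hot(batch)
    design_blocks = [B - B.mean(axis=0, keepdims=True)]
    if covariates is not None:
        C, _ = _one_hot(np.asarray(covariates, dtype=object))
        design_blocks.append(C - C.mean(axis=0, keepdims=True))
    Cdes = np.hstack(design_blocks)  # centered covariate design (no intercept col)

    K = params.n_clusters
    if prior is not None:
        if K is not None and K != prior.probs.shape[1]:
            raise ValueError("n_clusters must equal the prior's meta-cluster count")
        K = prior.probs.shape[1]
        if prior.probs.shape[0] != n:
            raise IntegrityError("prior rows != number of cells")
    if K is None:
        K = max(min(100, n // 30), 2)

    log_prior = None
    if prior is not None and params.prior_weight > 0:
        log_prior = params.prior_weight * np.log(np.maximum(prior.probs, 1e-300))

    def _cosnorm(M: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.where(nrm > 0, nrm, 1.0)

    rng_state = int(params.seed)
    R_prev = None
    batch_props = B.mean(axis=0)
    O = E = None
    for _ in range(params.max_iter):
        Zcos = _cosnorm(Z - Z.mean(axis=0, keepdims=True))
        if R_prev is None:
            km = KMeans(n_clusters=K, n_init=3, random_state=rng_state)
            Y = _cosnorm(km.fit(Zcos).cluster_centers_)
        else:
            Y = _cosnorm(R_prev.T @ Zcos)
        log_R = (2.0 * (Zcos @ Y.T) - 2.0) / params.sigma  # -dist^2/sigma
        if O is not None and params.theta > 0:
            log_pen = params.theta * (np.log(E + 1.0) - np.log(O + 1.0))  # K x B
            log_R = log_R + (B @ log_pen.T)
        if log_prior is not None:
            log_R = log_R + log_prior
        log_R -= log_R.max(axis=1, keepdims=True)
        R = np.exp(log_R)
        R /= R.sum(axis=1, keepdims=True)
        O = R.T @ B  # K x n_batches observed soft counts
        E = np.outer(R.sum(axis=0), batch_props)

        # correction step: weighted ridge per cluster, intercept unpenalized
        D = np.hstack([np.ones((n, 1)), Cdes])
        p = D.shape[1]
        lam_diag = np.full(p, params.lam)
        lam_diag[0] = 0.0
        Znew = Z.copy()
        for k in range(K):
            w = R[:, k]
            Dw = D * w[:, None]
            A = D.T @ Dw + np.diag(lam_diag)
            Wk = np.linalg.solve(A, Dw.T @ Z)
            Znew -= (w[:, None] * Cdes) @ Wk[1:, :]
        delta = np.mean(np.abs(R - R_prev)) if R_prev is not None else np.inf
        Z = Znew
        R_prev = R
        if delta < params.tol:
            break
    return Embedding(coords=Z, name="harmony")


@dataclass
class IntegrationConfig:
    qc: QCThresholds | dict[str, QCThresholds] | None = None
    min_cells_per_gene: int = 10
    n_pcs: int = 40
    knn_k: int = 30
    marker_cutoffs: MarkerCutoffs = field(default_factory=MarkerCutoffs)
    n_perm: int = 1000
    prior_confidence: float = 0.9
    harmony: HarmonyParams = field(default_factory=HarmonyParams)
    seed: int = 0


@dataclass
class IntegrationResult:
    corrected: Embedding
    joint_pca: Embedding
    meta: MetaClusterMap
    match_matrix: pd.DataFrame
    prior: PriorMatrix
    unit_of_cell: np.ndarray
    per_sample_clusters: dict[str, ClusterAssignment]
    per_sample_markers: dict[str, pd.DataFrame]
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray
    manifest: dict


def cluster_sample(
    matrix: CountMatrix, config: IntegrationConfig, seed: int
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Normalize, select HVG, run PCA, build the SNN graph and Louvain-cluster
    one sample; returns the assignment and its marker table."""
    norm = normalize(matrix)
    hvg = select_hvg(norm)
    n_pcs = min(config.n_pcs, min(matrix.n_cells, len(hvg.selected_genes)) - 1)
    emb = run_pca(norm, hvg, n_pcs=n_pcs)
    graph = build_snn_graph(emb, k=min(config.knn_k, matrix.n_cells - 1), seed=seed)
    clusters = louvain_communities(graph, seed=seed)
    table = find_markers(norm, clusters, cutoffs=config.marker_cutoffs)
    return clusters, table


def run_supervised_integration(
    matrices: dict[str, CountMatrix] | CountMatrix,
    config: IntegrationConfig | None = None,
) -> IntegrationResult:
    """End-to-end supervised integration over >= 2 samples.

    Orchestrates per-sample preprocessing, clustering and marker detection;
    builds the cluster gene-set database and GSEA match matrix; groups
    clusters into meta-clusters; constructs per-cell priors; and applies the
    prior-aware correction to the joint PCA embedding.
    """
    config = config or IntegrationConfig()
    if isinstance(matrices, CountMatrix):
        matrices = {
            s: matrices.subset_cells(matrices.sample_of_cell == s)
            for s in matrices.samples
        }
    if len(matrices) < 2:
        raise ValueError("integration requires >= 2 samples")

    per_sample: dict[str, CountMatrix] = {}
    clusters: dict[str, ClusterAssignment] = {}
    tables: dict[str, pd.DataFrame] = {}
    for i, (sample, m) in enumerate(matrices.items()):
        if config.qc is not None:
            thr = config.qc if isinstance(config.qc, QCThresholds) else {sample: config.qc[sample]}
            m = filter_cells(m, thr)
        m = filter_genes(m, config.min_cells_per_gene)
        per_sample[sample] = m
        cl, table = cluster_sample(m, config, seed=config.seed + 11 * i)
        clusters[sample] = cl
        tables[sample] = table

    db = build_cluster_geneset_db(tables)
    match = compute_match_matrix(tables, db, n_perm=config.n_perm, seed=config.seed)
    meta = match_clusters(match)

    # joint matrix over the common gene panel, in sample order
    common = set(per_sample[next(iter(per_sample))].gene_ids)
    for m in per_sample.values():
        common &= set(m.gene_ids)
    joint_blocks, unit_of_cell, cell_ids, sample_of_cell = [], [], [], []
    for sample, m in per_sample.items():
        keep = np.isin(m.gene_ids, sorted(common))
        sub = m.subset_genes(keep)
        order = np.argsort(sub.gene_ids)
        joint_blocks.append(sub.subset_genes(order))
        unit_of_cell.extend(unit_name(sample, c) for c in clusters[sample].labels)
        cell_ids.extend(sub.cell_ids)
        sample_of_cell.extend([sample] * sub.n_cells)
    import scipy.sparse as sp

    joint = CountMatrix(
        values=sp.vstack([b.values for b in joint_blocks]).tocsr(),
        cell_ids=np.asarray(cell_ids, dtype=object),
        gene_ids=joint_blocks[0].gene_ids,
        sample_of_cell=np.asarray(sample_of_cell, dtype=object),
    )
    norm = normalize(joint)
    hvg = select_hvg(norm)
    n_pcs = min(config.n_pcs, min(joint.n_cells, len(hvg.selected_genes)) - 1)
    joint_pca = run_pca(norm, hvg, n_pcs=n_pcs)

    prior = build_prior_matrix(
        meta, np.asarray(unit_of_cell, dtype=object), confidence=config.prior_confidence
    )
    hp = HarmonyParams(**{**config.harmony.__dict__})
    hp.n_clusters = meta.n_meta
    hp.seed = config.seed
    corrected = harmony_correct(
        joint_pca, joint.sample_of_cell, covariates=None, prior=prior, params=hp
    )
    manifest = {
        "samples": list(per_sample),
        "n_cells": joint.n_cells,
        "n_genes": joint.n_genes,
        "n_meta_clusters": meta.n_meta,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "harmony": hp.__dict__,
    }
    return IntegrationResult(
        corrected=corrected,
        joint_pca=joint_pca,
        meta=meta,
        match_matrix=match,
        prior=prior,
        unit_of_cell=np.asarray(unit_of_cell, dtype=object),
        per_sample_clusters=clusters,
        per_sample_markers=tables,
        cell_ids=joint.cell_ids,
        sample_of_cell=joint.sample_of_cell,
        manifest=manifest,
    )
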