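"""Quality control, normalization, variable-gene selection and PCA.

The stages mirror standard scRNA-seq preprocessing: per-sample cell QC,
gene prevalence filtering, library-size normalization to a fixed total with
log1p transform, Brennecke-style highly-variable-gene selection (gamma GLM
of squared coefficient of variation against reciprocal mean), and truncated
SVD of the scaled HVG submatrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import CountMatrix, Embedding, QCThresholds

SCALE_TOTAL = 10_000.0

_MITO_RE = re.compile(r"^MT-", re.IGNORECASE)
_RIBO_RE = re.compile(r"^RP[SL]", re.IGNORECASE)


def is_mito(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([bool(_MITO_RE.match(str(g))) for g in gene_ids])


def is_ribo(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([bool(_RIBO_RE.match(str(g))) for g in gene_ids])


@dataclass
class NormalizedMatrix:
    """log1p-normalized expression, cells x genes, natural log, total 10,000."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray
    scale_total: float = SCALE_TOTAL

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class HVGResult:
    """Selected highly variable genes plus the fitted mean-CV^2 trend."""

    selected_genes: list[str]
    fit_params: dict[str, float]
    per_gene: pd.DataFrame = field(repr=False)


def cell_qc_stats(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell UMI total, detected-gene count and mitochondrial fraction."""
    v = matrix.values
    umi = np.asarray(v.sum(axis=1)).ravel()
    detected = np.asarray((v > 0).sum(axis=1)).ravel()
    mito_mask = is_mito(matrix.gene_ids)
    if mito_mask.any():
        mito = np.asarray(v[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umi > 0, mito / np.maximum(umi, 1), 0.0)
    return pd.DataFrame(
        {"umi": umi, "n_genes": detected, "mito_fraction": frac},
        index=matrix.cell_ids.astype(str),
    )


def filter_cells(
    matrix: CountMatrix, thresholds: QCThresholds | dict[str, QCThresholds]
) -> CountMatrix:
    """Remove low-quality cells, per sample.

    Keeps cells with UMI > min_umi and <= max_umi, detected genes > min_genes
    and <= max_genes, mito fraction <= max_mito_fraction. ``thresholds`` may
    be a single QCThresholds applied everywhere or a per-sample dict that
    must cover every sample present.
    """
    if isinstance(thresholds, QCThresholds):
        per_sample = {s: thresholds for s in matrix.samples}
    else:
        per_sample = thresholds
        missing = [s for s in matrix.samples if s not in per_sample]
        if missing:
            raise ValueError(f"no QC thresholds for samples: {missing}")
    stats_df = cell_qc_stats(matrix)
    keep = np.zeros(matrix.n_cells, dtype=bool)
    for s, thr in per_sample.items():
        in_sample = matrix.sample_of_cell == s
        keep |= (
            in_sample
            & (stats_df["umi"].to_numpy() > thr.min_umi)
            & (stats_df["umi"].to_numpy() <= thr.max_umi)
            & (stats_df["n_genes"].to_numpy() > thr.min_genes)
            & (stats_df["n_genes"].to_numpy() <= thr.max_genes)
            & (stats_df["mito_fraction"].to_numpy() <= thr.max_mito_fraction)
        )
    return matrix.subset_cells(keep)


def filter_genes(matrix: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_expr = np.asarray((matrix.values > 0).sum(axis=0)).ravel()
    return matrix.subset_genes(n_expr >= min_cells)


def normalize(matrix: CountMatrix, scale_total: float = SCALE_TOTAL) -> NormalizedMatrix:
    """value(c, g) = ln(1 + scale_total * count(c, g) / total(c)).

    Cells with zero total stay all-zero (with a warning).
    """
    v = sp.csr_matrix(matrix.values, dtype=float)
    totals = np.asarray(v.sum(axis=1)).ravel()
    if np.any(totals == 0):
        warnings.warn(
            f"{int(np.sum(totals == 0))} cells have zero total counts; rows left at zero",
            stacklevel=2,
        )
    scale = np.where(totals > 0, scale_total / np.maximum(totals, 1.0), 0.0)
    v = sp.diags(scale) @ v
    v.data = np.log1p(v.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(v),
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        sample_of_cell=matrix.sample_of_cell,
        scale_total=scale_total,
    )


def _sparse_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[0]
    mean = np.asarray(values.mean(axis=0)).ravel()
    sq = values.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(
    norm: NormalizedMatrix,
    alpha: float = 0.05,
    min_mean: float = 1e-3,
    exclude_ribo_mito: bool = True,
) -> HVGResult:
    """Select highly variable genes by a gamma-GLM mean-CV^2 trend.

    De-logged normalized expression per gene is summarized by its mean mu and
    squared coefficient of variation CV^2 = var / mu^2. The technical trend
    CV^2 ~ a1 / mu + a0 is fitted by a gamma-family GLM with identity link
    (iteratively reweighted least squares); a gene's departure above the
    trend is scored with the chi-square statistic (n-1) * CV^2 / CV^2_trend,
    upper tail, BH-adjusted. Genes with adjusted p < alpha and positive
    residual are selected, excluding ribosomal (RPS*/RPL*) and mitochondrial
    (MT-*) symbols.
    """
    expm1 = norm.values.copy()
    expm1.data = np.expm1(expm1.data)
    mean, var = _sparse_mean_var(sp.csr_matrix(expm1))
    n = norm.n_cells
    testable = mean > min_mean
    if int(testable.sum()) < 100:
        raise ValueError("need >= 100 genes with nonzero mean to fit the trend")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(testable, var / np.maximum(mean, 1e-300) ** 2, np.nan)

    mu_t = mean[testable]
    cv2_t = cv2[testable]
    # Fit on genes below the upper CV^2 quantile so outliers (true HVGs) do
    # not drag the technical trend up.
    fit_mask = cv2_t <= np.nanquantile(cv2_t, 0.95)
    import statsmodels.api as sm

    X = sm.add_constant(1.0 / mu_t[fit_mask])
    y = cv2_t[fit_mask]
    try:
        with warnings.catch_warnings():
            # identity link on the Gamma family is the intended trend model
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
            res = glm.fit()
        a0, a1 = float(res.params[0]), float(res.params[1])
    except Exception as exc:  # noqa: BLE001
        raise np.linalg.LinAlgError(
            f"gamma GLM trend fit failed (singular or degenerate design): {exc}"
        ) from exc
    trend = a1 / mu_t + a0
    trend = np.maximum(trend, 1e-12)
    ratio = cv2_t / trend
    pvals = stats.chi2.sf(ratio * (n - 1), df=n - 1)
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(pvals, method="fdr_bh")[1]
    residual = cv2_t - trend

    selected_mask_t = (padj < alpha) & (residual > 0)
    per_gene = pd.DataFrame(
        {
            "mean": mean,
            "cv2": cv2,
            "trend": np.nan,
            "residual": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
            "selected": False,
        },
        index=norm.gene_ids.astype(str),
    )
    t_idx = np.flatnonzero(testable)
    per_gene.iloc[t_idx, per_gene.columns.get_loc("trend")] = trend
    per_gene.iloc[t_idx, per_gene.columns.get_loc("residual")] = residual
    per_gene.iloc[t_idx, per_gene.columns.get_loc("p")] = pvals
    per_gene.iloc[t_idx, per_gene.columns.get_loc("p_adj")] = padj
    sel = np.zeros(norm.n_genes, dtype=bool)
    sel[t_idx[selected_mask_t]] = True
    if exclude_ribo_mito:
        sel &= ~(is_ribo(norm.gene_ids) | is_mito(norm.gene_ids))
    per_gene["selected"] = sel
    return HVGResult(
        selected_genes=[str(g) for g in norm.gene_ids[sel]],
        fit_params={"a0": a0, "a1": a1},
        per_gene=per_gene,
    )


def run_pca(
    norm: NormalizedMatrix,
    hvg: HVGResult | list[str],
    n_pcs: int = 40,
    scale_cap: float = 10.0,
) -> Embedding:
    """Truncated SVD of the centered, unit-scaled HVG submatrix.

    Per-gene z-scores are capped at ``scale_cap`` standard deviations to
    bound outlier leverage. Components are ordered by decreasing singular
    value with the sign convention that the largest-absolute loading of each
    component is positive.
    """
    genes = hvg.selected_genes if isinstance(hvg, HVGResult) else list(hvg)
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    cols = [gene_index[g] for g in genes if g in gene_index]
    if not cols:
        raise ValueError("no HVG present in the matrix")
    if n_pcs >= min(norm.n_cells, len(cols)):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(n_cells={norm.n_cells}, n_hvg={len(cols)})"
        )
    X = np.asarray(norm.values[:, cols].todense(), dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -scale_cap, scale_cap)
    # X is centered (up to clipping); dense SVD keeps the result exact and
    # deterministic at this scale.
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    signs = np.sign(Vt[np.arange(n_pcs), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    coords = U * S * signs
    return Embedding(coords=coords, name="pca")
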