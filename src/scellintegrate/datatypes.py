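"""Shared data model for the integration pipeline.

The containers are deliberately small: a sparse UMI matrix with cell/gene
metadata, QC thresholds, gene-set collections, and low-dimensional
embeddings. Each validates its own invariants on construction so that
downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """A file or table does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """Internally inconsistent data (dimension or label mismatches)."""


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes, with sample annotations.

    Parameters
    ----------
    values
        Non-negative integer counts, CSR, shape (n_cells, n_genes).
    cell_ids
        Unique barcode strings, one per row.
    gene_ids
        Unique gene symbols, one per column.
    sample_of_cell
        Sample label per cell.
    tissue_of_sample
        Optional map from sample label to tissue label.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray
    tissue_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise IntegrityError(
                f"{len(self.cell_ids)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_ids)} genes for {n_genes} matrix columns"
            )
        if len(self.sample_of_cell) != n_cells:
            raise IntegrityError("sample_of_cell length != number of cells")
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("cell barcodes are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene symbols are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise IntegrityError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample labels in order of first appearance."""
        return list(pd.unique(pd.Series(self.sample_of_cell)))

    def subset_cells(self, mask_or_index: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            values=self.values[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            sample_of_cell=self.sample_of_cell[idx],
            tissue_of_sample=dict(self.tissue_of_sample),
        )

    def subset_genes(self, mask_or_index: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            values=sp.csr_matrix(self.values[:, idx]),
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            sample_of_cell=self.sample_of_cell,
            tissue_of_sample=dict(self.tissue_of_sample),
        )

    def to_anndata(self):
        """Bridge to an AnnData object (requires the optional anndata dep)."""
        import anndata as ad

        obs = pd.DataFrame(
            {"sample": pd.Categorical(self.sample_of_cell)},
            index=pd.Index(self.cell_ids.astype(str), name="barcode"),
        )
        if self.tissue_of_sample:
            obs["tissue"] = [
                self.tissue_of_sample.get(s, "NA") for s in self.sample_of_cell
            ]
        var = pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene"))
        return ad.AnnData(X=self.values.copy(), obs=obs, var=var)


@dataclass
class QCThresholds:
    """Per-sample cell/gene quality-control cutoffs.

    Cells are kept when UMI total > ``min_umi`` and <= ``max_umi``, detected
    genes > ``min_genes`` and <= ``max_genes``, and mitochondrial fraction
    <= ``max_mito_fraction`` (strict/inclusive senses follow the filtering
    contract exactly).
    """

    min_umi: int = 1000
    max_umi: float = np.inf
    min_genes: int = 500
    max_genes: float = np.inf
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.min_umi > self.max_umi or self.min_genes > self.max_genes:
            raise ValueError("min threshold exceeds max threshold")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. lineage signatures or per-cluster marker sets)."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            provenance={n: self.provenance.get(n, "") for n in names},
        )


@dataclass
class Embedding:
    """Dense low-dimensional representation of cells (PCA, corrected PCA...)."""

    coords: np.ndarray
    name: str = "pca"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("embedding coords must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]
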