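"""Readers/writers for 10x-style matrices, GMT gene sets and TSV tables."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import CountMatrix, FormatError, GeneSetCollection, IntegrityError, QCThresholds

# v2 layout uses genes.tsv / barcodes.tsv / matrix.mtx; v3 gzips everything
# and renames genes.tsv to features.tsv. Both appear in GEO deposits.
_MATRIX_NAMES = ["matrix.mtx", "matrix.mtx.gz"]
_GENE_NAMES = ["genes.tsv", "genes.tsv.gz", "features.tsv", "features.tsv.gz"]
_BARCODE_NAMES = ["barcodes.tsv", "barcodes.tsv.gz"]


def _find_file(dir_path: Path, candidates: list[str]) -> Path:
    for name in candidates:
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(
        f"none of {candidates} found in {dir_path}"
    )


def _read_tsv_column(path: Path, column: int) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    out: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            out.append(fields[min(column, len(fields) - 1)])
    return out


def _dedupe_symbols(symbols: list[str]) -> tuple[np.ndarray, dict[str, str]]:
    """Disambiguate duplicate gene symbols with a numeric suffix."""
    seen: dict[str, int] = {}
    out = []
    provenance: dict[str, str] = {}
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            provenance[new] = f"duplicate of symbol {s}"
            out.append(new)
        else:
            seen[s] = 0
            out.append(s)
    return np.asarray(out, dtype=object), provenance


def read_10x_matrix(dir_path: str | Path, sample: str | None = None) -> CountMatrix:
    """Read a 10x-style Matrix Market directory into a CountMatrix.

    Accepts both v2 (``genes.tsv``) and v3 (``features.tsv.gz``) layouts,
    plain or gzipped. The on-disk orientation (genes x cells) is transposed
    to cells x genes. ``sample`` defaults to the directory name.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"not a directory: {dir_path}")
    mtx_path = _find_file(dir_path, _MATRIX_NAMES)
    gene_path = _find_file(dir_path, _GENE_NAMES)
    barcode_path = _find_file(dir_path, _BARCODE_NAMES)

    try:
        m = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
    m = sp.csr_matrix(m.T)  # cells x genes

    # features.tsv has (id, symbol, type); genes.tsv has (id, symbol). Use
    # the symbol column when present, else the sole column.
    symbols = _read_tsv_column(gene_path, 1)
    barcodes = _read_tsv_column(barcode_path, 0)
    if len(symbols) != m.shape[1]:
        raise IntegrityError(
            f"{gene_path.name} lists {len(symbols)} genes but matrix has {m.shape[1]}"
        )
    if len(barcodes) != m.shape[0]:
        raise IntegrityError(
            f"{barcode_path.name} lists {len(barcodes)} barcodes but matrix has {m.shape[0]}"
        )
    gene_ids, provenance = _dedupe_symbols(symbols)
    sample = sample if sample is not None else dir_path.name
    cm = CountMatrix(
        values=m,
        cell_ids=np.asarray(barcodes, dtype=object),
        gene_ids=gene_ids,
        sample_of_cell=np.full(m.shape[0], sample, dtype=object),
    )
    return cm


def write_10x_matrix(matrix: CountMatrix, dir_path: str | Path) -> None:
    """Write a CountMatrix as an uncompressed v2-style 10x directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(matrix.values.T))
    with open(dir_path / "genes.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for b in matrix.cell_ids:
            fh.write(f"{b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (name, description, genes...).

    Duplicate genes within a set are dropped keeping the first occurrence;
    duplicate set names raise a format error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = deduped
            provenance[name] = desc
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def downsample_equal(
    matrix: CountMatrix, n_per_group: int, group_key: np.ndarray | str, seed: int
) -> CountMatrix:
    """Sample exactly ``n_per_group`` cells per group without replacement.

    ``group_key`` is either "sample" (use the sample labels) or an explicit
    per-cell label array. Raises if any group is smaller than the request.
    """
    if isinstance(group_key, str):
        if group_key != "sample":
            raise ValueError("group_key must be 'sample' or a per-cell label array")
        labels = matrix.sample_of_cell
    else:
        labels = np.asarray(group_key, dtype=object)
        if len(labels) != matrix.n_cells:
            raise IntegrityError("group label length != number of cells")
    groups = list(pd.unique(pd.Series(labels)))
    deficient = [
        str(g) for g in groups if int(np.sum(labels == g)) < n_per_group
    ]
    if deficient:
        raise ValueError(
            f"groups smaller than n_per_group={n_per_group}: {', '.join(deficient)}"
        )
    rng = np.random.Generator(np.random.Philox(seed))
    keep: list[np.ndarray] = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        keep.append(rng.choice(idx, size=n_per_group, replace=False))
    order = np.sort(np.concatenate(keep))
    return matrix.subset_cells(order)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, tissue, path, QC columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a sample_id column")
    return df


def thresholds_from_metadata(row: pd.Series) -> QCThresholds:
    """Build QCThresholds from one metadata row; missing columns use defaults."""

    def _get(col: str, default: float) -> float:
        if col in row.index and pd.notna(row[col]) and str(row[col]) != "":
            return float(row[col])
        return default

    return QCThresholds(
        min_umi=int(_get("min_umi", 1000)),
        max_umi=_get("max_umi", np.inf),
        min_genes=int(_get("min_genes", 500)),
        max_genes=_get("max_genes", np.inf),
        max_mito_fraction=_get("max_mito_fraction", 0.10),
        min_cells_per_gene=int(_get("min_cells_per_gene", 10)),
    )


def write_manifest(path: str | Path, **entries) -> None:
    """Write a run manifest (inputs, parameters, seeds, versions) as JSON."""
    from . import __version__

    payload = {"tool": "scellintegrate", "version": __version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
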