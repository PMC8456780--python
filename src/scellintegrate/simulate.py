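"""Multi-batch scRNA-seq count simulator with planted ground truth.

The generative model: per-gene baseline rates are gamma-distributed; each
cell type multiplies its (disjoint) marker genes by 2**marker_log2fc; each
batch multiplies every gene by an independent log-normal factor (the batch
effect); per-cell rates are renormalized and scaled to a log-normal library
size; UMI counts are negative binomial (gamma-Poisson) with a shared
dispersion. All randomness flows through a counter-based Philox generator,
so a seed fully determines the output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datatypes import CountMatrix, GeneSetCollection


@dataclass
class SimConfig:
    """Simulation parameters; defaults match the canonical benchmark scenario."""

    n_batches: int = 3
    cells_per_batch: int = 2000
    n_genes: int = 2000
    n_types: int = 5
    # types present per batch (indices into 0..n_types-1); None = all types
    types_per_batch: list[list[int]] | None = None
    # per-batch proportions over the types present; None = equal
    type_proportions: list[list[float]] | None = None
    markers_per_type: int = 40
    marker_log2fc: float = 3.0
    baseline_shape: float = 0.6
    baseline_scale: float = 2.0
    nb_dispersion: float = 2.0
    library_mean: float = 2500.0
    library_sd_log: float = 0.3
    batch_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                "markers_per_type x n_types exceeds n_genes; infeasible config"
            )
        if self.types_per_batch is not None:
            for t in self.types_per_batch:
                if not t or max(t) >= self.n_types:
                    raise ValueError("types_per_batch entries must index valid types")
        if self.type_proportions is not None:
            for p in self.type_proportions:
                if abs(sum(p) - 1.0) > 1e-9 or min(p) <= 0:
                    raise ValueError("per-batch type proportions must be positive and sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated CountMatrix."""

    type_of_cell: np.ndarray
    batch_of_cell: np.ndarray
    markers: dict[str, list[str]]
    batch_effects: np.ndarray = field(repr=False)  # n_batches x n_genes
    seed: int = 0

    @property
    def types(self) -> list[str]:
        return list(self.markers)


def simulate(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a multi-batch count matrix plus its ground truth from ``config``."""
    rng = np.random.Generator(np.random.Philox(config.seed))
    G, T, B = config.n_genes, config.n_types, config.n_batches
    gene_ids = np.array([f"G{j:04d}" for j in range(G)], dtype=object)
    type_names = [f"type{t}" for t in range(T)]
    batch_names = [f"batch{b + 1}" for b in range(B)]

    baseline = rng.gamma(config.baseline_shape, config.baseline_scale, size=G)
    baseline = np.maximum(baseline, 1e-6)

    # markers emulate canonical lineage genes, which are robustly expressed:
    # they are planted on the upper half of the baseline-rate distribution
    # (a silent gene could never satisfy an expressing-frequency cutoff,
    # whatever its fold change)
    n_markers = config.markers_per_type * T
    expressed_pool = np.argsort(-baseline)[: max(G // 2, n_markers)]
    marker_pool = rng.permutation(expressed_pool)[:n_markers]
    markers = {
        type_names[t]: sorted(
            gene_ids[marker_pool[t * config.markers_per_type : (t + 1) * config.markers_per_type]]
        )
        for t in range(T)
    }
    marker_idx = {
        t: marker_pool[t * config.markers_per_type : (t + 1) * config.markers_per_type]
        for t in range(T)
    }

    type_rates = np.tile(baseline, (T, 1))
    for t in range(T):
        type_rates[t, marker_idx[t]] *= 2.0**config.marker_log2fc

    batch_effects = (
        rng.lognormal(mean=0.0, sigma=config.batch_effect_sd, size=(B, G))
        if config.batch_effect_sd > 0
        else np.ones((B, G))
    )

    types_per_batch = (
        config.types_per_batch
        if config.types_per_batch is not None
        else [list(range(T)) for _ in range(B)]
    )

    counts_blocks = []
    type_labels: list[str] = []
    batch_labels: list[str] = []
    cell_ids: list[str] = []
    r = config.nb_dispersion
    for b in range(B):
        present = types_per_batch[b]
        props = (
            np.asarray(config.type_proportions[b])
            if config.type_proportions is not None
            else np.full(len(present), 1.0 / len(present))
        )
        if len(props) != len(present):
            raise ValueError("type_proportions shape does not match types_per_batch")
        cell_types = rng.choice(present, size=config.cells_per_batch, p=props)
        libs = rng.lognormal(
            mean=np.log(config.library_mean), sigma=config.library_sd_log,
            size=config.cells_per_batch,
        )
        rates = type_rates[cell_types] * batch_effects[b][None, :]
        rates = rates / rates.sum(axis=1, keepdims=True)
        mu = rates * libs[:, None]
        lam = rng.gamma(shape=r, scale=mu / r)
        counts_blocks.append(rng.poisson(lam))
        type_labels.extend(type_names[t] for t in cell_types)
        batch_labels.extend([batch_names[b]] * config.cells_per_batch)
        cell_ids.extend(
            f"{batch_names[b]}_cell{i:05d}" for i in range(config.cells_per_batch)
        )

    counts = sp.csr_matrix(np.vstack(counts_blocks))
    matrix = CountMatrix(
        values=counts,
        cell_ids=np.asarray(cell_ids, dtype=object),
        gene_ids=gene_ids,
        sample_of_cell=np.asarray(batch_labels, dtype=object),
        tissue_of_sample={b: "synthetic" for b in batch_names},
    )
    truth = SyntheticTruth(
        type_of_cell=np.asarray(type_labels, dtype=object),
        batch_of_cell=np.asarray(batch_labels, dtype=object),
        markers=markers,
        batch_effects=batch_effects,
        seed=config.seed,
    )
    return matrix, truth


def truth_gene_sets(truth: SyntheticTruth) -> GeneSetCollection:
    """One gene set per simulated type, from its planted marker list."""
    if not truth.markers:
        raise ValueError("truth carries no cell types")
    return GeneSetCollection(
        sets={t: list(g) for t, g in truth.markers.items()},
        provenance={t: "planted synthetic markers" for t in truth.markers},
    )


BENCHMARK_SEED = 20210914


def default_benchmark() -> tuple[CountMatrix, SyntheticTruth]:
    """The canonical 3-batch benchmark: 4 shared types everywhere plus one
    type (type4) unique to batch 3; 2,000 cells/batch, 2,000 genes, 40
    markers/type at log2FC 3, batch effect SD 0.5, fixed seed."""
    config = SimConfig(
        n_batches=3,
        cells_per_batch=2000,
        n_genes=2000,
        n_types=5,
        types_per_batch=[[0, 1, 2, 3], [0, 1, 2, 3], [0, 1, 2, 3, 4]],
        type_proportions=[[0.25] * 4, [0.25] * 4, [0.2] * 5],
        markers_per_type=40,
        marker_log2fc=3.0,
        batch_effect_sd=0.5,
        seed=BENCHMARK_SEED,
    )
    return simulate(config)
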