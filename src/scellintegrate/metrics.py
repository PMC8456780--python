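"""Batch-mixing and cell-type-purity metrics on an embedding.

kBET: for cells of a group, a chi-square goodness-of-fit test compares the
batch composition of each cell's k0 nearest neighbors against the group's
global batch composition; the acceptance rate is the fraction of tested
cells with p >= alpha. LISI: the inverse Simpson index of the batch (iLISI)
or cell-type (cLISI) label distribution in a Gaussian neighborhood whose
bandwidth is calibrated per cell to a target perplexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .datatypes import Embedding


@dataclass
class MetricReport:
    kbet_acceptance: dict[str, float]
    ilisi_median: float
    clisi_median: float
    ilisi: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    clisi: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    params: dict = field(default_factory=dict)


def _chi2_gof_p(observed: np.ndarray, expected: np.ndarray,
                rng: np.random.Generator | None, n_draws: int = 2000) -> float:
    """Chi-square GOF p; Monte-Carlo multinomial fallback for small expecteds."""
    k0 = observed.sum()
    keep = expected > 0
    obs, exp = observed[keep], expected[keep]
    stat = float(((obs - exp) ** 2 / exp).sum())
    if exp.min() >= 5 or rng is None:
        return float(stats.chi2.sf(stat, df=max(len(exp) - 1, 1)))
    draws = rng.multinomial(int(k0), exp / exp.sum(), size=n_draws)
    stats_null = ((draws - exp) ** 2 / exp).sum(axis=1)
    return float((1 + np.sum(stats_null >= stat - 1e-12)) / (n_draws + 1))


def kbet_acceptance(
    embedding: Embedding,
    batch: np.ndarray,
    group: np.ndarray | None = None,
    k0: int | None = None,
    alpha: float = 0.05,
    subsample: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """kBET acceptance rate per group.

    ``group`` partitions cells (e.g. annotated lineage); ``None`` treats all
    cells as one group. ``k0`` defaults to min(ceil(0.1 * group size), 100).
    Returns {group: fraction of tested cells whose neighborhood batch
    composition is compatible with the group's global composition}.
    """
    coords = embedding.coords
    batch = np.asarray(batch, dtype=object)
    group = (
        np.full(len(batch), "all", dtype=object) if group is None
        else np.asarray(group, dtype=object)
    )
    rng = np.random.Generator(np.random.Philox(seed))
    out: dict[str, float] = {}
    batch_levels = pd.unique(pd.Series(batch))
    for g in pd.unique(pd.Series(group)):
        idx = np.flatnonzero(group == g)
        k0_g = k0 if k0 is not None else min(int(np.ceil(0.1 * len(idx))), 100)
        if len(idx) < k0_g + 1:
            warnings.warn(f"group {g!r} has < k0+1 cells; skipped", stacklevel=2)
            continue
        g_batch = batch[idx]
        levels_here = [b for b in batch_levels if np.any(g_batch == b)]
        if len(levels_here) < 2:
            out[str(g)] = 1.0  # degenerate single-batch test accepts
            continue
        props = np.array([np.mean(g_batch == b) for b in levels_here])
        test_idx = (
            rng.choice(len(idx), size=subsample, replace=False)
            if len(idx) > subsample
            else np.arange(len(idx))
        )
        nn = NearestNeighbors(n_neighbors=k0_g + 1).fit(coords[idx])
        _, nbrs = nn.kneighbors(coords[idx[test_idx]])
        nbrs = nbrs[:, 1:]  # drop self
        expected = k0_g * props
        accept = 0
        for row in nbrs:
            obs = np.array([np.sum(g_batch[row] == b) for b in levels_here], dtype=float)
            p = _chi2_gof_p(obs, expected, rng)
            accept += p >= alpha
        out[str(g)] = accept / len(test_idx)
    return out


def _perplexity_weights(d2_row: np.ndarray, perplexity: float,
                        tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Gaussian weights over neighbors with entropy log(perplexity), by
    bisection on the precision beta (t-SNE style calibration)."""
    target = np.log(perplexity)
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
    d2 = d2_row - d2_row.min()
    for _ in range(max_iter):
        w = np.exp(-d2 * beta)
        sw = w.sum()
        if sw <= 0:
            w = np.ones_like(d2)
            sw = w.sum()
        p = w / sw
        h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        if abs(h - target) < tol:
            break
        if h > target:  # too flat -> increase beta
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
        else:
            beta_hi = beta
            beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
    return p


def lisi(
    embedding: Embedding, labels: np.ndarray, perplexity: int = 30
) -> np.ndarray:
    """Per-cell inverse Simpson index of labels in a perplexity-weighted
    neighborhood: 1 = locally pure, #labels = perfectly mixed."""
    labels = np.asarray(labels, dtype=object)
    n = embedding.n_cells
    levels, lab_idx = np.unique(labels.astype(str), return_inverse=True)
    if len(levels) == 1:
        return np.ones(n)
    k = min(perplexity * 3, n - 1)
    if n < perplexity * 3:
        warnings.warn(
            f"{n} cells < 3x perplexity ({perplexity}); LISI may be unstable",
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coords)
    dist, nbrs = nn.kneighbors(embedding.coords)
    dist, nbrs = dist[:, 1:], nbrs[:, 1:]
    out = np.empty(n)
    d2 = dist**2
    for i in range(n):
        p = _perplexity_weights(d2[i], perplexity)
        mass = np.bincount(lab_idx[nbrs[i]], weights=p, minlength=len(levels))
        out[i] = 1.0 / np.sum(mass**2)
    return out


def metric_report(
    embedding: Embedding,
    batch: np.ndarray,
    cell_type: np.ndarray,
    group: np.ndarray | None = None,
    k0: int | None = None,
    alpha: float = 0.05,
    perplexity: int = 30,
    subsample: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Full report: kBET acceptance per group plus median iLISI and cLISI."""
    kbet = kbet_acceptance(
        embedding, batch, group=group, k0=k0, alpha=alpha, subsample=subsample, seed=seed
    )
    il = lisi(embedding, batch, perplexity=perplexity)
    cl = lisi(embedding, cell_type, perplexity=perplexity)
    return MetricReport(
        kbet_acceptance=kbet,
        ilisi_median=float(np.median(il)),
        clisi_median=float(np.median(cl)),
        ilisi=il,
        clisi=cl,
        params={
            "k0": k0, "alpha": alpha, "perplexity": perplexity,
            "subsample": subsample, "seed": seed, "dim": embedding.d,
        },
    )
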