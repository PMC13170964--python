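"""Synthetic two-batch count data with controllable batch effects.

A minimal analogue of the Splatter simulation scheme: per-gene base means
drawn from a Gamma distribution, multiplicative log-normal differential-
expression (DE) factors per cell group, multiplicative log-normal batch
factors per batch, log-normal library sizes, and Poisson count sampling.
The target batch can be restricted to a subset of the groups to create a
partial label-space setting.  Also provides isotropic Gaussian blob
fixtures for clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar

import numpy as np

from .datasets import ExpressionDataset

__all__ = ["SimulationConfig", "simulate_counts", "simulate_gaussian_clusters"]


@dataclass
class SimulationConfig:
    """Parameters of the two-batch count simulation.

    Defaults mirror the study conditions of the simulated experiments:
    two batches of 600 cells, 2,000 genes, five balanced cell types, and
    a tunable log-normal batch-factor scale (the ``batch.facScale``
    analogue).  DE factors are log-normal(loc=0.3, scale=0.4) on 10% of
    genes per group — strong enough that cell types are identifiable
    within a batch, weak enough that the batch-factor sweep creates a
    genuine cross-batch annotation gap; library sizes are
    log-normal(9.2, 0.25) counts per cell.
    """

    n_cells_per_batch: int = 600
    n_genes: int = 2000
    n_groups: int = 5
    group_proportions: tuple[float, ...] | None = None
    batch_fac_scale: float = 0.5
    de_prob: float = 0.1
    de_loc: float = 0.3
    de_fac_scale: float = 0.4
    lib_size_mean: float = 9.2
    lib_size_sd: float = 0.25
    target_groups_kept: tuple[int, ...] | None = None
    zero_inflation: float = 0.0
    seed: int = 0

    #: imbalanced preset for five groups (fixed, arbitrary ratios)
    IMBALANCED_5: ClassVar[tuple[float, ...]] = (0.40, 0.25, 0.15, 0.12, 0.08)

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_genes < 1 or self.n_cells_per_batch < 1:
            raise ValueError("sizes must be positive")
        if self.group_proportions is None:
            self.group_proportions = tuple([1.0 / self.n_groups] * self.n_groups)
        self.group_proportions = tuple(float(p) for p in self.group_proportions)
        if len(self.group_proportions) != self.n_groups:
            raise ValueError("group_proportions length must equal n_groups")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if self.target_groups_kept is None:
            self.target_groups_kept = tuple(range(self.n_groups))
        self.target_groups_kept = tuple(sorted(set(int(g) for g in self.target_groups_kept)))
        if not self.target_groups_kept:
            raise ValueError("target_groups_kept must be non-empty")
        if not all(0 <= g < self.n_groups for g in self.target_groups_kept):
            raise ValueError("target_groups_kept must be group indices in [0, n_groups)")
        if self.batch_fac_scale < 0:
            raise ValueError("batch_fac_scale must be nonnegative")


def _allocate_groups(n: int, groups: np.ndarray, props: np.ndarray, rng) -> np.ndarray:
    """Deterministic largest-remainder allocation so every group appears."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    counts[counts == 0] = 1
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    rema = raw - np.floor(raw)
    while counts.sum() < n:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    labels = np.repeat(groups, counts)
    rng.shuffle(labels)
    return labels


def simulate_counts(cfg: SimulationConfig) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Draw a (source, target) pair of labelled count matrices.

    The source batch contains every group; the target batch only the
    groups in ``cfg.target_groups_kept`` and carries its true labels too
    (for evaluation — the model never sees them).  Counts are Poisson with
    cell mean = library size × normalized(base mean × DE factor × batch
    factor).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    G, K = cfg.n_genes, cfg.n_groups
    props = np.asarray(cfg.group_proportions)

    base = rng.gamma(shape=0.6, scale=1.0 / 0.3, size=G) + 1e-8
    de = np.ones((K, G))
    for g in range(K):
        mask = rng.random(G) < cfg.de_prob
        fac = rng.lognormal(cfg.de_loc, cfg.de_fac_scale, size=int(mask.sum()))
        down = rng.random(int(mask.sum())) < 0.5
        fac = np.where(down, 1.0 / fac, fac)
        de[g, mask] = fac
    batch_fac = np.ones((2, G))
    if cfg.batch_fac_scale > 0:
        batch_fac = rng.lognormal(0.0, cfg.batch_fac_scale, size=(2, G))

    datasets = []
    for b, (tag, groups) in enumerate(
        [("source", np.arange(K)), ("target", np.asarray(cfg.target_groups_kept))]
    ):
        p = props[groups] / props[groups].sum()
        cell_groups = _allocate_groups(cfg.n_cells_per_batch, groups, p, rng)
        lib = rng.lognormal(cfg.lib_size_mean, cfg.lib_size_sd, size=cfg.n_cells_per_batch)
        profile = base[None, :] * de[cell_groups, :] * batch_fac[b][None, :]
        profile /= profile.sum(axis=1, keepdims=True)
        lam = lib[:, None] * profile
        counts = rng.poisson(lam).astype(float)
        if cfg.zero_inflation > 0:
            counts *= rng.random(counts.shape) >= cfg.zero_inflation
        prefix = "s" if tag == "source" else "t"
        datasets.append(
            ExpressionDataset(
                matrix=counts,
                gene_ids=[f"g{j:05d}" for j in range(G)],
                cell_ids=[f"{prefix}_{i:05d}" for i in range(cfg.n_cells_per_batch)],
                labels=[f"type_{g}" for g in cell_groups],
                domain_tag=tag,
            )
        )
    return datasets[0], datasets[1]


def simulate_gaussian_clusters(
    k: int, n_per: int, dim: int, separation: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance isotropic Gaussian blobs with centroids ≥ ``separation`` apart."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    scale = max(separation, 1.0) * max(1.0, k ** (1.0 / dim))
    centers = rng.normal(0.0, scale, size=(1, dim))
    tries = 0
    while centers.shape[0] < k:
        cand = rng.normal(0.0, scale, size=(1, dim))
        d = np.linalg.norm(centers - cand, axis=1)
        if np.all(d >= separation):
            centers = np.vstack([centers, cand])
        tries += 1
        if tries > 2000 * k:  # widen the proposal box if packing is tight
            scale *= 1.5
            tries = 0
    labels = np.repeat(np.arange(k), n_per)
    points = centers[labels] + rng.standard_normal((k * n_per, dim))
    return points, labels
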