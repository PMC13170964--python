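"""Source class ↔ target cluster matching and the alignment loss.

Each target cluster is matched to the source class whose latent samples
have the lowest CS divergence from the cluster's samples (argmin over a
full p × Ĉ divergence table).  Several clusters may map to one class,
and a class may receive no cluster at all — this is what confines the
alignment to the shared label space and prevents negative transfer from
source-only classes.  The alignment loss sums, over clusters, the CS
divergence between the minibatch samples of a cluster and of its matched
class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .divergence import KernelConfig, cs_divergence

__all__ = ["MatchMap", "match_clusters", "alignment_loss", "total_loss"]

logger = logging.getLogger(__name__)

#: minimum samples on each side of a minibatch divergence term
MIN_BATCH_SUPPORT = 2


@dataclass(frozen=True)
class MatchMap:
    """Cluster→class assignment ``a`` with the full divergence table.

    ``divergence_table[j, i]`` is the CS divergence between source class
    ``j`` and target cluster ``i``; ``a[i] = argmin_j table[j, i]`` with
    ties broken toward the lowest class index.
    """

    a: np.ndarray
    divergence_table: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.a)

    def matched_classes(self) -> set[int]:
        return set(int(c) for c in self.a)

    def unmatched_classes(self) -> set[int]:
        return set(range(self.divergence_table.shape[0])) - self.matched_classes()


def match_clusters(
    source_latent_by_class: Sequence[np.ndarray],
    target_latent_by_cluster: Sequence[np.ndarray],
    cfg: KernelConfig = KernelConfig(),
) -> MatchMap:
    """Match every target cluster to its lowest-divergence source class."""
    p, C = len(source_latent_by_class), len(target_latent_by_cluster)
    if p < 1 or C < 1:
        raise ValueError("need at least one class and one cluster")
    for name, sets in (("class", source_latent_by_class), ("cluster", target_latent_by_cluster)):
        for i, Z in enumerate(sets):
            if len(Z) == 0:
                raise ValueError(f"empty {name} sample set at index {i}")
    table = np.empty((p, C))
    for j, Zs in enumerate(source_latent_by_class):
        for i, Zt in enumerate(target_latent_by_cluster):
            table[j, i] = cs_divergence(Zs, Zt, cfg)
    return MatchMap(a=table.argmin(axis=0), divergence_table=table)


def alignment_loss(
    match: MatchMap,
    source_batch_by_class: Sequence[np.ndarray],
    target_batch_by_cluster: Sequence[np.ndarray],
    cfg: KernelConfig = KernelConfig(),
    min_batch_support: int = MIN_BATCH_SUPPORT,
) -> float:
    """Σ_i D_CS(class a_i batch samples, cluster i batch samples).

    Terms whose class or cluster has fewer than ``min_batch_support``
    cells in the current minibatch are skipped (and logged): a one-point
    KDE term is degenerate for gradients.
    """
    loss = 0.0
    skipped = 0
    for i, a_i in enumerate(match.a):
        Zs = np.atleast_2d(source_batch_by_class[int(a_i)])
        Zt = np.atleast_2d(target_batch_by_cluster[i])
        if min(Zs.shape[0], Zt.shape[0]) < min_batch_support or Zs.size == 0 or Zt.size == 0:
            skipped += 1
            continue
        loss += cs_divergence(Zs, Zt, cfg)
    if skipped:
        logger.debug("alignment_loss skipped %d low-support terms", skipped)
    return loss


def total_loss(l_cls: float, l_cs: float, lam: float) -> float:
    """Combined objective ``L = L_cls + λ·L_cs``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return float(l_cls) + float(lam) * float(l_cs)
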