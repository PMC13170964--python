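"""Partial-domain-adaptation model for cross-modality label transfer.

:class:`CellTypeAdapter` is built from a labelled source expression
dataset and an unlabelled target dataset sharing a gene vocabulary.
``fit`` runs the two-stage training procedure:

* **Stage 1 (warm-up).**  The shared two-layer encoder and the linear
  classifier are trained for ``warmup_epochs`` on source minibatches with
  the class-weighted cross-entropy loss only.
* **Stage 2 (adaptation).**  Each epoch (at the configured cadence) the
  full target latents are clustered with a diagonal-covariance GMM whose
  cluster count adapts through NIW split/merge moves; every cluster is
  matched to the source class with minimal CS divergence; minibatch
  updates then minimize ``L_cls + λ·L_cs`` with the cluster assignments
  and matches frozen.

``fit`` returns an :class:`AdaptationResults` carrying the target
predictions, the final clustering and match map, the training history and
a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .clustering import (
    ClusterState,
    NIWPrior,
    fit_subclusters,
    init_gmm,
    split_merge_epoch,
)
from .datasets import ExpressionDataset, LabelCodec, harmonize_genes, normalize
from .divergence import KernelConfig, cs_divergence_grad
from .matching import MatchMap, match_clusters, total_loss
from .nn import Adam, EncoderSpec, Network, classification_loss, compute_class_weights

__all__ = ["TrainConfig", "CellTypeAdapter", "AdaptationResults"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``warmup_epochs`` (T) source-only epochs precede ``max_epochs - T``
    adaptation epochs.  ``initial_clusters`` is the GMM component count K
    before split/merge adaptation; ``lam`` the trade-off weight on the
    alignment loss; ``split_merge=False`` freezes the cluster count at K
    (ablation).  ``accept_policy`` is ``threshold`` (accept iff H > 1,
    deterministic) or ``mh`` (accept with probability min(1, H)).
    """

    warmup_epochs: int = 40
    max_epochs: int = 80
    recluster_every: int = 1
    lam: float = 1.0
    lr: float = 1e-3
    batch_size: int = 256
    early_stop_patience: int = 10
    initial_clusters: int = 10
    accept_policy: str = "threshold"
    split_merge: bool = True
    warm_start_gmm: bool = False
    niw_kappa: float = 1e-4
    niw_psi_scale: float = 0.005
    niw_nu: float | None = None
    class_weight_overrides: dict[str, float] = field(default_factory=dict)
    min_batch_support: int = 2

    def __post_init__(self) -> None:
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if self.max_epochs < self.warmup_epochs:
            raise ValueError("max_epochs must be >= warmup_epochs")
        if self.recluster_every < 1:
            raise ValueError("recluster_every must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


class CellTypeAdapter:
    """Label-transfer model from a labelled source to an unlabelled target.

    Parameters
    ----------
    source, target
        Expression datasets; the source must carry labels.  Gene spaces
        are harmonized to their ordered intersection and both matrices
        pass through the normalization contract (``normalize_mode``).
    encoder_spec, kernel, config
        Architecture, CS-divergence kernel and training settings.
    scale_genes
        Optionally z-score genes after log-normalization (off by default).
    """

    def __init__(
        self,
        source: ExpressionDataset,
        target: ExpressionDataset,
        *,
        encoder_spec: EncoderSpec | None = None,
        kernel: KernelConfig | None = None,
        config: TrainConfig | None = None,
        normalize_mode: str = "lognorm",
        scale_genes: bool = False,
    ):
        if source.labels is None:
            raise ValueError("source dataset must carry labels")
        if source.gene_ids != target.gene_ids:
            source, target = harmonize_genes(source, target)
        source = normalize(source, mode=normalize_mode)
        target = normalize(target, mode=normalize_mode)
        if scale_genes:
            mu = source.matrix.mean(axis=0)
            sd = source.matrix.std(axis=0) + 1e-8
            source.matrix = (source.matrix - mu) / sd
            target.matrix = (target.matrix - mu) / sd
        self.source = source
        self.target = target
        self.normalize_mode = normalize_mode
        self.codec = LabelCodec.from_labels(source.labels)
        self.y_source = self.codec.encode(source.labels)
        self.kernel = kernel or KernelConfig()
        self.config = config or TrainConfig()
        self.encoder_spec = encoder_spec or EncoderSpec(input_dim=source.n_genes)
        if self.encoder_spec.input_dim != source.n_genes:
            raise ValueError(
                f"encoder input_dim {self.encoder_spec.input_dim} != "
                f"{source.n_genes} harmonized genes"
            )

    # -- helpers -----------------------------------------------------------

    def _class_weight_vector(self):
        counts = np.bincount(self.y_source, minlength=self.codec.n_classes)
        weights = compute_class_weights(counts)
        override = np.ones(self.codec.n_classes)
        for name, mult in self.config.class_weight_overrides.items():
            override[self.codec.encode([name])[0]] = float(mult)
        return weights.normalized * override

    def _recluster(
        self,
        net: Network,
        state: ClusterState | None,
        cluster_seed: int,
        diagnostics: list | None,
    ) -> tuple[ClusterState, MatchMap, np.ndarray, np.ndarray]:
        cfg = self.config
        Zt = net.encode(self.target.matrix)
        Zs = net.encode(self.source.matrix)
        if state is None or not cfg.warm_start_gmm:
            state = init_gmm(Zt, cfg.initial_clusters, seed=cluster_seed)
        else:
            state = init_gmm(Zt, state.C, seed=cluster_seed, means_init=state.centroids)
        if cfg.split_merge:
            prior = NIWPrior.from_data(
                Zt, cfg.initial_clusters, kappa=cfg.niw_kappa,
                psi_scale=cfg.niw_psi_scale, nu=cfg.niw_nu,
            )
            state = fit_subclusters(Zt, state, seed=cluster_seed)
            state = split_merge_epoch(
                Zt, state, prior, policy=cfg.accept_policy,
                seed=cluster_seed, diagnostics=diagnostics,
            )
        match = match_clusters(
            [Zs[self.y_source == j] for j in range(self.codec.n_classes)],
            [Zt[state.assignments == i] for i in range(state.C)],
            self.kernel,
        )
        return state, match, Zs, Zt

    def _alignment_grads(
        self,
        match: MatchMap,
        Zs_b: np.ndarray,
        yb: np.ndarray,
        Zt_b: np.ndarray,
        clusters_b: np.ndarray,
    ) -> tuple[float, np.ndarray, np.ndarray, int]:
        """Minibatch alignment loss and latent gradients (frozen matches)."""
        l_cs = 0.0
        dZs = np.zeros_like(Zs_b)
        dZt = np.zeros_like(Zt_b)
        skipped = 0
        for i, a_i in enumerate(match.a):
            s_idx = np.flatnonzero(yb == a_i)
            t_idx = np.flatnonzero(clusters_b == i)
            if min(s_idx.size, t_idx.size) < self.config.min_batch_support:
                skipped += 1
                continue
            d, gs, gt = cs_divergence_grad(Zs_b[s_idx], Zt_b[t_idx], self.kernel)
            l_cs += d
            dZs[s_idx] += gs
            dZt[t_idx] += gt
        return l_cs, dZs, dZt, skipped

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> "AdaptationResults":
        """Run the two-stage training loop; deterministic given ``seed``
        under the threshold accept policy."""
        cfg = self.config
        ss = np.random.SeedSequence(int(seed) % (2**31))
        s_init, s_batch, s_cluster = ss.spawn(3)
        rng_init = np.random.default_rng(s_init)
        rng_batch = np.random.default_rng(s_batch)
        cluster_seeds = s_cluster.generate_state(max(cfg.max_epochs, 1))

        net = Network(self.encoder_spec, self.codec.n_classes, rng_init)
        adam = Adam(net.params, lr=cfg.lr)
        w = self._class_weight_vector()
        Xs, ys = self.source.matrix, self.y_source
        Xt = self.target.matrix
        ns, nt = Xs.shape[0], Xt.shape[0]
        bs = cfg.batch_size
        history: list[dict[str, Any]] = []
        diagnostics: list[dict] = []

        # ---- stage 1: source-only warm-up
        for epoch in range(cfg.warmup_epochs):
            order = rng_batch.permutation(ns)
            losses = []
            for start in range(0, ns, bs):
                idx = order[start : start + bs]
                Z, cache = net.encode(Xs[idx], return_cache=True)
                logits = net.classify(Z)
                loss, dlogits = classification_loss(logits, ys[idx], w, return_grad=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"classification loss diverged (epoch {epoch})"
                    )
                adam.step(net.backward(cache, Z, dlogits=dlogits))
                losses.append(loss)
            history.append(
                {"epoch": epoch, "stage": 1, "loss_cls": float(np.mean(losses)),
                 "loss_cs": 0.0, "loss_total": float(np.mean(losses)),
                 "C": None, "matches": None}
            )

        # ---- stage 2: adaptation
        state: ClusterState | None = None
        match: MatchMap | None = None
        best = np.inf
        stall = 0
        for epoch in range(cfg.warmup_epochs, cfg.max_epochs):
            k = epoch - cfg.warmup_epochs
            if match is None or k % cfg.recluster_every == 0:
                state, match, _, Zt_full = self._recluster(
                    net, state, int(cluster_seeds[epoch]), diagnostics
                )
            assignments = state.assignments
            n_steps = int(np.ceil(max(ns, nt) / bs))
            ep_cls, ep_cs, ep_skip = [], [], 0
            for _ in range(n_steps):
                si = rng_batch.choice(ns, size=min(bs, ns), replace=False)
                ti = rng_batch.choice(nt, size=min(bs, nt), replace=False)
                Zs_b, cache_s = net.encode(Xs[si], return_cache=True)
                logits = net.classify(Zs_b)
                l_cls, dlogits = classification_loss(logits, ys[si], w, return_grad=True)
                Zt_b, cache_t = net.encode(Xt[ti], return_cache=True)
                l_cs, dZs, dZt, skipped = self._alignment_grads(
                    match, Zs_b, ys[si], Zt_b, assignments[ti]
                )
                if not np.isfinite(l_cls):
                    raise FloatingPointError(f"classification loss diverged (epoch {epoch})")
                if not np.isfinite(l_cs):
                    raise FloatingPointError(f"alignment loss diverged (epoch {epoch})")
                grads = net.backward(cache_s, Zs_b, dZ=cfg.lam * dZs, dlogits=dlogits)
                grads_t = net.backward(cache_t, Zt_b, dZ=cfg.lam * dZt)
                for key in grads:
                    grads[key] += grads_t[key]
                adam.step(grads)
                ep_cls.append(l_cls)
                ep_cs.append(l_cs)
                ep_skip += skipped
            mean_cls, mean_cs = float(np.mean(ep_cls)), float(np.mean(ep_cs))
            loss_epoch = total_loss(mean_cls, mean_cs, cfg.lam)
            history.append(
                {"epoch": epoch, "stage": 2, "loss_cls": mean_cls,
                 "loss_cs": mean_cs, "loss_total": loss_epoch,
                 "C": int(state.C), "matches": [int(a) for a in match.a],
                 "skipped_terms": ep_skip}
            )
            if loss_epoch < best - 1e-6:
                best = loss_epoch
                stall = 0
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break

        logits_t = net.classify(net.encode(Xt))
        predicted = self.codec.decode(logits_t.argmax(axis=1))
        return AdaptationResults(
            model=self,
            network=net,
            history=history,
            cluster_state=state,
            match_map=match,
            predicted_labels=predicted,
            diagnostics=diagnostics,
            seed=int(seed),
        )


@dataclass
class AdaptationResults:
    """Fitted model state: predictions, clustering, matches, history."""

    model: CellTypeAdapter
    network: Network
    history: list[dict]
    cluster_state: ClusterState | None
    match_map: MatchMap | None
    predicted_labels: list[str]
    diagnostics: list[dict]
    seed: int

    # -- prediction --------------------------------------------------------

    def predict(self, dataset: ExpressionDataset | None = None) -> list[str]:
        """Predicted cell-type labels for ``dataset`` (default: the fitted target)."""
        if dataset is None:
            return list(self.predicted_labels)
        if dataset.gene_ids != self.model.source.gene_ids:
            raise ValueError("gene space of new dataset does not match training genes")
        ds = normalize(dataset, mode=self.model.normalize_mode)
        logits = self.network.classify(self.network.encode(ds.matrix))
        return self.model.codec.decode(logits.argmax(axis=1))

    def encode(self, dataset: ExpressionDataset) -> np.ndarray:
        """Latent representations of an (already gene-matched) dataset."""
        if dataset.gene_ids != self.model.source.gene_ids:
            raise ValueError("gene space of dataset does not match training genes")
        ds = normalize(dataset, mode=self.model.normalize_mode)
        return self.network.encode(ds.matrix)

    def predictions_frame(self) -> pd.DataFrame:
        """Per-cell table: cell_id, predicted_label, cluster_id."""
        clusters = (
            self.cluster_state.assignments
            if self.cluster_state is not None
            else np.full(len(self.predicted_labels), -1)
        )
        return pd.DataFrame(
            {"cell_id": self.model.target.cell_ids,
             "predicted_label": self.predicted_labels,
             "cluster_id": clusters}
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Partial domain adaptation — cell-type label transfer",
            "=" * 52,
            f"source cells:        {m.source.n_cells}",
            f"target cells:        {m.target.n_cells}",
            f"shared genes:        {m.source.n_genes}",
            f"source classes:      {m.codec.n_classes} "
            f"({', '.join(m.codec.classes)})",
            f"latent dim:          {m.encoder_spec.latent_dim}",
            f"epochs run:          {len(self.history)} "
            f"(warm-up {m.config.warmup_epochs})",
        ]
        if self.cluster_state is not None and self.match_map is not None:
            unmatched = sorted(
                m.codec.classes[c] for c in self.match_map.unmatched_classes()
            )
            lines += [
                f"final clusters:      {self.cluster_state.C}",
                f"matched classes:     "
                f"{sorted(m.codec.classes[c] for c in self.match_map.matched_classes())}",
                f"unmatched classes:   {unmatched if unmatched else 'none'}",
            ]
        if self.history:
            last = self.history[-1]
            lines.append(
                f"final losses:        cls={last['loss_cls']:.4f} "
                f"cs={last['loss_cs']:.4f} total={last['loss_total']:.4f}"
            )
        comp = pd.Series(self.predicted_labels).value_counts()
        lines.append("predicted composition:")
        for name, count in comp.items():
            lines.append(f"    {name:<20s} {count}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save network parameters + metadata (``.npz`` and ``.json``)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_dict())
        meta = {
            "encoder_spec": asdict(self.model.encoder_spec),
            "classes": list(self.model.codec.classes),
            "normalize_mode": self.model.normalize_mode,
            "gene_ids": self.model.source.gene_ids,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    def write_history(self, path: str | Path) -> None:
        """Per-epoch training history as JSONL."""
        with open(path, "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")
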