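"""Split/merge clustering of target latents with NIW marginal likelihoods.

Target representations are first hard-clustered with a diagonal-
covariance Gaussian mixture.  The number of clusters then adapts through
split and merge moves: each cluster is subdivided into two sub-clusters
by a second 2-component mixture, and a split (or merge of nearest-
neighbour clusters) is scored by a Hastings ratio of Normal–Inverse–
Wishart (NIW) marginal likelihoods,

    H_split = Γ(N₁)·L(Z₁)·Γ(N₂)·L(Z₂) / (Γ(N)·L(Z)),
    H_merge(i,j) = 1 / H_split(union → (i, j)),

with L the closed-form NIW marginal of a point set.  Moves are accepted
either deterministically when H > 1 (default) or with Metropolis–
Hastings probability min(1, H).  Everything is computed in log-space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, multigammaln
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "NIWPrior",
    "ClusterState",
    "init_gmm",
    "fit_subclusters",
    "log_marginal_likelihood",
    "split_log_ratio",
    "merge_log_ratio",
    "split_merge_epoch",
    "adapt_clusters",
]

_JITTER = 1e-8


@dataclass
class NIWPrior:
    """Normal–Inverse–Wishart hyperparameters (ν, κ, m, ψ).

    Defaults follow the model's convention: κ = 1e-4, m = mean of the
    target latents, ψ = 0.005·I, and ν = K + 2 with K the initial
    cluster hyperparameter — floored at latent_dim + 2 so the
    multivariate gamma is defined in every dimension.
    """

    nu: float
    kappa: float
    m: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.psi = np.asarray(self.psi, dtype=float)
        d = self.m.shape[0]
        if self.psi.shape != (d, d):
            raise ValueError("psi must be (d, d) matching the prior mean")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.nu <= d - 1:
            raise ValueError(f"nu must exceed dim-1 = {d - 1}")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")

    @classmethod
    def from_data(
        cls,
        Z: np.ndarray,
        initial_clusters: int,
        kappa: float = 1e-4,
        psi_scale: float = 0.005,
        nu: float | None = None,
    ) -> "NIWPrior":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        d = Z.shape[1]
        if nu is None:
            nu = max(initial_clusters + 2, d + 2)
        return cls(nu=float(nu), kappa=kappa, m=Z.mean(axis=0), psi=psi_scale * np.eye(d))


@dataclass
class ClusterState:
    """Hard cluster assignments of target cells plus 2-way sub-assignments.

    ``assignments[i] ∈ [0, C)``; ``sub_assignments[i] ∈ {1, 2}`` within
    cluster ``assignments[i]``; clusters listed in ``split_exempt`` are
    too small or degenerate to be split this round.
    """

    assignments: np.ndarray
    sub_assignments: np.ndarray
    C: int
    centroids: np.ndarray
    split_exempt: set = field(default_factory=set)

    def validate(self) -> None:
        counts = np.bincount(self.assignments, minlength=self.C)
        if len(counts) != self.C or np.any(counts == 0):
            raise ValueError("every cluster index in [0, C) must be non-empty")
        if not np.all(np.isin(self.sub_assignments, (1, 2))):
            raise ValueError("sub_assignments must be 1 or 2")

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == c)


def _centroids(Z: np.ndarray, assignments: np.ndarray, C: int) -> np.ndarray:
    return np.vstack([Z[assignments == c].mean(axis=0) for c in range(C)])


def _relabel(assignments: np.ndarray) -> tuple[np.ndarray, int]:
    """Compact cluster labels to contiguous [0, C) preserving order."""
    uniq = np.unique(assignments)
    lut = {int(u): i for i, u in enumerate(uniq)}
    return np.array([lut[int(a)] for a in assignments]), len(uniq)


def init_gmm(
    Zt: np.ndarray,
    C: int,
    seed: int,
    means_init: np.ndarray | None = None,
) -> ClusterState:
    """Hard-assign target latents with a diagonal-covariance GMM.

    Empty components are dropped (reducing C).  ``means_init`` allows
    warm-starting from previous centroids.
    """
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    if C < 1:
        raise ValueError("C must be >= 1")
    if Zt.shape[0] < C:
        raise ValueError(f"need at least C={C} points, got {Zt.shape[0]}")
    kwargs = {}
    if means_init is not None and means_init.shape[0] == C:
        kwargs["means_init"] = means_init
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=C,
            covariance_type="diag",
            random_state=int(seed) % (2**32),
            reg_covar=1e-6,
            **kwargs,
        ).fit(Zt)
    assignments = gm.predict(Zt)
    assignments, C_eff = _relabel(assignments)
    return ClusterState(
        assignments=assignments,
        sub_assignments=np.ones(Zt.shape[0], dtype=int),
        C=C_eff,
        centroids=_centroids(Zt, assignments, C_eff),
    )


def fit_subclusters(Zt: np.ndarray, state: ClusterState, seed: int) -> ClusterState:
    """Divide each cluster into two sub-clusters with a 2-component diag GMM.

    Clusters with fewer than 4 members, or whose 2-component fit leaves a
    component empty, get all members in sub-cluster 1 and are exempt from
    splitting this round.
    """
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    sub = np.ones(Zt.shape[0], dtype=int)
    exempt: set[int] = set()
    ss = np.random.SeedSequence([int(seed) % (2**31), 17])
    child_seeds = ss.generate_state(state.C)
    for c in range(state.C):
        idx = state.members(c)
        if idx.size < 4:
            exempt.add(c)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm = GaussianMixture(
                    n_components=2,
                    covariance_type="diag",
                    random_state=int(child_seeds[c]) % (2**32),
                    reg_covar=1e-6,
                ).fit(Zt[idx])
            labels = gm.predict(Zt[idx])
        except (ValueError, np.linalg.LinAlgError):
            exempt.add(c)
            continue
        if len(np.unique(labels)) < 2:
            exempt.add(c)
            continue
        sub[idx] = labels + 1
    return ClusterState(
        assignments=state.assignments.copy(),
        sub_assignments=sub,
        C=state.C,
        centroids=state.centroids.copy(),
        split_exempt=exempt,
    )


def _chol_logdet(A: np.ndarray) -> float:
    """log|A| via Cholesky, with diagonal jitter on failure."""
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(A + _JITTER * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "posterior scale matrix not positive definite after jitter"
            ) from e
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def log_marginal_likelihood(Z: np.ndarray, prior: NIWPrior) -> float:
    """Log marginal likelihood of points ``Z`` under the NIW conjugate prior.

    Closed form of ∫ Π N(z_i | μ, Σ) NIW(μ, Σ | ν, κ, m, ψ) dμ dΣ:

        −(k·d/2)·log π + logΓ_d(ν_k/2) − logΓ_d(ν/2)
        + (ν/2)·log|ψ| − (ν_k/2)·log|ψ_k| + (d/2)·(log κ − log κ_k)

    with κ_k = κ+k, ν_k = ν+k and ψ_k = ψ + S + κk/(κ+k)·(z̄−m)(z̄−m)ᵀ
    (S the centered scatter).  Returns 0 for the empty set.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        return 0.0
    Z = np.atleast_2d(Z)
    k, d = Z.shape
    zbar = Z.mean(axis=0)
    dev = Z - zbar
    S = dev.T @ dev
    diff = (zbar - prior.m)[:, None]
    kappa_k = prior.kappa + k
    nu_k = prior.nu + k
    psi_k = prior.psi + S + (prior.kappa * k / kappa_k) * (diff @ diff.T)
    return (
        -0.5 * k * d * np.log(np.pi)
        + multigammaln(nu_k / 2.0, d)
        - multigammaln(prior.nu / 2.0, d)
        + 0.5 * prior.nu * _chol_logdet(prior.psi)
        - 0.5 * nu_k * _chol_logdet(psi_k)
        + 0.5 * d * (np.log(prior.kappa) - np.log(kappa_k))
    )


def split_log_ratio(
    Zc: np.ndarray, Z1: np.ndarray, Z2: np.ndarray, prior: NIWPrior
) -> float:
    """log H_split for dividing cluster ``Zc`` into (``Z1``, ``Z2``)."""
    n1, n2 = len(Z1), len(Z2)
    if n1 < 1 or n2 < 1:
        raise ValueError("both sub-clusters must be non-empty")
    return (
        gammaln(n1)
        + gammaln(n2)
        - gammaln(n1 + n2)
        + log_marginal_likelihood(Z1, prior)
        + log_marginal_likelihood(Z2, prior)
        - log_marginal_likelihood(Zc, prior)
    )


def merge_log_ratio(Zi: np.ndarray, Zj: np.ndarray, prior: NIWPrior) -> float:
    """log H_merge for fusing clusters ``Zi`` and ``Zj`` (= −log H_split of the union)."""
    ni, nj = len(Zi), len(Zj)
    if ni < 1 or nj < 1:
        raise ValueError("both clusters must be non-empty")
    union = np.vstack([np.atleast_2d(Zi), np.atleast_2d(Zj)])
    return (
        gammaln(ni + nj)
        - gammaln(ni)
        - gammaln(nj)
        + log_marginal_likelihood(union, prior)
        - log_marginal_likelihood(Zi, prior)
        - log_marginal_likelihood(Zj, prior)
    )


def _accept(log_h: float, policy: str, rng: np.random.Generator) -> bool:
    if policy == "threshold":
        return log_h > 0.0
    if policy == "mh":
        return np.log(rng.random()) < min(0.0, log_h)
    raise ValueError("policy must be 'threshold' or 'mh'")


def split_merge_epoch(
    Zt: np.ndarray,
    state: ClusterState,
    prior: NIWPrior,
    policy: str = "threshold",
    seed: int = 0,
    diagnostics: list | None = None,
) -> ClusterState:
    """One pass of split moves followed by nearest-neighbour merge moves.

    Splits replace a cluster by its sub-cluster 1 and append sub-cluster 2
    as a new cluster.  Merges consider, for each post-split cluster, only
    its nearest neighbour by centroid distance; candidate pairs are
    processed greedily by descending ratio, each cluster merging at most
    once per epoch.  Membership is conserved and no empty cluster survives.
    """
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    rng = np.random.default_rng([int(seed) % (2**31), 29])
    assignments = state.assignments.copy()
    C = state.C
    n_split = n_merge = 0

    # --- split pass
    for c in range(state.C):
        if c in state.split_exempt:
            continue
        idx = state.members(c)
        sub = state.sub_assignments[idx]
        i1, i2 = idx[sub == 1], idx[sub == 2]
        if i1.size == 0 or i2.size == 0:
            continue
        log_h = split_log_ratio(Zt[idx], Zt[i1], Zt[i2], prior)
        if diagnostics is not None:
            diagnostics.append({"move": "split", "cluster": int(c), "log_h": float(log_h)})
        if _accept(log_h, policy, rng):
            assignments[i2] = C
            C += 1
            n_split += 1

    assignments, C = _relabel(assignments)
    centroids = _centroids(Zt, assignments, C)

    # --- merge pass on the post-split clustering
    if C >= 2:
        dist = cdist(centroids, centroids)
        np.fill_diagonal(dist, np.inf)
        nearest = dist.argmin(axis=1)
        pairs = {tuple(sorted((i, int(nearest[i])))) for i in range(C)}
        scored = []
        for i, j in pairs:
            log_h = merge_log_ratio(Zt[assignments == i], Zt[assignments == j], prior)
            if diagnostics is not None:
                diagnostics.append(
                    {"move": "merge", "pair": [int(i), int(j)], "log_h": float(log_h)}
                )
            scored.append((log_h, i, j))
        used: set[int] = set()
        for log_h, i, j in sorted(scored, key=lambda t: -t[0]):
            if i in used or j in used:
                continue
            if _accept(log_h, policy, rng):
                assignments[assignments == j] = i
                used.update((i, j))
                n_merge += 1
        assignments, C = _relabel(assignments)
        centroids = _centroids(Zt, assignments, C)

    if diagnostics is not None:
        diagnostics.append({"C": int(C), "splits": n_split, "merges": n_merge})
    out = ClusterState(
        assignments=assignments,
        sub_assignments=np.ones(Zt.shape[0], dtype=int),
        C=C,
        centroids=centroids,
    )
    out.validate()
    return out


def adapt_clusters(
    Zt: np.ndarray,
    initial_C: int,
    prior: NIWPrior | None = None,
    policy: str = "threshold",
    seed: int = 0,
    max_rounds: int = 10,
    diagnostics: list | None = None,
) -> ClusterState:
    """Initialize with a GMM and iterate split/merge epochs to a fixed point."""
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    if prior is None:
        prior = NIWPrior.from_data(Zt, initial_C)
    ss = np.random.SeedSequence(int(seed) % (2**31))
    seeds = ss.generate_state(2 * max_rounds + 1)
    state = init_gmm(Zt, initial_C, seed=int(seeds[0]))
    for r in range(max_rounds):
        state = fit_subclusters(Zt, state, seed=int(seeds[2 * r + 1]))
        new = split_merge_epoch(
            Zt, state, prior, policy=policy, seed=int(seeds[2 * r + 2]),
            diagnostics=diagnostics,
        )
        if new.C == state.C and np.array_equal(new.assignments, state.assignments):
            return new
        state = new
    return state
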