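import numpy as np
import pytest

from celladapt import (
    CellTypeAdapter,
    ExpressionDataset,
    SimulationConfig,
    TrainConfig,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_expression():
    """Tiny labelled dataset for I/O round trips."""
    rng = np.random.default_rng(7)
    mat = rng.poisson(3.0, size=(6, 4)).astype(float)
    return ExpressionDataset(
        matrix=mat,
        gene_ids=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(6)],
        labels=["a", "a", "b", "b", "c", "c"],
    )


def partial_task(bfs: float, seed: int):
    """Study-condition synthetic task: 5 source groups, 3 kept in target."""
    cfg = SimulationConfig(
        batch_fac_scale=bfs, target_groups_kept=(0, 1, 2), seed=seed
    )
    source, target = simulate_counts(cfg)
    truth = list(target.labels)
    target_unlabelled = ExpressionDataset(
        target.matrix, target.gene_ids, target.cell_ids, None, "target"
    )
    return source, target_unlabelled, truth


def fit_task(bfs: float, seed: int, **config_kwargs):
    source, target, truth = partial_task(bfs, seed)
    model = CellTypeAdapter(source, target, config=TrainConfig(**config_kwargs))
    res = model.fit(seed=seed)
    return res, truth


@pytest.fixture(scope="session")
def full_model_runs():
    """Full-model results over 5 seeds x both batch-effect strengths.

    Shared between the end-to-end transfer tests and the ablation
    comparisons so each condition is trained once.
    """
    out = {}
    for bfs in (0.5, 1.0):
        for seed in range(5):
            out[(bfs, seed)] = fit_task(bfs, seed)
    return out
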