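"""Hyperparameter grid handling and model ensembling.

A single embedding+MLP model is sensitive to its hyperparameters (embedding
dimensions, MLP depth and width), so the imputer is deployed as an ensemble:
several configurations are drawn from a search grid, each member trains with
its own random seed and its own MCAR validation split of the shared training
entries, and the final reconstruction is the unweighted entrywise mean of the
member prediction matrices. By convexity of squared error, the averaged
prediction can never have higher MSE on a fixed target set than the mean of
the members' MSEs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import QuantMatrix
from .model import FactorModel, ModelConfig, TrainingLog, init_model, predict_matrix, train
from .partition import PartitionMasks, PartitionParams, mcar_validation_split

__all__ = [
    "HyperparamGrid",
    "EnsembleResult",
    "enumerate_grid",
    "sample_configs",
    "fit_ensemble",
]

DEFAULT_ENSEMBLE_SIZE = 10


@dataclass(frozen=True)
class HyperparamGrid:
    """Search space over the four architecture hyperparameters."""

    protein_factors: tuple[int, ...] = (64, 128, 256, 512, 1024)
    sample_factors: tuple[int, ...] = (64, 128, 256, 512, 1024)
    hidden_layers: tuple[int, ...] = (1, 2, 4)
    nodes_per_layer: tuple[int, ...] = (512, 1024, 2048)

    def __post_init__(self) -> None:
        for name in ("protein_factors", "sample_factors", "hidden_layers", "nodes_per_layer"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    @property
    def cardinality(self) -> int:
        return (
            len(self.protein_factors)
            * len(self.sample_factors)
            * len(self.hidden_layers)
            * len(self.nodes_per_layer)
        )


@dataclass
class EnsembleResult:
    """Trained members and their averaged reconstruction."""

    member_configs: list[ModelConfig]
    member_predictions: list[np.ndarray]
    averaged_prediction: np.ndarray
    member_logs: list[TrainingLog]
    members: list[FactorModel] = field(default_factory=list)


def enumerate_grid(grid: HyperparamGrid, base: ModelConfig | None = None) -> list[ModelConfig]:
    """All grid combinations, in deterministic lexicographic order."""
    base = base or ModelConfig()
    return [
        replace(
            base,
            n_protein_factors=p,
            n_sample_factors=s,
            n_hidden_layers=h,
            n_nodes_per_layer=n,
        )
        for p, s, h, n in itertools.product(
            grid.protein_factors,
            grid.sample_factors,
            grid.hidden_layers,
            grid.nodes_per_layer,
        )
    ]


def sample_configs(
    grid: HyperparamGrid,
    n: int,
    seed: int = 0,
    base: ModelConfig | None = None,
) -> list[ModelConfig]:
    """Uniform sample of ``n`` grid configurations without replacement."""
    configs = enumerate_grid(grid, base=base)
    if n > len(configs):
        raise ValueError(
            f"requested {n} configurations but the grid holds only {len(configs)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(configs), size=n, replace=False)
    return [configs[k] for k in chosen]


def fit_ensemble(
    qm: QuantMatrix,
    masks: PartitionMasks,
    n_models: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    grid: HyperparamGrid | None = None,
    configs: list[ModelConfig] | None = None,
    base_config: ModelConfig | None = None,
    val_fraction: float = 0.10,
    partition_params: PartitionParams | None = None,
) -> EnsembleResult:
    """Train an ensemble and average the member prediction matrices.

    Members either use an explicit ``configs`` list or are sampled from the
    grid. Member k derives seed ``seed + k``, carves its own 10% MCAR
    validation split out of the shared training mask (so no member trains
    on its own stopping signal), trains to convergence and predicts the
    full matrix. The ensemble prediction is the arithmetic mean.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if configs is None:
        grid = grid or HyperparamGrid()
        configs = sample_configs(grid, n_models, seed=seed, base=base_config)
    elif len(configs) != n_models:
        raise ValueError("len(configs) must equal n_models")

    member_predictions: list[np.ndarray] = []
    member_logs: list[TrainingLog] = []
    members: list[FactorModel] = []
    resolved: list[ModelConfig] = []
    for k, cfg in enumerate(configs):
        cfg_k = replace(cfg, seed=int(seed) + k)
        member_masks = mcar_validation_split(
            PartitionMasks(
                masks.train_mask | masks.val_mask,
                np.zeros_like(masks.train_mask),
                masks.test_mask,
            ),
            fraction=val_fraction,
            seed=cfg_k.seed,
        )
        model = init_model(cfg_k, qm.n_proteins, qm.n_samples)
        try:
            model, log = train(
                model, qm, member_masks, cfg_k, partition_params=partition_params
            )
        except FloatingPointError as exc:
            raise RuntimeError(f"ensemble member {k} aborted: {exc}") from exc
        member_predictions.append(predict_matrix(model))
        member_logs.append(log)
        members.append(model)
        resolved.append(cfg_k)

    averaged = np.mean(member_predictions, axis=0)
    return EnsembleResult(
        member_configs=resolved,
        member_predictions=member_predictions,
        averaged_prediction=averaged,
        member_logs=member_logs,
        members=members,
    )
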