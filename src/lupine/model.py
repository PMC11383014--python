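"""The imputation network: protein/sample embeddings feeding an MLP.

Each protein i carries a learned factor vector (row i of W, length p) and
each MS sample j a factor vector (column j of H, length s). To predict the
quantification of entry (i, j), the two vectors are concatenated and passed
through a fully-connected multilayer perceptron with leaky-ReLU hidden
activations and a scalar linear output. W, H and the MLP weights are trained
jointly by minimising the mean squared error over training-set entries with
the Adam optimizer, using the left-biased batch stream from
:mod:`lupine.partition`, and early stopping is driven by a held-out MCAR
validation set via two criteria: a relative-improvement plateau and a
rank-sum test detecting a rising validation-error trend.

Everything here is plain NumPy: forward pass, backpropagation and Adam are
implemented explicitly, which keeps the package dependency-light and makes
the computation easy to verify against hand-worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .matrix import QuantMatrix
from .partition import PartitionMasks, PartitionParams, biased_batches

__all__ = [
    "ModelConfig",
    "FactorModel",
    "TrainingLog",
    "init_model",
    "predict_entry",
    "predict_matrix",
    "train",
    "check_convergence",
    "impute_matrix",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and training-control knobs.

    n_protein_factors, n_sample_factors : embedding dimensions p and s.
    n_hidden_layers, n_nodes_per_layer : MLP depth and width.
    leaky_slope : negative slope of the leaky-ReLU activations (0.1).
    learning_rate : Adam step size (0.001).
    batch_size : entries per training batch (128).
    tolerance, patience : plateau stopping — relative improvement below
        ``tolerance`` for ``patience`` successive epochs stops training.
    wilcoxon_alpha : significance level of the rising-error rank-sum stop.
    max_epochs : hard cap as a safety net on top of the two criteria.
    """

    n_protein_factors: int = 128
    n_sample_factors: int = 128
    n_hidden_layers: int = 2
    n_nodes_per_layer: int = 1024
    leaky_slope: float = 0.1
    learning_rate: float = 0.001
    batch_size: int = 128
    tolerance: float = 0.001
    patience: int = 10
    wilcoxon_alpha: float = 0.05
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_protein_factors",
            "n_sample_factors",
            "n_hidden_layers",
            "n_nodes_per_layer",
            "batch_size",
            "patience",
            "max_epochs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in [0, 1)")


@dataclass
class TrainingLog:
    """Per-epoch loss trajectories and the stopping outcome."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    stop_reason: str | None = None
    epochs_run: int = 0
    best_epoch: int = -1


class FactorModel:
    """Learned parameters: embeddings W, H and the MLP layer stack.

    W has shape (n_proteins, p); H has shape (s, n_samples); the MLP maps
    p + s inputs through ``n_hidden_layers`` leaky-ReLU layers of width
    ``n_nodes_per_layer`` to a single linear output.
    """

    def __init__(
        self,
        W: np.ndarray,
        H: np.ndarray,
        layers: list[tuple[np.ndarray, np.ndarray]],
        config: ModelConfig,
    ) -> None:
        self.W = W
        self.H = H
        self.layers = layers  # [(weight (in, out), bias (out,)), ...]
        self.config = config
        expect = W.shape[1] + H.shape[0]
        for w, b in layers:
            if w.shape[0] != expect or b.shape != (w.shape[1],):
                raise ValueError("MLP layer shapes do not chain")
            expect = w.shape[1]
        if expect != 1:
            raise ValueError("final MLP layer must output a scalar")

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {"W": self.W, "H": self.H}
        for k, (w, b) in enumerate(self.layers):
            out[f"w{k}"] = w
            out[f"b{k}"] = b
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.W = params["W"]
        self.H = params["H"]
        self.layers = [
            (params[f"w{k}"], params[f"b{k}"]) for k in range(len(self.layers))
        ]

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    @property
    def n_proteins(self) -> int:
        return self.W.shape[0]

    @property
    def n_samples(self) -> int:
        return self.H.shape[1]

    # -- forward / backward -------------------------------------------
    def _forward(self, idx: np.ndarray, need_grad: bool = False):
        """Forward pass for a batch of (protein, sample) index pairs."""
        i, j = idx[:, 0], idx[:, 1]
        x = np.concatenate([self.W[i], self.H[:, j].T], axis=1)
        slope = self.config.leaky_slope
        pre_acts: list[np.ndarray] = []
        post_acts: list[np.ndarray] = [x]
        h = x
        n_layers = len(self.layers)
        for k, (w, b) in enumerate(self.layers):
            z = h @ w + b
            if k < n_layers - 1:  # hidden layer: leaky ReLU
                h = np.where(z >= 0, z, slope * z)
            else:  # linear scalar output
                h = z
            if need_grad:
                pre_acts.append(z)
                post_acts.append(h)
        pred = h[:, 0]
        if need_grad:
            return pred, pre_acts, post_acts
        return pred

    def predict_batch(self, idx: np.ndarray) -> np.ndarray:
        """Predicted intensities for an array of (protein, sample) pairs."""
        idx = np.asarray(idx)
        if idx.ndim != 2 or idx.shape[1] != 2:
            raise ValueError("idx must have shape (n, 2)")
        if (idx[:, 0] >= self.n_proteins).any() or (idx[:, 1] >= self.n_samples).any():
            raise IndexError("entry index out of range")
        if (idx < 0).any():
            raise IndexError("entry index out of range")
        return self._forward(idx)

    def _backward(
        self,
        idx: np.ndarray,
        pred: np.ndarray,
        target: np.ndarray,
        pre_acts: list[np.ndarray],
        post_acts: list[np.ndarray],
    ) -> dict[str, np.ndarray]:
        """Gradients of batch-mean squared error w.r.t. all parameters."""
        i, j = idx[:, 0], idx[:, 1]
        slope = self.config.leaky_slope
        batch = idx.shape[0]
        grads: dict[str, np.ndarray] = {}
        # d(mean (pred - y)^2)/d pred
        delta = (2.0 / batch) * (pred - target)[:, None]
        n_layers = len(self.layers)
        for k in range(n_layers - 1, -1, -1):
            w, _ = self.layers[k]
            a_in = post_acts[k]
            grads[f"w{k}"] = a_in.T @ delta
            grads[f"b{k}"] = delta.sum(axis=0)
            delta = delta @ w.T
            if k > 0:
                z_prev = pre_acts[k - 1]
                delta = delta * np.where(z_prev >= 0, 1.0, slope)
        # delta is now the gradient w.r.t. the concatenated input features
        p = self.W.shape[1]
        gW = np.zeros_like(self.W)
        np.add.at(gW, i, delta[:, :p])
        gHT = np.zeros((self.H.shape[1], self.H.shape[0]))
        np.add.at(gHT, j, delta[:, p:])
        grads["W"] = gW
        grads["H"] = gHT.T
        return grads


def init_model(config: ModelConfig, n_proteins: int, n_samples: int) -> FactorModel:
    """Randomly initialise embeddings and MLP weights (seed-deterministic).

    Embedding entries are Normal(0, 1/sqrt(factors)); MLP weights use
    uniform fan-in scaling U(-1/sqrt(fan_in), 1/sqrt(fan_in)) with zero
    biases, keeping initial predictions O(1) on the log-intensity scale.
    """
    if n_proteins < 1 or n_samples < 1:
        raise ValueError("need at least one protein and one sample")
    rng = np.random.default_rng(config.seed)
    p, s = config.n_protein_factors, config.n_sample_factors
    W = rng.normal(0.0, 1.0 / math.sqrt(p), size=(n_proteins, p))
    H = rng.normal(0.0, 1.0 / math.sqrt(s), size=(s, n_samples))
    widths = [p + s] + [config.n_nodes_per_layer] * config.n_hidden_layers + [1]
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / math.sqrt(fan_in)
        layers.append(
            (rng.uniform(-bound, bound, size=(fan_in, fan_out)), np.zeros(fan_out))
        )
    return FactorModel(W, H, layers, config)


def predict_entry(model: FactorModel, i: int, j: int) -> float:
    """Predicted intensity for protein i in sample j."""
    return float(model.predict_batch(np.array([[i, j]]))[0])


def predict_matrix(model: FactorModel, block: int = 4096) -> np.ndarray:
    """Full (n_proteins × n_samples) prediction matrix, computed blockwise."""
    n, m = model.n_proteins, model.n_samples
    out = np.empty((n, m))
    rows_per_block = max(1, block // max(m, 1))
    cols = np.arange(m)
    for start in range(0, n, rows_per_block):
        stop = min(start + rows_per_block, n)
        rows = np.arange(start, stop)
        idx = np.column_stack(
            [np.repeat(rows, m), np.tile(cols, stop - start)]
        )
        out[start:stop, :] = model.predict_batch(idx).reshape(stop - start, m)
    return out


# ----------------------------------------------------------------------
# Convergence


def check_convergence(
    val_history: Sequence[float], config: ModelConfig
) -> tuple[bool, str | None]:
    """Decide whether to stop training, from the validation-MSE history.

    Criterion 1 (plateau): each epoch after the first, the signed ratio
    (best-so-far − current) / best-so-far is computed; when it stays below
    ``tolerance`` for ``patience`` successive epochs, stop. Worsening
    epochs give a negative ratio and therefore qualify.

    Criterion 2 (rising error; needs ≥ 15 epochs): a one-sided rank-sum
    test compares the five most recent validation MSEs against the five
    MSEs from ten epochs earlier; a significant result (older window
    stochastically smaller) means validation error has started to rise.
    """
    hist = list(val_history)
    if not hist:
        raise ValueError("validation history is empty")
    # criterion 1: trailing run of sub-tolerance relative improvements
    streak = 0
    for n in range(1, len(hist)):
        best = min(hist[:n])
        ratio = 0.0 if best <= 0 else (best - hist[n]) / best
        streak = streak + 1 if ratio < config.tolerance else 0
    if streak >= config.patience:
        return True, "tolerance"
    # criterion 2: recent window vs the window ten epochs back
    if len(hist) >= 15:
        window1 = hist[-5:]
        window2 = hist[-15:-10]
        res = mannwhitneyu(window2, window1, alternative="less", method="auto")
        if res.pvalue < config.wilcoxon_alpha:
            return True, "wilcoxon"
    return False, None


# ----------------------------------------------------------------------
# Training


class _Adam:
    """Dense Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _masked_mse(model: FactorModel, qm: QuantMatrix, mask: np.ndarray,
                chunk: int = 65536) -> float:
    idx = np.column_stack(np.nonzero(mask))
    total = 0.0
    for start in range(0, idx.shape[0], chunk):
        part = idx[start : start + chunk]
        pred = model.predict_batch(part)
        truth = qm.values[part[:, 0], part[:, 1]]
        total += float(np.sum((pred - truth) ** 2))
    return total / idx.shape[0]


def train(
    model: FactorModel,
    qm: QuantMatrix,
    masks: PartitionMasks,
    config: ModelConfig | None = None,
    sampler: Iterator[np.ndarray] | None = None,
    partition_params: PartitionParams | None = None,
) -> tuple[FactorModel, TrainingLog]:
    """Fit the model to training entries with Adam and early stopping.

    One epoch draws ``ceil(|train| / batch_size)`` biased batches (the
    sampler draws with replacement, so an epoch covers the training set in
    expectation). After each epoch the full validation MSE is recorded and
    the convergence criteria consulted; the parameters from the epoch with
    the lowest validation MSE are returned.
    """
    config = config or model.config
    n_train = int(masks.train_mask.sum())
    n_val = int(masks.val_mask.sum())
    if n_train == 0:
        raise ValueError("training mask is empty")
    if n_val == 0:
        raise ValueError("validation mask is empty (run mcar_validation_split)")
    if sampler is None:
        sampler = biased_batches(
            qm,
            masks,
            batch_size=config.batch_size,
            params=partition_params,
            seed=config.seed,
        )
    batches_per_epoch = math.ceil(n_train / config.batch_size)
    params = model.parameters()
    opt = _Adam(params, config.learning_rate)
    log = TrainingLog()
    best_val = np.inf
    best_params = model.copy_parameters()

    for epoch in range(config.max_epochs):
        epoch_loss = 0.0
        for _ in range(batches_per_epoch):
            idx = next(sampler)
            target = qm.values[idx[:, 0], idx[:, 1]]
            pred, pre_acts, post_acts = model._forward(idx, need_grad=True)
            loss = float(np.mean((pred - target) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            grads = model._backward(idx, pred, target, pre_acts, post_acts)
            opt.step(params, grads)
            model.set_parameters(params)
            epoch_loss += loss
        log.train_mse.append(epoch_loss / batches_per_epoch)
        val_mse = _masked_mse(model, qm, masks.val_mask)
        if not np.isfinite(val_mse):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        log.val_mse.append(val_mse)
        log.epochs_run = epoch + 1
        if val_mse < best_val:
            best_val = val_mse
            best_params = model.copy_parameters()
            log.best_epoch = epoch
        stop, reason = check_convergence(log.val_mse, config)
        if stop:
            log.stop_reason = reason
            break
    else:
        log.stop_reason = "max_epochs"

    model.set_parameters(best_params)
    return model, log


# ----------------------------------------------------------------------
# Imputation and persistence


def impute_matrix(
    qm: QuantMatrix,
    predictions: np.ndarray,
    keep_observed: bool = True,
) -> QuantMatrix:
    """Complete a matrix by filling missing entries from a prediction matrix.

    With ``keep_observed`` (default) observed entries are kept verbatim;
    otherwise the full prediction matrix is returned (reconstruction mode).
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != qm.values.shape:
        raise ValueError("prediction matrix shape mismatch")
    missing = qm.missing_mask()
    if not np.isfinite(predictions[missing]).all():
        raise ValueError("non-finite predictions at missing positions")
    out = qm.copy()
    if keep_observed:
        out.values = np.where(missing, predictions, qm.values)
    else:
        out.values = predictions.copy()
    return out


def save_model(model: FactorModel, path: str | Path) -> None:
    """Persist parameters + config in a single .npz archive."""
    cfg = model.config
    np.savez(
        path,
        n_layers=len(model.layers),
        config=np.array(
            [
                cfg.n_protein_factors,
                cfg.n_sample_factors,
                cfg.n_hidden_layers,
                cfg.n_nodes_per_layer,
                cfg.leaky_slope,
                cfg.learning_rate,
                cfg.batch_size,
                cfg.tolerance,
                cfg.patience,
                cfg.wilcoxon_alpha,
                cfg.max_epochs,
                cfg.seed,
            ]
        ),
        **model.parameters(),
    )


def load_model(path: str | Path) -> FactorModel:
    with np.load(path) as data:
        c = data["config"]
        cfg = ModelConfig(
            n_protein_factors=int(c[0]),
            n_sample_factors=int(c[1]),
            n_hidden_layers=int(c[2]),
            n_nodes_per_layer=int(c[3]),
            leaky_slope=float(c[4]),
            learning_rate=float(c[5]),
            batch_size=int(c[6]),
            tolerance=float(c[7]),
            patience=int(c[8]),
            wilcoxon_alpha=float(c[9]),
            max_epochs=int(c[10]),
            seed=int(c[11]),
        )
        n_layers = int(data["n_layers"])
        layers = [(data[f"w{k}"], data[f"b{k}"]) for k in range(n_layers)]
        return FactorModel(data["W"], data["H"], layers, cfg)
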