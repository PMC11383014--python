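"""MNAR data partitioning and biased training-batch selection.

Mass-spectrometry missingness is left-censored: low-intensity peptides are
preferentially absent. To evaluate imputation under that regime, present
entries are split into train and test sets with a threshold mechanism: each
entry X_ij is compared against a random cutoff T_ij drawn from a Normal
distribution centred near the low end of the observed intensities (the 25th
percentile by default, sd = 1.1 × the matrix sd). Entries falling below their
cutoff become test-set candidates and enter the test set on a Bernoulli(0.61)
success; everything else trains. The resulting test set is left-skewed
relative to the training set, mimicking the values a real instrument drops.

A validation set for early stopping is carved out of the training entries
completely at random (MCAR), and training batches are drawn with replacement
using the same threshold mechanism so the batch stream is itself left-shifted
toward the intensities the model must ultimately predict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.stats import norm

from .matrix import QuantMatrix

__all__ = [
    "PartitionParams",
    "PartitionMasks",
    "mnar_partition",
    "calibrate_bernoulli_p",
    "mcar_validation_split",
    "biased_batches",
    "write_masks",
    "read_masks",
]


@dataclass(frozen=True)
class PartitionParams:
    """Parameters of the threshold distribution and test-assignment trial.

    center_quantile : quantile of present values at which the threshold
        distribution is centred (default 0.25, the 25th percentile).
    sd_multiplier : threshold sd = sd_multiplier × sd of present values
        (default 1.1).
    bernoulli_p : probability that a below-threshold entry is assigned to
        the test set (default 0.61, calibrated so ~20% of present entries
        land in the test set on roughly-normal data).
    target_test_fraction : desired test share used by the calibration helper.
    """

    center_quantile: float = 0.25
    sd_multiplier: float = 1.1
    bernoulli_p: float = 0.61
    target_test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bernoulli_p <= 1.0:
            raise ValueError("bernoulli_p must be in [0, 1]")
        if not 0.0 < self.center_quantile < 1.0:
            raise ValueError("center_quantile must be in (0, 1)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if not 0.0 <= self.target_test_fraction < 1.0:
            raise ValueError("target_test_fraction must be in [0, 1)")


@dataclass
class PartitionMasks:
    """Disjoint boolean train/validation/test masks over present entries."""

    train_mask: np.ndarray
    val_mask: np.ndarray
    test_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.train_mask, self.val_mask, self.test_mask)}
        if len(shapes) != 1:
            raise ValueError("masks must share one shape")
        if (
            (self.train_mask & self.val_mask).any()
            or (self.train_mask & self.test_mask).any()
            or (self.val_mask & self.test_mask).any()
        ):
            raise ValueError("masks must be pairwise disjoint")

    def union(self) -> np.ndarray:
        return self.train_mask | self.val_mask | self.test_mask

    def copy(self) -> "PartitionMasks":
        return PartitionMasks(
            self.train_mask.copy(), self.val_mask.copy(), self.test_mask.copy()
        )


def _threshold_moments(qm: QuantMatrix, params: PartitionParams) -> tuple[float, float]:
    present = qm.values[qm.present_mask()]
    if present.size == 0:
        raise ValueError("matrix has no present entries")
    center = float(np.quantile(present, params.center_quantile))
    sd = params.sd_multiplier * float(np.std(present))
    return center, sd


def mnar_partition(qm: QuantMatrix, params: PartitionParams) -> PartitionMasks:
    """Split present entries into train/test with the threshold mechanism.

    Each present entry draws an independent threshold
    ``T_ij ~ Normal(center, sd)``; entries with ``X_ij < T_ij`` (low relative
    to their cutoff) run a Bernoulli(``bernoulli_p``) trial — success sends
    them to the test set — while all other entries train. The validation
    mask is empty at this stage (see :func:`mcar_validation_split`).
    Deterministic given ``params.seed``.
    """
    center, sd = _threshold_moments(qm, params)
    present = qm.present_mask()
    rng = np.random.default_rng(params.seed)
    thresholds = rng.normal(center, sd, size=qm.values.shape)
    with np.errstate(invalid="ignore"):
        below = (qm.values < thresholds) & present
    trials = rng.random(qm.values.shape) < params.bernoulli_p
    test = below & trials
    train = present & ~test
    return PartitionMasks(
        train_mask=train,
        val_mask=np.zeros_like(train, dtype=bool),
        test_mask=test,
    )


def censoring_probability(qm: QuantMatrix, params: PartitionParams) -> float:
    """Mean analytic probability that a present entry falls below its threshold.

    Per entry, ``P(x < T) = Phi((center - x) / sd)`` under the threshold
    Normal; averaged over present entries this is the maximum achievable
    test fraction (reached at bernoulli_p = 1).
    """
    center, sd = _threshold_moments(qm, params)
    present = qm.values[qm.present_mask()]
    return float(np.mean(norm.cdf((center - present) / sd)))


def calibrate_bernoulli_p(
    qm: QuantMatrix,
    params: PartitionParams,
    target: float | None = None,
) -> float:
    """Solve for the Bernoulli success probability giving a target test share.

    The expected test fraction is ``p × P(X < T)``; the censoring probability
    is computed analytically per entry from the Normal CDF (no resampling),
    and ``p = target / P(X < T)``, clipped to [0, 1].
    """
    if target is None:
        target = params.target_test_fraction
    if not 0.0 <= target < 1.0:
        raise ValueError("target must be in [0, 1)")
    q = censoring_probability(qm, params)
    if target == 0.0:
        return 0.0
    if target > q:
        raise ValueError(
            f"target test fraction {target:.3f} unreachable: at bernoulli_p=1 "
            f"the expected maximum is {q:.3f}"
        )
    return float(np.clip(target / q, 0.0, 1.0))


def mcar_validation_split(
    masks: PartitionMasks,
    fraction: float = 0.10,
    seed: int = 0,
) -> PartitionMasks:
    """Move a uniformly random subset of training entries into validation.

    Exactly ``floor(fraction × |train|)`` entries move; the test mask is
    untouched. Because the draw is uniform (MCAR), validation intensities
    are unbiased with respect to the training distribution.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    train_idx = np.flatnonzero(masks.train_mask)
    if train_idx.size == 0:
        raise ValueError("training mask is empty")
    n_val = int(fraction * train_idx.size)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(train_idx, size=n_val, replace=False)
    out = masks.copy()
    flat_train = out.train_mask.reshape(-1)
    flat_val = out.val_mask.reshape(-1)
    flat_train[chosen] = False
    flat_val[chosen] = True
    return out


def biased_batches(
    qm: QuantMatrix,
    masks: PartitionMasks,
    batch_size: int = 128,
    params: PartitionParams | None = None,
    seed: int = 0,
    n_batches: int | None = None,
    uniform: bool = False,
) -> Iterator[np.ndarray]:
    """Yield training batches biased toward low-intensity entries.

    Candidates are drawn uniformly with replacement from training entries.
    Each candidate draws a fresh threshold ``T ~ Normal(center, sd)`` (the
    partitioning distribution): values below T are accepted outright, values
    at or above T are accepted with probability 0.5, and rejected candidates
    are redrawn until the batch holds exactly ``batch_size`` (protein,
    sample) index pairs. Pooled over many batches the accepted values are
    therefore left-shifted relative to the full training set. ``uniform=True``
    disables the acceptance rule (plain uniform resampling, for comparison).
    Deterministic given ``seed``; yields forever unless ``n_batches`` is set.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    params = params or PartitionParams()
    train_idx = np.flatnonzero(masks.train_mask)
    if train_idx.size == 0:
        raise ValueError("training mask is empty")
    center, sd = _threshold_moments(qm, params)
    flat_values = qm.values.reshape(-1)
    rng = np.random.default_rng(seed)

    yielded = 0
    while n_batches is None or yielded < n_batches:
        accepted: list[np.ndarray] = []
        n_have = 0
        while n_have < batch_size:
            draw = max(batch_size - n_have, 64)
            cand = rng.choice(train_idx, size=draw, replace=True)
            if uniform:
                keep = cand
            else:
                thresholds = rng.normal(center, sd, size=draw)
                below = flat_values[cand] < thresholds
                coin = rng.random(draw) < 0.5
                keep = cand[below | coin]
            accepted.append(keep)
            n_have += keep.size
        flat = np.concatenate(accepted)[:batch_size]
        yield np.column_stack(np.unravel_index(flat, qm.values.shape)).astype(np.int64)
        yielded += 1


# ----------------------------------------------------------------------
# Mask serialization: delimited (protein_id, sample_id, split) triplets


def write_masks(
    masks: PartitionMasks,
    qm: QuantMatrix,
    path,
    header_lines=(),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tsample_id\tsplit\n")
        for name, mask in (
            ("train", masks.train_mask),
            ("val", masks.val_mask),
            ("test", masks.test_mask),
        ):
            rows, cols = np.nonzero(mask)
            for i, j in zip(rows, cols):
                fh.write(f"{qm.protein_ids[i]}\t{qm.sample_ids[j]}\t{name}\n")


def read_masks(path, qm: QuantMatrix) -> PartitionMasks:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    prot_idx = {p: i for i, p in enumerate(qm.protein_ids)}
    samp_idx = {s: j for j, s in enumerate(qm.sample_ids)}
    shape = qm.values.shape
    out = {
        "train": np.zeros(shape, dtype=bool),
        "val": np.zeros(shape, dtype=bool),
        "test": np.zeros(shape, dtype=bool),
    }
    for p, s, split in df.itertuples(index=False):
        try:
            out[split][prot_idx[p], samp_idx[s]] = True
        except KeyError as exc:
            raise ValueError(f"mask entry refers to unknown id: {exc}") from exc
    return PartitionMasks(out["train"], out["val"], out["test"])
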