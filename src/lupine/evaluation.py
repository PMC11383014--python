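"""Imputation accuracy metrics.

Accuracy is measured on held-out test entries whose true values are known:
mean squared error overall and per cohort, per-protein residual summaries,
and the "fraction better" statistic comparing two imputers protein by
protein (restricted to proteins where at least one method errs appreciably,
so near-perfect proteins do not dilute the comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import QuantMatrix

__all__ = ["EvalReport", "test_mse", "per_protein_residual", "fraction_better"]


@dataclass
class EvalReport:
    overall_mse: float
    mse_by_cohort: dict[str, float]
    n_test_entries_by_cohort: dict[str, int]
    n_test_entries: int = 0


def test_mse(
    predictions: np.ndarray,
    qm_truth: QuantMatrix,
    test_mask: np.ndarray,
    by_cohort: bool = True,
) -> EvalReport:
    """Mean squared prediction error over test entries, overall and per cohort.

    A cohort with no test entries is reported as NaN (undefined), never 0.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != qm_truth.values.shape:
        raise ValueError("prediction matrix shape mismatch")
    if not test_mask.any():
        raise ValueError("test mask is empty")
    if np.isnan(qm_truth.values[test_mask]).any():
        raise ValueError("truth missing at some test entries")
    sq = (predictions - qm_truth.values) ** 2
    overall = float(sq[test_mask].mean())
    mse_by_cohort: dict[str, float] = {}
    n_by_cohort: dict[str, int] = {}
    if by_cohort:
        labels = qm_truth.cohort_labels()
        for cohort in qm_truth.cohorts():
            cols = labels == cohort
            m = test_mask[:, cols]
            n = int(m.sum())
            n_by_cohort[cohort] = n
            mse_by_cohort[cohort] = float(sq[:, cols][m].mean()) if n else float("nan")
    return EvalReport(
        overall_mse=overall,
        mse_by_cohort=mse_by_cohort,
        n_test_entries_by_cohort=n_by_cohort,
        n_test_entries=int(test_mask.sum()),
    )


def per_protein_residual(
    predictions: np.ndarray,
    qm_truth: QuantMatrix,
    test_mask: np.ndarray,
    aggregate: str = "mean_abs",
) -> dict[str, float]:
    """Per-protein residual summary over that protein's test entries.

    ``aggregate`` is ``"mean_abs"`` (mean absolute residual, default),
    ``"rms"`` (root mean square), or ``"signed_mean"`` (mean signed
    residual, useful for scatter plots). Proteins without test entries are
    omitted.
    """
    predictions = np.asarray(predictions, dtype=float)
    resid = predictions - qm_truth.values
    out: dict[str, float] = {}
    for i, pid in enumerate(qm_truth.protein_ids):
        row = resid[i, test_mask[i]]
        if row.size == 0:
            continue
        if aggregate == "mean_abs":
            out[pid] = float(np.abs(row).mean())
        elif aggregate == "rms":
            out[pid] = float(np.sqrt((row**2).mean()))
        elif aggregate == "signed_mean":
            out[pid] = float(row.mean())
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    return out


def fraction_better(
    residuals_a: dict[str, float],
    residuals_b: dict[str, float],
    min_residual: float = 0.25,
) -> float:
    """Fraction of proteins on which method A out-predicts method B.

    Restricted to shared proteins where either method's residual exceeds
    ``min_residual``; ties count against A (conservative). Returns NaN with
    a warning when the restriction empties the comparison set.
    """
    shared = sorted(set(residuals_a) & set(residuals_b))
    if not shared:
        raise ValueError("residual mappings share no proteins")
    kept = [p for p in shared if max(residuals_a[p], residuals_b[p]) > min_residual]
    if not kept:
        warnings.warn(
            "no protein exceeds the residual threshold; fraction undefined",
            stacklevel=2,
        )
        return float("nan")
    better = sum(1 for p in kept if residuals_a[p] < residuals_b[p])
    return better / len(kept)
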