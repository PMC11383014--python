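"""Downstream biology: differential expression and complex co-expression.

Two analyses probe whether an imputed matrix supports the inferences
practitioners actually draw from TMT cohorts:

* **Differential expression** — per protein, a paired t-test between tumor
  and matched non-tumor samples of the same patients, Benjamini-Hochberg
  adjustment across tested proteins, and a call of up/down/none at an
  adjusted-p and absolute log2-fold-change cutoff. Proteins that were mostly
  missing before imputation are excluded, since their tests would rest
  almost entirely on imputed values.

* **Complex co-expression** — subunits of an annotated protein complex
  (CORUM-style) should co-vary; the Spearman correlation of every
  within-complex protein pair is compared with an equally sized set of
  random non-complex pairs. A good imputer preserves the within-complex
  signal and leaves the background near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import QuantMatrix

__all__ = [
    "bh_adjust",
    "spearman",
    "run_de",
    "complex_correlations",
    "ComplexCorrReport",
    "read_complex_table",
    "write_de_table",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted p-values are scaled by m/rank, a running minimum from the largest
    rank down enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; ties averaged).

    Pairs with a missing member are dropped first. Returns NaN when fewer
    than three complete pairs remain or either sequence is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


# ----------------------------------------------------------------------
# Differential expression


def _tumor_normal_pairs(qm: QuantMatrix) -> list[tuple[int, int]]:
    """Column-index pairs (tumor, non_tumor) matched by patient."""
    if qm.sample_type is None or qm.patient_of_sample is None:
        raise ValueError("sample_type and patient_of_sample annotations required")
    tumor: dict[str, int] = {}
    normal: dict[str, int] = {}
    for j, s in enumerate(qm.sample_ids):
        stype = qm.sample_type.get(s)
        patient = qm.patient_of_sample.get(s)
        if patient is None or stype is None:
            continue
        if stype == "tumor":
            tumor.setdefault(patient, j)
        elif stype == "non_tumor":
            normal.setdefault(patient, j)
    return [(tumor[p], normal[p]) for p in tumor if p in normal]


def run_de(
    completed: QuantMatrix,
    pre_imputation: QuantMatrix,
    alpha: float = 0.01,
    lfc_cut: float = 0.5,
    max_missing: float = 0.5,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Tumor vs matched non-tumor differential expression.

    Proteins whose pre-imputation missing fraction exceeds ``max_missing``
    are excluded. For each remaining protein a two-sided paired t-test is
    run on per-patient tumor-minus-normal differences (values are assumed
    log2-like, so the mean paired difference is the log2 fold change).
    P-values are BH-adjusted across tested proteins; a protein is called
    ``up`` when adjusted p < alpha and log2FC > lfc_cut, ``down`` when
    adjusted p < alpha and log2FC < -lfc_cut, else ``none``.

    Passing a matrix that still contains missing values runs the
    no-imputation mode: patient pairs with a missing member are dropped
    per protein, and proteins left with fewer than two pairs get undefined
    p-values and are excluded from the BH family.

    Returns a DataFrame indexed by protein ID with columns
    ``log2_fold_change, t_statistic, p_value, adjusted_p, direction,
    pre_imputation_missing_fraction, n_pairs``.
    """
    if completed.protein_ids != pre_imputation.protein_ids:
        raise ValueError("completed and pre-imputation matrices must share proteins")
    if cohort is not None:
        keep = [s for s in completed.sample_ids
                if completed.cohort_of_sample[s] == cohort]
        completed = completed.subset(samples=keep)
        pre_imputation = pre_imputation.subset(samples=keep)
    pairs = _tumor_normal_pairs(completed)
    if len(pairs) < 2:
        raise ValueError("need at least two complete tumor/non-tumor patient pairs")
    t_cols = np.array([t for t, _ in pairs])
    n_cols = np.array([n for _, n in pairs])

    pre_missing = np.isnan(pre_imputation.values).mean(axis=1)
    rows = []
    for i, pid in enumerate(completed.protein_ids):
        if pre_missing[i] > max_missing:
            continue
        diffs = completed.values[i, t_cols] - completed.values[i, n_cols]
        diffs = diffs[~np.isnan(diffs)]
        if diffs.size < 2:
            rows.append((pid, float("nan"), float("nan"), float("nan"),
                         float(pre_missing[i]), int(diffs.size)))
            continue
        lfc = float(diffs.mean())
        if np.allclose(diffs, diffs[0]):
            # zero-variance differences: t undefined unless the shift is 0
            t_stat, p = (0.0, 1.0) if np.isclose(lfc, 0.0) else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(
                completed.values[i, t_cols], completed.values[i, n_cols],
                nan_policy="omit",
            )
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append((pid, lfc, t_stat, p, float(pre_missing[i]), int(diffs.size)))

    table = pd.DataFrame(
        rows,
        columns=["protein_id", "log2_fold_change", "t_statistic", "p_value",
                 "pre_imputation_missing_fraction", "n_pairs"],
    ).set_index("protein_id")
    tested = table["p_value"].notna()
    adjusted = np.full(len(table), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table["adjusted_p"] = adjusted
    direction = np.where(
        (table["adjusted_p"] < alpha) & (table["log2_fold_change"] > lfc_cut), "up",
        np.where(
            (table["adjusted_p"] < alpha) & (table["log2_fold_change"] < -lfc_cut),
            "down", "none",
        ),
    )
    table["direction"] = direction
    return table


# ----------------------------------------------------------------------
# Complex correlations


@dataclass
class ComplexCorrReport:
    """Within-complex vs random-background Spearman correlation sets."""

    within_correlations: np.ndarray
    background_correlations: np.ndarray
    mean_within: float
    mean_background: float
    p_value: float
    n_pairs: int


def complex_correlations(
    completed: QuantMatrix,
    complexes: dict[str, set[str]],
    cohort: str | None = None,
    tumor_only: bool = True,
    max_missing: float = 0.5,
    pre_imputation: QuantMatrix | None = None,
    seed: int = 0,
) -> ComplexCorrReport:
    """Compare within-complex to random non-complex pair correlations.

    Columns are restricted to the requested cohort (and, when annotations
    allow, to tumor samples); proteins are restricted to those with
    pre-imputation missing fraction below ``max_missing``. The within set
    holds the Spearman correlation of every unordered within-complex pair
    (deduplicated across complexes); the background set holds equally many
    uniformly drawn pairs that are internal to no complex. The two sets'
    means are compared with a Welch two-sample t-test.
    """
    pre = pre_imputation if pre_imputation is not None else completed
    if completed.protein_ids != pre.protein_ids:
        raise ValueError("completed and pre-imputation matrices must share proteins")
    samples = completed.sample_ids
    if cohort is not None:
        samples = [s for s in samples if completed.cohort_of_sample[s] == cohort]
    if tumor_only and completed.sample_type is not None:
        tumor = [s for s in samples if completed.sample_type.get(s) == "tumor"]
        if tumor:
            samples = tumor
    sub = completed.subset(samples=samples)
    pre_sub = pre.subset(samples=samples)

    pre_missing = np.isnan(pre_sub.values).mean(axis=1)
    eligible = {
        pid for pid, frac in zip(sub.protein_ids, pre_missing) if frac < max_missing
    }
    index = {pid: i for i, pid in enumerate(sub.protein_ids)}

    within_pairs: set[frozenset[str]] = set()
    complex_pairs: set[frozenset[str]] = set()
    for members in complexes.values():
        present = sorted(m for m in members if m in index)
        for a_i in range(len(present)):
            for b_i in range(a_i + 1, len(present)):
                pair = frozenset((present[a_i], present[b_i]))
                complex_pairs.add(pair)
                if present[a_i] in eligible and present[b_i] in eligible:
                    within_pairs.add(pair)
    if not within_pairs:
        raise ValueError("no complex retains at least two eligible members")

    def _corr(pair: frozenset[str]) -> float:
        a, b = sorted(pair)
        return spearman(sub.values[index[a]], sub.values[index[b]])

    within = np.array([_corr(p) for p in sorted(within_pairs, key=sorted)])
    within = within[~np.isnan(within)]
    n_pairs = within.size
    if n_pairs == 0:
        raise ValueError("all within-complex correlations are undefined")

    pool = sorted(eligible)
    total_pairs = len(pool) * (len(pool) - 1) // 2
    if total_pairs - len(complex_pairs) < n_pairs:
        raise ValueError("not enough eligible non-complex pairs for the background")
    rng = np.random.default_rng(seed)
    background: list[float] = []
    chosen: set[frozenset[str]] = set()
    while len(background) < n_pairs:
        a, b = rng.choice(len(pool), size=2, replace=False)
        pair = frozenset((pool[a], pool[b]))
        if pair in complex_pairs or pair in chosen:
            continue
        rho = _corr(pair)
        if np.isnan(rho):
            continue
        chosen.add(pair)
        background.append(rho)
    background_arr = np.array(background)

    p_value = float(
        stats.ttest_ind(within, background_arr, equal_var=False).pvalue
    )
    return ComplexCorrReport(
        within_correlations=within,
        background_correlations=background_arr,
        mean_within=float(within.mean()),
        mean_background=float(background_arr.mean()),
        p_value=p_value,
        n_pairs=n_pairs,
    )


# ----------------------------------------------------------------------
# I/O helpers


def read_complex_table(path: str | Path, dialect: str | None = None) -> dict[str, set[str]]:
    """Read a flat complex-membership table (columns complex_id, protein_id)."""
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if not {"complex_id", "protein_id"}.issubset(df.columns):
        raise ValueError("complex table needs complex_id and protein_id columns")
    out: dict[str, set[str]] = {}
    for cid, pid in zip(df["complex_id"], df["protein_id"]):
        out.setdefault(cid, set()).add(pid)
    return out


def write_de_table(table: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t")
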