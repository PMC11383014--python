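"""Reference imputers: downshifted Gaussian sampling and column minimum.

Both are per-sample (per-column) procedures widely used in proteomics
practice. Gaussian random sampling draws each missing value from a Normal
distribution centred below the column's observed mean — emulating the
left-censored values the instrument failed to record — while column-minimum
replaces every missing value with the lowest observed quantification in
that MS sample. They serve as the naive comparison points for the learned
imputer.
"""

from __future__ import annotations

import numpy as np

from .matrix import QuantMatrix

__all__ = ["gaussian_sample_impute", "column_min_impute"]


def gaussian_sample_impute(
    qm: QuantMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> QuantMatrix:
    """Fill missing entries by downshifted per-column Gaussian sampling.

    For a column with observed mean mu and standard deviation sigma, each
    missing entry is drawn i.i.d. from Normal(mu - downshift*sigma,
    (width*sigma)^2). ``width=0.3`` and ``downshift=1.8`` are the customary
    defaults for log-scale intensities. Observed entries are untouched.
    """
    if width < 0 or downshift < 0:
        raise ValueError("width and downshift must be non-negative")
    rng = np.random.default_rng(seed)
    out = qm.copy()
    values = out.values
    for j in range(qm.n_samples):
        col = values[:, j]
        observed = col[~np.isnan(col)]
        if observed.size < 2:
            raise ValueError(
                f"column {qm.sample_ids[j]!r} has fewer than 2 observed values"
            )
        mu = float(observed.mean())
        sigma = float(observed.std())
        miss = np.isnan(col)
        n_miss = int(miss.sum())
        if n_miss:
            col[miss] = rng.normal(mu - downshift * sigma, width * sigma, size=n_miss)
    return out


def column_min_impute(qm: QuantMatrix) -> QuantMatrix:
    """Fill missing entries with the column's lowest observed value."""
    out = qm.copy()
    values = out.values
    for j in range(qm.n_samples):
        col = values[:, j]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise ValueError(f"column {qm.sample_ids[j]!r} is fully missing")
        col[np.isnan(col)] = observed.min()
    return out
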