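"""Protein-by-sample quantification matrices.

The central container is :class:`QuantMatrix`: a proteins × samples matrix of
log-scale intensities in which ``NaN`` marks a missing quantification, plus
per-sample annotations (cohort, tumor/non-tumor status, patient pairing, TMT
plex). Reporter-ion intensities from multi-plex TMT experiments are assumed to
have been de-multiplexed, reference-normalized and log-transformed upstream;
this module only reads, joins, filters and writes such tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "read_quant_table",
    "write_quant_table",
    "read_sample_metadata",
    "join_cohorts",
    "filter_matrix",
    "missing_fraction",
    "DEFAULT_EXCLUDE_KEYWORDS",
]

#: Sample-ID substrings identifying reference channels, QC runs and pooled
#: samples; matching is case-insensitive so "ref" also catches "RefInt".
DEFAULT_EXCLUDE_KEYWORDS: tuple[str, ...] = (
    "RefInt",
    "QC",
    "pool",
    "pooled",
    "reference",
    "NCI",
    "NX",
    "ref",
)


@dataclass
class QuantMatrix:
    """A proteins × samples log-intensity matrix with missing entries as NaN.

    Parameters
    ----------
    values
        Float array of shape ``(n_proteins, n_samples)``. ``NaN`` is the only
        permitted non-finite value and marks a missing quantification.
    protein_ids, sample_ids
        Unique identifiers for the rows and columns.
    cohort_of_sample
        Mapping ``sample_id -> cohort label``; every sample must have one.
    sample_type
        Optional mapping ``sample_id -> {"tumor", "non_tumor"}``.
    patient_of_sample
        Optional mapping ``sample_id -> patient identifier`` (used to pair
        tumor with matched non-tumor columns).
    plex_of_sample
        Optional mapping ``sample_id -> TMT plex identifier``.
    """

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    cohort_of_sample: dict[str, str] = field(default_factory=dict)
    sample_type: dict[str, str] | None = None
    patient_of_sample: dict[str, str] | None = None
    plex_of_sample: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_prot, n_samp = self.values.shape
        if n_prot != len(self.protein_ids):
            raise ValueError(
                f"{n_prot} rows but {len(self.protein_ids)} protein ids"
            )
        if n_samp != len(self.sample_ids):
            raise ValueError(
                f"{n_samp} columns but {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.protein_ids, "protein")
        _check_unique(self.sample_ids, "sample")
        with np.errstate(invalid="ignore"):
            bad = np.isinf(self.values)
        if bad.any():
            raise ValueError("infinite values present; only NaN marks missing")
        if not self.cohort_of_sample:
            # a single unlabeled cohort is the default for single-table input
            self.cohort_of_sample = {s: "cohort0" for s in self.sample_ids}
        missing_cohort = [s for s in self.sample_ids if s not in self.cohort_of_sample]
        if missing_cohort:
            raise ValueError(f"samples without a cohort label: {missing_cohort[:5]}")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def present_mask(self) -> np.ndarray:
        """Boolean matrix, True where a quantification was observed."""
        return ~np.isnan(self.values)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def cohorts(self) -> list[str]:
        """Cohort labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.cohort_of_sample[s], None)
        return list(seen)

    def cohort_labels(self) -> np.ndarray:
        """Per-column cohort label array (length n_samples)."""
        return np.array([self.cohort_of_sample[s] for s in self.sample_ids])

    def subset(
        self,
        proteins: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "QuantMatrix":
        """Row/column subset by identifier, preserving annotation mappings."""
        prot = list(proteins) if proteins is not None else self.protein_ids
        samp = list(samples) if samples is not None else self.sample_ids
        ridx = [self.protein_ids.index(p) for p in prot]
        cidx = [self.sample_ids.index(s) for s in samp]
        keep = set(samp)

        def _sub(m: dict[str, str] | None) -> dict[str, str] | None:
            if m is None:
                return None
            return {s: m[s] for s in samp if s in m}

        return QuantMatrix(
            values=self.values[np.ix_(ridx, cidx)].copy(),
            protein_ids=prot,
            sample_ids=samp,
            cohort_of_sample={s: self.cohort_of_sample[s] for s in keep},
            sample_type=_sub(self.sample_type),
            patient_of_sample=_sub(self.patient_of_sample),
            plex_of_sample=_sub(self.plex_of_sample),
        )

    def copy(self) -> "QuantMatrix":
        return replace(self, values=self.values.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )

    def with_annotations(self, metadata: pd.DataFrame) -> "QuantMatrix":
        """Attach sample annotations from a metadata table.

        Expected columns: ``sample_id`` plus any of ``cohort``,
        ``sample_type``, ``patient_id``, ``plex``. Samples absent from the
        table keep their current annotations.
        """
        meta = metadata.set_index(metadata["sample_id"].astype(str))
        out = self.copy()

        def _merge(current: dict[str, str] | None, col: str) -> dict[str, str] | None:
            if col not in meta.columns:
                return current
            new = dict(current or {})
            for s in self.sample_ids:
                if s in meta.index and not pd.isna(meta.at[s, col]):
                    new[s] = str(meta.at[s, col])
            return new or None

        out.cohort_of_sample = _merge(self.cohort_of_sample, "cohort") or {}
        out.sample_type = _merge(self.sample_type, "sample_type")
        out.patient_of_sample = _merge(self.patient_of_sample, "patient_id")
        out.plex_of_sample = _merge(self.plex_of_sample, "plex")
        return out


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {axis} ID: {x!r}")
        seen.add(x)


# ----------------------------------------------------------------------
# I/O

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def read_quant_table(
    path: str | Path,
    dialect: str | None = None,
    log2: bool = False,
) -> QuantMatrix:
    """Read a delimited proteins × samples quantification table.

    First column holds protein IDs, the header row holds sample IDs. Blank
    cells and NA/NaN tokens become missing values. Values are assumed to be
    log-scale already; pass ``log2=True`` to log2-transform raw intensities
    on read (zeros/negatives then become missing).
    """
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix == ".csv" else "\t")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, comment="#")
    protein_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(protein_ids, "protein")
    _check_unique(sample_ids, "sample")

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                values[i, j] = np.nan
                continue
            token = str(cell).strip()
            if token.lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(token)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {token!r} at protein {protein_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from exc
    if log2:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(values > 0, np.log2(values), np.nan)
    return QuantMatrix(values=values, protein_ids=protein_ids, sample_ids=sample_ids)


def write_quant_table(
    qm: QuantMatrix,
    path: str | Path,
    dialect: str | None = None,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a QuantMatrix as a delimited table (missing entries blank).

    ``header_lines`` are emitted first as ``#``-prefixed comment lines
    (used by the CLI for provenance stamping).
    """
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix == ".csv" else "\t")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        qm.to_frame().to_csv(fh, sep=sep, na_rep="")


def read_sample_metadata(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table (columns: sample_id, cohort, ...)."""
    path = Path(path)
    sep = dialect if dialect is not None else ("," if path.suffix == ".csv" else "\t")
    meta = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if "sample_id" not in meta.columns:
        raise ValueError("metadata table must have a 'sample_id' column")
    return meta


# ----------------------------------------------------------------------
# Joining and filtering


def join_cohorts(
    matrices: Sequence[QuantMatrix],
    labels: Sequence[str],
) -> QuantMatrix:
    """Concatenate per-cohort matrices into one joint quantification matrix.

    Rows are the union of all protein IDs (first-appearance order); columns
    are the concatenation of all samples. A protein absent from a cohort's
    table is missing (NaN) in every column of that cohort. Sample IDs must be
    globally unique; they are prefixed with the cohort label when not.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one cohort matrix to join")
    if len(labels) != len(matrices):
        raise ValueError("one label per cohort matrix required")

    all_samples: list[str] = []
    for qm in matrices:
        all_samples.extend(qm.sample_ids)
    prefix_needed = len(set(all_samples)) != len(all_samples)

    proteins: dict[str, int] = {}
    for qm in matrices:
        for p in qm.protein_ids:
            proteins.setdefault(p, len(proteins))
    protein_ids = list(proteins)

    sample_ids: list[str] = []
    cohort_of_sample: dict[str, str] = {}
    sample_type: dict[str, str] = {}
    patient_of_sample: dict[str, str] = {}
    plex_of_sample: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for qm, label in zip(matrices, labels):
        block = np.full((len(protein_ids), qm.n_samples), np.nan)
        ridx = np.array([proteins[p] for p in qm.protein_ids])
        block[ridx, :] = qm.values
        blocks.append(block)
        for s in qm.sample_ids:
            sid = f"{label}.{s}" if prefix_needed else s
            sample_ids.append(sid)
            cohort_of_sample[sid] = str(label)
            if qm.sample_type and s in qm.sample_type:
                sample_type[sid] = qm.sample_type[s]
            if qm.patient_of_sample and s in qm.patient_of_sample:
                patient_of_sample[sid] = qm.patient_of_sample[s]
            if qm.plex_of_sample and s in qm.plex_of_sample:
                plex_of_sample[sid] = qm.plex_of_sample[s]

    return QuantMatrix(
        values=np.concatenate(blocks, axis=1),
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        cohort_of_sample=cohort_of_sample,
        sample_type=sample_type or None,
        patient_of_sample=patient_of_sample or None,
        plex_of_sample=plex_of_sample or None,
    )


def filter_matrix(
    qm: QuantMatrix,
    min_present: int = 18,
    exclude_keywords: Sequence[str] = DEFAULT_EXCLUDE_KEYWORDS,
) -> QuantMatrix:
    """Drop reference/QC samples, then sparsely-quantified proteins.

    Samples whose ID contains any keyword (case-insensitive substring) are
    removed first; then proteins observed in fewer than ``min_present`` of
    the remaining samples are removed. Row/column order is preserved.
    """
    if min_present < 0:
        raise ValueError("min_present must be non-negative")
    kws = [k.lower() for k in exclude_keywords]
    keep_samples = [
        s for s in qm.sample_ids if not any(k in s.lower() for k in kws)
    ]
    if not keep_samples:
        raise ValueError("keyword filtering removed every sample")
    sub = qm.subset(samples=keep_samples)
    present_per_protein = sub.present_mask().sum(axis=1)
    keep_proteins = [
        p for p, n in zip(sub.protein_ids, present_per_protein) if n >= min_present
    ]
    if not keep_proteins:
        raise ValueError(
            f"no protein is quantified in at least {min_present} samples"
        )
    return sub.subset(proteins=keep_proteins)


def missing_fraction(qm: QuantMatrix) -> float:
    """Fraction of matrix entries that are missing, in [0, 1]."""
    if qm.values.size == 0:
        raise ValueError("empty matrix")
    return float(np.isnan(qm.values).mean())
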