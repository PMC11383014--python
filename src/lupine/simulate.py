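"""Synthetic multi-cohort TMT-like data with known ground truth.

The generator emulates the structure of a joint multi-cohort quantification
matrix on the log-intensity scale: a shared low-rank signal (proteins and
samples living near a low-dimensional subspace), correlated protein blocks
standing in for complexes, additive cohort and TMT-plex batch offsets,
planted tumor-vs-non-tumor shifts on a known protein set, Gaussian
measurement noise, and two layers of missingness — structural (a protein
simply not quantified in a cohort) and intensity-dependent left-censoring,
where the probability that an entry is missing decreases logistically with
its value. Every draw is seed-deterministic, so tests and examples need no
bundled data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import QuantMatrix

__all__ = ["SimSpec", "SimTruth", "simulate_cohorts", "mcar_mask"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic joint-matrix generator.

    Defaults are sized for desk-scale runs: 4 cohorts × 300 proteins × 40
    samples each, rank-5 signal, ~30% intensity-dependent missingness.
    """

    n_cohorts: int = 4
    proteins_per_cohort: int = 300
    samples_per_cohort: int = 40
    shared_protein_fraction: float = 0.7
    latent_rank: int = 5
    factor_scale: float = 1.0
    noise_sd: float = 0.25
    cohort_offset_sd: float = 0.3
    plex_offset_sd: float = 0.2
    n_plexes_per_cohort: int = 4
    paired_patients_per_cohort: int = 20
    n_de_proteins: int = 30
    de_log2_shift: float = 1.0
    de_fraction_up: float = 1.0
    n_complexes: int = 10
    complex_size: int = 5
    complex_loading: float = 0.8
    mnar_slope: float = 1.0
    target_missing_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cohorts",
            "proteins_per_cohort",
            "samples_per_cohort",
            "latent_rank",
            "n_plexes_per_cohort",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("shared_protein_fraction", "target_missing_fraction",
                     "de_fraction_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("noise_sd", "cohort_offset_sd", "plex_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if 2 * self.paired_patients_per_cohort > self.samples_per_cohort:
            raise ValueError("2 × paired patients cannot exceed samples per cohort")
        if self.target_missing_fraction > 0 and self.mnar_slope <= 0:
            raise ValueError("mnar_slope must be positive to censor entries")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated observed matrix."""

    truth: QuantMatrix  # complete matrix (structural absences remain NaN)
    complete_values: np.ndarray  # fully dense truth, no missingness at all
    missing_mask: np.ndarray  # MNAR mask actually applied (True = censored)
    structural_mask: np.ndarray  # protein-not-in-cohort absences
    de_proteins: dict[str, int] = field(default_factory=dict)  # id -> +1/-1
    complexes: dict[str, set[str]] = field(default_factory=dict)


def _calibrate_censor_center(
    values: np.ndarray, slope: float, target: float
) -> float:
    """Bisect for the logistic midpoint giving the target missing rate."""
    if target <= 0:
        return -np.inf

    def expected(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(slope * (values - c)))))

    lo, hi = float(values.min()) - 50.0, float(values.max()) + 50.0
    if not expected(lo) <= target <= expected(hi):
        raise ValueError(f"target missing fraction {target} is infeasible")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohorts(spec: SimSpec) -> tuple[QuantMatrix, SimTruth]:
    """Draw one observed joint matrix and its ground truth.

    Entry values are built as low-rank signal + complex-block factors +
    cohort offset + plex offset + tumor shift (planted proteins only) +
    Gaussian noise. Censoring is entrywise Bernoulli with probability
    ``sigmoid(-mnar_slope * (x - c))``, with c calibrated by bisection so
    the expected missing fraction over structurally present entries hits
    ``target_missing_fraction``.
    """
    rng = np.random.default_rng(spec.seed)

    # protein universe: a shared core plus cohort-private tails
    n_shared = int(round(spec.shared_protein_fraction * spec.proteins_per_cohort))
    n_unique = spec.proteins_per_cohort - n_shared
    n_proteins = n_shared + spec.n_cohorts * n_unique
    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]
    cohort_names = [f"cohort{c}" for c in range(spec.n_cohorts)]
    cohort_proteins = {
        name: list(range(n_shared))
        + list(range(n_shared + c * n_unique, n_shared + (c + 1) * n_unique))
        for c, name in enumerate(cohort_names)
    }

    # samples: paired tumor/non-tumor patients first, unpaired tumor after
    sample_ids: list[str] = []
    cohort_of_sample: dict[str, str] = {}
    sample_type: dict[str, str] = {}
    patient_of_sample: dict[str, str] = {}
    plex_of_sample: dict[str, str] = {}
    tumor_cols: list[int] = []
    col = 0
    for c, name in enumerate(cohort_names):
        for k in range(spec.samples_per_cohort):
            sid = f"{name}.S{k:03d}"
            sample_ids.append(sid)
            cohort_of_sample[sid] = name
            plex_of_sample[sid] = f"{name}.plex{k % spec.n_plexes_per_cohort}"
            if k < 2 * spec.paired_patients_per_cohort:
                patient = f"{name}.patient{k // 2:03d}"
                patient_of_sample[sid] = patient
                stype = "tumor" if k % 2 == 0 else "non_tumor"
            else:
                patient_of_sample[sid] = f"{name}.patient{k:03d}"
                stype = "tumor"
            sample_type[sid] = stype
            if stype == "tumor":
                tumor_cols.append(col)
            col += 1
    n_samples = len(sample_ids)

    # low-rank signal; matched tumor/non-tumor columns share their patient's
    # sample factor, so paired differences isolate the planted effects
    U = rng.normal(0.0, spec.factor_scale, size=(n_proteins, spec.latent_rank))
    V = rng.normal(0.0, 1.0, size=(spec.latent_rank, n_samples))
    patient_col: dict[str, int] = {}
    for j, sid in enumerate(sample_ids):
        patient = patient_of_sample[sid]
        if patient in patient_col:
            V[:, j] = V[:, patient_col[patient]]
        else:
            patient_col[patient] = j
    values = (U @ V) / np.sqrt(spec.latent_rank)

    # correlated complex blocks on proteins outside the planted DE set
    de_idx = rng.choice(n_shared, size=min(spec.n_de_proteins, n_shared),
                        replace=False)
    de_set = set(int(i) for i in de_idx)
    free = [i for i in range(n_proteins) if i not in de_set]
    complexes: dict[str, set[str]] = {}
    needed = spec.n_complexes * spec.complex_size
    if spec.n_complexes > 0 and needed <= len(free):
        members = rng.choice(len(free), size=needed, replace=False)
        for k in range(spec.n_complexes):
            rows = [free[m] for m in members[k * spec.complex_size:(k + 1) * spec.complex_size]]
            shared_factor = rng.normal(0.0, 1.0, size=n_samples)
            for j, sid in enumerate(sample_ids):  # patient-level, like V
                shared_factor[j] = shared_factor[patient_col[patient_of_sample[sid]]]
            values[rows, :] += spec.complex_loading * shared_factor
            complexes[f"complex{k:03d}"] = {protein_ids[r] for r in rows}

    # batch structure: cohort- and plex-level additive offsets
    cohort_offsets = {n: rng.normal(0.0, spec.cohort_offset_sd) for n in cohort_names}
    plex_names = sorted(set(plex_of_sample.values()))
    plex_offsets = {n: rng.normal(0.0, spec.plex_offset_sd) for n in plex_names}
    for j, sid in enumerate(sample_ids):
        values[:, j] += cohort_offsets[cohort_of_sample[sid]]
        values[:, j] += plex_offsets[plex_of_sample[sid]]

    # planted tumor effects on the shared-core DE proteins
    de_proteins: dict[str, int] = {}
    n_up = int(round(spec.de_fraction_up * len(de_set)))
    for rank, i in enumerate(sorted(de_set)):
        sign = 1 if rank < n_up else -1
        de_proteins[protein_ids[i]] = sign
        values[i, tumor_cols] += sign * spec.de_log2_shift

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    # structural absences: protein not quantified in a cohort at all
    structural = np.ones((n_proteins, n_samples), dtype=bool)
    for name in cohort_names:
        cols = [j for j, s in enumerate(sample_ids) if cohort_of_sample[s] == name]
        rows = cohort_proteins[name]
        structural[np.ix_(rows, cols)] = False

    # left-censoring on the structurally present entries
    present_values = values[~structural]
    mnar = np.zeros_like(structural)
    if spec.target_missing_fraction > 0:
        center = _calibrate_censor_center(
            present_values, spec.mnar_slope, spec.target_missing_fraction
        )
        p_miss = 1.0 / (1.0 + np.exp(spec.mnar_slope * (values - center)))
        mnar = (rng.random(values.shape) < p_miss) & ~structural

    observed_values = values.copy()
    observed_values[structural | mnar] = np.nan
    annotations = dict(
        cohort_of_sample=cohort_of_sample,
        sample_type=sample_type,
        patient_of_sample=patient_of_sample,
        plex_of_sample=plex_of_sample,
    )
    observed = QuantMatrix(
        values=observed_values,
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        **annotations,
    )
    truth_values = values.copy()
    truth_values[structural] = np.nan
    truth = QuantMatrix(
        values=truth_values,
        protein_ids=list(protein_ids),
        sample_ids=list(sample_ids),
        **{k: dict(v) for k, v in annotations.items()},
    )
    return observed, SimTruth(
        truth=truth,
        complete_values=values,
        missing_mask=mnar,
        structural_mask=structural,
        de_proteins=de_proteins,
        complexes=complexes,
    )


def mcar_mask(matrix: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Uniformly random entry mask covering ``floor(fraction × size)`` cells."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    matrix = np.asarray(matrix)
    n_mask = int(fraction * matrix.size)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(matrix.size, size=n_mask, replace=False)
    mask = np.zeros(matrix.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(matrix.shape)
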