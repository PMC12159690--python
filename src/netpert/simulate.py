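"""Synthetic cohort generator.

Emulates the statistical structure the perturbation analysis assumes:
a healthy-control cohort whose regional SUVr values follow a
multivariate normal with block-structured inter-regional correlations
plus linear age and sex effects; patient groups that deviate from the
control distribution through a directional network perturbation; and
longitudinal baseline/follow-up pairs with a subject-stable component.

The generator exists so that every downstream stage (reference network,
deviation matrices, metrics, statistics, classification, fingerprinting)
can be exercised and validated without access to any patient data.  It
deliberately does not model PET acquisition physics or voxel images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import CovariateTable, RegionalUptakeTable

__all__ = [
    "CohortSpec",
    "PerturbationSpec",
    "LongitudinalSpec",
    "make_reference_cohort",
    "make_patient_group",
    "make_longitudinal_pairs",
    "nearest_correlation",
]

#: default number of atlas regions
DEFAULT_N_REGIONS = 83
#: indices treated as "striatal-like" (high-uptake, strongly coupled) by default
DEFAULT_STRIATAL = tuple(range(8))


def nearest_correlation(corr: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues below ``eps`` are clipped, the matrix is reconstructed and
    rescaled to unit diagonal.  Returns the (possibly repaired) matrix and
    a flag saying whether a repair was needed.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= eps:
        return corr, False
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


@dataclass
class CohortSpec:
    """Generative description of a control cohort.

    Defaults emulate an FDOPA-like study: 83 regions, a strongly
    correlated high-uptake striatal block (mean SUVr ~2.5) embedded in a
    moderately correlated cortical background (mean SUVr ~1.2), a small
    age-related decline and a small sex offset.

    Parameters
    ----------
    n_subjects : int
    n_regions : int, default 83
    block_structure : list of (indices, rho)
        Region index sets with their within-block correlation.  Default
        (for 83 regions): striatal regions 0-7 at rho=0.85, a 40-region
        association block at rho=0.7 and the remaining 35 regions at
        rho=0.2 — a heterogeneous spread of edge strengths like that of
        real molecular covariance matrices.
    between_block_correlation : float, default 0.05
    region_means, region_sds : array-like, per region
        Defaults: means 2.5 (striatal-like block) / 1.2 elsewhere, sds at
        10% of the mean.
    age_slope : float or per-region array, SUVr per year (default -0.003)
    sex_offset : float or per-region array, SUVr (default 0.05, male)
    age_range : (low, high) years, ages drawn uniformly (default 20-65)
    sex_ratio : fraction male (default 0.5)
    seed : int
    """

    n_subjects: int
    n_regions: int = DEFAULT_N_REGIONS
    block_structure: list[tuple[Sequence[int], float]] | None = None
    between_block_correlation: float = 0.05
    region_means: np.ndarray | None = None
    region_sds: np.ndarray | None = None
    age_slope: float | np.ndarray = -0.003
    sex_offset: float | np.ndarray = 0.05
    age_range: tuple[float, float] = (20.0, 65.0)
    sex_ratio: float = 0.5
    seed: int = 0
    #: set True by correlation() if the implied matrix needed PSD repair
    psd_repaired: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        m = self.n_regions
        striatal = [i for i in DEFAULT_STRIATAL if i < m]
        if self.block_structure is None:
            # heterogeneous three-tier structure emulating molecular
            # covariance data: tightly coupled striatal block, a large
            # strongly covarying association block, loosely coupled rest
            rest = [i for i in range(m) if i not in striatal]
            cut = len(rest) * 8 // 15  # ~40 of 75 regions at m=83
            self.block_structure = [(striatal, 0.85)]
            if rest[:cut]:
                self.block_structure.append((rest[:cut], 0.7))
            if rest[cut:]:
                self.block_structure.append((rest[cut:], 0.2))
        self.block_structure = [
            (tuple(int(i) for i in idx), float(r)) for idx, r in self.block_structure
        ]
        for idx, r in self.block_structure:
            if any(i < 0 or i >= m for i in idx):
                raise ValueError("block region index out of range")
            if not -1.0 <= r <= 1.0:
                raise ValueError("within-block correlation must be in [-1, 1]")
        if not -1.0 <= self.between_block_correlation <= 1.0:
            raise ValueError("between_block_correlation must be in [-1, 1]")
        if self.region_means is None:
            means = np.full(m, 1.2)
            means[list(striatal)] = 2.5
            self.region_means = means
        else:
            self.region_means = np.broadcast_to(
                np.asarray(self.region_means, dtype=float), (m,)
            ).copy()
        if self.region_sds is None:
            self.region_sds = 0.1 * self.region_means
        else:
            self.region_sds = np.broadcast_to(
                np.asarray(self.region_sds, dtype=float), (m,)
            ).copy()
        if np.any(self.region_sds <= 0):
            raise ValueError("region_sds must be strictly positive")
        self.age_slope = np.broadcast_to(np.asarray(self.age_slope, float), (m,)).copy()
        self.sex_offset = np.broadcast_to(np.asarray(self.sex_offset, float), (m,)).copy()
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be (low, high) with low < high")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")

    def region_labels(self) -> list[str]:
        from .atlas import default_region_labels

        return default_region_labels(self.n_regions)

    def correlation(self) -> np.ndarray:
        """Target inter-regional correlation matrix (PSD-repaired if needed)."""
        m = self.n_regions
        corr = np.full((m, m), self.between_block_correlation)
        for idx, r in self.block_structure:
            ix = np.asarray(idx, dtype=int)
            corr[np.ix_(ix, ix)] = r
        np.fill_diagonal(corr, 1.0)
        corr, repaired = nearest_correlation(corr)
        if repaired:
            self.psd_repaired = True
            warnings.warn(
                "implied correlation matrix was not positive semi-definite; "
                "repaired by eigenvalue clipping",
                stacklevel=2,
            )
        return corr

    def covariance(self) -> np.ndarray:
        d = self.region_sds
        return self.correlation() * np.outer(d, d)

    def mean_structure(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Deterministic part of each subject's region vector."""
        mid_age = 0.5 * (self.age_range[0] + self.age_range[1])
        return (
            self.region_means[None, :]
            + np.outer(np.asarray(age) - mid_age, self.age_slope)
            + np.outer(np.asarray(sex), self.sex_offset)
        )


@dataclass
class PerturbationSpec:
    """Directional network perturbation applied to a patient group.

    ``mean_shift`` mode displaces every patient's affected-region vector
    along an eigen-axis of the affected block's covariance: along the
    leading axis to strengthen apparent coupling when the subject is
    appended to the reference cohort, or along the minor axis (the
    direction most at odds with the dominant covariance pattern) to
    weaken it.  ``correlation_scale`` mode instead rescales the affected
    block's correlations in the patient generative distribution.

    ``magnitude`` is in standard deviations along the chosen axis;
    magnitude 0 reduces to the unmodified cohort distribution.
    """

    affected_regions: Sequence[int]
    direction: str = "strengthen"
    magnitude: float = 3.25
    mode: str = "mean_shift"
    #: between-patient sd of the severity multiplier (1 = homogeneous group);
    #: patient i's shift is scaled by max(0, Normal(1, severity_sd))
    severity_sd: float = 0.4

    def __post_init__(self) -> None:
        self.affected_regions = tuple(int(i) for i in self.affected_regions)
        if self.direction not in ("strengthen", "weaken"):
            raise ValueError("direction must be 'strengthen' or 'weaken'")
        if self.mode not in ("mean_shift", "correlation_scale"):
            raise ValueError("mode must be 'mean_shift' or 'correlation_scale'")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be >= 0")
        if self.magnitude > 0 and len(self.affected_regions) == 0:
            raise ValueError("magnitude > 0 requires a non-empty affected region set")
        if len(set(self.affected_regions)) != len(self.affected_regions):
            raise ValueError("affected_regions contains duplicates")

    def shift_vector(self, spec: CohortSpec) -> np.ndarray:
        """Per-region mean shift implied by this perturbation (mean_shift mode)."""
        m = spec.n_regions
        shift = np.zeros(m)
        if self.magnitude == 0 or self.mode != "mean_shift" or not self.affected_regions:
            return shift
        ix = np.asarray(self.affected_regions, dtype=int)
        if ix.max() >= m:
            raise ValueError("affected region index out of range")
        block_cov = spec.covariance()[np.ix_(ix, ix)]
        w, v = np.linalg.eigh(block_cov)
        # strengthen: displace along the leading covariance axis; weaken:
        # along the minor axis, the direction most at odds with the block's
        # correlation pattern.  Both are scaled by the leading-axis sd so
        # `magnitude` means the same displacement size in either direction.
        axis = -1 if self.direction == "strengthen" else 0
        u = v[:, axis]
        u = u * np.sign(u[np.argmax(np.abs(u))])  # deterministic sign
        shift[ix] = self.magnitude * np.sqrt(max(w[-1], 0.0)) * u
        return shift

    def patient_covariance(self, spec: CohortSpec) -> np.ndarray:
        """Generative covariance for patients (correlation_scale mode)."""
        corr = spec.correlation().copy()
        if self.magnitude > 0 and self.mode == "correlation_scale":
            ix = np.asarray(self.affected_regions, dtype=int)
            factor = (
                1.0 + self.magnitude
                if self.direction == "strengthen"
                else max(0.0, 1.0 - self.magnitude)
            )
            block = corr[np.ix_(ix, ix)] * factor
            np.clip(block, -0.99, 0.99, out=block)
            corr[np.ix_(ix, ix)] = block
            np.fill_diagonal(corr, 1.0)
            corr, _ = nearest_correlation(corr)
        d = spec.region_sds
        return corr * np.outer(d, d)


@dataclass
class LongitudinalSpec:
    """Baseline/follow-up coupling for longitudinal pairs.

    stability_rho : correlation of the subject-specific noise component
        between timepoints (1 = identical component, 0 = independent).
    treatment_shrink : factor applied to the perturbation mean shift at
        follow-up (1 = unchanged disease effect, 0 = fully normalized).
    noise_sd : additional independent measurement noise at follow-up, SUVr.
    """

    stability_rho: float = 0.7
    treatment_shrink: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stability_rho <= 1.0:
            raise ValueError("stability_rho must be in [0, 1]")
        if not 0.0 <= self.treatment_shrink <= 1.0:
            raise ValueError("treatment_shrink must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_covariates(
    spec: CohortSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = (rng.random(n) < spec.sex_ratio).astype(float)
    return age, sex


def _correlated_noise(
    cov: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "cohort covariance is not positive definite even after repair"
        ) from exc
    return rng.standard_normal((n, cov.shape[0])) @ chol.T


def make_reference_cohort(
    spec: CohortSpec, id_prefix: str = "HC"
) -> tuple[RegionalUptakeTable, CovariateTable]:
    """Draw a control cohort from the generative model.

    Values are ``mean_structure(age, sex) + correlated noise`` with the
    block-structured covariance; deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    age, sex = _draw_covariates(spec, spec.n_subjects, rng)
    noise = _correlated_noise(spec.covariance(), spec.n_subjects, rng)
    values = spec.mean_structure(age, sex) + noise
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(spec.n_subjects)]
    table = RegionalUptakeTable(ids, spec.region_labels(), values)
    cov = CovariateTable(ids, age, sex)
    return table, cov


def make_patient_group(
    spec: CohortSpec,
    pert: PerturbationSpec,
    n_patients: int,
    seed: int,
    id_prefix: str = "PT",
) -> tuple[RegionalUptakeTable, CovariateTable]:
    """Draw a patient group: the control distribution plus the perturbation.

    With ``magnitude == 0`` patients are exact draws from the cohort
    distribution; the expected size of their network deviations grows
    monotonically with ``magnitude``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    age, sex = _draw_covariates(spec, n_patients, rng)
    cov_matrix = pert.patient_covariance(spec)
    noise = _correlated_noise(cov_matrix, n_patients, rng)
    # per-patient severity: disease effects differ between individuals
    severity = np.maximum(0.0, 1.0 + pert.severity_sd * rng.standard_normal(n_patients))
    values = (
        spec.mean_structure(age, sex)
        + noise
        + severity[:, None] * pert.shift_vector(spec)[None, :]
    )
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n_patients)]
    return (
        RegionalUptakeTable(ids, spec.region_labels(), values),
        CovariateTable(ids, age, sex),
    )


def make_longitudinal_pairs(
    baseline: RegionalUptakeTable,
    baseline_cov: CovariateTable,
    spec: CohortSpec,
    pert: PerturbationSpec,
    lspec: LongitudinalSpec,
    seed: int,
) -> tuple[RegionalUptakeTable, RegionalUptakeTable]:
    """Generate follow-up scans paired with an existing patient baseline.

    The baseline is decomposed as mean structure + perturbation shift +
    subject noise; the follow-up keeps a fraction ``stability_rho`` of
    the subject noise (refreshing the rest from the same covariance),
    scales the perturbation shift by ``treatment_shrink`` and adds
    independent measurement noise.  Returns ``(baseline, follow_up)``
    with shared subject ids.
    """
    baseline_cov.check_aligned(baseline)
    rng = np.random.default_rng(seed)
    mu = spec.mean_structure(baseline_cov.age, baseline_cov.sex)
    shift = pert.shift_vector(spec)[None, :]
    subject_noise = baseline.values - mu - shift
    rho = lspec.stability_rho
    fresh = _correlated_noise(pert.patient_covariance(spec), baseline.n_subjects, rng)
    follow_values = (
        mu
        + lspec.treatment_shrink * shift
        + rho * subject_noise
        + np.sqrt(1.0 - rho**2) * fresh
        + lspec.noise_sd * rng.standard_normal(baseline.values.shape)
    )
    follow = RegionalUptakeTable(
        list(baseline.subject_ids), list(baseline.region_labels), follow_values
    )
    return baseline, follow
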