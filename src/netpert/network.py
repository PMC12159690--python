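"""Covariate-adjusted partial-correlation networks and single-subject
perturbation z-matrices.

The reference network over a control cohort of size n is the matrix of
partial Pearson correlations PCC_n between all region pairs, adjusting
for nuisance covariates (age, sex) by least-squares residualization.
Appending one test subject and rebuilding the network gives PCC_{n+1};
the edge-wise difference dPCC = PCC_{n+1} - PCC_n follows a symmetric
null distribution whose large-n standard deviation is
(1 - PCC_n**2) / (n - 1), so each edge standardizes to

    z = dPCC * (n - 1) / (1 - PCC_n**2)

with n the reference cohort size.  The resulting z-matrix quantifies how
abnormal the subject's position is with respect to every pairwise
coupling in the normative cohort; two-tailed normal p-values follow
directly from z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CovariateTable, RegionalUptakeTable

__all__ = [
    "ReferenceNetwork",
    "DeviationMatrix",
    "residualize_covariates",
    "build_reference_network",
    "perturb_network",
    "edge_pvalues",
]

#: off-diagonal partial correlations at or beyond 1 - DEGENERATE_TOL are
#: rejected: the z denominator vanishes and deviations become unbounded
DEGENERATE_TOL = 1e-12


@dataclass
class ReferenceNetwork:
    """Partial-correlation network estimated from a control cohort."""

    pcc: np.ndarray
    n_ref: int
    region_labels: list[str]
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.pcc = np.asarray(self.pcc, dtype=float)
        m = len(self.region_labels)
        if self.pcc.shape != (m, m):
            raise ValueError("pcc shape does not match region labels")
        if not np.allclose(self.pcc, self.pcc.T, atol=1e-12):
            raise ValueError("pcc must be symmetric")
        if not np.allclose(np.diag(self.pcc), 1.0):
            raise ValueError("pcc diagonal must be 1")
        off = self.pcc[~np.eye(m, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0 - DEGENERATE_TOL:
            raise ValueError("degenerate off-diagonal correlation (|pcc| ~ 1)")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def lower_triangle(self) -> np.ndarray:
        """Strict lower triangle in row-major order (length m(m-1)/2)."""
        i, j = np.tril_indices(self.n_regions, k=-1)
        return self.pcc[i, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcc, index=self.region_labels, columns=self.region_labels)


@dataclass
class DeviationMatrix:
    """Edge-wise z-scores of one subject against a reference network."""

    z: np.ndarray
    subject_id: str
    n_ref: int
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        m = len(self.region_labels)
        if self.z.shape != (m, m):
            raise ValueError("z shape does not match region labels")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("z must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise ValueError("z diagonal must be 0")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite everywhere")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n_regions, k=-1)
        return self.z[i, j]

    def threshold(self, tau: float = 4.13):
        from .metrics import threshold_extreme

        return threshold_extreme(self, tau=tau)

    def edge_pvalues(self) -> np.ndarray:
        return edge_pvalues(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.region_labels, columns=self.region_labels)


def residualize_covariates(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each column of ``values`` by its least-squares residual
    against an intercept plus the covariate columns.

    With no covariates this is plain column mean-centering.  Residuals
    are exactly orthogonal to the design.  Raises if the design (with
    intercept) is rank-deficient, naming the collinear columns.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        design = np.ones((n, 1))
        k = 0
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != n:
            raise ValueError("covariates and values must have the same number of rows")
        k = covariates.shape[1]
        design = np.column_stack([np.ones(n), covariates])
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} rows to residualize, got {n}")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept = np.ones((n, 0))
        for col in range(design.shape[1]):
            cand = np.column_stack([kept, design[:, col]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append("intercept" if col == 0 else f"covariate {col - 1}")
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def _pcc_from_residuals(resid: np.ndarray, region_labels: list[str]) -> np.ndarray:
    sd = resid.std(axis=0)
    if np.any(sd == 0):
        bad = [region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance residuals for regions {bad}")
    pcc = np.corrcoef(resid, rowvar=False)
    pcc = (pcc + pcc.T) / 2.0
    np.fill_diagonal(pcc, 1.0)
    return pcc


def build_reference_network(
    table: RegionalUptakeTable, cov: CovariateTable | None = None
) -> ReferenceNetwork:
    """Estimate the reference partial-correlation network PCC_n.

    Each region is residualized against the covariates (age, sex) and
    the residual columns are pairwise Pearson-correlated.  Edges with
    |pcc| ~ 1 off-diagonal (duplicate or affinely dependent regions)
    are rejected at build time.
    """
    if table.n_subjects < 4:
        raise ValueError("need at least 4 subjects to build a reference network")
    design = None
    cov_names: list[str] = []
    if cov is not None:
        cov.check_aligned(table)
        design = cov.design()
        cov_names = cov.covariate_names
    resid = residualize_covariates(table.values, design)
    pcc = _pcc_from_residuals(resid, table.region_labels)
    m = table.n_regions
    off = np.abs(pcc[~np.eye(m, dtype=bool)])
    if off.size and off.max() >= 1.0 - DEGENERATE_TOL:
        i, j = np.unravel_index(
            np.argmax(np.abs(pcc - np.eye(m)), axis=None), pcc.shape
        )
        raise ValueError(
            f"degenerate edge between {table.region_labels[i]!r} and "
            f"{table.region_labels[j]!r} (|pcc| ~ 1); remove duplicate regions"
        )
    return ReferenceNetwork(
        pcc=pcc,
        n_ref=table.n_subjects,
        region_labels=list(table.region_labels),
        covariate_names=cov_names,
    )


def _check_subject(
    table: RegionalUptakeTable,
    subject_values: np.ndarray,
    region_labels: list[str] | None,
) -> np.ndarray:
    subject_values = np.asarray(subject_values, dtype=float).reshape(-1)
    if region_labels is not None and list(region_labels) != list(table.region_labels):
        raise ValueError("subject region labels do not match the reference regions")
    if subject_values.shape[0] != table.n_regions:
        raise ValueError(
            f"subject has {subject_values.shape[0]} regions, reference has {table.n_regions}"
        )
    if not np.all(np.isfinite(subject_values)):
        raise ValueError("subject values must be finite (no missing data)")
    return subject_values


def perturb_network(
    ref_table: RegionalUptakeTable,
    ref_cov: CovariateTable | None,
    subject_values: np.ndarray,
    subject_cov: np.ndarray | None = None,
    *,
    subject_id: str = "subject",
    subject_region_labels: list[str] | None = None,
    reference: ReferenceNetwork | None = None,
    dof_adjust: bool = False,
) -> DeviationMatrix:
    """Compute one subject's deviation z-matrix against a reference cohort.

    The subject's row is appended to the reference table, the covariate
    regression is refit on all n+1 subjects and the perturbed network
    PCC_{n+1} is rebuilt; then z = (PCC_{n+1} - PCC_n) * (n - 1) /
    (1 - PCC_n**2) elementwise, with n the reference cohort size and
    the diagonal forced to zero.

    Parameters
    ----------
    subject_cov : array-like (age, sex) or None
        Required when the reference network uses covariates.
    reference : ReferenceNetwork, optional
        Pass a prebuilt reference to avoid recomputing PCC_n when
        perturbing many subjects against the same cohort.
    dof_adjust : bool
        If True, replace n - 1 by n - 1 - k in the z denominator to
        account for the k fitted covariates.  Off by default: the
        standard large-n formula uses n - 1.
    """
    subject_values = _check_subject(ref_table, subject_values, subject_region_labels)
    if reference is None:
        reference = build_reference_network(ref_table, ref_cov)
    k = 0
    if ref_cov is not None:
        ref_cov.check_aligned(ref_table)
        if subject_cov is None:
            raise ValueError("reference uses covariates; subject_cov is required")
        subject_cov = np.asarray(subject_cov, dtype=float).reshape(-1)
        k = subject_cov.shape[0]
        if k != ref_cov.design().shape[1]:
            raise ValueError("subject covariates do not match the reference covariates")
        lo, hi = ref_cov.age.min(), ref_cov.age.max()
        if not lo <= subject_cov[0] <= hi:
            warnings.warn(
                f"subject age {subject_cov[0]:.1f} outside reference range "
                f"[{lo:.1f}, {hi:.1f}]; covariate adjustment extrapolates",
                stacklevel=2,
            )
        design = np.vstack([ref_cov.design(), subject_cov])
    else:
        design = None
    stacked = np.vstack([ref_table.values, subject_values])
    resid = residualize_covariates(stacked, design)
    pcc_pert = _pcc_from_residuals(resid, ref_table.region_labels)
    n = reference.n_ref
    dof = n - 1 - (k if dof_adjust else 0)
    if dof <= 0:
        raise ValueError("not enough reference subjects for the requested dof adjustment")
    dpcc = pcc_pert - reference.pcc
    denom = 1.0 - reference.pcc**2
    np.fill_diagonal(denom, 1.0)  # diagonal is forced to 0 below
    z = dpcc * dof / denom
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return DeviationMatrix(
        z=z,
        subject_id=str(subject_id),
        n_ref=n,
        region_labels=list(ref_table.region_labels),
    )


def edge_pvalues(dev: DeviationMatrix) -> np.ndarray:
    """Two-tailed standard-normal p-values for every edge (diagonal = 1)."""
    p = 2.0 * stats.norm.sf(np.abs(dev.z))
    np.fill_diagonal(p, 1.0)
    return p
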