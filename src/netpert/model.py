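"""Model/Results interface over the perturbation analysis.

`NetworkPerturbationModel` holds the control cohort (and covariates);
`fit()` estimates the covariate-adjusted partial-correlation reference
network and returns a `ReferenceNetworkResults` carrying the estimated
network with everything downstream hanging off it: single-subject
perturbation, cohort-level deviation matrices, SED/RED extraction,
stability resampling, summary tables and plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CovariateTable, RegionalUptakeTable
from .fingerprint import StabilityCurve, reference_stability
from .metrics import (
    DEFAULT_TAU,
    REDMatrix,
    regional_extreme_deviation,
    sed_table,
    threshold_extreme,
)
from .network import (
    DeviationMatrix,
    ReferenceNetwork,
    build_reference_network,
    perturb_network,
)

__all__ = ["NetworkPerturbationModel", "ReferenceNetworkResults"]


class NetworkPerturbationModel:
    """Normative molecular-connectivity model built from a control cohort.

    Parameters
    ----------
    uptake : RegionalUptakeTable
        Control subjects x regions SUVr table.
    covariates : CovariateTable, optional
        Age/sex covariates regressed out of every region before the
        pairwise correlations (partial correlation).
    dof_adjust : bool
        Propagated to the deviation z denominator (n-1-k instead of n-1).

    Examples
    --------
    >>> model = NetworkPerturbationModel(controls, control_covariates)
    >>> ref = model.fit()
    >>> dev = ref.perturb(patient_row, patient_cov, subject_id="PT001")
    """

    def __init__(
        self,
        uptake: RegionalUptakeTable,
        covariates: CovariateTable | None = None,
        dof_adjust: bool = False,
    ):
        if covariates is not None:
            covariates.check_aligned(uptake)
        self.uptake = uptake
        self.covariates = covariates
        self.dof_adjust = dof_adjust

    @classmethod
    def from_dataframes(
        cls,
        uptake: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        dof_adjust: bool = False,
    ) -> "NetworkPerturbationModel":
        """Build from pandas DataFrames (`subject_id` column plus region
        columns; covariates need `subject_id`, `age`, `sex`)."""
        table = RegionalUptakeTable.from_dataframe(uptake)
        cov = None if covariates is None else CovariateTable.from_dataframe(covariates)
        return cls(table, cov, dof_adjust=dof_adjust)

    def fit(self) -> "ReferenceNetworkResults":
        network = build_reference_network(self.uptake, self.covariates)
        return ReferenceNetworkResults(model=self, network=network)


@dataclass
class ReferenceNetworkResults:
    """Fitted reference network plus the downstream analysis surface."""

    model: NetworkPerturbationModel
    network: ReferenceNetwork

    @property
    def pcc(self) -> np.ndarray:
        return self.network.pcc

    @property
    def n_ref(self) -> int:
        return self.network.n_ref

    @property
    def region_labels(self) -> list[str]:
        return self.network.region_labels

    def perturb(
        self,
        subject_values: np.ndarray,
        subject_cov: np.ndarray | None = None,
        subject_id: str = "subject",
    ) -> DeviationMatrix:
        """Deviation z-matrix of one subject against this reference."""
        return perturb_network(
            self.model.uptake,
            self.model.covariates,
            subject_values,
            subject_cov,
            subject_id=subject_id,
            reference=self.network,
            dof_adjust=self.model.dof_adjust,
        )

    def perturb_cohort(
        self, table: RegionalUptakeTable, cov: CovariateTable | None = None
    ) -> list[DeviationMatrix]:
        """Deviation matrices for every subject of a patient table."""
        if cov is not None:
            cov.check_aligned(table)
        out = []
        for i, sid in enumerate(table.subject_ids):
            out.append(
                self.perturb(
                    table.values[i],
                    None if cov is None else np.array([cov.age[i], cov.sex[i]]),
                    subject_id=sid,
                )
            )
        return out

    def deviation_metrics(
        self,
        table: RegionalUptakeTable,
        cov: CovariateTable | None = None,
        tau: float = DEFAULT_TAU,
        signed_red: bool = False,
    ) -> tuple[pd.Series, REDMatrix]:
        """SED series and RED matrix for a patient cohort at threshold tau."""
        devs = self.perturb_cohort(table, cov)
        ts = [threshold_extreme(d, tau=tau) for d in devs]
        return sed_table(ts), regional_extreme_deviation(ts, signed=signed_red)

    def stability(
        self, sizes=None, reps: int = 20, seed: int = 0
    ) -> StabilityCurve:
        """Subsampling stability of this reference network."""
        from .fingerprint import DEFAULT_STABILITY_SIZES

        return reference_stability(
            self.model.uptake,
            self.model.covariates,
            sizes=DEFAULT_STABILITY_SIZES if sizes is None else sizes,
            reps=reps,
            seed=seed,
        )

    def summary(self) -> str:
        tri = self.network.lower_triangle()
        lines = [
            "Reference molecular-connectivity network",
            f"  subjects (n_ref)    : {self.n_ref}",
            f"  regions             : {self.network.n_regions}",
            f"  edges               : {tri.size}",
            f"  covariates          : {', '.join(self.network.covariate_names) or 'none'}",
            "  partial correlations:",
            f"    mean {tri.mean(): .3f}   sd {tri.std(): .3f}",
            f"    quartiles {np.percentile(tri, 25): .3f} / "
            f"{np.percentile(tri, 50): .3f} / {np.percentile(tri, 75): .3f}",
            f"    range [{tri.min(): .3f}, {tri.max(): .3f}]",
        ]
        return "\n".join(lines)

    def plot_network(self, ax=None):
        """Heatmap of the reference partial-correlation matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.pcc, vmin=-1, vmax=1, cmap="coolwarm")
        ax.figure.colorbar(im, ax=ax, label="partial correlation")
        ax.set_title(f"reference network (n={self.n_ref})")
        return ax
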