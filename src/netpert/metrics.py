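"""Extreme-deviation summary metrics.

Deviation z-matrices are thresholded at |z| > tau (default tau = 4.13, a
Bonferroni-style cut that keeps only edges deviating far beyond chance)
and condensed into two summaries:

* SED (subject extreme deviations): the sum of absolute supra-threshold
  z-scores over the strict lower triangle, divided by the number of
  edges C = m(m-1)/2.  One number per subject; note it can exceed 1
  because magnitudes, not counts, are summed.
* RED (regional extreme deviations): for each subject, the row-wise mean
  of the absolute thresholded matrix (divisor m, the zero diagonal
  included), stacked into a subjects x regions matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import DeviationMatrix

__all__ = [
    "DEFAULT_TAU",
    "ThresholdedDeviation",
    "REDMatrix",
    "threshold_extreme",
    "subject_extreme_deviation",
    "extreme_edge_fraction",
    "regional_extreme_deviation",
    "sed_table",
]

#: default extreme-deviation threshold on |z|
DEFAULT_TAU = 4.13


@dataclass
class ThresholdedDeviation:
    """Deviation matrix with sub-threshold entries zeroed."""

    zt: np.ndarray
    tau: float
    subject_id: str
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.zt = np.asarray(self.zt, dtype=float)
        nz = self.zt[self.zt != 0]
        if nz.size and np.min(np.abs(nz)) <= self.tau:
            raise ValueError("thresholded matrix has nonzero entries with |z| <= tau")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class REDMatrix:
    """Subjects x regions matrix of regional extreme-deviation means."""

    red: np.ndarray
    subject_ids: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        if self.red.shape != (len(self.subject_ids), len(self.region_labels)):
            raise ValueError("red shape does not match subject/region labels")

    @property
    def n_subjects(self) -> int:
        return self.red.shape[0]

    @property
    def n_regions(self) -> int:
        return self.red.shape[1]

    def column_means(self) -> np.ndarray:
        return self.red.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.red, columns=self.region_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "REDMatrix":
        regions = [c for c in df.columns if c != "subject_id"]
        return cls(df[regions].to_numpy(dtype=float), list(df["subject_id"]), regions)


def threshold_extreme(dev: DeviationMatrix, tau: float = DEFAULT_TAU) -> ThresholdedDeviation:
    """Zero all entries with |z| <= tau; strictly supra-threshold entries
    keep their signed value."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    zt = np.where(np.abs(dev.z) > tau, dev.z, 0.0)
    return ThresholdedDeviation(
        zt=zt, tau=float(tau), subject_id=dev.subject_id,
        region_labels=list(dev.region_labels),
    )


def subject_extreme_deviation(t: ThresholdedDeviation) -> float:
    """SED = sum of |thresholded z| over the strict lower triangle, divided
    by the edge count C = m(m-1)/2."""
    m = t.n_regions
    if m < 2:
        raise ValueError("SED requires at least 2 regions")
    i, j = np.tril_indices(m, k=-1)
    total = np.abs(t.zt[i, j]).sum()
    return float(total / (m * (m - 1) / 2))


def extreme_edge_fraction(t: ThresholdedDeviation) -> float:
    """Count-based variant of SED: fraction of lower-triangle edges that
    survive the threshold (always in [0, 1])."""
    m = t.n_regions
    if m < 2:
        raise ValueError("requires at least 2 regions")
    i, j = np.tril_indices(m, k=-1)
    return float(np.count_nonzero(t.zt[i, j]) / (m * (m - 1) / 2))


def regional_extreme_deviation(
    ts: Sequence[ThresholdedDeviation], signed: bool = False
) -> REDMatrix:
    """Stack per-subject row means of the (absolute) thresholded matrix.

    red[j, i] = (1/m) * sum_k |zt_j[i, k]|; the zero diagonal contributes
    nothing to the sum but m stays the divisor.  ``signed=True`` averages
    the raw signed values instead (non-default; mixing signs can cancel).
    """
    ts = list(ts)
    if not ts:
        raise ValueError("need at least one subject")
    labels = ts[0].region_labels
    for t in ts[1:]:
        if t.region_labels != labels:
            raise ValueError("all subjects must share the same region labels")
    m = len(labels)
    rows = []
    for t in ts:
        mat = t.zt if signed else np.abs(t.zt)
        rows.append(mat.sum(axis=1) / m)
    return REDMatrix(
        red=np.vstack(rows),
        subject_ids=[t.subject_id for t in ts],
        region_labels=list(labels),
    )


def sed_table(ts: Iterable[ThresholdedDeviation]) -> pd.Series:
    """SED values for a collection of subjects, indexed by subject id."""
    ts = list(ts)
    return pd.Series(
        [subject_extreme_deviation(t) for t in ts],
        index=[t.subject_id for t in ts],
        name="sed",
    )
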