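"""Core tabular containers shared across the package.

A study consists of a subjects-by-regions table of standardized uptake
value ratios (SUVr) and an aligned covariate table (age in years, sex
coded 0=female / 1=male).  Region labels are opaque strings; nothing in
the package interprets them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionalUptakeTable", "CovariateTable"]


@dataclass
class RegionalUptakeTable:
    """Subjects x regions matrix of regional SUVr values.

    Parameters
    ----------
    subject_ids : list of str
        One unique identifier per row.
    region_labels : list of str
        One unique label per column.
    values : ndarray, shape (n_subjects, n_regions)
        SUVr values (unitless ratios).  Must be finite everywhere: the
        analysis assumes complete data and performs no imputation.
    """

    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.region_labels = [str(r) for r in self.region_labels]
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.subject_ids)} subject ids"
            )
        if m != len(self.region_labels):
            raise ValueError(
                f"values has {m} columns but {len(self.region_labels)} region labels"
            )
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        if len(set(self.region_labels)) != m:
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            i, j = bad[0]
            raise ValueError(
                f"non-finite SUVr value at subject {self.subject_ids[i]!r}, "
                f"region {self.region_labels[j]!r} (missing data is not supported)"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def row(self, subject_id: str) -> np.ndarray:
        """Return one subject's region vector."""
        try:
            i = self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject id {subject_id!r}") from None
        return self.values[i]

    def subset(self, indices: np.ndarray | list[int]) -> "RegionalUptakeTable":
        idx = np.asarray(indices, dtype=int)
        return RegionalUptakeTable(
            [self.subject_ids[i] for i in idx], list(self.region_labels), self.values[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionalUptakeTable":
        if "subject_id" not in df.columns:
            raise ValueError("expected a 'subject_id' column")
        regions = [c for c in df.columns if c != "subject_id"]
        return cls(list(df["subject_id"]), regions, df[regions].to_numpy(dtype=float))


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates, order-aligned with an uptake table."""

    subject_ids: list[str]
    age: np.ndarray = field(default_factory=lambda: np.empty(0))
    sex: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n = len(self.subject_ids)
        if self.age.shape != (n,) or self.sex.shape != (n,):
            raise ValueError("age and sex must each have one entry per subject")
        if not set(np.unique(self.sex)) <= {0.0, 1.0}:
            raise ValueError("sex must be coded 0 (female) / 1 (male)")

    @property
    def covariate_names(self) -> list[str]:
        return ["age", "sex"]

    def design(self) -> np.ndarray:
        """n x 2 covariate matrix (age, sex), without intercept."""
        return np.column_stack([self.age, self.sex])

    def check_aligned(self, table: RegionalUptakeTable) -> None:
        if self.subject_ids != table.subject_ids:
            only_cov = sorted(set(self.subject_ids) - set(table.subject_ids))
            only_tab = sorted(set(table.subject_ids) - set(self.subject_ids))
            if only_cov or only_tab:
                raise ValueError(
                    "covariate/uptake subject ids differ; "
                    f"only in covariates: {only_cov}; only in uptake: {only_tab}"
                )
            raise ValueError("covariate rows are not in the same order as the uptake table")

    def row(self, subject_id: str) -> np.ndarray:
        try:
            i = self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject id {subject_id!r}") from None
        return np.array([self.age[i], self.sex[i]])

    def subset(self, indices: np.ndarray | list[int]) -> "CovariateTable":
        idx = np.asarray(indices, dtype=int)
        return CovariateTable(
            [self.subject_ids[i] for i in idx], self.age[idx], self.sex[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_ids, "age": self.age, "sex": self.sex.astype(int)}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovariateTable":
        for col in ("subject_id", "age", "sex"):
            if col not in df.columns:
                raise ValueError(f"expected a {col!r} column")
        return cls(
            list(df["subject_id"]),
            df["age"].to_numpy(dtype=float),
            df["sex"].to_numpy(dtype=float),
        )
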