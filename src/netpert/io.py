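"""Readers and writers for the package's tabular artifacts, plus optional
NIfTI regional SUVr extraction.

CSV (comma, UTF-8, header row) is the canonical dialect; TSV is accepted
on read by sniffing the delimiter.  Floats are serialized with 17
significant digits so write/read round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasLabels
from .containers import CovariateTable, RegionalUptakeTable
from .metrics import REDMatrix
from .network import DeviationMatrix

__all__ = [
    "read_uptake_csv",
    "write_uptake_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_deviation_csv",
    "write_deviation_csv",
    "write_sed_csv",
    "read_red_csv",
    "write_red_csv",
    "join_covariates",
    "extract_regional_suvr",
]

FLOAT_FMT = "%.17g"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= max(1, header.count(",")) else ","
    # round_trip parsing keeps write/read exact to the last bit
    df = pd.read_csv(path, sep=sep, encoding="utf-8", float_precision="round_trip")
    if df.isna().any().any():
        rows, cols = np.where(df.isna().to_numpy())
        # +2: header line plus 1-based numbering
        locs = [f"line {r + 2}, column {df.columns[c]!r}" for r, c in zip(rows, cols)][:5]
        raise ValueError(f"{path}: missing values are not supported ({'; '.join(locs)})")
    return df


def read_uptake_csv(path: str | Path) -> RegionalUptakeTable:
    """Read a subjects x regions SUVr table (first column `subject_id`,
    remaining columns one region each)."""
    return RegionalUptakeTable.from_dataframe(_read_table(path))


def write_uptake_csv(table: RegionalUptakeTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_covariates_csv(path: str | Path) -> CovariateTable:
    return CovariateTable.from_dataframe(_read_table(path))


def write_covariates_csv(cov: CovariateTable, path: str | Path) -> None:
    cov.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def join_covariates(table: RegionalUptakeTable, cov: CovariateTable) -> CovariateTable:
    """Reorder a covariate table to the uptake table's subject order.

    Raises with the symmetric difference when the id sets differ.
    """
    missing = sorted(set(table.subject_ids) - set(cov.subject_ids))
    extra = sorted(set(cov.subject_ids) - set(table.subject_ids))
    if missing or extra:
        raise ValueError(
            f"covariate/uptake id mismatch; missing from covariates: {missing}; "
            f"not in uptake table: {extra}"
        )
    order = [cov.subject_ids.index(s) for s in table.subject_ids]
    return cov.subset(order)


def write_deviation_csv(dev: DeviationMatrix, path: str | Path) -> None:
    """m x m z-matrix with region labels as header row and first column."""
    dev.to_dataframe().to_csv(path, index=True, index_label="region", float_format=FLOAT_FMT)


def read_deviation_csv(path: str | Path, subject_id: str = "subject", n_ref: int = 0) -> DeviationMatrix:
    df = pd.read_csv(
        path, index_col="region", encoding="utf-8", float_precision="round_trip"
    )
    return DeviationMatrix(
        z=df.to_numpy(dtype=float),
        subject_id=subject_id,
        n_ref=n_ref,
        region_labels=list(df.columns),
    )


def write_sed_csv(sed: pd.Series, path: str | Path) -> None:
    sed.rename_axis("subject_id").reset_index().to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_red_csv(red: REDMatrix, path: str | Path) -> None:
    red.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_red_csv(path: str | Path) -> REDMatrix:
    return REDMatrix.from_dataframe(_read_table(path))


def extract_regional_suvr(
    parametric_image, label_image, atlas: AtlasLabels
) -> pd.Series:
    """Regional SUVr from a parametric PET image and an integer label image.

    Each analysis region's value is the mean voxel activity inside its
    label mask divided by the mean activity over the cerebellar
    reference labels.  Inputs may be file paths or nibabel images; both
    must live on the same voxel grid.  Requires the optional ``nibabel``
    dependency.
    """
    import nibabel as nib

    if isinstance(parametric_image, (str, Path)):
        parametric_image = nib.load(str(parametric_image))
    if isinstance(label_image, (str, Path)):
        label_image = nib.load(str(label_image))
    data = np.asarray(parametric_image.dataobj, dtype=float)
    labels = np.asarray(label_image.dataobj)
    if data.shape != labels.shape:
        raise ValueError(
            f"image grids differ: activity {data.shape} vs labels {labels.shape}"
        )
    if not np.allclose(parametric_image.affine, label_image.affine, atol=1e-4):
        raise ValueError("activity and label images have different affines")
    labels = np.round(labels).astype(int)
    present = set(np.unique(labels)) - {0}
    unknown = present - set(atlas.names)
    if unknown:
        raise ValueError(f"label image contains ids not in the atlas: {sorted(unknown)}")
    ref_mask = np.isin(labels, list(atlas.reference_ids))
    if not ref_mask.any():
        raise ValueError("no reference-region (cerebellar) voxels in the label image")
    ref_mean = data[ref_mask].mean()
    if ref_mean == 0:
        raise ZeroDivisionError("reference-region mean activity is zero")
    values = {}
    for rid in atlas.analysis_ids:
        mask = labels == rid
        if not mask.any():
            raise ValueError(f"empty mask for region {atlas.names[rid]!r} (id {rid})")
        values[atlas.names[rid]] = data[mask].mean() / ref_mean
    return pd.Series(values, name="suvr")
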