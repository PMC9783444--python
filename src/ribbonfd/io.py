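"""Volume and table I/O (MGZ / NIfTI via nibabel, CSV via pandas)."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fd import BinaryMask
from .parcellation import LabelVolume

logger = logging.getLogger(__name__)

SEX_CODES = {"F": 0, "M": 1}


class VolumeFormatError(ValueError):
    """The file is not a readable 3D MGZ/NIfTI volume."""


def read_volume(path: str | Path, kind: str = "auto") -> LabelVolume | BinaryMask:
    """Load an MGZ or NIfTI volume as a label volume or binary mask.

    ``kind`` is "labels", "mask", or "auto" (mask when the data is 0/1,
    labels otherwise).  A trailing singleton 4th dimension is squeezed;
    a genuinely 4D volume is a format error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: header field dim reports ndim={data.ndim}, need a 3D volume"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(data, np.round(data)):
        raise VolumeFormatError(f"{path}: voxel values are not integers")
    data = np.round(data).astype(np.int32)
    if kind == "auto":
        kind = "mask" if data.max(initial=0) <= 1 else "labels"
    if kind == "mask":
        return BinaryMask(data != 0, zooms)
    if kind == "labels":
        return LabelVolume(data, zooms)
    raise ValueError(f"kind must be 'auto', 'mask' or 'labels', got {kind!r}")


def write_volume(path: str | Path, volume: LabelVolume | BinaryMask) -> None:
    """Write a label volume (int32) or mask (uint8) as MGZ or NIfTI."""
    path = Path(path)
    if isinstance(volume, BinaryMask):
        data = volume.grid.astype(np.uint8)
    else:
        data = volume.grid.astype(np.int32)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    if path.name.endswith(".mgz") or path.name.endswith(".mgh"):
        img = nib.MGHImage(data, affine)
    else:
        img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a subject covariate/FD CSV; sex given as F/M strings is recoded 0/1.

    Unknown sex codes are hard errors (no imputation).
    """
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "tbv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["sex"].dtype == object:
        codes = df["sex"].str.strip().str.upper()
        unknown = sorted(set(codes) - set(SEX_CODES))
        if unknown:
            raise ValueError(f"{path}: unknown sex codes {unknown}; expected F/M")
        df["sex"] = codes.map(SEX_CODES)
    elif not df["sex"].isin([0, 1]).all():
        raise ValueError(f"{path}: numeric sex column must be 0 (female) / 1 (male)")
    if (df["tbv"] <= 0).any():
        raise ValueError(f"{path}: tbv must be positive")
    return df


def write_table(path: str | Path, df: pd.DataFrame, full_precision: bool = False) -> None:
    """Write a results CSV (6 significant digits, or 17 when full precision)."""
    fmt = "%.17g" if full_precision else "%.6g"
    df.to_csv(path, index=False, float_format=fmt)
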