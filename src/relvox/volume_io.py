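"""Volume, mask and atlas containers plus NIfTI input/output.

All downstream code (training, relevance propagation, heatmap metrics)
operates on the in-memory containers defined here.  Volumes are held as 3D
float arrays in a single canonical axes convention: axis 0 runs left-right
(sagittal), axis 1 posterior-anterior (coronal), axis 2 inferior-superior
(axial).  NIfTI files are reoriented to RAS+ on load so that this holds for
arbitrarily oriented inputs.  Masks and atlases must share the working grid
of their partner volume exactly; no implicit resampling happens inside
metric code.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize as _skimage_resize

__all__ = [
    "Volume",
    "BinaryMask",
    "LabelAtlas",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_atlas",
    "resample_volume",
    "resample_mask",
    "minmax_scale",
    "read_manifest",
    "write_manifest",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in arbitrary units (float).
    spacing : tuple of float
        Voxel edge lengths in mm along each axis.
    subject_id : str
        Identifier of the subject the scan belongs to.
    orientation : str
        Canonical axes tag; always ``"RAS"`` after loading.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"Volume shape must be strictly positive, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A voxel-aligned {0,1} mask (e.g. a lesion or white-matter mask)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Mask data must be 3D, got ndim={arr.ndim}")
        uniques = np.unique(arr)
        if not np.all(np.isin(uniques, (0, 1))):
            raise ValueError(f"Mask values must be in {{0,1}}, got {uniques[:10]}")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelAtlas:
    """Integer-labelled region map with optional left/right merge table.

    ``label_table`` maps each nonzero integer label to a region name.
    ``merge_table`` optionally maps labels onto merged region names (for
    example collapsing left and right hemisphere homologues); labels not
    listed there keep their own region name.
    """

    data: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)
    merge_table: dict[int, str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("Atlas data must be 3D")
        if np.any(arr < 0):
            raise ValueError("Atlas labels must be non-negative")
        self.data = arr.astype(np.int32)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"Atlas labels missing from label_table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def merged_name(self, label: int) -> str:
        if self.merge_table and label in self.merge_table:
            return self.merge_table[label]
        return self.label_table[label]

    def region_mask(self, name: str) -> BinaryMask:
        """Binary mask of all labels whose (merged) region name equals ``name``."""
        labels = [l for l in self.label_table if self.merged_name(l) == name]
        if not labels:
            raise KeyError(f"No atlas label maps to region {name!r}")
        return BinaryMask(np.isin(self.data, labels).astype(np.uint8))


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...]]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"No such NIfTI file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"Expected a single-channel 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing


def read_volume(path: str | os.PathLike, subject_id: str = "") -> Volume:
    """Read a single-channel 3D NIfTI as a :class:`Volume` in RAS+ orientation."""
    data, spacing = _load_canonical(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"NIfTI {path} contains non-finite voxels")
    return Volume(data=data, spacing=spacing, subject_id=subject_id)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (float32, RAS+ affine from spacing)."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    data, _ = _load_canonical(path)
    return BinaryMask(np.rint(data).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | os.PathLike, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def read_atlas(
    path: str | os.PathLike,
    label_table: dict[int, str],
    merge_table: dict[int, str] | None = None,
) -> LabelAtlas:
    data, _ = _load_canonical(path)
    return LabelAtlas(np.rint(data).astype(np.int32), label_table, merge_table)


def resample_volume(volume: Volume, target_shape: tuple[int, int, int], order: int = 1) -> Volume:
    """Resample an intensity volume to ``target_shape``.

    Trilinear interpolation (``order=1``) by default; use
    :func:`resample_mask` for masks and atlases, which must stay integer.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if min(target_shape) < 1:
        raise ValueError(f"target_shape must be strictly positive, got {target_shape}")
    out = _skimage_resize(
        volume.data,
        target_shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    new_spacing = tuple(
        sp * old / new for sp, old, new in zip(volume.spacing, volume.shape, target_shape)
    )
    return Volume(out, spacing=new_spacing, subject_id=volume.subject_id)


def resample_mask(mask: BinaryMask, target_shape: tuple[int, int, int]) -> BinaryMask:
    """Nearest-neighbour resampling; output remains strictly binary."""
    target_shape = tuple(int(s) for s in target_shape)
    if min(target_shape) < 1:
        raise ValueError(f"target_shape must be strictly positive, got {target_shape}")
    out = _skimage_resize(
        mask.data.astype(np.float64),
        target_shape,
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return BinaryMask(np.rint(out).astype(np.uint8))


def minmax_scale(volume: Volume) -> Volume:
    """Per-subject min-max standardization to [0, 1].

    Raises on a constant volume, for which the scaling is undefined.
    """
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi <= lo:
        raise ValueError("Cannot min-max scale a constant volume (max == min)")
    return Volume(
        (volume.data - lo) / (hi - lo), spacing=volume.spacing, subject_id=volume.subject_id
    )


MANIFEST_COLUMNS = ["subject_id", "label", "volume_path", "lesion_mask_path", "wm_mask_path"]


def write_manifest(records: list[dict], path: str | os.PathLike) -> None:
    """Write a subject manifest CSV (columns: subject_id, label, paths)."""
    df = pd.DataFrame(records)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]].to_csv(
        path, index=False
    )


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "label", "volume_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Manifest {path} is missing columns: {sorted(missing)}")
    return df
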