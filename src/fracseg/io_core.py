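"""Volumetric image plumbing: read/write, resampling, normalization, cropping.

Index convention used throughout the package
--------------------------------------------
Arrays are indexed ``data[x, y, z]`` with 0-based, half-open bounding boxes
``((x0, x1), (y0, y1), (z0, z1))``.  Axis 0 is the fastest-varying on-disk
axis of the supported formats (NIfTI/NRRD/MetaImage), so ``spacing[i]``
always refers to array axis ``i``.  SimpleITK's ``GetArrayFromImage``
returns (z, y, x); we transpose at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LabelMap",
    "BoneRegion",
    "FormatError",
    "DegenerateInputError",
    "EmptyLabelError",
    "read_volume",
    "write_volume",
    "resample",
    "zscore_normalize",
    "crop_to_bbox",
    "paste_region",
    "ANATOMICAL_LABELS",
    "FRAGMENT_LABELS",
]

#: anatomical scheme: id -> name
ANATOMICAL_LABELS = {0: "background", 1: "sacrum", 2: "left_hipbone", 3: "right_hipbone"}
#: fragment scheme: id -> name
FRAGMENT_LABELS = {0: "background", 1: "main", 2: "minor"}

_SUPPORTED_EXT = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


class FormatError(ValueError):
    """Unreadable file or unsupported volumetric format."""


class DegenerateInputError(ValueError):
    """Input without enough variation to process (e.g. constant intensities)."""


class EmptyLabelError(ValueError):
    """A requested label is absent from a label map."""


def _as_tuple3(x) -> Tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, in HU for raw CT or dimensionless after z-scoring.
    spacing : (sx, sy, sz)
        Voxel size in mm along each array axis; strictly positive.
    origin : (ox, oy, oz)
        Physical position of voxel (0, 0, 0) in mm.
    direction : (3, 3) ndarray
        Orthonormal orientation matrix mapping index axes to physical axes.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all shape components must be >= 1, got {self.data.shape}")
        self.spacing = _as_tuple3(self.spacing)
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal within 1e-6")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same geometry, new voxel values."""
        return replace(self, data=data)


_SCHEMES = {
    "anatomical": set(ANATOMICAL_LABELS),
    "fragment": set(FRAGMENT_LABELS),
    "instance": None,  # 0 = background, 1 = main, 2..K = minors; open-ended
}


@dataclass
class LabelMap(Volume):
    """Integer-valued :class:`Volume` carrying a label scheme.

    Schemes: ``anatomical`` (0 bg, 1 sacrum, 2 left hipbone, 3 right
    hipbone), ``fragment`` (0 bg, 1 main, 2 minor), ``instance`` (0 bg,
    1 main, 2..K enumerated minor fragments).
    """

    scheme: str = "fragment"

    def __post_init__(self):
        super().__post_init__()
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown label scheme {self.scheme!r}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.data, 1), 0)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        allowed = _SCHEMES[self.scheme]
        if allowed is not None:
            present = set(np.unique(self.data).tolist())
            if not present <= allowed:
                raise ValueError(
                    f"labels {sorted(present - allowed)} outside scheme {self.scheme!r}"
                )

    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class BoneRegion:
    """A cropped, z-scored bone volume plus its location in the source grid."""

    volume: Volume
    bbox: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]
    source_label: int
    margin_vox: Tuple[int, int, int]
    #: affine (scale, shift) of the z-scoring, to invert or reapply it
    norm_affine: Tuple[float, float] = (1.0, 0.0)


# ---------------------------------------------------------------------------
# I/O


def _to_sitk(v: Volume) -> sitk.Image:
    data = v.data
    if isinstance(v, LabelMap):
        data = data.astype(np.uint16 if data.max() < 2**16 else np.int32)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(v.spacing))
    img.SetOrigin(tuple(v.origin))
    img.SetDirection(tuple(v.direction.flatten()))
    return img


def _from_sitk(img: sitk.Image, scheme: Optional[str] = None) -> Volume:
    data = sitk.GetArrayFromImage(img).T
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if scheme is not None:
        return LabelMap(
            data=data.astype(np.int32), spacing=spacing, origin=origin,
            direction=direction, scheme=scheme,
        )
    return Volume(data=data, spacing=spacing, origin=origin, direction=direction)


def read_volume(path: str | os.PathLike, scheme: Optional[str] = None) -> Volume:
    """Read a NIfTI/NRRD/MetaImage volume.

    Pass ``scheme`` to get a :class:`LabelMap` instead of a :class:`Volume`.
    Raises :class:`FormatError` for missing files or unsupported formats.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if not path.lower().endswith(_SUPPORTED_EXT):
        raise FormatError(f"unsupported volume format: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises RuntimeError on bad files
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    return _from_sitk(img, scheme=scheme)


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume; labels go to disk as integers, floats as float32.

    ``.nii.gz`` gets gzip compression via the NIfTI writer.
    """
    path = os.fspath(path)
    if not path.lower().endswith(_SUPPORTED_EXT):
        raise FormatError(f"unsupported volume format: {path}")
    try:
        sitk.WriteImage(_to_sitk(v), path)
    except Exception as exc:
        raise IOError(f"could not write volume {path}: {exc}") from exc


def write_label_sidecar(path: str | os.PathLike, scheme: str) -> None:
    """Write a ``labels.json`` sidecar mapping label ids to names."""
    table = ANATOMICAL_LABELS if scheme == "anatomical" else FRAGMENT_LABELS
    with open(path, "w") as fh:
        json.dump({"scheme": scheme, "labels": {str(k): v for k, v in table.items()}}, fh, indent=2)


# ---------------------------------------------------------------------------
# Resampling and normalization


def resample(
    v: Volume,
    target_spacing: Sequence[float],
    mode: str = "bspline",
) -> Volume:
    """Resample to ``target_spacing`` (mm), preserving physical extent.

    Intensities use 3rd-order b-spline interpolation; label maps always use
    nearest-neighbour regardless of ``mode``.
    """
    target_spacing = _as_tuple3(target_spacing)
    if min(target_spacing) <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if mode not in ("bspline", "nearest", "linear"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if np.allclose(target_spacing, v.spacing):
        return v.with_data(v.data.copy())

    is_label = isinstance(v, LabelMap)
    img = _to_sitk(v)
    new_size = [
        max(1, int(round(sz * sp / tsp)))
        for sz, sp, tsp in zip(v.shape, v.spacing, target_spacing)
    ]
    interp = sitk.sitkNearestNeighbor if (is_label or mode == "nearest") else (
        sitk.sitkBSpline if mode == "bspline" else sitk.sitkLinear
    )
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        tuple(target_spacing),
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )
    out = _from_sitk(res, scheme=v.scheme if is_label else None)
    return out


def zscore_normalize(
    v: Volume,
    mask: Optional[LabelMap | np.ndarray] = None,
    return_affine: bool = False,
):
    """Z-score a volume: zero mean, unit standard deviation.

    With a mask, the mean/sd are fitted over masked voxels only and the
    resulting affine map ``x -> (x - mu) / sd`` is applied everywhere.
    """
    dom = None
    if mask is not None:
        dom = mask.foreground() if isinstance(mask, LabelMap) else np.asarray(mask) > 0
        if dom.sum() < 2:
            raise DegenerateInputError("normalization mask must cover at least 2 voxels")
        vals = v.data[dom]
    else:
        vals = v.data.reshape(-1)
    mu = float(np.mean(vals))
    sd = float(np.std(vals))
    if sd <= 0:
        raise DegenerateInputError("cannot z-score a constant volume")
    out = v.with_data(((v.data - mu) / sd).astype(np.float32))
    if return_affine:
        return out, (1.0 / sd, -mu / sd)
    return out


# ---------------------------------------------------------------------------
# Cropping and pasting


def label_bbox(labels: LabelMap, label: int):
    """Tight half-open bounding box of a label; EmptyLabelError if absent."""
    mask = labels.data == label
    if not mask.any():
        raise EmptyLabelError(f"label {label} absent from label map")
    bbox = []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        bbox.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(bbox)


def crop_to_bbox(
    ct: Volume,
    anat: LabelMap,
    label: int,
    margin_vox: int | Sequence[int] = 8,
    fill_hu: float = 0.0,
) -> BoneRegion:
    """Extract one bone: crop to its padded bounding box and z-score.

    Voxels belonging to *other* bones inside the crop are replaced with
    ``fill_hu`` (soft-tissue baseline) before normalization so neighbouring
    bones do not leak context into the fracture network's input.
    """
    if ct.data.shape != anat.data.shape:
        raise ValueError("CT and anatomical label map shapes differ")
    tight = label_bbox(anat, label)
    margins = (margin_vox,) * 3 if np.isscalar(margin_vox) else tuple(margin_vox)
    bbox = tuple(
        (max(0, lo - m), min(n, hi + m))
        for (lo, hi), m, n in zip(tight, margins, ct.shape)
    )
    sl = tuple(slice(lo, hi) for lo, hi in bbox)
    sub_ct = ct.data[sl].astype(np.float32).copy()
    sub_anat = anat.data[sl]
    other = (sub_anat > 0) & (sub_anat != label)
    sub_ct[other] = fill_hu
    new_origin = tuple(
        o + lo * s for o, (lo, _), s in zip(ct.origin, bbox, ct.spacing)
    )
    vol = Volume(sub_ct, spacing=ct.spacing, origin=new_origin, direction=ct.direction)
    vol, affine = zscore_normalize(vol, return_affine=True)
    return BoneRegion(
        volume=vol, bbox=bbox, source_label=int(label),
        margin_vox=margins, norm_affine=affine,
    )


def paste_region(
    region_labels: LabelMap,
    bbox,
    full_shape: Sequence[int],
    into: Optional[np.ndarray] = None,
) -> LabelMap:
    """Place cropped labels back into a full-size grid (inverse of crop).

    Foreground of ``region_labels`` overwrites whatever is at the bbox
    location; pass ``into`` to paste several regions into one array.  The
    number of overwritten foreground voxels is recorded on the result as
    ``overlap_count``.
    """
    full_shape = tuple(int(n) for n in full_shape)
    ext = tuple(hi - lo for lo, hi in bbox)
    if ext != region_labels.data.shape:
        raise ValueError(f"bbox extent {ext} != region shape {region_labels.data.shape}")
    for (lo, hi), n in zip(bbox, full_shape):
        if lo < 0 or hi > n:
            raise ValueError(f"bbox {bbox} does not fit inside shape {full_shape}")
    canvas = np.zeros(full_shape, dtype=np.int32) if into is None else into
    sl = tuple(slice(lo, hi) for lo, hi in bbox)
    fg = region_labels.data > 0
    overlap = int(np.count_nonzero(canvas[sl][fg]))
    patch = canvas[sl]
    patch[fg] = region_labels.data[fg]
    canvas[sl] = patch
    out = LabelMap(
        data=canvas,
        spacing=region_labels.spacing,
        origin=(0.0, 0.0, 0.0),
        direction=region_labels.direction,
        scheme=region_labels.scheme if region_labels.scheme != "anatomical" else "instance",
    )
    out.overlap_count = overlap
    return out
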