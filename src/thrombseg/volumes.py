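"""Volume/mask containers, NIfTI I/O, and CT intensity preprocessing.

A :class:`Volume` is a 3-D scalar grid with millimetre voxel spacing and a
modality tag (``"NCCT"`` or ``"CTA"``).  The axis convention is fixed
throughout the package: axis 0 is the longitudinal axis with increasing index
pointing cranially; axes 1 and 2 are the frontal and sagittal axes.  Phantoms
are generated in this convention and clinical inputs are assumed to have been
reoriented (and co-registered) upstream.

Preprocessing clips each modality to its Hounsfield-unit window -- (0, 100) HU
for NCCT, (0, 250) HU for CTA -- and maps the window linearly onto [0, 1].
The window is fixed per modality rather than per image so that normalized
intensities are comparable across cases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

MODALITIES = ("NCCT", "CTA")

Spacing = Tuple[float, float, float]


class VolumeError(ValueError):
    """Base error for volume I/O and preprocessing contract violations."""


class NotAVolumeError(VolumeError):
    """Raised when an image on disk is not a 3-D volume."""


class BadSpacingError(VolumeError):
    """Raised when header voxel spacing is not strictly positive."""


class UnknownModalityError(VolumeError):
    """Raised for a modality tag other than NCCT or CTA."""


@dataclass
class Volume:
    """3-D scalar grid with voxel spacing (mm) and a modality tag."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    modality: str = "NCCT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"not a 3-D volume: ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise BadSpacingError(f"non-positive voxel spacing {self.spacing}")
        if self.modality not in MODALITIES:
            raise UnknownModalityError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class Mask:
    """3-D boolean grid aligned to a paired :class:`Volume`."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"not a 3-D mask: ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise BadSpacingError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))


@dataclass(frozen=True)
class PreprocessConfig:
    """Per-modality HU clip windows; each window maps linearly onto [0, 1]."""

    ncct_clip: Tuple[float, float] = (0.0, 100.0)
    cta_clip: Tuple[float, float] = (0.0, 250.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.ncct_clip, self.cta_clip):
            if not lo < hi:
                raise VolumeError(f"clip window ({lo}, {hi}) needs low < high")

    def window(self, modality: str) -> Tuple[float, float]:
        if modality == "NCCT":
            return self.ncct_clip
        if modality == "CTA":
            return self.cta_clip
        raise UnknownModalityError(f"unknown modality {modality!r}")


def _spacing_from_header(img: nib.Nifti1Image) -> Spacing:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)  # type: ignore[return-value]


def read_volume(path: str | Path, modality: str = "NCCT") -> Volume:
    """Read a 3-D NIfTI image into a :class:`Volume`.

    Raises ``FileNotFoundError`` for a missing file, :class:`NotAVolumeError`
    for a non-3-D image, and :class:`BadSpacingError` for a header with
    non-positive voxel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise NotAVolumeError(f"{path} is not a 3-D volume (ndim={data.ndim})")
    spacing = _spacing_from_header(img)
    if any(s <= 0 for s in spacing):
        raise BadSpacingError(f"{path} has non-positive spacing {spacing}")
    return Volume(data=data, spacing=spacing, modality=modality)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; spacing goes into the affine diagonal."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> Mask:
    """Read a binary NIfTI mask (any nonzero voxel counts as foreground)."""
    vol = read_volume(path, modality="NCCT")
    return Mask(data=vol.data != 0, spacing=vol.spacing)


def write_mask(mask: Mask, path: str | Path) -> Path:
    """Write a mask as an 8-bit {0,1} NIfTI-1 image."""
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path


def clip_and_normalize(vol: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clip to the modality's HU window and map it linearly onto [0, 1].

    An NCCT voxel at 150 HU clips to 100 HU and maps to 1.0; a voxel at
    -5 HU maps to 0.0.  Shape, spacing and modality are unchanged.  The map
    is monotone and idempotent once expressed in normalized units.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.window(vol.modality)
    data = np.clip(np.asarray(vol.data, dtype=np.float64), lo, hi)
    data = (data - lo) / (hi - lo)
    return replace(vol, data=data)
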