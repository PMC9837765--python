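"""Volume/mask/saliency I/O and gray-level quantization.

MRI intensities arrive with arbitrary dynamic range; every histogram
method downstream operates on discrete gray levels ``0 .. L-1``.  This
module owns the containers (:class:`Volume`, :class:`Frame`,
:class:`MaskStack`, :class:`SaliencyStack`) and the only place raw
intensities are mapped onto that discrete domain (:func:`quantize`).

Conventions
-----------
* Volumes are ``(slices, rows, cols)``, axis 0 is the slice axis.
* Coordinates are 0-based, row-major; boxes are half-open.
* Mask foreground is 1.
* NIfTI (.nii/.nii.gz) for stacks, PNG for single frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image

from ._rounding import round_levels

REGION_LABELS = ("WG", "TZ", "PZ")


class FormatError(ValueError):
    """Raised when an on-disk input does not match the expected layout."""


@dataclass
class Volume:
    """A 3D scalar grid of shape (slices, rows, cols) with physical spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("Volume.voxels must be 3D with all dimensions >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("Volume.spacing must be three strictly positive floats")

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.voxels.min()), float(self.voxels.max())

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Frame:
    """One 2D quantized grayscale slice, the unit all enhancers act on."""

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Frame.pixels must be 2D")
        if self.levels < 2:
            raise ValueError("Frame.levels must be >= 2")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            if not np.array_equal(self.pixels, np.round(self.pixels)):
                raise ValueError("Frame.pixels must be integer-valued")
            self.pixels = self.pixels.astype(np.int64)
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > self.levels - 1):
            raise ValueError("Frame pixels must lie in [0, levels-1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "Frame":
        return Frame(self.pixels.copy(), self.levels)


@dataclass
class MaskStack:
    """Ordered binary masks for one anatomical region (WG, TZ or PZ)."""

    frames: list[np.ndarray]
    region_label: str = "WG"

    def __post_init__(self) -> None:
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"region_label must be one of {REGION_LABELS}")
        frames = []
        shape = None
        for f in self.frames:
            a = np.asarray(f)
            if not np.isin(a, (0, 1)).all():
                raise ValueError("mask values must be 0/1")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("all mask frames must share one shape")
            frames.append(a.astype(np.uint8))
        self.frames = frames

    @property
    def nsl(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


@dataclass
class SaliencyStack:
    """Ordered non-negative relevance maps, one per slice, values in [0, 1]."""

    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        frames = []
        shape = None
        for f in self.frames:
            a = np.asarray(f, dtype=float)
            if a.min() < 0 or a.max() > 1:
                raise ValueError("saliency frames must lie in [0, 1]; load with normalize=True")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("all saliency frames must share one shape")
            frames.append(a)
        self.frames = frames

    @property
    def nsl(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape  # type: ignore[return-value]

    def as_array(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI file, or a directory of equally-sized PNG slices, as a Volume.

    NIfTI voxel data are interpreted with axis 0 as the slice axis and the
    header zooms as (slice, row, col) spacing.  PNG directories are read in
    sorted filename order with unit spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        pngs = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not pngs:
            raise FormatError(f"no PNG slices found in {path}")
        slices = [np.asarray(Image.open(p).convert("I")) for p in pngs]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        return Volume(np.stack(slices, axis=0))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) if z > 0 else 1.0 for z in zooms)
    return Volume(data, spacing)


def write_volume(vol: Volume, path: str | os.PathLike) -> Path:
    """Write a Volume to NIfTI; the file round-trips through :func:`read_volume`."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    data = np.asarray(vol.voxels)
    if data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)  # NIfTI has no 64-bit integer type
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask_stack(stack: MaskStack, path: str | os.PathLike,
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    return write_volume(Volume(stack.as_array(), spacing), path)


def read_mask_stack(path: str | os.PathLike, region_label: str = "WG") -> MaskStack:
    vol = read_volume(path)
    data = np.asarray(vol.voxels)
    binary = (data > 0).astype(np.uint8)
    if not np.array_equal(binary, data):
        raise FormatError(f"{path} contains non-binary mask values")
    return MaskStack(list(binary), region_label=region_label)


def load_saliency_stack(path: str | os.PathLike, normalize: bool = True) -> SaliencyStack:
    """Load a NIfTI saliency stack; optionally min-max scale each frame to [0, 1].

    With ``normalize`` each frame is independently rescaled so its minimum
    maps to 0 and its maximum to 1; constant frames become all-zero.  With
    normalization off, frames must already lie in [0, 1] (negative values
    are rejected).
    """
    vol = read_volume(path)
    frames = []
    for sl in vol.voxels:
        a = np.asarray(sl, dtype=float)
        if normalize:
            lo, hi = a.min(), a.max()
            a = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
        elif a.min() < 0:
            raise ValueError("negative saliency values; pass normalize=True")
        frames.append(a)
    return SaliencyStack(frames)


def write_frame_png(frame: Frame, path: str | os.PathLike) -> Path:
    """Write an 8-bit PNG rendering of a frame (levels rescaled to 0..255)."""
    path = Path(path)
    px = frame.pixels.astype(float) * (255.0 / (frame.levels - 1))
    Image.fromarray(np.round(px).astype(np.uint8), mode="L").save(path)
    return path


# ---------------------------------------------------------------------------
# Quantization


def quantize(
    vol: Volume,
    levels: int = 256,
    clip_percentiles: tuple[float, float] = (0.0, 100.0),
    rounding: str = "half-up",
) -> list[Frame]:
    """Map a volume's intensity range linearly onto integers [0, levels-1].

    The mapping is per-volume (all slices share one lookup) so relative
    brightness across slices is preserved.  ``clip_percentiles`` allows a
    robust range, e.g. (0.5, 99.5) to discard hot pixels; the default is
    pure min-max.  Constant volumes map to all zeros.  The map is
    order-preserving: x <= y implies q(x) <= q(y).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    low, high = clip_percentiles
    if not (0 <= low < high <= 100):
        raise ValueError("clip_percentiles must satisfy 0 <= low < high <= 100")
    data = np.asarray(vol.voxels, dtype=float)
    lo, hi = np.percentile(data, [low, high])
    if hi == lo:
        q = np.zeros(data.shape, dtype=np.int64)
    else:
        scaled = (np.clip(data, lo, hi) - lo) / (hi - lo) * (levels - 1)
        q = round_levels(scaled, rounding)
    return [Frame(sl, levels) for sl in q]


def frames_to_volume(frames: Sequence[Frame],
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Volume:
    """Stack quantized frames back into a Volume (e.g. for writing to NIfTI)."""
    return Volume(np.stack([f.pixels for f in frames], axis=0), spacing)
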