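"""DaTscan SPECT image preparation.

Pipeline for preparing 2-D network inputs from DaTscan-style volumes
(91 slices of 109 x 91 voxels, as distributed for the PPMI cohort):
pick a single axial slice (the 41st by default, which cuts through the
striatum), crop away the black border, resize to 224 x 224, and min-max
scale to [0, 1].  A brightness multiplier in [0.1, 1.5] is available as
a training-time augmentation, and a seeded 80:20 train/test splitter
rounds out the stage.

DICOM and PNG I/O are thin wrappers around pydicom and Pillow so tests
can run entirely on synthetic arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Volume",
    "SliceImage",
    "extract_slice",
    "crop_black_border",
    "resize_and_scale",
    "brightness_augment",
    "split_dataset",
    "preprocess_volume",
    "read_dicom_volume",
    "read_png_slice",
    "write_png_slice",
    "BRIGHTNESS_RANGE",
]

#: Allowed multiplicative brightness-augmentation range.
BRIGHTNESS_RANGE = (0.1, 1.5)

#: Default DaTscan volume layout: (slices, height, width).
DATSCAN_SHAPE = (91, 109, 91)


@dataclass(frozen=True)
class Volume:
    """3-D intensity volume, axes ordered (slice, height, width)."""

    voxels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=float)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"voxels must be a nonempty 3-D array, got shape {arr.shape}")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("voxel intensities must be finite and >= 0")
        object.__setattr__(self, "voxels", arr)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class SliceImage:
    """2-D slice with provenance: source volume id, 1-based slice index,
    and the crop box (top, left, bottom, right) in 0-based half-open
    pixel coordinates once cropped."""

    pixels: np.ndarray
    slice_index: int = 0
    crop_box: Optional[tuple[int, int, int, int]] = None
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"pixels must be a nonempty 2-D array, got shape {arr.shape}")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def extract_slice(vol: Volume, index: int = 41) -> SliceImage:
    """Return the ``index``-th slice, counted 1-based (default: the 41st)."""
    if not 1 <= index <= vol.n_slices:
        raise ValueError(f"slice index {index} out of range 1..{vol.n_slices}")
    return SliceImage(vol.voxels[index - 1].copy(), slice_index=index, source=vol.source)


def crop_black_border(img: SliceImage, threshold: float = 0.0) -> SliceImage:
    """Crop to the tight bounding box of pixels with intensity above
    ``threshold``.  An image that is black everywhere degenerates to its
    1 x 1 centre pixel."""
    arr = img.pixels
    mask = arr > threshold
    if not mask.any():
        r, c = arr.shape[0] // 2, arr.shape[1] // 2
        box = (r, c, r + 1, c + 1)
    else:
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    top, left, bottom, right = box
    return SliceImage(
        arr[top:bottom, left:right].copy(),
        slice_index=img.slice_index,
        crop_box=box,
        source=img.source,
    )


def resize_and_scale(img: SliceImage, side: int = 224) -> SliceImage:
    """Bilinear-resize to ``side`` x ``side``, then min-max scale to [0, 1].

    A constant image has no contrast to stretch and maps to all zeros.
    """
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    arr = _sk_resize(
        img.pixels, (side, side), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    lo, hi = float(arr.min()), float(arr.max())
    arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    return SliceImage(arr, slice_index=img.slice_index, crop_box=img.crop_box, source=img.source)


def brightness_augment(
    img: SliceImage,
    factor: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> SliceImage:
    """Multiply intensities by ``factor`` and clip to [0, 1].

    Training-time augmentation only.  When ``factor`` is None one is
    drawn uniformly from the configured range using ``rng`` (a Generator
    or a seed).
    """
    lo, hi = BRIGHTNESS_RANGE
    if factor is None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        factor = float(gen.uniform(lo, hi))
    if not lo <= factor <= hi:
        raise ValueError(f"brightness factor {factor} outside allowed range [{lo}, {hi}]")
    arr = np.clip(img.pixels * factor, 0.0, 1.0)
    return SliceImage(arr, slice_index=img.slice_index, crop_box=img.crop_box, source=img.source)


def preprocess_volume(vol: Volume, slice_index: int = 41, side: int = 224,
                      crop_threshold: float = 0.0) -> SliceImage:
    """extract -> crop -> resize_and_scale, the full evaluation-time chain."""
    return resize_and_scale(
        crop_black_border(extract_slice(vol, slice_index), crop_threshold), side
    )


def split_dataset(
    samples: Sequence[tuple[Hashable, Hashable]],
    test_fraction: float = 0.2,
    seed: int | None = 0,
    stratify: bool = False,
) -> tuple[list[tuple[Hashable, Hashable]], list[tuple[Hashable, Hashable]]]:
    """Seeded random train/test partition of ``(sample_id, label)`` pairs.

    The test set receives ``round(test_fraction * n)`` samples.  The
    default draw is unstratified; ``stratify=True`` applies the same
    rounding per label group instead.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    if stratify:
        train: list = []
        test: list = []
        labels = sorted({lab for _, lab in samples}, key=repr)
        for lab in labels:
            group = [s for s in samples if s[1] == lab]
            perm = rng.permutation(len(group))
            n_test = round(test_fraction * len(group))
            test.extend(group[i] for i in perm[:n_test])
            train.extend(group[i] for i in perm[n_test:])
        return train, test
    perm = rng.permutation(n)
    n_test = round(test_fraction * n)
    test = [samples[i] for i in perm[:n_test]]
    train = [samples[i] for i in perm[n_test:]]
    return train, test


def read_dicom_volume(path: str | Path) -> Volume:
    """Load a multi-frame DICOM file as a Volume (slice axis first)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return Volume(arr, source=str(path))


def read_png_slice(path: str | Path) -> SliceImage:
    """Load a grayscale PNG/JPEG as a SliceImage (values as stored)."""
    from PIL import Image

    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("I")).astype(float)
    return SliceImage(arr, source=str(path))


def write_png_slice(img: SliceImage, path: str | Path) -> None:
    """Write a [0, 1]-scaled slice as 16-bit grayscale PNG (lossless to
    ~1.5e-5, avoiding 8-bit quantization)."""
    from PIL import Image

    arr = img.pixels
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("expected pixels scaled to [0, 1] before PNG export")
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(str(path))
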