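"""Gray-image data model, histogram extraction and threshold application.

The segmentation pipeline operates on 2D integer gray images with ``Z``
representable levels (pixel values in ``[0, Z-1]``).  A threshold vector
``u_1 < ... < u_m`` of cut points partitions the gray range into ``m+1``
classes; applying it to an image yields a per-pixel label map.

Two interval dialects are supported:

``partition`` (default)
    Class ``i`` is ``[u_i, u_{i+1})`` with sentinels ``u_0 = 0`` and
    ``u_{m+1} = Z``.  Every gray level receives exactly one class; for a
    single cut ``U`` this is the classic two-region rule ``o < U -> 0``,
    ``o >= U -> 1``.

``paper-eq2``
    Left-open classes ``(u_i, u_{i+1}]``: a pixel equal to a cut value lands
    one class lower than under ``partition``.  The rule as written covers only
    gray levels ``>= 1``; gray level 0 is assigned to class 0 here so the
    label map stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "GrayImage",
    "GrayHistogram",
    "ThresholdVector",
    "LabelMap",
    "DomainError",
    "ChannelError",
    "FormatError",
    "read_image",
    "write_image",
    "compute_histogram",
    "apply_thresholds",
    "write_label_map",
    "read_label_map",
]

Dialect = Literal["partition", "paper-eq2"]

# Rec. 709 luminance weights, as used by scikit-image's rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


class DomainError(ValueError):
    """A value violates a documented precondition (e.g. cut outside [1, Z-1])."""


class ChannelError(DomainError):
    """Multi-channel input supplied without requesting luminance conversion."""


class FormatError(DomainError):
    """File could not be read as a supported grayscale image."""


def _best_uint_dtype(n_levels: int) -> np.dtype:
    if n_levels <= 256:
        return np.dtype(np.uint8)
    if n_levels <= 65536:
        return np.dtype(np.uint16)
    return np.dtype(np.uint32)


@dataclass(frozen=True)
class GrayImage:
    """A 2D grid of integer gray values in ``[0, n_levels - 1]``."""

    pixels: np.ndarray
    n_levels: int = 256
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise DomainError(f"pixels must be a non-empty 2D grid, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise DomainError(f"pixels must be integer-typed, got {px.dtype}")
        if self.n_levels < 2:
            raise DomainError(f"n_levels must be >= 2, got {self.n_levels}")
        if px.min() < 0 or px.max() > self.n_levels - 1:
            raise DomainError(
                f"pixel values must lie in [0, {self.n_levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GrayHistogram:
    """Normalized gray-level histogram: ``probs[o]`` is the pixel fraction at level ``o``."""

    probs: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise DomainError("probs must be a 1D vector of length >= 2")
        if (p < 0).any():
            raise DomainError("histogram probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise DomainError(f"histogram must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "probs", p)

    @property
    def n_levels(self) -> int:
        return self.probs.size

    def nonzero_levels(self) -> np.ndarray:
        """Gray levels carrying nonzero mass, ascending."""
        return np.flatnonzero(self.probs > 0)


@dataclass(frozen=True)
class ThresholdVector:
    """Strictly increasing cut points ``u_1..u_m``, each in ``[1, n_levels - 1]``."""

    cuts: tuple[int, ...]
    n_levels: int = 256

    def __post_init__(self) -> None:
        cuts = tuple(int(c) for c in self.cuts)
        if len(cuts) < 1:
            raise DomainError("at least one cut is required")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise DomainError(f"cuts must be strictly increasing, got {cuts}")
        if cuts[0] < 1 or cuts[-1] > self.n_levels - 1:
            raise DomainError(
                f"cuts must lie in [1, {self.n_levels - 1}], got {cuts}"
            )
        object.__setattr__(self, "cuts", cuts)

    @property
    def m(self) -> int:
        return len(self.cuts)

    @property
    def n_classes(self) -> int:
        return len(self.cuts) + 1

    def bounds(self) -> np.ndarray:
        """Class boundaries with sentinels: ``[0, u_1, ..., u_m, Z]``."""
        return np.array([0, *self.cuts, self.n_levels])


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class indices in ``[0, n_classes - 1]``."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise DomainError("labels must be a non-empty 2D grid")
        if not np.issubdtype(lab.dtype, np.integer):
            raise DomainError("labels must be integer-typed")
        if self.n_classes < 1:
            raise DomainError("n_classes must be >= 1")
        if lab.min() < 0 or lab.max() > self.n_classes - 1:
            raise DomainError("label values must lie in [0, n_classes-1]")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_classes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(
    path: str | Path,
    format: str | None = None,
    *,
    n_levels: int | None = None,
    to_gray: bool = False,
    nifti_slice: int = 0,
    window_center: float | None = None,
    window_width: float | None = None,
) -> GrayImage:
    """Read a grayscale image from PNG/TIFF (8/16-bit) or a single NIfTI slice.

    Parameters
    ----------
    format
        ``"png"``, ``"tiff"`` or ``"nifti"``; inferred from the suffix when
        omitted.
    n_levels
        Override the gray-level count ``Z`` (default: 256 for 8-bit input,
        65536 for 16-bit).
    to_gray
        Convert RGB(A) input to luminance; without it multi-channel input
        raises :class:`ChannelError`.
    nifti_slice, window_center, window_width
        For NIfTI volumes: axial slice index and the linear intensity window
        mapped onto ``[0, Z-1]``.  Both window parameters are required for
        NIfTI input.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".nii", ".gz"} or path.name.lower().endswith(".nii.gz"):
            format = "nifti"
        elif suffix in {".tif", ".tiff"}:
            format = "tiff"
        else:
            format = "png"

    if format == "nifti":
        return _read_nifti_slice(path, nifti_slice, window_center, window_width, n_levels)

    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"cannot read {path}: {exc}") from exc

    if arr.ndim == 3:
        if not to_gray:
            raise ChannelError(
                f"{path} has {arr.shape[-1]} channels; pass to_gray=True for luminance conversion"
            )
        rgb = arr[..., :3].astype(float)
        arr = np.rint(rgb @ _LUMA)
    elif arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, got shape {arr.shape}")

    if np.issubdtype(arr.dtype, np.floating):
        arr = np.rint(arr)
    bit16 = arr.max() > 255 or (hasattr(arr, "dtype") and arr.dtype == np.uint16)
    z = n_levels if n_levels is not None else (65536 if bit16 else 256)
    arr = arr.astype(_best_uint_dtype(z))
    return GrayImage(arr, n_levels=z, meta={"source": str(path), "format": format})


def _read_nifti_slice(
    path: Path,
    slice_index: int,
    window_center: float | None,
    window_width: float | None,
    n_levels: int | None,
) -> GrayImage:
    import nibabel as nib

    if window_center is None or window_width is None:
        raise DomainError("NIfTI input requires an explicit window_center and window_width")
    if window_width <= 0:
        raise DomainError("window_width must be positive")
    z = n_levels if n_levels is not None else 256
    try:
        vol = np.asanyarray(nib.load(str(path)).dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    if vol.ndim == 2:
        sl = vol
    elif vol.ndim >= 3:
        if not 0 <= slice_index < vol.shape[2]:
            raise DomainError(
                f"slice index {slice_index} out of range for volume with {vol.shape[2]} slices"
            )
        sl = vol[..., slice_index] if vol.ndim == 3 else vol[..., slice_index, 0]
    else:
        raise FormatError(f"{path}: unsupported NIfTI dimensionality {vol.ndim}")
    lo = window_center - window_width / 2.0
    scaled = (np.asarray(sl, dtype=float) - lo) / window_width * (z - 1)
    px = np.clip(np.rint(scaled), 0, z - 1).astype(_best_uint_dtype(z))
    return GrayImage(
        px,
        n_levels=z,
        meta={
            "source": str(path),
            "format": "nifti",
            "slice": slice_index,
            "window_center": window_center,
            "window_width": window_width,
        },
    )


def write_image(image: GrayImage, path: str | Path) -> Path:
    """Write a gray image to PNG or TIFF (dtype chosen from ``n_levels``)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, image.pixels.astype(_best_uint_dtype(image.n_levels)))
    return path


# ---------------------------------------------------------------------------
# Histogram and thresholding
# ---------------------------------------------------------------------------

def compute_histogram(image: GrayImage) -> GrayHistogram:
    """Normalized gray-level histogram ``q_o = #{pixels == o} / (N*M)``."""
    counts = np.bincount(image.pixels.ravel(), minlength=image.n_levels)
    n = image.pixels.size
    return GrayHistogram(probs=counts / n, n_pixels=n)


def apply_thresholds(
    image: GrayImage,
    thresholds: ThresholdVector,
    dialect: Dialect = "partition",
) -> LabelMap:
    """Label every pixel with the class its gray value falls into.

    With ``dialect="partition"`` class ``i`` is ``[u_i, u_{i+1})`` (sentinels
    ``u_0 = 0``, ``u_{m+1} = Z``); a pixel's label is the number of cuts
    ``<=`` its value.  With ``dialect="paper-eq2"`` classes are left-open
    ``(u_i, u_{i+1}]`` and the label is the number of cuts ``<`` the value;
    gray level 0, which the left-open rule does not cover, goes to class 0.
    """
    if thresholds.n_levels != image.n_levels:
        raise DomainError(
            f"threshold vector is for Z={thresholds.n_levels}, image has Z={image.n_levels}"
        )
    cuts = np.asarray(thresholds.cuts)
    if dialect == "partition":
        labels = np.searchsorted(cuts, image.pixels.ravel(), side="right")
    elif dialect == "paper-eq2":
        labels = np.searchsorted(cuts, image.pixels.ravel(), side="left")
    else:
        raise DomainError(f"unknown dialect {dialect!r}")
    labels = labels.reshape(image.shape).astype(_best_uint_dtype(thresholds.n_classes))
    return LabelMap(labels=labels, n_classes=thresholds.n_classes)


def write_label_map(
    labels: LabelMap,
    path: str | Path,
    mode: Literal["indexed", "scaled"] = "indexed",
) -> Path:
    """Write a label map as an image.

    ``indexed`` stores raw class indices (lossless round-trip via
    :func:`read_label_map`); ``scaled`` maps class ``i`` to
    ``round(i * 255 / m)`` for visual inspection.
    """
    import imageio.v3 as iio

    path = Path(path)
    if mode == "indexed":
        arr = labels.labels.astype(_best_uint_dtype(labels.n_classes))
    elif mode == "scaled":
        m = max(labels.n_classes - 1, 1)
        arr = np.rint(labels.labels * (255.0 / m)).astype(np.uint8)
    else:
        raise DomainError(f"unknown mode {mode!r}")
    iio.imwrite(path, arr)
    return path


def read_label_map(path: str | Path, n_classes: int) -> LabelMap:
    """Read back an indexed label map written by :func:`write_label_map`."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label maps must be single-channel")
    return LabelMap(labels=arr.astype(np.int64), n_classes=n_classes)
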