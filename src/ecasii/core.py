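"""Containers and spectral-angle arithmetic shared by every stage.

A multiband image is held as an ``H x W x B`` float array of reflectance-like
intensities; after :func:`normalize` every value lies in ``[0, 1]``.  All
dissimilarity in the package is the normalized spectral angle, which is
invariant to a positive rescaling of either spectrum and therefore independent
of the number of bands — the property that lets rule sets trained on 3-band
scenes run unchanged on cubes with tens or hundreds of bands.

Grid convention: row-major arrays, ``x`` = column index increasing rightward,
``y`` = row index increasing downward; every angle in the package is
``atan2(GY, GX)`` in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralImage",
    "LabelMap",
    "BorderMap",
    "spectral_angle",
    "spectral_angle_maps",
    "angular_transform",
    "normalize",
    "NEIGHBOR_OFFSETS_8",
]

#: numerical guard on vector norms; below this a spectrum counts as zero
EPS_NORM = 1e-12

#: the 8-connected neighbor offsets as (dy, dx) pairs
NEIGHBOR_OFFSETS_8 = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


@dataclass
class SpectralImage:
    """An ``H x W x B`` cube of cell states (pixel spectra).

    Parameters
    ----------
    data : ndarray
        Float array of shape ``(height, width, bands)``.  Any number of
        bands >= 1 is accepted; the method is dimension-independent.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError(f"expected H x W x B array, got shape {arr.shape}")
        if arr.shape[2] < 1:
            raise ValueError("image must have at least one band")
        self.data = arr

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "SpectralImage":
        return SpectralImage(self.data.copy())


@dataclass
class LabelMap:
    """An ``H x W`` integer grid of class ids, canonicalized to ``1..M``.

    Arbitrary input label values are remapped to contiguous ids in order of
    first appearance (row-major); the original values are kept in
    ``original_values`` so the mapping can be persisted or inverted.
    """

    labels: np.ndarray
    original_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {arr.shape}")
        values, first = np.unique(arr, return_index=True)
        order = np.argsort(first)            # order of first appearance
        values = values[order]
        lut = {v: i + 1 for i, v in enumerate(values)}
        canon = np.vectorize(lut.__getitem__, otypes=[np.int32])(arr)
        self.labels = canon
        self.original_values = np.asarray(values)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def raw(self) -> np.ndarray:
        """The grid in its original (pre-canonicalization) label values."""
        return self.original_values[self.labels - 1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_ids(self) -> np.ndarray:
        return np.arange(1, self.n_classes + 1)


@dataclass
class BorderMap:
    """Binary ``H x W`` grid: 0 marks a border pixel, 1 an interior pixel.

    A pixel is a border pixel iff one of its 8-neighbors carries a different
    label (frame pixels only consider in-image neighbors).
    """

    flags: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.flags, dtype=np.int8)
        if arr.ndim != 2:
            raise ValueError("border map must be 2-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("border map entries must be 0 or 1")
        self.flags = arr

    @classmethod
    def from_labels(cls, labels: LabelMap | np.ndarray) -> "BorderMap":
        lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
        border = np.zeros(lab.shape, dtype=bool)
        for dy, dx in NEIGHBOR_OFFSETS_8:
            shifted, valid = _shift2d(lab, dy, dx)
            border |= valid & (shifted != lab)
        return cls(np.where(border, 0, 1).astype(np.int8))


def _shift2d(arr: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Shift a 2-D (or 2-D+bands) array so out[y, x] = arr[y+dy, x+dx].

    Returns the shifted array (zero-filled outside) and a boolean validity
    mask of in-image source positions.
    """
    h, w = arr.shape[:2]
    out = np.zeros_like(arr)
    valid = np.zeros((h, w), dtype=bool)
    ys0, ys1 = max(0, -dy), min(h, h - dy)
    xs0, xs1 = max(0, -dx), min(w, w - dx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0:ys1, xs0:xs1] = arr[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
        valid[ys0:ys1, xs0:xs1] = True
    return out, valid


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized spectral angle between two spectra, in ``[0, 1]``.

    ``(2/pi) * arccos(<a, b> / (|a| |b|))`` with the cosine argument clamped
    to ``[-1, 1]``.  Symmetric, scale-invariant, and zero iff the spectra are
    parallel.  If either norm is (numerically) zero the angle is defined as 0.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"spectra have different lengths: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < EPS_NORM or nb < EPS_NORM:
        return 0.0
    u = a / na
    v = b / nb
    # stable at both ends (exact 0 for parallel spectra), unlike arccos
    theta = 2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    return float((2.0 / np.pi) * theta)


def spectral_angle_maps(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel normalized spectral angle between two ``... x B`` arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("arrays must share a shape")
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    ok = (na >= EPS_NORM) & (nb >= EPS_NORM)
    u = a / np.where(na >= EPS_NORM, na, 1.0)[..., None]
    v = b / np.where(nb >= EPS_NORM, nb, 1.0)[..., None]
    diff = np.linalg.norm(u - v, axis=-1)
    summ = np.linalg.norm(u + v, axis=-1)
    ang = (4.0 / np.pi) * np.arctan2(diff, summ)
    ang[~ok] = 0.0
    return ang


def angular_transform(img: SpectralImage) -> np.ndarray:
    """2-D angular view of a cube: angle of each pixel against a saturated
    reference spectrum (all bands at 1).  Useful for visualizing a cube of any
    dimensionality as a single grayscale image."""
    ref = np.ones_like(img.data)
    return spectral_angle_maps(img.data, ref)


def normalize(img: SpectralImage) -> SpectralImage:
    """Affine rescale of the whole cube into ``[0, 1]`` by global min/max.

    A constant cube maps to all zeros.  Idempotent.
    """
    data = img.data
    if not np.isfinite(data).all():
        raise ValueError("image contains non-finite values")
    lo = float(data.min())
    hi = float(data.max())
    if hi - lo < EPS_NORM:
        return SpectralImage(np.zeros_like(data))
    return SpectralImage((data - lo) / (hi - lo))
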