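"""Segmentation cost evaluated against a labeled ground truth.

The cost driving the evolutionary search is the maximum of two errors, each
in ``[0, 1]``:

* *intra-class error* — how spectrally inhomogeneous the ground-truth regions
  are in the (partially) segmented image.  Itself the max of a local term
  (mean spectral angle of interior pixels to their 8-neighbors, pooled over
  classes) and a non-local term (mean angle over randomly sampled pairs of
  interior pixels of the same class, class-size weighted).
* *inter-class error* — how spectrally confusable distinct regions are across
  their shared borders: for sampled pairs of border pixels from classes k and
  k', count the pair as an error when their angle does not exceed the sum of
  the two classes' local homogeneities ``H_k + H_k'``; combine pair rates by
  nested region-size weighted means.

A perfect segmentation (constant regions, spectrally separated across every
border) scores 0; a spectrally constant image with two or more classes
scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    NEIGHBOR_OFFSETS_8,
    BorderMap,
    LabelMap,
    SpectralImage,
    _shift2d,
    spectral_angle_maps,
)

__all__ = [
    "GroundTruth",
    "FitnessConfig",
    "FitnessReport",
    "derive_ground_truth",
    "local_intra_error",
    "class_homogeneity",
    "nonlocal_intra_error",
    "inter_error",
    "total_cost",
]


@dataclass
class GroundTruth:
    """Labels plus derived border/interior index sets.

    ``interior[k]`` / ``border[k]`` hold flat pixel indices of class ``k``
    (1-based class ids); ``shared_border[(k, k2)]`` the border pixels of
    class ``k`` having an 8-neighbor of class ``k2``.
    """

    labels: LabelMap
    borders: BorderMap
    interior: dict[int, np.ndarray]
    border: dict[int, np.ndarray]
    shared_border: dict[tuple[int, int], np.ndarray]
    region_size: dict[int, int]

    @property
    def n_classes(self) -> int:
        return self.labels.n_classes

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class FitnessConfig:
    """Sampling sizes of the Monte-Carlo error terms.

    V : pixel pairs sampled per class for the non-local intra term.
    U : pixel pairs sampled per ordered class pair for the inter term.
    """

    V: int = 100
    U: int = 100
    seed: int | None = None
    rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.V < 1 or self.U < 1:
            raise ValueError("V and U must be >= 1")

    def make_rng(self) -> np.random.Generator:
        if self.rng is not None:
            return self.rng
        return np.random.default_rng(self.seed)


@dataclass
class FitnessReport:
    e_local_intra: float
    e_nonlocal_intra: float
    e_intra: float
    e_inter: float
    e: float
    homogeneity: np.ndarray  # H_k per class, index 0 = class 1

    def to_dict(self) -> dict:
        return {
            "e_local_intra": self.e_local_intra,
            "e_nonlocal_intra": self.e_nonlocal_intra,
            "e_intra": self.e_intra,
            "e_inter": self.e_inter,
            "e": self.e,
            "homogeneity": self.homogeneity.tolist(),
        }


def derive_ground_truth(labels: LabelMap) -> GroundTruth:
    """Partition a label map into per-class interior/border index sets.

    A pixel is a border pixel iff some 8-neighbor has a different label;
    ``shared_border[(k, k2)]`` collects class-k border pixels abutting class
    k2.  A single-class map yields empty border sets.
    """
    lab = labels.labels
    borders = BorderMap.from_labels(labels)
    flat = lab.ravel()
    interior_mask = borders.flags.astype(bool).ravel()

    interior: dict[int, np.ndarray] = {}
    border: dict[int, np.ndarray] = {}
    region_size: dict[int, int] = {}
    for k in labels.class_ids():
        in_class = flat == k
        interior[k] = np.flatnonzero(in_class & interior_mask)
        border[k] = np.flatnonzero(in_class & ~interior_mask)
        region_size[k] = int(in_class.sum())

    # neighbor labels per border pixel -> shared-border sets
    shared: dict[tuple[int, int], list] = {}
    h, w = lab.shape
    for dy, dx in NEIGHBOR_OFFSETS_8:
        shifted, valid = _shift2d(lab, dy, dx)
        differs = valid & (shifted != lab)
        ys, xs = np.nonzero(differs)
        ks = lab[ys, xs]
        k2s = shifted[ys, xs]
        idxs = ys * w + xs
        for k, k2, i in zip(ks.tolist(), k2s.tolist(), idxs.tolist()):
            shared.setdefault((k, k2), []).append(i)
    shared_border = {
        key: np.unique(np.asarray(v, dtype=np.int64)) for key, v in shared.items()
    }
    return GroundTruth(
        labels=labels,
        borders=borders,
        interior=interior,
        border=border,
        shared_border=shared_border,
        region_size=region_size,
    )


# ---------------------------------------------------------------------------
# error components
# ---------------------------------------------------------------------------

def _neighbor_angle_field(img: SpectralImage) -> np.ndarray:
    """Per-pixel mean spectral angle to in-image 8-neighbors."""
    data = img.data
    total = np.zeros(data.shape[:2])
    count = np.zeros(data.shape[:2])
    for dy, dx in NEIGHBOR_OFFSETS_8:
        shifted, valid = _shift2d(data, dy, dx)
        total += np.where(valid, spectral_angle_maps(data, shifted), 0.0)
        count += valid
    return total / np.maximum(count, 1)


def local_intra_error(img: SpectralImage, gt: GroundTruth) -> float:
    """Mean neighbor angle over all interior pixels, classes pooled.

    Interior pixels on the image frame average over their in-image neighbors
    only.  Returns 0 (with a warning) when no class has interior pixels.
    """
    _check_shapes(img, gt)
    field_ = _neighbor_angle_field(img).ravel()
    all_interior = np.concatenate([gt.interior[k] for k in sorted(gt.interior)])
    if all_interior.size == 0:
        warnings.warn("no interior pixels in any class; local intra error is 0")
        return 0.0
    return float(field_[all_interior].mean())


def class_homogeneity(img: SpectralImage, gt: GroundTruth, k: int) -> float:
    """H_k: mean neighbor angle over the interior pixels of class ``k``.

    0 by convention for a class without interior pixels.
    """
    _check_shapes(img, gt)
    idx = gt.interior[k]
    if idx.size == 0:
        return 0.0
    return float(_neighbor_angle_field(img).ravel()[idx].mean())


def _all_homogeneities(img: SpectralImage, gt: GroundTruth) -> np.ndarray:
    field_ = _neighbor_angle_field(img).ravel()
    out = np.zeros(gt.n_classes)
    for k in sorted(gt.interior):
        idx = gt.interior[k]
        if idx.size:
            out[k - 1] = field_[idx].mean()
    return out


def nonlocal_intra_error(
    img: SpectralImage, gt: GroundTruth, cfg: FitnessConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Class-size-weighted mean angle of sampled same-class interior pairs.

    For each class with interior pixels, ``V`` pairs are drawn uniformly with
    replacement from its interior set (classes visited in ascending id order
    so a fixed seed fixes the sample); class means are combined weighted by
    interior size.  Classes without interior pixels are skipped and excluded
    from the weighting.
    """
    _check_shapes(img, gt)
    cfg = cfg or FitnessConfig()
    rng = rng if rng is not None else cfg.make_rng()
    spectra = img.data.reshape(-1, img.bands)
    num = 0.0
    den = 0.0
    for k in sorted(gt.interior):
        idx = gt.interior[k]
        if idx.size < 1:
            continue
        pairs = rng.integers(0, idx.size, size=(cfg.V, 2))
        ang = spectral_angle_maps(spectra[idx[pairs[:, 0]]], spectra[idx[pairs[:, 1]]])
        num += ang.mean() * idx.size
        den += idx.size
    if den == 0.0:
        warnings.warn("no interior pixels in any class; non-local intra error is 0")
        return 0.0
    return float(num / den)


def inter_error(
    img: SpectralImage, gt: GroundTruth, homogeneity: np.ndarray,
    cfg: FitnessConfig | None = None, rng: np.random.Generator | None = None,
) -> float:
    """Border-pair confusability, nested region-size weighted.

    For every ordered class pair (k, k') whose shared border is sampleable on
    both sides, ``U`` pairs (x in the k-side border, y in the k'-side border)
    are drawn with replacement; a pair counts as an error when its spectral
    angle is <= ``H_k + H_k'``.  Pair rates are combined as a
    ``#B_k'``-weighted mean over k' (renormalized over sampleable partners)
    and then a ``#B_k``-weighted mean over k.  Returns 0 (with a warning)
    when no pair of classes shares a border.
    """
    _check_shapes(img, gt)
    cfg = cfg or FitnessConfig()
    rng = rng if rng is not None else cfg.make_rng()
    spectra = img.data.reshape(-1, img.bands)
    classes = sorted(gt.interior)

    outer_num = 0.0
    outer_den = 0.0
    any_pair = False
    for k in classes:
        inner_num = 0.0
        inner_den = 0.0
        for k2 in classes:
            if k2 == k:
                continue
            f_kk2 = gt.shared_border.get((k, k2))
            f_k2k = gt.shared_border.get((k2, k))
            if f_kk2 is None or f_k2k is None or not f_kk2.size or not f_k2k.size:
                continue
            xs = f_kk2[rng.integers(0, f_kk2.size, size=cfg.U)]
            ys = f_k2k[rng.integers(0, f_k2k.size, size=cfg.U)]
            ang = spectral_angle_maps(spectra[xs], spectra[ys])
            thresh = homogeneity[k - 1] + homogeneity[k2 - 1]
            rate = float((ang <= thresh).mean())
            inner_num += rate * gt.region_size[k2]
            inner_den += gt.region_size[k2]
            any_pair = True
        if inner_den > 0.0:
            outer_num += (inner_num / inner_den) * gt.region_size[k]
            outer_den += gt.region_size[k]
    if not any_pair:
        warnings.warn("no class pair shares a border; inter error is 0")
        return 0.0
    return float(outer_num / outer_den)


def total_cost(
    img: SpectralImage, gt: GroundTruth, cfg: FitnessConfig | None = None
) -> FitnessReport:
    """Compose all error components: ``e = max(e_intra, e_inter)``.

    One random stream (from ``cfg``) feeds the non-local intra sampling and
    then the inter sampling, so a fixed seed makes the whole report
    bit-reproducible.
    """
    cfg = cfg or FitnessConfig()
    rng = cfg.make_rng()
    hk = _all_homogeneities(img, gt)
    e_local = local_intra_error(img, gt)
    e_nonlocal = nonlocal_intra_error(img, gt, cfg, rng=rng)
    e_intra = max(e_local, e_nonlocal)
    e_inter = inter_error(img, gt, hk, cfg, rng=rng)
    return FitnessReport(
        e_local_intra=e_local,
        e_nonlocal_intra=e_nonlocal,
        e_intra=e_intra,
        e_inter=e_inter,
        e=max(e_intra, e_inter),
        homogeneity=hk,
    )


def _check_shapes(img: SpectralImage, gt: GroundTruth) -> None:
    if img.data.shape[:2] != gt.shape:
        raise ValueError(
            f"image {img.data.shape[:2]} and ground truth {gt.shape} differ in shape"
        )
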