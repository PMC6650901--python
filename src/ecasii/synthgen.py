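"""Parametric generator of labeled training scenes, and its inverse estimator.

Training the automaton requires labeled images whose ground truth is exact.
Real annotated multiband scenes are scarce and their border labels dubious,
so training scenes are synthesized from four knobs that summarize the
spatial/spectral character of the images one intends to segment:

* ``N`` — number of region classes,
* ``Dmax`` in [0, 1] — ruggedness of the region borders,
* ``rmax`` — target mean intra-class spectral angle between neighboring
  pixels (per-pixel noisiness),
* ``[smin, smax]`` — range of spectral angles between the base spectra of
  adjacent classes.

Geometry is a nearest-seed (Voronoi) partition computed on distance fields
perturbed by smoothed noise whose amplitude grows with ``Dmax``; base spectra
are drawn by rejection sampling until every adjacent class pair's angle lies
in ``[smin, smax]``; per-pixel noise is calibrated by a closed loop until the
realized mean intra-class neighbor angle is within 10% of ``rmax``.

``estimate_params`` inverts the process: given any labeled image it reports
per-class intra-class distances and inter-class distances plus a border
tortuosity, so the knobs can be read off real scenes of interest.

The module also builds the multiband test fixtures used to benchmark the
whole pipeline: ~80 x 80 five-region 64-band cubes corrupted either by strong
i.i.d. noise or by convex endmember mixtures near region borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BorderMap,
    LabelMap,
    SpectralImage,
    spectral_angle,
    spectral_angle_maps,
)
from .fitness import derive_ground_truth, local_intra_error

__all__ = [
    "SceneSpec",
    "SceneBundle",
    "generate_scene",
    "estimate_params",
    "default_base_spectra",
    "make_multiband_fixture",
]

MAX_SPECTRA_ATTEMPTS = 10_000


@dataclass
class SceneSpec:
    """Generator parameters of one labeled scene."""

    N: int = 5
    Dmax: float = 0.3
    rmax: float = 0.05
    smin: float = 0.15
    smax: float = 0.45
    height: int = 32
    width: int = 32
    bands: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.Dmax <= 1.0:
            raise ValueError("Dmax must lie in [0, 1]")
        if not 0.0 <= self.smin <= self.smax <= 1.0:
            raise ValueError("need 0 <= smin <= smax <= 1")
        if self.rmax < 0:
            raise ValueError("rmax must be >= 0")
        if self.rmax >= self.smin > 0:
            warnings.warn(
                "rmax >= smin: intra-class variation rivals inter-class "
                "separation; such scenes are atypical"
            )

    def replace(self, **kw) -> "SceneSpec":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class SceneBundle:
    """A generated scene: image, exact labels, borders, realized parameters."""

    image: SpectralImage
    labels: LabelMap
    borders: BorderMap
    report: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _region_partition(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Nearest-seed labels on a Dmax-perturbed distance field.

    Retries (new seeds/noise) until all N classes survive the perturbation.
    """
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    # perturbation amplitude relative to the typical seed spacing
    spacing = np.sqrt(h * w / spec.N)
    amp = spec.Dmax * 0.9 * spacing
    smooth_sigma = max(1.5, 0.15 * spacing)
    for _ in range(50):
        seeds = np.column_stack(
            [rng.uniform(0, h, size=spec.N), rng.uniform(0, w, size=spec.N)]
        )
        fields = np.empty((spec.N, h, w))
        for i, (sy, sx) in enumerate(seeds):
            dist = np.hypot(yy - sy, xx - sx)
            if amp > 0:
                noise = rng.standard_normal((h, w))
                noise = ndimage.gaussian_filter(noise, smooth_sigma)
                std = noise.std()
                if std > 0:
                    noise *= amp / std
                dist = dist + noise
            fields[i] = dist
        labels = fields.argmin(axis=0) + 1
        if np.unique(labels).size == spec.N:
            return labels.astype(np.int32)
    raise RuntimeError(
        f"could not place {spec.N} regions on a {h}x{w} grid; "
        "reduce N or Dmax, or enlarge the scene"
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _adjacent_pairs(labels: np.ndarray) -> list[tuple[int, int]]:
    pairs = set()
    h, w = labels.shape
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = labels[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
        b = labels[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
        differ = a != b
        for k, k2 in zip(a[differ].ravel().tolist(), b[differ].ravel().tolist()):
            pairs.add((min(k, k2), max(k, k2)))
    return sorted(pairs)


def _draw_base_spectra(
    n: int,
    bands: int,
    pairs: list[tuple[int, int]],
    smin: float,
    smax: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Base spectra with every adjacent-class angle inside [smin, smax].

    Rejection sampling with targeted redraws: each attempt resamples only the
    spectra participating in a violated constraint.
    """
    spectra = rng.uniform(0.1, 1.0, size=(n, bands))
    for _ in range(MAX_SPECTRA_ATTEMPTS):
        bad: set[int] = set()
        for k, k2 in pairs:
            a = spectral_angle(spectra[k - 1], spectra[k2 - 1])
            if not (smin <= a <= smax):
                bad.add(k if rng.random() < 0.5 else k2)
        if not bad:
            return spectra
        for k in bad:
            spectra[k - 1] = rng.uniform(0.1, 1.0, size=bands)
    raise RuntimeError(
        f"no base-spectrum assignment with adjacent angles in "
        f"[{smin}, {smax}] found for {n} classes after "
        f"{MAX_SPECTRA_ATTEMPTS} attempts"
    )


def _apply_noise(
    clean: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-Gaussian pixel noise, 70% multiplicative / 30% additive."""
    if sigma == 0.0:
        return clean.copy()
    g1 = rng.standard_normal(clean.shape)
    g2 = rng.standard_normal(clean.shape)
    noisy = clean * (1.0 + 0.7 * sigma * g1) + 0.3 * sigma * g2
    return np.clip(noisy, 0.0, 1.0)


def _realized_rmax(data: np.ndarray, gt) -> float:
    return local_intra_error(SpectralImage(data), gt)


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Generate one labeled scene per the four-knob parameterization.

    The noise scale is calibrated by bisection until the realized mean
    intra-class neighbor spectral angle lies within 10% of ``spec.rmax``
    (``rmax = 0`` gives a piecewise-constant image).
    """
    rng = np.random.default_rng(spec.seed)
    labels_arr = _region_partition(spec, rng)
    labels = LabelMap(labels_arr)
    pairs = _adjacent_pairs(labels.labels)
    base = _draw_base_spectra(spec.N, spec.bands, pairs, spec.smin, spec.smax, rng)
    clean = base[labels.labels - 1]

    gt = derive_ground_truth(labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scenes may lack interior pixels
        sigma, realized, probe_seed = _calibrate_noise(clean, gt, spec.rmax, rng)
    data = _apply_noise(clean, sigma, np.random.default_rng(probe_seed))

    adj_angles = {
        f"{k}-{k2}": spectral_angle(base[k - 1], base[k2 - 1]) for k, k2 in pairs
    }
    report = {
        "requested_rmax": spec.rmax,
        "realized_rmax": realized if spec.rmax > 0 else 0.0,
        "noise_sigma": sigma,
        "adjacent_base_angles": adj_angles,
        "n_classes": spec.N,
    }
    return SceneBundle(
        image=SpectralImage(data),
        labels=labels,
        borders=gt.borders,
        report=report,
    )


def _calibrate_noise(
    clean: np.ndarray, gt, rmax: float, rng: np.random.Generator
) -> tuple[float, float, int]:
    """Bisect the noise scale so the realized intra angle hits rmax +-10%.

    Returns ``(sigma, realized_rmax, probe_seed)``; the probe seed fixes the
    noise draw so the calibrated value is exactly the one realized.
    """
    probe_seed = int(rng.integers(0, 2**31))
    if rmax <= 0.0:
        return 0.0, 0.0, probe_seed

    def realized_fixed(sigma: float) -> float:
        return _realized_rmax(
            _apply_noise(clean, sigma, np.random.default_rng(probe_seed)), gt
        )

    lo, hi = 0.0, 0.05
    while realized_fixed(hi) < rmax and hi < 8.0:
        hi *= 2.0
    val = realized_fixed(hi)
    if val < rmax:
        warnings.warn(f"requested rmax={rmax} unreachable; realized {val:.4f}")
        return hi, val, probe_seed
    mid = hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        val = realized_fixed(mid)
        if abs(val - rmax) <= 0.1 * rmax:
            return mid, val, probe_seed
        if val < rmax:
            lo = mid
        else:
            hi = mid
    return mid, val, probe_seed


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_params(
    image: SpectralImage,
    labels: LabelMap,
    pairs_per_class: int = 1000,
    seed: int | None = 0,
) -> dict:
    """Estimate the four scene knobs from any labeled image.

    Per class ``i``: ``rmax_i`` is the mean neighbor spectral angle over its
    interior pixels and ``s_i`` the mean angle of sampled pixel pairs between
    class ``i`` and all other classes.  Reported ``rmax`` is the max of the
    ``rmax_i``; ``[smin, smax]`` the min/max of the ``s_i``; ``Dmax`` comes
    from border tortuosity (border length over the border length of a
    median-smoothed label map, shifted and clipped into [0, 1]).
    """
    if image.data.shape[:2] != labels.shape:
        raise ValueError("image and labels differ in shape")
    rng = np.random.default_rng(seed)
    gt = derive_ground_truth(labels)
    from .fitness import _neighbor_angle_field

    field_ = _neighbor_angle_field(image).ravel()
    spectra = image.data.reshape(-1, image.bands)
    flat = labels.labels.ravel()

    per_class = {}
    rmax_values = []
    s_values = []
    for k in labels.class_ids():
        k = int(k)
        idx = gt.interior[k]
        if idx.size == 0:
            warnings.warn(f"class {k} has no interior pixels; skipped in rmax")
            rmax_i = None
        else:
            rmax_i = float(field_[idx].mean())
            rmax_values.append(rmax_i)
        own = np.flatnonzero(flat == k)
        other = np.flatnonzero(flat != k)
        if own.size and other.size:
            a = own[rng.integers(0, own.size, size=pairs_per_class)]
            b = other[rng.integers(0, other.size, size=pairs_per_class)]
            s_i = float(spectral_angle_maps(spectra[a], spectra[b]).mean())
            s_values.append(s_i)
        else:
            s_i = None
        per_class[k] = {"rmax_i": rmax_i, "s_i": s_i}

    dmax = _estimate_dmax(labels)
    return {
        "N": labels.n_classes,
        "rmax": max(rmax_values) if rmax_values else 0.0,
        "smin": min(s_values) if s_values else 0.0,
        "smax": max(s_values) if s_values else 0.0,
        "Dmax": dmax,
        "per_class": per_class,
    }


def _estimate_dmax(labels: LabelMap) -> float:
    """Border tortuosity: border mass relative to a smoothed label map's.

    Ratio 1 (already-smooth borders) maps to 0; ratio >= 2 saturates at 1.
    """
    lab = labels.labels
    raw_border = (BorderMap.from_labels(labels).flags == 0).sum()
    smooth = ndimage.median_filter(lab, size=5, mode="nearest")
    smooth_border = (BorderMap.from_labels(LabelMap(smooth)).flags == 0).sum()
    if smooth_border == 0 or raw_border == 0:
        return 0.0
    ratio = raw_border / smooth_border
    return float(np.clip(ratio - 1.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# multiband test fixtures
# ---------------------------------------------------------------------------

def default_base_spectra(
    n: int = 5, bands: int = 64, seed: int = 2887
) -> np.ndarray:
    """Smooth synthetic reflectance-like base spectra (sums of Gaussian bumps).

    A stand-in endmember library: each spectrum is a positive, band-limited
    curve in [0.05, 1], mutually separated in spectral angle.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, bands)
    for _ in range(200):
        spectra = np.empty((n, bands))
        for i in range(n):
            s = np.full(bands, rng.uniform(0.05, 0.3))
            for _ in range(rng.integers(2, 5)):
                center = rng.uniform(0, 1)
                width = rng.uniform(0.05, 0.3)
                height = rng.uniform(0.2, 0.9)
                s = s + height * np.exp(-0.5 * ((x - center) / width) ** 2)
            spectra[i] = s
        spectra /= spectra.max()
        spectra = np.clip(spectra, 0.05, 1.0)
        angles = [
            spectral_angle(spectra[i], spectra[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        if min(angles) >= 0.08:
            return spectra
    raise RuntimeError("could not draw separated base spectra")


def make_multiband_fixture(
    mode: str,
    level: float,
    seed: int | None = 0,
    base_spectra: np.ndarray | None = None,
    height: int = 80,
    width: int = 80,
    Dmax: float = 0.3,
) -> SceneBundle:
    """A five-region multiband test scene with exact ground truth.

    mode='noise' : each pixel is its region's base spectrum plus i.i.d.
        additive Gaussian noise of standard deviation ``level`` (clipped to
        [0, 1]) — a heavily corrupted cube at the default level.
    mode='mixture' : each pixel is a convex combination of its region's base
        spectrum and the base spectra of nearby regions; ``level`` in [0, 1]
        is the maximum total foreign abundance, reached at region borders and
        decaying with distance into the region.
    """
    rng = np.random.default_rng(seed)
    if base_spectra is None:
        base_spectra = default_base_spectra()  # fixed built-in endmember library
    base_spectra = np.asarray(base_spectra, dtype=np.float64)
    n, bands = base_spectra.shape
    if bands < 2:
        raise ValueError("base spectra need at least two bands")

    geo_spec = SceneSpec(
        N=n, Dmax=Dmax, rmax=0.0, smin=0.0, smax=1.0,
        height=height, width=width, bands=bands,
        seed=int(rng.integers(0, 2**31)),
    )
    labels_arr = _region_partition(geo_spec, np.random.default_rng(geo_spec.seed))
    labels = LabelMap(labels_arr)
    clean = base_spectra[labels.labels - 1]

    if mode == "noise":
        data = np.clip(clean + level * rng.standard_normal(clean.shape), 0.0, 1.0)
    elif mode == "mixture":
        if not 0.0 <= level <= 1.0:
            raise ValueError("mixture level must lie in [0, 1]")
        data = _mix_endmembers(labels.labels, base_spectra, level, rng)
    else:
        raise ValueError("mode must be 'noise' or 'mixture'")

    bundle = SceneBundle(
        image=SpectralImage(data),
        labels=labels,
        borders=BorderMap.from_labels(labels),
        report={"mode": mode, "level": level, "n_classes": n, "bands": bands},
    )
    return bundle


def _mix_endmembers(
    labels: np.ndarray,
    base: np.ndarray,
    level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-pixel convex endmember mixing.

    Each pixel keeps abundance ``1 - a`` of its own region's base spectrum,
    with ``a ~ U(0, level)`` drawn independently per pixel, and distributes
    ``a`` over the base spectra of the regions adjacent to its own
    (Dirichlet-weighted).  Regions without neighbors stay pure.
    """
    n = base.shape[0]
    h, w = labels.shape
    adjacency: dict[int, list[int]] = {k: [] for k in range(1, n + 1)}
    for k, k2 in _adjacent_pairs(labels):
        adjacency[k].append(k2)
        adjacency[k2].append(k)

    abundance = np.zeros((h, w, n))
    a = rng.uniform(0.0, level, size=(h, w))
    for k in range(1, n + 1):
        mask = labels == k
        neigh = adjacency[k]
        if not neigh:
            abundance[mask, k - 1] = 1.0
            continue
        m = int(mask.sum())
        weights = rng.dirichlet(np.ones(len(neigh)), size=m)
        abundance[mask, k - 1] = 1.0 - a[mask]
        for j, k2 in enumerate(neigh):
            abundance[mask, k2 - 1] = a[mask] * weights[:, j]
    return np.einsum("hwk,kb->hwb", abundance, base)
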