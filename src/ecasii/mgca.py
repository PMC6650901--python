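"""The multi-gradient cellular automaton (MGCA).

Each pixel of a multiband image is a cell whose state is its spectrum.  Every
iteration, for every cell:

1. *Sense* — spectral-angle gradients are computed against the cell's
   neighborhood at window sizes 3, 5 and 7 (``extract_gradients``), giving
   three 2-D vectors that summarize how much, and in which direction, the
   local spectra change at three spatial scales.
2. *Match* — the triple of gradient vectors is compared against every rule in
   a transition-rule table.  A rule's condition is itself a triple of 2-D
   vectors defined up to rotation and reflection; the rule whose vectors can
   be rotated/reflected closest to the cell's (sum of Euclidean norms of the
   three differences) is selected (``match_rule``).
3. *Act* — the cell's spectrum is replaced by a convex combination of itself
   and the spectra of lattice pixels within one pixel of the point reached by
   stepping one pixel from the cell along the matched rotation plus the
   rule's action angle (``update_cell``).

Run for ``K`` synchronous iterations (``run_mgca``) with a well-chosen rule
table, the automaton homogenizes the spectra inside regions while leaving
region borders intact, which is exactly what a downstream pixel-wise
classifier needs.  Because every comparison is a spectral angle, the same
rule table applies to images with any number of bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpectralImage, _shift2d, spectral_angle_maps
from .masks import WINDOW_SIZES, mask_bank
from .rules import RuleSet

__all__ = [
    "GradientFeature",
    "UpdateConfig",
    "extract_gradient_fields",
    "extract_gradients",
    "match_rule",
    "match_rules_batch",
    "update_cell",
    "update_image",
    "run_mgca",
    "mean_neighbor_angle",
]

_TWO_PI = 2.0 * np.pi
_PAD = max(WINDOW_SIZES) // 2  # 3


@dataclass
class GradientFeature:
    """Gradient vectors of one cell at window sizes 3, 5, 7.

    ``gx``/``gy`` are length-3 arrays (x and y components per scale);
    moduli and angles are derived views.  The angle of a zero-modulus
    gradient is 0 by convention.
    """

    gx: np.ndarray
    gy: np.ndarray

    @property
    def moduli(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    @property
    def angles(self) -> np.ndarray:
        ang = np.mod(np.arctan2(self.gy, self.gx), _TWO_PI)
        ang[self.moduli == 0.0] = 0.0
        return ang


@dataclass
class UpdateConfig:
    """Knobs of the state update and iteration loop.

    f_th : weight cap of the distance-based contributor weighting; also the
        weight given to the cell's own spectrum (default 2.0).
    iterations : number of synchronous sweeps K (default 10).
    refine_steps : optional fine rotation grid evaluated on top of the
        closed-form candidates during rule matching (0 = off).
    """

    f_th: float = 2.0
    iterations: int = 10
    refine_steps: int = 0

    def __post_init__(self) -> None:
        if self.f_th <= 0:
            raise ValueError("f_th must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


# ---------------------------------------------------------------------------
# gradient extraction
# ---------------------------------------------------------------------------

def extract_gradient_fields(img: SpectralImage) -> tuple[np.ndarray, np.ndarray]:
    """Gradient vectors for every cell, at all three window sizes.

    Returns ``(gx, gy)`` of shape ``(H, W, 3)`` (last axis: window sizes 3,
    5, 7).  The component at scale NS is the mask-weighted sum of the
    spectral angles between the cell and each pixel of its NS x NS window;
    the cube is symmetrically reflect-padded so frame cells see a full
    window.
    """
    data = img.data
    h, w, _ = data.shape
    padded = np.pad(data, ((_PAD, _PAD), (_PAD, _PAD), (0, 0)), mode="symmetric")
    bank = mask_bank()

    # unit spectra are shared by every window offset; compute them once
    from .core import EPS_NORM

    pad_norm = np.linalg.norm(padded, axis=-1)
    pad_ok = pad_norm >= EPS_NORM
    unit = padded / np.where(pad_ok, pad_norm, 1.0)[..., None]

    gx = np.zeros((h, w, len(WINDOW_SIZES)))
    gy = np.zeros((h, w, len(WINDOW_SIZES)))
    # alpha is symmetric, so one angle map per offset pair {(dy,dx), (-dy,-dx)}
    # serves both orientations; the masks are point-antisymmetric.
    for dy in range(0, _PAD + 1):
        for dx in range(-_PAD, _PAD + 1):
            if dy == 0 and dx <= 0:
                continue
            ys = _PAD - dy
            xs = _PAD - max(dx, 0)
            hr = h + dy
            wr = w + abs(dx)
            a = unit[ys : ys + hr, xs : xs + wr]
            b = unit[ys + dy : ys + dy + hr, xs + dx : xs + dx + wr]
            diff = np.linalg.norm(a - b, axis=-1)
            summ = np.linalg.norm(a + b, axis=-1)
            alpha = (4.0 / np.pi) * np.arctan2(diff, summ)
            ok = (
                pad_ok[ys : ys + hr, xs : xs + wr]
                & pad_ok[ys + dy : ys + dy + hr, xs + dx : xs + dx + wr]
            )
            alpha[~ok] = 0.0
            ox_p = max(dx, 0)
            ox_m = max(-dx, 0)
    # neighbor maps at (+dy,+dx) and (-dy,-dx); masks are point-antisymmetric
            net = alpha[dy : dy + h, ox_p : ox_p + w] - alpha[0:h, ox_m : ox_m + w]
            for si, ns in enumerate(WINDOW_SIZES):
                r = ns // 2
                if abs(dy) > r or abs(dx) > r:
                    continue
                mx, my = bank[ns]
                cx = mx[dy + r, dx + r]
                cy = my[dy + r, dx + r]
                if cx:
                    gx[:, :, si] += cx * net
                if cy:
                    gy[:, :, si] += cy * net
    return gx, gy


def extract_gradients(img: SpectralImage, cell: tuple[int, int]) -> GradientFeature:
    """Gradient feature of a single cell ``(row, col)``."""
    y, x = cell
    data = img.data
    padded = np.pad(data, ((_PAD, _PAD), (_PAD, _PAD), (0, 0)), mode="symmetric")
    bank = mask_bank()
    gx = np.zeros(len(WINDOW_SIZES))
    gy = np.zeros(len(WINDOW_SIZES))
    center = data[y, x]
    for si, ns in enumerate(WINDOW_SIZES):
        r = ns // 2
        mx, my = bank[ns]
        window = padded[_PAD + y - r : _PAD + y + r + 1, _PAD + x - r : _PAD + x + r + 1]
        alpha = spectral_angle_maps(np.broadcast_to(center, window.shape), window)
        gx[si] = float((alpha * mx).sum())
        gy[si] = float((alpha * my).sum())
    return GradientFeature(gx=gx, gy=gy)


# ---------------------------------------------------------------------------
# rule matching
# ---------------------------------------------------------------------------

def _min_distance_pairs(
    gx: np.ndarray,
    gy: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    refine_steps: int = 0,
    irls_iters: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimize the unsquared alignment distance over rotations, pairwise.

    All inputs are ``(N, 3)``: one (cell-gradient, rule-vector) pair per row.
    The unsquared objective ``sum_n |G_n - R(psi) v_n|`` has no closed-form
    minimizer, so candidate rotations — the squared-objective optimum
    ``atan2(sum cross, sum dot)`` and the three per-scale perfect-alignment
    angles — are each polished by a few iteratively-reweighted closed-form
    steps (IRLS with weights 1/residual, whose fixed points are stationary
    points of the unsquared objective); the best polished candidate wins.
    Optionally a uniform rotation grid of ``refine_steps`` angles joins the
    candidate set.  No trigonometric calls are needed: every rotation is
    carried as a (cos, sin) pair obtained by normalization.

    Returns ``(d, cos_psi, sin_psi)`` of shape ``(N,)``.
    """
    dots = gx * vx + gy * vy          # (N, 3)
    crosses = gy * vx - gx * vy
    g2v2 = gx**2 + gy**2 + vx**2 + vy**2

    def distance(c, s):
        sq = g2v2 - 2.0 * (c[:, None] * dots + s[:, None] * crosses)
        np.maximum(sq, 0.0, out=sq)
        np.sqrt(sq, out=sq)
        return sq.sum(axis=1)

    def normalized(csum, ssum):
        norm = np.sqrt(csum**2 + ssum**2)
        zero = norm < 1e-300
        norm[zero] = 1.0
        c = csum / norm
        s = ssum / norm
        c[zero] = 1.0
        s[zero] = 0.0
        return c, s

    def polish(c, s):
        for _ in range(irls_iters):
            sq = g2v2 - 2.0 * (c[:, None] * dots + s[:, None] * crosses)
            np.maximum(sq, 0.0, out=sq)
            np.sqrt(sq, out=sq)
            w = 1.0 / np.maximum(sq, 1e-9)
            c, s = normalized((w * dots).sum(axis=1), (w * crosses).sum(axis=1))
        return c, s

    candidates = [normalized(dots.sum(axis=1), crosses.sum(axis=1))]
    candidates += [
        normalized(dots[:, n].copy(), crosses[:, n].copy()) for n in range(3)
    ]
    if refine_steps:
        for cand in np.linspace(0.0, _TWO_PI, refine_steps, endpoint=False):
            candidates.append(
                (np.full(len(g2v2), np.cos(cand)), np.full(len(g2v2), np.sin(cand)))
            )

    best_d = best_c = best_s = None
    for c0, s0 in candidates:
        c, s = polish(c0, s0)
        d = distance(c, s)
        if best_d is None:
            best_d, best_c, best_s = d, c, s
        else:
            better = d < best_d
            best_c = np.where(better, c, best_c)
            best_s = np.where(better, s, best_s)
            best_d = np.where(better, d, best_d)
    return best_d, best_c, best_s


def match_rules_batch(
    gx: np.ndarray,
    gy: np.ndarray,
    rules: RuleSet,
    refine_steps: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Match every cell's gradient triple against every rule.

    For each cell and rule the rule's three condition vectors are rotated (and
    optionally reflected about the x-axis) to minimize the sum of Euclidean
    norms of the vector differences; the rule with the smallest such distance
    wins (ties: smallest rule index, unreflected before reflected).

    Two stages keep this exact yet affordable.  A cheap pass evaluates, for
    every (cell, rule, reflection), the unsquared distance at the
    squared-objective optimal rotation — an upper bound on the true minimum.
    The modulus bound ``sum_n ||G_n| - |v_n||`` (what remains when every pair
    could be aligned perfectly) is a lower bound, so any pair whose lower
    bound exceeds the cell's best upper bound can never win and is pruned.
    Surviving pairs are re-minimized properly (see
    :func:`_min_distance_pairs`).

    Parameters
    ----------
    gx, gy : ndarray, shape (..., 3)
        Cell gradient components per window size.
    Returns
    -------
    idx, phi, reflected, dist : ndarrays of shape ``(...)``
        Selected rule index (0-based), its optimal rotation in ``[0, 2*pi)``,
        whether the reflected configuration won, and the matching distance.
    """
    vx, vy = rules.condition_vectors()  # (M, 3)
    lead = gx.shape[:-1]
    gxf = np.ascontiguousarray(gx.reshape(-1, 3))
    gyf = np.ascontiguousarray(gy.reshape(-1, 3))
    n_scales = 3

    # ---- stage 1: closed-form candidate, per-scale (P, M) contiguous ops --
    g2v2 = [
        (gxf[:, n] ** 2 + gyf[:, n] ** 2)[:, None] + (vx[:, n] ** 2 + vy[:, n] ** 2)
        for n in range(n_scales)
    ]
    axx = [gxf[:, n, None] * vx[None, :, n] for n in range(n_scales)]
    ayy = [gyf[:, n, None] * vy[None, :, n] for n in range(n_scales)]
    ayx = [gyf[:, n, None] * vx[None, :, n] for n in range(n_scales)]
    axy = [gxf[:, n, None] * vy[None, :, n] for n in range(n_scales)]

    d_refl, cos_refl, sin_refl = [], [], []
    for reflected in (False, True):
        # reflection about the x-axis only flips the sign of the vy terms
        dot_s = [axx[n] - ayy[n] if reflected else axx[n] + ayy[n] for n in range(n_scales)]
        cross_s = [ayx[n] + axy[n] if reflected else ayx[n] - axy[n] for n in range(n_scales)]
        csum = dot_s[0] + dot_s[1] + dot_s[2]
        ssum = cross_s[0] + cross_s[1] + cross_s[2]
        norm = np.sqrt(csum**2 + ssum**2)
        zero = norm == 0.0
        norm[zero] = 1.0
        cpsi = csum / norm
        spsi = ssum / norm
        cpsi[zero] = 1.0  # zero gradient against zero rule: rotation 0
        spsi[zero] = 0.0
        d = None
        for n in range(n_scales):
            sq = g2v2[n] - 2.0 * (cpsi * dot_s[n] + spsi * cross_s[n])
            np.maximum(sq, 0.0, out=sq)
            np.sqrt(sq, out=sq)
            d = sq if d is None else d + sq
        d_refl.append(d)
        cos_refl.append(cpsi)
        sin_refl.append(spsi)

    # ---- stage 2: exact pruning + proper minimization of survivors --------
    gmod = np.hypot(gxf, gyf)  # (P, 3)
    vmod = np.hypot(vx, vy)    # (M, 3)
    lower = None               # (P, M)
    for n in range(n_scales):
        term = np.abs(gmod[:, n, None] - vmod[None, :, n])
        lower = term if lower is None else lower + term
    best_ub = np.minimum(d_refl[0].min(axis=1), d_refl[1].min(axis=1))
    cells, ks = np.nonzero(lower <= best_ub[:, None] + 1e-12)
    if cells.size:
        gsel_x = gxf[cells]
        gsel_y = gyf[cells]
        for r, sgn in ((0, 1.0), (1, -1.0)):
            d, c, s = _min_distance_pairs(
                gsel_x, gsel_y, vx[ks], sgn * vy[ks], refine_steps=refine_steps
            )
            improved = d < d_refl[r][cells, ks]
            d_refl[r][cells[improved], ks[improved]] = d[improved]
            cos_refl[r][cells[improved], ks[improved]] = c[improved]
            sin_refl[r][cells[improved], ks[improved]] = s[improved]

    m = vx.shape[0]
    d_all = np.hstack(d_refl)  # (P, 2M): unreflected rules then reflected
    flat_idx = np.argmin(d_all, axis=-1)
    refl = flat_idx >= m
    idx = np.where(refl, flat_idx - m, flat_idx)
    ar = np.arange(idx.size)
    cos_sel = np.where(refl, cos_refl[1][ar, idx], cos_refl[0][ar, idx])
    sin_sel = np.where(refl, sin_refl[1][ar, idx], sin_refl[0][ar, idx])
    phi = np.mod(np.arctan2(sin_sel, cos_sel), _TWO_PI)
    return (
        idx.reshape(lead),
        phi.reshape(lead),
        refl.reshape(lead),
        d_all[ar, flat_idx].reshape(lead),
    )


def match_rule(
    feat: GradientFeature, rules: RuleSet, refine_steps: int = 0
) -> tuple[int, float, bool, float]:
    """Match a single cell's gradients; see :func:`match_rules_batch`."""
    idx, phi, refl, d = match_rules_batch(
        feat.gx[None, :], feat.gy[None, :], rules, refine_steps=refine_steps
    )
    return int(idx[0]), float(phi[0]), bool(refl[0]), float(d[0])


# ---------------------------------------------------------------------------
# state update
# ---------------------------------------------------------------------------

# lattice offsets (dy, dx) that can lie within distance 1 of a point one
# pixel away from the origin
_CANDIDATE_OFFSETS = [
    (dy, dx)
    for dy in range(-2, 3)
    for dx in range(-2, 3)
    if (dy, dx) != (0, 0) and dy * dy + dx * dx <= 4
]
_R_TOL = 1e-9


def _fr(r: np.ndarray, f_th: float) -> np.ndarray:
    """Distance weighting: min(1/r, f_th), with f_th at r = 0."""
    out = np.full(np.shape(r), f_th, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    far = r > 1.0 / f_th
    np.divide(1.0, r, out=out, where=far)
    return out


def update_image(
    data: np.ndarray, direction: np.ndarray, f_th: float = 2.0
) -> np.ndarray:
    """Synchronous state update of every cell.

    ``direction[y, x]`` is the angle (matched rotation + action angle) along
    which cell ``(y, x)`` steps one pixel to the attraction point ``P``.
    Lattice pixels within Euclidean distance 1 of ``P`` — excluding the cell
    itself and out-of-image positions — contribute with weight
    ``fr(r) = min(1/r, f_th)``; the cell itself contributes with weight
    ``f_th``; weights are normalized to sum to one.
    """
    px = np.cos(direction)
    py = np.sin(direction)
    num = np.zeros_like(data)
    denom = np.zeros(data.shape[:2])
    for dy, dx in _CANDIDATE_OFFSETS:
        r = np.hypot(dx - px, dy - py)
        active = r <= 1.0 + _R_TOL
        if not active.any():
            continue
        shifted, valid = _shift2d(data, dy, dx)
        wmap = np.where(active & valid, _fr(r, f_th), 0.0)
        num += wmap[..., None] * shifted
        denom += wmap
    denom += f_th
    return (num + f_th * data) / denom[..., None]


def update_cell(
    img: SpectralImage,
    cell: tuple[int, int],
    phi: float,
    theta: float,
    cfg: UpdateConfig | None = None,
) -> np.ndarray:
    """Updated spectrum of a single cell; reference (loop) implementation."""
    cfg = cfg or UpdateConfig()
    y, x = cell
    h, w, _ = img.shape
    px, py = np.cos(phi + theta), np.sin(phi + theta)
    weights, spectra = [], []
    for dy, dx in _CANDIDATE_OFFSETS:
        r = float(np.hypot(dx - px, dy - py))
        if r > 1.0 + _R_TOL:
            continue
        yy, xx = y + dy, x + dx
        if not (0 <= yy < h and 0 <= xx < w):
            continue
        weights.append(float(_fr(r, cfg.f_th)))
        spectra.append(img.data[yy, xx])
    total = sum(weights) + cfg.f_th
    out = (cfg.f_th / total) * img.data[y, x].copy()
    for wgt, spec in zip(weights, spectra):
        out = out + (wgt / total) * spec
    return out


# ---------------------------------------------------------------------------
# iteration loop
# ---------------------------------------------------------------------------

def run_mgca(
    img: SpectralImage,
    rules: RuleSet,
    cfg: UpdateConfig | None = None,
    callback=None,
) -> SpectralImage:
    """Run the automaton for ``cfg.iterations`` synchronous sweeps.

    All new states of a sweep are computed from the previous sweep's image
    before any is committed (double buffering), so the result does not depend
    on cell visiting order.  When a rule matches best in its reflected
    configuration, its action angle is mirrored along with its condition
    (``theta -> -theta``) so the automaton is equivariant under image
    reflection.

    ``callback(iteration, image)`` — if given — is invoked after each sweep.
    """
    cfg = cfg or UpdateConfig()
    data = img.data.copy()
    for it in range(cfg.iterations):
        current = SpectralImage(data)
        gx, gy = extract_gradient_fields(current)
        idx, phi, refl, _ = match_rules_batch(gx, gy, rules, cfg.refine_steps)
        theta = rules.table[idx, 5]
        direction = phi + np.where(refl, -theta, theta)
        data = update_image(data, direction, cfg.f_th)
        np.clip(data, 0.0, 1.0, out=data)
        if callback is not None:
            callback(it + 1, SpectralImage(data))
    return SpectralImage(data)


def mean_neighbor_angle(img: SpectralImage, mask: np.ndarray | None = None) -> float:
    """Mean over pixels of the mean spectral angle to in-image 8-neighbors.

    A cheap homogeneity diagnostic: it decreases as the automaton smooths
    regions.  ``mask`` optionally restricts the averaged pixels.
    """
    from .core import NEIGHBOR_OFFSETS_8

    data = img.data
    total = np.zeros(data.shape[:2])
    count = np.zeros(data.shape[:2])
    for dy, dx in NEIGHBOR_OFFSETS_8:
        shifted, valid = _shift2d(data, dy, dx)
        ang = spectral_angle_maps(data, shifted)
        total += np.where(valid, ang, 0.0)
        count += valid
    per_pixel = total / count
    if mask is not None:
        per_pixel = per_pixel[mask]
    return float(per_pixel.mean())
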