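"""Multi-scale gradient masks.

For window size ``NS`` in {3, 5, 7} the horizontal mask ``MX`` has, at offset
``(dx, dy)`` from the window center, the coefficient

    sign(dx) / (dx**2 + dy**2)        (0 on the central column)

scaled so positive entries sum to (almost exactly) one: scale factors 1/2 for
NS=3, 10/33 for NS=5 and 361/1527 for NS=7.  ``MY`` is the transpose of
``MX``.  The NS=7 factor is the conventionally printed value; the exact
positive-sum normalizer would be 1170/4949, which differs only in the seventh
decimal (the discrepancy is asserted in the test suite).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["WINDOW_SIZES", "gradient_mask", "mask_bank"]

WINDOW_SIZES = (3, 5, 7)

_SCALES = {3: 0.5, 5: 10.0 / 33.0, 7: 361.0 / 1527.0}


def gradient_mask(ns: int, axis: str = "x") -> np.ndarray:
    """Return the ``ns x ns`` gradient mask for ``axis`` ('x' or 'y').

    Row index corresponds to dy (downward), column index to dx (rightward).
    """
    if ns not in _SCALES:
        raise ValueError(f"window size must be one of {WINDOW_SIZES}, got {ns}")
    r = ns // 2
    dx = np.arange(-r, r + 1)[None, :]
    dy = np.arange(-r, r + 1)[:, None]
    r2 = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = np.where(dx == 0, 0.0, np.sign(dx) / np.where(r2 == 0, 1, r2))
    mx = _SCALES[ns] * mx
    if axis == "x":
        return mx
    if axis == "y":
        return mx.T
    raise ValueError("axis must be 'x' or 'y'")


@lru_cache(maxsize=None)
def mask_bank() -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """All six masks, keyed by window size, as ``(MX, MY)`` pairs."""
    return {ns: (gradient_mask(ns, "x"), gradient_mask(ns, "y")) for ns in WINDOW_SIZES}
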