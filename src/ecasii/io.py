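"""File formats: ENVI cubes, portable ``.npz`` cubes, PNG/CSV label maps.

ENVI support covers the plain header (``.hdr``) + flat-binary pair with BSQ,
BIL or BIP interleaves and the common integer/float data types — enough to
interchange cubes with the usual hyperspectral tooling.  The ``.npz``
container is the round-trip-exact workhorse for tests and pipelines.

Label maps round-trip through paletted PNG (class ids as palette indices) or
integer CSV.  Rule-set JSON lives with :class:`~ecasii.rules.RuleSet`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .core import LabelMap, SpectralImage

__all__ = [
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "FormatError",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ENVI data type codes <-> numpy dtypes
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


# ---------------------------------------------------------------------------
# cubes
# ---------------------------------------------------------------------------

def write_cube(img: SpectralImage, path: str | Path) -> None:
    """Write a cube; format chosen by suffix (.npz, or .hdr for ENVI)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, data=img.data)
    elif path.suffix == ".hdr":
        _write_envi(img, path)
    else:
        raise FormatError(f"unsupported cube format: {path.suffix!r}")


def read_cube(path: str | Path) -> SpectralImage:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            if "data" not in f:
                raise FormatError(f"{path}: missing 'data' array")
            return SpectralImage(f["data"])
    if path.suffix == ".hdr":
        return _read_envi(path)
    raise FormatError(f"unsupported cube format: {path.suffix!r}")


def _write_envi(img: SpectralImage, hdr_path: Path) -> None:
    raw_path = hdr_path.with_suffix(".raw")
    data = img.data.astype(np.float64)
    h, w, b = data.shape
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float64)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
    )
    hdr_path.write_text(hdr)
    # BSQ: band-sequential -> (bands, lines, samples)
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(raw_path)


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError(f"{hdr_path}: missing ENVI magic line")
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _read_envi(hdr_path: Path) -> SpectralImage:
    fields = _parse_envi_header(hdr_path)
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise FormatError(f"{hdr_path}: header is missing field '{required}'")
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        code = int(fields["data type"])
    except ValueError as exc:
        raise FormatError(f"{hdr_path}: non-integer dimension field ({exc})") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError(f"{hdr_path}: only little-endian (byte order 0) supported")
    interleave = fields["interleave"].lower()
    offset = int(fields.get("header offset", "0"))

    raw_path = None
    for cand in (hdr_path.with_suffix(".raw"), hdr_path.with_suffix(""),
                 hdr_path.with_suffix(".img"), hdr_path.with_suffix(".dat")):
        if cand.exists() and cand != hdr_path:
            raw_path = cand
            break
    if raw_path is None:
        raise FormatError(f"{hdr_path}: no companion binary file found")

    flat = np.fromfile(raw_path, dtype=_ENVI_DTYPES[code], offset=offset)
    if flat.size != h * w * b:
        raise FormatError(
            f"{raw_path}: expected {h * w * b} samples "
            f"(lines x samples x bands), found {flat.size}"
        )
    if interleave == "bsq":
        data = flat.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(h, w, b)
    else:
        raise FormatError(f"{hdr_path}: unknown interleave '{interleave}'")
    return SpectralImage(np.asarray(data, dtype=np.float64))


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

def write_labels(labels: LabelMap, path: str | Path) -> None:
    """Write labels as paletted PNG (.png) or integer CSV (.csv)."""
    path = Path(path)
    grid = labels.labels
    if path.suffix == ".png":
        if grid.max() > 255:
            raise FormatError("paletted PNG supports at most 256 classes")
        img = Image.fromarray(grid.astype(np.uint8), mode="P")
        img.putpalette(_class_palette())
        img.save(path)
    elif path.suffix == ".csv":
        np.savetxt(path, grid, fmt="%d", delimiter=",")
    else:
        raise FormatError(f"unsupported label format: {path.suffix!r}")


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    if path.suffix == ".png":
        img = Image.open(path)
        if img.mode != "P":
            img = img.convert("P")
        return LabelMap(np.asarray(img, dtype=np.int32))
    if path.suffix == ".csv":
        try:
            grid = np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: not an integer CSV grid ({exc})") from exc
        return LabelMap(grid)
    raise FormatError(f"unsupported label format: {path.suffix!r}")


def _class_palette(n: int = 256) -> list[int]:
    """A fixed, high-contrast 256-color palette (golden-angle hues)."""
    import colorsys

    palette = [0, 0, 0]
    for i in range(1, n):
        hue = (i * 0.61803398875) % 1.0
        r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 0.95)
        palette += [int(255 * r), int(255 * g), int(255 * b)]
    return palette
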