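"""Hyperspectral cube container and ENVI-style I/O.

Cubes are stored in memory as ``(rows, cols, bands)`` arrays and on disk as an
ASCII ENVI header (``.hdr``) next to a raw band-sequential (BSQ) binary
(``.img``).  Only the small subset of the ENVI header dialect needed for these
scenes is implemented: ``samples``, ``lines``, ``bands``, ``data type``,
``interleave``, ``byte order`` and the ``wavelength`` block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpectralCube", "write_envi", "read_envi"]

# ENVI "data type" codes for the dtypes we emit.
_DTYPE_TO_ENVI = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_ENVI_TO_DTYPE = {4: np.dtype("float32"), 5: np.dtype("float64")}


@dataclass
class SpectralCube:
    """Recorded intensity ``I(y, x, lambda)`` with its wavelength grid.

    Parameters
    ----------
    data
        Array of shape ``(rows, cols, bands)``; rows follow the scan
        direction, cols are the spatial slit pixels.
    wavelengths
        Strictly increasing wavelength grid in nm, length ``bands``.
    saturation_level
        Digital number at which the sensor saturates, if known.  ``None``
        disables saturation handling downstream.
    cube_id
        Free-form provenance identifier.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    saturation_level: float | None = None
    cube_id: str = "cube"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def saturated_mask(self, threshold_fraction: float = 0.98) -> np.ndarray:
        """Boolean ``(rows, cols)`` map of pixels saturated in any band."""
        if self.saturation_level is None:
            return np.zeros(self.data.shape[:2], dtype=bool)
        level = threshold_fraction * self.saturation_level
        return np.any(self.data >= level, axis=2)


def write_envi(path_base: str | Path, cube: SpectralCube) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` + ``<base>.img`` (BSQ, little-endian)."""
    base = Path(path_base)
    hdr_path = base.with_suffix(".hdr")
    img_path = base.with_suffix(".img")
    data = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0))  # BSQ: band-major
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_TO_ENVI:
        data = data.astype(np.float32)
        dtype = np.dtype("float32")
    rows, cols, bands = cube.shape
    wl = ",\n".join(f" {w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"description = {{{cube.cube_id}}}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        "wavelength = {",
        wl,
        "}",
    ]
    if cube.saturation_level is not None:
        lines.append(f"data saturation value = {cube.saturation_level!r}")
    hdr_path.write_text("\n".join(lines) + "\n")
    data.astype(dtype).tofile(img_path)
    return hdr_path, img_path


def _parse_header(text: str) -> dict:
    # Collapse brace-delimited blocks onto one line first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path_base: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_envi`."""
    base = Path(path_base)
    hdr_path = base if base.suffix == ".hdr" else base.with_suffix(".hdr")
    img_path = hdr_path.with_suffix(".img")
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_TO_DTYPE[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave: {interleave}")
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("binary size does not match header dimensions")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    wl_block = fields.get("wavelength", "")
    wavelengths = np.array(
        [float(tok) for tok in re.findall(r"[-+0-9.eE]+", wl_block)], dtype=float
    )
    if wavelengths.size != bands:
        raise ValueError("wavelength block does not match band count")
    saturation = fields.get("data saturation value")
    desc = fields.get("description", "").strip("{} ")
    return SpectralCube(
        data=data,
        wavelengths=wavelengths,
        saturation_level=float(saturation) if saturation else None,
        cube_id=desc or "cube",
    )
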