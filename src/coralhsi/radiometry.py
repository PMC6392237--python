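"""Reflectance calibration from Spectralon and inclined-PVC references.

The conversion chain:

1. ``fit_spectralon``      A_spec(x, lam) = <I_spec(x, lam)> / R_spec(lam)
2. ``derive_pvc_reflectance``  R_PVC(lam) = mean_x I_PVC(x, z=panel, lam) / A_spec(x, lam)
3. ``build_height_calibration``  A(x, z, lam) = I_PVC(x, z, lam) / R_PVC(lam)
4. ``to_reflectance``      R(x, y, lam) = I(x, y, lam) / A(x, z=sample, lam)

Panel statistics average over the masked frames along the scan direction (the
mean over both mask axes per spatial column).  The conversion factor is
interpolated linearly in object height z between the heights sampled by the
inclined plate.  Saturated pixels are masked, never clipped; negative
reflectance from noise at dark wavelengths is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from coralhsi.cube import SpectralCube

__all__ = [
    "PanelCalibration",
    "HeightCalibration",
    "ReflectanceCube",
    "fit_spectralon",
    "derive_pvc_reflectance",
    "build_height_calibration",
    "to_reflectance",
    "save_calibration",
    "load_calibration",
]

SATURATION_THRESHOLD_FRACTION = 0.98


@dataclass
class PanelCalibration:
    """Per-column conversion factor from the flat Spectralon panel."""

    r_spec: np.ndarray  # (bands,) calibrated Spectralon reflectance
    a_spec: np.ndarray  # (cols, bands); NaN where the panel covers no frames
    n_spec: int  # number of panel pixels used
    panel_height_cm: float
    wavelengths: np.ndarray
    n_saturated_excluded: int = 0

    @property
    def covered_columns(self) -> np.ndarray:
        return ~np.isnan(self.a_spec[:, 0])


@dataclass
class HeightCalibration:
    """Conversion factor A(x, z, lam) on a height grid, linear in z between nodes."""

    a: np.ndarray  # (n_heights, cols, bands)
    height_grid_cm: np.ndarray  # increasing
    r_pvc: np.ndarray  # (bands,)
    wavelengths: np.ndarray
    provenance: dict = field(default_factory=dict)

    def at_height(self, z_cm: float) -> np.ndarray:
        """A(x, lam) at height ``z_cm``; exact at grid nodes, linear between."""
        z = float(z_cm)
        grid = self.height_grid_cm
        if z < grid[0] or z > grid[-1]:
            raise ValueError(
                f"height {z} cm outside calibrated range "
                f"[{grid[0]:.3f}, {grid[-1]:.3f}] cm"
            )
        i = int(np.searchsorted(grid, z))
        if i < grid.size and grid[i] == z:
            return self.a[i]
        lo, hi = i - 1, i
        t = (z - grid[lo]) / (grid[hi] - grid[lo])
        return (1.0 - t) * self.a[lo] + t * self.a[hi]


@dataclass
class ReflectanceCube:
    """Calibrated reflectance R(x, y, lam) at a stated object height."""

    data: np.ndarray  # (rows, cols, bands)
    wavelengths: np.ndarray
    invalid_mask: np.ndarray  # (rows, cols) True = saturated/invalid
    sample_height_cm: float
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.size != b.size or not np.allclose(a, b, rtol=0, atol=1e-9):
        raise ValueError(f"wavelength grid mismatch between cube and {what}")


def fit_spectralon(
    cube: SpectralCube,
    spectralon_mask: np.ndarray,
    r_spec: np.ndarray | float,
    panel_height_cm: float = 3.0,
    saturation_threshold: float = SATURATION_THRESHOLD_FRACTION,
) -> PanelCalibration:
    """Build A_spec(x, lam) by averaging masked panel frames per spatial column."""
    mask = np.asarray(spectralon_mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    r_spec = np.broadcast_to(
        np.asarray(r_spec, dtype=float), (cube.wavelengths.size,)
    ).copy()
    if np.any(r_spec <= 0):
        raise ValueError("R_spec must be strictly positive")
    saturated = cube.saturated_mask(saturation_threshold)
    n_saturated = int(np.count_nonzero(mask & saturated))
    mask = mask & ~saturated
    if not mask.any():
        raise ValueError("no usable Spectralon pixels (empty or all saturated)")

    cols, bands = cube.data.shape[1], cube.data.shape[2]
    ys, xs = np.nonzero(mask)
    counts = np.bincount(xs, minlength=cols)
    sums = np.zeros((cols, bands))
    np.add.at(sums, xs, cube.data[ys, xs, :].astype(float))
    a_spec = np.full((cols, bands), np.nan)
    covered = counts > 0
    a_spec[covered] = sums[covered] / counts[covered, None] / r_spec[None, :]
    return PanelCalibration(
        r_spec=r_spec,
        a_spec=a_spec,
        n_spec=int(mask.sum()),
        panel_height_cm=panel_height_cm,
        wavelengths=cube.wavelengths.copy(),
        n_saturated_excluded=n_saturated,
    )


def derive_pvc_reflectance(
    cube: SpectralCube,
    pvc_mask_at_panel_height: np.ndarray,
    panel_cal: PanelCalibration,
    saturation_threshold: float = SATURATION_THRESHOLD_FRACTION,
) -> np.ndarray:
    """Single pooled PVC reflectance spectrum from pixels at the panel's height."""
    _check_grid(cube.wavelengths, panel_cal.wavelengths, "panel calibration")
    mask = np.asarray(pvc_mask_at_panel_height, dtype=bool)
    mask = mask & ~cube.saturated_mask(saturation_threshold)
    mask = mask & panel_cal.covered_columns[None, :]
    if not mask.any():
        raise ValueError("empty PVC mask at panel height")
    ys, xs = np.nonzero(mask)
    ratios = cube.data[ys, xs, :].astype(float) / panel_cal.a_spec[xs, :]
    return ratios.mean(axis=0)


def build_height_calibration(
    cube: SpectralCube,
    pvc_mask: np.ndarray,
    height_map_cm: np.ndarray,
    r_pvc: np.ndarray,
    saturation_threshold: float = SATURATION_THRESHOLD_FRACTION,
    height_decimals: int = 4,
) -> HeightCalibration:
    """A(x, z, lam) from the inclined plate; one node per distinct pixel height."""
    r_pvc = np.asarray(r_pvc, dtype=float)
    if np.any(r_pvc <= 0):
        raise ValueError("R_PVC must be strictly positive")
    if r_pvc.size != cube.wavelengths.size:
        raise ValueError("R_PVC length does not match cube bands")
    mask = np.asarray(pvc_mask, dtype=bool) & ~cube.saturated_mask(saturation_threshold)
    if not mask.any():
        raise ValueError("empty inclined-PVC mask")
    heights = np.round(np.asarray(height_map_cm, dtype=float), height_decimals)
    z_grid = np.unique(heights[mask])
    cols, bands = cube.data.shape[1], cube.data.shape[2]
    a = np.full((z_grid.size, cols, bands), np.nan)
    for zi, z in enumerate(z_grid):
        level = mask & (heights == z)
        ys, xs = np.nonzero(level)
        counts = np.bincount(xs, minlength=cols)
        sums = np.zeros((cols, bands))
        np.add.at(sums, xs, cube.data[ys, xs, :].astype(float))
        covered = counts > 0
        a[zi, covered] = sums[covered] / counts[covered, None] / r_pvc[None, :]
    if np.isnan(a).any():
        # Columns the plate never covered at some height cannot be calibrated.
        bad = np.unique(np.nonzero(np.isnan(a))[1])
        raise ValueError(f"inclined plate does not cover columns {bad.tolist()}")
    return HeightCalibration(
        a=a,
        height_grid_cm=z_grid,
        r_pvc=r_pvc,
        wavelengths=cube.wavelengths.copy(),
        provenance={"source_cube": cube.cube_id},
    )


def to_reflectance(
    cube: SpectralCube,
    height_cal: HeightCalibration,
    sample_height_cm: float = 7.0,
    saturation_threshold: float = SATURATION_THRESHOLD_FRACTION,
) -> ReflectanceCube:
    """Per-pixel division by A(x, z=sample height, lam); saturated pixels masked."""
    _check_grid(cube.wavelengths, height_cal.wavelengths, "height calibration")
    a = height_cal.at_height(sample_height_cm)  # (cols, bands)
    data = cube.data.astype(float) / a[None, :, :]
    invalid = cube.saturated_mask(saturation_threshold)
    return ReflectanceCube(
        data=data,
        wavelengths=cube.wavelengths.copy(),
        invalid_mask=invalid,
        sample_height_cm=sample_height_cm,
        provenance={
            "source_cube": cube.cube_id,
            **height_cal.provenance,
            "sample_height_cm": sample_height_cm,
        },
    )


def save_calibration(
    path: str | Path,
    panel_cal: PanelCalibration,
    height_cal: HeightCalibration,
) -> None:
    """Serialize both calibration stages into one HDF5 container."""
    with h5py.File(path, "w") as f:
        g = f.create_group("panel")
        g.create_dataset("r_spec", data=panel_cal.r_spec)
        g.create_dataset("a_spec", data=panel_cal.a_spec)
        g.attrs["n_spec"] = panel_cal.n_spec
        g.attrs["panel_height_cm"] = panel_cal.panel_height_cm
        g.attrs["n_saturated_excluded"] = panel_cal.n_saturated_excluded
        h = f.create_group("height")
        h.create_dataset("a", data=height_cal.a)
        h.create_dataset("height_grid_cm", data=height_cal.height_grid_cm)
        h.create_dataset("r_pvc", data=height_cal.r_pvc)
        for k, v in height_cal.provenance.items():
            h.attrs[k] = v
        f.create_dataset("wavelengths", data=height_cal.wavelengths)


def load_calibration(path: str | Path) -> tuple[PanelCalibration, HeightCalibration]:
    with h5py.File(path, "r") as f:
        wavelengths = f["wavelengths"][()]
        g = f["panel"]
        panel = PanelCalibration(
            r_spec=g["r_spec"][()],
            a_spec=g["a_spec"][()],
            n_spec=int(g.attrs["n_spec"]),
            panel_height_cm=float(g.attrs["panel_height_cm"]),
            wavelengths=wavelengths,
            n_saturated_excluded=int(g.attrs["n_saturated_excluded"]),
        )
        h = f["height"]
        height = HeightCalibration(
            a=h["a"][()],
            height_grid_cm=h["height_grid_cm"][()],
            r_pvc=h["r_pvc"][()],
            wavelengths=wavelengths,
            provenance={k: v for k, v in h.attrs.items()},
        )
    return panel, height
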