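"""Synthetic tank scenes and exposure-experiment tables.

Everything downstream (calibration, extraction, dose-response, classification)
is exercised against scenes produced here, since no raw images were deposited
with the study this mirrors.  The generator provides:

* ``generate_endmembers`` -- smooth reflectance spectra per color morph and
  exposure category, with configurable within-class variation;
* ``simulate_experiment`` -- beaker chemistry time series and polyp
  alive/dead counts driven by a known sigmoidal dose-response;
* ``render_scene`` -- a forward optical model producing a recorded-intensity
  cube with a flat Spectralon panel, an inclined PVC reference plate, coral
  sample blobs at a common height, and background:

      I(x, y, lam) = R_true(x, y, lam) * E(lam)
                     * exp(-a(lam) * 2 * (H - z)) * g(x) * (1 + eps)

  where ``H`` is the camera altitude, ``z`` the object height (downwelling +
  upwelling path, doubled), ``g(x)`` a smooth across-slit illumination
  profile and ``eps`` multiplicative sensor noise.

All generators are pure functions of their seeds; no global random state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from coralhsi.cube import SpectralCube
from coralhsi.dose_response import (
    CategoryRule,
    assign_category,
    curve_params_from_lcs,
    predict_mortality,
)

__all__ = [
    "SceneSpec",
    "ExperimentDesign",
    "GroundTruth",
    "EndmemberConfig",
    "generate_endmembers",
    "simulate_experiment",
    "render_scene",
    "masks_from_ground_truth",
    "save_scenario",
    "load_scenario",
    "default_attenuation",
    "zero_attenuation",
    "default_illumination",
    "flat_illumination",
]

MORPHS = ("white", "orange")
CATEGORIES = ("low", "medium", "high")
_SEVERITY = {"low": 0, "medium": 1, "high": 2}

# Region codes in GroundTruth.region_map
BACKGROUND, SPECTRALON, PVC, CORAL = 0, 1, 2, 3

# The instrument sampled ~0.5 nm over 381-846 nm; a step of 465/822 nm makes
# the closed-interval 400-750 nm crop contain exactly 619 grid points.
DEFAULT_WAVELENGTH_STEP_NM = 465.0 / 822.0


def default_attenuation(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Clear-seawater-like attenuation [1/m]: minimum near 480 nm, steep red rise."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 0.05 + 0.0025 * ((lam - 480.0) / 100.0) ** 2 + 2.2 * expit((lam - 720.0) / 18.0)


def zero_attenuation(wavelengths_nm: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.asarray(wavelengths_nm, dtype=float))


def default_illumination(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Halogen-like spectrum, brighter toward the red."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 0.4 + 0.6 * expit((lam - 550.0) / 80.0)


def flat_illumination(wavelengths_nm: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(wavelengths_nm, dtype=float))


_CURVES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "default_attenuation": default_attenuation,
    "zero_attenuation": zero_attenuation,
    "default_illumination": default_illumination,
    "flat_illumination": flat_illumination,
}


@dataclass
class EndmemberConfig:
    """Controls class templates and within-class spectral variation."""

    effect_scale: float = 1.0  # multiplies exposure-linked feature amplitudes
    within_sd: float = 0.015  # sd of smooth within-class perturbation
    smooth_sigma_nm: float = 12.0  # correlation length of the perturbation


@dataclass
class SceneSpec:
    """Geometry, optics and sensor settings of a rendered tank scene."""

    wavelength_start_nm: float = 381.0
    wavelength_end_nm: float = 846.0
    wavelength_step_nm: float = DEFAULT_WAVELENGTH_STEP_NM
    image_shape: tuple[int, int] | None = None  # (rows, cols); None = auto-size
    camera_altitude_m: float = 0.35
    sample_height_cm: float = 7.0
    panel_height_cm: float = 3.0
    pvc_max_height_cm: float = 10.0
    spectralon_reflectance: float = 0.99
    pvc_reflectance: float = 0.50
    background_reflectance: float = 0.08
    attenuation_curve: Callable[[np.ndarray], np.ndarray] = default_attenuation
    illumination_spectrum: Callable[[np.ndarray], np.ndarray] = default_illumination
    geometry_falloff: float = 0.15  # quadratic across-slit brightness drop; 0 = flat
    noise_sd_relative: float = 0.01
    blob_side_range: tuple[int, int] = (18, 21)  # coral blob side lengths, px
    brightness_jitter_sd: float = 0.04  # per-pixel multiplicative reflectance jitter
    pixel_perturbation_sd: float = 0.012  # per-pixel smooth additive perturbation
    sample_perturbation_sd: float = 0.008  # per-sample smooth additive perturbation
    endmember_config: EndmemberConfig = field(default_factory=EndmemberConfig)
    saturation_level: float | None = None
    dtype: str = "float32"  # use float64 for exact noiseless round-trip checks
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength_step_nm <= 0:
            raise ValueError("wavelength step must be positive")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength range must be increasing")
        for name in ("sample_height_cm", "panel_height_cm", "pvc_max_height_cm"):
            if getattr(self, name) / 100.0 >= self.camera_altitude_m:
                raise ValueError(f"{name} must be below the camera altitude")
        if self.noise_sd_relative < 0:
            raise ValueError("noise sd must be non-negative")
        wl = self.wavelength_grid()
        if np.any(self.attenuation_curve(wl) < 0):
            raise ValueError("attenuation must be non-negative on the grid")
        if np.any(self.illumination_spectrum(wl) <= 0):
            raise ValueError("illumination must be positive on the grid")

    def wavelength_grid(self) -> np.ndarray:
        n = int(
            round(
                (self.wavelength_end_nm - self.wavelength_start_nm)
                / self.wavelength_step_nm
            )
        ) + 1
        return np.linspace(
            self.wavelength_start_nm,
            self.wavelength_start_nm + (n - 1) * self.wavelength_step_nm,
            n,
        )


@dataclass
class ExperimentDesign:
    """Treatment layout: groups x replicates x samples, doses and mortality."""

    n_groups: int = 5
    n_replicates: int = 4
    samples_per_beaker: int = 3  # first sample orange, remainder white
    polyps_min: int = 3
    polyps_max: int = 9
    nominal_concentrations: tuple[float, ...] = (0.0, 1.0, 2.3, 5.0, 8.0)
    realized_fraction_mean: float = 0.35
    realized_fraction_sd: float = 0.06
    concentration_noise_sd: float = 0.12  # relative, per time point & duplicate
    mortality_params: tuple[float, float] = field(
        default_factory=lambda: curve_params_from_lcs(1.25, 2.30)
    )
    realized_fraction_overrides: dict[tuple[str, str], float] = field(
        default_factory=dict
    )  # e.g. {("C3", "R2"): 0.02} reproduces a faulty pump channel
    category_rule: CategoryRule = field(default_factory=CategoryRule)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_replicates < 1 or self.samples_per_beaker < 1:
            raise ValueError("group/replicate/sample counts must be positive")
        if len(self.nominal_concentrations) != self.n_groups:
            raise ValueError("need one nominal concentration per group")
        if any(c < 0 for c in self.nominal_concentrations):
            raise ValueError("nominal concentrations must be non-negative")
        if not 1 <= self.polyps_min <= self.polyps_max:
            raise ValueError("polyp count range invalid")

    @property
    def groups(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_groups)]

    @property
    def replicates(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replicates)]

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_replicates * self.samples_per_beaker

    def sample_morph(self, index_in_beaker: int) -> str:
        # One orange and (samples_per_beaker - 1) white morphs per beaker.
        return "orange" if index_in_beaker == 0 else "white"


@dataclass
class GroundTruth:
    """Oracle for calibration and classification tests."""

    r_true: np.ndarray  # (rows, cols, bands) true reflectance
    region_map: np.ndarray  # (rows, cols) int codes BACKGROUND/SPECTRALON/PVC/CORAL
    sample_map: np.ndarray  # (rows, cols) sample index, -1 outside corals
    height_map: np.ndarray  # (rows, cols) object height in cm
    samples: pd.DataFrame  # per-sample registry incl. morph/conc/mortality/category
    chemistry: pd.DataFrame
    wavelengths: np.ndarray

    def write_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.chemistry.to_csv(out / "chemistry.csv", index=False)
        np.savetxt(out / "sample_map.csv", self.sample_map, fmt="%d", delimiter=",")
        np.savetxt(out / "region_map.csv", self.region_map, fmt="%d", delimiter=",")
        np.savetxt(out / "height_map.csv", self.height_map, fmt="%.4f", delimiter=",")


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def _smooth_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, sigma_bands: float
) -> np.ndarray:
    """Smooth (GP-like) zero-mean perturbation with per-band sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = gaussian_filter1d(raw, sigma=sigma_bands, axis=-1, mode="nearest")
    # Renormalize so the per-band sd survives the smoothing.
    scale = sd / max(np.std(sm), 1e-12)
    return sm * scale


def _base_spectrum(morph: str, lam: np.ndarray) -> np.ndarray:
    if morph == "white":
        return 0.50 + 0.18 * expit((lam - 450.0) / 60.0)
    if morph == "orange":
        # Carotenoid-like absorption in the blue-green, bright in the red.
        return 0.22 + 0.55 * expit((lam - 585.0) / 22.0) + 0.05 * _gauss(lam, 440, 30)
    raise ValueError(f"unknown morph: {morph!r}")


def _category_effect(category: str, lam: np.ndarray, scale: float) -> np.ndarray:
    """Exposure-linked spectral features; magnitude monotone in severity."""
    if category not in _SEVERITY:
        raise ValueError(f"unknown exposure category: {category!r}")
    s = _SEVERITY[category]
    if s == 0 or scale == 0:
        return np.zeros_like(lam)
    # Amplitude grows with severity and the 520 nm feature drifts redward,
    # emulating tissue pigment loss (amplitude + band-position changes).
    return scale * s * (
        0.05 * _gauss(lam, 520.0 + 4.0 * s, 18.0)
        - 0.04 * _gauss(lam, 605.0, 15.0)
        + 0.03 * _gauss(lam, 470.0, 25.0)
    )


def class_template(
    morph: str, category: str, wavelengths: np.ndarray, effect_scale: float = 1.0
) -> np.ndarray:
    """Noise-free class mean spectrum (the generating endmember)."""
    lam = np.asarray(wavelengths, dtype=float)
    return np.clip(_base_spectrum(morph, lam) + _category_effect(category, lam, effect_scale), 0.01, 1.0)


def generate_endmembers(
    morph: str,
    exposure_category: str,
    rng: np.random.Generator | int,
    wavelengths: np.ndarray | None = None,
    config: EndmemberConfig | None = None,
) -> np.ndarray:
    """One realization of a class spectrum: template + within-class variation."""
    if morph not in MORPHS:
        raise ValueError(f"unknown morph: {morph!r}")
    if exposure_category not in CATEGORIES:
        raise ValueError(f"unknown exposure category: {exposure_category!r}")
    cfg = config or EndmemberConfig()
    if wavelengths is None:
        wavelengths = SceneSpec().wavelength_grid()
    lam = np.asarray(wavelengths, dtype=float)
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    step = float(np.median(np.diff(lam))) if lam.size > 1 else 1.0
    sigma_bands = max(cfg.smooth_sigma_nm / step, 1e-6)
    spectrum = class_template(morph, exposure_category, lam, cfg.effect_scale)
    spectrum = spectrum + _smooth_noise(rng, lam.shape, cfg.within_sd, sigma_bands)
    return np.clip(spectrum, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

TIME_POINTS_H = (0, 24, 48, 72)
DUPLICATES = ("I", "II")


def simulate_experiment(
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate beaker chemistry and polyp mortality tables.

    Returns
    -------
    chemistry : DataFrame
        Columns group, replicate, beaker, time_h, phase, duplicate,
        concentration (mg/L), measured at 0/24/48/72 h in duplicate.
    polyps : DataFrame
        One row per coral sample: sample_id, group, replicate, beaker,
        morph, alive_before, dead_after, mortality, beaker_mean_concentration,
        category.
    """
    rng = np.random.default_rng(design.rng_seed)
    beta0, beta1 = design.mortality_params

    chem_rows = []
    beaker_means: dict[str, float] = {}
    for gi, group in enumerate(design.groups):
        nominal = design.nominal_concentrations[gi]
        for rep in design.replicates:
            frac = rng.normal(design.realized_fraction_mean, design.realized_fraction_sd)
            frac = max(float(frac), 0.0)
            frac = design.realized_fraction_overrides.get((group, rep), frac)
            beaker = f"{group}-{rep}"
            vals = []
            for t in TIME_POINTS_H:
                for dup in DUPLICATES:
                    noise = rng.normal(0.0, design.concentration_noise_sd)
                    conc = max(frac * nominal * (1.0 + noise), 0.0)
                    chem_rows.append(
                        {
                            "group": group,
                            "replicate": rep,
                            "beaker": beaker,
                            "time_h": t,
                            "phase": "beaker",
                            "duplicate": dup,
                            "concentration": conc,
                        }
                    )
                    vals.append(conc)
            beaker_means[beaker] = float(np.mean(vals))
    chemistry = pd.DataFrame(chem_rows)

    polyp_rows = []
    idx = 0
    for group in design.groups:
        for rep in design.replicates:
            beaker = f"{group}-{rep}"
            conc = beaker_means[beaker]
            p = float(predict_mortality(beta0, beta1, conc))
            for j in range(design.samples_per_beaker):
                alive = int(rng.integers(design.polyps_min, design.polyps_max + 1))
                dead = int(rng.binomial(alive, p))
                polyp_rows.append(
                    {
                        "sample_index": idx,
                        "sample_id": f"{beaker}-S{j + 1}",
                        "group": group,
                        "replicate": rep,
                        "beaker": beaker,
                        "morph": design.sample_morph(j),
                        "alive_before": alive,
                        "dead_after": dead,
                        "mortality": dead / alive,
                        "beaker_mean_concentration": conc,
                        "category": assign_category(conc, design.category_rule),
                    }
                )
                idx += 1
    polyps = pd.DataFrame(polyp_rows)
    return chemistry, polyps


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

_PANEL_ROWS = 10
_PVC_ROWS = 31
_REGION_GAP = 2
_CELL_PAD = 4


def _pvc_ramp_heights(spec: SceneSpec) -> np.ndarray:
    """Ramp 0 -> max height with nodes snapped exactly onto the panel and
    sample heights, so height-calibration queries there hit grid nodes."""
    heights = np.linspace(0.0, spec.pvc_max_height_cm, _PVC_ROWS)
    for target in (spec.panel_height_cm, spec.sample_height_cm):
        if heights[0] <= target <= heights[-1]:
            heights[np.argmin(np.abs(heights - target))] = target
    heights = np.sort(heights)
    # Snapping two nodes onto the same target would break strict ordering.
    for i in range(1, heights.size):
        if heights[i] <= heights[i - 1]:
            heights[i] = np.nextafter(heights[i - 1], np.inf)
    return heights


def _layout(
    spec: SceneSpec, n_samples: int
) -> tuple[tuple[int, int], int, int, list[tuple[int, int]]]:
    """Compute (shape, cell_rows0, cell_size, top-left corners per sample)."""
    cell = spec.blob_side_range[1] + _CELL_PAD
    cells_per_row = int(np.ceil(np.sqrt(n_samples)))
    cell_rows = int(np.ceil(n_samples / cells_per_row))
    coral_r0 = _PANEL_ROWS + _REGION_GAP + _PVC_ROWS + _REGION_GAP
    min_rows = coral_r0 + cell_rows * cell
    min_cols = cells_per_row * cell
    if spec.image_shape is None:
        shape = (min_rows, min_cols)
    else:
        shape = tuple(spec.image_shape)
        if shape[0] < min_rows or shape[1] < min_cols:
            raise ValueError(
                f"image too small to place all regions: need at least "
                f"({min_rows}, {min_cols}), got {shape}"
            )
        cells_per_row = shape[1] // cell
        cell_rows = int(np.ceil(n_samples / cells_per_row))
        if coral_r0 + cell_rows * cell > shape[0]:
            raise ValueError(
                f"image too small to place all regions: need at least "
                f"({min_rows}, {min_cols}), got {shape}"
            )
    corners = []
    for k in range(n_samples):
        cr, cc = divmod(k, cells_per_row)
        corners.append((coral_r0 + cr * cell, cc * cell))
    return shape, coral_r0, cell, corners


def render_scene(
    spec: SceneSpec, design: ExperimentDesign
) -> tuple[SpectralCube, GroundTruth]:
    """Render a recorded-intensity cube plus its ground truth.

    Deterministic under fixed ``spec.rng_seed`` / ``design.rng_seed``.
    """
    wavelengths = spec.wavelength_grid()
    n_bands = wavelengths.size
    chemistry, polyps = simulate_experiment(design)
    shape, _, cell, corners = _layout(spec, design.n_samples)
    rows, cols = shape

    rng = np.random.default_rng(spec.rng_seed)
    step = float(np.median(np.diff(wavelengths))) if n_bands > 1 else 1.0
    sigma_bands = max(spec.endmember_config.smooth_sigma_nm / step, 1e-6)

    dt = np.dtype(spec.dtype)
    r_true = np.full((rows, cols, n_bands), spec.background_reflectance, dtype=dt)
    region_map = np.full((rows, cols), BACKGROUND, dtype=np.int8)
    sample_map = np.full((rows, cols), -1, dtype=np.int32)
    height_map = np.zeros((rows, cols), dtype=float)

    # Flat Spectralon panel at panel height.
    region_map[:_PANEL_ROWS, :] = SPECTRALON
    height_map[:_PANEL_ROWS, :] = spec.panel_height_cm
    r_true[:_PANEL_ROWS, :, :] = spec.spectralon_reflectance

    # Inclined PVC plate: height ramps 0 -> pvc_max_height_cm along the scan.
    pvc_r0 = _PANEL_ROWS + _REGION_GAP
    pvc_heights = _pvc_ramp_heights(spec)
    region_map[pvc_r0 : pvc_r0 + _PVC_ROWS, :] = PVC
    height_map[pvc_r0 : pvc_r0 + _PVC_ROWS, :] = pvc_heights[:, None]
    r_true[pvc_r0 : pvc_r0 + _PVC_ROWS, :, :] = spec.pvc_reflectance

    # Coral blobs.
    placements = []
    lo, hi = spec.blob_side_range
    for k, row in polyps.iterrows():
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
        r0 = corners[k][0] + (cell - h) // 2
        c0 = corners[k][1] + (cell - w) // 2
        endmember = generate_endmembers(
            row["morph"],
            row["category"],
            rng,
            wavelengths,
            replace(spec.endmember_config, within_sd=spec.sample_perturbation_sd),
        )
        n_px = h * w
        jitter = 1.0 + spec.brightness_jitter_sd * rng.standard_normal((n_px, 1))
        perturb = _smooth_noise(rng, (n_px, n_bands), spec.pixel_perturbation_sd, sigma_bands)
        pix = np.clip(endmember[None, :] * jitter + perturb, 0.0, 1.2)
        r_true[r0 : r0 + h, c0 : c0 + w, :] = pix.reshape(h, w, n_bands).astype(dt)
        region_map[r0 : r0 + h, c0 : c0 + w] = CORAL
        sample_map[r0 : r0 + h, c0 : c0 + w] = int(row["sample_index"])
        height_map[r0 : r0 + h, c0 : c0 + w] = spec.sample_height_cm
        placements.append({"row0": r0, "col0": c0, "height_px": h, "width_px": w, "n_pixels": n_px})

    samples = pd.concat([polyps, pd.DataFrame(placements)], axis=1)

    # Forward optical model, applied in row blocks to bound peak memory.
    attenuation = spec.attenuation_curve(wavelengths).astype(float)
    illum = spec.illumination_spectrum(wavelengths).astype(float)
    x = np.arange(cols, dtype=float)
    if cols > 1 and spec.geometry_falloff != 0:
        half = (cols - 1) / 2.0
        geometry = 1.0 - spec.geometry_falloff * ((x - half) / half) ** 2
    else:
        geometry = np.ones(cols)
    path_m = 2.0 * (spec.camera_altitude_m - height_map / 100.0)
    if np.any(path_m < 0):
        raise ValueError("object height exceeds camera altitude")

    intensity = np.empty_like(r_true)
    block = max(1, int(4e6 // (cols * n_bands)) or 1)
    for r0 in range(0, rows, block):
        r1 = min(r0 + block, rows)
        trans = np.exp(-path_m[r0:r1, :, None] * attenuation[None, None, :])
        signal = r_true[r0:r1] * illum[None, None, :] * trans * geometry[None, :, None]
        if spec.noise_sd_relative > 0:
            signal = signal * (
                1.0 + spec.noise_sd_relative * rng.standard_normal(signal.shape)
            )
        intensity[r0:r1] = signal.astype(dt)

    cube = SpectralCube(
        data=intensity,
        wavelengths=wavelengths,
        saturation_level=spec.saturation_level,
        cube_id=f"synthetic-seed{spec.rng_seed}",
    )
    truth = GroundTruth(
        r_true=r_true,
        region_map=region_map,
        sample_map=sample_map,
        height_map=height_map,
        samples=samples,
        chemistry=chemistry,
        wavelengths=wavelengths,
    )
    return cube, truth


def masks_from_ground_truth(truth: GroundTruth) -> dict[str, np.ndarray]:
    """Per-sample boolean ROI masks keyed by sample_id."""
    masks = {}
    for _, row in truth.samples.iterrows():
        masks[row["sample_id"]] = truth.sample_map == int(row["sample_index"])
    return masks


def spectralon_mask(truth: GroundTruth) -> np.ndarray:
    return truth.region_map == SPECTRALON


def pvc_mask_at_height(
    truth: GroundTruth, height_cm: float, tol_cm: float = 0.25
) -> np.ndarray:
    return (truth.region_map == PVC) & (np.abs(truth.height_map - height_cm) <= tol_cm)


def pvc_mask(truth: GroundTruth) -> np.ndarray:
    return truth.region_map == PVC


# ---------------------------------------------------------------------------
# Scenario serialization (YAML)
# ---------------------------------------------------------------------------


def save_scenario(path: str | Path, spec: SceneSpec, design: ExperimentDesign) -> None:
    """One YAML file capturing SceneSpec + ExperimentDesign (named curves only)."""
    curve_names = {v: k for k, v in _CURVES.items()}
    for curve in (spec.attenuation_curve, spec.illumination_spectrum):
        if curve not in curve_names:
            raise ValueError("only registered named curves can be serialized")
    doc = {
        "scene": {
            "wavelength_start_nm": spec.wavelength_start_nm,
            "wavelength_end_nm": spec.wavelength_end_nm,
            "wavelength_step_nm": spec.wavelength_step_nm,
            "image_shape": list(spec.image_shape) if spec.image_shape else None,
            "camera_altitude_m": spec.camera_altitude_m,
            "sample_height_cm": spec.sample_height_cm,
            "panel_height_cm": spec.panel_height_cm,
            "pvc_max_height_cm": spec.pvc_max_height_cm,
            "spectralon_reflectance": spec.spectralon_reflectance,
            "pvc_reflectance": spec.pvc_reflectance,
            "background_reflectance": spec.background_reflectance,
            "attenuation_curve": curve_names[spec.attenuation_curve],
            "illumination_spectrum": curve_names[spec.illumination_spectrum],
            "geometry_falloff": spec.geometry_falloff,
            "noise_sd_relative": spec.noise_sd_relative,
            "blob_side_range": list(spec.blob_side_range),
            "brightness_jitter_sd": spec.brightness_jitter_sd,
            "pixel_perturbation_sd": spec.pixel_perturbation_sd,
            "sample_perturbation_sd": spec.sample_perturbation_sd,
            "effect_scale": spec.endmember_config.effect_scale,
            "within_sd": spec.endmember_config.within_sd,
            "smooth_sigma_nm": spec.endmember_config.smooth_sigma_nm,
            "saturation_level": spec.saturation_level,
            "dtype": spec.dtype,
            "rng_seed": spec.rng_seed,
        },
        "design": {
            "n_groups": design.n_groups,
            "n_replicates": design.n_replicates,
            "samples_per_beaker": design.samples_per_beaker,
            "polyps_min": design.polyps_min,
            "polyps_max": design.polyps_max,
            "nominal_concentrations": list(design.nominal_concentrations),
            "realized_fraction_mean": design.realized_fraction_mean,
            "realized_fraction_sd": design.realized_fraction_sd,
            "concentration_noise_sd": design.concentration_noise_sd,
            "mortality_params": list(design.mortality_params),
            "realized_fraction_overrides": {
                f"{g}/{r}": v for (g, r), v in design.realized_fraction_overrides.items()
            },
            "lc5_threshold": design.category_rule.lc5_threshold,
            "lc25_threshold": design.category_rule.lc25_threshold,
            "rng_seed": design.rng_seed,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> tuple[SceneSpec, ExperimentDesign]:
    doc = yaml.safe_load(Path(path).read_text())
    s = doc["scene"]
    d = doc["design"]
    spec = SceneSpec(
        wavelength_start_nm=s["wavelength_start_nm"],
        wavelength_end_nm=s["wavelength_end_nm"],
        wavelength_step_nm=s["wavelength_step_nm"],
        image_shape=tuple(s["image_shape"]) if s["image_shape"] else None,
        camera_altitude_m=s["camera_altitude_m"],
        sample_height_cm=s["sample_height_cm"],
        panel_height_cm=s["panel_height_cm"],
        pvc_max_height_cm=s["pvc_max_height_cm"],
        spectralon_reflectance=s["spectralon_reflectance"],
        pvc_reflectance=s["pvc_reflectance"],
        background_reflectance=s["background_reflectance"],
        attenuation_curve=_CURVES[s["attenuation_curve"]],
        illumination_spectrum=_CURVES[s["illumination_spectrum"]],
        geometry_falloff=s["geometry_falloff"],
        noise_sd_relative=s["noise_sd_relative"],
        blob_side_range=tuple(s["blob_side_range"]),
        brightness_jitter_sd=s["brightness_jitter_sd"],
        pixel_perturbation_sd=s["pixel_perturbation_sd"],
        sample_perturbation_sd=s["sample_perturbation_sd"],
        endmember_config=EndmemberConfig(
            effect_scale=s["effect_scale"],
            within_sd=s["within_sd"],
            smooth_sigma_nm=s["smooth_sigma_nm"],
        ),
        saturation_level=s["saturation_level"],
        dtype=s.get("dtype", "float32"),
        rng_seed=s["rng_seed"],
    )
    overrides = {
        tuple(k.split("/")): v for k, v in d["realized_fraction_overrides"].items()
    }
    design = ExperimentDesign(
        n_groups=d["n_groups"],
        n_replicates=d["n_replicates"],
        samples_per_beaker=d["samples_per_beaker"],
        polyps_min=d["polyps_min"],
        polyps_max=d["polyps_max"],
        nominal_concentrations=tuple(d["nominal_concentrations"]),
        realized_fraction_mean=d["realized_fraction_mean"],
        realized_fraction_sd=d["realized_fraction_sd"],
        concentration_noise_sd=d["concentration_noise_sd"],
        mortality_params=tuple(d["mortality_params"]),
        realized_fraction_overrides=overrides,
        category_rule=CategoryRule(d["lc5_threshold"], d["lc25_threshold"]),
        rng_seed=d["rng_seed"],
    )
    return spec, design
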