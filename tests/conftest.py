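"""Shared fixtures: small synthetic scenes rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from coralhsi import radiometry, synthetic


def tiny_scene_spec(**overrides) -> synthetic.SceneSpec:
    """Coarse-grid, small-blob scene for fast unit tests."""
    defaults = dict(
        wavelength_step_nm=3.0,
        blob_side_range=(6, 8),
        noise_sd_relative=0.005,
        rng_seed=7,
    )
    defaults.update(overrides)
    return synthetic.SceneSpec(**defaults)


def tiny_design(**overrides) -> synthetic.ExperimentDesign:
    defaults = dict(n_replicates=2, polyps_min=3, polyps_max=9, rng_seed=7)
    defaults.update(overrides)
    return synthetic.ExperimentDesign(**defaults)


@pytest.fixture(scope="session")
def tiny_scene():
    spec = tiny_scene_spec()
    design = tiny_design()
    cube, truth = synthetic.render_scene(spec, design)
    return spec, design, cube, truth


@pytest.fixture(scope="session")
def tiny_calibrated(tiny_scene):
    spec, design, cube, truth = tiny_scene
    panel = radiometry.fit_spectralon(
        cube, synthetic.spectralon_mask(truth), spec.spectralon_reflectance
    )
    r_pvc = radiometry.derive_pvc_reflectance(
        cube, synthetic.pvc_mask_at_height(truth, spec.panel_height_cm), panel
    )
    height_cal = radiometry.build_height_calibration(
        cube, synthetic.pvc_mask(truth), truth.height_map, r_pvc
    )
    refl = radiometry.to_reflectance(cube, height_cal, spec.sample_height_cm)
    return spec, design, cube, truth, panel, height_cal, refl


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
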