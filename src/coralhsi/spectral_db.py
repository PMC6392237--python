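"""Labeled pixel-spectra tables: the X / Y_h / Y_c matrices for modelling.

``X`` holds one reflectance spectrum per row (columns = wavelengths),
``Y_h`` the continuous annotations (beaker mean concentration, polyp
mortality) used by the PLS stage, and ``Y_c`` the categorical exposure label
used by the classifier.  Tables serialize to a flat CSV plus a JSON metadata
sidecar, favoring diff-ability over binary stores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coralhsi.dose_response import CategoryRule, assign_category
from coralhsi.radiometry import ReflectanceCube

__all__ = ["SpectraTable", "extract_pixels", "crop_wavelengths", "annotate"]


@dataclass
class SpectraTable:
    """Pixel spectra with per-row sample identity and annotations."""

    X: np.ndarray  # (n_pixels, n_wavelengths)
    wavelengths: np.ndarray  # (n_wavelengths,) nm
    meta: pd.DataFrame  # columns: sample_id, morph, pixel_row, pixel_col
    y_h: pd.DataFrame | None = None  # columns: concentration, mortality
    y_c: pd.Series | None = None  # exposure category per row
    pixel_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.wavelengths.size:
            raise ValueError("X must be (n_pixels, n_wavelengths)")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta row count must match X")
        if self.y_h is not None and len(self.y_h) != len(self.meta):
            raise ValueError("y_h row count must match X")
        if self.y_c is not None and len(self.y_c) != len(self.meta):
            raise ValueError("y_c length must match X")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    def subset(self, row_mask: np.ndarray) -> "SpectraTable":
        row_mask = np.asarray(row_mask)
        idx = np.nonzero(row_mask)[0] if row_mask.dtype == bool else row_mask
        return SpectraTable(
            X=self.X[idx],
            wavelengths=self.wavelengths,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            y_h=self.y_h.iloc[idx].reset_index(drop=True) if self.y_h is not None else None,
            y_c=self.y_c.iloc[idx].reset_index(drop=True) if self.y_c is not None else None,
            pixel_counts=dict(
                self.meta.iloc[idx]["sample_id"].value_counts().items()
            ),
        )

    def split_by_morph(self) -> dict[str, "SpectraTable"]:
        return {
            morph: self.subset((self.meta["morph"] == morph).to_numpy())
            for morph in self.meta["morph"].unique()
        }

    # -- serialization: CSV + JSON sidecar ---------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = [f"wl_{w:.4f}" for w in self.wavelengths]
        df = pd.concat(
            [self.meta.reset_index(drop=True), pd.DataFrame(self.X, columns=cols)],
            axis=1,
        )
        if self.y_h is not None:
            df[["yh_concentration", "yh_mortality"]] = self.y_h.to_numpy()
        if self.y_c is not None:
            df["yc_category"] = self.y_c.to_numpy()
        df.to_csv(path, index=False)
        sidecar = {
            "wavelengths_nm": self.wavelengths.tolist(),
            "n_pixels": int(self.n_pixels),
            "pixel_counts": {k: int(v) for k, v in self.pixel_counts.items()},
            "annotated": self.y_h is not None,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        path = Path(path)
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        meta_cols = [
            c
            for c in df.columns
            if not c.startswith(("wl_", "yh_", "yc_"))
        ]
        y_h = None
        if "yh_concentration" in df.columns:
            y_h = df[["yh_concentration", "yh_mortality"]].rename(
                columns={"yh_concentration": "concentration", "yh_mortality": "mortality"}
            )
        y_c = df["yc_category"] if "yc_category" in df.columns else None
        counts = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            counts = json.loads(sidecar.read_text()).get("pixel_counts", {})
        return cls(
            X=df[wl_cols].to_numpy(),
            wavelengths=wavelengths,
            meta=df[meta_cols],
            y_h=y_h,
            y_c=y_c,
            pixel_counts=counts,
        )


def extract_pixels(
    refl_cube: ReflectanceCube,
    roi_masks: dict[str, np.ndarray],
    sample_registry: pd.DataFrame | None = None,
) -> SpectraTable:
    """One table row per masked, valid pixel; pixel positions preserved.

    ``roi_masks`` maps sample_id -> boolean (rows, cols) mask.  Masks must be
    pairwise disjoint.  ``sample_registry`` (optional) provides a ``morph``
    column indexed by ``sample_id``; otherwise morph is left empty.
    """
    shape = refl_cube.data.shape[:2]
    occupancy = np.zeros(shape, dtype=int)
    for sid, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask for {sid!r} has wrong shape")
        occupancy += mask
    if (occupancy > 1).any():
        raise ValueError("ROI masks overlap across samples")

    morphs = {}
    if sample_registry is not None:
        reg = sample_registry.set_index("sample_id") if "sample_id" in sample_registry else sample_registry
        morphs = reg["morph"].to_dict()

    rows_X, rows_meta, counts = [], [], {}
    for sid, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool) & ~refl_cube.invalid_mask
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"sample {sid!r}: empty/fully-invalid mask; excluded")
            continue
        ys, xs = np.nonzero(mask)
        rows_X.append(refl_cube.data[ys, xs, :])
        rows_meta.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "morph": morphs.get(sid, ""),
                    "pixel_row": ys,
                    "pixel_col": xs,
                }
            )
        )
        counts[sid] = n
    if not rows_X:
        raise ValueError("no usable pixels in any ROI mask")
    return SpectraTable(
        X=np.vstack(rows_X),
        wavelengths=refl_cube.wavelengths.copy(),
        meta=pd.concat(rows_meta, ignore_index=True),
        pixel_counts=counts,
    )


def crop_wavelengths(
    table: SpectraTable, low_nm: float = 400.0, high_nm: float = 750.0
) -> SpectraTable:
    """Keep columns with wavelength in the closed interval [low_nm, high_nm]."""
    wl = table.wavelengths
    if low_nm < wl[0] - 1e-9 or high_nm > wl[-1] + 1e-9:
        raise ValueError(
            f"requested range [{low_nm}, {high_nm}] outside recorded "
            f"range [{wl[0]:.2f}, {wl[-1]:.2f}]"
        )
    keep = (wl >= low_nm) & (wl <= high_nm)
    if not keep.any():
        raise ValueError("wavelength crop removes every column")
    return SpectraTable(
        X=table.X[:, keep],
        wavelengths=wl[keep],
        meta=table.meta,
        y_h=table.y_h,
        y_c=table.y_c,
        pixel_counts=dict(table.pixel_counts),
    )


def annotate(
    table: SpectraTable,
    beaker_means: pd.DataFrame,
    polyp_table: pd.DataFrame,
    rule: CategoryRule | None = None,
) -> SpectraTable:
    """Fill Y_h (beaker mean concentration, sample mortality) and Y_c.

    ``beaker_means`` needs columns ``beaker`` and ``concentration`` (the study
    mean over the measured time points); ``polyp_table`` maps ``sample_id`` to
    ``beaker``, ``alive_before`` and ``dead_after``.
    """
    rule = rule or CategoryRule()
    pol = polyp_table.set_index("sample_id")
    bm = beaker_means.set_index("beaker")["concentration"]

    sample_ids = table.meta["sample_id"]
    missing_samples = sorted(set(sample_ids) - set(pol.index))
    if missing_samples:
        raise KeyError(f"samples missing from polyp table: {missing_samples}")
    beakers = pol.loc[sample_ids, "beaker"]
    missing_beakers = sorted(set(beakers) - set(bm.index))
    if missing_beakers:
        raise KeyError(f"missing chemistry for beakers: {missing_beakers}")

    conc = bm.loc[beakers].to_numpy(dtype=float)
    mortality = (
        pol.loc[sample_ids, "dead_after"].to_numpy(dtype=float)
        / pol.loc[sample_ids, "alive_before"].to_numpy(dtype=float)
    )
    if np.any((mortality < 0) | (mortality > 1)):
        raise ValueError("mortality outside [0, 1]")
    y_h = pd.DataFrame({"concentration": conc, "mortality": mortality})
    y_c = pd.Series([assign_category(c, rule) for c in conc], name="category")
    return SpectraTable(
        X=table.X,
        wavelengths=table.wavelengths,
        meta=table.meta,
        y_h=y_h,
        y_c=y_c,
        pixel_counts=dict(table.pixel_counts),
    )
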