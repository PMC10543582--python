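"""ALPS index computation from per-axis diffusivity maps.

The ALPS index is the ratio of mean diffusivity along the perivascular-space
direction (the x-axis, measured in the projection- and association-fiber areas
lateral to the lateral-ventricle bodies) to mean diffusivity perpendicular to
both the dominant fiber direction and the perivascular space::

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

Dominant fibers run along z in the projection area and along y in the
association area, so the denominator takes the y-axis diffusivity in the
projection area and the z-axis diffusivity in the association area.  An index
near 1.0 indicates minimal perivascular diffusivity; larger values indicate
freer flow along the perivascular space.

This module consumes already-fitted diffusivity maps (Dxx, Dyy, Dzz) on a
common grid.  Template registration and ROI placement on a color-coded FA map
are upstream concerns; ROIs arrive either as explicit masks or as a
center + in-plane-size placement rule realized by :func:`build_roi_from_center`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

REGIONS = ("projection", "association")
HEMISPHERES = ("left", "right")
#: canonical (region, hemisphere) keys of a complete ROI set
ROI_KEYS = tuple((r, h) for r in REGIONS for h in HEMISPHERES)


@dataclass
class DiffusivityMaps:
    """Three co-registered diffusivity volumes (mm²/s) on one grid.

    ``dxx``/``dyy``/``dzz`` are the diffusion coefficients along the
    right–left, anterior–posterior, and inferior–superior axes from a DTI fit.
    ``affine`` maps voxel indices to world coordinates in mm.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.dxx = np.asarray(self.dxx, dtype=float)
        self.dyy = np.asarray(self.dyy, dtype=float)
        self.dzz = np.asarray(self.dzz, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not (self.dxx.shape == self.dyy.shape == self.dzz.shape):
            raise ValueError(
                f"axis maps must share one grid, got shapes "
                f"{self.dxx.shape}, {self.dyy.shape}, {self.dzz.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 voxel-to-world matrix")
        for name, vol in (("dxx", self.dxx), ("dyy", self.dyy), ("dzz", self.dzz)):
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(vol < 0):
                warnings.warn(
                    f"{name} contains negative diffusivities; they are kept in "
                    "ROI means (small negatives are common in DTI fits)",
                    stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dxx.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, dxx_path, dyy_path, dzz_path) -> "DiffusivityMaps":
        imgs = [nib.load(str(p)) for p in (dxx_path, dyy_path, dzz_path)]
        ref = imgs[0].affine
        for img, p in zip(imgs[1:], (dyy_path, dzz_path)):
            if not np.allclose(img.affine, ref, atol=1e-4):
                raise ValueError(f"affine of {p} does not match the Dxx map")
        arrs = [np.asarray(img.get_fdata(), dtype=float) for img in imgs]
        return cls(*arrs, affine=ref)

    def to_nifti(self, out_dir, prefix: str = "") -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, vol in (("dxx", self.dxx), ("dyy", self.dyy), ("dzz", self.dzz)):
            p = out_dir / f"{prefix}{name}.nii"
            nib.Nifti1Image(vol, self.affine).to_filename(str(p))
            paths[name] = p
        return paths


@dataclass
class ROISet:
    """Labeled projection/association masks per hemisphere.

    ``masks`` maps ``(region, hemisphere)`` — region in {"projection",
    "association"}, hemisphere in {"left", "right"} — to boolean volumes on
    the analysis grid.  ``provenance`` records how each mask was obtained
    (mask file path or center+size placement).
    """

    masks: Mapping[tuple[str, str], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        missing = [k for k in ROI_KEYS if k not in self.masks]
        if missing:
            raise ValueError(f"ROI set is missing masks for {missing}")
        shapes = {v.shape for v in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"ROI masks are on different grids: {shapes}")
        for key, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"ROI mask {key} is empty")
        for region in REGIONS:
            overlap = self.masks[(region, "left")] & self.masks[(region, "right")]
            if overlap.any():
                raise ValueError(f"left/right {region} masks overlap")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape

    def to_nifti(self, path) -> Path:
        """Write all masks as one integer-label volume (labels 1..4)."""
        lab = np.zeros(self.shape, dtype=np.int16)
        for i, key in enumerate(ROI_KEYS, start=1):
            lab[self.masks[key]] = i
        nib.Nifti1Image(lab, np.eye(4)).to_filename(str(path))
        return Path(path)


@dataclass(frozen=True)
class ALPSMeasurement:
    """Component ROI means (mm²/s) and the ALPS index for one hemisphere."""

    hemisphere: str
    d_xx_proj: float
    d_xx_assoc: float
    d_yy_proj: float
    d_zz_assoc: float
    alps_index: float


def build_roi_from_center(
    center_mm: np.ndarray,
    size_mm: float,
    shape: tuple[int, ...],
    affine: np.ndarray,
) -> np.ndarray:
    """Place a single-slice axial square ROI of edge ``size_mm``.

    The square is centered on the voxel containing ``center_mm``; a voxel is
    included if its center falls inside the half-open square
    ``[c - size/2, c + size/2)`` along both in-plane axes.  Requires an
    axis-aligned affine.  Raises if the center is outside the grid or the
    square extends past the grid edge.
    """
    center_mm = np.asarray(center_mm, dtype=float)
    if center_mm.shape != (3,):
        raise ValueError("center_mm must be a 3-vector of world coordinates")
    if size_mm <= 0:
        raise ValueError("size_mm must be positive")
    affine = np.asarray(affine, dtype=float)
    rot = affine[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-9):
        raise ValueError("ROI placement requires an axis-aligned (diagonal) affine")

    ijk = np.linalg.solve(affine, np.append(center_mm, 1.0))[:3]
    center_vox = np.round(ijk).astype(int)
    if np.any(center_vox < 0) or np.any(center_vox >= np.asarray(shape)):
        raise ValueError(
            f"ROI center {center_mm.tolist()} mm falls outside the grid "
            f"(voxel {center_vox.tolist()}, shape {tuple(shape)})"
        )

    mask = np.zeros(shape, dtype=bool)
    half = size_mm / 2.0
    spacing = np.abs(np.diag(rot))
    k = center_vox[2]
    sel = []
    for axis in (0, 1):
        dx = spacing[axis]
        # voxel-center offsets o = m*dx with -half <= o < half
        m_lo = int(np.ceil((-half) / dx - 1e-12))
        m_hi = int(np.floor((half - 1e-12) / dx))
        # exclude the upper boundary exactly at +half (half-open square)
        if np.isclose(m_hi * dx, half):
            m_hi -= 1
        idx = center_vox[axis] + np.arange(m_lo, m_hi + 1)
        if idx[0] < 0 or idx[-1] >= shape[axis]:
            raise ValueError(
                f"ROI of size {size_mm} mm at {center_mm.tolist()} extends "
                f"outside the grid along axis {axis}"
            )
        sel.append(idx)
    ii, jj = np.meshgrid(sel[0], sel[1], indexing="ij")
    mask[ii, jj, k] = True
    return mask


def extract_roi_means(maps: DiffusivityMaps, rois: ROISet) -> pd.DataFrame:
    """Mean of each axis map over each ROI.

    Returns a table indexed by (region, hemisphere) with columns
    ``dxx``, ``dyy``, ``dzz`` (mm²/s) and ``n_voxels``.
    """
    if rois.shape != maps.shape:
        raise ValueError(
            f"ROI grid {rois.shape} does not match map grid {maps.shape}"
        )
    rows = []
    for (region, hemi) in ROI_KEYS:
        m = rois.masks[(region, hemi)]
        rows.append(
            {
                "region": region,
                "hemisphere": hemi,
                "dxx": float(maps.dxx[m].mean()),
                "dyy": float(maps.dyy[m].mean()),
                "dzz": float(maps.dzz[m].mean()),
                "n_voxels": int(m.sum()),
            }
        )
    return pd.DataFrame(rows).set_index(["region", "hemisphere"])


def compute_alps(
    d_xx_proj: float,
    d_xx_assoc: float,
    d_yy_proj: float,
    d_zz_assoc: float,
    hemisphere: str = "",
) -> ALPSMeasurement:
    """ALPS index from its four component ROI means.

    ``mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)``; the denominator
    must be positive (diffusivities perpendicular to fibers cannot vanish in
    tissue).
    """
    comps = (d_xx_proj, d_xx_assoc, d_yy_proj, d_zz_assoc)
    if not all(np.isfinite(comps)):
        raise ValueError(f"non-finite ROI mean among {comps}")
    denom = (d_yy_proj + d_zz_assoc) / 2.0
    if denom <= 0:
        raise ValueError(
            f"non-physical denominator mean(Dyy_proj={d_yy_proj}, "
            f"Dzz_assoc={d_zz_assoc}) = {denom} <= 0"
        )
    numer = (d_xx_proj + d_xx_assoc) / 2.0
    return ALPSMeasurement(
        hemisphere=hemisphere,
        d_xx_proj=float(d_xx_proj),
        d_xx_assoc=float(d_xx_assoc),
        d_yy_proj=float(d_yy_proj),
        d_zz_assoc=float(d_zz_assoc),
        alps_index=float(numer / denom),
    )


def measure_alps(
    maps: DiffusivityMaps, rois: ROISet
) -> dict[str, ALPSMeasurement]:
    """Full path from volumes + ROIs to left/right ALPS measurements."""
    means = extract_roi_means(maps, rois)
    out = {}
    for hemi in HEMISPHERES:
        out[hemi] = compute_alps(
            d_xx_proj=means.loc[("projection", hemi), "dxx"],
            d_xx_assoc=means.loc[("association", hemi), "dxx"],
            d_yy_proj=means.loc[("projection", hemi), "dyy"],
            d_zz_assoc=means.loc[("association", hemi), "dzz"],
            hemisphere=hemi,
        )
    return out


def measurements_to_table(
    measurements: Mapping[str, Mapping[str, ALPSMeasurement]]
) -> pd.DataFrame:
    """Stack per-subject left/right measurements into a cohort ALPS table."""
    rows = []
    for subject_id, per_hemi in measurements.items():
        row: dict = {"subject_id": subject_id}
        for hemi, m in per_hemi.items():
            row[f"alps_{hemi}"] = m.alps_index
            row[f"dxx_proj_{hemi}"] = m.d_xx_proj
            row[f"dxx_assoc_{hemi}"] = m.d_xx_assoc
            row[f"dyy_proj_{hemi}"] = m.d_yy_proj
            row[f"dzz_assoc_{hemi}"] = m.d_zz_assoc
        rows.append(row)
    return pd.DataFrame(rows)
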