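"""Labelled short-axis segmentation stacks and their NIfTI round-trip.

Axis convention: array axes are (x, y, slice); slice index 0 is the most
basal slice and the LV landmark label may appear only there.  In-plane
spacing is isotropic; the effective slice spacing is slice thickness
plus inter-slice gap, which is what Simpson slice summation must use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_LEGEND = {"background": 0, "rv_myocardium": 1, "rv_cavity": 2, "lv_landmark": 3}


@dataclass
class SegmentationStack:
    data: np.ndarray  # (nx, ny, n_slices) integer labels
    voxel_mm: float  # in-plane spacing, isotropic
    slice_thickness_mm: float
    slice_gap_mm: float = 0.0
    legend: dict = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("segmentation stack must be a 3D label array")
        if self.voxel_mm <= 0 or self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise ValueError("spacings must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def effective_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    def label(self, name: str) -> int:
        return self.legend[name]

    def mask(self, name: str) -> np.ndarray:
        return self.data == self.legend[name]

    def slice_areas_mm2(self, name: str) -> np.ndarray:
        """Per-slice labelled area (mm^2), base to apex."""
        return self.mask(name).sum(axis=(0, 1)) * self.voxel_mm**2

    def label_volume_ml(self, name: str) -> float:
        """Simpson slice-summation volume of one label."""
        return float(self.slice_areas_mm2(name).sum() * self.effective_spacing_mm / 1000.0)

    def voxel_centers_mm(self, slice_index: int) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.data.shape[:2]
        xs = self.origin_mm[0] + (np.arange(nx) + 0.5) * self.voxel_mm
        ys = self.origin_mm[1] + (np.arange(ny) + 0.5) * self.voxel_mm
        return xs, ys

    def slice_z_mm(self, slice_index: int) -> float:
        return float(self.origin_mm[2] + (slice_index + 0.5) * self.effective_spacing_mm)

    def landmark_point_mm(self) -> np.ndarray:
        """Centroid (mm) of the LV landmark label."""
        idx = np.argwhere(self.mask("lv_landmark"))
        if idx.size == 0:
            raise ValueError("missing landmark")
        xyz = (idx + 0.5) * np.array(
            [self.voxel_mm, self.voxel_mm, self.effective_spacing_mm]
        )
        return self.origin_mm + xyz.mean(axis=0)

    # -- IO ----------------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm, self.voxel_mm, self.effective_spacing_mm, 1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def save_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine())
        img.header.set_zooms((self.voxel_mm, self.voxel_mm, self.effective_spacing_mm))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, legend: dict | None = None,
                   slice_gap_mm: float = 0.0) -> "SegmentationStack":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int16)
        zooms = img.header.get_zooms()[:3]
        if abs(zooms[0] - zooms[1]) > 1e-6:
            raise ValueError("anisotropic in-plane spacing is not supported")
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(data=data, voxel_mm=float(zooms[0]),
                   slice_thickness_mm=float(zooms[2]) - slice_gap_mm,
                   slice_gap_mm=slice_gap_mm,
                   legend=dict(legend or DEFAULT_LEGEND), origin_mm=origin)
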