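"""Volumetric and 2D geometric measurements of the systemic RV.

Implements Simpson slice-summation volumetry (EDV/ESV/SV/EF), myocardial
mass, the traditional 2D indices extracted from personalized meshes
(length, caliper diameters, sphericity ratio, wall-thickness statistics),
Haycock body-surface area, allometric indexing and tricuspid-
regurgitation grading.

Conventions
-----------
* EF = (EDV - ESV) / EDV x 100; ED and ES are the volume-curve extremes.
* Sphericity ratio = base-to-apex length / maximum cavity diameter;
  lower values mean a rounder ventricle.
* Volumes are indexed to BSA^1.3, lengths to sqrt(BSA); the mass
  exponent is configurable and defaults to 1.3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import CorrespondedMesh, enclosed_volume

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

# Haycock, Schwartz & Wisotsky coefficients: BSA = 0.024265 W^0.5378 H^0.3964
_HAYCOCK_A, _HAYCOCK_WEXP, _HAYCOCK_HEXP = 0.024265, 0.5378, 0.3964

TR_BINS = (
    ("none", 0.0, 0.0),
    ("mild", 0.0, 0.15),
    ("moderate", 0.15, 0.25),
    ("moderate-severe", 0.25, 0.45),
    ("severe", 0.45, 1.0),
)


@dataclass
class VolumeCurve:
    volume_ml: np.ndarray
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    ed_frame: int
    es_frame: int


@dataclass
class TRGrade:
    category: str
    fraction: float


def volume_curve(slice_areas_mm2: np.ndarray, effective_spacing_mm: float) -> VolumeCurve:
    """Simpson slice-summation volumetry over a cine.

    Parameters
    ----------
    slice_areas_mm2 : (n_frames, n_slices) array
        Cavity cross-sectional area per short-axis slice and frame.
    effective_spacing_mm : float
        Slice thickness plus inter-slice gap.

    ED and ES are defined as the frames of maximum and minimum volume.
    """
    areas = np.atleast_2d(np.asarray(slice_areas_mm2, dtype=float))
    if areas.shape[0] < 2:
        raise ValueError("volume curve requires at least 2 frames")
    vol = areas.sum(axis=1) * effective_spacing_mm / 1000.0
    ed, es = int(np.argmax(vol)), int(np.argmin(vol))
    edv, esv = float(vol[ed]), float(vol[es])
    if edv <= 0:
        raise ValueError("EDV is zero; ejection fraction undefined")
    return VolumeCurve(volume_ml=vol, edv_ml=edv, esv_ml=esv, sv_ml=edv - esv,
                       ef_pct=(edv - esv) / edv * 100.0, ed_frame=ed, es_frame=es)


def stack_cavity_volume_ml(stack) -> float:
    """Single-phase Simpson volume of the cavity label in a segmentation stack."""
    return stack.label_volume_ml("rv_cavity")


def myocardial_mass(endo: CorrespondedMesh | np.ndarray,
                    epi: np.ndarray | None = None,
                    density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML) -> float:
    """Myocardial mass in grams: (epi volume - endo volume) x 1.05 g/ml."""
    if isinstance(endo, CorrespondedMesh):
        endo_v, epi_v = endo.endo, endo.epi
        if epi_v is None:
            raise ValueError("mass requires an epicardial surface")
    else:
        endo_v, epi_v = endo, epi
    wall_ml = (enclosed_volume(epi_v) - enclosed_volume(endo_v)) / 1000.0
    if wall_ml < -1e-9:
        raise ValueError("epicardial surface lies inside the endocardial surface")
    return max(wall_ml, 0.0) * density_g_per_ml


def _ring_caliper(rings_xy: np.ndarray) -> float:
    """Max in-plane caliper width over cross-sectional rings, (n_rings, n_circ, 2)."""
    best = 0.0
    for ring in rings_xy:
        d = np.linalg.norm(ring[:, None, :] - ring[None, :, :], axis=2)
        best = max(best, float(d.max()))
    return best


def geometric_indices(mesh: CorrespondedMesh) -> dict:
    """Traditional 2D indices automatically extracted from a fitted mesh.

    Returns length (base-to-apex extent along the long axis), maximum
    cavity and epicardial caliper diameters perpendicular to the long
    axis, sphericity ratio (length / max cavity diameter), maximum wall
    thickness and the SD of septal wall thickness.  All in mm except the
    unitless sphericity.
    """
    surf = mesh.epi if mesh.epi is not None else mesh.endo
    length = float(surf[:, 2].max() - surf[:, 2].min())
    cavity_diam = _ring_caliper(mesh.rings("endo")[..., :2])
    out = {
        "length_mm": length,
        "max_cavity_diameter_mm": cavity_diam,
        "sphericity_ratio": length / cavity_diam,
    }
    if mesh.epi is not None:
        out["max_epicardial_diameter_mm"] = _ring_caliper(mesh.rings("epi")[..., :2])
        thickness = mesh.wall_thickness()
        out["max_wall_thickness_mm"] = float(thickness.max())
        if mesh.septal_mask.any():
            out["sd_septal_wall_thickness_mm"] = float(thickness[mesh.septal_mask].std(ddof=1))
        else:
            warnings.warn("no septal mask; septal wall-thickness SD omitted")
    return out


def haycock_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) by the Haycock formula."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return _HAYCOCK_A * weight_kg**_HAYCOCK_WEXP * height_cm**_HAYCOCK_HEXP


def haycock_weight(bsa_m2: float, height_cm: float) -> float:
    """Weight (kg) consistent with a Haycock BSA at a given height."""
    if bsa_m2 <= 0 or height_cm <= 0:
        raise ValueError("BSA and height must be positive")
    return (bsa_m2 / (_HAYCOCK_A * height_cm**_HAYCOCK_HEXP)) ** (1.0 / _HAYCOCK_WEXP)


ALLOMETRIC_EXPONENTS = {"volume": 1.3, "length": 0.5}


def allometric_index(value: float, bsa_m2: float, kind: str,
                     mass_exponent: float = 1.3) -> float:
    """Allometrically index a measurement to body surface area.

    Volumes are divided by BSA^1.3, lengths by sqrt(BSA); the exponent
    for mass is configurable (default 1.3).
    """
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    if kind == "mass":
        exponent = mass_exponent
    elif kind in ALLOMETRIC_EXPONENTS:
        exponent = ALLOMETRIC_EXPONENTS[kind]
    else:
        raise ValueError(f"unknown measurement kind {kind!r}")
    return value / bsa_m2**exponent


def grade_tr(fraction: float) -> TRGrade:
    """Grade tricuspid regurgitation from the regurgitant fraction.

    Bins: mild <15%, moderate 15-25%, moderate-severe 25-45%, severe
    >45%; a fraction of exactly 0 is 'none'.  Boundary values fall in
    the lower-severity bin.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("regurgitant fraction must lie in [0, 1]")
    if fraction == 0.0:
        return TRGrade("none", fraction)
    for name, lo, hi in TR_BINS[1:]:
        if lo < fraction <= hi:
            return TRGrade(name, fraction)
    return TRGrade("severe", fraction)
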