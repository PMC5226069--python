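"""Synthetic systemic-RV cohort generator.

Produces two-group, two-stage cohorts of idealized right-ventricular
anatomies (label stacks + LV landmark) and cine motion (tracked contour
sequences) with exact ground truth for volumes, ejection fraction and
strain, so that every downstream stage of the pipeline has a known
recovery target.

The anatomy is a crescent-section half-ellipsoid: each surface is a grid
of ``n_rings`` cross-sectional rings whose radius follows an ellipsoidal
base-to-apex profile and whose cross-section is a limacon
``r(phi) = R (1 - c cos phi)``; the inward dimple at ``phi = 0`` plays
the role of the septum.  The cross-section is star-shaped about its
axis, so every geometric property (volume, caliper diameter, wall
thickness) is analytically checkable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.optimize import brentq

from .contours import ContourSequence, SAX_LEVELS, resample_closed, resample_open
from .mesh import CorrespondedMesh, N_CIRC, N_RINGS, surface_trimesh, enclosed_volume
from .segmentation import SegmentationStack, DEFAULT_LEGEND

# -- parameter containers ---------------------------------------------------


@dataclass
class ShapeParams:
    """Generative shape parameters for one subject.

    dilation_scale
        Uniform similarity scale; cavity volume scales with its cube.
    sphericity_factor
        Long-axis stretch; directly controls the length-to-diameter
        (sphericity) ratio.  Values < 1 give a rounder ventricle.
    base_width_factor
        In-plane widening at the base, tapering linearly to the apex.
    apex_tilt_deg
        Shear of the long axis toward the free wall, in degrees.
    wall_thickness_mm
        Nominal end-diastolic wall thickness.
    noise_sd_mm
        SD of i.i.d. vertex perturbations applied along surface normals.
    """

    dilation_scale: float = 1.0
    sphericity_factor: float = 1.0
    base_width_factor: float = 1.0
    apex_tilt_deg: float = 0.0
    wall_thickness_mm: float = 4.0
    noise_sd_mm: float = 0.0

    def validate(self) -> None:
        if self.dilation_scale <= 0:
            raise ValueError("dilation_scale must be > 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be > 0")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")


@dataclass
class MotionParams:
    """Cine motion prescription for one subject.

    Peak strains are Lagrangian fractions relative to end-diastole
    (frame 0) and must be negative: shortening of the circumference and
    of the long axis.  Positive strain means lengthening, as seen in
    radial thickening.  When ``incompressible_wall`` is set, the
    epicardial in-plane scale is solved per frame so that wall volume is
    conserved.
    """

    n_frames: int = 25
    rr_interval_s: float = 0.5
    peak_circ_strain: float = -0.15
    peak_long_strain: float = -0.14
    systole_fraction: float = 0.4
    incompressible_wall: bool = True

    def validate(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        for s in (self.peak_circ_strain, self.peak_long_strain):
            if not -1.0 < s < 0.0:
                raise ValueError("peak strains must lie in (-1, 0)")
        if not 0.0 < self.systole_fraction < 1.0:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if self.rr_interval_s <= 0:
            raise ValueError("rr_interval_s must be > 0")


@dataclass
class GroundTruth:
    """Analytic per-subject recovery targets recorded by the generator."""

    shape_params: ShapeParams
    times_s: np.ndarray
    volume_ml: np.ndarray  # cavity volume per frame
    wall_volume_ml: np.ndarray
    edv_ml: float
    esv_ml: float
    ef_pct: float
    ed_frame: int
    es_frame: int
    strain_pct: dict  # (direction, level) -> per-frame % curve

    def to_dict(self) -> dict:
        return {
            "shape_params": asdict(self.shape_params),
            "times_s": self.times_s.tolist(),
            "volume_ml": self.volume_ml.tolist(),
            "wall_volume_ml": self.wall_volume_ml.tolist(),
            "edv_ml": self.edv_ml,
            "esv_ml": self.esv_ml,
            "ef_pct": self.ef_pct,
            "ed_frame": self.ed_frame,
            "es_frame": self.es_frame,
            "strain_pct": {f"{d}_{lv}": np.asarray(c).tolist()
                           for (d, lv), c in self.strain_pct.items()},
        }


# -- template ---------------------------------------------------------------

TEMPLATE_LENGTH_MM = 50.0
TEMPLATE_EPI_RADIUS_MM = 22.0
TEMPLATE_WALL_MM = 4.0
CRESCENT = 0.55  # limacon dimple depth; < 1 keeps the section star-shaped
SEPTAL_HALF_ANGLE_DEG = 60.0
_PSI_MAX = 0.93 * math.pi / 2  # apex ring stops short of the pole; cap closes it


def _ring_surface(length_mm: float, base_radius_mm: float,
                  n_rings: int = N_RINGS, n_circ: int = N_CIRC,
                  crescent: float = CRESCENT) -> np.ndarray:
    """Vertices of one crescent-section half-ellipsoid surface, ring-major."""
    psi = np.linspace(0.0, _PSI_MAX, n_rings)
    z = length_mm * np.sin(psi) / np.sin(_PSI_MAX)
    r = base_radius_mm * np.cos(psi)
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    a = 1.0 - crescent * np.cos(phi)
    verts = np.empty((n_rings, n_circ, 3))
    verts[..., 0] = r[:, None] * a[None, :] * np.cos(phi)[None, :]
    verts[..., 1] = r[:, None] * a[None, :] * np.sin(phi)[None, :]
    verts[..., 2] = z[:, None]
    return verts.reshape(-1, 3)


def generate_template(n_rings: int = N_RINGS, n_circ: int = N_CIRC,
                      length_mm: float = TEMPLATE_LENGTH_MM,
                      epi_radius_mm: float = TEMPLATE_EPI_RADIUS_MM,
                      wall_mm: float = TEMPLATE_WALL_MM) -> CorrespondedMesh:
    """Build the fixed-topology RV template (endo + epi crescent half-ellipsoids).

    The vertex budget is fixed: ``n_rings * n_circ`` must equal 576 per
    surface so that the flattened endo+epi shape vector has exactly 3456
    entries.
    """
    if n_rings * n_circ != N_RINGS * N_CIRC:
        raise ValueError(
            f"resolution {n_rings}x{n_circ} does not yield 576 vertices per surface"
        )
    epi = _ring_surface(length_mm, epi_radius_mm, n_rings, n_circ)
    endo = _ring_surface(length_mm - wall_mm, epi_radius_mm - wall_mm, n_rings, n_circ)
    phi = 2 * np.pi * np.arange(n_circ) / n_circ
    septal_ang = np.minimum(phi, 2 * np.pi - phi) <= math.radians(SEPTAL_HALF_ANGLE_DEG)
    septal = np.tile(septal_ang, n_rings)
    landmark = np.array([epi_radius_mm * (1.0 - CRESCENT) + 6.0, 0.0, 0.0])
    return CorrespondedMesh(endo=endo, epi=epi, septal_mask=septal, landmark=landmark,
                            n_rings=n_rings, n_circ=n_circ,
                            meta={"wall_mm": wall_mm, "length_mm": length_mm})


# -- deformation ------------------------------------------------------------


def deform_shape(template: CorrespondedMesh, params: ShapeParams,
                 seed: int | np.random.Generator | None = None) -> CorrespondedMesh:
    """Apply generative deformations to the template.

    Order is fixed: wall thickness -> uniform dilation -> long-axis
    (sphericity) stretch -> base widening -> apex tilt -> vertex noise
    along surface normals.  Correspondence and topology are preserved.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    endo = template.endo.copy()
    epi = template.epi.copy()
    landmark = template.landmark.copy()

    # wall thickness: rescale the matched endo->epi gap
    t0 = template.meta.get("wall_mm", TEMPLATE_WALL_MM)
    endo = epi + (endo - epi) * (params.wall_thickness_mm / t0)

    s = params.dilation_scale
    endo, epi, landmark = endo * s, epi * s, landmark * s

    f = params.sphericity_factor
    for v in (endo, epi, landmark):
        v[..., 2] *= f

    b = params.base_width_factor
    zmax = epi[:, 2].max()
    for v in (endo, epi):
        g = b + (1.0 - b) * (v[:, 2] / zmax)
        v[:, 0] *= g
        v[:, 1] *= g
    landmark[:2] *= b  # landmark sits on the base plane

    tilt = math.tan(math.radians(params.apex_tilt_deg))
    endo[:, 0] += tilt * endo[:, 2]
    epi[:, 0] += tilt * epi[:, 2]

    # deterministic parameters must not collapse the wall
    gap = np.linalg.norm(epi - endo, axis=1)
    if gap.min() <= 0.2:
        raise ValueError(
            f"deformation produced endo/epi intersection "
            f"(min matched wall {gap.min():.3f} mm)"
        )

    if params.noise_sd_mm > 0:
        direction = (epi - endo) / gap[:, None]
        for v in (endo, epi):
            normals = surface_trimesh(v).vertex_normals
            v += normals * rng.normal(0.0, params.noise_sd_mm, size=(len(v), 1))
        # noise is texture, not topology: clamp so surfaces never cross
        floor = 0.3
        thickness = np.einsum("ij,ij->i", epi - endo, direction)
        bad = thickness < floor
        endo[bad] = epi[bad] - direction[bad] * floor

    out = template.with_vertices(endo, epi)
    out.landmark = landmark
    out.meta = dict(template.meta, wall_mm=params.wall_thickness_mm)
    return out


# -- rasterization ----------------------------------------------------------


def _section_polygons(tm, z: float) -> list[np.ndarray]:
    sec = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if sec is None:
        return []
    return [np.asarray(d)[:, :2] for d in sec.discrete]


def _contains(polys: list[np.ndarray], pts: np.ndarray) -> np.ndarray:
    inside = np.zeros(len(pts), dtype=bool)
    for poly in polys:
        inside |= MplPath(poly).contains_points(pts)
    return inside


def rasterize_segmentation(mesh: CorrespondedMesh, voxel_mm: float = 1.5,
                           slice_thickness_mm: float = 5.0,
                           landmark_radius_mm: float = 3.0) -> SegmentationStack:
    """Voxelize a mesh into a labelled short-axis stack, base slice first.

    Labels: 0 background, 1 RV myocardium, 2 RV cavity, 3 LV landmark
    (a small disc around the landmark point, on the most basal slice
    only).  Slices are perpendicular to the long axis (+z) and ordered
    base to apex; trailing empty slices are trimmed.
    """
    if voxel_mm <= 0 or slice_thickness_mm <= 0:
        raise ValueError("voxel and slice spacings must be positive")
    endo_tm = surface_trimesh(mesh.endo)
    epi_tm = surface_trimesh(mesh.epi) if mesh.epi is not None else None
    outer = epi_tm if epi_tm is not None else endo_tm

    z0, z1 = outer.vertices[:, 2].min(), outer.vertices[:, 2].max()
    n_slices = int(np.floor((z1 - z0) / slice_thickness_mm + 1e-9))
    if n_slices < 1:
        raise ValueError("slice thickness exceeds the object extent")

    margin = 2 * voxel_mm + landmark_radius_mm
    lo = np.minimum(outer.vertices.min(axis=0)[:2], mesh.landmark[:2]) - margin
    hi = np.maximum(outer.vertices.max(axis=0)[:2], mesh.landmark[:2]) + margin
    nx = int(np.ceil((hi[0] - lo[0]) / voxel_mm))
    ny = int(np.ceil((hi[1] - lo[1]) / voxel_mm))
    xs = lo[0] + (np.arange(nx) + 0.5) * voxel_mm
    ys = lo[1] + (np.arange(ny) + 0.5) * voxel_mm
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)

    legend = dict(DEFAULT_LEGEND)
    data = np.zeros((nx, ny, n_slices), dtype=np.int16)
    for k in range(n_slices):
        z = z0 + (k + 0.5) * slice_thickness_mm
        cavity = _contains(_section_polygons(endo_tm, z), grid)
        plane = np.zeros(len(grid), dtype=np.int16)
        if epi_tm is not None:
            myo = _contains(_section_polygons(epi_tm, z), grid) & ~cavity
            plane[myo] = legend["rv_myocardium"]
        plane[cavity] = legend["rv_cavity"]
        data[:, :, k] = plane.reshape(nx, ny)

    # LV landmark disc on the most basal slice, outside the RV labels
    d2 = (grid[:, 0] - mesh.landmark[0]) ** 2 + (grid[:, 1] - mesh.landmark[1]) ** 2
    lm = (d2 <= landmark_radius_mm**2).reshape(nx, ny)
    base = data[:, :, 0]
    base[lm & (base == 0)] = legend["lv_landmark"]

    keep = np.any(data > 0, axis=(0, 1))
    last = np.max(np.nonzero(keep)) if keep.any() else 0
    data = data[:, :, : last + 1]
    return SegmentationStack(data=data, voxel_mm=voxel_mm,
                             slice_thickness_mm=slice_thickness_mm,
                             legend=legend, origin_mm=np.array([lo[0], lo[1], z0]))


# -- cine motion ------------------------------------------------------------


def _activation(times: np.ndarray, rr: float, systole_fraction: float) -> np.ndarray:
    """Smooth contraction waveform: 0 at frame 0, 1 at end-systole, back to 0."""
    ts = systole_fraction * rr
    w = np.empty_like(times)
    sys_mask = times <= ts
    w[sys_mask] = np.sin(0.5 * np.pi * times[sys_mask] / ts) ** 2
    w[~sys_mask] = np.cos(0.5 * np.pi * (times[~sys_mask] - ts) / (rr - ts)) ** 2
    return w


def _mesh_sax_contour(mesh: CorrespondedMesh, surface: str, z: float,
                      n_points: int = 48) -> np.ndarray:
    """Closed in-plane contour at height z by interpolating between rings."""
    rings = mesh.rings(surface)
    ring_z = rings[..., 2].mean(axis=1)
    i = int(np.clip(np.searchsorted(ring_z, z) - 1, 0, mesh.n_rings - 2))
    t = (z - ring_z[i]) / (ring_z[i + 1] - ring_z[i])
    pts = (1 - t) * rings[i] + t * rings[i + 1]
    return resample_closed(pts[:, :2], n_points)


def _mesh_4ch_polyline(mesh: CorrespondedMesh, surface: str,
                       n_points: int = 48) -> np.ndarray:
    """Open long-axis polyline (x, z) through the septum-free-wall plane."""
    rings = mesh.rings(surface)
    j_sept, j_free = 0, mesh.n_circ // 2
    down = rings[:, j_sept, :][:, [0, 2]]  # base -> apex on the septal side
    up = rings[::-1, j_free, :][:, [0, 2]]  # apex -> base on the free wall
    return resample_open(np.vstack([down, up]), n_points)


def generate_cine(mesh: CorrespondedMesh, motion: MotionParams,
                  n_points: int = 48) -> tuple[dict, GroundTruth]:
    """Generate tracked cine contours and the analytic ground truth.

    Per frame the endocardium undergoes an affine contraction
    ``diag(c, c, l)``: the in-plane scale ``c`` realizes the prescribed
    peak circumferential strain and the long-axis scale ``l`` is solved
    so the four-chamber polyline shortens by the prescribed peak
    longitudinal strain at end-systole.  With ``incompressible_wall``
    the epicardial in-plane scale is solved per frame so wall volume is
    conserved exactly.

    Returns ``(contours, truth)`` where ``contours`` maps
    ``(level, surface)`` to a :class:`ContourSequence`.
    """
    motion.validate()
    if mesh.epi is None:
        raise ValueError("cine generation requires an epicardial surface")
    dt = motion.rr_interval_s / motion.n_frames
    times = np.arange(motion.n_frames) * dt
    w = _activation(times, motion.rr_interval_s, motion.systole_fraction)
    c = 1.0 + motion.peak_circ_strain * w

    # solve the end-systolic long-axis scale from the 4ch polyline length
    la0 = _mesh_4ch_polyline(mesh, "endo", n_points)
    len0 = np.linalg.norm(np.diff(la0, axis=0), axis=1).sum()
    c_es = 1.0 + motion.peak_circ_strain

    def _la_strain(l: float) -> float:
        p = la0 * np.array([c_es, l])
        return np.linalg.norm(np.diff(p, axis=0), axis=1).sum() / len0 - 1.0

    l_es = brentq(lambda l: _la_strain(l) - motion.peak_long_strain, 0.2, 2.0)
    l = 1.0 + (l_es - 1.0) * w

    vol_c0 = enclosed_volume(mesh.endo) / 1000.0
    vol_e0 = enclosed_volume(mesh.epi) / 1000.0
    wall0 = vol_e0 - vol_c0
    if motion.incompressible_wall:
        e = np.sqrt((wall0 / l + c**2 * vol_c0) / vol_e0)
    else:
        e = c.copy()

    zext = mesh.endo[:, 2].max() - mesh.endo[:, 2].min()
    zbase = mesh.endo[:, 2].min()
    levels = {lv: zbase + frac * zext
              for lv, frac in zip(SAX_LEVELS, (0.25, 0.5, 0.75))}

    contours: dict[tuple[str, str], ContourSequence] = {}
    ref: dict[tuple[str, str], np.ndarray] = {}
    for lv, z in levels.items():
        ref[(lv, "endo")] = _mesh_sax_contour(mesh, "endo", z, n_points)
        ref[(lv, "epi")] = _mesh_sax_contour(mesh, "epi", z, n_points)
    ref[("4ch", "endo")] = la0
    ref[("4ch", "epi")] = _mesh_4ch_polyline(mesh, "epi", n_points)

    for (lv, surf), p0 in ref.items():
        inplane = c if surf == "endo" else e
        if lv == "4ch":
            frames = p0[None, :, :] * np.stack([inplane, l], axis=1)[:, None, :]
        else:
            frames = p0[None, :, :] * inplane[:, None, None]
        contours[(lv, surf)] = ContourSequence(
            points=frames, frame_interval_s=dt, level=lv, surface=surf)

    # analytic ground truth, computed from the generated contours themselves
    volume = c**2 * l * vol_c0
    wall_volume = e**2 * l * vol_e0 - volume
    es_frame = int(np.argmin(volume))
    edv, esv = float(volume[0]), float(volume.min())
    strain: dict[tuple[str, str], np.ndarray] = {}
    for lv in SAX_LEVELS:
        per = contours[(lv, "endo")].arc_lengths()
        strain[("circumferential", lv)] = 100.0 * (per / per[0] - 1.0)
        th = np.linalg.norm(contours[(lv, "epi")].points
                            - contours[(lv, "endo")].points, axis=2).mean(axis=1)
        if th.min() <= 0:
            raise ValueError("prescribed strains imply non-positive wall thickness")
        strain[("radial", lv)] = 100.0 * (th / th[0] - 1.0)
    la_len = contours[("4ch", "endo")].arc_lengths()
    strain[("longitudinal", "4ch")] = 100.0 * (la_len / la_len[0] - 1.0)

    truth = GroundTruth(
        shape_params=ShapeParams(), times_s=times, volume_ml=volume,
        wall_volume_ml=wall_volume, edv_ml=edv, esv_ml=esv,
        ef_pct=(edv - esv) / edv * 100.0, ed_frame=0, es_frame=es_frame,
        strain_pct=strain)
    return contours, truth


def cine_slice_areas(mesh: CorrespondedMesh, motion: MotionParams,
                     slice_thickness_mm: float = 4.0) -> tuple[np.ndarray, float]:
    """Measure per-frame cavity areas on fixed short-axis planes (Simpson input).

    The endocardial mesh is moved through the cine and sectioned at
    fixed z planes, mimicking the acquisition geometry of a short-axis
    stack.  Returns ``(areas, effective_spacing)`` with areas of shape
    ``(n_frames, n_slices)`` in mm^2.
    """
    motion.validate()
    dt = motion.rr_interval_s / motion.n_frames
    times = np.arange(motion.n_frames) * dt
    w = _activation(times, motion.rr_interval_s, motion.systole_fraction)
    c = 1.0 + motion.peak_circ_strain * w
    la0 = _mesh_4ch_polyline(mesh, "endo")
    len0 = np.linalg.norm(np.diff(la0, axis=0), axis=1).sum()
    c_es = 1.0 + motion.peak_circ_strain

    def _la_strain(l: float) -> float:
        p = la0 * np.array([c_es, l])
        return np.linalg.norm(np.diff(p, axis=0), axis=1).sum() / len0 - 1.0

    l_es = brentq(lambda l: _la_strain(l) - motion.peak_long_strain, 0.2, 2.0)
    l = 1.0 + (l_es - 1.0) * w

    z0, z1 = mesh.endo[:, 2].min(), mesh.endo[:, 2].max()
    n_slices = int(np.floor((z1 - z0) / slice_thickness_mm))
    z_planes = z0 + (np.arange(n_slices) + 0.5) * slice_thickness_mm
    areas = np.zeros((motion.n_frames, n_slices))
    for k in range(motion.n_frames):
        verts = mesh.endo * np.array([c[k], c[k], l[k]])
        tm = surface_trimesh(verts)
        for s, z in enumerate(z_planes):
            for poly in _section_polygons(tm, z):
                x, y = poly[:, 0], poly[:, 1]
                areas[k, s] += 0.5 * abs(np.dot(x, np.roll(y, -1))
                                         - np.dot(y, np.roll(x, -1)))
    return areas, slice_thickness_mm


# -- cohort generation ------------------------------------------------------


@dataclass
class ArmSpec:
    """Distributional description of one (surgical group, stage) arm.

    Defaults for the four study arms encode the cohort structure of a
    two-centre HLHS population: per-arm sample size, BSA distribution,
    indexed EDV level (ml/BSA^1.3) that sets ventricular dilation, a
    target sphericity ratio, and peak-strain distributions.
    """

    group: str
    stage: str
    n: int
    bsa_mean_m2: float
    bsa_sd_m2: float
    iedv_ml: float  # mean indexed EDV, ml/BSA^1.3
    iedv_sigma_log: float = 0.18  # lognormal sigma of the indexed EDV
    sphericity_mean: float = 1.45  # target length/diameter ratio
    sphericity_sd: float = 0.12
    base_width_sd: float = 0.05
    apex_tilt_sd_deg: float = 3.0
    wall_mean_mm: float = 4.0  # at BSA 0.4; scales with sqrt(BSA)
    wall_sd_mm: float = 0.4
    noise_sd_mm: float = 0.4
    peak_circ_mean: float = -0.15
    peak_circ_sd: float = 0.035
    peak_long_mean: float = -0.14
    peak_long_sd: float = 0.035
    height_mean_cm: float = 68.0
    height_sd_cm: float = 6.0
    tr_probs: tuple = (0.45, 0.40, 0.12, 0.0, 0.03)  # none..severe bins
    lv_shape_probs: tuple = (0.50, 0.35, 0.15)  # globular, slit-like, borderline


@dataclass
class CohortConfig:
    """Cohort layout: one ArmSpec per (group, stage) cell plus a master seed.

    Per-subject random streams are derived from ``SeedSequence([seed,
    arm_index, subject_index])`` so that changing one arm's size never
    reshuffles the subjects of another.
    """

    arms: list
    seed: int = 0
    n_frames: int = 25
    rr_interval_s: float = 0.5
    systole_fraction: float = 0.4
    incompressible_wall: bool = True

    def validate(self) -> None:
        if any(a.n < 2 for a in self.arms):
            raise ValueError("each arm needs n >= 2 for downstream statistics")


def default_cohort_config(seed: int = 0, scale: float = 1.0) -> CohortConfig:
    """The study-like cohort: 93 subjects in four arms (MBT/RVPA x stage I/II).

    Arm sizes, BSA distributions, indexed EDV levels and sphericity
    targets follow the two-centre HLHS cohort this package emulates.
    ``scale`` shrinks arm sizes proportionally for quick runs.
    """
    def n_of(n):
        return max(2, round(n * scale))

    arms = [
        ArmSpec("MBT", "I", n_of(30), 0.40, 0.04, 83.0, sphericity_mean=1.47,
                height_mean_cm=62, height_sd_cm=5),
        ArmSpec("RVPA", "I", n_of(20), 0.44, 0.06, 110.0, sphericity_mean=1.41,
                height_mean_cm=65, height_sd_cm=5),
        ArmSpec("MBT", "II", n_of(29), 0.67, 0.17, 77.0, sphericity_mean=1.52,
                height_mean_cm=88, height_sd_cm=8),
        ArmSpec("RVPA", "II", n_of(14), 0.70, 0.11, 98.0, sphericity_mean=1.24,
                height_mean_cm=88, height_sd_cm=8),
    ]
    return CohortConfig(arms=arms, seed=seed)


def two_group_config(n_per_arm: int = 40, dilation_d: float = 0.0,
                     seed: int = 0) -> CohortConfig:
    """Two equal arms differing only in generative dilation.

    ``dilation_d`` is the standardized effect size on log indexed EDV:
    group B's mean is shifted by ``d`` within-group SDs.  All other
    shape parameters share one distribution, so any recovered group
    difference is attributable to dilation alone; their spreads are kept
    moderate relative to the dilation spread so that dilation is a
    separable factor of shape variation rather than one entangled with
    long-axis stretch.
    """
    sigma = 0.25
    base = dict(n=n_per_arm, bsa_mean_m2=0.5, bsa_sd_m2=0.0, iedv_sigma_log=sigma,
                sphericity_sd=0.04, base_width_sd=0.04, apex_tilt_sd_deg=2.0,
                noise_sd_mm=0.3)
    arm_a = ArmSpec("A", "I", iedv_ml=85.0, **base)
    arm_b = ArmSpec("B", "I", iedv_ml=85.0 * math.exp(dilation_d * sigma), **base)
    return CohortConfig(arms=[arm_a, arm_b], seed=seed)


@dataclass
class SubjectSpec:
    subject_id: str
    group: str
    stage: str
    bsa_m2: float
    weight_kg: float
    height_cm: float
    tr_fraction: float
    lv_shape: str
    shape_params: ShapeParams
    motion_params: MotionParams
    seed: int


TR_SAMPLING = (  # (bin fraction range) aligned with ArmSpec.tr_probs
    (0.0, 0.0), (0.02, 0.15), (0.15, 0.25), (0.25, 0.45), (0.45, 0.60))
LV_SHAPES = ("globular", "slit-like", "borderline")


def _subject_rng(seed: int, arm_index: int, k: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence([seed, arm_index, k])
    return np.random.default_rng(ss), int(ss.generate_state(1)[0] % (2**31))


def sample_cohort(config: CohortConfig,
                  template: CorrespondedMesh | None = None) -> list[SubjectSpec]:
    """Draw per-subject metadata, shape and motion parameters (no images).

    The dilation scale is solved so that each subject's end-diastolic
    cavity volume equals its drawn indexed EDV times BSA^1.3, which
    makes the cohort allometrically consistent by construction.
    """
    from .geometry import geometric_indices, haycock_weight

    config.validate()
    template = template or generate_template()
    v_ref = template.cavity_volume_ml()
    sph_ref = geometric_indices(
        CorrespondedMesh(endo=template.endo, epi=template.epi,
                         septal_mask=template.septal_mask,
                         landmark=template.landmark))["sphericity_ratio"]
    subjects: list[SubjectSpec] = []
    for ai, arm in enumerate(config.arms):
        for k in range(arm.n):
            rng, subj_seed = _subject_rng(config.seed, ai, k)
            bsa = max(0.15, rng.normal(arm.bsa_mean_m2, arm.bsa_sd_m2))
            height = max(45.0, rng.normal(arm.height_mean_cm, arm.height_sd_cm))
            weight = haycock_weight(bsa, height)
            probs = np.asarray(arm.tr_probs, float)
            tr_bin = rng.choice(len(probs), p=probs / probs.sum())
            lo, hi = TR_SAMPLING[tr_bin]
            tr = float(lo if tr_bin == 0 else rng.uniform(lo, hi))
            lv_shape = LV_SHAPES[rng.choice(3, p=np.asarray(arm.lv_shape_probs))]

            target_edv = arm.iedv_ml * bsa**1.3 * math.exp(
                rng.normal(0.0, arm.iedv_sigma_log))
            sphericity = max(0.6, rng.normal(arm.sphericity_mean, arm.sphericity_sd))
            params = ShapeParams(
                dilation_scale=1.0,
                sphericity_factor=sphericity / sph_ref,
                base_width_factor=max(0.7, rng.normal(1.0, arm.base_width_sd)),
                apex_tilt_deg=rng.normal(0.0, arm.apex_tilt_sd_deg),
                wall_thickness_mm=max(1.5, rng.normal(
                    arm.wall_mean_mm * math.sqrt(bsa / 0.4), arm.wall_sd_mm)),
                noise_sd_mm=arm.noise_sd_mm,
            )
            # solve dilation so the noiseless cavity volume hits target_edv
            probe = replace(params, dilation_scale=1.0, noise_sd_mm=0.0)
            v1 = deform_shape(template, probe).cavity_volume_ml()
            params.dilation_scale = (target_edv / v1) ** (1.0 / 3.0)

            motion = MotionParams(
                n_frames=config.n_frames, rr_interval_s=config.rr_interval_s,
                peak_circ_strain=float(np.clip(
                    rng.normal(arm.peak_circ_mean, arm.peak_circ_sd), -0.35, -0.03)),
                peak_long_strain=float(np.clip(
                    rng.normal(arm.peak_long_mean, arm.peak_long_sd), -0.35, -0.03)),
                systole_fraction=config.systole_fraction,
                incompressible_wall=config.incompressible_wall,
            )
            subjects.append(SubjectSpec(
                subject_id=f"{arm.group}{arm.stage}_{k:03d}", group=arm.group,
                stage=arm.stage, bsa_m2=float(bsa), weight_kg=float(weight),
                height_cm=float(height), tr_fraction=tr, lv_shape=lv_shape,
                shape_params=params, motion_params=motion, seed=subj_seed))
    return subjects


def cohort_table(subjects: list[SubjectSpec]):
    import pandas as pd

    return pd.DataFrame([{
        "subject_id": s.subject_id, "group": s.group, "stage": s.stage,
        "weight_kg": round(s.weight_kg, 3), "height_cm": round(s.height_cm, 1),
        "bsa_m2": round(s.bsa_m2, 4), "tr_fraction": round(s.tr_fraction, 4),
        "lv_shape": s.lv_shape,
    } for s in subjects])


def build_subject(spec: SubjectSpec,
                  template: CorrespondedMesh | None = None) -> tuple[CorrespondedMesh, dict, GroundTruth]:
    """Deform the template for one subject and generate its cine contours."""
    template = template or generate_template()
    mesh = deform_shape(template, spec.shape_params, seed=spec.seed)
    contours, truth = generate_cine(mesh, spec.motion_params)
    truth.shape_params = spec.shape_params
    return mesh, contours, truth


def generate_cohort(config: CohortConfig, out_dir=None, voxel_mm: float = 2.0,
                    slice_thickness_mm: float = 5.0, write_images: bool = True):
    """Generate a full synthetic cohort, optionally writing it to disk.

    Output layout (when ``out_dir`` is given): ``cohort.csv`` plus, per
    subject, ``seg.nii.gz``, ``contours_<level>_<surface>.json`` and
    ``truth.json``.

    Returns ``(table, records)`` where each record holds the subject
    spec, mesh, contours and ground truth.
    """
    import json as _json
    from pathlib import Path as _Path

    template = generate_template()
    subjects = sample_cohort(config, template)
    table = cohort_table(subjects)
    records = []
    out = _Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
    for spec in subjects:
        mesh, contours, truth = build_subject(spec, template)
        stack = None
        if write_images:
            stack = rasterize_segmentation(mesh, voxel_mm=voxel_mm,
                                           slice_thickness_mm=slice_thickness_mm)
        if out is not None:
            sdir = out / spec.subject_id
            sdir.mkdir(exist_ok=True)
            if stack is not None:
                stack.save_nifti(sdir / "seg.nii.gz")
            for (lv, surf), seq in contours.items():
                seq.to_json(sdir / f"contours_{lv}_{surf}.json")
            (sdir / "truth.json").write_text(_json.dumps(truth.to_dict()))
        records.append({"spec": spec, "mesh": mesh, "stack": stack,
                        "contours": contours, "truth": truth})
    return table, records
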