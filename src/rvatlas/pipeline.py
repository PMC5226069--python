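"""End-to-end cohort analysis: geometry, atlas, strain, report tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from .atlas import build_atlas, compare_modes
from .contours import ContourSequence
from .personalize import load_segmentation, personalize
from .stats import build_report_tables
from .strain import analyze_cine, peaks_table
from .synthetic import generate_template


def subject_geometry_row(mesh, volume_ml: np.ndarray, bsa: float,
                         subject_id: str) -> dict:
    """Per-subject geometric and volumetric report row (indexed to BSA)."""
    edv, esv = float(np.max(volume_ml)), float(np.min(volume_ml))
    g = geo.geometric_indices(mesh)
    mass = geo.myocardial_mass(mesh)
    idx_v = lambda v: geo.allometric_index(v, bsa, "volume")
    idx_l = lambda v: geo.allometric_index(v, bsa, "length")
    row = {
        "subject_id": subject_id,
        "edv_ml": edv, "esv_ml": esv, "sv_ml": edv - esv,
        "ef_pct": (edv - esv) / edv * 100.0,
        "iedv": idx_v(edv), "iesv": idx_v(esv), "isv": idx_v(edv - esv),
        "mass_g": mass, "imass": geo.allometric_index(mass, bsa, "mass"),
        "length_mm": g["length_mm"], "ilength": idx_l(g["length_mm"]),
        "icavity_diam": idx_l(g["max_cavity_diameter_mm"]),
        "sphericity_ratio": g["sphericity_ratio"],
    }
    if "max_epicardial_diameter_mm" in g:
        row["iepi_diam"] = idx_l(g["max_epicardial_diameter_mm"])
        row["imax_wall"] = idx_l(g["max_wall_thickness_mm"])
    if "sd_septal_wall_thickness_mm" in g:
        row["isd_septal_wall"] = idx_l(g["sd_septal_wall_thickness_mm"])
    return row


def analyze_cohort(table: pd.DataFrame, records: list, k_modes: int = 10) -> dict:
    """Analyze an in-memory generated cohort (see synthetic.generate_cohort).

    Computes per-subject geometry and strain peaks, builds the pooled
    shape atlas, runs the mode-wise group comparison, and assembles the
    report tables.  Returns a dict with 'geometry', 'strain_peaks',
    'atlas', 'mode_comparison' and 'tables'.
    """
    geometry_rows, vectors, peak_frames = [], [], []
    for rec in records:
        spec, mesh, truth = rec["spec"], rec["mesh"], rec["truth"]
        geometry_rows.append(subject_geometry_row(
            mesh, truth.volume_ml, spec.bsa_m2, spec.subject_id))
        vectors.append(mesh.shape_vector())
        peak_frames.append(peaks_table(
            analyze_cine(rec["contours"], es_frame=truth.es_frame),
            subject_id=spec.subject_id))
    geometry = pd.DataFrame(geometry_rows)
    strain_peaks = pd.concat(peak_frames, ignore_index=True)
    atlas = build_atlas(np.asarray(vectors), k=k_modes)
    labels = table.set_index("subject_id").loc[geometry["subject_id"], "group"].to_numpy()
    mode_cmp = (compare_modes(atlas.scores, labels)
                if np.unique(labels).size >= 2 else None)
    tables = build_report_tables(table, geometry, mode_cmp, strain_peaks)
    return {"geometry": geometry, "strain_peaks": strain_peaks, "atlas": atlas,
            "mode_comparison": mode_cmp, "tables": tables}


def analyze_cohort_dir(cohort_dir: str | Path, k_modes: int = 10) -> dict:
    """Analyze an on-disk cohort layout (cohort.csv + per-subject files).

    Meshes are re-personalized from each subject's label stack, so this
    exercises the full measurement pipeline rather than generator truth.
    Returns the report tables.
    """
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    template = generate_template()
    geometry_rows, vectors, peak_frames = [], [], []
    for _, row in table.iterrows():
        sdir = cohort_dir / row["subject_id"]
        stack = load_segmentation(sdir / "seg.nii.gz")
        mesh = personalize(stack, template)
        truth = json.loads((sdir / "truth.json").read_text())
        contours = {}
        for f in sorted(sdir.glob("contours_*.json")):
            seq = ContourSequence.from_json(f)
            contours[(seq.level, seq.surface)] = seq
        volume = np.asarray(truth["volume_ml"])
        geometry_rows.append(subject_geometry_row(
            mesh, volume, row["bsa_m2"], row["subject_id"]))
        vectors.append(mesh.shape_vector())
        peak_frames.append(peaks_table(
            analyze_cine(contours, es_frame=int(truth["es_frame"])),
            subject_id=row["subject_id"]))
    geometry = pd.DataFrame(geometry_rows)
    strain_peaks = pd.concat(peak_frames, ignore_index=True)
    atlas = build_atlas(np.asarray(vectors), k=k_modes)
    labels = table["group"].to_numpy()
    mode_cmp = (compare_modes(atlas.scores, labels)
                if np.unique(labels).size >= 2 else None)
    return build_report_tables(table, geometry, mode_cmp, strain_peaks)
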