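"""The eight left-atrial metric categories computed from a label map.

(1) LA chamber volume (ostial-plane exclusion of sleeves), (2-4) AP/ML/SI
maximum-chord diameters from orthogonal slice sweeps, (5) left/right PV
ostial equivalent diameters (side averages, per-vein values retained),
(6) left/right PV inter-ostial angles, (7) LAA volume distal of its ostial
plane, and (8) the LAA ostial equivalent diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AxesFrame,
    Centerline,
    OstialPlane,
    OstiumNotFoundError,
    establish_axes,
    extract_centerline,
    find_ostial_plane,
    ostial_direction,
)
from .labelmap import (
    CANONICAL_SCHEMA,
    LabelMap,
    LabelSchema,
    PV_STRUCTURES,
    postprocess_labels,
    resample_isotropic,
)

__all__ = [
    "MetricReport",
    "chamber_volume",
    "appendage_volume",
    "la_diameters",
    "pv_side_diameters",
    "inter_ostial_angle",
    "laa_ostial_diameter",
    "compute_all_metrics",
]

REPORT_COLUMNS = [
    "la_volume_ml",
    "laa_volume_ml",
    "ap_diameter_mm",
    "ml_diameter_mm",
    "si_diameter_mm",
    "left_pv_diameter_mm",
    "right_pv_diameter_mm",
    "lspv_diameter_mm",
    "lipv_diameter_mm",
    "rspv_diameter_mm",
    "ripv_diameter_mm",
    "left_pv_angle_deg",
    "right_pv_angle_deg",
    "laa_ostial_diameter_mm",
    "flags",
]


@dataclass
class MetricReport:
    """All metric categories for one case, with QC flags and grade inputs.

    ``grade_inputs`` holds the three per-category success booleans used for
    usability grading: (i) LA volume + diameters, (ii) PV ostial sizes +
    configuration (angles), (iii) LAA volume + ostial plane.
    Values that could not be computed are ``None`` and explained by a flag.
    """

    la_volume: float | None = None  # mL
    laa_volume: float | None = None  # mL
    ap_diameter: float | None = None  # mm
    ml_diameter: float | None = None  # mm
    si_diameter: float | None = None  # mm
    left_pv_diameter: float | None = None  # mm, side average
    right_pv_diameter: float | None = None  # mm, side average
    per_vein_diameters: dict[str, float] = field(default_factory=dict)
    left_pv_angle: float | None = None  # degrees
    right_pv_angle: float | None = None  # degrees
    laa_ostial_diameter: float | None = None  # mm
    flags: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    grade_inputs: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "la_volume_ml": self.la_volume,
            "laa_volume_ml": self.laa_volume,
            "ap_diameter_mm": self.ap_diameter,
            "ml_diameter_mm": self.ml_diameter,
            "si_diameter_mm": self.si_diameter,
            "left_pv_diameter_mm": self.left_pv_diameter,
            "right_pv_diameter_mm": self.right_pv_diameter,
            **{f"{v}_diameter_mm": self.per_vein_diameters.get(v) for v in PV_STRUCTURES},
            "left_pv_angle_deg": self.left_pv_angle,
            "right_pv_angle_deg": self.right_pv_angle,
            "laa_ostial_diameter_mm": self.laa_ostial_diameter,
            "flags": list(self.flags),
            "notes": list(self.notes),
            "grade_inputs": dict(self.grade_inputs),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> dict:
        row = self.to_dict()
        row["flags"] = ";".join(self.flags)
        row["notes"] = ";".join(self.notes)
        row.pop("grade_inputs")
        return row


def _half_space_counts(
    lm: LabelMap, code: int, plane: OstialPlane
) -> tuple[int, int]:
    """(proximal, distal) voxel counts of a structure w.r.t. its ostial plane.

    Voxel centers exactly on the plane count as distal (signed distance >= 0).
    """
    pos = lm.structure_positions(code)
    if len(pos) == 0:
        return 0, 0
    d = plane.signed_distance(pos)
    distal = int(np.count_nonzero(d >= 0))
    return len(pos) - distal, distal


def chamber_volume(
    lm: LabelMap,
    pv_planes: dict[str, OstialPlane] | None = None,
    laa_plane: OstialPlane | None = None,
    schema: LabelSchema = CANONICAL_SCHEMA,
    flags: list[str] | None = None,
) -> float:
    """LA cavity volume (mL) by voxel summation with ostial-plane exclusion.

    Counts every LA-labeled voxel plus each sleeve's voxels on the proximal
    (LA) side of that sleeve's own ostial plane.  A sleeve with no plane is
    excluded entirely and a flag is raised.
    """
    la_count = int(np.count_nonzero(lm.voxels == schema["la"]))
    if la_count == 0:
        raise ValueError("LA mask is empty")
    total = la_count
    planes = dict(pv_planes or {})
    if laa_plane is not None:
        planes["laa"] = laa_plane
    for name in (*PV_STRUCTURES, "laa"):
        if name not in schema:
            continue
        code = schema[name]
        if not (lm.voxels == code).any():
            continue
        plane = planes.get(name)
        if plane is None:
            if flags is not None:
                flags.append(f"{name}:no_ostial_plane_structure_excluded_from_la")
            continue
        proximal, _ = _half_space_counts(lm, code, plane)
        total += proximal
    return total * lm.voxel_volume / 1000.0


def appendage_volume(
    lm: LabelMap,
    laa_plane: OstialPlane,
    schema: LabelSchema = CANONICAL_SCHEMA,
) -> float:
    """LAA volume (mL): LAA-labeled voxels distal of the LAA ostial plane."""
    code = schema["laa"]
    if not (lm.voxels == code).any():
        raise ValueError("LAA mask is empty")
    _, distal = _half_space_counts(lm, code, laa_plane)
    return distal * lm.voxel_volume / 1000.0


def _axis_aligned(lm: LabelMap, axes: AxesFrame) -> bool:
    frame = np.column_stack([axes.ml, axes.ap, axes.si])  # grid x, y, z order
    return (
        np.abs(lm.direction - np.eye(3)).max() < 1e-9
        and np.abs(np.abs(frame) - np.eye(3)).max() < 1e-9
    )


def _extent_diameters_grid(mask: np.ndarray, pitch: np.ndarray) -> tuple[float, float, float]:
    """Max first-to-last chord (mm) along grid x, y, z over orthogonal lines.

    The chord spans the outer edges of the first and last labeled sample on
    the line (caliper convention), so a single voxel has a one-voxel chord.
    """
    out = []
    for axis in range(3):
        if not mask.any():
            out.append(0.0)
            continue
        n = mask.shape[axis]
        idx = np.arange(n).reshape([-1 if a == axis else 1 for a in range(3)])
        first = np.where(mask, idx, n).min(axis=axis)
        last = np.where(mask, idx, -1).max(axis=axis)
        extent = (last - first + 1).astype(float) * pitch[axis]
        extent[last < 0] = 0.0
        out.append(float(extent.max()))
    return tuple(out)


def la_diameters(
    lm: LabelMap,
    axes: AxesFrame | None = None,
    schema: LabelSchema = CANONICAL_SCHEMA,
    pitch: float | None = None,
) -> tuple[float, float, float]:
    """(AP, ML, SI) diameters (mm) by slice-sweep maximum chords on the LA.

    Axial slices are swept for the AP and ML chords and sagittal slices for
    the SI chord; each chord is the first-to-last extent of LA samples along
    a scan line parallel to the axis, and the diameter is the maximum across
    slices.  Only the LA label is used (LAA/PV sleeves excluded).  With a
    non-image-aligned frame the mask is first sampled on a grid aligned with
    the anatomical axes.
    """
    mask = lm.voxels == schema["la"]
    if not mask.any():
        raise ValueError("LA mask is empty")
    if axes is None:
        axes = AxesFrame(ap=[0, 1, 0], ml=[1, 0, 0], si=[0, 0, 1])
    if _axis_aligned(lm, axes):
        ml_d, ap_d, si_d = _extent_diameters_grid(mask, lm.spacing)
        return ap_d, ml_d, si_d
    # sample the LA on a frame-aligned grid
    h = pitch if pitch is not None else float(min(lm.spacing))
    pos = lm.structure_positions(schema["la"])
    frame = np.column_stack([axes.ml, axes.ap, axes.si])
    proj = pos @ frame  # coordinates along (ml, ap, si)
    lo, hi = proj.min(axis=0) - h, proj.max(axis=0) + h
    n = np.ceil((hi - lo) / h).astype(int) + 1
    grids = [lo[k] + h * np.arange(n[k]) for k in range(3)]
    gm, ga, gs = np.meshgrid(*grids, indexing="ij")
    pts = (
        gm[..., None] * axes.ml + ga[..., None] * axes.ap + gs[..., None] * axes.si
    )
    sampled = lm.labels_at(pts) == schema["la"]
    ml_d, ap_d, si_d = _extent_diameters_grid(sampled, np.full(3, h))
    return ap_d, ml_d, si_d


def _vein_plane(
    lm: LabelMap,
    vein: str,
    schema: LabelSchema,
    flags: list[str],
) -> tuple[OstialPlane, Centerline]:
    centerline = extract_centerline(lm, vein, schema)
    plane = find_ostial_plane(lm, vein, centerline, schema, flags=flags)
    return plane, centerline


def pv_side_diameters(
    lm: LabelMap,
    schema: LabelSchema = CANONICAL_SCHEMA,
    planes: dict[str, OstialPlane] | None = None,
    flags: list[str] | None = None,
) -> tuple[float | None, float | None, dict[str, float]]:
    """(left mm, right mm, per-vein map) of PV ostial equivalent diameters.

    Side values average the superior and inferior veins; with one vein
    missing the available vein is used and a flag raised; with both missing
    the side is ``None``.
    """
    flags = flags if flags is not None else []
    per_vein: dict[str, float] = {}
    for vein in PV_STRUCTURES:
        if vein not in schema or not (lm.voxels == schema[vein]).any():
            flags.append(f"{vein}:missing")
            continue
        try:
            if planes is not None and vein in planes:
                plane = planes[vein]
            else:
                plane, _ = _vein_plane(lm, vein, schema, flags)
            per_vein[vein] = plane.equivalent_diameter
        except (ValueError, OstiumNotFoundError) as exc:
            flags.append(f"{vein}:ostium_failed:{exc}")

    def side(sup: str, inf: str) -> float | None:
        vals = [per_vein[v] for v in (sup, inf) if v in per_vein]
        if not vals:
            flags.append(f"{sup}/{inf}:side_absent")
            return None
        if len(vals) == 1:
            flags.append(f"{sup}/{inf}:single_vein_side_average")
        return float(np.mean(vals))

    return side("lspv", "lipv"), side("rspv", "ripv"), per_vein


def inter_ostial_angle(dir_superior: np.ndarray, dir_inferior: np.ndarray) -> float:
    """3D angle (degrees, [0, 180]) between two distally oriented unit vectors."""
    a = np.asarray(dir_superior, dtype=float)
    b = np.asarray(dir_inferior, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero direction vector")
    return float(np.degrees(np.arccos(np.clip((a @ b) / (na * nb), -1.0, 1.0))))


def laa_ostial_diameter(
    lm: LabelMap,
    schema: LabelSchema = CANONICAL_SCHEMA,
    flags: list[str] | None = None,
) -> float:
    """Equivalent diameter (mm) of the minimal-area LAA ostial plane."""
    plane, _ = _vein_plane(lm, "laa", schema, flags if flags is not None else [])
    return plane.equivalent_diameter


def compute_all_metrics(
    labelmap: LabelMap,
    annulus_points: np.ndarray | None = None,
    schema: LabelSchema = CANONICAL_SCHEMA,
    target_spacing: float = 0.5,
    postprocess: bool = True,
) -> MetricReport:
    """Run the full pipeline and return a :class:`MetricReport`.

    Resampling to isotropic ``target_spacing`` → label cleanup → axes →
    centerlines → ostial planes → all eight metric categories.  Partial
    failures degrade to flags and absent values; only an empty LA aborts.
    """
    lm = resample_isotropic(labelmap, target_spacing)
    if postprocess:
        lm = postprocess_labels(lm)
    if not (lm.voxels == schema["la"]).any():
        raise ValueError("LA mask is empty")

    report = MetricReport()
    flags = report.flags
    axes = establish_axes(lm, annulus_points, schema)

    planes: dict[str, OstialPlane] = {}
    directions: dict[str, np.ndarray] = {}
    for name in (*PV_STRUCTURES, "laa"):
        if name not in schema or not (lm.voxels == schema[name]).any():
            flags.append(f"{name}:missing")
            continue
        try:
            plane, centerline = _vein_plane(lm, name, schema, flags)
            planes[name] = plane
            # a proximal arm clamped at the junction is expected anatomy,
            # recorded as a note rather than a QC flag
            directions[name] = ostial_direction(centerline, plane, flags=report.notes)
        except (ValueError, OstiumNotFoundError) as exc:
            flags.append(f"{name}:ostium_failed:{exc}")

    pv_planes = {k: v for k, v in planes.items() if k != "laa"}
    laa_plane = planes.get("laa")

    report.la_volume = chamber_volume(lm, pv_planes, laa_plane, schema, flags)
    report.ap_diameter, report.ml_diameter, report.si_diameter = la_diameters(
        lm, axes, schema
    )

    left, right, per_vein = pv_side_diameters(lm, schema, planes=planes, flags=flags)
    report.left_pv_diameter, report.right_pv_diameter = left, right
    report.per_vein_diameters = per_vein

    for side, sup, inf in (("left", "lspv", "lipv"), ("right", "rspv", "ripv")):
        if sup in directions and inf in directions:
            angle = inter_ostial_angle(directions[sup], directions[inf])
            setattr(report, f"{side}_pv_angle", angle)
        else:
            flags.append(f"{side}_pv_angle:absent")

    if laa_plane is not None:
        report.laa_ostial_diameter = laa_plane.equivalent_diameter
        report.laa_volume = appendage_volume(lm, laa_plane, schema)

    report.grade_inputs = {
        "la_volume_diameters": all(
            v is not None
            for v in (
                report.la_volume,
                report.ap_diameter,
                report.ml_diameter,
                report.si_diameter,
            )
        ),
        "pv_ostia_configuration": all(
            v is not None
            for v in (
                report.left_pv_diameter,
                report.right_pv_diameter,
                report.left_pv_angle,
                report.right_pv_angle,
            )
        ),
        "laa_volume_ostium": all(
            v is not None for v in (report.laa_volume, report.laa_ostial_diameter)
        ),
    }
    report.flags = list(dict.fromkeys(report.flags))
    report.notes = list(dict.fromkeys(report.notes))
    return report
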