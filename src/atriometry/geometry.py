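"""Geometric primitives for ostial quantification on label maps.

Centerlines through venous sleeves, LA junction localization, planar
cross-sections, the minimal-area ostial-plane search, flow-oriented direction
vectors, and anatomical axes.  Everything operates in physical mm coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as cc_label

from .labelmap import CANONICAL_SCHEMA, LabelMap, LabelSchema

__all__ = [
    "Centerline",
    "OstialPlane",
    "AxesFrame",
    "OstiumNotFoundError",
    "extract_centerline",
    "find_junction_point",
    "planar_cross_section",
    "find_ostial_plane",
    "ostial_direction",
    "equivalent_diameter",
    "establish_axes",
]


class OstiumNotFoundError(RuntimeError):
    """No candidate cross-section intersected both the structure and the LA."""


@dataclass
class Centerline:
    """Ordered, arc-length-parameterized polyline through a tubular structure.

    Points run from the LA-facing end to the distal tip, at steps of at most
    0.5 mm of arc length.
    """

    points: np.ndarray  # (n, 3) mm
    arclength: np.ndarray  # (n,) cumulative mm, strictly increasing
    structure: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if not np.all(np.diff(self.arclength) > 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of the polyline at arc length ``s`` (clamped)."""
        s = float(np.clip(s, self.arclength[0], self.arclength[-1]))
        return np.array(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float, window: float = 1.0) -> np.ndarray:
        """Unit tangent from a centered chord of half-width ``window`` mm."""
        lo = self.point_at(s - window)
        hi = self.point_at(s + window)
        d = hi - lo
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("degenerate tangent")
        return d / n

    def nearest_arclength(self, point: np.ndarray) -> float:
        """Arc length of the polyline vertex closest to ``point``."""
        i = int(np.argmin(np.linalg.norm(self.points - np.asarray(point), axis=1)))
        return float(self.arclength[i])


@dataclass
class OstialPlane:
    """Minimal-area cross-section at an LA-PV or LA-LAA junction."""

    center: np.ndarray  # mm
    normal: np.ndarray  # unit, oriented distally (away from the LA)
    area: float  # mm^2
    equivalent_diameter: float  # mm
    junction_offset: float  # signed arc length from the junction, mm
    structure: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n
        expected = 2.0 * np.sqrt(self.area / np.pi)
        if abs(self.equivalent_diameter - expected) > 1e-9:
            raise ValueError("equivalent_diameter inconsistent with area")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed mm distance of points from the plane; positive = distal."""
        return (np.asarray(points) - self.center) @ self.normal


@dataclass
class AxesFrame:
    """Orthonormal right-handed anatomical axes (AP, ML, SI) in patient mm."""

    ap: np.ndarray
    ml: np.ndarray
    si: np.ndarray
    source: str = "image-axes"

    def __post_init__(self) -> None:
        for name in ("ap", "ml", "si"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v / np.linalg.norm(v))
        if max(
            abs(self.ap @ self.ml), abs(self.ap @ self.si), abs(self.ml @ self.si)
        ) >= 1e-9:
            raise ValueError("axes must be pairwise orthogonal")


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the same area: ``2*sqrt(area/pi)``."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * np.sqrt(area / np.pi)


# six face-neighbor structuring element
_CONN6 = ndimage.generate_binary_structure(3, 1)
_CONN26 = np.ones((3, 3, 3), dtype=bool)

# positive-half 26-neighborhood offsets for graph construction
_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _interface_mask(labelmap: LabelMap, structure_code: int, la_code: int) -> np.ndarray:
    """Structure voxels sharing a face with an LA voxel."""
    la_dilated = ndimage.binary_dilation(labelmap.voxels == la_code, structure=_CONN6)
    return (labelmap.voxels == structure_code) & la_dilated


def find_junction_point(
    labelmap: LabelMap,
    structure: str,
    schema: LabelSchema = CANONICAL_SCHEMA,
    flags: list[str] | None = None,
) -> np.ndarray:
    """Centroid (mm) of the structure voxels face-adjacent to the LA.

    If the adjacency interface splits into several 26-connected patches, the
    largest patch is used and a QC flag is appended to ``flags``.
    """
    schema.require("la", structure)
    iface = _interface_mask(labelmap, schema[structure], schema["la"])
    if not iface.any():
        raise ValueError(f"structure '{structure}' has no adjacency with the LA")
    labeled, n = ndimage.label(iface, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(iface, labeled, index=np.arange(1, n + 1))
        iface = labeled == (1 + int(np.argmax(sizes)))
        if flags is not None:
            flags.append(f"{structure}:junction_interface_multiple_patches")
    pos = labelmap.index_to_physical(np.argwhere(iface))
    return pos.mean(axis=0)


def _geodesic_distances(
    labelmap: LabelMap, mask: np.ndarray, sources: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source geodesic distance through ``mask`` (26-connectivity).

    Returns (coords, dist): integer voxel coords of the mask, and the minimal
    physical path length (mm) from any source voxel, in the same order.
    """
    coords = np.argwhere(mask)
    n = len(coords)
    idmap = np.full(mask.shape, -1, dtype=np.int64)
    idmap[tuple(coords.T)] = np.arange(n)
    rows, cols, weights = [], [], []
    spacing = labelmap.spacing
    for off in _OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        nb_id = np.full(n, -1, dtype=np.int64)
        nb_id[ok] = idmap[tuple(nb[ok].T)]
        valid = nb_id >= 0
        rows.append(np.flatnonzero(valid))
        cols.append(nb_id[valid])
        weights.append(
            np.full(valid.sum(), np.linalg.norm(np.asarray(off) * spacing))
        )
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    src_ids = idmap[tuple(sources.T)]
    src_ids = src_ids[src_ids >= 0]
    dist = dijkstra(graph, directed=False, indices=src_ids, min_only=True)
    return coords, dist


def _moving_average(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of a polyline; endpoints are pinned."""
    if len(points) <= window:
        return points
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(points[:, k], kernel, mode="same") for k in range(3)]
    )
    half = window // 2
    sm[:half] = points[:half]
    sm[-half:] = points[-half:]
    return sm


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    points = points[keep]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    total = s[-1]
    new_s = np.arange(0.0, total, step)
    if total - new_s[-1] > 1e-9:
        new_s = np.append(new_s, total)
    new_pts = np.column_stack(
        [np.interp(new_s, s, points[:, k]) for k in range(3)]
    )
    return new_pts, new_s


def extract_centerline(
    labelmap: LabelMap,
    structure: str,
    schema: LabelSchema = CANONICAL_SCHEMA,
    step: float = 0.5,
    bin_width: float = 1.0,
) -> Centerline:
    """Centerline of a tubular structure, from its LA-facing end to its tip.

    Construction: geodesic distance from the LA-adjacency interface is
    propagated through the structure mask (26-connectivity, physical edge
    lengths); voxels are then grouped into ``bin_width`` arc-length slabs and
    each slab's medialness-weighted centroid (weight = squared distance to
    the structure boundary) becomes a polyline vertex.  The weighting keeps
    vertices on the lumen axis even where the sleeve base hugs the chamber
    wall asymmetrically.  The polyline is anchored at the interface centroid,
    moving-average smoothed (window 5) and resampled at ``step`` mm.
    """
    schema.require("la", structure)
    mask = labelmap.voxels == schema[structure]
    if not mask.any():
        raise ValueError(f"structure '{structure}' is empty")
    labeled, ncc = ndimage.label(mask, structure=_CONN26)
    if ncc > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, ncc + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
        warnings.warn(
            f"structure '{structure}' has {ncc} components; using largest",
            stacklevel=2,
        )
    iface = _interface_mask(labelmap, schema[structure], schema["la"]) & mask
    if not iface.any():
        raise ValueError(f"structure '{structure}' has no interface with the LA")
    coords, dist = _geodesic_distances(labelmap, mask, np.argwhere(iface))
    finite = np.isfinite(dist)
    coords, dist = coords[finite], dist[finite]
    positions = labelmap.index_to_physical(coords)
    medial = ndimage.distance_transform_edt(mask, sampling=labelmap.spacing)
    weights = medial[tuple(coords.T)] ** 2

    # weighted slab centroids; the last slab anchors the distal tip (the set
    # of geodesically farthest voxels is the whole end cap, so any single
    # argmax voxel would sit on the cap rim, off-axis)
    bins = np.floor(dist / bin_width).astype(int)
    verts = []
    for b in np.unique(bins):
        sel = bins == b
        w = weights[sel]
        if w.sum() <= 0:
            w = np.ones_like(w)
        verts.append(np.average(positions[sel], axis=0, weights=w))
    poly = np.asarray(verts)
    # The slab touching the junction is contaminated by the sleeve base
    # hugging the chamber wall asymmetrically, and resampling leaves a
    # voxel-scale stair wave on the others.  The ostial region is therefore
    # modeled as locally straight: a total-least-squares line is fitted
    # through the first ~10 mm of clean slabs, the proximal vertices are
    # projected onto it, and it is extended back to the interface's axial
    # position so the polyline reaches the junction.
    if len(poly) >= 4:
        fit = poly[1 : min(11, len(poly) - 1)]
        center = fit.mean(axis=0)
        u = np.linalg.svd(fit - center, full_matrices=False)[2][0]
        if (poly[-1] - poly[0]) @ u < 0:
            u = -u
        j0 = labelmap.index_to_physical(np.argwhere(iface)).mean(axis=0)

        def on_line(p):
            return center + ((p - center) @ u) * u

        n_straight = min(7, len(poly))
        poly[:n_straight] = [on_line(p) for p in poly[:n_straight]]
        anchor = on_line(j0)
        if (poly[0] - anchor) @ u > 1e-6:
            poly = np.vstack([anchor, poly])
    poly = _moving_average(poly, window=5)
    pts, s = _resample_polyline(poly, step)
    if len(pts) < 3:
        raise ValueError(f"structure '{structure}' too short for a centerline")
    return Centerline(points=pts, arclength=s, structure=structure)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    normal = np.asarray(normal, dtype=float)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _section_labels(
    labelmap: LabelMap,
    center: np.ndarray,
    normal: np.ndarray,
    pitch: float,
    radius: float,
) -> np.ndarray:
    """Nearest-neighbor label samples on a square in-plane grid (2D array)."""
    u, v = _plane_basis(normal)
    ticks = np.arange(-radius, radius + pitch / 2, pitch)
    uu, vv = np.meshgrid(ticks, ticks, indexing="ij")
    pts = center + uu[..., None] * u + vv[..., None] * v
    return labelmap.labels_at(pts)


def _region_area(
    samples: np.ndarray,
    codes: set[int],
    pitch: float,
    snap_radius: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Area of the 8-connected in-plane region at the grid center.

    If the exact center sample is unlabeled, the region owning the nearest
    labeled sample within ``snap_radius`` mm is used; 0 if none.
    Returns (area mm^2, boolean mask of that region).
    """
    inside = np.isin(samples, list(codes))
    empty = np.zeros_like(inside)
    if not inside.any():
        return 0.0, empty
    cc = cc_label(inside, connectivity=2)
    ci = samples.shape[0] // 2
    if inside[ci, ci]:
        rid = cc[ci, ci]
    else:
        lab = np.argwhere(inside)
        d = np.linalg.norm((lab - [ci, ci]) * pitch, axis=1)
        k = int(np.argmin(d))
        if d[k] > snap_radius:
            return 0.0, empty
        rid = cc[lab[k, 0], lab[k, 1]]
    region = cc == rid
    return float(region.sum()) * pitch * pitch, region


def planar_cross_section(
    labelmap: LabelMap,
    center: np.ndarray,
    normal: np.ndarray,
    labels: set[str] | tuple[str, ...],
    schema: LabelSchema = CANONICAL_SCHEMA,
    pitch: float = 0.25,
    radius: float = 30.0,
) -> float:
    """Cross-section area (mm^2) of the given labels in the plane at ``center``.

    The plane is sampled on a grid of ``pitch`` mm within ``radius`` mm of the
    center; the area is that of the 8-connected component of the union of
    labels containing (or nearest within 2 mm to) the center.
    """
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("zero normal vector")
    samples = _section_labels(labelmap, np.asarray(center, float), normal / nn, pitch, radius)
    codes = {schema[name] for name in labels}
    area, _ = _region_area(samples, codes, pitch)
    return area


def find_ostial_plane(
    labelmap: LabelMap,
    structure: str,
    centerline: Centerline,
    schema: LabelSchema = CANONICAL_SCHEMA,
    search_halfwidth: float = 5.0,
    step: float = 0.5,
    pitch: float = 0.25,
    radius: float = 30.0,
    flags: list[str] | None = None,
) -> OstialPlane:
    """Minimal-area cross-section within ±5 mm (arc length) of the junction.

    Candidate planes are centered on centerline points within
    ``search_halfwidth`` mm of the junction's centerline projection, stepped at
    ``step`` mm, each orthogonal to the local centerline tangent.  A candidate
    is retained only if its sampled window intersects voxels of both the
    structure and the LA; among retained candidates the minimal enclosed area
    wins.  Because the cross-section of a voxelized lumen oscillates by about
    one half-voxel times its perimeter depending on where the plane slices the
    voxel rows, areas within ``sqrt(pi*A_min)*h`` of the minimum (h = mean
    voxel size) are treated as ties, and the tie goes to the smallest
    |junction offset| — anchoring the plane to the anatomic junction instead
    of letting it drift along a uniform vessel.  The returned normal points
    distally.  A topology flag is raised when the structure's in-plane
    footprint is not a single 8-connected component.
    """
    schema.require("la", structure)
    junction = find_junction_point(labelmap, structure, schema, flags=flags)
    s_j = centerline.nearest_arclength(junction)
    la_code, st_code = schema["la"], schema[structure]

    offsets = np.arange(-search_halfwidth, search_halfwidth + step / 2, step)
    candidates = []
    for off in offsets:
        s = s_j + off
        if s < centerline.arclength[0] or s > centerline.arclength[-1]:
            continue
        center = centerline.point_at(s)
        tangent = centerline.tangent_at(s)
        samples = _section_labels(labelmap, center, tangent, pitch, radius)
        # intersects-both-labels is tested on a slab just over one voxel
        # thick: an infinitely thin plane through a voxel-face boundary is
        # ambiguous on a categorical grid
        half_slab = 0.6 * float(np.mean(labelmap.spacing))
        slab = [samples] + [
            _section_labels(labelmap, center + d * tangent, tangent, pitch, radius)
            for d in (-half_slab, half_slab)
        ]
        if not (
            any((sl == st_code).any() for sl in slab)
            and any((sl == la_code).any() for sl in slab)
        ):
            continue
        area, _ = _region_area(samples, {la_code, st_code}, pitch)
        if area <= 0:
            continue
        n_st_cc = int(cc_label(samples == st_code, connectivity=2).max())
        candidates.append((area, abs(off), off, center, tangent, n_st_cc))
    if not candidates:
        raise OstiumNotFoundError(
            f"no cross-section of '{structure}' intersected both labels "
            f"within ±{search_halfwidth} mm of the junction"
        )
    amin = min(c[0] for c in candidates)
    tie_tol = np.sqrt(np.pi * amin) * float(np.mean(labelmap.spacing))
    ties = [c for c in candidates if c[0] <= amin + tie_tol]
    area, _, off, center, tangent, n_st_cc = min(ties, key=lambda c: c[1])
    # place the cut at the proximal face of the winning voxel layer: a plane
    # through the layer's centers makes center-based half-space assignment
    # depend on grid obliquity, a half-voxel proximal shift does not
    half_voxel = 0.5 * float(np.mean(labelmap.spacing))
    center = center - half_voxel * tangent
    off = max(-search_halfwidth, off - half_voxel)
    if n_st_cc > 1 and flags is not None:
        flags.append(f"{structure}:ostial_section_multiple_components")
    return OstialPlane(
        center=center,
        normal=tangent,
        area=area,
        equivalent_diameter=equivalent_diameter(area),
        junction_offset=float(off),
        structure=structure,
    )


def ostial_direction(
    centerline: Centerline,
    plane: OstialPlane,
    arm: float = 5.0,
    flags: list[str] | None = None,
) -> np.ndarray:
    """Flow-oriented unit vector at the ostium.

    The direction of the centerline segment from ``arm`` mm proximal to
    ``arm`` mm distal of the ostial plane (along arc length), oriented
    distally.  It is estimated as the total-least-squares line through the
    window's polyline points — identical to the chord between the ±``arm``
    endpoints for a straight segment, but insensitive to voxel-scale
    jitter of any single point.  The proximal arm is clamped to the
    centerline start (with a flag) if shorter; a distal arm shorter than
    ``arm`` mm is an error.
    """
    s_p = centerline.nearest_arclength(plane.center)
    if centerline.length - s_p < arm - 1e-6:
        raise ValueError(
            f"centerline extends only {centerline.length - s_p:.1f} mm distal "
            f"of the ostial plane (need {arm} mm)"
        )
    s_prox = s_p - arm
    if s_prox < centerline.arclength[0]:
        s_prox = float(centerline.arclength[0])
        if flags is not None:
            flags.append(f"{centerline.structure}:proximal_arm_clamped")
    sel = (centerline.arclength >= s_prox - 1e-9) & (
        centerline.arclength <= s_p + arm + 1e-9
    )
    pts = centerline.points[sel]
    if len(pts) < 3:
        d = centerline.point_at(s_p + arm) - centerline.point_at(s_prox)
        return d / np.linalg.norm(d)
    u = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)[2][0]
    if (pts[-1] - pts[0]) @ u < 0:
        u = -u
    return u


def establish_axes(
    labelmap: LabelMap,
    annulus_points: np.ndarray | None = None,
    schema: LabelSchema = CANONICAL_SCHEMA,
) -> AxesFrame:
    """Anatomical AP/ML/SI axes, from image axes or a mitral-annulus ring.

    Without landmarks the patient image axes are used directly (LPS: ML = +x,
    AP = +y, SI = +z).  With ≥3 non-collinear annulus points, the basal plane
    is the least-squares plane through them; SI is its normal oriented toward
    the LA centroid, AP is the projection of the image AP axis onto the plane,
    and ML completes the right-handed frame.
    """
    if annulus_points is None:
        return AxesFrame(
            ap=np.array([0.0, 1.0, 0.0]),
            ml=np.array([1.0, 0.0, 0.0]),
            si=np.array([0.0, 0.0, 1.0]),
            source="image-axes",
        )
    pts = np.asarray(annulus_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 annulus points of dimension 3")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("annulus points are collinear")
    normal = vt[2]
    la_centroid = labelmap.structure_positions(schema["la"]).mean(axis=0)
    if (la_centroid - pts.mean(axis=0)) @ normal < 0:
        normal = -normal
    si = normal / np.linalg.norm(normal)
    ap_img = np.array([0.0, 1.0, 0.0])
    ap = ap_img - (ap_img @ si) * si
    if np.linalg.norm(ap) < 1e-9:
        raise ValueError("basal plane is orthogonal to the AP image axis")
    ap /= np.linalg.norm(ap)
    ml = np.cross(ap, si)
    return AxesFrame(ap=ap, ml=ml, si=si, source="annulus-plane")
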