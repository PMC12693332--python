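"""Landmark-driven scar quantification.

Two complementary geometries are built on every quantified slice:

* the **AHA 16-segment partition** — slices are grouped into base, mid
  and apex levels; base/mid slices are split into 6 angular sectors and
  apical slices into 4, anchored on the two RV insertion landmarks; the
  per-segment scar extent is the scar pixel percentage of each segment;
* the **100-chord centerline analysis** — each slice is partitioned into
  100 chords perpendicular to a centerline equidistant between the
  endocardial and epicardial contours; scar transmurality is the scar
  fraction of the wall thickness along each chord.

Angular conventions
-------------------
Angles are measured about the per-slice LV centroid (endocardial contour
centroid) with ``theta = atan2(y - cy, x - cx)`` in degrees, normalized
to [0, 360); "counterclockwise" means increasing ``theta`` in this
(x=col, y=row) frame.  Sector boundaries and chord 1 are anchored at the
anterior RV insertion ray; a pixel or chord exactly on a boundary angle
belongs to the counterclockwise-following sector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LinearRing, LineString

from .imaging_io import (
    ContourSet,
    GeometryError,
    ImageGeometry,
    LandmarkPair,
    LandmarkSet,
    MyocardiumMask,
    polygon_centroid,
)
from .scar_detect import ContainmentError, ScarMask

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_CM3",
    "LEVELS",
    "Chord",
    "ChordSet",
    "TransmuralityProfile",
    "SegmentMap",
    "SegmentExtent",
    "ScarMetrics",
    "SectorLayout",
    "assign_levels",
    "sector_boundaries",
    "build_segment_map",
    "segment_extent",
    "build_centerline_chords",
    "chord_transmurality",
    "global_metrics",
]

#: Conventional myocardial tissue density used to convert volume to mass.
MYOCARDIAL_DENSITY_G_PER_CM3 = 1.05

LEVELS = ("base", "mid", "apex")

# AHA labels in counterclockwise order starting at the anterior-insertion ray.
# Walking CCW from the anterior insertion crosses the septum first:
# anteroseptal, inferoseptal, then inferior, inferolateral, anterolateral,
# anterior.  Apex: septal, inferior, lateral, anterior.
_LABELS_CCW = {
    "base": (2, 3, 4, 5, 6, 1),
    "mid": (8, 9, 10, 11, 12, 7),
    "apex": (14, 15, 16, 13),
}


class LevelAssignmentError(ValueError):
    """Too few usable slices to split into base / mid / apex."""


def _angle_deg(point, center) -> float:
    return float(np.degrees(np.arctan2(point[1] - center[1], point[0] - center[0]))) % 360.0


# ---------------------------------------------------------------------------
# anatomical levels
# ---------------------------------------------------------------------------


def assign_levels(
    myo: MyocardiumMask,
    override: Optional[dict] = None,
    basal_first: bool = True,
) -> dict:
    """Map each myocardium-bearing slice index to ``base``/``mid``/``apex``.

    Slices are split into three contiguous index groups by terciles, the
    remainder distributed base-first (10 slices -> 4 base, 3 mid, 3
    apex).  ``basal_first`` states that the lowest indices are basal;
    flip it for stacks ordered apex-to-base.  ``override`` is a
    slice->level dict used verbatim.
    """
    usable = [i for i in range(myo.geometry.n_slices) if myo.data[i].any()]
    if override is not None:
        bad = {v for v in override.values()} - set(LEVELS)
        if bad:
            raise LevelAssignmentError(f"unknown level names in override: {bad}")
        return {int(k): v for k, v in override.items()}
    n = len(usable)
    if n < 3:
        raise LevelAssignmentError(f"need >= 3 slices containing myocardium, got {n}")
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    order = LEVELS if basal_first else LEVELS[::-1]
    out: dict = {}
    pos = 0
    for level, size in zip(order, sizes):
        for i in usable[pos:pos + size]:
            out[i] = level
        pos += size
    return out


# ---------------------------------------------------------------------------
# sectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorLayout:
    """Ordered sector boundary angles (degrees, CCW from the anterior ray)
    and the AHA label of the sector starting at each boundary."""

    boundaries_deg: tuple
    labels: tuple
    level: str

    def sector_of_angle(self, theta_deg) -> np.ndarray:
        """AHA label for each angle; boundary angles go to the CCW-following
        sector."""
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float)) % 360.0
        start = self.boundaries_deg[0]
        rel = (theta - start) % 360.0
        rel_bounds = (np.asarray(self.boundaries_deg) - start) % 360.0
        idx = np.searchsorted(rel_bounds, rel, side="right") - 1
        return np.asarray(self.labels)[idx]


def sector_boundaries(
    landmarks: LandmarkPair,
    centroid: tuple[float, float],
    level: str,
) -> SectorLayout:
    """Angular sector boundaries for one slice from the RV insertion points.

    Base/mid (6 sectors): the two landmark rays bound the septal arc,
    whose bisector is the midline splitting it into two sectors; the
    complementary arc is split into four equal sectors.  Apex
    (4 sectors): the two landmark rays together with their reversals
    (the direction vectors from each landmark to the centroid, reversed)
    bound septal, inferior, lateral and anterior sectors.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    a1 = _angle_deg(landmarks.anterior, centroid)
    a2 = _angle_deg(landmarks.inferior, centroid)
    if abs((a1 - a2) % 360.0) < 1e-9:
        raise GeometryError("landmarks subtend a zero angle at the centroid")
    septal = (a2 - a1) % 360.0  # CCW width of the septal arc
    if level in ("base", "mid"):
        mid = a1 + septal / 2.0
        free = 360.0 - septal
        bounds = [a1, mid, a2, a2 + free / 4.0, a2 + free / 2.0, a2 + 3.0 * free / 4.0]
    else:
        bounds = [a1, a2, a1 + 180.0, a2 + 180.0]
    bounds = tuple(float(b % 360.0) for b in bounds)
    return SectorLayout(bounds, _LABELS_CCW[level], level)


@dataclass
class SegmentMap:
    """Per-pixel AHA segment labels (0 = none) plus per-slice metadata."""

    labels: np.ndarray  # int16 (n_slices, rows, cols)
    levels: dict  # slice -> level
    layouts: dict  # slice -> SectorLayout
    centroids: dict  # slice -> (cx, cy)
    geometry: ImageGeometry


def build_segment_map(
    myo: MyocardiumMask,
    contours: ContourSet,
    landmarks: LandmarkSet,
    levels: Optional[dict] = None,
) -> SegmentMap:
    """Assign every myocardial pixel to its AHA segment.

    The per-slice LV centroid is the endocardial-contour centroid;
    landmarks missing on a slice are propagated from the nearest slice
    that has them.
    """
    g = myo.geometry
    if levels is None:
        levels = assign_levels(myo)
    labels = np.zeros((g.n_slices, g.rows, g.cols), dtype=np.int16)
    layouts: dict = {}
    centroids: dict = {}
    xs, ys = np.meshgrid(np.arange(g.cols, dtype=float), np.arange(g.rows, dtype=float))
    for i, level in sorted(levels.items()):
        if contours.endo[i] is None:
            raise GeometryError(f"slice {i} is quantified but has no contours")
        cx, cy = polygon_centroid(contours.endo[i])
        layout = sector_boundaries(landmarks.nearest(i), (cx, cy), level)
        wall = myo.data[i]
        theta = np.degrees(np.arctan2(ys[wall] - cy, xs[wall] - cx)) % 360.0
        labels[i][wall] = layout.sector_of_angle(theta)
        layouts[i] = layout
        centroids[i] = (cx, cy)
    return SegmentMap(labels, dict(levels), layouts, centroids, g)


@dataclass
class SegmentExtent:
    """Per-segment scar percentage with the pixel counts behind it.

    Segments absent from the quantified stack (zero myocardial pixels)
    are missing from the dicts rather than reported as 0.
    """

    percent: dict  # segment -> % in [0, 100]
    scar_px: dict
    total_px: dict

    def to_rows(self) -> list[dict]:
        return [
            {"segment": s, "percent": self.percent[s],
             "scar_px": self.scar_px[s], "total_px": self.total_px[s]}
            for s in sorted(self.percent)
        ]


def segment_extent(scar: ScarMask, segmap: SegmentMap) -> SegmentExtent:
    """Scar pixel percentage per AHA segment."""
    if scar.geometry != segmap.geometry:
        raise GeometryError("scar mask and segment map geometries differ")
    if (scar.data & (segmap.labels == 0)).any():
        raise ContainmentError("scar mask has pixels outside the segmented myocardium")
    percent: dict = {}
    scar_px: dict = {}
    total_px: dict = {}
    for s in range(1, 17):
        sel = segmap.labels == s
        total = int(sel.sum())
        if total == 0:
            continue
        n_scar = int((scar.data & sel).sum())
        percent[s] = 100.0 * n_scar / total
        scar_px[s] = n_scar
        total_px[s] = total
    return SegmentExtent(percent, scar_px, total_px)


# ---------------------------------------------------------------------------
# chords
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chord:
    """One wall-crossing chord of the centerline analysis."""

    angle_deg: float
    center: tuple[float, float]  # centerline point (x, y)
    direction: tuple[float, float]  # outward unit vector, perpendicular to the centerline
    endo_point: tuple[float, float]
    epi_point: tuple[float, float]
    thickness_mm: float


@dataclass
class ChordSet:
    """Exactly ``n`` ordered chords per quantified slice."""

    chords: dict  # slice -> list[Chord]
    n: int = 100

    def __post_init__(self) -> None:
        for i, ch in self.chords.items():
            if len(ch) != self.n:
                raise GeometryError(f"slice {i}: expected {self.n} chords, got {len(ch)}")


def _ring_hits(ring: LinearRing, origin: np.ndarray, direction: np.ndarray, reach: float):
    """Intersection distances (>0) of a ray with a contour ring, sorted."""
    end = origin + direction * reach
    inter = LineString([tuple(origin), tuple(end)]).intersection(ring)
    if inter.is_empty:
        return []
    if inter.geom_type == "Point":
        pts = [inter]
    elif hasattr(inter, "geoms"):
        pts = [p for p in inter.geoms if p.geom_type == "Point"]
    else:
        pts = []
    dists = []
    for p in pts:
        v = np.array([p.x, p.y]) - origin
        t = float(v @ direction)
        if t > 1e-9:
            dists.append((t, (p.x, p.y)))
    return sorted(dists)


def build_centerline_chords(
    contours: ContourSet,
    landmarks: LandmarkSet,
    geometry: ImageGeometry,
    slices: Optional[Sequence[int]] = None,
    n: int = 100,
) -> ChordSet:
    """Build 100 centerline chords per slice.

    The centerline is sampled at ``n`` angles equally spaced about the LV
    centroid, starting at the anterior-insertion ray and proceeding
    counterclockwise; the point at each angle is the midpoint of the
    endocardial and epicardial ray intersections.  Each chord passes
    through its centerline point perpendicular to the local centerline
    tangent (central difference over the cyclic neighbors) and extends
    inward to the endocardium and outward to the epicardium; thickness is
    the endo-epi distance scaled by the in-plane spacing.
    """
    if slices is None:
        slices = contours.slices_with_contours()
    spacing = float(np.mean(geometry.in_plane_spacing_mm))
    reach = 2.0 * float(np.hypot(geometry.rows, geometry.cols))
    out: dict = {}
    for i in slices:
        endo_poly, epi_poly = contours.endo[i], contours.epi[i]
        if endo_poly is None:
            raise GeometryError(f"slice {i} has no contours for chord construction")
        endo_ring, epi_ring = LinearRing(endo_poly), LinearRing(epi_poly)
        c = np.array(polygon_centroid(endo_poly))
        a1 = _angle_deg(landmarks.nearest(i).anterior, c)
        angles = (a1 + 360.0 * np.arange(n) / n) % 360.0
        centers = np.empty((n, 2))
        for k, ang in enumerate(angles):
            d = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
            hit_endo = _ring_hits(endo_ring, c, d, reach)
            hit_epi = _ring_hits(epi_ring, c, d, reach)
            if not hit_endo or not hit_epi:
                raise GeometryError(f"slice {i}: ray at {ang:.2f} deg misses a contour")
            centers[k] = (np.array(hit_endo[0][1]) + np.array(hit_epi[0][1])) / 2.0
        chords = []
        for k, ang in enumerate(angles):
            tang = centers[(k + 1) % n] - centers[(k - 1) % n]
            tn = np.linalg.norm(tang)
            if tn < 1e-12:
                raise GeometryError(f"slice {i}: degenerate centerline tangent at chord {k}")
            normal = np.array([-tang[1], tang[0]]) / tn
            radial = centers[k] - c
            if normal @ radial < 0:
                normal = -normal
            hit_endo = _ring_hits(endo_ring, centers[k], -normal, reach)
            hit_epi = _ring_hits(epi_ring, centers[k], normal, reach)
            if not hit_endo or not hit_epi:
                raise GeometryError(f"slice {i}: chord at {ang:.2f} deg misses a contour")
            p_endo = np.array(hit_endo[0][1])
            p_epi = np.array(hit_epi[0][1])
            thickness = float(np.linalg.norm(p_epi - p_endo)) * spacing
            if thickness <= 0:
                raise GeometryError(f"slice {i}: non-positive wall thickness at chord {k}")
            chords.append(
                Chord(float(ang), tuple(centers[k]), tuple(normal),
                      tuple(p_endo), tuple(p_epi), thickness)
            )
        out[i] = chords
    return ChordSet(out, n=n)


@dataclass
class TransmuralityProfile:
    """Per-chord transmurality in [0, 1] with per-slice summaries."""

    values: dict  # slice -> np.ndarray of len n
    slice_mean: dict
    slice_max: dict

    def all_values(self) -> np.ndarray:
        if not self.values:
            return np.zeros(0)
        return np.concatenate([self.values[i] for i in sorted(self.values)])


def chord_transmurality(
    scar: ScarMask,
    chords: ChordSet,
    myo: Optional[MyocardiumMask] = None,
    step_px: float = 0.25,
) -> TransmuralityProfile:
    """Scar fraction of the wall along every chord.

    Each chord is sampled from its endocardial to its epicardial
    intersection at ``step_px`` sub-pixel steps with nearest-pixel mask
    lookup.  Transmurality is the ratio of scar samples to wall samples
    (the scar thickness over the wall thickness along the path); when no
    myocardium mask is supplied every sample counts as wall.  Values are
    clamped to [0, 1].
    """
    g = scar.geometry
    values: dict = {}
    for i, chs in chords.chords.items():
        vals = np.empty(len(chs))
        for k, ch in enumerate(chs):
            p0, p1 = np.array(ch.endo_point), np.array(ch.epi_point)
            length = np.linalg.norm(p1 - p0)
            m = max(int(np.ceil(length / step_px)), 1) + 1
            ts = np.linspace(0.0, 1.0, m)
            pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
            cols = np.clip(np.rint(pts[:, 0]).astype(int), 0, g.cols - 1)
            rows = np.clip(np.rint(pts[:, 1]).astype(int), 0, g.rows - 1)
            n_scar = int(scar.data[i, rows, cols].sum())
            n_wall = int(myo.data[i, rows, cols].sum()) if myo is not None else m
            frac = n_scar / n_wall if n_wall else 0.0
            vals[k] = min(max(float(frac), 0.0), 1.0)
        values[i] = vals
    return TransmuralityProfile(
        values,
        {i: float(v.mean()) for i, v in values.items()},
        {i: float(v.max()) for i, v in values.items()},
    )


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------


@dataclass
class ScarMetrics:
    """The clinical numbers: volumes, mass, extent, transmurality, segments."""

    myocardial_volume_ml: float
    scar_volume_ml: float
    scar_mass_g: float
    scar_extent_percent: float
    mean_transmurality: float
    max_transmurality: float
    segment_extents: SegmentExtent

    def to_dict(self) -> dict:
        return {
            "myocardial_volume_ml": self.myocardial_volume_ml,
            "scar_volume_ml": self.scar_volume_ml,
            "scar_mass_g": self.scar_mass_g,
            "scar_extent_percent": self.scar_extent_percent,
            "mean_transmurality": self.mean_transmurality,
            "max_transmurality": self.max_transmurality,
            "segment_extents": {
                str(s): {
                    "percent": self.segment_extents.percent[s],
                    "scar_px": self.segment_extents.scar_px[s],
                    "total_px": self.segment_extents.total_px[s],
                }
                for s in sorted(self.segment_extents.percent)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScarMetrics":
        seg = d["segment_extents"]
        extents = SegmentExtent(
            {int(s): v["percent"] for s, v in seg.items()},
            {int(s): v["scar_px"] for s, v in seg.items()},
            {int(s): v["total_px"] for s, v in seg.items()},
        )
        return cls(
            d["myocardial_volume_ml"], d["scar_volume_ml"], d["scar_mass_g"],
            d["scar_extent_percent"], d["mean_transmurality"], d["max_transmurality"],
            extents,
        )


def global_metrics(
    myo: MyocardiumMask,
    scar: ScarMask,
    transmurality: TransmuralityProfile,
    extents: SegmentExtent,
    geometry: ImageGeometry,
    density_g_per_cm3: float = MYOCARDIAL_DENSITY_G_PER_CM3,
) -> ScarMetrics:
    """Assemble the global scar metrics.

    Volumes are pixel counts times the voxel volume; scar mass converts
    the scar volume with the conventional myocardial density of
    1.05 g/cm^3; extent is the scar/myocardium volume ratio in percent;
    mean and max transmurality pool every chord of every quantified
    slice.
    """
    n_myo = myo.pixel_count()
    if n_myo == 0:
        raise GeometryError("empty myocardium; no metrics to compute")
    n_scar = scar.pixel_count()
    vox_ml = geometry.voxel_volume_mm3 / 1000.0
    myo_ml = n_myo * vox_ml
    scar_ml = n_scar * vox_ml
    tv = transmurality.all_values()
    return ScarMetrics(
        myocardial_volume_ml=myo_ml,
        scar_volume_ml=scar_ml,
        scar_mass_g=scar_ml * density_g_per_cm3,
        scar_extent_percent=100.0 * n_scar / n_myo,
        mean_transmurality=float(tv.mean()) if tv.size else 0.0,
        max_transmurality=float(tv.max()) if tv.size else 0.0,
        segment_extents=extents,
    )
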