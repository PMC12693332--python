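"""Synthetic co-registered BR/BL short-axis phantom with known truth.

The phantom emulates the contrast regime the pipeline is built for: on
black-blood (BL) images, scar sits at the top of the intensity range
(255 before noise) while healthy myocardium occupies a dark band
(roughly 0-30), with an optional gray-zone rim at intermediate
intensity; on bright-blood (BR) images the blood pool is bright and the
wall is mid-gray.  The left ventricle is a circular annulus per slice;
scar regions are annular sectors specified by slice, angular interval
and a radial interval expressed as fractions of the wall depth, so the
true transmurality of every scar is known by construction.

Nothing here simulates MR physics — no signal model, no motion, no coil
profiles.  The generator exists to make every downstream stage testable
against an analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .imaging_io import (
    BL,
    BR,
    ContourSet,
    CoRegisteredPair,
    ImageGeometry,
    ImageStack,
    LandmarkPair,
    LandmarkSet,
    MyocardiumMask,
    rasterize_myocardium,
)
from .quantify import (
    MYOCARDIAL_DENSITY_G_PER_CM3,
    ScarMetrics,
    SegmentExtent,
    assign_levels,
    sector_boundaries,
)
from .scar_detect import ScarMask

__all__ = [
    "PhantomSpecError",
    "ScarSector",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "truth_metrics_analytic",
    "spec_for_scar",
]


class PhantomSpecError(ValueError):
    """A phantom specification violates its invariants."""


# BL intensity model (working 0-255 scale, before noise)
BL_BACKGROUND = 0.0
BL_BLOOD = 5.0
BL_HEALTHY_LO = 5.0   # healthy wall spans [5, 25]: a radial gradient keeps
BL_HEALTHY_HI = 25.0  # the histogram non-degenerate even without noise
BL_GRAY_ZONE = 128.0
BL_SCAR = 255.0
# BR intensity model
BR_BACKGROUND = 20.0
BR_MYOCARDIUM = 100.0
BR_BLOOD = 230.0

_CONTOUR_VERTICES = 180


@dataclass(frozen=True)
class ScarSector:
    """One scar region: an annular sector on one slice.

    ``theta_start/theta_end`` are degrees about the LV center (the sector
    runs counterclockwise from start to end); ``r_frac_lo/r_frac_hi`` are
    fractions of the wall depth, 0 at the endocardium and 1 at the
    epicardium, so ``(0, 0.5)`` is a subendocardial half-wall scar and
    ``(0, 1)`` is transmural.
    """

    slice_index: int
    theta_start_deg: float
    theta_end_deg: float
    r_frac_lo: float = 0.0
    r_frac_hi: float = 1.0

    @property
    def transmurality(self) -> float:
        return self.r_frac_hi - self.r_frac_lo

    def covers_angle(self, theta_deg) -> np.ndarray:
        width = (self.theta_end_deg - self.theta_start_deg) % 360.0
        if width == 0.0:
            width = 360.0
        rel = (np.asarray(theta_deg, dtype=float) - self.theta_start_deg) % 360.0
        return rel <= width


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom case deterministically."""

    rows: int = 160
    cols: int = 160
    n_slices: int = 12
    in_plane_spacing_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 8.0
    endo_radius_px: float = 20.0
    epi_radius_px: float = 35.0
    scar_sectors: tuple = ()
    gray_zone_rim_px: float = 0.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    landmark_angles_deg: tuple[float, float] = (60.0, 120.0)

    def validate(self) -> None:
        if self.rows < 2 or self.cols < 2 or self.n_slices < 1:
            raise PhantomSpecError("rows/cols/n_slices: must be >= 2 / >= 2 / >= 1")
        if self.in_plane_spacing_mm[0] <= 0 or self.in_plane_spacing_mm[1] <= 0:
            raise PhantomSpecError("in_plane_spacing_mm: must be positive")
        if self.slice_thickness_mm <= 0:
            raise PhantomSpecError("slice_thickness_mm: must be positive")
        if not (0 < self.endo_radius_px < self.epi_radius_px):
            raise PhantomSpecError("endo_radius_px: need 0 < endo_radius_px < epi_radius_px")
        if self.rows < 2 * self.epi_radius_px or self.cols < 2 * self.epi_radius_px:
            raise PhantomSpecError("rows: image must be at least twice the epicardial radius")
        for s in self.scar_sectors:
            if not (0 <= s.r_frac_lo < s.r_frac_hi <= 1):
                raise PhantomSpecError(
                    f"scar_sectors: radial fractions must satisfy 0 <= lo < hi <= 1, got {s}"
                )
            if not (0 <= s.slice_index < self.n_slices):
                raise PhantomSpecError(f"scar_sectors: slice index {s.slice_index} out of range")
        if self.gray_zone_rim_px < 0:
            raise PhantomSpecError("gray_zone_rim_px: must be >= 0")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd: must be >= 0")

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(
            rows=self.rows, cols=self.cols, n_slices=self.n_slices,
            in_plane_spacing_mm=self.in_plane_spacing_mm,
            slice_thickness_mm=self.slice_thickness_mm,
        )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.cols - 1) / 2.0, (self.rows - 1) / 2.0)

    def to_dict(self) -> dict:
        d = {
            "rows": self.rows, "cols": self.cols, "n_slices": self.n_slices,
            "in_plane_spacing_mm": list(self.in_plane_spacing_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
            "endo_radius_px": self.endo_radius_px, "epi_radius_px": self.epi_radius_px,
            "scar_sectors": [
                [s.slice_index, s.theta_start_deg, s.theta_end_deg, s.r_frac_lo, s.r_frac_hi]
                for s in self.scar_sectors
            ],
            "gray_zone_rim_px": self.gray_zone_rim_px,
            "noise_sd": self.noise_sd, "rng_seed": self.rng_seed,
            "landmark_angles_deg": list(self.landmark_angles_deg),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "scar_sectors" in d:
            d["scar_sectors"] = tuple(ScarSector(int(s[0]), *map(float, s[1:])) for s in d["scar_sectors"])
        if "in_plane_spacing_mm" in d:
            d["in_plane_spacing_mm"] = tuple(d["in_plane_spacing_mm"])
        if "landmark_angles_deg" in d:
            d["landmark_angles_deg"] = tuple(d["landmark_angles_deg"])
        return cls(**d)


@dataclass
class PhantomCase:
    """A generated phantom: images, contours, landmarks and ground truth."""

    pair: CoRegisteredPair
    contours: ContourSet
    landmarks: LandmarkSet
    truth_scar: ScarMask
    truth_metrics: ScarMetrics
    spec: PhantomSpec

    @property
    def myocardium(self) -> MyocardiumMask:
        return rasterize_myocardium(self.contours, self.pair.bl.geometry)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _circle(center: tuple[float, float], radius: float, n: int = _CONTOUR_VERTICES) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)])


def _polar_grid(spec: PhantomSpec):
    cx, cy = spec.center
    xs, ys = np.meshgrid(np.arange(spec.cols, dtype=float), np.arange(spec.rows, dtype=float))
    r = np.hypot(xs - cx, ys - cy)
    theta = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    return r, theta


def _truth_masks(spec: PhantomSpec, myo: np.ndarray):
    """Rasterized scar and gray-zone-rim masks for all slices."""
    from scipy import ndimage

    r, theta = _polar_grid(spec)
    wall = spec.epi_radius_px - spec.endo_radius_px
    frac = np.clip((r - spec.endo_radius_px) / wall, 0.0, 1.0)
    scar = np.zeros_like(myo, dtype=bool)
    for s in spec.scar_sectors:
        sel = myo[s.slice_index] & s.covers_angle(theta) \
            & (frac >= s.r_frac_lo) & (frac <= s.r_frac_hi)
        scar[s.slice_index] |= sel
    rim = np.zeros_like(scar)
    if spec.gray_zone_rim_px > 0:
        for i in range(spec.n_slices):
            if not scar[i].any():
                continue
            dist = ndimage.distance_transform_edt(~scar[i])
            rim[i] = myo[i] & ~scar[i] & (dist <= spec.gray_zone_rim_px)
    return scar, rim


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate a fully synthetic co-registered BR/BL case with ground truth.

    The contours are the exact circles used for rasterization, landmarks
    sit on the epicardial circle at the configured angles, and the truth
    metrics are recomputable exactly from the rasterized truth masks.
    Identical spec (including ``rng_seed``) yields bit-identical stacks.
    """
    spec.validate()
    g = spec.geometry
    cx, cy = spec.center

    contours = ContourSet(
        endo=[_circle((cx, cy), spec.endo_radius_px) for _ in range(spec.n_slices)],
        epi=[_circle((cx, cy), spec.epi_radius_px) for _ in range(spec.n_slices)],
    )
    myo = rasterize_myocardium(contours, g).data
    scar, rim = _truth_masks(spec, myo)

    r, _ = _polar_grid(spec)
    wall = spec.epi_radius_px - spec.endo_radius_px
    frac = np.clip((r - spec.endo_radius_px) / wall, 0.0, 1.0)
    blood = r < spec.endo_radius_px

    bl = np.full((spec.n_slices, spec.rows, spec.cols), BL_BACKGROUND)
    br = np.full_like(bl, BR_BACKGROUND)
    for i in range(spec.n_slices):
        bl[i][blood & ~myo[i]] = BL_BLOOD
        healthy = myo[i] & ~scar[i] & ~rim[i]
        bl[i][healthy] = BL_HEALTHY_LO + (BL_HEALTHY_HI - BL_HEALTHY_LO) * frac[healthy]
        bl[i][rim[i]] = BL_GRAY_ZONE
        bl[i][scar[i]] = BL_SCAR
        br[i][myo[i]] = BR_MYOCARDIUM
        br[i][blood & ~myo[i]] = BR_BLOOD

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_sd > 0:
        bl = bl + rng.normal(0.0, spec.noise_sd, bl.shape)
        br = br + rng.normal(0.0, spec.noise_sd, br.shape)
    bl = np.clip(np.rint(bl), 0, 255).astype(np.uint16)
    br = np.clip(np.rint(br), 0, 255).astype(np.uint16)

    pair = CoRegisteredPair(
        br=ImageStack(br, g, BR),
        bl=ImageStack(bl, g, BL),
    )
    a1, a2 = spec.landmark_angles_deg
    lm = LandmarkPair(
        anterior=(cx + spec.epi_radius_px * np.cos(np.radians(a1)),
                  cy + spec.epi_radius_px * np.sin(np.radians(a1))),
        inferior=(cx + spec.epi_radius_px * np.cos(np.radians(a2)),
                  cy + spec.epi_radius_px * np.sin(np.radians(a2))),
    )
    landmarks = LandmarkSet([lm] * spec.n_slices)
    truth_scar = ScarMask(scar, g)
    return PhantomCase(
        pair=pair,
        contours=contours,
        landmarks=landmarks,
        truth_scar=truth_scar,
        truth_metrics=truth_metrics_analytic(spec),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------


def _truth_chord_transmurality(spec: PhantomSpec, n_chords: int = 100) -> np.ndarray:
    """Transmurality at the 100 chord angles per slice, from the radial
    construction alone (no chord engine involved)."""
    a1 = spec.landmark_angles_deg[0]
    angles = (a1 + 360.0 * np.arange(n_chords) / n_chords) % 360.0
    out = np.zeros((spec.n_slices, n_chords))
    for s in spec.scar_sectors:
        hit = s.covers_angle(angles)
        out[s.slice_index][hit] += s.transmurality
    return np.clip(out, 0.0, 1.0)


def truth_metrics_analytic(spec: PhantomSpec) -> ScarMetrics:
    """Ground-truth metrics from the phantom construction.

    Volumes are pixel counts of the rasterized truth masks times the
    voxel volume; per-chord transmurality follows directly from the
    radial-fraction construction evaluated at the 100 chord angles;
    per-segment extents count truth-scar pixels inside each AHA sector
    by direct angle binning.
    """
    spec.validate()
    g = spec.geometry
    cx, cy = spec.center
    contours = ContourSet(
        endo=[_circle((cx, cy), spec.endo_radius_px) for _ in range(spec.n_slices)],
        epi=[_circle((cx, cy), spec.epi_radius_px) for _ in range(spec.n_slices)],
    )
    myo = rasterize_myocardium(contours, g).data
    scar, _ = _truth_masks(spec, myo)
    n_myo = int(myo.sum())
    n_scar = int(scar.sum())
    vox_ml = g.voxel_volume_mm3 / 1000.0

    trans = _truth_chord_transmurality(spec)
    levels = assign_levels(MyocardiumMask(myo, g))
    used = sorted(levels)
    tvals = trans[used].ravel()

    a1, a2 = spec.landmark_angles_deg
    lm = LandmarkPair(
        anterior=(cx + spec.epi_radius_px * np.cos(np.radians(a1)),
                  cy + spec.epi_radius_px * np.sin(np.radians(a1))),
        inferior=(cx + spec.epi_radius_px * np.cos(np.radians(a2)),
                  cy + spec.epi_radius_px * np.sin(np.radians(a2))),
    )
    _, theta = _polar_grid(spec)
    percent: dict = {}
    scar_px: dict = {}
    total_px: dict = {}
    for i in used:
        layout = sector_boundaries(lm, (cx, cy), levels[i])
        labels = layout.sector_of_angle(theta[myo[i]])
        scar_lab = layout.sector_of_angle(theta[myo[i] & scar[i]]) if scar[i].any() else np.zeros(0, int)
        for seg in np.unique(labels):
            total_px[int(seg)] = total_px.get(int(seg), 0) + int((labels == seg).sum())
            scar_px[int(seg)] = scar_px.get(int(seg), 0) + int((scar_lab == seg).sum())
    for seg, tot in total_px.items():
        percent[seg] = 100.0 * scar_px[seg] / tot

    return ScarMetrics(
        myocardial_volume_ml=n_myo * vox_ml,
        scar_volume_ml=n_scar * vox_ml,
        scar_mass_g=n_scar * vox_ml * MYOCARDIAL_DENSITY_G_PER_CM3,
        scar_extent_percent=100.0 * n_scar / n_myo if n_myo else 0.0,
        mean_transmurality=float(tvals.mean()) if tvals.size else 0.0,
        max_transmurality=float(tvals.max()) if tvals.size else 0.0,
        segment_extents=SegmentExtent(percent, scar_px, total_px),
    )


def spec_for_scar(
    angular_width_deg: float,
    transmurality: float,
    noise_sd: float = 0.0,
    center_angle_deg: float = 270.0,
    slices: Optional[Sequence[int]] = None,
    rng_seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """Convenience builder: one subendocardial scar of the given angular
    width and transmurality on each of ``slices`` (default: every slice).

    Extent and transmurality are coupled for an annular sector (extent =
    width/360 x the area fraction of the radial interval), so phantom
    grids are parameterized by angular width and transmurality.
    """
    base = PhantomSpec(noise_sd=noise_sd, rng_seed=rng_seed, **kwargs)
    if slices is None:
        slices = range(base.n_slices)
    t0 = center_angle_deg - angular_width_deg / 2.0
    t1 = center_angle_deg + angular_width_deg / 2.0
    sectors = tuple(
        ScarSector(i, t0 % 360.0, t1 % 360.0, 0.0, transmurality) for i in slices
    )
    return replace(base, scar_sectors=sectors)
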