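"""Image, contour and landmark I/O, and the coordinate conventions shared
by every other module.

Conventions
-----------
* Voxel arrays are indexed ``(slice, row, col)``, 0-based.
* Polygon vertices and landmark points are continuous ``(x, y)`` pixel
  coordinates with ``x = col``, ``y = row``; the pixel center sits at
  integer coordinates.
* A pixel belongs to a polygon iff its center passes an even-odd
  (crossing-number) test; boundary pixels are decided by that same test.
* Stacks are stored either as NIfTI-1 (axes ordered ``x, y, slice`` on
  disk) or as a directory of 16-bit grayscale PNG slices with a JSON
  geometry sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "BR",
    "BL",
    "FormatError",
    "GeometryError",
    "ImageGeometry",
    "ImageStack",
    "CoRegisteredPair",
    "ContourSet",
    "LandmarkPair",
    "LandmarkSet",
    "MyocardiumMask",
    "point_in_polygon",
    "polygon_is_simple",
    "polygon_centroid",
    "read_stack",
    "write_stack",
    "read_contours",
    "write_contours",
    "read_landmarks",
    "write_landmarks",
    "read_mask",
    "write_mask",
    "rasterize_myocardium",
]

BR = "BR"
BL = "BL"


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


class GeometryError(ValueError):
    """Spatial metadata or spatial invariants are violated."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGeometry:
    """Grid size and physical spacing of a short-axis stack."""

    rows: int
    cols: int
    n_slices: int
    in_plane_spacing_mm: tuple[float, float] = (1.5, 1.5)
    slice_thickness_mm: float = 8.0

    def __post_init__(self) -> None:
        for name in ("rows", "cols", "n_slices"):
            if int(getattr(self, name)) <= 0:
                raise GeometryError(f"{name} must be positive, got {getattr(self, name)}")
        sx, sy = self.in_plane_spacing_mm
        if sx <= 0 or sy <= 0 or self.slice_thickness_mm <= 0:
            raise GeometryError("spacing and thickness must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy = self.in_plane_spacing_mm
        return sx * sy * self.slice_thickness_mm

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "n_slices": self.n_slices,
            "spacing_mm": list(self.in_plane_spacing_mm),
            "thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGeometry":
        try:
            return cls(
                rows=int(d["rows"]),
                cols=int(d["cols"]),
                n_slices=int(d["n_slices"]),
                in_plane_spacing_mm=(float(d["spacing_mm"][0]), float(d["spacing_mm"][1])),
                slice_thickness_mm=float(d["thickness_mm"]),
            )
        except KeyError as exc:  # pragma: no cover - message detail
            raise FormatError(f"geometry sidecar missing key {exc}") from exc


@dataclass
class ImageStack:
    """A 3-D grayscale stack with geometry and a contrast tag (BR or BL)."""

    voxels: np.ndarray
    geometry: ImageGeometry
    contrast: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError(f"voxels must be 3-D (slice,row,col), got ndim={self.voxels.ndim}")
        g = self.geometry
        if self.voxels.shape != (g.n_slices, g.rows, g.cols):
            raise GeometryError(
                f"voxel shape {self.voxels.shape} does not match geometry "
                f"({g.n_slices}, {g.rows}, {g.cols})"
            )
        if self.contrast not in (BR, BL):
            raise ValueError(f"contrast must be 'BR' or 'BL', got {self.contrast!r}")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxels contain non-finite values")

    def with_voxels(self, voxels: np.ndarray, geometry: ImageGeometry | None = None) -> "ImageStack":
        return ImageStack(voxels, geometry or self.geometry, self.contrast)


@dataclass
class CoRegisteredPair:
    """Bright-blood and black-blood stacks acquired on one shared grid."""

    br: ImageStack
    bl: ImageStack

    def __post_init__(self) -> None:
        if self.br.geometry != self.bl.geometry:
            raise GeometryError("BR and BL stacks must share identical geometry")
        if self.br.contrast != BR or self.bl.contrast != BL:
            raise ValueError("pair must hold br.contrast='BR' and bl.contrast='BL'")


@dataclass
class ContourSet:
    """Per-slice endocardial and epicardial closed polygons.

    ``endo[i]`` / ``epi[i]`` are ``(V, 2)`` arrays of (x, y) vertices for
    slice ``i``, or ``None`` where the slice carries no contour.
    """

    endo: list
    epi: list

    def __post_init__(self) -> None:
        if len(self.endo) != len(self.epi):
            raise GeometryError("endo and epi lists must have equal length")
        for i, (en, ep) in enumerate(zip(self.endo, self.epi)):
            if (en is None) != (ep is None):
                raise GeometryError(f"slice {i}: endo and epi must both be present or both absent")
            if en is None:
                continue
            en = np.asarray(en, dtype=float)
            ep = np.asarray(ep, dtype=float)
            for name, poly in (("endo", en), ("epi", ep)):
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise FormatError(f"slice {i}: {name} polygon needs >= 3 (x,y) vertices")
                if not polygon_is_simple(poly):
                    raise GeometryError(f"slice {i}: {name} polygon self-intersects")
            if not point_in_polygon(en, ep).all():
                raise GeometryError(f"slice {i}: endo contour is not strictly inside epi contour")
            if point_in_polygon(ep, en).any():
                raise GeometryError(f"slice {i}: epi contour crosses into endo interior")
            self.endo[i], self.epi[i] = en, ep

    @property
    def n_slices(self) -> int:
        return len(self.endo)

    def slices_with_contours(self) -> list[int]:
        return [i for i, en in enumerate(self.endo) if en is not None]


@dataclass(frozen=True)
class LandmarkPair:
    """Anterior and inferior RV insertion points on one slice, (x, y) px."""

    anterior: tuple[float, float]
    inferior: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.anterior) == tuple(self.inferior):
            raise GeometryError("anterior and inferior insertion points must be distinct")


@dataclass
class LandmarkSet:
    """Per-slice RV-insertion landmark pairs (``None`` where absent)."""

    pairs: list

    @property
    def n_slices(self) -> int:
        return len(self.pairs)

    def nearest(self, index: int) -> LandmarkPair:
        """Landmarks for ``index``, propagated from the nearest slice if absent."""
        if index < len(self.pairs) and self.pairs[index] is not None:
            return self.pairs[index]
        have = [i for i, p in enumerate(self.pairs) if p is not None]
        if not have:
            raise GeometryError("no slice carries landmarks; cannot propagate")
        j = min(have, key=lambda i: (abs(i - index), i))
        return self.pairs[j]


@dataclass
class MyocardiumMask:
    """Binary LV-wall mask: epicardial interior minus endocardial interior."""

    data: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        g = self.geometry
        if self.data.shape != (g.n_slices, g.rows, g.cols):
            raise GeometryError("mask shape does not match geometry")

    def pixel_count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------


def point_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) membership test, vectorized over points.

    Parameters
    ----------
    points : (N, 2) array of (x, y)
    polygon : (V, 2) array of vertices, implicitly closed
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0][:, None], pts[:, 1][:, None]
    x1, y1 = poly[:, 0][None, :], poly[:, 1][None, :]
    x2, y2 = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]
    straddles = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
    crossings = (straddles & (x < x_cross)).sum(axis=1)
    return (crossings % 2).astype(bool)


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return min(a[0], b[0]) <= c[0] <= max(a[0], b[0]) and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_seg(p1, p2, p3):
        return True
    if o2 == 0 and on_seg(p1, p2, p4):
        return True
    if o3 == 0 and on_seg(p3, p4, p1):
        return True
    if o4 == 0 and on_seg(p3, p4, p2):
        return True
    return False


def polygon_is_simple(polygon: np.ndarray) -> bool:
    """True iff no two non-adjacent edges of the closed polygon intersect."""
    poly = np.asarray(polygon, dtype=float)
    n = len(poly)
    edges = [(tuple(poly[i]), tuple(poly[(i + 1) % n])) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j == (i + 1) % n) or ((j + 1) % n == i) or (i == 0 and j == n - 1):
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def polygon_centroid(polygon: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple closed polygon (shoelace formula)."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def rasterize_myocardium(contours: ContourSet, geometry: ImageGeometry) -> MyocardiumMask:
    """Rasterize the LV wall: pixel centers inside epi and not inside endo.

    Uses the even-odd rule on pixel centers; the center-in test alone
    decides boundary pixels.
    """
    g = geometry
    xs, ys = np.meshgrid(np.arange(g.cols, dtype=float), np.arange(g.rows, dtype=float))
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    mask = np.zeros((g.n_slices, g.rows, g.cols), dtype=bool)
    for i in contours.slices_with_contours():
        if i >= g.n_slices:
            raise GeometryError(f"contour slice index {i} exceeds stack depth {g.n_slices}")
        epi, endo = contours.epi[i], contours.endo[i]
        for poly in (epi, endo):
            if (poly[:, 0] < 0).any() or (poly[:, 1] < 0).any() or \
               (poly[:, 0] > g.cols - 1).any() or (poly[:, 1] > g.rows - 1).any():
                raise GeometryError(f"slice {i}: contour extends outside image bounds")
        inside_epi = point_in_polygon(centers, epi)
        inside_endo = point_in_polygon(centers, endo)
        mask[i] = (inside_epi & ~inside_endo).reshape(g.rows, g.cols)
    return MyocardiumMask(mask, geometry)


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

_SIDE_CAR = "geometry.json"
_SLICE_RE = re.compile(r"slice_(\d+)\.png$")


def _is_nifti(path: Path) -> bool:
    s = str(path)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as NIfTI-1 (``.nii``/``.nii.gz``) or a PNG-slice directory.

    Integer data up to 16 bits round-trips losslessly through both formats.
    """
    path = Path(path)
    g = stack.geometry
    if _is_nifti(path):
        data = np.transpose(stack.voxels, (2, 1, 0))  # (x=col, y=row, slice)
        affine = np.diag([g.in_plane_spacing_mm[0], g.in_plane_spacing_mm[1], g.slice_thickness_mm, 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(data), affine)
        img.header.set_zooms((g.in_plane_spacing_mm[0], g.in_plane_spacing_mm[1], g.slice_thickness_mm))
        nib.save(img, str(path))
    else:
        path.mkdir(parents=True, exist_ok=True)
        v = stack.voxels
        if not np.issubdtype(v.dtype, np.integer):
            raise FormatError(f"PNG export requires integer voxels, got dtype {v.dtype} ({path})")
        if v.min() < 0 or v.max() > 65535:
            raise FormatError(f"PNG export requires values in [0, 65535] ({path})")
        for i in range(g.n_slices):
            iio.imwrite(path / f"slice_{i:04d}.png", v[i].astype(np.uint16))
        (path / _SIDE_CAR).write_text(json.dumps(g.to_dict(), indent=1))


def read_stack(path: str | Path, contrast: str) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    NIfTI geometry comes from the header zooms; the PNG layout requires a
    ``geometry.json`` sidecar whose declared slice count must match the
    number of ``slice_*.png`` files.
    """
    path = Path(path)
    if _is_nifti(path):
        if not path.exists():
            raise FormatError(f"no such NIfTI file: {path}")
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"expected 3-D NIfTI, got shape {data.shape} ({path})")
        zooms = img.header.get_zooms()[:3]
        voxels = np.transpose(data, (2, 1, 0))
        geometry = ImageGeometry(
            rows=voxels.shape[1],
            cols=voxels.shape[2],
            n_slices=voxels.shape[0],
            in_plane_spacing_mm=(float(zooms[0]), float(zooms[1])),
            slice_thickness_mm=float(zooms[2]),
        )
        return ImageStack(voxels, geometry, contrast)
    if not path.is_dir():
        raise FormatError(f"no such stack (expected NIfTI file or PNG directory): {path}")
    sidecar = path / _SIDE_CAR
    if not sidecar.exists():
        raise FormatError(f"missing geometry sidecar {sidecar}")
    geometry = ImageGeometry.from_dict(json.loads(sidecar.read_text()))
    files = sorted(p for p in path.iterdir() if _SLICE_RE.search(p.name))
    if len(files) != geometry.n_slices:
        raise FormatError(
            f"{path}: sidecar declares {geometry.n_slices} slices but found {len(files)} PNG files"
        )
    slices = [iio.imread(f) for f in files]
    voxels = np.stack(slices, axis=0)
    if voxels.shape[1:] != (geometry.rows, geometry.cols):
        raise FormatError(f"{path}: PNG dimensions {voxels.shape[1:]} do not match sidecar")
    return ImageStack(voxels, geometry, contrast)


def write_mask(mask, path: str | Path) -> None:
    """Write a binary mask (``MyocardiumMask`` or any object with .data/.geometry)."""
    stack = ImageStack(mask.data.astype(np.uint8), mask.geometry, BL)
    write_stack(stack, path)


def read_mask(path: str | Path) -> MyocardiumMask:
    stack = read_stack(path, BL)
    return MyocardiumMask(stack.voxels > 0, stack.geometry)


# ---------------------------------------------------------------------------
# contours / landmarks JSON
# ---------------------------------------------------------------------------


def _check_contiguous(indices: Sequence[int], what: str) -> None:
    if sorted(indices) != list(range(len(indices))):
        raise FormatError(f"{what}: slice indices must be contiguous from 0, got {sorted(indices)}")


def write_contours(contours: ContourSet, path: str | Path) -> None:
    slices = []
    for i in contours.slices_with_contours():
        slices.append(
            {
                "index": i,
                "endo": [[float(x), float(y)] for x, y in contours.endo[i]],
                "epi": [[float(x), float(y)] for x, y in contours.epi[i]],
            }
        )
    Path(path).write_text(json.dumps({"slices": slices}, indent=1))


def read_contours(path: str | Path) -> ContourSet:
    try:
        doc = json.loads(Path(path).read_text())
    except OSError as exc:
        raise FormatError(f"cannot read contours file {path}: {exc}") from exc
    slices = doc.get("slices")
    if slices is None:
        raise FormatError(f"{path}: missing 'slices' key")
    indices = [int(s["index"]) for s in slices]
    _check_contiguous(indices, str(path))
    n = len(slices)
    endo: list = [None] * n
    epi: list = [None] * n
    for s in slices:
        endo[int(s["index"])] = np.asarray(s["endo"], dtype=float)
        epi[int(s["index"])] = np.asarray(s["epi"], dtype=float)
    return ContourSet(endo, epi)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    slices = []
    for i, p in enumerate(landmarks.pairs):
        if p is None:
            continue
        slices.append(
            {"index": i, "anterior": [float(p.anterior[0]), float(p.anterior[1])],
             "inferior": [float(p.inferior[0]), float(p.inferior[1])]}
        )
    Path(path).write_text(json.dumps({"slices": slices}, indent=1))


def read_landmarks(path: str | Path) -> LandmarkSet:
    try:
        doc = json.loads(Path(path).read_text())
    except OSError as exc:
        raise FormatError(f"cannot read landmarks file {path}: {exc}") from exc
    slices = doc.get("slices")
    if slices is None:
        raise FormatError(f"{path}: missing 'slices' key")
    indices = [int(s["index"]) for s in slices]
    _check_contiguous(indices, str(path))
    pairs: list = [None] * len(slices)
    for s in slices:
        pairs[int(s["index"])] = LandmarkPair(
            anterior=(float(s["anterior"][0]), float(s["anterior"][1])),
            inferior=(float(s["inferior"][0]), float(s["inferior"][1])),
        )
    return LandmarkSet(pairs)
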