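"""Scar detection on black-blood LGE images.

Two detectors are implemented in full, plus a plug-in slot:

* **Multi-level Otsu** — three intensity thresholds on the 0–255 working
  scale chosen by exhaustively maximizing the between-class variance of
  the four resulting classes; pixels above the top threshold are scar,
  the next interval is gray zone, everything below is healthy (the two
  lowest intervals merge; black-blood imaging drives suppressed signal
  toward zero, so the lowest interval is near-zero background within the
  wall).
* **Seeded region growing** — starting from the gravity center of the
  largest hyperintense component, repeatedly admit the 4-connected
  neighbor whose intensity deviates least from the running region mean,
  updating the mean after every admission, until that minimal deviation
  exceeds ``max_deviation`` or the wall is exhausted.  Growth is
  confined to the myocardium and runs slice by slice.
* **external** — a pre-computed mask file/array or a callable detector
  (the slot where a learned model would plug in), validated for
  containment in the myocardium.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .imaging_io import (
    CoRegisteredPair,
    GeometryError,
    ImageGeometry,
    ImageStack,
    MyocardiumMask,
    read_mask,
)

__all__ = [
    "DegenerateHistogramError",
    "ContainmentError",
    "SeedError",
    "ThresholdTriple",
    "TissueClassMap",
    "ScarMask",
    "RegionGrowParams",
    "multiotsu_thresholds",
    "classify_tissue",
    "default_seed",
    "region_grow",
    "detect_scar",
    "dice",
    "LABEL_OUTSIDE",
    "LABEL_HEALTHY",
    "LABEL_GRAY_ZONE",
    "LABEL_SCAR",
]


class DegenerateHistogramError(ValueError):
    """Too few distinct intensities to place three thresholds."""


class ContainmentError(ValueError):
    """A scar mask leaks outside the myocardium."""


class SeedError(ValueError):
    """A region-growing seed lies outside the myocardium."""


LABEL_OUTSIDE, LABEL_HEALTHY, LABEL_GRAY_ZONE, LABEL_SCAR = 0, 1, 2, 3
LABEL_LOW = 4  # sub-t1 interval, only emitted with merge_lowest=False

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ThresholdTriple:
    """Three ordered intensity thresholds on the 0–255 working scale."""

    t1: int
    t2: int
    t3: int

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2 < self.t3 <= 255):
            raise ValueError(f"thresholds must satisfy 0 <= t1 < t2 < t3 <= 255, got {self}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.t1, self.t2, self.t3)


@dataclass
class TissueClassMap:
    """Per-pixel tissue labels: outside / healthy / gray zone / scar."""

    labels: np.ndarray  # uint8, (n_slices, rows, cols)
    thresholds: ThresholdTriple
    geometry: ImageGeometry
    method: str = "otsu"

    def scar_mask(self) -> "ScarMask":
        return ScarMask(self.labels == LABEL_SCAR, self.geometry)


@dataclass
class ScarMask:
    """Per-slice binary scar grid."""

    data: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        g = self.geometry
        if self.data.shape != (g.n_slices, g.rows, g.cols):
            raise GeometryError("scar mask shape does not match geometry")

    def pixel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class RegionGrowParams:
    """Parameters for seeded region growing (connectivity is fixed at 4)."""

    seeds: Optional[dict] = None  # slice index -> (row, col); auto-seeded if absent
    max_deviation: float = 25.0

    def __post_init__(self) -> None:
        if self.max_deviation < 0:
            raise ValueError("max_deviation must be >= 0")


# ---------------------------------------------------------------------------
# multi-level Otsu
# ---------------------------------------------------------------------------


def multiotsu_thresholds(values: np.ndarray, k: int = 3) -> ThresholdTriple:
    """Three Otsu thresholds maximizing between-class variance over 4 classes.

    The search is exhaustive over every ordered integer triple
    ``0 <= t1 < t2 < t3 <= 255`` on a 256-bin histogram, so the returned
    triple is a global maximizer; ties are broken by the lexicographically
    smallest ``(t1, t2, t3)``.

    Parameters
    ----------
    values : intensities on the 0–255 working scale (rounded to integer
        bins internally); typically the myocardial pixels of one stack.
    k : number of thresholds; only ``k=3`` is supported.
    """
    if k != 3:
        raise ValueError("only k=3 thresholds are supported")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateHistogramError("empty intensity sample")
    bins = np.clip(np.rint(v), 0, 255).astype(np.int64)
    counts = np.bincount(bins, minlength=256).astype(np.float64)
    if (counts > 0).sum() < 4:
        raise DegenerateHistogramError(
            f"need >= 4 distinct intensity bins, got {(counts > 0).sum()}"
        )
    return _exhaustive_multiotsu(counts)


def _exhaustive_multiotsu(counts: np.ndarray) -> ThresholdTriple:
    # Between-class variance = sum_k W_k mu_k^2 - mu_g^2; the global term is
    # constant, so maximize sum_k S_k^2 / W_k via prefix sums.  The search is
    # equivalent to scanning all ordered triples 0 <= t1 < t2 < t3 <= 255:
    # every maximizer's thresholds reduce to occupied histogram bins without
    # changing the class partition (and reducing never increases the triple
    # lexicographically), and no maximizer has an empty class when >= 4 bins
    # are occupied, so scanning occupied bins only is exact — including the
    # smallest-(t1,t2,t3) tie-break.
    levels = np.arange(256, dtype=np.float64)
    P = np.concatenate([[0.0], np.cumsum(counts)])           # P[t+1] = sum counts[0..t]
    Q = np.concatenate([[0.0], np.cumsum(counts * levels)])  # intensity-weighted

    def seg(a, b):
        # class covering bins (a, b]: returns S^2/W, 0 for an empty class
        w = P[b + 1] - P[a + 1]
        s = Q[b + 1] - Q[a + 1]
        w_safe = np.where(w > 0, w, 1.0)
        return np.where(w > 0, s * s / w_safe, 0.0)

    occ = np.nonzero(counts)[0]
    cand = occ[:-1]  # t3 < max occupied bin keeps the top class nonempty
    j = cand[:, None]
    k = cand[None, :]
    pair = seg(j, k) + seg(k, 255)  # class (t2, t3] + class (t3, 255]
    valid = k > j
    best_score = -np.inf
    best = None
    for t1 in cand[:-2]:
        row = seg(int(t1), cand)  # class (t1, t2] for every t2 candidate
        score = np.where(valid & (j > t1), seg(-1, int(t1)) + row[:, None] + pair, -np.inf)
        idx = int(np.argmax(score))  # first max -> smallest (t2, t3)
        s = score.flat[idx]
        if s > best_score:
            best_score = s
            jj, kk = divmod(idx, len(cand))
            best = (int(t1), int(cand[jj]), int(cand[kk]))
    return ThresholdTriple(*best)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_tissue(
    bl: ImageStack,
    myo: MyocardiumMask,
    thr: ThresholdTriple,
    merge_lowest: bool = True,
) -> TissueClassMap:
    """Label myocardial pixels as healthy / gray zone / scar by thresholds.

    Within the wall: ``v <= t2`` is healthy, ``t2 < v <= t3`` gray zone,
    ``v > t3`` scar.  Three thresholds define four intervals but only
    three tissue categories are reported: the two lowest intervals merge
    into healthy (the sub-``t1`` interval captures blood-suppressed,
    near-zero signal).  With ``merge_lowest=False`` the sub-``t1``
    interval keeps the distinct label ``LABEL_LOW`` instead.
    """
    if bl.geometry != myo.geometry:
        raise GeometryError("BL stack and myocardium mask geometries differ")
    v = bl.voxels
    labels = np.zeros(v.shape, dtype=np.uint8)
    m = myo.data
    labels[m] = LABEL_LOW if not merge_lowest else LABEL_HEALTHY
    labels[m & (v > thr.t1)] = LABEL_HEALTHY
    labels[m & (v > thr.t2)] = LABEL_GRAY_ZONE
    labels[m & (v > thr.t3)] = LABEL_SCAR
    return TissueClassMap(labels, thr, bl.geometry)


def default_seed(
    bl: ImageStack, myo: MyocardiumMask, thr: ThresholdTriple
) -> dict:
    """Per-slice auto seed: gravity center of the largest scar-class blob.

    For each slice the scar class of :func:`classify_tissue` is split into
    4-connected components; the centroid of the largest (ties: the
    component appearing first in row-major order) is snapped to its
    nearest member pixel (Euclidean, ties by row-major order).  Slices
    with no scar-class pixel are absent from the returned dict.
    """
    cmap = classify_tissue(bl, myo, thr)
    seeds: dict = {}
    for i in range(bl.geometry.n_slices):
        scar = cmap.labels[i] == LABEL_SCAR
        if not scar.any():
            continue
        lab, n = ndimage.label(scar, structure=_FOUR_CONNECTED)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1  # argmax -> first max -> row-major first
        rows, cols = np.nonzero(lab == biggest)
        cr, cc = rows.mean(), cols.mean()
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        j = int(np.argmin(d2))  # row-major tie-break: nonzero() is row-major
        seeds[i] = (int(rows[j]), int(cols[j]))
    return seeds


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------


def _grow_slice(
    image: np.ndarray, wall: np.ndarray, seed: tuple[int, int], max_deviation: float
) -> np.ndarray:
    rows, cols = image.shape
    region = np.zeros_like(wall, dtype=bool)
    if not wall[seed]:
        raise SeedError(f"seed {seed} lies outside the myocardium")
    region[seed] = True
    total = float(image[seed])
    count = 1
    frontier: list[tuple[int, int]] = []  # sorted (row, col); row-major ties
    fvals: list[float] = []
    in_frontier = np.zeros_like(wall, dtype=bool)

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and wall[rr, cc] \
                    and not region[rr, cc] and not in_frontier[rr, cc]:
                pos = bisect.bisect_left(frontier, (rr, cc))
                frontier.insert(pos, (rr, cc))
                fvals.insert(pos, float(image[rr, cc]))
                in_frontier[rr, cc] = True

    push_neighbors(*seed)
    while frontier:
        mean = total / count
        dev = np.abs(np.asarray(fvals) - mean)
        j = int(np.argmin(dev))  # first minimum = smallest (row, col)
        if dev[j] > max_deviation:
            break
        r, c = frontier.pop(j)
        val = fvals.pop(j)
        in_frontier[r, c] = False
        region[r, c] = True
        total += val
        count += 1
        push_neighbors(r, c)
    return region


def region_grow(
    bl: ImageStack, myo: MyocardiumMask, params: RegionGrowParams
) -> ScarMask:
    """Adaptive seeded region growing, each slice grown independently.

    At every step the 4-connected frontier of the current region
    (restricted to the myocardium) is scanned and the pixel with minimal
    absolute deviation from the current region mean is admitted, after
    which the mean is updated; growth stops when that minimal deviation
    exceeds ``params.max_deviation`` or the wall component is exhausted.
    Ties among equal deviations go to the smallest ``(row, col)``.
    """
    if bl.geometry != myo.geometry:
        raise GeometryError("BL stack and myocardium mask geometries differ")
    seeds = params.seeds
    if seeds is None:
        thr = multiotsu_thresholds(bl.voxels[myo.data])
        seeds = default_seed(bl, myo, thr)
    out = np.zeros_like(myo.data, dtype=bool)
    for i, seed in sorted(seeds.items()):
        out[i] = _grow_slice(
            np.asarray(bl.voxels[i], dtype=float), myo.data[i], tuple(seed), params.max_deviation
        )
    return ScarMask(out, bl.geometry)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def detect_scar(
    pair: CoRegisteredPair,
    myo: MyocardiumMask,
    method: str = "otsu",
    *,
    max_deviation: float = 25.0,
    seeds: Optional[dict] = None,
    external_mask=None,
    detector: Optional[Callable] = None,
    otsu_on_myocardium_only: bool = True,
) -> tuple[ScarMask, Optional[TissueClassMap]]:
    """Run one of the scar detectors on the BL stack of a co-registered pair.

    ``method`` is one of ``"otsu"``, ``"region_growing"``, ``"external"``.
    The BL stack is expected on the 0–255 working scale (see
    :func:`scarquant.preprocess.normalize_255`).  Returns the scar mask
    and, for the Otsu route, the full tissue-class map.
    """
    bl = pair.bl
    if method == "otsu":
        sample = bl.voxels[myo.data] if otsu_on_myocardium_only else bl.voxels
        thr = multiotsu_thresholds(sample)
        cmap = classify_tissue(bl, myo, thr)
        return cmap.scar_mask(), cmap
    if method == "region_growing":
        params = RegionGrowParams(seeds=seeds, max_deviation=max_deviation)
        if params.seeds is not None:
            for i, (r, c) in params.seeds.items():
                if not myo.data[i, r, c]:
                    raise SeedError(f"seed {(r, c)} on slice {i} lies outside the myocardium")
        return region_grow(bl, myo, params), None
    if method == "external":
        if detector is not None:
            mask = detector(pair, myo)
        elif external_mask is not None:
            if isinstance(external_mask, (str, Path)):
                mask = read_mask(external_mask)
            else:
                mask = external_mask
        else:
            raise ValueError("external method requires a mask or a detector callable")
        data = mask.data if hasattr(mask, "data") else np.asarray(mask).astype(bool)
        scar = ScarMask(data, bl.geometry)
        if (scar.data & ~myo.data).any():
            raise ContainmentError("external scar mask is not contained in the myocardium")
        return scar, None
    raise ValueError(f"unknown detection method {method!r}; expected otsu, region_growing or external")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom
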