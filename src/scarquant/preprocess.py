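"""Intensity preprocessing and BR->BL propagation.

The chain mirrors the standard preparation of short-axis LGE stacks for
analysis: center crop to a fixed field of view (default 160x160), clip
the brightest 2% of pixels per slice, standardize with dataset
statistics, rescale to [0, 1] or — for the thresholding route — stretch
a percentile window (default 1st-99th) to the 0-255 working scale.
Because BR and BL stacks are co-registered by acquisition, contour and
mask propagation between them is an identity coordinate transfer.

All percentiles use linear interpolation between order statistics
(``numpy.percentile`` default), which pins down exactly which pixels the
2% clip touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import (
    ContourSet,
    GeometryError,
    ImageGeometry,
    ImageStack,
    MyocardiumMask,
)

__all__ = [
    "PreprocessConfig",
    "center_crop",
    "clip_top_percent",
    "standardize",
    "normalize_unit",
    "normalize_255",
    "propagate_mask",
    "build_masked_scar_input",
]


@dataclass(frozen=True)
class PreprocessConfig:
    crop_size: int = 160
    clip_top_percent: float = 2.0
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    standardize_mode: str = "self"  # "self": stats from the stack; "fixed": use mean/sd below
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")
        if not (0 <= self.clip_top_percent < 100):
            raise ValueError("clip_top_percent must be in [0, 100)")
        if self.standardize_mode not in ("self", "fixed"):
            raise ValueError("standardize_mode must be 'self' or 'fixed'")
        if self.standardize_mode == "fixed" and (self.sd is None or self.sd <= 0):
            raise ValueError("fixed standardization requires sd > 0")


def _with_geometry(stack: ImageStack, voxels: np.ndarray, rows=None, cols=None) -> ImageStack:
    g = stack.geometry
    geometry = ImageGeometry(
        rows=rows if rows is not None else g.rows,
        cols=cols if cols is not None else g.cols,
        n_slices=g.n_slices,
        in_plane_spacing_mm=g.in_plane_spacing_mm,
        slice_thickness_mm=g.slice_thickness_mm,
    )
    return ImageStack(voxels, geometry, stack.contrast)


def center_crop(stack: ImageStack, size: int = 160) -> ImageStack:
    """Crop a centered ``size x size`` window from every slice.

    The offset is ``floor((dim - size) / 2)``, so for odd remainders the
    extra row/column is dropped from the bottom/right.
    """
    g = stack.geometry
    if size > min(g.rows, g.cols):
        raise GeometryError(f"crop size {size} exceeds image dimensions {(g.rows, g.cols)}")
    r0 = (g.rows - size) // 2
    c0 = (g.cols - size) // 2
    voxels = stack.voxels[:, r0:r0 + size, c0:c0 + size].copy()
    return _with_geometry(stack, voxels, rows=size, cols=size)


def clip_top_percent(stack: ImageStack, p: float = 2.0) -> ImageStack:
    """Clip the brightest ``p`` percent of pixels, slice by slice.

    The per-slice threshold is the ``(100 - p)``-th percentile (linear
    interpolation); values above it are set to it.  ``p=0`` is the
    identity.
    """
    if not (0 <= p < 100):
        raise ValueError(f"clip percentage must be in [0, 100), got {p}")
    v = np.asarray(stack.voxels, dtype=float).copy()
    if p > 0:
        for i in range(v.shape[0]):
            tau = np.percentile(v[i], 100.0 - p)
            v[i] = np.minimum(v[i], tau)
    return stack.with_voxels(v)


def standardize(stack: ImageStack, mean: float | None = None, sd: float | None = None) -> ImageStack:
    """Subtract ``mean`` and divide by ``sd`` (dataset statistics).

    When omitted, the statistics are computed from the stack itself
    (population standard deviation).
    """
    v = np.asarray(stack.voxels, dtype=float)
    if mean is None:
        mean = float(v.mean())
    if sd is None:
        sd = float(v.std())
    if sd <= 0:
        raise ValueError("standard deviation must be positive (constant stack?)")
    return stack.with_voxels((v - mean) / sd)


def normalize_unit(stack: ImageStack) -> ImageStack:
    """Linearly rescale the whole stack to [0, 1]."""
    v = np.asarray(stack.voxels, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("degenerate intensity range; cannot normalize a constant stack")
    return stack.with_voxels((v - lo) / (hi - lo))


def normalize_255(
    stack: ImageStack, stretch_percentiles: tuple[float, float] = (1.0, 99.0)
) -> ImageStack:
    """Percentile contrast stretch to the 0-255 working scale, per slice.

    The window between the two percentiles maps linearly onto [0, 255];
    values outside the window clamp to the endpoints.  This is the
    adaptive contrast step feeding the Otsu detector: it adapts the
    mapping to each slice's own intensity distribution.
    """
    lo_p, hi_p = stretch_percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError(f"invalid stretch percentiles {stretch_percentiles}")
    v = np.asarray(stack.voxels, dtype=float).copy()
    for i in range(v.shape[0]):
        lo = np.percentile(v[i], lo_p)
        hi = np.percentile(v[i], hi_p)
        if hi <= lo:
            raise ValueError(f"slice {i}: degenerate percentile window [{lo}, {hi}]")
        v[i] = np.clip((v[i] - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return stack.with_voxels(v)


def propagate_mask(obj, source: ImageStack, target: ImageStack):
    """Transfer a mask or contour set between co-registered stacks.

    The stacks share one grid by acquisition, so this is an identity
    coordinate transfer; it exists to enforce the co-registration
    contract and to re-home the object on the target geometry.
    """
    if source.geometry != target.geometry:
        raise GeometryError(
            "stacks are not co-registered: "
            f"{source.geometry} vs {target.geometry}"
        )
    if isinstance(obj, MyocardiumMask):
        if obj.geometry != source.geometry:
            raise GeometryError("mask geometry does not match the source stack")
        return MyocardiumMask(obj.data.copy(), target.geometry)
    if isinstance(obj, ContourSet):
        return ContourSet(
            [None if e is None else e.copy() for e in obj.endo],
            [None if e is None else e.copy() for e in obj.epi],
        )
    raise TypeError(f"cannot propagate object of type {type(obj).__name__}")


def build_masked_scar_input(bl: ImageStack, myo: MyocardiumMask) -> ImageStack:
    """Voxelwise product of the preprocessed BL stack and the LV-wall mask.

    The result carries scar information only inside the myocardium and is
    zero elsewhere — the input a learned scar detector consumes.
    """
    if bl.geometry != myo.geometry:
        raise GeometryError("BL stack and myocardium mask geometries differ")
    return bl.with_voxels(np.asarray(bl.voxels, dtype=float) * myo.data)
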