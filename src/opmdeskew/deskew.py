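"""Remapping deskew and streaming maximum-intensity projection.

The core trick: instead of materialising the full deskewed 3D stack and
projecting it afterwards, each raw frame is placed into a larger 2D canvas
at its per-slice row offset ``k * l`` and folded into a running pixelwise
maximum.  Because ``max`` is associative and commutative, the result after
all slices equals the maximum-intensity projection (MIP) of the deskewed
volume, but the memory footprint never exceeds one frame plus one canvas,
and the projection is available incrementally while the stack streams in.

Viewing rotation uses the shear-warp algorithm: rotating the viewing
direction by ``theta`` is realised by evaluating the shear at
``alpha + theta`` and then vertically rescaling the finished projection by
``cos(theta)`` with bilinear interpolation.

``oracle_deskew_then_mip`` and ``oracle_rotate_then_mip`` are deliberate
brute-force reference paths (full volume in memory) used to validate the
streaming path; they are not meant for production-sized stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import GeometryError, StateError, ValidationError
from .geometry import (
    AcquisitionGeometry,
    CanvasSpec,
    ViewParams,
    canvas_spec,
    shear_per_slice,
    warp_factor,
)

__all__ = [
    "RawSlice",
    "ProjectionCanvas",
    "DeskewedVolume",
    "effective_shear",
    "new_canvas",
    "remap_slice",
    "placed_block",
    "fold_max",
    "apply_warp",
    "project_full_stack",
    "oracle_deskew_then_mip",
    "oracle_rotate_then_mip",
    "projection_nrmse",
]

#: sub-pixel offset handling: round to nearest row, or split linearly
OFFSET_MODES = ("nearest", "linear")


@dataclass(frozen=True)
class RawSlice:
    """One camera frame tagged with its position in the scan."""

    pixels: np.ndarray
    index: int
    channel: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValidationError(f"slice pixels must be 2D, got {self.pixels.ndim}D")
        if self.index < 0:
            raise ValidationError(f"slice index must be >= 0, got {self.index}")


@dataclass
class ProjectionCanvas:
    """Running maximum-intensity projection with its shear/warp provenance."""

    pixels: np.ndarray
    shear_px_per_slice: float
    slices_absorbed: int = 0
    warped: bool = False
    theta_deg: Optional[float] = None
    partial: bool = False
    channel: int = 0

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "ProjectionCanvas":
        return ProjectionCanvas(
            pixels=self.pixels.copy(),
            shear_px_per_slice=self.shear_px_per_slice,
            slices_absorbed=self.slices_absorbed,
            warped=self.warped,
            theta_deg=self.theta_deg,
            partial=self.partial,
            channel=self.channel,
        )


@dataclass
class DeskewedVolume:
    """Full remapped stack (reference path only): one canvas-sized plane
    per raw slice, zero outside each slice's shifted footprint."""

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    shear_px_per_slice: float = field(default=0.0)


def effective_shear(geom: AcquisitionGeometry, view: ViewParams) -> float:
    """Per-slice shear (px) after rotating the viewing direction by theta.

    Setting the shear for sheet angle ``alpha + theta`` instead of ``alpha``
    tilts the projection's viewing direction by ``theta``; together with the
    ``cos(theta)`` warp this realises the shear-warp rotation.  ``theta = 0``
    recovers the plain deskew shear.
    """
    combined = geom.sheet_angle_deg + view.rotation_deg
    if not 0.0 < combined <= 90.0:
        raise GeometryError(
            f"sheet angle + rotation = {combined} deg outside (0, 90]"
        )
    if view.rotation_deg == 0.0:
        return shear_per_slice(geom)
    l_um = geom.z_step_um * math.cos(math.radians(combined))
    if combined == 90.0:
        l_um = 0.0
    return l_um / geom.pixel_size_um


def new_canvas(
    geom: AcquisitionGeometry,
    shear_px: Optional[float] = None,
    mode: str = "nearest",
    dtype=None,
    channel: int = 0,
) -> ProjectionCanvas:
    """Fresh all-zero canvas sized so every shifted slice fits."""
    _check_mode(mode)
    spec: CanvasSpec = canvas_spec(geom, shear_px)
    if dtype is None:
        dtype = np.float64 if mode == "linear" else np.uint16
    pixels = np.zeros((spec.height_px, spec.width_px), dtype=dtype)
    return ProjectionCanvas(
        pixels=pixels, shear_px_per_slice=spec.shear_px_per_slice, channel=channel
    )


def _check_mode(mode: str) -> None:
    if mode not in OFFSET_MODES:
        raise ValidationError(f"offset mode must be one of {OFFSET_MODES}, got {mode!r}")


def remap_slice(
    raw: RawSlice,
    geom: AcquisitionGeometry,
    shear_px: Optional[float] = None,
    mode: str = "nearest",
) -> Tuple[float, Tuple[int, int]]:
    """Row offset and canvas footprint of one raw slice.

    Returns ``(offset, (row_start, row_stop))``: the exact (real-valued)
    row offset ``index * l`` and the integer row range the placed slice
    occupies on the canvas.  In ``nearest`` mode the offset is rounded to
    the nearest row (ties toward +inf) and the footprint is the raw height;
    in ``linear`` mode a fractional offset spreads over one extra row.
    """
    _check_mode(mode)
    if raw.index >= geom.n_slices:
        raise ValidationError(
            f"slice index {raw.index} out of range for {geom.n_slices} slices"
        )
    l = shear_per_slice(geom) if shear_px is None else shear_px
    # shear_sign = -1 mirrors the scan: slice 0 lands at the largest offset
    eff_index = raw.index if geom.shear_sign > 0 else geom.n_slices - 1 - raw.index
    offset = eff_index * l
    h = raw.pixels.shape[0]
    if mode == "nearest":
        r0 = int(np.floor(offset + 0.5))
        return offset, (r0, r0 + h)
    r0 = int(np.floor(offset))
    frac = offset - r0
    extra = 1 if frac > 0 else 0
    return offset, (r0, r0 + h + extra)


def placed_block(
    raw: RawSlice,
    geom: AcquisitionGeometry,
    shear_px: Optional[float] = None,
    mode: str = "nearest",
) -> Tuple[int, np.ndarray]:
    """The slice as it lands on the canvas: ``(row_start, block)``.

    ``nearest`` mode returns the raw pixels unchanged at the rounded
    offset.  ``linear`` mode resamples the slice at its fractional offset:
    each output row is the linear blend of the two straddling input rows
    with complementary weights, giving a (height + 1)-row block whose edge
    rows taper against the implicit zeros outside the slice.
    """
    offset, (r0, r1) = remap_slice(raw, geom, shear_px, mode)
    if mode == "nearest":
        return r0, raw.pixels
    frac = offset - math.floor(offset)
    if frac == 0.0:
        return r0, raw.pixels.astype(np.float64)
    h, w = raw.pixels.shape
    block = np.zeros((h + 1, w), dtype=np.float64)
    px = raw.pixels.astype(np.float64)
    block[:h] += (1.0 - frac) * px
    block[1:] += frac * px
    return r0, block


def fold_max(
    canvas: ProjectionCanvas,
    raw: RawSlice,
    geom: AcquisitionGeometry,
    mode: str = "nearest",
) -> ProjectionCanvas:
    """Fold one slice into the running projection (in place).

    Within the slice's shifted footprint the canvas becomes the pixelwise
    max of its previous values and the placed slice; everything outside is
    untouched.  Idempotent, order-independent and monotone, because
    ``max`` is.
    """
    if canvas.warped:
        raise StateError("cannot fold slices into a canvas after warping")
    if raw.pixels.shape != (geom.raw_height_px, geom.raw_width_px):
        raise ValidationError(
            f"slice shape {raw.pixels.shape} does not match ROI "
            f"{(geom.raw_height_px, geom.raw_width_px)}"
        )
    r0, block = placed_block(raw, geom, canvas.shear_px_per_slice, mode)
    r1 = r0 + block.shape[0]
    if r0 < 0 or r1 > canvas.pixels.shape[0]:
        raise StateError(
            f"slice footprint rows [{r0}, {r1}) exceed canvas height "
            f"{canvas.pixels.shape[0]}; canvas was sized for a different shear"
        )
    region = canvas.pixels[r0:r1]
    np.maximum(region, block.astype(canvas.pixels.dtype, copy=False), out=region)
    canvas.slices_absorbed += 1
    return canvas


def apply_warp(canvas: ProjectionCanvas, view: ViewParams) -> ProjectionCanvas:
    """Vertically rescale the finished projection by cos(theta).

    This is the "warp" half of the shear-warp rotation: the canvas height
    shrinks to ``round(Y * cos(theta))`` by bilinear (linear-in-rows)
    interpolation.  Returns a new canvas; theta = 0 returns an identical
    copy.  Integer canvases are rounded half-up back to their dtype.
    """
    if canvas.warped:
        raise StateError("canvas already warped")
    factor = warp_factor(view)
    src = canvas.pixels
    out = canvas.copy()
    out.warped = True
    out.theta_deg = view.rotation_deg
    if factor == 1.0 or not view.warp_enabled:
        return out
    height = src.shape[0]
    new_height = max(1, int(round(height * factor)))
    # endpoint-aligned linear resample along rows; columns untouched
    y = np.linspace(0.0, height - 1.0, new_height)
    lo = np.floor(y).astype(np.intp)
    hi = np.minimum(lo + 1, height - 1)
    w = (y - lo)[:, None]
    resampled = (1.0 - w) * src[lo].astype(np.float64) + w * src[hi].astype(np.float64)
    if np.issubdtype(src.dtype, np.integer):
        resampled = np.floor(resampled + 0.5)
    out.pixels = resampled.astype(src.dtype)
    return out


def project_full_stack(
    stack: Sequence[RawSlice],
    geom: AcquisitionGeometry,
    view: Optional[ViewParams] = None,
    mode: str = "nearest",
) -> ProjectionCanvas:
    """Deskew-project a complete stack through the streaming path.

    Folds every slice into a fresh canvas at the shear implied by the
    geometry and viewing rotation, then applies the warp.  Deterministic;
    equals what the streaming engine emits for the same frames.
    """
    view = view or ViewParams()
    if len(stack) != geom.n_slices:
        raise ValidationError(
            f"stack has {len(stack)} slices, geometry expects {geom.n_slices}"
        )
    shear = effective_shear(geom, view)
    dtype = stack[0].pixels.dtype if mode == "nearest" else None
    canvas = new_canvas(geom, shear, mode, dtype=dtype)
    for raw in stack:
        fold_max(canvas, raw, geom, mode)
    return apply_warp(canvas, view)


def oracle_deskew_then_mip(
    stack: Sequence[RawSlice],
    geom: AcquisitionGeometry,
    view: Optional[ViewParams] = None,
    mode: str = "nearest",
) -> ProjectionCanvas:
    """Reference path: materialise the deskewed volume, then project.

    Remaps every slice into its own canvas-sized plane, takes the pixelwise
    max across planes, then warps.  Memory scales with n_slices; used to
    validate the streaming path, which must agree bit-exactly in nearest
    mode.
    """
    view = view or ViewParams()
    if len(stack) != geom.n_slices:
        raise ValidationError(
            f"stack has {len(stack)} slices, geometry expects {geom.n_slices}"
        )
    shear = effective_shear(geom, view)
    spec = canvas_spec(geom, shear)
    dtype = stack[0].pixels.dtype if mode == "nearest" else np.float64
    vol = np.zeros((geom.n_slices, spec.height_px, spec.width_px), dtype=dtype)
    for raw in stack:
        r0, block = placed_block(raw, geom, shear, mode)
        plane = vol[raw.index]
        np.maximum(
            plane[r0 : r0 + block.shape[0]],
            block.astype(dtype, copy=False),
            out=plane[r0 : r0 + block.shape[0]],
        )
    mip = vol.max(axis=0)
    canvas = ProjectionCanvas(
        pixels=mip, shear_px_per_slice=spec.shear_px_per_slice,
        slices_absorbed=len(stack),
    )
    return apply_warp(canvas, view)


def oracle_rotate_then_mip(volume: np.ndarray, theta_deg: float) -> np.ndarray:
    """Brute-force rotation + MIP, the ground truth for shear-warp views.

    Rotates the volume about its centre in the (slice, row) plane with
    linear interpolation and projects along the slice axis.  Convention:
    positive shear (later slices shifted to larger rows) corresponds to
    rotating with this sign of ``theta_deg``.
    """
    if volume.ndim != 3:
        raise ValidationError("oracle expects a 3D volume")
    rotated = ndimage.rotate(
        volume.astype(np.float64),
        theta_deg,
        axes=(0, 1),
        reshape=True,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return rotated.max(axis=0)


def projection_nrmse(reference: np.ndarray, test: np.ndarray) -> float:
    """Normalised RMS difference between two projections after alignment.

    Pads both images to a common shape, aligns ``test`` onto ``reference``
    by a deterministic best-shift search (whole-pixel grid, then subpixel
    refinement with linear interpolation), and returns
    RMS(difference) / RMS(reference) over the full common frame.  The two
    renderings differ by a pure translation by construction, so shift-only
    alignment is exact up to interpolation; used to compare
    interpolation-limited renderings of the same scene.
    """
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(test, dtype=np.float64)
    pad = 4
    shape = (max(a.shape[0], b.shape[0]) + 2 * pad, max(a.shape[1], b.shape[1]) + 2 * pad)

    def _pad_center(img: np.ndarray) -> np.ndarray:
        out = np.zeros(shape, dtype=np.float64)
        r = (shape[0] - img.shape[0]) // 2
        c = (shape[1] - img.shape[1]) // 2
        out[r : r + img.shape[0], c : c + img.shape[1]] = img
        return out

    a_p, b_p = _pad_center(a), _pad_center(b)
    denom = np.sqrt(np.mean(a_p**2))
    if denom == 0:
        raise ValidationError("reference projection is identically zero")

    def _rms_at(dy: float, dx: float) -> float:
        moved = ndimage.shift(b_p, (dy, dx), order=1, mode="constant", cval=0.0)
        return float(np.sqrt(np.mean((a_p - moved) ** 2)))

    # coarse integer search around zero shift
    span = max(3, min(shape) // 3)
    best = (0.0, 0.0)
    best_rms = _rms_at(0.0, 0.0)
    for dy in range(-span, span + 1):
        for dx in range(-span, span + 1):
            r = _rms_at(float(dy), float(dx))
            if r < best_rms:
                best_rms, best = r, (float(dy), float(dx))
    # subpixel refinement, coordinate descent on a shrinking step
    step = 0.5
    while step >= 0.05:
        improved = True
        while improved:
            improved = False
            for dy, dx in (
                (best[0] + step, best[1]),
                (best[0] - step, best[1]),
                (best[0], best[1] + step),
                (best[0], best[1] - step),
            ):
                r = _rms_at(dy, dx)
                if r < best_rms:
                    best_rms, best, improved = r, (dy, dx), True
        step /= 2.0
    return float(best_rms / denom)
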