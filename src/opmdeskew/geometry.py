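"""Scalar acquisition geometry for angled-scan lightsheet imaging.

In oblique-plane microscopy (OPM) and related lightsheet variants the
excitation sheet makes an angle ``alpha`` with the scan axis, so successive
camera frames are laterally offset from one another.  The per-slice offset
(the shear factor)

    l = z * cos(alpha)

with ``z`` the scan step between frames, is the single number that drives
deskewing: reintroducing ``l`` between frames restores the true sample
geometry.  This module holds that formula, the cos(theta) warp factor used
by the shear-warp viewing rotation, canvas sizing for the remapped
projection, the FOV -> scan-step conversion, the physical depth of a
slice-mode band, and the device-memory budget of the streaming projector.

All angles are accepted in degrees at every interface and converted to
radians exactly once, here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import GeometryError

__all__ = [
    "AcquisitionGeometry",
    "ViewParams",
    "CanvasSpec",
    "shear_per_slice",
    "warp_factor",
    "derive_z_step",
    "canvas_spec",
    "slice_band_depth",
    "estimate_device_memory",
]

#: relative tolerance for the fov == z_step * n_slices consistency check
_FOV_RTOL = 1e-9


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical description of one angled-scan acquisition.

    Parameters
    ----------
    sheet_angle_deg
        Angle ``alpha`` between the excitation sheet and the scan axis,
        in degrees, in ``(0, 90]``.  90 means the sheet is perpendicular
        to the scan axis and no shear is needed.
    pixel_size_um
        Effective camera pixel size projected into the sample, in µm.
    z_step_um
        Distance along the scan axis between successive frames, in µm.
    n_slices
        Number of frames per stack.
    raw_height_px, raw_width_px
        Camera region of interest, in pixels.  Rows run along the sheet
        (the sheared axis); columns are the lateral axis.
    fov_um
        Optional total field of view along the scan axis.  When given it
        must satisfy ``z_step_um == fov_um / n_slices``.
    shear_sign
        +1 shifts later slices toward larger row indices, -1 mirrors the
        scan direction.
    """

    sheet_angle_deg: float
    pixel_size_um: float
    z_step_um: float
    n_slices: int
    raw_height_px: int
    raw_width_px: int
    fov_um: Optional[float] = None
    shear_sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.sheet_angle_deg <= 90.0:
            raise GeometryError(
                f"sheet_angle_deg must be in (0, 90], got {self.sheet_angle_deg}"
            )
        if self.pixel_size_um <= 0:
            raise GeometryError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.z_step_um <= 0:
            raise GeometryError(f"z_step_um must be > 0, got {self.z_step_um}")
        if self.n_slices < 1:
            raise GeometryError(f"n_slices must be >= 1, got {self.n_slices}")
        if self.raw_height_px < 1 or self.raw_width_px < 1:
            raise GeometryError(
                f"camera ROI must be positive, got "
                f"{self.raw_height_px}x{self.raw_width_px}"
            )
        if self.shear_sign not in (-1, 1):
            raise GeometryError(f"shear_sign must be +1 or -1, got {self.shear_sign}")
        if self.fov_um is not None:
            expected = self.fov_um / self.n_slices
            if not math.isclose(self.z_step_um, expected, rel_tol=_FOV_RTOL):
                raise GeometryError(
                    f"inconsistent geometry: z_step_um={self.z_step_um} but "
                    f"fov_um/n_slices={expected}"
                )

    @classmethod
    def from_fov(
        cls,
        sheet_angle_deg: float,
        pixel_size_um: float,
        fov_um: float,
        n_slices: int,
        raw_height_px: int,
        raw_width_px: int,
        shear_sign: int = 1,
    ) -> "AcquisitionGeometry":
        """Build a geometry with the scan step derived from the FOV."""
        return cls(
            sheet_angle_deg=sheet_angle_deg,
            pixel_size_um=pixel_size_um,
            z_step_um=derive_z_step(fov_um, n_slices),
            n_slices=n_slices,
            raw_height_px=raw_height_px,
            raw_width_px=raw_width_px,
            fov_um=fov_um,
            shear_sign=shear_sign,
        )

    def with_slices(self, n_slices: int) -> "AcquisitionGeometry":
        """Same optics, different stack length (drops any stored FOV)."""
        return replace(self, n_slices=n_slices, fov_um=None)


@dataclass(frozen=True)
class ViewParams:
    """Viewing rotation applied through the shear-warp algorithm.

    ``rotation_deg`` (theta) tilts the projection's viewing direction away
    from the deskewed default; the projection is then vertically rescaled
    by ``cos(theta)`` when ``warp_enabled`` is on.
    """

    rotation_deg: float = 0.0
    warp_enabled: bool = True

    def __post_init__(self) -> None:
        if not abs(self.rotation_deg) < 90.0:
            raise GeometryError(
                f"|rotation_deg| must be < 90, got {self.rotation_deg}"
            )


@dataclass(frozen=True)
class CanvasSpec:
    """Size of the projection canvas and the shear used to fill it.

    ``height_px`` is the raw frame height plus the total accumulated shear
    (rounded up so no shifted slice is ever clipped); ``width_px`` equals
    the raw width.
    """

    height_px: int
    width_px: int
    shear_px_per_slice: float


def shear_per_slice(geom: AcquisitionGeometry) -> float:
    """Per-slice lateral shear in pixels: ``z * cos(alpha) / pixel_size``.

    This is the printed shear formula converted from micrometres to camera
    pixels.  At ``alpha = 90`` the result is exactly 0 (no deskewing
    required).  The magnitude is returned; the shift direction is carried
    separately by ``geom.shear_sign``.
    """
    alpha = math.radians(geom.sheet_angle_deg)
    l_um = geom.z_step_um * math.cos(alpha)
    # cos(pi/2) in floats is ~6e-17, not 0; pin the degenerate limit.
    if geom.sheet_angle_deg == 90.0:
        l_um = 0.0
    return l_um / geom.pixel_size_um


def warp_factor(view: ViewParams) -> float:
    """Vertical scaling ``cos(theta)`` that completes a shear-warp rotation.

    Identity (exactly 1.0) at ``theta = 0``; e.g. a 45° rotation scales the
    projection to 0.71 of its height.
    """
    theta = view.rotation_deg
    if not abs(theta) < 90.0:
        raise GeometryError(f"|theta| must be < 90 degrees, got {theta}")
    if theta == 0.0:
        return 1.0
    return math.cos(math.radians(theta))


def derive_z_step(fov_um: float, n_slices: int) -> float:
    """Scan step from the total field of view along the scan axis.

    The scan covers ``fov_um`` with ``n_slices`` evenly spaced frames, so
    the step is simply ``fov_um / n_slices``.
    """
    if n_slices < 1:
        raise GeometryError(f"n_slices must be >= 1, got {n_slices}")
    if fov_um <= 0:
        raise GeometryError(f"fov_um must be > 0, got {fov_um}")
    return fov_um / n_slices


def canvas_spec(
    geom: AcquisitionGeometry, shear_px_per_slice: Optional[float] = None
) -> CanvasSpec:
    """Projection-canvas dimensions for a given (possibly overridden) shear.

    The last slice is shifted by ``(n_slices - 1) * l`` rows, so the canvas
    height is the raw height plus that total shift, rounded up so that a
    fractional shear never pushes a slice off the edge.
    """
    l = shear_per_slice(geom) if shear_px_per_slice is None else shear_px_per_slice
    if l < 0:
        raise GeometryError(f"shear_px_per_slice must be >= 0, got {l}")
    height = geom.raw_height_px + math.ceil((geom.n_slices - 1) * l)
    return CanvasSpec(
        height_px=height, width_px=geom.raw_width_px, shear_px_per_slice=l
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    exponent = math.ceil(math.log10(abs(x)))
    factor = 10.0 ** (sig - exponent)
    return round(x * factor) / factor


def slice_band_depth(
    n_band_px: int, geom: AcquisitionGeometry, sig_figs: Optional[int] = 2
) -> float:
    """Physical depth (µm) of the optical slice kept by a central band.

    In slice mode only a central horizontal band of each raw frame is
    reconstructed; a band of ``n_band_px`` rows spans
    ``n_band_px * pixel_size_um`` micrometres of sample.  The value is
    reported to 2 significant figures by default (``sig_figs=None`` for
    the exact product): e.g. a 12-pixel band at 115 nm pixels is a 1.4 µm
    slice.
    """
    if not 0 < n_band_px <= geom.raw_height_px:
        raise GeometryError(
            f"band of {n_band_px} px must be in (0, {geom.raw_height_px}]"
        )
    depth = n_band_px * geom.pixel_size_um
    return depth if sig_figs is None else _round_sig(depth, sig_figs)


def estimate_device_memory(
    raw_height: int,
    raw_width: int,
    proj_height: int,
    proj_width: int,
    bytes_per_px: int,
) -> int:
    """Device memory (bytes) held by the streaming projector.

    The running-MIP scheme keeps 3 raw-frame-sized arrays (the incoming
    frame plus two scratch arrays for the per-slice max) and 1 array for
    the final projection; nothing the size of the full deskewed volume is
    ever allocated.
    """
    if min(raw_height, raw_width, proj_height, proj_width, bytes_per_px) < 1:
        raise GeometryError("all dimensions and bytes_per_px must be positive")
    return (3 * raw_height * raw_width + proj_height * proj_width) * bytes_per_px
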