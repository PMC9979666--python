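"""Synthetic phantoms: ground-truth 3D scenes forward-sampled into oblique
raw stacks.

The generator makes the whole pipeline testable without a microscope.  A
scene is a voxelised volume in sample coordinates ``(s, v, x)`` — scan
axis, vertical, lateral — containing simple analytic objects (a cylinder
whose axis runs along the lateral axis, or spherical beads).  Forward
sampling mimics angled-scan acquisition: raw frame ``k`` samples the
volume on the plane of the excitation sheet, tilted at the sheet angle
``alpha`` to the scan axis and displaced ``k * z_step`` along it.  Camera
row ``j`` and column ``i`` of that frame map to sample coordinates

    s = k * z_step + j * p * cos(alpha)
    v = j * p * sin(alpha)
    x = i * p

with ``p`` the projected pixel size.  Sampling is trilinear; regions where
the plane leaves the volume read as zero.  This reproduces the
characteristic distortion of raw lightsheet stacks: a cylinder's circular
cross-section appears stretched by ``1 / sin(alpha)`` in a naive stack
MIP, and deskewing restores it to a circle.

The camera noise model is optional Poisson shot noise on the signal plus
Gaussian read noise, both seed-controlled.  The sheet is modelled as an
ideal plane of zero thickness; excitation/detection optics are not
simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage import measure

from .deskew import ProjectionCanvas, RawSlice
from .errors import MeasurementError, ValidationError
from .geometry import AcquisitionGeometry

__all__ = [
    "Cylinder",
    "Bead",
    "PhantomScene",
    "render_oblique_stack",
    "stack_as_array",
    "naive_stack_mip",
    "measure_aspect_ratio",
    "cylinder_scene_for",
]


@dataclass(frozen=True)
class Cylinder:
    """Cylinder with its axis along the lateral (x) axis.

    ``center_sv`` is the axis position in the scan/vertical plane (µm);
    ``x_range`` the lateral extent (µm)."""

    center_sv: Tuple[float, float]
    radius_um: float
    x_range: Tuple[float, float]
    intensity: float = 1000.0


@dataclass(frozen=True)
class Bead:
    """Solid spherical bead at ``center`` = (s, v, x) in µm."""

    center: Tuple[float, float, float]
    radius_um: float
    intensity: float = 1000.0


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth scene: extents, voxel grid, objects and noise model.

    ``extent_um`` is the (S, V, X) size of the volume in µm; the voxel grid
    has isotropic pitch ``voxel_size_um`` with voxel ``[a, b, c]`` centred
    at ``(a, b, c) * voxel_size_um``.  Noise: ``poisson_noise`` applies
    shot noise to the sampled signal, ``read_noise_sigma`` adds Gaussian
    read noise (camera counts); both are reproducible from ``seed``.
    """

    extent_um: Tuple[float, float, float]
    voxel_size_um: float
    objects: Sequence[Union[Cylinder, Bead]] = ()
    background: float = 0.0
    poisson_noise: bool = False
    read_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValidationError("voxel_size_um must be > 0")
        if any(e <= 0 for e in self.extent_um):
            raise ValidationError("scene extents must be positive")
        if self.background < 0 or self.read_noise_sigma < 0:
            raise ValidationError("background and noise levels must be >= 0")
        for obj in self.objects:
            if obj.intensity < 0 or obj.radius_um <= 0:
                raise ValidationError("objects need intensity >= 0 and radius > 0")

    def grid_shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(e / self.voxel_size_um)) + 1 for e in self.extent_um)  # type: ignore[return-value]

    def ground_truth_volume(self) -> np.ndarray:
        """Rasterise the analytic objects onto the voxel grid (float32)."""
        ns, nv, nx = self.grid_shape()
        p = self.voxel_size_um
        s = np.arange(ns)[:, None, None] * p
        v = np.arange(nv)[None, :, None] * p
        x = np.arange(nx)[None, None, :] * p
        vol = np.full((ns, nv, nx), self.background, dtype=np.float32)
        for obj in self.objects:
            if isinstance(obj, Cylinder):
                s0, v0 = obj.center_sv
                inside = ((s - s0) ** 2 + (v - v0) ** 2 <= obj.radius_um**2) & (
                    (x >= obj.x_range[0]) & (x <= obj.x_range[1])
                )
            else:
                s0, v0, x0 = obj.center
                inside = (s - s0) ** 2 + (v - v0) ** 2 + (
                    x - x0
                ) ** 2 <= obj.radius_um**2
            np.maximum(vol, np.where(inside, np.float32(obj.intensity), 0.0), out=vol)
        return vol


def render_oblique_stack(
    scene: PhantomScene, geom: AcquisitionGeometry
) -> List[RawSlice]:
    """Forward-sample the scene into a raw angled-scan stack.

    Each of the ``geom.n_slices`` frames samples the ground-truth volume
    trilinearly on the tilted sheet plane for that scan position; noise is
    applied afterwards per the scene's noise model.  Deterministic for a
    fixed scene (the seed lives in the scene).  Planes that exit the
    volume sample as zero.  Output frames are uint16.
    """
    vol = scene.ground_truth_volume()
    p = geom.pixel_size_um
    alpha = math.radians(geom.sheet_angle_deg)
    j = np.arange(geom.raw_height_px, dtype=np.float64)
    i = np.arange(geom.raw_width_px, dtype=np.float64)
    # in-plane pixel coordinates -> sample coordinates (µm)
    v_um = j * p * math.sin(alpha)
    s_row = j * p * math.cos(alpha)
    x_um = i * p

    rng = np.random.default_rng(scene.seed)
    stack: List[RawSlice] = []
    vox = scene.voxel_size_um
    v_idx = np.broadcast_to((v_um / vox)[:, None], (j.size, i.size))
    x_idx = np.broadcast_to((x_um / vox)[None, :], (j.size, i.size))
    for k in range(geom.n_slices):
        s_um = k * geom.z_step_um + s_row
        s_idx = np.broadcast_to((s_um / vox)[:, None], (j.size, i.size))
        img = ndimage.map_coordinates(
            vol, [s_idx, v_idx, x_idx], order=1, mode="constant", cval=0.0
        )
        if scene.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if scene.read_noise_sigma > 0:
            img = img + rng.normal(0.0, scene.read_noise_sigma, img.shape)
        frame = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        stack.append(RawSlice(pixels=frame, index=k))
    return stack


def stack_as_array(stack: Sequence[RawSlice]) -> np.ndarray:
    """Stack of RawSlice -> (n_slices, height, width) array in scan order."""
    return np.stack([s.pixels for s in sorted(stack, key=lambda s: s.index)])


def naive_stack_mip(stack: Sequence[RawSlice]) -> np.ndarray:
    """Pixelwise max over the raw stack with no deskewing — the distorted
    view a viewer unaware of the lateral shifts would show."""
    return stack_as_array(stack).max(axis=0)


def measure_aspect_ratio(
    projection: Union[ProjectionCanvas, np.ndarray], threshold_fraction: float = 0.5
) -> float:
    """Height/width extent ratio of the single object in a projection.

    Thresholds at ``threshold_fraction * max``, requires exactly one
    connected above-threshold component, and returns its bounding-box
    extent along canvas rows divided by the extent along columns.  A
    circular cross-section gives 1.0; the naive MIP of a tilted-scan
    cylinder gives ``1 / sin(alpha)``.
    """
    pixels = projection.pixels if isinstance(projection, ProjectionCanvas) else projection
    pixels = np.asarray(pixels, dtype=np.float64)
    if not 0.0 < threshold_fraction < 1.0:
        raise MeasurementError("threshold_fraction must be in (0, 1)")
    peak = pixels.max()
    if peak <= 0:
        raise MeasurementError("projection is empty: nothing above zero")
    mask = pixels >= threshold_fraction * peak
    labels, n_objects = measure.label(mask, return_num=True)
    if n_objects != 1:
        raise MeasurementError(
            f"expected one connected object above threshold, found {n_objects}"
        )
    rows, cols = np.nonzero(mask)
    extent_y = rows.max() - rows.min() + 1
    extent_x = cols.max() - cols.min() + 1
    return float(extent_y) / float(extent_x)


def cylinder_scene_for(
    geom: AcquisitionGeometry,
    radius_um: float = 5.0,
    intensity: float = 1000.0,
    voxel_size_um: float = 0.25,
    seed: int = 0,
) -> PhantomScene:
    """Noiseless cylinder scene guaranteed to be fully swept by the scan.

    Places a cylinder (axis along x, length = diameter so its deskewed
    projection is a square patch with a circular cross-section profile)
    where every point of its cross-section is intersected by at least one
    sheet plane of the given geometry: sheet plane ``k`` reaches sample
    point ``(s, v)`` iff ``0 <= (s - v / tan(alpha)) / z_step <= n - 1``.
    """
    alpha = math.radians(geom.sheet_angle_deg)
    p = geom.pixel_size_um
    v_max = geom.raw_height_px * p * math.sin(alpha)
    v0 = v_max / 2.0
    if v0 - radius_um <= 0:
        raise ValidationError("camera ROI too short to contain the cylinder vertically")
    cot = math.cos(alpha) / math.sin(alpha)
    margin = 2.0 * geom.z_step_um
    s0 = v0 * cot + radius_um / math.sin(alpha) + margin
    span_needed = s0 + radius_um / math.sin(alpha) - (v0 * cot) + margin
    if (geom.n_slices - 1) * geom.z_step_um < span_needed - margin:
        raise ValidationError(
            f"scan of {(geom.n_slices - 1) * geom.z_step_um:.1f} µm cannot sweep the "
            f"cylinder (needs ~{span_needed:.1f} µm); increase n_slices"
        )
    x_extent = geom.raw_width_px * p
    x_mid = x_extent / 2.0
    cyl = Cylinder(
        center_sv=(s0, v0),
        radius_um=radius_um,
        x_range=(x_mid - radius_um, x_mid + radius_um),
        intensity=intensity,
    )
    extent_s = max(s0 + radius_um + margin, (geom.n_slices - 1) * geom.z_step_um)
    return PhantomScene(
        extent_um=(extent_s, v_max, x_extent),
        voxel_size_um=voxel_size_um,
        objects=(cyl,),
        seed=seed,
    )
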