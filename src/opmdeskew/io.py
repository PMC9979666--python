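"""File I/O and run configuration.

Stacks travel as multi-page TIFF (page order = slice order = scan order),
projections as single-page TIFF with the acquisition provenance (sheet
angle, shear, rotation, mode) stored as JSON in the ImageDescription tag.
Canvas row 0 is the shallowest remapped position; that orientation is
written into the metadata so downstream viewers are not guessing.

The run configuration is a plain YAML (or JSON — YAML is a superset)
document; see :class:`RunConfig`.  Exactly one of ``fov_um`` /
``z_step_um`` must be given for the geometry, mirroring how the scan step
is set on the instrument (total field of view divided by images per
stack, or an explicit step).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
import yaml

from .deskew import ProjectionCanvas, RawSlice
from .engine import CHANNEL_LAYOUTS, EngineConfig
from .errors import ConfigError, IOFormatError
from .geometry import AcquisitionGeometry, ViewParams

__all__ = [
    "read_stack",
    "write_stack",
    "write_projection",
    "read_projection",
    "RunConfig",
    "load_config",
    "save_config",
]


def read_stack(path: Union[str, os.PathLike]) -> List[RawSlice]:
    """Read a multi-page TIFF stack, preserving bit depth and page order."""
    try:
        tif = tifffile.TiffFile(path)
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise IOFormatError(f"cannot read TIFF stack {path!s}: {exc}") from exc
    with tif:
        slices: List[RawSlice] = []
        shape: Optional[Tuple[int, ...]] = None
        for k, page in enumerate(tif.pages):
            img = page.asarray()
            if img.ndim != 2:
                raise IOFormatError(f"{path!s}: page {k} is not a 2D image")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise IOFormatError(
                    f"{path!s}: page {k} has shape {img.shape}, expected {shape}"
                )
            slices.append(RawSlice(pixels=img, index=k))
    if not slices:
        raise IOFormatError(f"{path!s}: TIFF contains no pages")
    return slices


def _refuse_overwrite(path: Union[str, os.PathLike], force: bool) -> None:
    if not force and os.path.exists(path):
        raise IOFormatError(f"{path!s} exists; pass force=True / --force to overwrite")


def write_stack(
    stack: Sequence[RawSlice], path: Union[str, os.PathLike], force: bool = False
) -> None:
    """Write slices as a multi-page TIFF in scan order."""
    _refuse_overwrite(path, force)
    data = np.stack([s.pixels for s in sorted(stack, key=lambda s: s.index)])
    tifffile.imwrite(path, data, photometric="minisblack")


def write_projection(
    canvas: ProjectionCanvas,
    path: Union[str, os.PathLike],
    metadata: Optional[Dict[str, Any]] = None,
    force: bool = False,
) -> None:
    """Write a projection as single-page TIFF with JSON provenance tags."""
    _refuse_overwrite(path, force)
    meta = {
        "shear_px_per_slice": canvas.shear_px_per_slice,
        "slices_absorbed": canvas.slices_absorbed,
        "warped": canvas.warped,
        "theta_deg": canvas.theta_deg,
        "partial": canvas.partial,
        "channel": canvas.channel,
        "row0": "shallowest remapped position",
    }
    if metadata:
        meta.update(metadata)
    pixels = canvas.pixels
    if pixels.dtype == np.float64:  # linear-mode canvases
        pixels = pixels.astype(np.float32)
    tifffile.imwrite(path, pixels, description=json.dumps(meta))


def read_projection(
    path: Union[str, os.PathLike],
) -> Tuple[np.ndarray, Dict[str, Any]]:
    """Read back a projection and its JSON metadata."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            pixels = page.asarray()
            desc = page.description or "{}"
    except (tifffile.TiffFileError, FileNotFoundError, OSError, IndexError) as exc:
        raise IOFormatError(f"cannot read projection {path!s}: {exc}") from exc
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return pixels, meta


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one deskewing run.

    Serialises to/from the YAML layout::

        geometry:
          sheet_angle_deg: 30.0
          pixel_size_um: 0.115
          fov_um: 50.0          # or: z_step_um: 0.5 (exactly one)
          n_slices: 100
          roi: {height_px: 87, width_px: 1304}
        engine:
          mode: global          # or rolling
          band_height_px: null  # slice mode when set
          offset_mode: nearest  # or linear
        view:
          rotation_deg: 0.0
          warp_enabled: true
        channels: full          # or top-bottom / left-right
        seed: 0
    """

    geometry: AcquisitionGeometry
    engine: EngineConfig = field(default_factory=EngineConfig)
    channels: str = "full"
    seed: int = 0
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.channels not in CHANNEL_LAYOUTS:
            raise ConfigError(
                f"channels: must be one of {CHANNEL_LAYOUTS}, got {self.channels!r}"
            )

    def to_dict(self) -> Dict[str, Any]:
        g = self.geometry
        gd: Dict[str, Any] = {
            "sheet_angle_deg": g.sheet_angle_deg,
            "pixel_size_um": g.pixel_size_um,
            "n_slices": g.n_slices,
            "roi": {"height_px": g.raw_height_px, "width_px": g.raw_width_px},
        }
        if g.fov_um is not None:
            gd["fov_um"] = g.fov_um
        else:
            gd["z_step_um"] = g.z_step_um
        if g.shear_sign != 1:
            gd["shear_sign"] = g.shear_sign
        d: Dict[str, Any] = {
            "geometry": gd,
            "engine": {
                "mode": self.engine.mode,
                "band_height_px": self.engine.band_height_px,
                "offset_mode": self.engine.offset_mode,
            },
            "view": {
                "rotation_deg": self.engine.view.rotation_deg,
                "warp_enabled": self.engine.view.warp_enabled,
            },
            "channels": self.channels,
            "seed": self.seed,
        }
        if self.output is not None:
            d["output"] = self.output
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        gd = _require(d, "geometry", dict)
        roi = _require(gd, "roi", dict, path="geometry")
        has_fov = "fov_um" in gd
        has_z = "z_step_um" in gd
        if has_fov == has_z:
            raise ConfigError(
                "geometry: exactly one of fov_um / z_step_um must be given"
            )
        common = dict(
            sheet_angle_deg=_num(gd, "sheet_angle_deg", "geometry"),
            pixel_size_um=_num(gd, "pixel_size_um", "geometry"),
            n_slices=int(_num(gd, "n_slices", "geometry")),
            raw_height_px=int(_num(roi, "height_px", "geometry.roi")),
            raw_width_px=int(_num(roi, "width_px", "geometry.roi")),
            shear_sign=int(gd.get("shear_sign", 1)),
        )
        try:
            if has_fov:
                geometry = AcquisitionGeometry.from_fov(
                    fov_um=_num(gd, "fov_um", "geometry"), **common
                )
            else:
                geometry = AcquisitionGeometry(
                    z_step_um=_num(gd, "z_step_um", "geometry"), **common
                )
        except Exception as exc:
            raise ConfigError(f"geometry: {exc}") from exc

        vd = d.get("view", {}) or {}
        try:
            view = ViewParams(
                rotation_deg=float(vd.get("rotation_deg", 0.0)),
                warp_enabled=bool(vd.get("warp_enabled", True)),
            )
        except Exception as exc:
            raise ConfigError(f"view: {exc}") from exc

        ed = d.get("engine", {}) or {}
        band = ed.get("band_height_px")
        try:
            engine = EngineConfig(
                mode=ed.get("mode", "global"),
                band_height_px=None if band is None else int(band),
                offset_mode=ed.get("offset_mode", "nearest"),
                view=view,
            )
        except Exception as exc:
            raise ConfigError(f"engine: {exc}") from exc

        return cls(
            geometry=geometry,
            engine=engine,
            channels=d.get("channels", "full"),
            seed=int(d.get("seed", 0)),
            output=d.get("output"),
        )


def _require(d: Dict[str, Any], key: str, typ: type, path: str = "") -> Any:
    where = f"{path}.{key}" if path else key
    if key not in d:
        raise ConfigError(f"{where}: missing required key")
    if not isinstance(d[key], typ):
        raise ConfigError(f"{where}: expected {typ.__name__}")
    return d[key]


def _num(d: Dict[str, Any], key: str, path: str) -> float:
    if key not in d:
        raise ConfigError(f"{path}.{key}: missing required key")
    v = d[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {v!r}")
    return float(v)


def load_config(path: Union[str, os.PathLike]) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise IOFormatError(f"config file not found: {path!s}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path!s}: not valid YAML: {exc}") from exc
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: Union[str, os.PathLike], force: bool = False) -> None:
    """Serialise a run configuration back to YAML (lossless round trip)."""
    _refuse_overwrite(path, force)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
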