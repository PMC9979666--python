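"""Stateful streaming orchestration: global / rolling updates, slice mode,
and multi-channel fan-out.

Two live-view refresh policies are supported.  *Global* mode folds frames
into an in-progress canvas and emits one warped projection per completed
stack — right for fast exposures, where whole stacks arrive at several Hz.
*Rolling* mode keeps a ring buffer of the last stack's worth of frames and
emits an updated projection after every single frame — right for long
exposures, where waiting for a full stack would make the view refresh far
too slowly.

Because ``max`` is not invertible, replacing a frame in rolling mode cannot
be done by subtraction; the engine instead recomputes the canvas rows the
evicted/inserted slice touches from the ring buffer (at most one frame
height plus the shear).

Slice mode zeroes every row outside a central horizontal band of each raw
frame before folding, so only a thin optical section around the sheet
centre is reconstructed — a contrast aid for scattering samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .deskew import (
    ProjectionCanvas,
    RawSlice,
    apply_warp,
    effective_shear,
    fold_max,
    new_canvas,
    placed_block,
)
from .errors import GeometryError, ValidationError
from .geometry import AcquisitionGeometry, ViewParams

__all__ = [
    "EngineConfig",
    "RingBuffer",
    "DeskewEngine",
    "mask_central_band",
    "split_channels",
    "run_multichannel",
    "CHANNEL_LAYOUTS",
]

logger = logging.getLogger(__name__)

#: supported image-splitter layouts
CHANNEL_LAYOUTS = ("full", "top-bottom", "left-right")


@dataclass(frozen=True)
class EngineConfig:
    """Behavioural settings for one deskewing engine.

    ``mode`` selects global (per-stack) or rolling (per-frame) emission.
    ``band_height_px`` switches slice mode on when set.  ``offset_mode``
    picks nearest-row or linear sub-pixel slice placement.
    """

    mode: str = "global"
    band_height_px: Optional[int] = None
    view: ViewParams = field(default_factory=ViewParams)
    offset_mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "rolling"):
            raise ValidationError(f"mode must be 'global' or 'rolling', got {self.mode!r}")
        if self.band_height_px is not None and self.band_height_px < 1:
            raise ValidationError("band_height_px must be positive when set")


def mask_central_band(raw: RawSlice, band_height_px: int) -> RawSlice:
    """Zero all rows outside a centred horizontal band (slice mode).

    For band height ``b`` on frame height ``h`` the retained rows are
    ``[floor((h - b) / 2), floor((h - b) / 2) + b)``; the band content is
    untouched.  ``b == h`` is the identity.
    """
    h = raw.pixels.shape[0]
    if not 0 < band_height_px <= h:
        raise ValidationError(
            f"band height {band_height_px} must be in (0, {h}]"
        )
    if band_height_px == h:
        return raw
    top = (h - band_height_px) // 2
    masked = np.zeros_like(raw.pixels)
    masked[top : top + band_height_px] = raw.pixels[top : top + band_height_px]
    return replace(raw, pixels=masked)


def split_channels(
    frame: np.ndarray, layout: str, index: int = 0
) -> List[RawSlice]:
    """Split one camera frame into per-channel slices.

    Image-splitter optics place channels side by side on the chip; the
    supported layouts are ``full`` (single channel), ``top-bottom`` and
    ``left-right`` halves.  The sub-frames tile the input exactly, so no
    pixel is lost or duplicated.
    """
    if layout not in CHANNEL_LAYOUTS:
        raise ValidationError(f"layout must be one of {CHANNEL_LAYOUTS}, got {layout!r}")
    if frame.ndim != 2:
        raise ValidationError(f"frame must be 2D, got {frame.ndim}D")
    h, w = frame.shape
    if layout == "full":
        return [RawSlice(pixels=frame, index=index, channel=0)]
    if layout == "top-bottom":
        if h % 2:
            raise ValidationError(f"top-bottom split needs even height, got {h}")
        half = h // 2
        parts = (frame[:half], frame[half:])
    else:  # left-right
        if w % 2:
            raise ValidationError(f"left-right split needs even width, got {w}")
        half = w // 2
        parts = (frame[:, :half], frame[:, half:])
    return [RawSlice(pixels=p, index=index, channel=c) for c, p in enumerate(parts)]


class RingBuffer:
    """The last stack's worth of frames, keyed by cyclic stack position."""

    def __init__(self, n_slices: int) -> None:
        self._slots: List[Optional[RawSlice]] = [None] * n_slices
        self.n_slices = n_slices

    def put(self, position: int, raw: RawSlice) -> Optional[RawSlice]:
        """Store a frame at its stack position, returning the evicted one."""
        evicted = self._slots[position]
        self._slots[position] = raw
        return evicted

    @property
    def full(self) -> bool:
        return all(s is not None for s in self._slots)

    def contents(self) -> List[RawSlice]:
        """Frames currently held, in stack-position order (gaps skipped)."""
        return [s for s in self._slots if s is not None]

    def __len__(self) -> int:
        return sum(s is not None for s in self._slots)


class DeskewEngine:
    """Streaming deskew-and-project engine for one channel.

    Feed frames in scan order with :meth:`submit_frame`; the engine folds
    them into a running projection at the shear implied by the geometry and
    current viewing rotation, and emits warped :class:`ProjectionCanvas`
    outputs according to its mode.  The viewing rotation can be changed
    between frames with :meth:`set_view`; no emission ever mixes two views.
    """

    def __init__(
        self,
        geom: AcquisitionGeometry,
        config: Optional[EngineConfig] = None,
        channel: int = 0,
    ) -> None:
        self.geom = geom
        self.config = config or EngineConfig()
        self.channel = channel
        self._view = self.config.view
        self._pending_view: Optional[ViewParams] = None
        self._frames_seen = 0
        self._stack_id = 0
        self._ring = RingBuffer(geom.n_slices)
        self._shear = effective_shear(geom, self._view)
        self._canvas = self._fresh_canvas()

    # -- internal helpers -------------------------------------------------

    def _fresh_canvas(self) -> ProjectionCanvas:
        dtype = None if self.config.offset_mode == "linear" else np.uint16
        return new_canvas(
            self.geom, self._shear, self.config.offset_mode,
            dtype=dtype, channel=self.channel,
        )

    def _prepare(self, raw: RawSlice) -> RawSlice:
        expected = (self.geom.raw_height_px, self.geom.raw_width_px)
        if raw.pixels.shape != expected:
            raise ValidationError(
                f"frame shape {raw.pixels.shape} does not match ROI {expected}"
            )
        if self.config.band_height_px is not None:
            raw = mask_central_band(raw, self.config.band_height_px)
        return raw

    def _emit(self, partial: bool = False) -> ProjectionCanvas:
        out = apply_warp(self._canvas, self._view)
        out.partial = partial
        out.channel = self.channel
        logger.info(
            "emit stack=%d mode=%s theta=%.2f slices=%d partial=%s channel=%d",
            self._stack_id, self.config.mode, self._view.rotation_deg,
            self._canvas.slices_absorbed, partial, self.channel,
        )
        return out

    def _recompute_rows(self, r0: int, r1: int) -> None:
        """Rebuild canvas rows [r0, r1) from the ring buffer.

        Needed because max-folding cannot un-absorb an evicted frame."""
        r0 = max(r0, 0)
        r1 = min(r1, self._canvas.pixels.shape[0])
        self._canvas.pixels[r0:r1] = 0
        for raw in self._ring.contents():
            q0, block = placed_block(
                raw, self.geom, self._shear, self.config.offset_mode
            )
            q1 = q0 + block.shape[0]
            o0, o1 = max(q0, r0), min(q1, r1)
            if o0 >= o1:
                continue
            region = self._canvas.pixels[o0:o1]
            np.maximum(
                region,
                block[o0 - q0 : o1 - q0].astype(region.dtype, copy=False),
                out=region,
            )

    def _rebuild_canvas(self) -> None:
        self._canvas = self._fresh_canvas()
        self._recompute_rows(0, self._canvas.pixels.shape[0])
        self._canvas.slices_absorbed = len(self._ring)

    # -- public API -------------------------------------------------------

    @property
    def view(self) -> ViewParams:
        return self._view

    def set_view(self, view: ViewParams) -> bool:
        """Change the viewing rotation for subsequent emissions.

        Returns True if accepted.  An out-of-range rotation is rejected and
        the previous view kept.  In rolling mode the next emission already
        reflects the new view (the canvas is rebuilt from the buffered
        frames); in global mode the change applies from the next stack so
        the in-progress canvas is never a mixture of two views.
        """
        try:
            new_shear = effective_shear(self.geom, view)
        except GeometryError as exc:
            logger.warning("rejected view change: %s", exc)
            return False
        if self.config.mode == "global" and self._canvas.slices_absorbed > 0:
            self._pending_view = view
            return True
        self._view = view
        self._pending_view = None
        self._shear = new_shear
        if self.config.mode == "rolling":
            self._rebuild_canvas()
        else:
            self._canvas = self._fresh_canvas()
        return True

    def submit_frame(self, raw: RawSlice) -> Optional[ProjectionCanvas]:
        """Process one camera frame; return an emitted projection, if any.

        Global mode folds the frame into the in-progress canvas and emits
        only when the stack completes, then resets.  Rolling mode replaces
        the frame at the cyclic stack position, patches the affected canvas
        rows, and emits after every frame (flagged partial until the buffer
        has filled once).
        """
        raw = self._prepare(raw)
        position = self._frames_seen % self.geom.n_slices
        raw = replace(raw, index=position)
        self._frames_seen += 1

        if self.config.mode == "global":
            fold_max(self._canvas, raw, self.geom, self.config.offset_mode)
            if self._canvas.slices_absorbed == self.geom.n_slices:
                out = self._emit()
                self._stack_id += 1
                if self._pending_view is not None:
                    self._view = self._pending_view
                    self._pending_view = None
                    self._shear = effective_shear(self.geom, self._view)
                self._canvas = self._fresh_canvas()
                return out
            return None

        # rolling mode
        evicted = self._ring.put(position, raw)
        _, (r0, r1) = self._affected_rows(raw)
        if evicted is not None:
            _, (e0, e1) = self._affected_rows(evicted)
            r0, r1 = min(r0, e0), max(r1, e1)
        self._recompute_rows(r0, r1)
        self._canvas.slices_absorbed = len(self._ring)
        if position == self.geom.n_slices - 1:
            self._stack_id += 1
        return self._emit(partial=not self._ring.full)

    def _affected_rows(self, raw: RawSlice) -> Tuple[float, Tuple[int, int]]:
        q0, block = placed_block(raw, self.geom, self._shear, self.config.offset_mode)
        return q0, (q0, q0 + block.shape[0])

    def project_buffer(self) -> ProjectionCanvas:
        """Warped projection of the ring buffer's current contents."""
        return self._emit(partial=not self._ring.full)


def run_multichannel(
    frames: Sequence[np.ndarray],
    geom: AcquisitionGeometry,
    config: EngineConfig,
    layout: str = "full",
) -> List[List[ProjectionCanvas]]:
    """Fan a frame sequence out to one independent engine per channel.

    Each raw frame is split according to ``layout`` and every channel is
    deskewed by its own engine, exactly as if it had been acquired alone.
    Returns the emitted projections per channel.
    """
    n_channels = 1 if layout == "full" else 2
    probe = split_channels(np.asarray(frames[0]), layout)
    ch_geom = replace(
        geom,
        raw_height_px=probe[0].pixels.shape[0],
        raw_width_px=probe[0].pixels.shape[1],
        fov_um=geom.fov_um,
    )
    engines = [DeskewEngine(ch_geom, config, channel=c) for c in range(n_channels)]
    outputs: List[List[ProjectionCanvas]] = [[] for _ in range(n_channels)]
    for i, frame in enumerate(frames):
        for sl in split_channels(np.asarray(frame), layout, index=i):
            emitted = engines[sl.channel].submit_frame(sl)
            if emitted is not None:
                outputs[sl.channel].append(emitted)
    return outputs
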