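"""Simulated acquisition pipeline: camera -> bounded queue -> engine.

The live system runs acquisition, processing and display as concurrent
stages joined by bounded FIFO queues; as long as processing keeps pace
with acquisition the raw-data queue never grows, so memory stays constant
no matter how long imaging runs.  Here that architecture is reproduced as
a deterministic discrete-event simulation: stages communicate through a
capacity-limited FIFO, timestamps come from a simulated clock, and the
scheduling is single-threaded.  The concurrency *contract* — exactly-once,
in-order delivery, bounded queue depth, backpressure instead of frame
drops — is what is preserved and tested; whether stages are OS processes
is a performance choice the simulation deliberately abstracts away.

``FrameSource`` is the plug-in point where a real camera adapter would
replace :class:`SimulatedCamera` without touching engine code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Protocol, Tuple

import numpy as np

from .deskew import ProjectionCanvas, RawSlice
from .engine import DeskewEngine
from .errors import ConfigError, ValidationError

__all__ = ["FrameSource", "SimulatedCamera", "simulated_camera", "QueueStats", "run_pipeline"]


class FrameSource(Protocol):
    """Anything that yields camera frames in scan order.

    Iterating produces ``(frame, stack_index, timestamp_ms)`` tuples with
    stack indices cycling ``0 .. frames_per_stack - 1`` and monotone
    timestamps.  ``frame_interval_ms`` is the nominal time between frames.
    """

    frames_per_stack: int
    frame_interval_ms: float

    def __iter__(self) -> Iterator[Tuple[np.ndarray, int, float]]: ...


@dataclass
class QueueStats:
    """Bookkeeping for one bounded queue over a pipeline run."""

    frames_in: int = 0
    frames_out: int = 0
    max_depth: int = 0
    overflow_events: int = 0
    depth_series: List[int] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return self.frames_in - self.frames_out


class SimulatedCamera:
    """Replays a phantom stack cyclically on a simulated clock.

    Stands in for real camera control: frame content is deterministic and
    independent of the timing parameters, and the inter-frame interval is
    ``exposure_ms + readout_ms`` (zero means as-fast-as-possible replay).
    """

    def __init__(
        self,
        stack: np.ndarray,
        exposure_ms: float = 0.0,
        readout_ms: float = 0.0,
        n_cycles: int = 1,
    ) -> None:
        stack = np.asarray(stack)
        if stack.ndim != 3 or stack.shape[0] == 0:
            raise ConfigError("camera stack must be a non-empty 3D array")
        if exposure_ms < 0 or readout_ms < 0:
            raise ConfigError("exposure and readout times must be >= 0")
        if n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        self._stack = stack
        self.frames_per_stack = stack.shape[0]
        self.frame_interval_ms = exposure_ms + readout_ms
        self.n_cycles = n_cycles

    def __iter__(self) -> Iterator[Tuple[np.ndarray, int, float]]:
        t = 0.0
        for _ in range(self.n_cycles):
            for k in range(self.frames_per_stack):
                t += self.frame_interval_ms
                yield self._stack[k], k, t


def simulated_camera(
    stack: np.ndarray,
    exposure_ms: float = 0.0,
    readout_ms: float = 0.0,
    n_cycles: int = 1,
) -> SimulatedCamera:
    """Convenience constructor mirroring :class:`SimulatedCamera`."""
    return SimulatedCamera(stack, exposure_ms, readout_ms, n_cycles)


def run_pipeline(
    source: FrameSource,
    engine: DeskewEngine,
    max_queue_depth: int = 8,
    processing_delay_ms: float = 0.0,
) -> Tuple[List[ProjectionCanvas], QueueStats]:
    """Run acquisition through the bounded raw-data queue into the engine.

    Every frame is delivered to the engine exactly once, in order, so the
    emitted projections are identical to a plain serial ``submit_frame``
    loop; the queue simulation only determines the timing statistics.

    A frame arriving at a full queue records one backpressure (overflow)
    event and stalls acquisition until the consumer frees a slot — frames
    are never dropped.  With a consumer at least as fast as the producer
    the recorded max depth stays at a small constant regardless of how
    many stacks are streamed (the bounded-memory contract of the live
    system).

    Returns the emitted projections and the raw-queue :class:`QueueStats`.
    """
    if max_queue_depth < 1:
        raise ConfigError("max_queue_depth must be >= 1")
    if processing_delay_ms < 0:
        raise ConfigError("processing_delay_ms must be >= 0")

    stats = QueueStats()
    outputs: List[ProjectionCanvas] = []

    # Discrete-event timing: e[k] = enqueue time, s[k] = dequeue (processing
    # start) time, f[k] = processing finish time.  FIFO, single consumer.
    dequeue_times: List[float] = []
    last_finish = 0.0
    last_enqueue = 0.0
    n_dequeued_before = 0  # pointer into dequeue_times (sorted, nondecreasing)

    for k, (frame, stack_index, timestamp) in enumerate(source):
        arrival = max(timestamp, last_enqueue)
        # count frames already dequeued by `arrival`
        while (
            n_dequeued_before < len(dequeue_times)
            and dequeue_times[n_dequeued_before] <= arrival
        ):
            n_dequeued_before += 1
        depth = k - n_dequeued_before
        if depth >= max_queue_depth:
            # queue full: backpressure — producer waits for a slot
            stats.overflow_events += 1
            arrival = dequeue_times[k - max_queue_depth]
            while (
                n_dequeued_before < len(dequeue_times)
                and dequeue_times[n_dequeued_before] <= arrival
            ):
                n_dequeued_before += 1
            depth = k - n_dequeued_before
        enqueue = arrival
        start = max(enqueue, last_finish)
        finish = start + processing_delay_ms
        dequeue_times.append(start)
        last_finish = finish
        last_enqueue = enqueue

        stats.frames_in += 1
        depth_after = depth + 1
        stats.depth_series.append(depth_after)
        stats.max_depth = max(stats.max_depth, depth_after)

        # content path: deliver exactly once, in order
        raw = RawSlice(pixels=np.asarray(frame), index=stack_index)
        emitted = engine.submit_frame(raw)
        stats.frames_out += 1
        if emitted is not None:
            outputs.append(emitted)

    if stats.frames_in != stats.frames_out:
        raise ValidationError("pipeline audit failed: frames lost in transit")
    return outputs, stats
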