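"""Streaming engine behaviour: update modes, slice band, channels, view."""

import numpy as np
import pytest

from opmdeskew import (
    DeskewEngine,
    EngineConfig,
    RawSlice,
    ValidationError,
    ViewParams,
    mask_central_band,
    project_full_stack,
    run_multichannel,
    split_channels,
)


def frames_for(rng, geom, n):
    return [
        rng.integers(0, 1000, (geom.raw_height_px, geom.raw_width_px), np.uint16)
        for _ in range(n)
    ]


class TestGlobalMode:
    def test_emits_once_per_completed_stack(self, geom_small, rng):
        eng = DeskewEngine(geom_small, EngineConfig(mode="global"))
        emitted_at = [
            k
            for k, f in enumerate(frames_for(rng, geom_small, 15))
            if eng.submit_frame(RawSlice(f, k)) is not None
        ]
        assert emitted_at == [4, 9, 14]

    def test_identical_stacks_give_identical_outputs(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 5)
        eng = DeskewEngine(geom_small, EngineConfig(mode="global"))
        outs = [eng.submit_frame(RawSlice(f, k)) for k, f in enumerate(frames * 2)]
        a, b = [o for o in outs if o is not None]
        assert np.array_equal(a.pixels, b.pixels)

    def test_emission_matches_full_stack_projection(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 5)
        eng = DeskewEngine(geom_small, EngineConfig(mode="global"))
        out = [eng.submit_frame(RawSlice(f, k)) for k, f in enumerate(frames)][-1]
        ref = project_full_stack(
            [RawSlice(f, k) for k, f in enumerate(frames)], geom_small
        )
        assert np.array_equal(out.pixels, ref.pixels)


class TestRollingMode:
    def test_every_frame_emits(self, geom_small, rng):
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        outs = [
            eng.submit_frame(RawSlice(f, k))
            for k, f in enumerate(frames_for(rng, geom_small, 12))
        ]
        assert all(o is not None for o in outs)

    def test_partial_flag_until_buffer_wraps(self, geom_small, rng):
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        outs = [
            eng.submit_frame(RawSlice(f, k))
            for k, f in enumerate(frames_for(rng, geom_small, 8))
        ]
        assert [o.partial for o in outs] == [True] * 4 + [False] * 4

    def test_matches_global_projection_of_buffer(self, geom_small, rng):
        n = geom_small.n_slices
        frames = frames_for(rng, geom_small, 3 * n)
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        for k, f in enumerate(frames):
            out = eng.submit_frame(RawSlice(f, k))
            if k < n - 1:
                continue
            buffer = {j % n: frames[j] for j in range(k - n + 1, k + 1)}
            ref = project_full_stack(
                [RawSlice(buffer[p], p) for p in range(n)], geom_small
            )
            assert np.array_equal(out.pixels, ref.pixels)


class TestSliceBand:
    def test_full_height_band_is_identity(self, rng):
        frame = rng.integers(0, 1000, (10, 6), np.uint16)
        raw = RawSlice(frame, 0)
        assert mask_central_band(raw, 10) is raw

    def test_worked_band_placement_12_of_87(self, rng):
        frame = rng.integers(1, 1000, (87, 4), np.uint16)
        out = mask_central_band(RawSlice(frame, 0), 12)
        assert np.array_equal(out.pixels[37:49], frame[37:49])
        assert not out.pixels[:37].any() and not out.pixels[49:].any()

    def test_all_zero_stays_zero(self):
        out = mask_central_band(RawSlice(np.zeros((20, 5), np.uint16), 0), 4)
        assert not out.pixels.any()

    def test_band_larger_than_frame_rejected(self):
        with pytest.raises(ValidationError):
            mask_central_band(RawSlice(np.zeros((8, 8), np.uint16), 0), 9)

    def test_full_band_engine_equals_plain_engine(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 5)
        plain = DeskewEngine(geom_small, EngineConfig(mode="global"))
        banded = DeskewEngine(
            geom_small,
            EngineConfig(mode="global", band_height_px=geom_small.raw_height_px),
        )
        for k, f in enumerate(frames):
            a = plain.submit_frame(RawSlice(f, k))
            b = banded.submit_frame(RawSlice(f, k))
        assert np.array_equal(a.pixels, b.pixels)

    def test_band_removes_off_centre_signal(self, geom_small, rng):
        frames = [np.zeros((8, 8), np.uint16) for _ in range(5)]
        frames[0][0, :] = 500  # top edge: outside any small central band
        eng = DeskewEngine(geom_small, EngineConfig(mode="global", band_height_px=2))
        out = [eng.submit_frame(RawSlice(f, k)) for k, f in enumerate(frames)][-1]
        assert not out.pixels.any()


class TestSplitChannels:
    def test_full_layout_is_identity(self, rng):
        frame = rng.integers(0, 9, (6, 4), np.uint16)
        (only,) = split_channels(frame, "full", index=3)
        assert only.channel == 0 and only.index == 3
        assert np.array_equal(only.pixels, frame)

    @pytest.mark.parametrize("layout", ["top-bottom", "left-right"])
    def test_two_way_splits_conserve_pixels(self, layout, rng):
        frame = rng.integers(0, 1000, (8, 12), np.uint16)
        parts = split_channels(frame, layout)
        assert len(parts) == 2
        assert sum(p.pixels.size for p in parts) == frame.size
        axis = 0 if layout == "top-bottom" else 1
        rejoined = np.concatenate([p.pixels for p in parts], axis=axis)
        assert np.array_equal(rejoined, frame)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValidationError):
            split_channels(np.zeros((7, 4), np.uint16), "top-bottom")
        with pytest.raises(ValidationError):
            split_channels(np.zeros((4, 7), np.uint16), "left-right")

    def test_channels_independent_of_each_other(self, geom_small, rng):
        # two-channel run must equal each channel deskewed alone
        from dataclasses import replace

        g = replace(geom_small, raw_height_px=16)
        frames = [
            rng.integers(0, 1000, (16, 8), np.uint16) for _ in range(g.n_slices)
        ]
        cfg = EngineConfig(mode="global")
        both = run_multichannel(frames, g, cfg, layout="top-bottom")
        for channel in (0, 1):
            half_geom = replace(g, raw_height_px=8)
            solo = DeskewEngine(half_geom, cfg)
            outs = []
            for k, f in enumerate(frames):
                part = split_channels(f, "top-bottom", index=k)[channel]
                o = solo.submit_frame(part)
                if o is not None:
                    outs.append(o)
            assert len(outs) == len(both[channel]) == 1
            assert np.array_equal(outs[0].pixels, both[channel][0].pixels)


class TestSetView:
    def test_rejected_view_keeps_previous(self, geom_small, rng):
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        before = eng.view
        assert not eng.set_view(ViewParams(45.0))  # 60 + 45 > 90
        assert eng.view == before

    def test_round_trip_rotation_is_bit_exact(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 5)
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        for k, f in enumerate(frames):
            eng.submit_frame(RawSlice(f, k))
        base = eng.project_buffer()
        assert eng.set_view(ViewParams(10.0))
        rotated = eng.project_buffer()
        assert rotated.pixels.shape != base.pixels.shape or not np.array_equal(
            rotated.pixels, base.pixels
        )
        assert eng.set_view(ViewParams(0.0))
        back = eng.project_buffer()
        assert np.array_equal(back.pixels, base.pixels)

    def test_global_mode_applies_from_next_stack(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 10)
        eng = DeskewEngine(geom_small, EngineConfig(mode="global"))
        outs = []
        for k, f in enumerate(frames):
            if k == 2:  # mid-stack change
                assert eng.set_view(ViewParams(10.0))
            o = eng.submit_frame(RawSlice(f, k))
            if o is not None:
                outs.append(o)
        stack1 = [RawSlice(f, k) for k, f in enumerate(frames[:5])]
        stack2 = [RawSlice(f, k) for k, f in enumerate(frames[5:])]
        ref1 = project_full_stack(stack1, geom_small, ViewParams(0.0))
        ref2 = project_full_stack(stack2, geom_small, ViewParams(10.0))
        assert np.array_equal(outs[0].pixels, ref1.pixels)
        assert np.array_equal(outs[1].pixels, ref2.pixels)

    def test_rolling_recomputes_immediately(self, geom_small, rng):
        frames = frames_for(rng, geom_small, 5)
        eng = DeskewEngine(geom_small, EngineConfig(mode="rolling"))
        for k, f in enumerate(frames):
            eng.submit_frame(RawSlice(f, k))
        assert eng.set_view(ViewParams(15.0))
        out = eng.project_buffer()
        ref = project_full_stack(
            [RawSlice(f, k) for k, f in enumerate(frames)], geom_small, ViewParams(15.0)
        )
        assert np.array_equal(out.pixels, ref.pixels)


class TestFrameValidation:
    def test_bad_shape_rejected_and_state_preserved(self, geom_small, rng):
        eng = DeskewEngine(geom_small, EngineConfig(mode="global"))
        with pytest.raises(ValidationError):
            eng.submit_frame(RawSlice(np.zeros((3, 3), np.uint16), 0))
        # engine still counts from zero: a clean stack completes normally
        outs = [
            eng.submit_frame(RawSlice(f, k))
            for k, f in enumerate(frames_for(rng, geom_small, 5))
        ]
        assert outs[-1] is not None
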