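"""Linear RGB interpolation and frame assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slowchange import pipeline
from slowchange.errors import GeometryError
from slowchange.morph import (
    FixationOverlay,
    MorphConfig,
    MorphSeries,
    apply_fixation_overlay,
    assemble_frames,
    build_morph_series,
    schedule_quick_changes,
)
from slowchange.scene import demo_spec


def _brute_force_morph(start, end, n):
    """Independent evaluation of the interpolation formula, pixel by pixel."""
    out = []
    for i in range(n):
        frac = i / (n - 1)
        vals = np.floor(
            start.astype(float) + frac * (end.astype(float) - start.astype(float)) + 0.5
        )
        out.append(vals.astype(np.uint8))
    return out


def test_unit_ramp_is_identity():
    """A 0 -> 191 ramp over 192 frames hits every 8-bit value in order."""
    start = np.zeros((1, 1, 3), np.uint8)
    end = np.full((1, 1, 3), 191, np.uint8)
    frames = build_morph_series(start, end, 192)
    for i, f in enumerate(frames):
        assert (f == i).all()


def test_default_morph_length():
    cfg = MorphConfig()
    assert cfg.n_morph_frames == 192
    start = np.zeros((2, 2, 3), np.uint8)
    end = np.full((2, 2, 3), 100, np.uint8)
    assert len(build_morph_series(start, end, cfg.n_morph_frames)) == 192


def test_degenerate_morph_start_equals_end():
    img = np.full((3, 3, 3), 77, np.uint8)
    for f in build_morph_series(img, img, 10):
        assert np.array_equal(f, img)


def test_half_up_rounding():
    start = np.zeros((1, 1, 3), np.uint8)
    end = np.ones((1, 1, 3), np.uint8)
    frames = build_morph_series(start, end, 3)  # fractions 0, .5, 1
    assert frames[1][0, 0, 0] == 1  # .5 rounds up


def test_dimension_mismatch_rejected():
    with pytest.raises(GeometryError):
        build_morph_series(np.zeros((2, 2, 3), np.uint8), np.zeros((3, 3, 3), np.uint8), 5)


@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(2, 40),
)
def test_morph_matches_formula_and_is_monotone(seed, n):
    rng = np.random.default_rng(seed)
    start = rng.integers(0, 256, (4, 5, 3), dtype=np.uint8)
    end = rng.integers(0, 256, (4, 5, 3), dtype=np.uint8)
    frames = build_morph_series(start, end, n)
    expected = _brute_force_morph(start, end, n)
    for got, want in zip(frames, expected):
        assert np.array_equal(got, want)
    # endpoints are exact copies
    assert np.array_equal(frames[0], start)
    assert np.array_equal(frames[-1], end)
    # per-pixel, per-channel monotone between the endpoints
    stack = np.stack(frames).astype(np.int16)
    diffs = np.diff(stack, axis=0)
    sign = np.sign(end.astype(np.int16) - start.astype(np.int16))
    assert ((diffs * sign[None]) >= 0).all()


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _series_map(cset, n_frames):
    return pipeline.LazySeriesMap(cset, n_frames)


def test_default_assembly_structure(small_cset, default_config):
    seq, schedule = pipeline.build_sequence(small_cset, default_config)
    assert len(seq) == 240
    assert seq.duration_s == pytest.approx(20.0)
    assert seq.fps == 12
    assert seq.segments.count("lead") == 24
    assert seq.segments.count("morph") == 192
    assert seq.segments.count("tail") == 24
    assert len(schedule.events) == 3
    for ev in schedule.events:
        assert ev.duration_frames == 12


def test_morph_index_advances_one_per_frame(small_cset, default_config):
    seq, _ = pipeline.build_sequence(small_cset, default_config)
    idx = [m for m, s in zip(seq.morph_indices, seq.segments) if s == "morph"]
    assert idx == list(range(192))


def test_zero_quick_changes_equals_plain_morph(small_cset):
    """With no quick changes the stimulus is exactly lead + morph series + tail."""
    cfg = MorphConfig(quick_change_count=0, seed=3)
    flat = pipeline.scene_composite_set(
        demo_spec(n_features=0, size=96), 1, pipeline.color_pair("purple-orange")
    )
    seq, schedule = pipeline.build_sequence(flat, cfg)
    assert schedule.events == ()
    start = flat.get(flat.color_labels[0], ())
    end = flat.get(flat.color_labels[1], ())
    series = build_morph_series(start, end, cfg.n_morph_frames)
    expected = [series[0]] * cfg.n_lead + series + [series[-1]] * cfg.n_tail
    assert len(seq) == len(expected)
    for got, want in zip(seq.frames, expected):
        assert np.array_equal(got, want)


def test_pixels_outside_windows_follow_pure_morph(small_cset, default_config):
    """Away from quick-change windows, every morph frame equals the series of
    the current state vector — the slow fade never pauses for quick changes."""
    seq, schedule = pipeline.build_sequence(small_cset, default_config)
    series_map = _series_map(small_cset, default_config.n_morph_frames)
    windows = {
        i for ev in schedule.events for i in range(ev.onset_frame, ev.end_frame)
    }
    initial = tuple(
        next(ev.from_state for ev in schedule.events if ev.feature_index == f)
        for f in range(small_cset.n_features)
    )
    for t, (seg, i) in enumerate(zip(seq.segments, seq.morph_indices)):
        if seg != "morph" or i in windows:
            continue
        states = list(initial)
        for ev in schedule.events:
            if i >= ev.end_frame:
                states[ev.feature_index] = ev.to_state
        assert np.array_equal(seq.frames[t], series_map[tuple(states)].frames[i])


def test_features_flip_exactly_once(small_cset, default_config):
    """After its window each feature stays in its to_state for the rest of
    the video (checked inside the feature's bbox)."""
    seq, schedule = pipeline.build_sequence(small_cset, default_config)
    series_map = _series_map(small_cset, default_config.n_morph_frames)
    final = [d[0] for d in small_cset.feature_state_domains]
    for ev in schedule.events:
        final[ev.feature_index] = ev.to_state
    post = series_map[tuple(final)].frames
    last_end = max(ev.end_frame for ev in schedule.events)
    for t, (seg, i) in enumerate(zip(seq.segments, seq.morph_indices)):
        if seg == "morph" and i >= last_end:
            assert np.array_equal(seq.frames[t], post[i])


def test_quick_change_window_is_a_linear_crossfade(small_cset, default_config):
    seq, schedule = pipeline.build_sequence(small_cset, default_config)
    series_map = _series_map(small_cset, default_config.n_morph_frames)
    ev = schedule.events[0]
    initial = tuple(
        next(e.from_state for e in schedule.events if e.feature_index == f)
        for f in range(small_cset.n_features)
    )
    pre = list(initial)
    post = list(initial)
    post[ev.feature_index] = ev.to_state
    for j in range(ev.duration_frames):
        i = ev.onset_frame + j
        alpha = (j + 1) / ev.duration_frames
        a = series_map[tuple(pre)].frames[i].astype(float)
        b = series_map[tuple(post)].frames[i].astype(float)
        want = np.floor((1 - alpha) * a + alpha * b + 0.5).astype(np.uint8)
        assert np.array_equal(seq.frames[default_config.n_lead + i], want)


# ---------------------------------------------------------------------------
# fixation overlay
# ---------------------------------------------------------------------------


def test_overlay_none_is_identity(small_cset, default_config):
    seq, _ = pipeline.build_sequence(small_cset, default_config)
    assert apply_fixation_overlay(seq, None) is seq


def test_overlay_geometry_and_timing(small_cset):
    overlay = FixationOverlay()
    cfg = MorphConfig(seed=5, overlay=overlay)
    plain, _ = pipeline.build_sequence(small_cset, MorphConfig(seed=5))
    marked, _ = pipeline.build_sequence(small_cset, cfg)
    h, w = plain.shape
    cy, cx = h // 2, w // 2
    mark = overlay.mark_mask(h, w)
    cross = overlay.crosshair_mask(h, w)
    flash = round(overlay.crosshair_flash_s * cfg.fps)

    # center pixel: white during lead, underlying scene mid-morph
    assert tuple(marked.frames[0][cy, cx]) == (255, 255, 255)
    mid = cfg.n_lead + cfg.n_morph_frames // 2
    assert np.array_equal(marked.frames[mid], plain.frames[mid])

    for t, seg in enumerate(plain.segments):
        diff = np.any(marked.frames[t] != plain.frames[t], axis=2)
        if seg == "morph":
            assert not diff.any()
            continue
        in_flash = (seg == "lead" and t >= cfg.n_lead - flash) or (
            seg == "tail" and t < len(plain) - cfg.n_tail + flash
        )
        allowed = (mark | cross) if in_flash else mark
        assert not (diff & ~allowed).any()
        assert (marked.frames[t][mark] == 255).all()
        if in_flash:
            assert (marked.frames[t][cross] == 255).all()
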