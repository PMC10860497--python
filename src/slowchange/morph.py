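"""Morph-series construction, quick-change scheduling and frame assembly.

A stimulus is a 20 s video (at the defaults): 2 s of the unchanged start
image, 16 s during which the slow-change region fades linearly in RGB from
the start color to the end color (192 frames at 12 fps), and 2 s of the
unchanged end image.  One *morph series* — the full run of interpolated
frames — exists for every combination of quick-change feature states; the
assembled video steps through the morph one frame per frame, switching
between parallel series when a scheduled quick change occurs, so the slow
fade never pauses.

All frame interpolation is done in floating point on the 8-bit values and
rounded half-up at the end; morph fractions use the inclusive-endpoint
convention ``i / (n - 1)`` so the first and last morph frames are bit-exact
copies of the input composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .composites import CompositeSet
from .errors import ConsistencyError, GeometryError, SchedulingError


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero-half upward.

    numpy's ``round`` rounds half to even; a fixed half-up convention keeps
    every interpolated frame reproducible across platforms.
    """
    return np.floor(x + 0.5)


@dataclass(frozen=True)
class FixationOverlay:
    """Central white fixation mark shown during the lead and tail segments,
    plus a full-image four-line cross-hair (horizontal, vertical, two
    diagonals, each ``crosshair_width_px`` wide) flashed when the mark
    disappears and reappears."""

    radius_px: int = 6
    crosshair_width_px: int = 5
    crosshair_flash_s: float = 0.5
    color: tuple[int, int, int] = (255, 255, 255)

    def mark_mask(self, height: int, width: int) -> np.ndarray:
        if 2 * self.radius_px >= min(height, width):
            raise GeometryError("fixation mark does not fit the canvas")
        cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
        yy, xx = np.mgrid[0:height, 0:width]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius_px**2

    def crosshair_mask(self, height: int, width: int) -> np.ndarray:
        cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
        yy, xx = np.mgrid[0:height, 0:width]
        half = self.crosshair_width_px / 2.0
        horiz = np.abs(yy - cy) <= half
        vert = np.abs(xx - cx) <= half
        # perpendicular distance to the diagonals y = x + c and y = -x + c
        d1 = np.abs((yy - cy) - (xx - cx)) / np.sqrt(2.0) <= half
        d2 = np.abs((yy - cy) + (xx - cx)) / np.sqrt(2.0) <= half
        return horiz | vert | d1 | d2


@dataclass(frozen=True)
class MorphConfig:
    """All timing parameters of a generation run.

    Defaults give the canonical stimulus: 12 fps, 2 s lead, 16 s morph
    (192 frames), 2 s tail, 1 s quick changes separated by at least 1 s.
    """

    fps: int = 12
    lead_s: float = 2.0
    morph_s: float = 16.0
    tail_s: float = 2.0
    quick_change_count: int = 3
    quick_change_duration_s: float = 1.0
    min_gap_s: float = 1.0
    seed: int = 0
    overlay: FixationOverlay | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("lead_s", "morph_s", "tail_s", "quick_change_duration_s", "min_gap_s"):
            frames = self.fps * getattr(self, name)
            if abs(frames - round(frames)) > 1e-9:
                raise ValueError(f"fps * {name} must be an integer number of frames")
        if not 0 <= self.quick_change_count <= 3:
            raise ValueError("quick_change_count must be 0..3")
        need = self.quick_change_count * (self.quick_change_duration_s + self.min_gap_s)
        if need > self.morph_s + 1e-9:
            raise SchedulingError(
                f"quick_change_count * (duration + min_gap) = {need} s exceeds "
                f"morph_s = {self.morph_s} s"
            )

    @property
    def n_lead(self) -> int:
        return round(self.fps * self.lead_s)

    @property
    def n_morph_frames(self) -> int:
        return round(self.fps * self.morph_s)

    @property
    def n_tail(self) -> int:
        return round(self.fps * self.tail_s)

    @property
    def n_total(self) -> int:
        return self.n_lead + self.n_morph_frames + self.n_tail

    @property
    def duration_frames(self) -> int:
        return round(self.fps * self.quick_change_duration_s)

    @property
    def gap_frames(self) -> int:
        return round(self.fps * self.min_gap_s)

    @property
    def duration_s(self) -> float:
        return self.lead_s + self.morph_s + self.tail_s

    def to_dict(self) -> dict:
        d = {
            "fps": self.fps,
            "lead_s": self.lead_s,
            "morph_s": self.morph_s,
            "tail_s": self.tail_s,
            "quick_change_count": self.quick_change_count,
            "quick_change_duration_s": self.quick_change_duration_s,
            "min_gap_s": self.min_gap_s,
            "seed": self.seed,
        }
        if self.overlay is not None:
            d["overlay"] = {
                "radius_px": self.overlay.radius_px,
                "crosshair_width_px": self.overlay.crosshair_width_px,
                "crosshair_flash_s": self.overlay.crosshair_flash_s,
                "color": list(self.overlay.color),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MorphConfig":
        d = dict(d)
        ov = d.pop("overlay", None)
        if ov is not None:
            ov = FixationOverlay(
                radius_px=ov.get("radius_px", 6),
                crosshair_width_px=ov.get("crosshair_width_px", 5),
                crosshair_flash_s=ov.get("crosshair_flash_s", 0.5),
                color=tuple(ov.get("color", (255, 255, 255))),
            )
        return cls(overlay=ov, **d)


@dataclass
class MorphSeries:
    """The ordered interpolated frames for one fixed quick-state vector."""

    quick_states: tuple[str, ...]
    frames: list[np.ndarray]


@dataclass(frozen=True)
class QuickChangeEvent:
    """One scheduled quick change: which feature flips, from/to which state,
    and the half-open morph-frame window ``[onset, onset + duration)`` over
    which the transition unfolds."""

    feature_index: int
    from_state: str
    to_state: str
    onset_frame: int
    duration_frames: int

    @property
    def end_frame(self) -> int:
        return self.onset_frame + self.duration_frames


@dataclass(frozen=True)
class Schedule:
    """Quick-change events sorted by onset, plus the seed that produced them."""

    events: tuple[QuickChangeEvent, ...]
    seed: int


def build_morph_series(
    start: np.ndarray, end: np.ndarray, n_frames: int
) -> list[np.ndarray]:
    """Linear RGB interpolation between two equal-sized images.

    Frame ``i`` (0-based) is, per pixel and channel,
    ``round(start + i/(n-1) * (end - start))`` with half-up rounding; the two
    endpoint frames are exact copies of the inputs.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    if start.shape != end.shape:
        raise GeometryError(f"image shapes differ: {start.shape} vs {end.shape}")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    s = start.astype(np.float64)
    delta = end.astype(np.float64) - s
    frames: list[np.ndarray] = [start.astype(np.uint8).copy()]
    for i in range(1, n_frames - 1):
        frac = i / (n_frames - 1)
        frames.append(_round_half_up(s + frac * delta).astype(np.uint8))
    frames.append(end.astype(np.uint8).copy())
    return frames


def schedule_quick_changes(config: MorphConfig, features: Sequence) -> Schedule:
    """Draw one non-overlapping transition window per feature at a uniformly
    random feasible onset, and assign events to features in a uniformly
    random order.  Deterministic for a fixed (config, feature list).

    ``features`` are objects with a two-label ``states`` attribute (or bare
    label pairs); every feature flips from its first state to its second.
    """
    k = len(features)
    if k != config.quick_change_count:
        raise ConsistencyError(
            f"config.quick_change_count = {config.quick_change_count} but "
            f"{k} features were given"
        )
    if k == 0:
        return Schedule(events=(), seed=config.seed)

    n_morph = config.n_morph_frames
    dur = config.duration_frames
    gap = config.gap_frames
    max_onset = n_morph - dur
    if max_onset < 0 or k * dur + (k - 1) * gap > n_morph:
        raise SchedulingError(
            f"cannot pack {k} windows of {dur} frames with gaps of {gap} frames "
            f"into {n_morph} morph frames: k*dur + (k-1)*gap = "
            f"{k * dur + (k - 1) * gap} > {n_morph}"
        )

    rng = np.random.default_rng(config.seed)
    feasible = np.arange(max_onset + 1)
    for _ in range(100_000):
        onsets = np.sort(rng.choice(feasible, size=k, replace=False))
        if k == 1 or np.all(np.diff(onsets) >= dur + gap):
            break
    else:  # pragma: no cover - analytically feasible configs converge fast
        raise SchedulingError("rejection sampling failed to place quick-change windows")

    order = rng.permutation(k)
    events = []
    for onset, feat_idx in zip(onsets, order):
        feat = features[feat_idx]
        states = tuple(feat.states) if hasattr(feat, "states") else tuple(feat)
        events.append(
            QuickChangeEvent(
                feature_index=int(feat_idx),
                from_state=states[0],
                to_state=states[1],
                onset_frame=int(onset),
                duration_frames=dur,
            )
        )
    return Schedule(events=tuple(events), seed=config.seed)


@dataclass
class FrameSequence:
    """The assembled stimulus: frames plus per-frame segment annotations.

    ``segments[t]`` is ``"lead"``, ``"morph"`` or ``"tail"``;
    ``morph_indices[t]`` is the morph-series index the frame was drawn from
    (lead frames carry 0, tail frames carry the last morph index).  Sequences
    decoded back from a video file carry no annotations (``None``).
    """

    fps: int
    frames: list[np.ndarray]
    segments: tuple[str, ...] | None = None
    morph_indices: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape[:2]


def _states_at(
    initial: tuple[str, ...], schedule: Schedule, i: int
) -> tuple[str, ...]:
    """State vector in effect at morph frame ``i`` (a feature counts as
    flipped once its window has fully elapsed)."""
    states = list(initial)
    for ev in schedule.events:
        if i >= ev.end_frame:
            states[ev.feature_index] = ev.to_state
    return tuple(states)


def assemble_frames(
    cset: CompositeSet,
    series_map: Mapping[tuple[str, ...], MorphSeries],
    schedule: Schedule,
    config: MorphConfig,
) -> FrameSequence:
    """Select one frame per time step from the parallel morph series.

    The morph index advances by exactly one per morph frame.  Outside any
    quick-change window the frame comes straight from the series of the
    current state vector; inside a window the frame is a per-pixel linear
    cross-fade between the pre-flip and post-flip series at the same morph
    index, with blend weight ``alpha = (j + 1) / duration`` at window offset
    ``j`` (so the final window frame equals the post-flip series exactly).
    """
    n_feat = cset.n_features
    for ev in schedule.events:
        if not 0 <= ev.feature_index < n_feat:
            raise ConsistencyError(f"event feature index {ev.feature_index} out of range")
        domain = cset.feature_state_domains[ev.feature_index]
        if ev.from_state not in domain or ev.to_state not in domain:
            raise ConsistencyError(
                f"event states {ev.from_state!r}->{ev.to_state!r} not in domain {domain}"
            )
        if not (0 <= ev.onset_frame and ev.end_frame <= config.n_morph_frames):
            raise ConsistencyError(f"event window {ev} outside the morph segment")
    seen = {ev.feature_index for ev in schedule.events}
    if len(seen) != len(schedule.events):
        raise ConsistencyError("a feature flips more than once in the schedule")

    initial = tuple(
        next(
            (ev.from_state for ev in schedule.events if ev.feature_index == f),
            cset.feature_state_domains[f][0],
        )
        for f in range(n_feat)
    )

    def series_frame(states: tuple[str, ...], i: int) -> np.ndarray:
        try:
            series = series_map[states]
        except KeyError:
            raise ConsistencyError(f"series map has no entry for state vector {states}")
        return series.frames[i]

    n_morph = config.n_morph_frames
    frames: list[np.ndarray] = []
    segments: list[str] = []
    morph_indices: list[int] = []

    lead_frame = series_frame(initial, 0)
    for _ in range(config.n_lead):
        frames.append(lead_frame)
        segments.append("lead")
        morph_indices.append(0)

    window_by_frame: dict[int, QuickChangeEvent] = {}
    for ev in schedule.events:
        for i in range(ev.onset_frame, ev.end_frame):
            if i in window_by_frame:
                raise ConsistencyError("quick-change windows overlap")
            window_by_frame[i] = ev

    for i in range(n_morph):
        current = _states_at(initial, schedule, i)
        ev = window_by_frame.get(i)
        if ev is None:
            frame = series_frame(current, i)
        else:
            pre = list(current)
            pre[ev.feature_index] = ev.from_state
            post = list(current)
            post[ev.feature_index] = ev.to_state
            alpha = (i - ev.onset_frame + 1) / ev.duration_frames
            a = series_frame(tuple(pre), i).astype(np.float64)
            b = series_frame(tuple(post), i).astype(np.float64)
            frame = _round_half_up((1.0 - alpha) * a + alpha * b).astype(np.uint8)
        frames.append(frame)
        segments.append("morph")
        morph_indices.append(i)

    final = _states_at(initial, schedule, n_morph)
    tail_frame = series_frame(final, n_morph - 1)
    for _ in range(config.n_tail):
        frames.append(tail_frame)
        segments.append("tail")
        morph_indices.append(n_morph - 1)

    return FrameSequence(
        fps=config.fps,
        frames=frames,
        segments=tuple(segments),
        morph_indices=tuple(morph_indices),
    )


def apply_fixation_overlay(
    seq: FrameSequence, overlay: FixationOverlay | None
) -> FrameSequence:
    """Return a copy of ``seq`` with the fixation mark drawn on every lead
    and tail frame and the cross-hair flashed on the last
    ``crosshair_flash_s`` of the lead and the first ``crosshair_flash_s`` of
    the tail.  With ``overlay=None`` the sequence is returned unchanged."""
    if overlay is None:
        return seq
    height, width = seq.shape
    mark = overlay.mark_mask(height, width)
    cross = overlay.crosshair_mask(height, width)
    flash = round(overlay.crosshair_flash_s * seq.fps)
    color = np.asarray(overlay.color, dtype=np.uint8)

    n_lead = sum(1 for s in seq.segments if s == "lead")
    first_tail = next(
        (t for t, s in enumerate(seq.segments) if s == "tail"), len(seq.frames)
    )

    out_frames: list[np.ndarray] = []
    for t, frame in enumerate(seq.frames):
        segment = seq.segments[t]
        if segment == "morph":
            out_frames.append(frame)
            continue
        new = frame.copy()
        in_flash = (segment == "lead" and t >= n_lead - flash) or (
            segment == "tail" and t < first_tail + flash
        )
        if in_flash:
            new[cross] = color
        new[mark] = color
        out_frames.append(new)
    return replace(seq, frames=out_frames)
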