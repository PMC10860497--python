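"""Frame-accurate quality control of generated stimuli.

The validator recovers the generation parameters from pixels alone: it
locates the flat-linear-flat structure of the region-mean color trajectory
(lead / morph / tail breakpoints), measures the linearity of the slow fade,
finds the quick-change onsets from frame-difference energy outside the
slow-change region, and reads off the endpoint colors — then compares all of
it against the manifest (or an expected timing configuration) at tolerances
appropriate for the codec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, NoChangeError
from .morph import FrameSequence, MorphConfig
from .video import StimulusManifest, decode, manifest_path_for

Rect = tuple[int, int, int, int]


def derive_region_mask(
    start: np.ndarray,
    end: np.ndarray,
    exclude_boxes: tuple[Rect, ...] = (),
    tol: int = 0,
) -> np.ndarray:
    """Mask of the slow-change region: pixels whose maximum per-channel
    |start - end| exceeds ``tol``, minus any excluded rectangles.

    For a clean composite pair only the slow-change element differs between
    the two colors, so the thresholded difference recovers it; feature boxes
    (which also differ when the quick states differ) can be excluded
    explicitly, and lossy inputs get a nonzero ``tol``.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    if start.shape != end.shape:
        raise GeometryError(f"image shapes differ: {start.shape} vs {end.shape}")
    diff = np.abs(start.astype(np.int16) - end.astype(np.int16)).max(axis=2)
    mask = diff > tol
    for x0, y0, x1, y1 in exclude_boxes:
        mask[y0:y1, x0:x1] = False
    if not mask.any():
        raise NoChangeError("start and end images do not differ outside excluded boxes")
    return mask


def region_mean_rgb(img: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic per-channel mean over the masked pixels."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    means = np.asarray(img, dtype=np.float64)[mask].mean(axis=0)
    return (float(means[0]), float(means[1]), float(means[2]))


def _refine_mask(frames: list[np.ndarray], mask: np.ndarray, step_tol: int = 8) -> np.ndarray:
    """Drop pixels that ever jump by more than ``step_tol`` counts between
    consecutive frames.  The slow fade moves any pixel by at most a couple of
    counts per frame, while a 1-s quick change moves its pixels an order of
    magnitude faster, so this separates quick-change pixels (which may
    overlap the slow region) from genuine slow-change pixels."""
    max_step = np.zeros(mask.shape, dtype=np.uint8)
    prev = frames[0].astype(np.int16)
    for f in frames[1:]:
        cur = f.astype(np.int16)
        np.maximum(max_step, np.abs(cur - prev).max(axis=2).astype(np.uint8), out=max_step)
        prev = cur
    refined = mask & (max_step <= step_tol)
    return refined if refined.any() else mask


def _flat_linear_flat(y: np.ndarray) -> tuple[int, int, np.ndarray, np.ndarray, float]:
    """Exhaustive least-squares fit of a flat-linear-flat model to a
    (n_frames x n_channels) trajectory.

    Returns ``(b1, b2, slopes, r2, sse)`` where the lead is ``[0, b1)``, the
    morph ``[b1, b2)`` and the tail ``[b2, n)``; slopes and per-channel R²
    are for the linear fit on the morph segment.  Sequences are a few
    hundred frames, so searching every integer breakpoint pair is cheap and
    fully deterministic (ties resolved to the first minimum).
    """
    n, c = y.shape
    t = np.arange(n, dtype=np.float64)
    # prefix sums for O(1) segment statistics
    S1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    St = np.concatenate([[0.0], np.cumsum(t)])
    Stt = np.concatenate([[0.0], np.cumsum(t * t)])
    Sy = np.vstack([np.zeros(c), np.cumsum(y, axis=0)])
    Syy = np.vstack([np.zeros(c), np.cumsum(y * y, axis=0)])
    Sty = np.vstack([np.zeros(c), np.cumsum(t[:, None] * y, axis=0)])

    def const_sse(a: int, b: int) -> np.ndarray:
        m = b - a
        s = Sy[b] - Sy[a]
        return (Syy[b] - Syy[a]) - s * s / m

    def lin_fit(a: int, b: int):
        m = b - a
        sy = Sy[b] - Sy[a]
        st = St[b] - St[a]
        stt = Stt[b] - Stt[a]
        sty = Sty[b] - Sty[a]
        syy = Syy[b] - Syy[a]
        ctt = stt - st * st / m
        cty = sty - st * sy / m
        cyy = syy - sy * sy / m
        slope = np.where(ctt > 0, cty / np.maximum(ctt, 1e-300), 0.0)
        sse = cyy - np.where(ctt > 0, cty * cty / np.maximum(ctt, 1e-300), 0.0)
        return slope, sse, cyy

    best = None
    for b1 in range(1, n - 2):
        for b2 in range(b1 + 2, n):
            sse = (
                const_sse(0, b1).sum()
                + lin_fit(b1, b2)[1].sum()
                + const_sse(b2, n).sum()
            )
            if best is None or sse < best[0] - 1e-12:
                best = (sse, b1, b2)
    sse, b1, b2 = best
    slopes, lin_sse, cyy = lin_fit(b1, b2)
    with np.errstate(invalid="ignore"):
        r2 = np.where(cyy > 0, 1.0 - lin_sse / np.maximum(cyy, 1e-300), 1.0)
    return b1, b2, slopes, r2, float(sse)


def _detect_onsets(
    frames: list[np.ndarray],
    outside: np.ndarray,
    b1: int,
    b2: int,
    median_factor: float = 5.0,
) -> list[int]:
    """Quick-change onsets (absolute frame indices) from frame-to-frame mean
    absolute difference outside the slow-change mask.  Frames above
    ``median_factor`` x the morph-segment median difference are grouped into
    events; each group's first changed frame is the onset."""
    if not outside.any():
        return []
    d = np.zeros(len(frames) - 1)
    prev = frames[0].astype(np.int16)
    for i, f in enumerate(frames[1:]):
        cur = f.astype(np.int16)
        d[i] = np.abs(cur - prev)[outside].mean()
        prev = cur
    seg = d[max(b1 - 1, 0) : b2 - 1]
    med = float(np.median(seg)) if seg.size else 0.0
    thr = median_factor * med if med > 0 else 1e-9
    above = d > thr
    onsets = []
    i = 0
    while i < len(above):
        if above[i]:
            onsets.append(i + 1)  # first changed frame (absolute index)
            while i < len(above) and above[i]:
                i += 1
        else:
            i += 1
    return onsets


def quantization_dead_zone(delta: float, n_morph_frames: int) -> int:
    """Number of morph frames at each end that are bit-identical to the
    bookend frame, for a region whose largest per-channel change is
    ``delta`` counts.

    Frame ``i`` of an ``n``-frame morph shifts a pixel by
    ``round(i * delta / (n - 1))`` counts, so until that quantity reaches 1
    the rendered frame cannot differ from the endpoint: the first
    ``ceil(0.5 * (n - 1) / delta)`` morph frames (and, symmetrically, the
    same number at the end) duplicate the bookends.  No validator can place
    the breakpoints inside this dead zone, so recovered segment lengths are
    corrected by it before comparison.
    """
    delta = abs(delta)
    if delta < 1:
        return n_morph_frames
    i = 1
    while np.floor(i * delta / (n_morph_frames - 1) + 0.5) < 1:
        i += 1
    return i


@dataclass
class QCReport:
    """Everything the validator measured, plus per-check pass/fail."""

    duration_s: float
    fps: int
    n_frames: int
    lead_frames: int
    morph_frames: int
    tail_frames: int
    slopes: tuple[float, float, float]
    r2: tuple[float, float, float]
    onsets: list[int]
    start_rgb: tuple[float, float, float]
    end_rgb: tuple[float, float, float]
    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "fps": self.fps,
            "n_frames": self.n_frames,
            "lead_frames": self.lead_frames,
            "morph_frames": self.morph_frames,
            "tail_frames": self.tail_frames,
            "slopes": list(self.slopes),
            "r2": list(self.r2),
            "onsets": self.onsets,
            "start_rgb": list(self.start_rgb),
            "end_rgb": list(self.end_rgb),
            "checks": {k: {"passed": ok, "detail": msg} for k, (ok, msg) in self.checks.items()},
            "passed": self.passed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            f"duration: {self.duration_s:.3f} s at {self.fps} fps ({self.n_frames} frames)",
            f"segments: lead={self.lead_frames} morph={self.morph_frames} tail={self.tail_frames}",
            f"morph linearity R^2 (R,G,B): "
            + ", ".join(f"{v:.6f}" for v in self.r2),
            f"region mean start: ({self.start_rgb[0]:.2f}, {self.start_rgb[1]:.2f}, {self.start_rgb[2]:.2f})",
            f"region mean end:   ({self.end_rgb[0]:.2f}, {self.end_rgb[1]:.2f}, {self.end_rgb[2]:.2f})",
            f"quick-change onsets (frame indices): {self.onsets}",
        ]
        for name, (ok, msg) in self.checks.items():
            lines.append(f"[{'PASS' if ok else 'FAIL'}] {name}: {msg}")
        lines.append("overall: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


def validate_sequence(
    seq: FrameSequence,
    expected: StimulusManifest | MorphConfig | None = None,
    lossless: bool | None = None,
    r2_min: float = 0.999,
) -> QCReport:
    """Validate an in-memory frame sequence (see :func:`validate_video`)."""
    frames = seq.frames
    n = len(frames)

    try:
        mask = derive_region_mask(
            frames[0], frames[-1], tol=0 if _is_lossless(expected, lossless) else 8
        )
    except NoChangeError:
        # a video with no slow change fails validation, it does not crash it
        report = QCReport(
            duration_s=n / seq.fps,
            fps=seq.fps,
            n_frames=n,
            lead_frames=0,
            morph_frames=0,
            tail_frames=n,
            slopes=(0.0, 0.0, 0.0),
            r2=(0.0, 0.0, 0.0),
            onsets=[],
            start_rgb=region_mean_rgb(frames[0], np.ones(frames[0].shape[:2], bool)),
            end_rgb=region_mean_rgb(frames[-1], np.ones(frames[-1].shape[:2], bool)),
        )
        report.checks["morph_linearity"] = (
            False,
            "no morph segment found (first and last frames are identical)",
        )
        return report
    mask = _refine_mask(frames, mask)
    y = np.empty((n, 3))
    for i, f in enumerate(frames):
        y[i] = np.asarray(f, dtype=np.float64)[mask].mean(axis=0)

    b1, b2, slopes, r2, _ = _flat_linear_flat(y)
    onsets = _detect_onsets(frames, ~mask, b1, b2)
    start_rgb = region_mean_rgb(frames[0], mask)
    end_rgb = region_mean_rgb(frames[-1], mask)

    report = QCReport(
        duration_s=n / seq.fps,
        fps=seq.fps,
        n_frames=n,
        lead_frames=b1,
        morph_frames=b2 - b1,
        tail_frames=n - b2,
        slopes=(float(slopes[0]), float(slopes[1]), float(slopes[2])),
        r2=(float(r2[0]), float(r2[1]), float(r2[2])),
        onsets=onsets,
        start_rgb=start_rgb,
        end_rgb=end_rgb,
    )
    _run_checks(report, y, b1, b2, expected, _is_lossless(expected, lossless), r2_min)
    return report


def _is_lossless(expected, lossless: bool | None) -> bool:
    if lossless is not None:
        return lossless
    if isinstance(expected, StimulusManifest):
        return expected.lossless
    return True


def _run_checks(
    report: QCReport,
    y: np.ndarray,
    b1: int,
    b2: int,
    expected,
    lossless: bool,
    r2_min: float,
) -> None:
    onset_tol = 1 if lossless else 2
    color_tol = 0.0 if lossless else 3.0

    # monotone region-mean trajectory over the morph segment
    seg = y[b1:b2]
    diffs = np.diff(seg, axis=0)
    wiggle = 1e-9 if lossless else 0.5
    mono = bool(np.all((diffs >= -wiggle).all(axis=0) | (diffs <= wiggle).all(axis=0)))
    report.checks["monotone_trajectory"] = (
        mono,
        "per-channel region mean is monotone across the morph"
        if mono
        else "trajectory reverses direction inside the morph segment",
    )
    # linearity is only assessable on channels with enough dynamic range:
    # the region mean of a quantized ramp with total range D counts has an
    # R^2 floor of about 1 - 1/D^2, so 0.999 is only meaningful for D >= 32
    deltas = np.abs(np.asarray(report.end_rgb) - np.asarray(report.start_rgb))
    assessable = deltas >= 32.0
    if seg.std(axis=0).max() <= 0:
        report.checks["morph_linearity"] = (
            False,
            "no morph segment found (trajectory is constant)",
        )
    elif not assessable.any():
        report.checks["morph_linearity"] = (
            False,
            "no channel changes by >= 32 counts; linearity is unmeasurable",
        )
    else:
        worst = float(min(r for r, a in zip(report.r2, assessable) if a))
        report.checks["morph_linearity"] = (
            worst >= r2_min,
            f"min R^2 over assessable channels = {worst:.6f} (threshold {r2_min})",
        )

    if expected is None:
        return
    config = expected.config if isinstance(expected, StimulusManifest) else expected
    if isinstance(config, dict):
        config = MorphConfig.from_dict(
            {k: v for k, v in config.items() if k != "overlay"}
        )
    if isinstance(config, MorphConfig):
        report.checks["fps"] = (
            report.fps == config.fps,
            f"container fps {report.fps}, expected {config.fps}",
        )
        report.checks["frame_count"] = (
            report.n_frames == config.n_total,
            f"{report.n_frames} frames, expected {config.n_total}",
        )
        deltas = np.abs(np.asarray(report.end_rgb) - np.asarray(report.start_rgb))
        dead = quantization_dead_zone(round(float(deltas.max())), config.n_morph_frames)
        slack = 0 if lossless else 1
        lead_err = report.lead_frames - (config.n_lead + dead)
        tail_err = report.tail_frames - (config.n_tail + dead)
        ok = abs(lead_err) <= slack and abs(tail_err) <= slack
        report.checks["breakpoints"] = (
            ok,
            f"lead/morph/tail = {report.lead_frames}/{report.morph_frames}/"
            f"{report.tail_frames}; expected {config.n_lead}/"
            f"{config.n_morph_frames}/{config.n_tail} with a quantization dead "
            f"zone of {dead} frame(s) at each morph end",
        )

    if isinstance(expected, StimulusManifest) and expected.schedule is not None:
        n_lead = config.n_lead if isinstance(config, MorphConfig) else report.lead_frames
        want = sorted(n_lead + ev["onset_frame"] for ev in expected.schedule)
        got = sorted(report.onsets)
        ok = len(want) == len(got) and all(
            abs(a - b) <= onset_tol for a, b in zip(want, got)
        )
        report.checks["quick_change_onsets"] = (
            ok,
            f"recovered {got}, manifest {want} (tolerance +/-{onset_tol} frames)",
        )
    if isinstance(expected, StimulusManifest) and expected.colors_rgb is not None:
        want_start = expected.colors_rgb.get("measured_start")
        want_end = expected.colors_rgb.get("measured_end")
        if want_start is not None and want_end is not None:
            err = max(
                max(abs(a - b) for a, b in zip(report.start_rgb, want_start)),
                max(abs(a - b) for a, b in zip(report.end_rgb, want_end)),
            )
            report.checks["endpoint_colors"] = (
                err <= color_tol,
                f"max endpoint region-mean error {err:.3f} (tolerance {color_tol})",
            )


def validate_video(
    path: str | Path,
    expected: StimulusManifest | MorphConfig | None = None,
    **kwargs,
) -> QCReport:
    """Decode a stimulus video and validate its structure.

    ``expected`` may be a manifest (checked in full: breakpoints, onsets,
    endpoint colors) or a bare timing configuration (structure only).  When
    omitted, the manifest sidecar next to the video is used if present.
    A structurally broken video yields a failing report, not an exception.
    """
    path = Path(path)
    if expected is None:
        sidecar = manifest_path_for(path)
        if sidecar.exists():
            expected = StimulusManifest.load(sidecar)
    seq = decode(path)
    return validate_sequence(seq, expected=expected, **kwargs)
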