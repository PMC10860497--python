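"""Procedural rendering of composite image sets for slow-change stimuli.

A stimulus is built from a *composite set*: one raster image per combination
of slow-change color (two options) and quick-change feature state (two options
per feature).  Real stimuli are drawn by hand in a graphics editor; this
module renders cartoon-like stand-ins with the same structure — one large,
centrally located colored region (the slow-change element, optionally with
deterministic luminance texture so its pixels are not all identical) plus a
small number of togglable glyph features (the quick changes) — so that every
downstream stage can be exercised without manual artwork.

Coordinates are pixel-based, origin top-left; rectangles are
``(x0, y0, x1, y1)`` with exclusive right/bottom edges.  Images are
``height x width x 3`` uint8 arrays (8-bit sRGB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import GeometryError, StateError
from . import composites

RGB8 = tuple[int, int, int]
Rect = tuple[int, int, int, int]

#: glyph ink used by every feature renderer
_INK: RGB8 = (0, 0, 0)

RENDERERS = ("arrow", "dot-cluster", "bar")


@dataclass(frozen=True)
class QuickFeature:
    """One togglable scene element with exactly two states.

    ``renderer_id`` selects the built-in glyph: ``arrow`` points left for the
    first state and right for the second; ``dot-cluster`` is absent for the
    first state and drawn for the second; ``bar`` is horizontal for the first
    state and vertical for the second.
    """

    name: str
    bbox: Rect
    states: tuple[str, str]
    renderer_id: str = "arrow"

    def __post_init__(self) -> None:
        if len(self.states) != 2 or self.states[0] == self.states[1]:
            raise ValueError(f"feature {self.name!r} needs two distinct states")
        for s in self.states:
            if not s or "_" in s:
                raise ValueError(f"state label {s!r} must be non-empty and underscore-free")
        x0, y0, x1, y1 = self.bbox
        if x1 <= x0 or y1 <= y0:
            raise GeometryError(f"feature {self.name!r} bbox has zero area")
        if self.renderer_id not in RENDERERS:
            raise ValueError(f"unknown renderer {self.renderer_id!r}")

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise StateError(
                f"state {label!r} not valid for feature {self.name!r}; "
                f"expected one of {self.states}"
            ) from None


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic scene.

    The slow-change region is an axis-aligned ellipse or rounded rectangle
    given by ``slow_shape`` ("ellipse" | "rounded_rect") and ``slow_bbox``,
    strictly inside the canvas.  ``texture_amplitude`` adds a deterministic
    per-pixel luminance offset (uniform on ``[-a, a]``, a pure function of
    ``render_seed`` and pixel coordinates) inside the region, emulating the
    pictorial structure of a hand-drawn scene while keeping the region mean
    within about one count of the nominal fill color.
    """

    width: int
    height: int
    background_color: RGB8
    slow_shape: str
    slow_bbox: Rect
    texture_amplitude: int = 0
    features: tuple[QuickFeature, ...] = ()
    render_seed: int = 0
    corner_radius: int | None = None  # rounded_rect only; default min side / 6

    def __post_init__(self) -> None:
        if self.slow_shape not in ("ellipse", "rounded_rect"):
            raise ValueError(f"unknown slow-region shape {self.slow_shape!r}")
        if not 0 <= self.texture_amplitude <= 32:
            raise ValueError("texture_amplitude must be in [0, 32]")
        x0, y0, x1, y1 = self.slow_bbox
        if not (0 < x0 < x1 < self.width and 0 < y0 < y1 < self.height):
            raise GeometryError("slow_bbox must lie strictly inside the canvas")
        for f in self.features:
            fx0, fy0, fx1, fy1 = f.bbox
            if not (0 <= fx0 < fx1 <= self.width and 0 <= fy0 < fy1 <= self.height):
                raise GeometryError(f"feature {f.name!r} bbox outside canvas")
        for i, a in enumerate(self.features):
            for b in self.features[i + 1 :]:
                if _rects_overlap(a.bbox, b.bbox):
                    raise GeometryError(
                        f"feature bboxes {a.name!r} and {b.name!r} overlap"
                    )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "background_color": list(self.background_color),
            "slow_shape": self.slow_shape,
            "slow_bbox": list(self.slow_bbox),
            "texture_amplitude": self.texture_amplitude,
            "features": [
                {
                    "name": f.name,
                    "bbox": list(f.bbox),
                    "states": list(f.states),
                    "renderer_id": f.renderer_id,
                }
                for f in self.features
            ],
            "render_seed": self.render_seed,
            "corner_radius": self.corner_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            width=d["width"],
            height=d["height"],
            background_color=tuple(d["background_color"]),
            slow_shape=d["slow_shape"],
            slow_bbox=tuple(d["slow_bbox"]),
            texture_amplitude=d.get("texture_amplitude", 0),
            features=tuple(
                QuickFeature(
                    name=f["name"],
                    bbox=tuple(f["bbox"]),
                    states=tuple(f["states"]),
                    renderer_id=f.get("renderer_id", "arrow"),
                )
                for f in d.get("features", ())
            ),
            render_seed=d.get("render_seed", 0),
            corner_radius=d.get("corner_radius"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SceneSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rects_overlap(a: Rect, b: Rect) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


# -- slow-change region ----------------------------------------------------


def slow_region_mask(spec: SceneSpec) -> np.ndarray:
    """Boolean ground-truth mask of the slow-change region (H x W)."""
    x0, y0, x1, y1 = spec.slow_bbox
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    if spec.slow_shape == "ellipse":
        cx, cy = (x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0
        rx, ry = (x1 - x0) / 2.0, (y1 - y0) / 2.0
        return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    # rounded rectangle: rectangle minus the four corner squares outside
    # quarter-circles of the given radius
    r = spec.corner_radius
    if r is None:
        r = min(x1 - x0, y1 - y0) // 6
    inside = (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
    if r > 0:
        for cx, cy in (
            (x0 + r - 0.5, y0 + r - 0.5),
            (x1 - r - 0.5, y0 + r - 0.5),
            (x0 + r - 0.5, y1 - r - 0.5),
            (x1 - r - 0.5, y1 - r - 0.5),
        ):
            corner = (
                ((xx - cx) ** 2 + (yy - cy) ** 2 > r * r)
                & (np.abs(xx - cx) <= r)
                & (np.abs(yy - cy) <= r)
                & ((xx < x0 + r) | (xx >= x1 - r))
                & ((yy < y0 + r) | (yy >= y1 - r))
            )
            inside &= ~corner
    return inside


def _texture_offsets(spec: SceneSpec) -> np.ndarray:
    """Deterministic per-pixel luminance offsets, uniform on [-a, a].

    A pure integer-mixing function of (render_seed, x, y): no RNG state, so
    the pattern is identical for every render of the same spec.
    """
    a = spec.texture_amplitude
    if a == 0:
        return np.zeros((spec.height, spec.width), dtype=np.int32)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    v = (
        xx.astype(np.uint64) * 0x9E3779B1
        + yy.astype(np.uint64) * 0x85EBCA77
        + np.uint64(spec.render_seed & 0xFFFFFFFF) * 0xC2B2AE3D
    ) & np.uint64(0xFFFFFFFF)
    v ^= v >> np.uint64(15)
    v = (v * np.uint64(0x2C1B3C6D)) & np.uint64(0xFFFFFFFF)
    v ^= v >> np.uint64(13)
    return (v % np.uint64(2 * a + 1)).astype(np.int32) - a


# -- feature glyphs --------------------------------------------------------


def _draw_feature(img: np.ndarray, feat: QuickFeature, state: str) -> None:
    """Fill the feature bbox and draw its glyph for ``state`` in place."""
    idx = feat.state_index(state)
    x0, y0, x1, y1 = feat.bbox
    h, w = y1 - y0, x1 - x0
    yy, xx = np.mgrid[0:h, 0:w]
    if feat.renderer_id == "arrow":
        # isoceles triangle pointing left (state 0) or right (state 1)
        u = xx / max(w - 1, 1)
        if idx == 0:
            u = 1.0 - u
        half = (u * (h / 2.0)) * 0.9 + 1.0
        mask = np.abs(yy - (h - 1) / 2.0) <= half
        mask &= (u >= 0.1) & (u <= 0.9)
    elif feat.renderer_id == "dot-cluster":
        mask = np.zeros((h, w), dtype=bool)
        if idx == 1:
            r = max(min(h, w) // 8, 1)
            for fx, fy in ((0.3, 0.3), (0.7, 0.4), (0.45, 0.72)):
                cx, cy = fx * (w - 1), fy * (h - 1)
                mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    else:  # bar
        t = max(min(h, w) // 5, 1)
        if idx == 0:
            mask = np.abs(yy - (h - 1) / 2.0) <= t / 2.0
        else:
            mask = np.abs(xx - (w - 1) / 2.0) <= t / 2.0
        mask &= (xx >= w // 8) & (xx < w - w // 8) & (yy >= h // 8) & (yy < h - h // 8)
    img[y0:y1, x0:x1][mask] = _INK


# -- rendering -------------------------------------------------------------


def render_scene(
    spec: SceneSpec, color: RGB8, quick_states: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Render one composite: slow region filled with ``color``, features in
    the given states, everything else the background.

    Deterministic: two calls with identical arguments are bit-identical.
    Feature bboxes are always repainted from the background, so their pixels
    never depend on ``color`` even where a bbox overlaps the slow region.
    """
    quick_states = tuple(quick_states)
    if len(quick_states) != len(spec.features):
        raise StateError(
            f"got {len(quick_states)} state labels for {len(spec.features)} features"
        )
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)

    region = slow_region_mask(spec)
    filled = np.asarray(color, dtype=np.int32)[None, None, :] + _texture_offsets(spec)[
        :, :, None
    ]
    img[region] = np.clip(filled, 0, 255).astype(np.uint8)[region]

    for feat, state in zip(spec.features, quick_states):
        x0, y0, x1, y1 = feat.bbox
        img[y0:y1, x0:x1] = np.asarray(spec.background_color, dtype=np.uint8)
        _draw_feature(img, feat, state)
    return img


def emit_composite_set(
    spec: SceneSpec,
    image_id: int,
    colors: list[tuple[str, RGB8]],
    out_dir: str | Path,
    fmt: str = "png",
    overwrite: bool = False,
) -> list[Path]:
    """Write the full 2 x 2**k composite grid to ``out_dir``.

    ``colors`` is the (label, RGB) pair list for the start and end color, in
    that order.  Returns the written paths sorted lexicographically.
    """
    if len(colors) != 2:
        raise ValueError("exactly two (label, RGB) color pairs are required")
    if fmt not in ("png", "jpg"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = []
    for label, rgb in colors:
        for states in composites.state_combinations(spec.features):
            key = composites.CompositeKey(image_id, label, states)
            path = out_dir / composites.format_name(key, ext=fmt)
            if path.exists() and not overwrite:
                raise FileExistsError(
                    f"{path} already exists; pass overwrite=True to replace it"
                )
            img = render_scene(spec, rgb, states)
            pil = Image.fromarray(img)
            if fmt == "jpg":
                pil.save(path, quality=95)
            else:
                pil.save(path)
            paths.append(path)
    return sorted(paths)


# -- demo / battery scene factories ----------------------------------------


def demo_spec(
    n_features: int = 3,
    size: int = 480,
    shape: str = "ellipse",
    texture_amplitude: int = 8,
    render_seed: int = 0,
    background_color: RGB8 = (235, 235, 228),
) -> SceneSpec:
    """A cartoon-like scene: large central slow-change region, up to three
    small quick-change features in the margins."""
    if not 0 <= n_features <= 3:
        raise ValueError("n_features must be 0..3")
    m = size // 24  # margin unit
    box = size // 6  # feature box side
    feature_pool = (
        QuickFeature("rocket", (m, m, m + box, m + box), ("Left", "Right"), "arrow"),
        QuickFeature(
            "balloons",
            (size - m - box, m, size - m, m + box),
            ("Absent", "Present"),
            "dot-cluster",
        ),
        QuickFeature(
            "antenna",
            (m, size - m - box, m + box, size - m),
            ("Flat", "Tall"),
            "bar",
        ),
    )
    pad = size // 5
    return SceneSpec(
        width=size,
        height=size,
        background_color=background_color,
        slow_shape=shape,
        slow_bbox=(pad, pad, size - pad, size - pad),
        texture_amplitude=texture_amplitude,
        features=feature_pool[:n_features],
        render_seed=render_seed,
    )


def battery_specs(n_scenes: int = 11, size: int = 480, texture_amplitude: int = 8):
    """A battery of distinct scenes (varying shape, geometry, feature count),
    mirroring a stimulus set built from several source images."""
    specs = []
    for i in range(n_scenes):
        spec = demo_spec(
            n_features=1 + i % 3,
            size=size,
            shape="ellipse" if i % 2 == 0 else "rounded_rect",
            texture_amplitude=texture_amplitude,
            render_seed=1000 + i,
            background_color=(235 - 4 * (i % 5), 235, 220 + 2 * (i % 7)),
        )
        specs.append(spec)
    return specs
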