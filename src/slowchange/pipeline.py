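"""End-to-end stimulus generation: composite set -> schedule -> frames -> video.

This is the glue the command-line interface drives: it owns the default
color-pair palette, derives per-stimulus seeds from a master seed, builds
the parallel morph series lazily (only the state vectors a schedule actually
visits are rendered), and records everything needed for bit-exact
regeneration in the stimulus manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import composites, qc, scene
from .composites import CompositeKey, CompositeSet
from .morph import (
    FrameSequence,
    MorphConfig,
    MorphSeries,
    Schedule,
    apply_fixation_overlay,
    assemble_frames,
    build_morph_series,
    schedule_quick_changes,
)
from .video import StimulusManifest, encode

RGB8 = tuple[int, int, int]

#: standardized slow-change palette: one nominal RGB per color name
STANDARD_COLORS: dict[str, RGB8] = {
    "Yellow": (230, 200, 40),
    "Orange": (226, 129, 33),
    "Purple": (128, 62, 160),
    "Blue": (58, 84, 196),
}

#: the five canonical color pairs of a validation battery; start color first.
#: "purple-orange-ns" is the non-standardized variant whose hue/brightness is
#: tailored per scene (see :func:`color_pair`).
COLOR_PAIR_NAMES = (
    "yellow-orange",
    "purple-blue",
    "purple-orange",
    "blue-yellow",
    "purple-orange-ns",
)

_PAIRS: dict[str, tuple[tuple[str, RGB8], tuple[str, RGB8]]] = {
    "yellow-orange": (("Yellow", STANDARD_COLORS["Yellow"]), ("Orange", STANDARD_COLORS["Orange"])),
    "purple-blue": (("Purple", STANDARD_COLORS["Purple"]), ("Blue", STANDARD_COLORS["Blue"])),
    "purple-orange": (("Purple", STANDARD_COLORS["Purple"]), ("Orange", STANDARD_COLORS["Orange"])),
    "blue-yellow": (("Blue", STANDARD_COLORS["Blue"]), ("Yellow", STANDARD_COLORS["Yellow"])),
}


def color_pair(name: str, scene_index: int = 0) -> tuple[tuple[str, RGB8], tuple[str, RGB8]]:
    """Resolve a color-pair name to ((start label, RGB), (end label, RGB)).

    The non-standardized pair shifts saturation/brightness deterministically
    per scene, emulating colors matched to each source image individually
    rather than standardized across the battery.
    """
    if name in _PAIRS:
        return _PAIRS[name]
    if name == "purple-orange-ns":
        def shift(rgb: RGB8, amount: int) -> RGB8:
            return tuple(int(np.clip(c + amount, 0, 255)) for c in rgb)

        amount = ((scene_index * 13) % 31) - 15
        return (
            ("Purple", shift(STANDARD_COLORS["Purple"], amount)),
            ("Orange", shift(STANDARD_COLORS["Orange"], -amount)),
        )
    raise KeyError(f"unknown color pair {name!r}; choose from {COLOR_PAIR_NAMES}")


def cell_seed(master_seed: int, scene_id: int | str, pair_name: str) -> int:
    """Stable per-stimulus seed: hashing (master seed, scene, pair) means
    adding or reordering battery cells never perturbs existing ones."""
    digest = hashlib.sha256(f"{master_seed}:{scene_id}:{pair_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def scene_composite_set(
    spec: scene.SceneSpec,
    image_id: int,
    colors: tuple[tuple[str, RGB8], tuple[str, RGB8]],
) -> CompositeSet:
    """Render a scene's full composite grid directly into memory (the
    disk-based equivalent is emit_composite_set + load_set)."""
    (start_label, start_rgb), (end_label, end_rgb) = colors
    images: dict[CompositeKey, np.ndarray] = {}
    for label, rgb in ((start_label, start_rgb), (end_label, end_rgb)):
        for states in composites.state_combinations(spec.features):
            images[CompositeKey(image_id, label, states)] = scene.render_scene(
                spec, rgb, states
            )
    return CompositeSet(
        image_id=image_id,
        width=spec.width,
        height=spec.height,
        color_labels=(start_label, end_label),
        feature_state_domains=tuple(f.states for f in spec.features),
        images=images,
    )


class LazySeriesMap:
    """Mapping from quick-state vector to its morph series, built on demand.

    The full map spans 2**k vectors but an assembled stimulus only ever
    touches k + 1 of them (one per flip, plus the start), so series are
    interpolated lazily and cached.
    """

    def __init__(self, cset: CompositeSet, n_frames: int):
        self._cset = cset
        self._n_frames = n_frames
        self._cache: dict[tuple[str, ...], MorphSeries] = {}

    def __getitem__(self, states: tuple[str, ...]) -> MorphSeries:
        states = tuple(states)
        if states not in self._cache:
            start_label, end_label = self._cset.color_labels
            frames = build_morph_series(
                self._cset.get(start_label, states),
                self._cset.get(end_label, states),
                self._n_frames,
            )
            self._cache[states] = MorphSeries(quick_states=states, frames=frames)
        return self._cache[states]


def build_sequence(
    cset: CompositeSet, config: MorphConfig
) -> tuple[FrameSequence, Schedule]:
    """Schedule the quick changes and assemble the full frame sequence."""
    schedule = schedule_quick_changes(config, cset.feature_state_domains)
    series_map = LazySeriesMap(cset, config.n_morph_frames)
    seq = assemble_frames(cset, series_map, schedule, config)
    if config.overlay is not None:
        seq = apply_fixation_overlay(seq, config.overlay)
    return seq, schedule


def _measured_endpoint_means(cset: CompositeSet, schedule: Schedule):
    """Region-mean RGB of the slow-change element in the start- and
    end-color composites, measured over the pixels that actually change."""
    initial = tuple(
        next(
            (ev.from_state for ev in schedule.events if ev.feature_index == f),
            cset.feature_state_domains[f][0],
        )
        for f in range(cset.n_features)
    )
    start_label, end_label = cset.color_labels
    start_img = cset.get(start_label, initial)
    end_img = cset.get(end_label, initial)
    mask = qc.derive_region_mask(start_img, end_img)
    return qc.region_mean_rgb(start_img, mask), qc.region_mean_rgb(end_img, mask)


def generate_stimulus(
    cset: CompositeSet,
    config: MorphConfig,
    out_path: str | Path,
    codec: str = "rawvideo",
    nominal_colors: dict | None = None,
) -> tuple[Path, StimulusManifest]:
    """Generate one stimulus video plus its reproducibility manifest."""
    seq, schedule = build_sequence(cset, config)
    start_mean, end_mean = _measured_endpoint_means(cset, schedule)
    colors_rgb = {
        "measured_start": list(start_mean),
        "measured_end": list(end_mean),
    }
    if nominal_colors:
        colors_rgb.update(nominal_colors)
    manifest_extra = {
        "config": config.to_dict(),
        "image_id": cset.image_id,
        "color_labels": cset.color_labels,
        "colors_rgb": colors_rgb,
        "schedule": [
            {
                "feature_index": ev.feature_index,
                "from_state": ev.from_state,
                "to_state": ev.to_state,
                "onset_frame": ev.onset_frame,
                "duration_frames": ev.duration_frames,
            }
            for ev in schedule.events
        ],
    }
    return encode(seq, out_path, codec=codec, manifest_extra=manifest_extra)


def generate_battery(
    specs: list[scene.SceneSpec],
    pair_names: list[str],
    base_config: MorphConfig,
    out_dir: str | Path,
    master_seed: int = 0,
    codec: str = "rawvideo",
) -> pd.DataFrame:
    """One video per (scene, color pair) cell; returns (and writes) the
    battery index.  A failing cell is recorded in the index and does not
    abort the rest of the battery."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        image_id = i + 1
        for pair_name in pair_names:
            stem = f"Img{image_id}_{pair_name}"
            row = {
                "image_id": image_id,
                "color_pair": pair_name,
                "video": "",
                "seed": cell_seed(master_seed, image_id, pair_name),
                "status": "ok",
                "error": "",
            }
            try:
                colors = color_pair(pair_name, scene_index=i)
                cset = scene_composite_set(spec, image_id, colors)
                config = replace(
                    base_config,
                    quick_change_count=len(spec.features),
                    seed=row["seed"],
                )
                path, _ = generate_stimulus(
                    cset,
                    config,
                    out_dir / f"{stem}.avi",
                    codec=codec,
                    nominal_colors={
                        "nominal_start": list(colors[0][1]),
                        "nominal_end": list(colors[1][1]),
                    },
                )
                row["video"] = path.name
            except Exception as exc:  # deliberate: partial failure is reported
                row["status"] = "failed"
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "battery_index.csv", index=False)
    return index
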