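"""Composite image sets: the naming grammar and directory loader.

A generation run consumes a flat folder of co-registered images named

    Img<N>_<Color>[_<state>...].png|jpg

one file per combination of slow-change color (two per run) and quick-change
feature state, i.e. ``2 * 2**k`` files for ``k`` binary features.  State
tokens appear in a fixed left-to-right order that defines the feature order;
the two labels observed at each token position define that feature's state
domain.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import AmbiguityError, CompletenessError, GeometryError, NameParseError

RASTER_EXTENSIONS = (".png", ".jpg", ".jpeg")

_IMG_TOKEN = re.compile(r"^Img(\d+)$")


@dataclass(frozen=True)
class CompositeKey:
    """Identity of one composite: image id, color label, state vector."""

    image_id: int
    color_label: str
    quick_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for tok in (self.color_label, *self.quick_states):
            if not tok or "_" in tok:
                raise ValueError(f"label {tok!r} must be non-empty and underscore-free")


def format_name(key: CompositeKey, ext: str = "png") -> str:
    """Render a key back into its canonical filename."""
    tokens = [f"Img{key.image_id}", key.color_label, *key.quick_states]
    return "_".join(tokens) + "." + ext.lstrip(".")


def parse_name(filename: str) -> CompositeKey:
    """Parse ``Img<N>_<Color>[_<state>...].<ext>`` into a :class:`CompositeKey`.

    Image ids may be zero-padded on disk; they are parsed as plain integers.
    """
    path = Path(filename)
    if path.suffix.lower() not in RASTER_EXTENSIONS:
        raise NameParseError(f"{filename!r}: extension {path.suffix!r} is not a raster format")
    tokens = path.stem.split("_")
    if len(tokens) < 2:
        raise NameParseError(
            f"{filename!r}: expected at least 'Img<N>_<Color>', got {len(tokens)} token(s)"
        )
    m = _IMG_TOKEN.match(tokens[0])
    if not m:
        raise NameParseError(f"{filename!r}: first token {tokens[0]!r} must match 'Img<digits>'")
    for tok in tokens[1:]:
        if not tok:
            raise NameParseError(f"{filename!r}: empty token in name")
    return CompositeKey(int(m.group(1)), tokens[1], tuple(tokens[2:]))


def state_combinations(features) -> list[tuple[str, ...]]:
    """All 2**k state vectors, in itertools.product order over each feature's
    ``states`` pair.  ``features`` may be QuickFeature objects or bare
    (label, label) domains."""
    domains = []
    for f in features:
        domains.append(tuple(f.states) if hasattr(f, "states") else tuple(f))
    return [tuple(c) for c in itertools.product(*domains)] if domains else [()]


@dataclass
class CompositeSet:
    """A complete, dimension-consistent grid of composites for one image id."""

    image_id: int
    width: int
    height: int
    color_labels: tuple[str, str]  # (start, end)
    feature_state_domains: tuple[tuple[str, str], ...]
    images: dict[CompositeKey, np.ndarray]

    @property
    def n_features(self) -> int:
        return len(self.feature_state_domains)

    def get(self, color_label: str, quick_states: tuple[str, ...]) -> np.ndarray:
        return self.images[CompositeKey(self.image_id, color_label, tuple(quick_states))]

    def initial_states(self) -> tuple[str, ...]:
        """Default starting state vector: the first label of every domain."""
        return tuple(d[0] for d in self.feature_state_domains)


def _discover(directory: Path, image_id: int) -> dict[CompositeKey, Path]:
    found: dict[CompositeKey, Path] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in RASTER_EXTENSIONS:
            continue
        try:
            key = parse_name(path.name)
        except NameParseError:
            continue
        if key.image_id != image_id:
            continue
        if key in found:
            raise AmbiguityError(f"duplicate composite key {key} in {directory}")
        found[key] = path
    return found


def load_set(
    directory: str | Path,
    image_id: int,
    color_order: tuple[str, str] | None = None,
) -> CompositeSet:
    """Load and validate the composite grid for ``image_id``.

    ``color_order`` fixes which color is the start and which the end of the
    slow change; it is part of the run configuration, not of the file names.
    When omitted, the two labels are taken in sorted order (with the caveat
    that the morph direction is then an arbitrary choice).

    Raises :class:`CompletenessError` listing any missing combination,
    :class:`AmbiguityError` if more than two color labels are present (stage
    the desired color *pair* in the folder instead), and
    :class:`GeometryError` on mixed image dimensions.
    """
    directory = Path(directory)
    found = _discover(directory, image_id)
    if not found:
        raise CompletenessError(f"no composites for image id {image_id} in {directory}")

    observed_colors = sorted({k.color_label for k in found})
    if len(observed_colors) > 2:
        raise AmbiguityError(
            f"found {len(observed_colors)} color labels {observed_colors} for "
            f"Img{image_id}; stage exactly one pair of colors per input folder"
        )
    if len(observed_colors) < 2:
        raise CompletenessError(
            f"need two color labels for Img{image_id}, found {observed_colors}"
        )
    if color_order is None:
        color_order = (observed_colors[0], observed_colors[1])
    elif sorted(color_order) != observed_colors:
        raise AmbiguityError(
            f"configured color order {color_order} does not match labels on disk "
            f"{observed_colors}"
        )

    # feature count must be consistent across the set
    n_states = {len(k.quick_states) for k in found}
    if len(n_states) != 1:
        raise CompletenessError(
            f"inconsistent quick-state token counts {sorted(n_states)} in {directory}"
        )
    k = n_states.pop()

    # per-position state domains, ordered by first appearance in sorted names
    domains: list[tuple[str, ...]] = []
    for pos in range(k):
        labels: list[str] = []
        for key in found:
            tok = key.quick_states[pos]
            if tok not in labels:
                labels.append(tok)
        if len(labels) != 2:
            raise CompletenessError(
                f"state token position {pos} has labels {labels}; expected exactly two"
            )
        domains.append(tuple(labels))

    expected = {
        CompositeKey(image_id, color, states)
        for color in color_order
        for states in state_combinations(domains)
    }
    missing = expected - set(found)
    if missing:
        names = ", ".join(sorted(format_name(m) for m in missing))
        raise CompletenessError(f"incomplete composite grid; missing: {names}")

    jpeg = [p for p in found.values() if p.suffix.lower() in (".jpg", ".jpeg")]
    if jpeg:
        warnings.warn(
            "composite set contains JPEG images; bit-exact QC assertions are "
            "relaxed for lossy inputs",
            stacklevel=2,
        )

    images: dict[CompositeKey, np.ndarray] = {}
    dims = set()
    for key, path in found.items():
        arr = np.asarray(Image.open(path).convert("RGB"))
        images[key] = arr
        dims.add(arr.shape[:2])
    if len(dims) != 1:
        raise GeometryError(f"mixed image dimensions {sorted(dims)} in {directory}")
    height, width = dims.pop()

    return CompositeSet(
        image_id=image_id,
        width=width,
        height=height,
        color_labels=(color_order[0], color_order[1]),
        feature_state_domains=tuple(domains),
        images=images,
    )
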