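"""Mesophyll airspace estimation by label-image pixel quantization.

The input is an RGB raster in which each anatomical region has been painted
a flat legend color — by convention green for cell interiors, grey for
intercellular (air) space, blue for the epidermises and yellow for regions
to ignore (vasculature, debris, background).  The estimator is a pure color
histogram: it counts pixels per class and reports the mesophyll porosity as

    airspace (%) = 100 × grey / (grey + green)

The epidermis and ignore classes never enter the ratio — the epidermis is
not part of the mesophyll.  No geometry is used, so the estimate is
invariant to any rearrangement of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from PIL import Image

from .errors import ClassificationError, InvalidInputError, NoMesophyllError

CLASS_NAMES = ("cell", "intercellular", "epidermis", "ignore")

#: Default legend: any four pairwise-distinct colors work; these are the
#: conventional choices and can be overridden per image set.
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "cell": (0, 255, 0),
    "intercellular": (128, 128, 128),
    "epidermis": (0, 0, 255),
    "ignore": (255, 255, 0),
}

UnresolvedPolicy = Literal["error", "ignore", "nearest"]


@dataclass(frozen=True)
class LabelLegend:
    """Class → RGB mapping plus the matching rule for off-legend pixels.

    ``match_tolerance`` is the maximum per-channel deviation (0–255) a pixel
    may have from a legend color and still match it.  The legend is valid
    only when ``2 × tolerance`` is strictly below the minimum pairwise
    Chebyshev distance between legend colors, so no pixel can ever match two
    classes.  ``unresolved_policy`` decides what happens to pixels matching
    no class: fail loudly (``error``, the default), count them separately
    (``ignore``), or snap them to the nearest legend color (``nearest``).
    """

    colors: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    match_tolerance: int = 0
    unresolved_policy: UnresolvedPolicy = "error"

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.colors)
        if missing:
            raise InvalidInputError(f"legend missing classes: {sorted(missing)}")
        for name, rgb in self.colors.items():
            if len(rgb) != 3 or any(not (0 <= c <= 255) for c in rgb):
                raise InvalidInputError(f"invalid RGB for class {name!r}: {rgb}")
        if self.match_tolerance < 0:
            raise InvalidInputError("match_tolerance must be >= 0")
        if self.unresolved_policy not in ("error", "ignore", "nearest"):
            raise InvalidInputError(
                f"unknown unresolved_policy {self.unresolved_policy!r}"
            )
        names = list(CLASS_NAMES)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d = _chebyshev(self.colors[a], self.colors[b])
                if d == 0:
                    raise InvalidInputError(f"classes {a!r} and {b!r} share a color")
                if 2 * self.match_tolerance >= d:
                    raise InvalidInputError(
                        f"tolerance {self.match_tolerance} is ambiguous: classes "
                        f"{a!r} and {b!r} are only {d} apart per channel"
                    )

    def color_array(self) -> np.ndarray:
        """Legend colors as a (4, 3) int array, ordered as CLASS_NAMES."""
        return np.array([self.colors[c] for c in CLASS_NAMES], dtype=np.int16)


def _chebyshev(a: tuple[int, int, int], b: tuple[int, int, int]) -> int:
    return max(abs(x - y) for x, y in zip(a, b))


@dataclass(frozen=True)
class LabelImage:
    """An RGB label raster plus provenance metadata.

    ``pixels`` is a (H, W, 3) uint8 array.  ``pixel_size_um`` is carried as
    metadata only; the airspace ratio is dimensionless so it never enters
    any computation.
    """

    pixels: np.ndarray
    source: str = "<array>"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"label image must be H x W x 3 RGB, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("label image must be at least 1 x 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @classmethod
    def from_file(cls, path: str | Path, pixel_size_um: float | None = None) -> "LabelImage":
        """Read a PNG/TIFF raster; RGBA and palette images are converted to
        RGB (alpha discarded), grayscale images are rejected — the legend is
        chromatic and a grey-only raster cannot carry it faithfully."""
        path = Path(path)
        with Image.open(path) as im:
            if im.mode in ("L", "LA", "I", "I;16", "F", "1"):
                raise InvalidInputError(
                    f"{path}: grayscale rasters are not supported; labels are RGB"
                )
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
        return cls(pixels=arr, source=str(path), pixel_size_um=pixel_size_um)


@dataclass(frozen=True)
class AirspaceResult:
    """Per-class pixel counts and the derived airspace percentage."""

    counts: dict[str, int]           # keys: CLASS_NAMES + "unresolved"
    total_pixels: int
    airspace_percent: float | None   # None until airspace_fraction is applied
    source: str = "<array>"

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_pixels:
            raise InvalidInputError("class counts do not sum to the pixel total")

    def class_percentages(self) -> dict[str, float]:
        """Each class as a percentage of the whole image (reporting only)."""
        return {k: 100.0 * v / self.total_pixels for k, v in self.counts.items()}


def classify_pixels(image: LabelImage, legend: LabelLegend) -> AirspaceResult:
    """Assign every pixel to exactly one legend class (or to ``unresolved``).

    Matching is exact when ``match_tolerance`` is 0, otherwise a pixel
    matches the unique class whose color is within the per-channel
    tolerance (the legend guarantees uniqueness).  Deterministic for a
    fixed image and legend.
    """
    px = image.pixels.astype(np.int16)
    flat = px.reshape(-1, 3)
    palette = legend.color_array()
    # (N, 4) per-channel Chebyshev distance to each legend color
    dist = np.abs(flat[:, None, :] - palette[None, :, :]).max(axis=2)
    matched = dist <= legend.match_tolerance
    label = np.argmax(matched, axis=1)
    unresolved = ~matched.any(axis=1)

    if unresolved.any():
        if legend.unresolved_policy == "error":
            idx = int(np.flatnonzero(unresolved)[0])
            h, w = image.pixels.shape[:2]
            coord = (idx // w, idx % w)
            color = tuple(int(c) for c in image.pixels[coord[0], coord[1]])
            raise ClassificationError(int(unresolved.sum()), coord, color)
        if legend.unresolved_policy == "nearest":
            label[unresolved] = np.argmin(dist[unresolved], axis=1)
            unresolved = np.zeros_like(unresolved)
        # policy == "ignore": leave them out of every class, counted below

    counts = {name: 0 for name in CLASS_NAMES}
    resolved_labels = label[~unresolved]
    bins = np.bincount(resolved_labels, minlength=len(CLASS_NAMES))
    for i, name in enumerate(CLASS_NAMES):
        counts[name] = int(bins[i])
    counts["unresolved"] = int(unresolved.sum())

    return AirspaceResult(
        counts=counts,
        total_pixels=flat.shape[0],
        airspace_percent=None,
        source=image.source,
    )


def airspace_fraction(result: AirspaceResult) -> float:
    """100 × intercellular / (intercellular + cell).

    Epidermis, ignore and unresolved pixels are excluded: the ratio is a
    property of the mesophyll alone.
    """
    cell = result.counts["cell"]
    inter = result.counts["intercellular"]
    if cell + inter == 0:
        raise NoMesophyllError(
            "no mesophyll pixels (cell + intercellular = 0) in " + result.source
        )
    # parenthesized so that percent == 100 * (ratio) bit-exactly, letting
    # generator ground-truth fractions be compared without tolerance
    return 100.0 * (inter / (inter + cell))


def quantify_section(image: LabelImage, legend: LabelLegend) -> AirspaceResult:
    """Classify a section raster and compute its airspace percentage."""
    counted = classify_pixels(image, legend)
    return AirspaceResult(
        counts=counted.counts,
        total_pixels=counted.total_pixels,
        airspace_percent=airspace_fraction(counted),
        source=counted.source,
    )
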