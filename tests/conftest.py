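import numpy as np
import pytest

from vincaleaf import LabelImage, LabelLegend
from vincaleaf.airspace import CLASS_NAMES, DEFAULT_COLORS


@pytest.fixture
def legend():
    return LabelLegend()


@pytest.fixture
def make_label_image():
    """Factory: random label raster with exact per-class pixel counts."""

    def _make(counts: dict[str, int], seed: int = 0,
              colors: dict | None = None) -> LabelImage:
        colors = colors or DEFAULT_COLORS
        total = sum(counts.values())
        side = max(1, int(np.ceil(np.sqrt(total))))
        n = side * side
        # pad with 'ignore' so the raster is square
        padded = dict(counts)
        padded["ignore"] = padded.get("ignore", 0) + (n - total)
        rng = np.random.default_rng(seed)
        labels = np.repeat(
            np.arange(len(CLASS_NAMES)),
            [padded.get(c, 0) for c in CLASS_NAMES],
        )
        rng.shuffle(labels)
        palette = np.array([colors[c] for c in CLASS_NAMES], dtype=np.uint8)
        return LabelImage(pixels=palette[labels].reshape(side, side, 3))

    return _make


def classify_by_loop(image: LabelImage, legend: LabelLegend) -> dict[str, int]:
    """Independent oracle: naive per-pixel loop over the raster."""
    counts = {name: 0 for name in (*CLASS_NAMES, "unresolved")}
    h, w, _ = image.pixels.shape
    for i in range(h):
        for j in range(w):
            px = image.pixels[i, j].astype(int)
            hit = None
            for name in CLASS_NAMES:
                color = legend.colors[name]
                if max(abs(int(px[k]) - color[k]) for k in range(3)) <= legend.match_tolerance:
                    hit = name
                    break
            counts[hit if hit is not None else "unresolved"] += 1
    return counts
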