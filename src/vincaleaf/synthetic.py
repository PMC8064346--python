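"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's raw material:

* :func:`generate_section` paints a labeled mesophyll cross-section —
  blue epidermis bands top and bottom, a green cell interior, and grey
  airspace blobs carved until a target porosity is reached.  The ground
  truth returned is the *realized* fraction, recounted from the finished
  raster, so estimator-recovery tests can demand exact agreement.
* :func:`generate_census` produces an epidermal census with prescribed
  expected densities, either exactly or with Poisson count noise.
* :func:`generate_section_profile` produces replicate thickness
  measurements whose tissue ratios recover prescribed CTR/SR targets.

The airspace geometry is deliberately simple (random ellipses rather than
a realistic spongy network): the estimator downstream is a pure pixel
histogram, so only the area fraction matters.

All randomness flows from a single integer seed per call; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .airspace import DEFAULT_COLORS, LabelImage, LabelLegend
from .errors import GenerationError, InvalidInputError
from .morphometry import SectionProfile, StomatalCensus


@dataclass(frozen=True)
class SectionSpec:
    """Geometry and target porosity for one synthetic labeled section."""

    width: int = 512
    height: int = 512
    band_px: int = 24                 # epidermis band thickness, top and bottom
    target_fraction: float = 0.6     # grey / (grey + green), open interval (0,1)
    blob_radius_min: int = 3
    blob_radius_max: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InvalidInputError("image dimensions must be >= 1")
        if self.band_px < 0 or 2 * self.band_px >= self.height:
            raise InvalidInputError(
                "epidermis bands must leave a non-empty interior: "
                f"2 x {self.band_px} >= height {self.height}"
            )
        if not 0.0 < self.target_fraction < 1.0:
            raise InvalidInputError("target_fraction must be in (0, 1)")
        if not 1 <= self.blob_radius_min <= self.blob_radius_max:
            raise InvalidInputError("need 1 <= blob_radius_min <= blob_radius_max")


@dataclass(frozen=True)
class CensusSpec:
    """Expected densities (per mm²) and the count noise model for a census."""

    area_mm2: float = 1.0
    stomatal_density: float = 100.0
    epidermal_cell_density: float = 500.0
    trichome_density: float = 20.0
    noise: str = "exact"             # "exact" or "poisson"
    seed: int = 0
    species_id: str = "synthetic"
    side: str = "abaxial"

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise InvalidInputError("area_mm2 must be > 0")
        for name in ("stomatal_density", "epidermal_cell_density", "trichome_density"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.noise not in ("exact", "poisson"):
            raise InvalidInputError(f"noise must be 'exact' or 'poisson', got {self.noise!r}")


def generate_section(
    spec: SectionSpec,
    legend: LabelLegend | None = None,
    max_blobs: int = 200_000,
) -> tuple[LabelImage, float]:
    """Paint a labeled cross-section and return it with its true porosity.

    The interior starts fully cell-green; grey ellipses are carved at
    random positions until the grey/(grey+green) fraction first reaches or
    exceeds the target.  The returned ground truth is the realized fraction
    recounted from the pixels, so it satisfies

        target <= realized <= target + (max blob area) / (interior area).

    Carving draws from one RNG stream, so for a fixed seed and geometry a
    higher target only extends the same blob sequence: the realized
    fraction is monotone in the target.
    """
    if legend is None:
        legend = LabelLegend()
    rng = np.random.default_rng(spec.seed)

    h, w, band = spec.height, spec.width, spec.band_px
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:, :] = legend.colors["cell"]
    if band > 0:
        img[:band, :] = legend.colors["epidermis"]
        img[h - band:, :] = legend.colors["epidermis"]

    top, bottom = band, h - band
    interior_area = (bottom - top) * w
    grey = np.zeros((bottom - top, w), dtype=bool)

    rows = np.arange(bottom - top)[:, None]
    cols = np.arange(w)[None, :]

    n_grey = 0
    for _ in range(max_blobs):
        frac = n_grey / interior_area
        if frac >= spec.target_fraction:
            break
        cy = rng.integers(0, bottom - top)
        cx = rng.integers(0, w)
        ry = rng.integers(spec.blob_radius_min, spec.blob_radius_max + 1)
        rx = rng.integers(spec.blob_radius_min, spec.blob_radius_max + 1)
        blob = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        grey |= blob
        n_grey = int(grey.sum())
    else:
        raise GenerationError(
            f"target fraction {spec.target_fraction} not reached after "
            f"{max_blobs} blobs (realized {n_grey / interior_area:.4f})"
        )

    img[top:bottom][grey] = legend.colors["intercellular"]
    realized = n_grey / interior_area
    image = LabelImage(
        pixels=img,
        source=f"synthetic:seed={spec.seed},target={spec.target_fraction}",
    )
    return image, realized


def generate_census(spec: CensusSpec) -> StomatalCensus:
    """Epidermal census with prescribed expected densities.

    With ``noise='exact'`` each count is ``round(density x area)``; with
    ``noise='poisson'`` counts are independent Poisson draws with those
    means, emulating sampling variation between micrograph fields.
    """
    means = (
        spec.stomatal_density * spec.area_mm2,
        spec.epidermal_cell_density * spec.area_mm2,
        spec.trichome_density * spec.area_mm2,
    )
    if spec.noise == "exact":
        counts = [int(round(m)) for m in means]
    else:
        rng = np.random.default_rng(spec.seed)
        counts = [int(rng.poisson(m)) for m in means]
    return StomatalCensus(
        species_id=spec.species_id,
        side=spec.side,  # type: ignore[arg-type]
        area_mm2=spec.area_mm2,
        n_stomata=counts[0],
        n_epidermal_cells=counts[1],
        n_trichomes=counts[2],
    )


def generate_section_profile(
    lt_um: float,
    ctr_target: float,
    sr_target: float,
    noise_cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    species_id: str = "synthetic",
    max_attempts: int = 1000,
) -> SectionProfile:
    """Replicate LT/PTT/STT thicknesses whose ratios recover CTR/SR targets.

    Each replicate triple is the target means scaled by independent
    multiplicative Gaussian factors ``1 + cv·z``; triples violating
    non-negativity or ``PTT + STT <= LT`` are redrawn (bounded), so every
    profile is internally consistent.  With ``noise_cv = 0`` the ratios of
    the means recover the targets exactly.
    """
    if not lt_um > 0:
        raise InvalidInputError("lt_um must be > 0")
    if ctr_target < 0 or sr_target < 0 or ctr_target + sr_target > 100:
        raise InvalidInputError(
            f"need ctr, sr >= 0 and ctr + sr <= 100; got {ctr_target} + {sr_target}"
        )
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be >= 0")
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")

    ptt_mean = ctr_target / 100.0 * lt_um
    stt_mean = sr_target / 100.0 * lt_um
    rng = np.random.default_rng(seed)

    lt_reps, ptt_reps, stt_reps = [], [], []
    for _ in range(n_reps):
        for _attempt in range(max_attempts):
            f = 1.0 + noise_cv * rng.standard_normal(3)
            lt, ptt, stt = lt_um * f[0], ptt_mean * f[1], stt_mean * f[2]
            if ptt_mean == 0.0:
                ptt = 0.0
            if stt_mean == 0.0:
                stt = 0.0
            if lt > 0 and ptt >= 0 and stt >= 0 and ptt + stt <= lt * (1 + 1e-12):
                lt_reps.append(lt)
                ptt_reps.append(ptt)
                stt_reps.append(stt)
                break
        else:
            raise GenerationError(
                f"could not draw a consistent replicate for ctr={ctr_target}, "
                f"sr={sr_target}, cv={noise_cv} after {max_attempts} attempts"
            )

    return SectionProfile(
        species_id=species_id,
        leaf_thickness_um=tuple(lt_reps),
        palisade_um=tuple(ptt_reps),
        spongy_um=tuple(stt_reps),
    )
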