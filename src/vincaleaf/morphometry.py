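"""Per-species leaf morphometric formulas.

Implements the standard epidermal and cross-section indices used in leaf
anatomy:

* stomatal index        SI (%)  = SD / (SD + E) × 100
* stomatal pore index   SPI (%) = SD × SL² × 10⁻⁴
* cell tense ratio      CTR (%) = PTT / LT × 100
* spongy tissue ratio   SR (%)  = STT / LT × 100

where SD and E are stomatal and epidermal-cell densities per mm², SL the
mean stomatal pore length in µm, and LT/PTT/STT the leaf, palisade and
spongy tissue thicknesses in µm.  The 10⁻⁴ in SPI converts SL² from µm²
to mm² so the index is an areal percentage.

Densities are stored as raw counts plus the surveyed area rather than
pre-divided rates: a unit mistake in the area then shows up as an absurd
density instead of silently cancelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import (
    InconsistentMeasurementError,
    InvalidInputError,
    UndefinedIndexError,
)

Side = Literal["adaxial", "abaxial"]

_SIDES = ("adaxial", "abaxial")


@dataclass(frozen=True)
class StomatalCensus:
    """Counts of stomata, pavement cells and trichomes over a known area.

    ``area_mm2`` is the surveyed epidermis area in mm².  A zero stomatal
    count is valid (e.g. the adaxial surface of a hypostomatic leaf).
    """

    species_id: str
    side: Side
    area_mm2: float
    n_stomata: int
    n_epidermal_cells: int
    n_trichomes: int = 0

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise InvalidInputError(f"side must be one of {_SIDES}, got {self.side!r}")
        if not self.area_mm2 > 0:
            raise InvalidInputError(f"area_mm2 must be > 0, got {self.area_mm2}")
        for name in ("n_stomata", "n_epidermal_cells", "n_trichomes"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class PoreLengthSample:
    """Replicate stomatal pore (aperture long-axis) lengths in µm."""

    species_id: str
    side: Side
    lengths_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise InvalidInputError(f"side must be one of {_SIDES}, got {self.side!r}")
        if len(self.lengths_um) < 1:
            raise InvalidInputError("at least one pore length is required")
        if any(not length > 0 for length in self.lengths_um):
            raise InvalidInputError("all pore lengths must be > 0")

    def summary(self) -> "TraitSummary":
        return summarize(self.lengths_um)


@dataclass(frozen=True)
class SectionProfile:
    """Replicate cross-section thickness measurements (µm) for one species.

    Palisade may be absent (all-zero PTT) in leaves whose mesophyll is
    entirely spongy.  Mean palisade plus mean spongy thickness may not
    exceed mean leaf thickness.
    """

    species_id: str
    leaf_thickness_um: tuple[float, ...]
    palisade_um: tuple[float, ...]
    spongy_um: tuple[float, ...]
    upper_epidermis_um: tuple[float, ...] = ()
    lower_epidermis_um: tuple[float, ...] = ()
    upper_cuticle_um: tuple[float, ...] = ()
    lower_cuticle_um: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("leaf_thickness_um", "palisade_um", "spongy_um",
                     "upper_epidermis_um", "lower_epidermis_um",
                     "upper_cuticle_um", "lower_cuticle_um"):
            if any(v < 0 for v in getattr(self, name)):
                raise InvalidInputError(f"{name} contains a negative value")
        if not self.leaf_thickness_um:
            raise InvalidInputError("leaf_thickness_um requires at least one value")
        lt = _mean(self.leaf_thickness_um)
        ptt = _mean(self.palisade_um) if self.palisade_um else 0.0
        stt = _mean(self.spongy_um) if self.spongy_um else 0.0
        if ptt + stt > lt * (1 + 1e-9):
            raise InconsistentMeasurementError(
                f"mean palisade + spongy thickness ({ptt + stt:.4g} um) exceeds "
                f"mean leaf thickness ({lt:.4g} um)"
            )


@dataclass(frozen=True)
class TraitSummary:
    """Point estimate with its standard error; ``sem`` is None when n = 1."""

    mean: float
    sem: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        if self.sem is not None and self.sem < 0:
            raise InvalidInputError("sem must be >= 0")


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


# ---------------------------------------------------------------------------
# densities

def stomatal_density(census: StomatalCensus) -> float:
    """Stomata per mm² of leaf surface."""
    return census.n_stomata / census.area_mm2


def epidermal_cell_density(census: StomatalCensus) -> float:
    """Pavement cells per mm², surveyed in the same field as the stomata."""
    return census.n_epidermal_cells / census.area_mm2


def trichome_density(census: StomatalCensus) -> float:
    """Trichomes (non-glandular hairs) per mm²."""
    return census.n_trichomes / census.area_mm2


# ---------------------------------------------------------------------------
# indices

def stomatal_index(sd: float, e: float) -> float:
    """SI (%) = SD / (SD + E) × 100.

    Expresses stomata as a fraction of all epidermal cells, which makes the
    index robust to cell-size differences between samples.  Both densities
    must share the same areal basis.

    Raises
    ------
    UndefinedIndexError
        When SD + E = 0: an all-zero census means "no data", not SI = 0.
    """
    if sd < 0 or e < 0:
        raise InvalidInputError("densities must be non-negative")
    if sd + e == 0:
        raise UndefinedIndexError("SI undefined: stomatal + epidermal density is zero")
    return 100.0 * sd / (sd + e)


def stomatal_pore_index(sd: float, sl_mean_um: float | None) -> float:
    """SPI (%) = SD × SL² × 10⁻⁴, with SD per mm² and SL in µm.

    A proxy for the total pore area fraction of the epidermis.  With no
    stomata (SD = 0) the index is 0 and SL may be omitted.
    """
    if sd < 0:
        raise InvalidInputError("stomatal density must be non-negative")
    if sd == 0:
        return 0.0
    if sl_mean_um is None or not sl_mean_um > 0:
        raise InvalidInputError("mean pore length must be > 0 when stomata are present")
    return sd * sl_mean_um**2 * 1e-4


def cell_tense_ratio(ptt_um: float, lt_um: float) -> float:
    """CTR (%) = PTT / LT × 100 — palisade fraction of total leaf thickness."""
    _check_thickness_pair("palisade", ptt_um, lt_um)
    return 100.0 * ptt_um / lt_um


def spongy_ratio(stt_um: float, lt_um: float) -> float:
    """SR (%) = STT / LT × 100 — spongy fraction of total leaf thickness."""
    _check_thickness_pair("spongy", stt_um, lt_um)
    return 100.0 * stt_um / lt_um


def _check_thickness_pair(name: str, tissue_um: float, lt_um: float) -> None:
    if not lt_um > 0:
        raise InvalidInputError(f"leaf thickness must be > 0, got {lt_um}")
    if tissue_um < 0:
        raise InvalidInputError(f"{name} thickness must be >= 0, got {tissue_um}")
    if tissue_um > lt_um:
        raise InconsistentMeasurementError(
            f"{name} thickness ({tissue_um} um) exceeds leaf thickness ({lt_um} um)"
        )


# ---------------------------------------------------------------------------
# aggregation

def summarize(values: Sequence[float]) -> TraitSummary:
    """Mean ± standard error of the mean.

    The s.e.m. uses the n−1 (sample) standard deviation divided by √n and
    is omitted for a single measurement.
    """
    n = len(values)
    if n == 0:
        raise InvalidInputError("cannot summarize an empty sample")
    mean = _mean(values)
    if n == 1:
        return TraitSummary(mean=mean, sem=None, n=1)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return TraitSummary(mean=mean, sem=math.sqrt(var / n), n=n)
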