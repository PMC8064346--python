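"""Published leaf-trait reference values for the four *Vinca* taxa.

These are the printed per-species measurements for *V. minor*, *V. major*,
*V. major* var. *variegata* and *V. herbacea*: stomatal density (SD, per
mm²), stomatal index (SI, %), mean stomatal pore length (SL, µm ± s.e.m.),
stomatal pore index (SPI, %), adaxial trichome density (TD, per mm²), and
the cross-section thicknesses (LT/PTT/STT, µm ± s.e.m.) with their derived
cell tense ratio (CTR, %) and spongy ratio (SR, %).

All four taxa are hypostomatic: stomata sit on the abaxial (lower)
surface, with *V. minor* lacking adaxial stomata entirely.  The derived
columns (SPI, CTR, SR) are as printed in the source report, rounded to two
decimals; its rounding is not perfectly consistent at the second decimal
(e.g. the variegate's abaxial SPI recomputes to 1.0188 but is printed as
1.01), so recomputation checks use an absolute band of ±0.02.

The raw epidermal-cell densities (E) behind the SI column were never
published, so SI cells cannot be independently recomputed; only SPI, CTR
and SR can.
"""

from __future__ import annotations

import pandas as pd

from .stats import TraitVector

SPECIES = (
    "V. minor",
    "V. major",
    "V. major var. variegata",
    "V. herbacea",
)

#: Reported mesophyll airspace percentages (labeled-section estimates).
AIRSPACE_PERCENT = {
    "V. minor": 62.8,
    "V. major": 63.8,
    "V. major var. variegata": 67.3,
    "V. herbacea": 67.2,
}


def epidermal_traits() -> pd.DataFrame:
    """Per-species, per-side epidermal traits (long over side).

    ``spi_percent`` is the printed value; ``td_per_mm2`` was reported for
    the adaxial side only (trichomes are confined to the upper surface and,
    in *V. minor*, to the midvein).
    """
    rows = [
        # species, side, sd, si, sl_mean, sl_sem, spi, td
        ("V. minor", "adaxial", 0, 0.0, None, None, 0.0, 31),
        ("V. minor", "abaxial", 223, 25.3, 9.57, 0.6, 2.04, None),
        ("V. major", "adaxial", 10, 4.5, 14.84, 1.1, 0.22, 14),
        ("V. major", "abaxial", 49, 23.2, 19.75, 0.4, 1.91, None),
        ("V. major var. variegata", "adaxial", 12, 4.2, 12.33, 1.0, 0.18, 25),
        ("V. major var. variegata", "abaxial", 68, 20.9, 12.24, 1.4, 1.01, None),
        ("V. herbacea", "adaxial", 16, 4.4, 12.56, 1.0, 0.25, 23),
        ("V. herbacea", "abaxial", 60, 25.0, 13.05, 1.2, 1.02, None),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "side", "sd_per_mm2", "si_percent",
            "sl_um_mean", "sl_um_sem", "spi_percent", "td_per_mm2",
        ],
    )


def section_traits() -> pd.DataFrame:
    """Per-species cross-section thicknesses and printed tissue ratios."""
    rows = [
        # species, lt, lt_sem, ptt, ptt_sem, stt, stt_sem, ctr, sr
        ("V. minor", 85.47, 2.6, 12.58, 0.7, 52.0, 0.5, 14.72, 60.84),
        ("V. major", 136.85, 1.4, 0.0, None, 124.0, 0.5, 0.0, 90.61),
        ("V. major var. variegata", 97.09, 1.5, 14.57, 4.4, 67.29, 1.7, 15.01, 69.31),
        ("V. herbacea", 133.38, 2.2, 36.66, 2.2, 68.42, 3.7, 27.48, 51.3),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "lt_um", "lt_sem", "ptt_um", "ptt_sem",
            "stt_um", "stt_sem", "ctr_percent", "sr_percent",
        ],
    )


def adaxial_trait_vector() -> TraitVector:
    """Adaxial trichome density paired with adaxial stomatal index.

    The trait pair whose inverse correlation across the four taxa is the
    headline trend (reported as r = -0.7).
    """
    df = epidermal_traits()
    ad = df[df["side"] == "adaxial"]
    return TraitVector(
        species_ids=tuple(ad["species_id"]),
        x=tuple(float(v) for v in ad["td_per_mm2"]),
        y=tuple(float(v) for v in ad["si_percent"]),
    )
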