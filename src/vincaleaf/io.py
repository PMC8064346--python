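"""Table I/O, legend configuration and the end-to-end pipeline.

Measurement CSVs are long-format (one value per row) so replicates are
preserved; the wide per-species trait tables are an *output* view.  Output
JSON carries full precision; two-decimal rounding is applied only when
rendering tables for display.  Runs are deterministic: identical inputs,
legend and seed give byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as mm
from .airspace import (
    CLASS_NAMES,
    LabelImage,
    LabelLegend,
    airspace_fraction,
    quantify_section,
)
from .errors import ConfigError, ParseError
from .morphometry import PoreLengthSample, SectionProfile, StomatalCensus
from .stats import linear_fit, pearson_r

logger = logging.getLogger("vincaleaf")

SECTION_STRUCTURES = (
    "leaf", "palisade", "spongy",
    "upper_epidermis", "lower_epidermis", "upper_cuticle", "lower_cuticle",
)

_CENSUS_COLUMNS = (
    "species_id", "side", "area_mm2", "n_stomata", "n_epidermal_cells", "n_trichomes",
)
_PORE_COLUMNS = ("species_id", "side", "length_um")
_SECTION_COLUMNS = ("species_id", "structure", "thickness_um")


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError("file is empty", path=path) from None
    if df.empty:
        raise ParseError("table has a header but no rows", path=path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}", path=path,
                         column=missing[0])
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=3)
    return df


def read_census_table(path: str | Path) -> list[StomatalCensus]:
    """Read a census CSV (one row per species × side) into typed records.

    Schema violations raise :class:`ParseError` naming the column and the
    1-based data row.
    """
    df = _read_table(path, _CENSUS_COLUMNS)
    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 1
        try:
            records.append(StomatalCensus(
                species_id=str(row["species_id"]),
                side=str(row["side"]),
                area_mm2=float(row["area_mm2"]),
                n_stomata=int(row["n_stomata"]),
                n_epidermal_cells=int(row["n_epidermal_cells"]),
                n_trichomes=int(row["n_trichomes"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, row=rownum) from exc
    return records


def read_pore_lengths(path: str | Path) -> list[PoreLengthSample]:
    """Read a long-format pore-length CSV into one sample per species × side."""
    df = _read_table(path, _PORE_COLUMNS)
    samples = []
    for (species, side), grp in df.groupby(["species_id", "side"], sort=True):
        first_row = int(grp.index[0]) + 1
        try:
            samples.append(PoreLengthSample(
                species_id=str(species),
                side=str(side),
                lengths_um=tuple(float(v) for v in grp["length_um"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, row=first_row,
                             column="length_um") from exc
    return samples


def read_section_table(path: str | Path) -> list[SectionProfile]:
    """Read a long-format section-thickness CSV into per-species profiles."""
    df = _read_table(path, _SECTION_COLUMNS)
    bad = ~df["structure"].isin(SECTION_STRUCTURES)
    if bad.any():
        rownum = int(df.index[bad][0]) + 1
        raise ParseError(
            f"unknown structure {df.loc[df.index[bad][0], 'structure']!r} "
            f"(expected one of {SECTION_STRUCTURES})",
            path=path, row=rownum, column="structure",
        )
    profiles = []
    for species, grp in df.groupby("species_id", sort=True):
        def reps(structure: str) -> tuple[float, ...]:
            return tuple(float(v) for v in
                         grp.loc[grp["structure"] == structure, "thickness_um"])
        first_row = int(grp.index[0]) + 1
        try:
            profiles.append(SectionProfile(
                species_id=str(species),
                leaf_thickness_um=reps("leaf"),
                palisade_um=reps("palisade"),
                spongy_um=reps("spongy"),
                upper_epidermis_um=reps("upper_epidermis"),
                lower_epidermis_um=reps("lower_epidermis"),
                upper_cuticle_um=reps("upper_cuticle"),
                lower_cuticle_um=reps("lower_cuticle"),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, row=first_row) from exc
    return profiles


def read_legend(path: str | Path) -> LabelLegend:
    """Read a JSON legend config: {"colors": {class: [R,G,B]}, "tolerance": int,
    "policy": "error"|"ignore"|"nearest"}."""
    path = Path(path)
    with open(path) as fh:
        cfg = json.load(fh)
    colors = {k: tuple(int(c) for c in v) for k, v in cfg.get("colors", {}).items()}
    return LabelLegend(
        colors=colors,
        match_tolerance=int(cfg.get("tolerance", 0)),
        unresolved_policy=cfg.get("policy", "error"),
    )


# ---------------------------------------------------------------------------
# trait-table assembly

def epidermal_trait_table(
    censuses: list[StomatalCensus],
    pore_samples: list[PoreLengthSample] | None = None,
) -> pd.DataFrame:
    """Wide per-(species, side) trait table: densities, SI, SL, SPI.

    SPI is 0 without stomata, and missing (NaN) when stomata are present
    but no pore lengths were supplied for that surface.
    """
    pores = {(s.species_id, s.side): s.summary() for s in (pore_samples or [])}
    rows = []
    for c in censuses:
        sd = mm.stomatal_density(c)
        e = mm.epidermal_cell_density(c)
        td = mm.trichome_density(c)
        si = mm.stomatal_index(sd, e)
        sl = pores.get((c.species_id, c.side))
        if sd == 0:
            spi = 0.0
        elif sl is not None:
            spi = mm.stomatal_pore_index(sd, sl.mean)
        else:
            spi = float("nan")
        rows.append({
            "species_id": c.species_id,
            "side": c.side,
            "sd_per_mm2": sd,
            "e_per_mm2": e,
            "td_per_mm2": td,
            "si_percent": si,
            "sl_um_mean": sl.mean if sl else float("nan"),
            "sl_um_sem": (sl.sem if sl and sl.sem is not None else float("nan")),
            "sl_n": sl.n if sl else 0,
            "spi_percent": spi,
        })
    return pd.DataFrame(rows)


def section_trait_table(profiles: list[SectionProfile]) -> pd.DataFrame:
    """Wide per-species section table: mean thicknesses ± s.e.m., CTR, SR."""
    rows = []
    for p in profiles:
        lt = mm.summarize(p.leaf_thickness_um)
        ptt = mm.summarize(p.palisade_um) if p.palisade_um else None
        stt = mm.summarize(p.spongy_um) if p.spongy_um else None
        ptt_mean = ptt.mean if ptt else 0.0
        stt_mean = stt.mean if stt else 0.0
        rows.append({
            "species_id": p.species_id,
            "lt_um": lt.mean,
            "lt_sem": lt.sem if lt.sem is not None else float("nan"),
            "ptt_um": ptt_mean,
            "ptt_sem": (ptt.sem if ptt and ptt.sem is not None else float("nan")),
            "stt_um": stt_mean,
            "stt_sem": (stt.sem if stt and stt.sem is not None else float("nan")),
            "ctr_percent": mm.cell_tense_ratio(ptt_mean, lt.mean),
            "sr_percent": mm.spongy_ratio(stt_mean, lt.mean),
        })
    return pd.DataFrame(rows)


def render_table(df: pd.DataFrame, decimals: int = 2) -> str:
    """Display view: floats rounded (half-even) to ``decimals`` places."""
    shown = df.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].round(decimals)
    return shown.to_string(index=False)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed is recorded in outputs."""

    out_dir: Path
    census_path: Path | None = None
    pore_lengths_path: Path | None = None
    section_path: Path | None = None
    image_paths: tuple[Path, ...] = ()
    legend_path: Path | None = None
    legend: LabelLegend = field(default_factory=LabelLegend)
    seed: int = 0
    correlate: bool = True

    def validate(self) -> None:
        for name in ("census_path", "pore_lengths_path", "section_path", "legend_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for p in self.image_paths:
            if not Path(p).exists():
                raise ConfigError(f"image does not exist: {p}")


def _file_hash(path: Path) -> str:
    return sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               allow_nan=False) + "\n")


def _jsonable(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in rec.items()})
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage and write its outputs under ``out_dir``.

    Stages: epidermal trait table (census + pore lengths), section trait
    table, per-image airspace quantification, and the adaxial trichome
    density vs stomatal index correlation (when >= 3 species carry both
    traits).  Any stage error halts the run with a stage-labeled message.
    Returns a mapping of output names to the paths written.
    """
    config.validate()
    legend = read_legend(config.legend_path) if config.legend_path else config.legend
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    provenance: dict[str, object] = {
        "seed": config.seed,
        "legend": {k: list(v) for k, v in legend.colors.items()},
        "tolerance": legend.match_tolerance,
        "policy": legend.unresolved_policy,
        "input_hashes": {},
    }

    def stage(name):
        logger.info("stage: %s", name)

    epidermal = None
    if config.census_path is not None:
        stage("epidermal traits")
        try:
            censuses = read_census_table(config.census_path)
            provenance["input_hashes"]["census"] = _file_hash(config.census_path)
            pores = None
            if config.pore_lengths_path is not None:
                pores = read_pore_lengths(config.pore_lengths_path)
                provenance["input_hashes"]["pore_lengths"] = _file_hash(
                    config.pore_lengths_path)
            epidermal = epidermal_trait_table(censuses, pores)
            p = out / "epidermal_traits.csv"
            epidermal.to_csv(p, index=False)
            written["epidermal_traits_csv"] = p
            p = out / "epidermal_traits.json"
            _write_json(p, _jsonable(epidermal))
            written["epidermal_traits_json"] = p
        except Exception as exc:
            raise type(exc)(f"[stage epidermal traits] {exc}") from exc

    if config.section_path is not None:
        stage("section traits")
        try:
            profiles = read_section_table(config.section_path)
            provenance["input_hashes"]["sections"] = _file_hash(config.section_path)
            table = section_trait_table(profiles)
            p = out / "section_traits.csv"
            table.to_csv(p, index=False)
            written["section_traits_csv"] = p
            p = out / "section_traits.json"
            _write_json(p, _jsonable(table))
            written["section_traits_json"] = p
        except Exception as exc:
            raise type(exc)(f"[stage section traits] {exc}") from exc

    if config.image_paths:
        stage("airspace")
        try:
            records = []
            for img_path in config.image_paths:
                image = LabelImage.from_file(img_path)
                result = quantify_section(image, legend)
                provenance["input_hashes"][str(img_path)] = _file_hash(img_path)
                records.append({
                    "image": str(img_path),
                    "counts": result.counts,
                    "percentages": result.class_percentages(),
                    "airspace_percent": result.airspace_percent,
                    "unresolved": result.counts["unresolved"],
                })
            p = out / "airspace.json"
            _write_json(p, records)
            written["airspace_json"] = p
            flat = pd.DataFrame([
                {"image": r["image"],
                 **{f"n_{k}": r["counts"][k] for k in (*CLASS_NAMES, "unresolved")},
                 "airspace_percent": r["airspace_percent"]}
                for r in records
            ])
            p = out / "airspace.csv"
            flat.to_csv(p, index=False)
            written["airspace_csv"] = p
        except Exception as exc:
            raise type(exc)(f"[stage airspace] {exc}") from exc

    if config.correlate and epidermal is not None:
        stage("correlation")
        try:
            ad = epidermal[epidermal["side"] == "adaxial"]
            if len(ad) >= 3:
                x = ad["td_per_mm2"].to_numpy(float)
                y = ad["si_percent"].to_numpy(float)
                fit = linear_fit(x, y)
                p = out / "correlation.json"
                _write_json(p, {
                    "trait_x": "td_per_mm2 (adaxial)",
                    "trait_y": "si_percent (adaxial)",
                    "n": fit.n,
                    "pearson_r": pearson_r(x, y),
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "p_value": fit.p_value,
                })
                written["correlation_json"] = p
        except Exception as exc:
            raise type(exc)(f"[stage correlation] {exc}") from exc

    _write_json(out / "provenance.json", provenance)
    written["provenance_json"] = out / "provenance.json"
    return written
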