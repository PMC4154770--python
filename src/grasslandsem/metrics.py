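"""Plot-level community metrics from species-level records.

Arthropod occurrence records (plot, year, month, species, life stage,
count) are reduced to per-guild richness, adult abundance and estimated
biomass.  Only adults count; June and August catches are pooled within a
year; decomposers are dropped from the analysis outputs (their share is
logged so the <2%-of-individuals screen can be recomputed).  Per-individual
mass comes from the general arthropod length-mass power law

    mass_mg = a * L^b        (L: mean body length in mm)

with configurable constants defaulting to a=0.0305, b=2.62; plot totals are
reported in grams.  Vegetation surveys reduce to species richness, mean
subplot dry biomass (g/m^2) and the grass share of total cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GUILDS",
    "ANALYSIS_GUILDS",
    "Allometry",
    "SpeciesTrait",
    "OccurrenceRecord",
    "VegetationSurvey",
    "PlotYearMetrics",
    "species_biomass",
    "plot_guild_metrics",
    "plant_metrics",
    "metrics_table",
]

logger = logging.getLogger(__name__)

GUILDS = ("herbivore", "predator", "decomposer")
ANALYSIS_GUILDS = ("herbivore", "predator")
MG_PER_G = 1000.0


@dataclass(frozen=True)
class Allometry:
    """Length-mass power-law constants (mass in mg for length in mm)."""

    coefficient_a: float = 0.0305
    exponent_b: float = 2.62

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0 or self.exponent_b <= 0:
            raise ValueError("allometry constants must be positive")


@dataclass(frozen=True)
class SpeciesTrait:
    species: str
    guild: str
    mean_length_mm: float

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r} for {self.species}")
        if self.mean_length_mm <= 0:
            raise ValueError(f"non-positive length for {self.species}")


@dataclass(frozen=True)
class OccurrenceRecord:
    plot: str
    year: int
    month: str  # "June" | "August"
    species: str
    life_stage: str  # "adult" | "juvenile"
    count: int

    def __post_init__(self) -> None:
        if self.month not in ("June", "August"):
            raise ValueError(f"month must be June or August, got {self.month!r}")
        if self.life_stage not in ("adult", "juvenile"):
            raise ValueError(f"bad life stage {self.life_stage!r}")
        if self.count < 0:
            raise ValueError("negative count")


@dataclass(frozen=True)
class VegetationSurvey:
    plot: str
    year: int
    covers: tuple[tuple[str, str, float], ...]  # (species, functional group, cover %)
    subplot_biomasses: tuple[float, ...]  # g/m^2

    def __post_init__(self) -> None:
        if not self.subplot_biomasses:
            raise ValueError("need at least one subplot biomass")
        if any(c < 0 for _, _, c in self.covers):
            raise ValueError("negative cover")


@dataclass
class PlotYearMetrics:
    """Every observed endogenous variable for one plot-year."""

    plot: str
    year: int
    plant_richness: int = 0
    plant_biomass: float = 0.0  # g/m^2
    grass_cover_share: float | None = None
    guild_richness: dict[str, int] = field(default_factory=dict)
    guild_abundance: dict[str, int] = field(default_factory=dict)
    guild_biomass_g: dict[str, float] = field(default_factory=dict)
    decomposer_share: float = 0.0


def species_biomass(length_mm: float, allometry: Allometry = Allometry()) -> float:
    """Per-individual body mass in mg from the length-mass power law."""
    if length_mm <= 0:
        raise ValueError("length must be positive")
    return allometry.coefficient_a * length_mm ** allometry.exponent_b


def plot_guild_metrics(
    records: list[OccurrenceRecord],
    traits: dict[str, SpeciesTrait],
    allometry: Allometry = Allometry(),
) -> tuple[dict[str, int], dict[str, int], dict[str, float], float]:
    """Per-guild richness, adult abundance and biomass for one plot-year.

    Returns ``(richness, abundance, biomass_g, decomposer_share)`` with one
    entry per analysis guild.  Juveniles are filtered out before anything is
    counted, months are pooled, and a species contributes
    ``a L^b x pooled adult count`` to its guild's biomass.

    Raises ``KeyError`` listing every species missing from the trait table.
    """
    missing = sorted({r.species for r in records} - set(traits))
    if missing:
        raise KeyError(f"species without trait entry: {', '.join(missing)}")

    pooled: dict[str, int] = {}
    for r in records:
        if r.life_stage != "adult":
            continue
        pooled[r.species] = pooled.get(r.species, 0) + r.count

    richness = {g: 0 for g in ANALYSIS_GUILDS}
    abundance = {g: 0 for g in ANALYSIS_GUILDS}
    biomass_mg = {g: 0.0 for g in ANALYSIS_GUILDS}
    decomposer_n = 0
    total_n = 0
    for species, count in pooled.items():
        if count <= 0:
            continue
        guild = traits[species].guild
        total_n += count
        if guild == "decomposer":
            decomposer_n += count
            continue
        richness[guild] += 1
        abundance[guild] += count
        biomass_mg[guild] += species_biomass(traits[species].mean_length_mm, allometry) * count
    share = decomposer_n / total_n if total_n else 0.0
    return (
        richness,
        abundance,
        {g: biomass_mg[g] / MG_PER_G for g in ANALYSIS_GUILDS},
        share,
    )


def plant_metrics(survey: VegetationSurvey) -> tuple[int, float, float | None]:
    """(richness, mean subplot biomass g/m^2, grass share of total cover)."""
    richness = len({s for s, _, c in survey.covers if c > 0})
    biomass = sum(survey.subplot_biomasses) / len(survey.subplot_biomasses)
    total = sum(c for _, _, c in survey.covers)
    if total <= 0:
        logger.warning("plot %s year %s: zero total cover, grass share missing", survey.plot, survey.year)
        return richness, biomass, None
    grass = sum(c for _, g, c in survey.covers if g == "grass")
    return richness, biomass, grass / total


def metrics_table(
    occurrences: list[OccurrenceRecord],
    surveys: list[VegetationSurvey],
    traits: dict[str, SpeciesTrait],
    allometry: Allometry = Allometry(),
) -> pd.DataFrame:
    """Assemble the plot-year response table for model fitting.

    One row per plot-year that has a vegetation survey; arthropod metrics are
    zero where no records exist for a surveyed plot-year (complete-case
    handling of genuinely missing plots is by absence of the survey row).
    """
    by_plot_year: dict[tuple[str, int], list[OccurrenceRecord]] = {}
    for r in occurrences:
        by_plot_year.setdefault((r.plot, r.year), []).append(r)

    rows = []
    for survey in surveys:
        key = (survey.plot, survey.year)
        richness, biomass, grass_share = plant_metrics(survey)
        g_rich, g_abund, g_bio, dec_share = plot_guild_metrics(
            by_plot_year.get(key, []), traits, allometry
        )
        if dec_share > 0.02:
            logger.info("plot %s year %s: decomposer share %.1f%%", survey.plot, survey.year, 100 * dec_share)
        rows.append(
            {
                "plot": survey.plot,
                "year": survey.year,
                "plant_diversity": richness,
                "plant_biomass": biomass,
                "grass_cover_share": grass_share,
                "herbivore_diversity": g_rich["herbivore"],
                "herbivore_abundance": g_abund["herbivore"],
                "herbivore_biomass": g_bio["herbivore"],
                "predator_diversity": g_rich["predator"],
                "predator_abundance": g_abund["predator"],
                "predator_biomass": g_bio["predator"],
                "decomposer_share": dec_share,
            }
        )
    return pd.DataFrame(rows)
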