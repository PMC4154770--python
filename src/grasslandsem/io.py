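"""Configuration, tabular input readers and result-table round-tripping.

All inputs are UTF-8 comma-separated files with a mandatory header row and
ISO-8601 dates; a Unicode minus sign is normalized to the ASCII hyphen on
read.  Missing plots are represented by absent rows, never sentinels: each
model fit later uses the complete-case plot set of its region and year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from .landuse import (
    DEFAULT_LIVESTOCK_UNITS,
    FertilizerApplication,
    GrazingPeriod,
    MowingEvent,
)
from .metrics import Allometry, OccurrenceRecord, SpeciesTrait, VegetationSurvey

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "SchemaError",
    "load_config",
    "read_tables",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

#: Variables a transform may legally target.
KNOWN_VARIABLES = (
    "mowing",
    "fertilization",
    "grazing",
    "grazing_sq",
    "time_after_mowing",
    "plant_biomass",
    "plant_diversity",
    "herbivore_diversity",
    "herbivore_biomass",
    "herbivore_abundance",
    "predator_diversity",
    "predator_biomass",
    "predator_abundance",
)

LANDUSE_COLUMNS = [
    "plot", "region", "event_type", "start_date", "end_date",
    "amount", "livestock_count", "livestock_type", "area_ha",
]
ARTHROPOD_COLUMNS = ["plot", "region", "year", "month", "species", "life_stage", "count"]
VEGETATION_COLUMNS = ["plot", "region", "year", "species", "functional_group", "cover", "subplot_biomasses"]
TRAIT_COLUMNS = ["species", "guild", "mean_length_mm"]


class ConfigError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Run-wide settings with the study's default thresholds filled in."""

    regions: list[str] = field(default_factory=lambda: ["ALB", "HAI", "SCH"])
    years: list[int] = field(default_factory=lambda: [2008, 2009])
    model_variants: list[str] = field(default_factory=lambda: ["rh", "ra"])
    allometry: Allometry = field(default_factory=Allometry)
    transforms: dict[str, str] = field(default_factory=dict)
    alpha_fit: float = 0.05
    gof_floor: float = 0.75
    seed: int = 0
    livestock_units: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIVESTOCK_UNITS)
    )
    #: per-region vegetation-onset month-day, applied to each year
    vegetation_onset: dict[str, str] = field(
        default_factory=lambda: {"ALB": "04-01", "HAI": "04-01", "SCH": "04-01"}
    )
    #: the two sampling month-days of each year
    sampling_dates: tuple[str, str] = ("06-15", "08-15")

    def __post_init__(self) -> None:
        if not (0 < self.alpha_fit < 1):
            raise ConfigError("alpha_fit must lie in (0, 1)")
        if not (0 < self.gof_floor < 1):
            raise ConfigError("gof_floor must lie in (0, 1)")
        unknown = set(self.transforms) - set(KNOWN_VARIABLES)
        if unknown:
            raise ConfigError(f"transforms name unknown variables: {sorted(unknown)}")
        for tag in self.transforms.values():
            if tag not in ("identity", "log1p"):
                raise ConfigError(f"unknown transform {tag!r}")

    def onset_date(self, region: str, year: int) -> date:
        md = self.vegetation_onset.get(region, "04-01")
        m, d = md.split("-")
        return date(year, int(m), int(d))

    def sampling_dates_for(self, year: int) -> tuple[date, date]:
        out = []
        for md in self.sampling_dates:
            m, d = md.split("-")
            out.append(date(year, int(m), int(d)))
        return tuple(out)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Read a YAML/JSON config; omitted fields fall back to defaults."""
    if path is None:
        return AnalysisConfig()
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    kwargs: dict = {}
    for key in (
        "regions", "years", "model_variants", "transforms", "alpha_fit",
        "gof_floor", "seed", "livestock_units", "vegetation_onset",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "sampling_dates" in data:
        kwargs["sampling_dates"] = tuple(data["sampling_dates"])
    if "allometry" in data:
        a = data["allometry"]
        try:
            kwargs["allometry"] = Allometry(
                coefficient_a=float(a["coefficient_a"]),
                exponent_b=float(a["exponent_b"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad allometry block: {a!r}") from exc
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# tabular inputs

def _normalize_minus(df: pd.DataFrame) -> pd.DataFrame:
    return df.replace("−", "-", regex=True)


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return _normalize_minus(df)


def _parse_date(value: str, path: Path, line: int, *, strict: bool) -> date | None:
    try:
        return date.fromisoformat(value)
    except ValueError:
        msg = f"{path.name} line {line}: unparseable date {value!r}"
        if strict:
            raise SchemaError(msg) from None
        logger.warning("%s (row dropped)", msg)
        return None


def read_tables(
    directory: str | Path, config: AnalysisConfig, *, strict: bool = True
) -> tuple[
    dict[str, list],  # landuse events keyed by kind
    list[OccurrenceRecord],
    list[VegetationSurvey],
    dict[str, SpeciesTrait],
]:
    """Read and type the four input tables of a fixture/data directory.

    In strict mode a malformed row aborts with a row-numbered error; in
    lenient mode it is dropped with a logged warning.
    """
    directory = Path(directory)

    lu = _read_csv(directory / "landuse.csv", LANDUSE_COLUMNS)
    ferts: list[FertilizerApplication] = []
    grazes: list[GrazingPeriod] = []
    mows: list[MowingEvent] = []
    plot_region: dict[str, str] = {}
    for i, row in lu.iterrows():
        line = i + 2  # header is line 1
        plot_region[row["plot"]] = row["region"]
        start = _parse_date(row["start_date"], directory / "landuse.csv", line, strict=strict)
        if start is None:
            continue
        kind = row["event_type"]
        if kind == "fertilize":
            ferts.append(FertilizerApplication(row["plot"], start, float(row["amount"])))
        elif kind == "graze":
            end = _parse_date(row["end_date"], directory / "landuse.csv", line, strict=strict)
            if end is None:
                continue
            weight = config.livestock_units.get(row["livestock_type"], 1.0)
            grazes.append(
                GrazingPeriod(
                    row["plot"], start, end,
                    float(row["livestock_count"]), weight, float(row["area_ha"]),
                )
            )
        elif kind == "mow":
            mows.append(MowingEvent(row["plot"], start))
        else:
            msg = f"landuse.csv line {line}: unknown event_type {kind!r}"
            if strict:
                raise SchemaError(msg)
            logger.warning("%s (row dropped)", msg)

    arth = _read_csv(directory / "arthropods.csv", ARTHROPOD_COLUMNS)
    occurrences = [
        OccurrenceRecord(
            row["plot"], int(row["year"]), row["month"],
            row["species"], row["life_stage"], int(row["count"]),
        )
        for _, row in arth.iterrows()
    ]

    veg = _read_csv(directory / "vegetation.csv", VEGETATION_COLUMNS)
    surveys: list[VegetationSurvey] = []
    for (plot, year), group in veg.groupby(["plot", "year"], sort=True):
        covers = tuple(
            (r["species"], r["functional_group"], float(r["cover"]))
            for _, r in group.iterrows()
        )
        biomasses = tuple(
            float(x) for x in str(group.iloc[0]["subplot_biomasses"]).split(";") if x
        )
        surveys.append(VegetationSurvey(plot, int(year), covers, biomasses))

    tr = _read_csv(directory / "traits.csv", TRAIT_COLUMNS)
    traits = {
        row["species"]: SpeciesTrait(row["species"], row["guild"], float(row["mean_length_mm"]))
        for _, row in tr.iterrows()
    }

    for region in config.regions:
        n = sum(1 for r in plot_region.values() if r == region)
        logger.info("region %s: %d plots with land-use records", region, n)

    events = {"fertilize": ferts, "graze": grazes, "mow": mows, "plot_region": plot_region}
    return events, occurrences, surveys, traits


# ---------------------------------------------------------------------------
# result tables

RESULT_KEY = ["region", "year", "model", "source", "target"]


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a keyed result table; duplicate keys or non-finite values abort."""
    if table.duplicated(subset=[c for c in RESULT_KEY if c in table.columns]).any():
        raise ValueError("duplicate result keys")
    num = table.select_dtypes("number")
    if num.isna().any().any():
        raise ValueError("non-finite value in result table")
    table.to_csv(path, index=False, encoding="utf-8")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
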