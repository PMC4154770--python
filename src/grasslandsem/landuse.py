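"""Land-use intensity indices per plot and year.

Four variables summarize grassland management: fertilization intensity
(kg N ha^-1 yr^-1), grazing intensity (livestock-unit days ha^-1 yr^-1),
mowing frequency (cuts yr^-1) and the mean number of days between each
arthropod sampling date and the last preceding cut.  The first three are
averaged over a three-year window — the sampling year plus the two prior
years — because management acts with a lag; only mowing is truncated at the
sampling date in the final year, since later cuts cannot have affected the
sample.  A never-mown plot falls back to the days since the regional onset
of the vegetation period.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

__all__ = [
    "FertilizerApplication",
    "GrazingPeriod",
    "MowingEvent",
    "IntensityVector",
    "DEFAULT_LIVESTOCK_UNITS",
    "fertilization_intensity",
    "grazing_intensity",
    "mowing_frequency",
    "time_after_mowing",
]

#: Conventional livestock-unit weights per adult animal; overridable in config.
DEFAULT_LIVESTOCK_UNITS = {"cattle": 1.0, "sheep": 0.15, "horse": 1.0, "goat": 0.15}


@dataclass(frozen=True)
class FertilizerApplication:
    plot: str
    date: date
    nitrogen_amount: float  # kg N per hectare

    def __post_init__(self) -> None:
        if self.nitrogen_amount < 0:
            raise ValueError(f"negative nitrogen amount on plot {self.plot}")


@dataclass(frozen=True)
class GrazingPeriod:
    plot: str
    start: date
    end: date
    livestock_count: float
    livestock_unit_weight: float  # livestock units per animal
    area_ha: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"grazing period ends before it starts on plot {self.plot}")
        if self.livestock_count < 0:
            raise ValueError("negative livestock count")
        if self.area_ha <= 0:
            raise ValueError(f"grazing area must be positive on plot {self.plot}")

    @property
    def duration_days(self) -> int:
        # A one-day visit counts one day of grazing pressure.
        return (self.end - self.start).days + 1

    @property
    def lu_days_per_ha(self) -> float:
        return (
            self.livestock_count * self.livestock_unit_weight * self.duration_days / self.area_ha
        )


@dataclass(frozen=True)
class MowingEvent:
    plot: str
    date: date


@dataclass(frozen=True)
class IntensityVector:
    """The four land-use variables for one plot-year."""

    plot: str
    year: int
    fertilization: float  # kg N / ha / yr, 3-year mean
    grazing: float  # LU days / ha / yr, 3-year mean
    mowing: float  # cuts / yr, 3-year mean, sampling-year truncated
    time_after_mowing: float  # days, mean over the year's sampling dates

    def __post_init__(self) -> None:
        for name in ("fertilization", "grazing", "mowing", "time_after_mowing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _window(sampling_year: int) -> range:
    return range(sampling_year - 2, sampling_year + 1)


def fertilization_intensity(
    apps: list[FertilizerApplication], sampling_year: int
) -> float:
    """Mean yearly nitrogen input over the sampling year and two prior years."""
    years = _window(sampling_year)
    total = sum(a.nitrogen_amount for a in apps if a.date.year in years)
    return total / len(years)


def grazing_intensity(periods: list[GrazingPeriod], sampling_year: int) -> float:
    """Mean yearly livestock-unit days per hectare over the 3-year window.

    Additive over disjoint periods and linear in livestock numbers; a period
    is attributed to the year it starts in (periods in these data do not
    straddle year boundaries).
    """
    years = _window(sampling_year)
    total = sum(p.lu_days_per_ha for p in periods if p.start.year in years)
    return total / len(years)


def mowing_frequency(
    events: list[MowingEvent], sampling_year: int, sampling_date: date
) -> float:
    """Mean cuts per year; sampling-year cuts only up to the sampling date.

    The boundary is inclusive: a cut on the sampling date itself has already
    disturbed the sward the net sweeps through.
    """
    if sampling_date.year != sampling_year:
        raise ValueError("sampling_date must fall in the sampling year")
    years = _window(sampling_year)
    count = 0
    for e in events:
        if e.date.year not in years:
            continue
        if e.date.year == sampling_year and e.date > sampling_date:
            continue
        count += 1
    return count / len(years)


def time_after_mowing(
    events: list[MowingEvent],
    sampling_dates: tuple[date, date],
    vegetation_onset: date,
) -> float:
    """Mean days since the last cut before each sampling date.

    For each of the year's two sampling dates the most recent cut on or
    before that date is found; an unmown interval falls back to the regional
    vegetation onset, so the value is the time the sward has grown
    undisturbed.  Returns the mean over the two dates.
    """
    out = []
    for d in sampling_dates:
        if d < vegetation_onset:
            raise ValueError("sampling date precedes vegetation onset")
        prior = [e.date for e in events if e.date <= d and e.date >= vegetation_onset]
        ref = max(prior) if prior else vegetation_onset
        out.append((d - ref).days)
    return sum(out) / len(out)
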