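"""Age x period mortality rate tables (Lexis tables).

Everything upstream of the model lives here: reading long-format GBD-style
extracts or generic wide CSV matrices, summing annual records into
equal-width calendar periods, deriving birth cohorts along the
anti-diagonals of the Lexis grid, restricting age ranges, and two small
rate utilities (attributable proportions and direct age standardization).

Conventions
-----------
* Bands are closed integer ranges ``[start, start + width - 1]`` labelled
  ``"start-end"``; all internal arithmetic uses band midpoints in
  continuous years (22.5 for 20-24).
* A birth cohort's mid-year is ``period midpoint - age midpoint`` and its
  label is the band of the same width centred on that midpoint, so a death
  at 75-79 during 1990-1994 belongs to the 1913-1917 cohort.
* Death counts may be non-integer: burden-of-disease extracts are model
  estimates, not registrations, and are never rounded here.
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "PeriodBand",
    "CohortBand",
    "Stratum",
    "RateTable",
    "StandardPopulation",
    "load_gbd_csv",
    "read_wide_pair",
    "write_wide_pair",
    "aggregate_periods",
    "build_cohorts",
    "restrict_ages",
    "attributable_proportion",
    "direct_standardize",
    "parse_band_label",
]


class RateTableError(ValueError):
    """Base class for table construction and IO errors."""


class GBDFormatError(RateTableError):
    """A required column is missing from a long-format extract."""


class EmptySelectionError(RateTableError):
    """Filters matched zero rows."""


class AggregationError(RateTableError):
    """Annual records do not form complete periods."""


class AlignmentError(RateTableError):
    """A requested age range does not align with band boundaries."""


class CoverageError(RateTableError):
    """A standard population does not cover the table's age bands."""


@dataclass(frozen=True, order=True)
class Band:
    """A closed integer interval of calendar years or ages."""

    start: int
    width: int = 5

    def __post_init__(self) -> None:
        if self.width < 1:
            raise RateTableError(f"band width must be >= 1, got {self.width}")

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @property
    def midpoint(self) -> float:
        return self.start + (self.width - 1) / 2.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


class AgeBand(Band):
    def __post_init__(self) -> None:
        super().__post_init__()
        if self.start < 0:
            raise RateTableError(f"age band start must be >= 0, got {self.start}")


class PeriodBand(Band):
    pass


class CohortBand(Band):
    """Birth-cohort band; always derived from ages and periods, never free input."""


_BAND_RE = re.compile(r"^\s*(\d+)\s*(?:to|[-–—])\s*(\d+)\s*(?:years?)?\s*$")


def parse_band_label(label: str) -> tuple[int, int]:
    """Parse ``"20-24"``, ``"20 to 24"`` or en-dash variants into (start, width)."""
    m = _BAND_RE.match(str(label))
    if not m:
        raise RateTableError(f"cannot parse band label {label!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise RateTableError(f"band label {label!r} has end < start")
    return start, end - start + 1


@dataclass(frozen=True)
class Stratum:
    """One analysis stratum: location x sex x cause x attributed risk factor.

    ``risk_factor="all"`` means total cause mortality; any other value means
    mortality attributable to that risk factor.
    """

    location: str = "unspecified"
    sex: str = "both"
    cause: str = "unspecified"
    risk_factor: str = "all"
    source: str = ""

    def __post_init__(self) -> None:
        if self.sex.lower() not in {"male", "female", "both"}:
            raise RateTableError(f"sex must be male/female/both, got {self.sex!r}")

    @property
    def name(self) -> str:
        parts = [self.location, self.sex, self.cause]
        if self.risk_factor != "all":
            parts.append(self.risk_factor)
        return "_".join(p.replace(" ", "-") for p in parts)

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            "sex": self.sex,
            "cause": self.cause,
            "risk_factor": self.risk_factor,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Stratum":
        return cls(**{k: d[k] for k in ("location", "sex", "cause", "risk_factor", "source") if k in d})


def build_cohorts(
    ages: Sequence[AgeBand], periods: Sequence[PeriodBand]
) -> tuple[tuple[CohortBand, ...], np.ndarray]:
    """Derive birth cohorts for an age x period grid.

    Returns the ``A + P - 1`` cohort bands (earliest first) and an
    integer ``(A, P)`` array mapping each cell to its cohort index.
    Cells on the same anti-diagonal of the Lexis grid share a cohort.
    """
    ages = tuple(ages)
    periods = tuple(periods)
    widths = {b.width for b in ages} | {b.width for b in periods}
    if len(widths) != 1:
        raise RateTableError(
            "cohort construction requires equal-width age and period bands, "
            f"got widths {sorted(widths)}"
        )
    width = widths.pop()
    A, P = len(ages), len(periods)
    index = np.empty((A, P), dtype=int)
    for i in range(A):
        for j in range(P):
            index[i, j] = (A - 1 - i) + j
    cohorts = []
    half = (width - 1) / 2.0
    for k in range(A + P - 1):
        # any (i, j) with (A-1-i)+j == k gives the same midpoint; use one
        i = A - 1 - k if k <= A - 1 else 0
        j = k - (A - 1 - i)
        mid = periods[j].midpoint - ages[i].midpoint
        start = int(round(mid - half))
        cohorts.append(CohortBand(start, width))
    return tuple(cohorts), index


@dataclass
class RateTable:
    """An age x period grid of death counts and person-years for one stratum.

    Parameters
    ----------
    stratum : Stratum
    ages : sequence of AgeBand
        Contiguous, equal-width, youngest first (A entries).
    periods : sequence of PeriodBand
        Contiguous, same width as the age bands (P entries).
    deaths : (A, P) array of non-negative reals
    person_years : (A, P) array of positive reals
    """

    stratum: Stratum
    ages: tuple[AgeBand, ...]
    periods: tuple[PeriodBand, ...]
    deaths: np.ndarray
    person_years: np.ndarray
    cohorts: tuple[CohortBand, ...] = field(init=False, repr=False)
    cohort_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ages = tuple(self.ages)
        self.periods = tuple(self.periods)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        A, P = len(self.ages), len(self.periods)
        if A == 0 or P == 0:
            raise RateTableError("table needs at least one age band and one period")
        if self.deaths.shape != (A, P) or self.person_years.shape != (A, P):
            raise RateTableError(
                f"grid shapes {self.deaths.shape}/{self.person_years.shape} "
                f"do not match {A} ages x {P} periods"
            )
        for seq, kind in ((self.ages, "age"), (self.periods, "period")):
            w = seq[0].width
            for prev, nxt in zip(seq, seq[1:]):
                if nxt.width != w or nxt.start != prev.start + w:
                    raise RateTableError(f"{kind} bands must be contiguous and equal-width")
        if not np.all(np.isfinite(self.deaths)) or np.any(self.deaths < 0):
            raise RateTableError("deaths must be finite and non-negative")
        if not np.all(np.isfinite(self.person_years)) or np.any(self.person_years <= 0):
            raise RateTableError("person-years must be finite and positive")
        self.cohorts, self.cohort_index = build_cohorts(self.ages, self.periods)

    # -- basic accessors -------------------------------------------------
    @property
    def A(self) -> int:
        return len(self.ages)

    @property
    def P(self) -> int:
        return len(self.periods)

    @property
    def C(self) -> int:
        return len(self.cohorts)

    @property
    def width(self) -> int:
        return self.ages[0].width

    @property
    def rates(self) -> np.ndarray:
        """Crude death rates per person-year."""
        return self.deaths / self.person_years

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum.to_dict(),
            "ages": [[b.start, b.width] for b in self.ages],
            "periods": [[b.start, b.width] for b in self.periods],
            "deaths": self.deaths.tolist(),
            "person_years": self.person_years.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateTable":
        return cls(
            stratum=Stratum.from_dict(d["stratum"]),
            ages=tuple(AgeBand(s, w) for s, w in d["ages"]),
            periods=tuple(PeriodBand(s, w) for s, w in d["periods"]),
            deaths=np.asarray(d["deaths"], dtype=float),
            person_years=np.asarray(d["person_years"], dtype=float),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "RateTable":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))


def restrict_ages(table: RateTable, min_age: int, max_age: int) -> RateTable:
    """Keep only age bands inside ``[min_age, max_age]`` (boundary-aligned)."""
    starts = [b.start for b in table.ages]
    ends = [b.end for b in table.ages]
    if min_age not in starts or max_age not in ends:
        raise AlignmentError(
            f"range {min_age}-{max_age} does not align with band boundaries "
            f"({table.ages[0].label} .. {table.ages[-1].label}, width {table.width})"
        )
    keep = [i for i, b in enumerate(table.ages) if b.start >= min_age and b.end <= max_age]
    return RateTable(
        stratum=table.stratum,
        ages=tuple(table.ages[i] for i in keep),
        periods=table.periods,
        deaths=table.deaths[keep, :],
        person_years=table.person_years[keep, :],
    )


# ---------------------------------------------------------------------------
# Long-format (GBD results-tool style) ingestion
# ---------------------------------------------------------------------------

_REQUIRED_LONG = ("measure", "location", "sex", "age", "metric", "year", "val")


def _norm(s) -> str:
    return str(s).strip().casefold()


def load_gbd_csv(path, stratum: Stratum) -> pd.DataFrame:
    """Read a long-format results-tool CSV and return annual records.

    The file must carry at least the columns measure, location, sex, age,
    metric, year and val (any case).  Death rows are those whose measure is
    "Deaths" and metric "Number", filtered to the stratum's location, sex,
    cause and risk factor (column ``cause`` and ``rei``/``risk`` when
    present; ``risk_factor="all"`` keeps rows with no attributed risk).
    Population rows (measure "Population") are matched on location and sex
    only.  Upper/lower uncertainty bounds are carried along as metadata
    columns when present but are never used in fitting.

    Returns a DataFrame with columns
    ``age_start, age_width, year, deaths, person_years`` (one row per age
    band per calendar year).
    """
    df = pd.read_csv(path)
    cols = {_norm(c): c for c in df.columns}
    for req in _REQUIRED_LONG:
        if req not in cols:
            raise GBDFormatError(f"missing required column: {req!r}")
    get = lambda key: df[cols[key]]

    measure = get("measure").map(_norm)
    metric = get("metric").map(_norm)
    loc_ok = get("location").map(_norm) == _norm(stratum.location)
    sex_ok = get("sex").map(_norm) == _norm(stratum.sex)
    number = metric == "number"

    death_mask = (measure == "deaths") & number & loc_ok & sex_ok
    if "cause" in cols and stratum.cause != "unspecified":
        death_mask &= get("cause").map(_norm) == _norm(stratum.cause)
    risk_col = cols.get("rei") or cols.get("risk")
    if stratum.risk_factor != "all":
        if risk_col is None:
            raise GBDFormatError("missing required column: 'rei' (risk-factor filter requested)")
        death_mask &= df[risk_col].map(_norm) == _norm(stratum.risk_factor)
    elif risk_col is not None:
        blank = df[risk_col].isna() | df[risk_col].map(_norm).isin({"", "nan", "all", "all risk factors"})
        death_mask &= blank

    pop_mask = (measure == "population") & number & loc_ok & sex_ok

    deaths = df[death_mask]
    pop = df[pop_mask]
    if len(deaths) == 0:
        raise EmptySelectionError(f"no death rows match stratum {stratum.name!r}")
    if len(pop) == 0:
        raise EmptySelectionError(f"no population rows match stratum {stratum.name!r}")

    def _records(sub: pd.DataFrame, value_name: str) -> pd.DataFrame:
        parsed = [parse_band_label(a) for a in sub[cols["age"]]]
        out = pd.DataFrame(
            {
                "age_start": [p[0] for p in parsed],
                "age_width": [p[1] for p in parsed],
                "year": sub[cols["year"]].astype(int).to_numpy(),
                value_name: sub[cols["val"]].astype(float).to_numpy(),
            }
        )
        return out.groupby(["age_start", "age_width", "year"], as_index=False)[value_name].sum()

    rec = _records(deaths, "deaths").merge(
        _records(pop, "person_years"), on=["age_start", "age_width", "year"], how="inner"
    )
    if len(rec) == 0:
        raise EmptySelectionError("death and population rows share no age/year cells")
    return rec.sort_values(["age_start", "year"], ignore_index=True)


def aggregate_periods(
    records: pd.DataFrame, period_width: int = 5, stratum: Stratum | None = None
) -> RateTable:
    """Sum annual records into equal-width calendar periods.

    ``records`` is the output of :func:`load_gbd_csv` (or any frame with the
    same five columns).  Deaths and person-years are *summed* over the years
    within each period, so period person-years are total person-time at
    risk.  Years must form complete runs of ``period_width`` for every age
    band, starting at the earliest year present.
    """
    req = {"age_start", "age_width", "year", "deaths", "person_years"}
    missing = req - set(records.columns)
    if missing:
        raise GBDFormatError(f"records missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise EmptySelectionError("no records to aggregate")

    years = np.sort(records["year"].unique())
    y0 = int(years[0])
    n_periods = int(np.ceil((years[-1] - y0 + 1) / period_width))
    expected = set(range(y0, y0 + n_periods * period_width))
    gaps = sorted(expected - set(int(y) for y in years))
    if gaps:
        raise AggregationError(
            f"incomplete periods of width {period_width} starting {y0}: missing years {gaps}"
        )
    age_keys = sorted(set(zip(records["age_start"], records["age_width"])))
    per_age_years = records.groupby(["age_start", "age_width"])["year"].apply(set)
    for key in age_keys:
        gaps = sorted(expected - set(int(y) for y in per_age_years[key]))
        if gaps:
            raise AggregationError(f"age band starting {key[0]}: missing years {gaps}")

    rec = records.copy()
    rec["period_start"] = y0 + ((rec["year"] - y0) // period_width) * period_width
    grouped = rec.groupby(["age_start", "age_width", "period_start"], as_index=False)[
        ["deaths", "person_years"]
    ].sum()

    ages = tuple(AgeBand(s, w) for s, w in age_keys)
    period_starts = sorted(grouped["period_start"].unique())
    periods = tuple(PeriodBand(int(p), period_width) for p in period_starts)
    A, P = len(ages), len(periods)
    deaths = np.zeros((A, P))
    py = np.zeros((A, P))
    a_pos = {k: i for i, k in enumerate(age_keys)}
    p_pos = {p: j for j, p in enumerate(period_starts)}
    for _, row in grouped.iterrows():
        i = a_pos[(row["age_start"], row["age_width"])]
        j = p_pos[row["period_start"]]
        deaths[i, j] = row["deaths"]
        py[i, j] = row["person_years"]
    return RateTable(stratum or Stratum(), ages, periods, deaths, py)


# ---------------------------------------------------------------------------
# Wide CSV pair (deaths.csv / population.csv)
# ---------------------------------------------------------------------------

def read_wide_pair(deaths_path, population_path, stratum: Stratum | None = None) -> RateTable:
    """Read a generic wide matrix pair: first column age labels, remaining
    columns period labels, values deaths (or person-years)."""
    d = pd.read_csv(deaths_path, index_col=0)
    n = pd.read_csv(population_path, index_col=0)
    if list(d.index) != list(n.index) or list(d.columns) != list(n.columns):
        raise RateTableError("deaths and population matrices must share labels")
    ages = tuple(AgeBand(*parse_band_label(a)) for a in d.index)
    periods = tuple(PeriodBand(*parse_band_label(p)) for p in d.columns)
    return RateTable(stratum or Stratum(), ages, periods, d.to_numpy(float), n.to_numpy(float))


def write_wide_pair(table: RateTable, deaths_path, population_path) -> None:
    idx = [b.label for b in table.ages]
    cols = [b.label for b in table.periods]
    pd.DataFrame(table.deaths, index=idx, columns=cols).to_csv(deaths_path, index_label="age")
    pd.DataFrame(table.person_years, index=idx, columns=cols).to_csv(population_path, index_label="age")


# ---------------------------------------------------------------------------
# Small rate utilities
# ---------------------------------------------------------------------------

def attributable_proportion(attributable_deaths: float, total_deaths: float) -> float:
    """Percent of deaths attributable to a risk factor.

    Returns ``100 * attributable / total``.  Attributable counts exceeding
    the total raise a warning only: population-attributable fractions for
    overlapping risk factors can legitimately sum past 100%.
    """
    if total_deaths <= 0:
        raise RateTableError(f"total deaths must be positive, got {total_deaths}")
    if attributable_deaths < 0:
        raise RateTableError("attributable deaths must be non-negative")
    if attributable_deaths > total_deaths:
        warnings.warn(
            f"attributable deaths ({attributable_deaths}) exceed total ({total_deaths}); "
            "overlapping risk factors can do this",
            stacklevel=2,
        )
    return 100.0 * attributable_deaths / total_deaths


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights for direct standardization; normalized on creation."""

    ages: tuple[AgeBand, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.ages) != len(w):
            raise RateTableError("ages and weights must have equal length")
        if np.any(w < 0) or w.sum() <= 0:
            raise RateTableError("weights must be non-negative with positive sum")
        object.__setattr__(self, "ages", tuple(self.ages))
        object.__setattr__(self, "weights", tuple((w / w.sum()).tolist()))

    def weight_for(self, band: AgeBand) -> float:
        for b, w in zip(self.ages, self.weights):
            if b.start == band.start and b.width == band.width:
                return w
        raise CoverageError(f"standard population does not cover age band {band.label}")


def direct_standardize(age_rates: Mapping[AgeBand, float], std: StandardPopulation) -> float:
    """Directly age-standardized rate, per 100,000 person-years.

    ``age_rates`` maps age bands to rates per person-year.  The weights of
    ``std`` are renormalized over the supplied bands, which must all be
    covered by the standard.
    """
    if len(age_rates) == 0:
        raise CoverageError("no age-specific rates supplied")
    bands = list(age_rates)
    w = np.array([std.weight_for(b) for b in bands])
    if w.sum() <= 0:
        raise CoverageError("standard population has zero weight on the supplied bands")
    w = w / w.sum()
    r = np.array([age_rates[b] for b in bands], dtype=float)
    return float(np.dot(w, r) * 1e5)
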