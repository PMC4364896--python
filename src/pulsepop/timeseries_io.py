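"""Time-series containers and CSV I/O for the mast/mouse analysis.

Two container types cover everything the pipeline consumes:

* :class:`AnnualSeries` — a year-indexed scalar series (mean summer
  temperature in degC, or annual seedfall in seeds m^-2).
* :class:`QuarterlyAbundanceSeries` — a quarterly consumer-abundance
  index (captures per 100 trap-nights, C/100TN) on an annual cycle that
  starts in February.  Internally every observation time is a real-valued
  year with February = offset 0, so quarters map to offsets
  {Feb: 0.0, May: 0.25, Aug: 0.5, Nov: 0.75}.

Annual series must be gap-free (the seedfall driver of the consumer model
cannot have holes); quarterly series may be sparse (trapping sessions can
be missing, and the fit simply skips absent quarters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QUARTER_OFFSETS",
    "QUARTERS",
    "AnnualSeries",
    "QuarterlyAbundanceSeries",
    "read_annual",
    "write_annual",
    "read_quarterly",
    "write_quarterly",
    "compute_delta_t",
]

#: Quarter label -> fractional-year offset from the February year start.
QUARTER_OFFSETS: dict[str, float] = {"Feb": 0.0, "May": 0.25, "Aug": 0.5, "Nov": 0.75}
QUARTERS: tuple[str, ...] = tuple(QUARTER_OFFSETS)


class SeriesValidationError(ValueError):
    """Raised when a series violates its structural invariants."""


@dataclass(frozen=True)
class AnnualSeries:
    """A gap-free, year-indexed scalar series.

    Parameters
    ----------
    years
        Consecutive integer calendar years, strictly increasing.
    values
        One real value per year.  Units depend on the quantity held
        (degC for temperature, seeds m^-2 for seedfall).
    name
        Optional label used in file headers and error messages.
    """

    years: np.ndarray
    values: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if years.ndim != 1 or values.ndim != 1 or years.size != values.size:
            raise SeriesValidationError("years and values must be 1-D and equal length")
        if years.size == 0:
            raise SeriesValidationError("empty series")
        diffs = np.diff(years)
        if np.any(diffs <= 0):
            raise SeriesValidationError("duplicate or non-increasing years")
        if np.any(diffs != 1):
            raise SeriesValidationError("non-consecutive years (gaps are not allowed)")
        if not np.all(np.isfinite(values)):
            raise SeriesValidationError("non-finite values")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.years.size)

    def value_for(self, year: int) -> float:
        """Return the value for ``year`` (KeyError if outside the record)."""
        i = int(year) - int(self.years[0])
        if i < 0 or i >= len(self):
            raise KeyError(f"year {year} outside record {self.years[0]}-{self.years[-1]}")
        return float(self.values[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, self.name: self.values})


@dataclass(frozen=True)
class QuarterlyAbundanceSeries:
    """Quarterly abundance index records on a February-start annual cycle.

    ``times`` are fractional years (year + quarter offset); ``values`` are
    the non-negative abundance index in C/100TN.  At most one record per
    (year, quarter) is permitted and records are kept sorted in time.
    """

    years: np.ndarray
    quarters: np.ndarray  # str labels from QUARTERS
    values: np.ndarray
    name: str = field(default="abundance")

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        quarters = np.asarray(self.quarters, dtype=object)
        values = np.asarray(self.values, dtype=np.float64)
        if not (years.size == quarters.size == values.size):
            raise SeriesValidationError("years/quarters/values length mismatch")
        if years.size == 0:
            raise SeriesValidationError("empty series")
        for q in quarters:
            if q not in QUARTER_OFFSETS:
                raise SeriesValidationError(f"unknown quarter label {q!r}; expected one of {QUARTERS}")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise SeriesValidationError("abundance values must be finite and >= 0")
        offsets = np.array([QUARTER_OFFSETS[q] for q in quarters])
        times = years + offsets
        order = np.argsort(times, kind="stable")
        times = times[order]
        if np.unique(times).size != times.size:
            raise SeriesValidationError("duplicate (year, quarter) record")
        object.__setattr__(self, "years", years[order])
        object.__setattr__(self, "quarters", quarters[order])
        object.__setattr__(self, "values", values[order])

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def times(self) -> np.ndarray:
        """Fractional-year observation times (Feb of year y is y.0)."""
        offsets = np.array([QUARTER_OFFSETS[q] for q in self.quarters])
        return self.years + offsets

    def value_at(self, year: int, quarter: str) -> float:
        mask = (self.years == year) & (self.quarters == quarter)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise KeyError(f"no record for ({year}, {quarter})")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "quarter": self.quarters, self.name: self.values}
        )


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, header=0, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error surface varies
        raise SeriesValidationError(f"could not parse {path}: {exc}") from exc
    return df


def read_annual(path, year_col: str = "year", value_col: str | None = None) -> AnnualSeries:
    """Read an annual series from a two-column CSV with a header row.

    The first column is the year; ``value_col`` selects the value column
    (default: the second column, whatever its header says).
    """
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise SeriesValidationError(f"{path}: expected two columns (year, value)")
    if value_col is None:
        value_col = [c for c in df.columns if c != year_col][0]
    years = pd.to_numeric(df[year_col], errors="raise").to_numpy()
    if np.any(years != np.floor(years)):
        raise SeriesValidationError(f"{path}: non-integer year")
    values = pd.to_numeric(df[value_col], errors="raise").to_numpy(dtype=float)
    return AnnualSeries(years.astype(np.int64), values, name=str(value_col))


def write_annual(series: AnnualSeries, path) -> None:
    """Write an annual series as CSV (header ``year,<name>``).

    Values are formatted with :func:`repr`-faithful precision so that a
    write/read round-trip reproduces the series bit-exactly.
    """
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_quarterly(path, value_col: str | None = None) -> QuarterlyAbundanceSeries:
    """Read a quarterly abundance series from a (year, quarter, value) CSV."""
    df = _read_csv(path)
    if df.shape[1] < 3:
        raise SeriesValidationError(f"{path}: expected columns (year, quarter, value)")
    year_col, quarter_col = df.columns[0], df.columns[1]
    if value_col is None:
        value_col = df.columns[2]
    years = pd.to_numeric(df[year_col], errors="raise").to_numpy()
    values = pd.to_numeric(df[value_col], errors="raise").to_numpy(dtype=float)
    quarters = df[quarter_col].astype(str).str.strip().to_numpy(dtype=object)
    return QuarterlyAbundanceSeries(years.astype(np.int64), quarters, values, name=str(value_col))


def write_quarterly(series: QuarterlyAbundanceSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.17g")


def compute_delta_t(temps: AnnualSeries) -> AnnualSeries:
    """Two-summer temperature differential, indexed by the year it predicts.

    For seedfall year ``y`` the predictor is ``dT_y = T_{y-1} - T_{y-2}``:
    the change in mean summer temperature between the two summers preceding
    seed production.  The output therefore starts two years after the
    temperature record and has length ``len(temps) - 2``.
    """
    if len(temps) < 3:
        raise SeriesValidationError("temperature series too short for dT (need >= 3 years)")
    dt = temps.values[1:-1] - temps.values[:-2]
    return AnnualSeries(temps.years[2:], dt, name="delta_t")
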