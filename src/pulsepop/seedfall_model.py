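"""Seedfall prediction from summer temperature, and mast-year analysis.

Annual beech seedfall ``F_y`` (seeds m^-2) is predicted from mean summer
temperature by ordinary least squares on a log scale, under one of two
climate cues:

* T model:   log10(F_y + offset) = a + b * T_{y-1}
* dT model:  log10(F_y + offset) = a + b * (T_{y-1} - T_{y-2})

The additive ``log_offset`` (default 1 seed m^-2) keeps near-zero
seedfall years finite under the log transform; predictions subtract it
back and floor at 0.

Mast years are classified by the standardized deviate of annual seedfall

    AD_y = (F_y - mean(F)) / sd(F)        (sample SD, n-1)

with threshold ``AD_thres = min_y |AD_y|``; a year is a mast when
``AD_y > AD_thres`` (strict).  From the mast years the minimum prior
summer temperature (``T_thres``) and minimum temperature change
(``dT_thres``) give climate thresholds for mast prediction, which can be
applied to bias-adjusted climate-scenario temperature series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import acorr_ljungbox

from .timeseries_io import AnnualSeries, compute_delta_t

__all__ = [
    "RegressionResult",
    "MastRecord",
    "IntervalStats",
    "fit_seedfall_regression",
    "predict_seedfall",
    "classify_masts",
    "climate_thresholds",
    "mast_interval_stats",
    "adjust_scenario",
    "distribution_checks",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log10 seedfall on a temperature predictor."""

    intercept: float  # a, log10 seeds m^-2
    slope: float  # b, (log10 seeds m^-2) per degC
    r_squared: float
    p_value: float  # two-sided, for the slope
    residual_sd: float  # log10 seeds m^-2
    mode: str  # "T" or "dT"
    log_offset: float  # seeds m^-2 added before the log transform
    n: int


@dataclass(frozen=True)
class MastRecord:
    """Per-year standardized deviates and mast flags for a seedfall record."""

    years: np.ndarray
    ad: np.ndarray  # standardized deviates AD_y
    flags: np.ndarray  # boolean; AD_y > ad_thres
    ad_thres: float
    t_thres: float | None = None  # degC; filled by climate_thresholds
    dt_thres: float | None = None  # degC


@dataclass(frozen=True)
class IntervalStats:
    """Mast frequency summaries over a boolean per-year flag sequence.

    ``prop_single``: fraction of years flagged as masts.
    ``prop_double``: fraction of years that begin two consecutive masts.
    ``mean_gap``: mean difference between successive mast-year indices
    (1 means consecutive years); ``None`` with fewer than two events.
    """

    prop_single: float
    prop_double: float
    mean_gap: float | None
    n_years: int
    n_events: int


def _predictor(temps: AnnualSeries, years: np.ndarray, mode: str) -> np.ndarray:
    """Predictor value for each target year y: T_{y-1} or T_{y-1}-T_{y-2}."""
    if mode == "T":
        return np.array([temps.value_for(y - 1) for y in years])
    if mode == "dT":
        return np.array([temps.value_for(y - 1) - temps.value_for(y - 2) for y in years])
    raise ValueError(f"mode must be 'T' or 'dT', got {mode!r}")


def fit_seedfall_regression(
    temps: AnnualSeries,
    seedfall: AnnualSeries,
    mode: str = "dT",
    log_offset: float = 1.0,
) -> RegressionResult:
    """OLS of log10(F_y + offset) on the chosen temperature predictor.

    Only seedfall years whose required temperature lags fall inside the
    temperature record are used; at least 5 overlapping years are
    required.
    """
    lag = 1 if mode == "T" else 2
    usable = [
        y
        for y in seedfall.years
        if temps.years[0] + lag <= y <= temps.years[-1] + 1
    ]
    if len(usable) < 5:
        raise ValueError("insufficient overlap between temperature and seedfall records")
    years = np.array(usable)
    x = _predictor(temps, years, mode)
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    f = np.array([seedfall.value_for(y) for y in years])
    if np.any(f < 0):
        raise ValueError("seedfall must be >= 0")
    y_log = np.log10(f + log_offset)
    if np.ptp(y_log) == 0:
        # constant response: slope 0, no explained variance
        return RegressionResult(
            intercept=float(y_log[0]), slope=0.0, r_squared=0.0, p_value=1.0,
            residual_sd=0.0, mode=mode, log_offset=log_offset, n=len(years),
        )
    X = sm.add_constant(x)
    fit = sm.OLS(y_log, X).fit()
    return RegressionResult(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        residual_sd=float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        mode=mode,
        log_offset=log_offset,
        n=len(years),
    )


def predict_seedfall(reg: RegressionResult, temps: AnnualSeries) -> AnnualSeries:
    """Back-transformed point predictions F_y = max(0, 10^(a+b*x_y) - offset).

    Predicts every year for which the temperature record covers the
    required lags: from ``temps.years[0] + 1`` (T mode) or ``+ 2`` (dT
    mode) through the year after the record ends.
    """
    lag = 1 if reg.mode == "T" else 2
    years = np.arange(temps.years[0] + lag, temps.years[-1] + 2)
    if years.size == 0:
        raise ValueError("temperature record too short to predict any year")
    x = _predictor(temps, years, reg.mode)
    f = np.power(10.0, reg.intercept + reg.slope * x) - reg.log_offset
    return AnnualSeries(years, np.maximum(f, 0.0), name="seedfall")


def classify_masts(seedfall: AnnualSeries) -> MastRecord:
    """Flag mast years by standardized deviate above min |AD_y|.

    Uses the sample standard deviation (n-1).  AD values are invariant
    under affine rescaling of the seedfall record.  Ties exactly at the
    threshold are not masts.
    """
    if len(seedfall) < 3:
        raise ValueError("need >= 3 years to classify masts")
    f = seedfall.values
    sd = np.std(f, ddof=1)
    if sd == 0:
        raise ValueError("constant seedfall record: standardized deviates undefined")
    ad = (f - np.mean(f)) / sd
    ad_thres = float(np.min(np.abs(ad)))
    flags = ad > ad_thres
    return MastRecord(years=seedfall.years, ad=ad, flags=flags, ad_thres=ad_thres)


def climate_thresholds(mast: MastRecord, temps: AnnualSeries) -> tuple[float, float]:
    """(T_thres, dT_thres): minimum prior-summer T and dT over mast years.

    For each mast year ``y`` the relevant climate cue is the summer
    before seedfall: ``T_{y-1}`` and ``T_{y-1} - T_{y-2}``.  Returns the
    minima over all mast years, the weakest cue that still produced a
    mast.
    """
    mast_years = mast.years[mast.flags]
    if mast_years.size == 0:
        raise ValueError("no mast years in record")
    t_vals = np.array([temps.value_for(y - 1) for y in mast_years])
    dt_vals = np.array(
        [temps.value_for(y - 1) - temps.value_for(y - 2) for y in mast_years]
    )
    return float(t_vals.min()), float(dt_vals.min())


def mast_interval_stats(flags) -> IntervalStats:
    """Frequency statistics of mast events in a boolean per-year sequence."""
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n < 2:
        raise ValueError("need >= 2 years")
    idx = np.nonzero(flags)[0]
    prop_single = idx.size / n
    prop_double = int(np.sum(flags[:-1] & flags[1:])) / n
    mean_gap = float(np.mean(np.diff(idx))) if idx.size >= 2 else None
    return IntervalStats(
        prop_single=float(prop_single),
        prop_double=float(prop_double),
        mean_gap=mean_gap,
        n_years=int(n),
        n_events=int(idx.size),
    )


def adjust_scenario(scenario: AnnualSeries, reference: AnnualSeries) -> AnnualSeries:
    """Bias-adjust a climate-scenario series to a reference record.

    Applies the affine map ``x -> (x - m_s)/s_s * s_r + m_r`` where the
    moments are computed on the overlapping years only, then applied to
    the full scenario series.  After adjustment the scenario's overlap
    mean and SD equal the reference's.  Idempotent given the same
    reference.
    """
    common = np.intersect1d(scenario.years, reference.years)
    if common.size < 3:
        raise ValueError("need >= 3 overlapping years")
    s_vals = np.array([scenario.value_for(y) for y in common])
    r_vals = np.array([reference.value_for(y) for y in common])
    m_s, s_s = np.mean(s_vals), np.std(s_vals, ddof=1)
    m_r, s_r = np.mean(r_vals), np.std(r_vals, ddof=1)
    if s_s == 0:
        raise ValueError("zero scenario variance on overlap")
    adjusted = (scenario.values - m_s) / s_s * s_r + m_r
    return AnnualSeries(scenario.years, adjusted, name=scenario.name)


def distribution_checks(
    series: AnnualSeries, comparison: AnnualSeries | None = None, lags: int = 5
) -> dict:
    """Autocorrelation and distribution diagnostics for an annual series.

    Returns Ljung-Box p-values for lags 1..``lags`` and, when a
    comparison series is given, the two-sample Kolmogorov-Smirnov
    statistic and p-value against it.
    """
    if len(series) < 10:
        raise ValueError("series too short for diagnostics (need >= 10)")
    lb = acorr_ljungbox(series.values, lags=list(range(1, lags + 1)), return_df=True)
    report = {
        "ljung_box_p": lb["lb_pvalue"].to_numpy(),
        "ljung_box_stat": lb["lb_stat"].to_numpy(),
    }
    if comparison is not None:
        ks = scipy.stats.ks_2samp(series.values, comparison.values)
        report["ks_statistic"] = float(ks.statistic)
        report["ks_pvalue"] = float(ks.pvalue)
    return report
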