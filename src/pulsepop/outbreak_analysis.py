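"""Outbreak-prediction analysis on long-horizon model output.

A long (default 1000-year) temperature series drives the fitted
consumer-resource model; from the quarterly output two annual consumer
summaries are taken:

* the **spring peak** — the August (early-spring) abundance each year,
  when the population approaches its annual maximum after seedfall;
* the **winter increase** — the finite rate of increase from
  mid-February to mid-August, ``M_Aug / max(M_Feb, floor)``.

Each summary is regressed against two predictors — the two-summer
temperature change dT and log10 of the seedfall delivered in the
preceding autumn — with both a straight line and a 4-parameter logistic
curve

    y = A + (B - A) / (1 + exp(-s (x - x0)))

fitted by least squares.  AICc (with the error variance counted as a
parameter) decides whether the threshold-shaped logistic beats the line;
a large positive ``delta_aicc`` (linear minus logistic) is the signature
of a climate threshold for outbreaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .consumer_model import DEFAULT_DT, ConsumerParams, simulate
from .fitting import aicc
from .seedfall_model import RegressionResult, predict_seedfall
from .synthetic_data import gen_temperatures
from .timeseries_io import (
    AnnualSeries,
    QuarterlyAbundanceSeries,
    compute_delta_t,
)

__all__ = [
    "LogisticFit",
    "LinearFit",
    "PairingResult",
    "Step4Report",
    "spring_peak_series",
    "winter_increase_series",
    "fit_logistic",
    "fit_linear",
    "compare_logistic_linear",
    "correlation_triplet",
    "run_step4",
]


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares 4-parameter logistic fit."""

    A: float  # lower asymptote
    B: float  # upper asymptote
    x0: float  # midpoint, predictor units
    s: float  # slope, per predictor unit
    rss: float
    aicc: float
    pearson_r: float
    n: int

    def predict(self, x) -> np.ndarray:
        return _logistic(np.asarray(x, dtype=float), self.A, self.B, self.x0, self.s)


@dataclass(frozen=True)
class LinearFit:
    intercept: float
    slope: float
    rss: float
    aicc: float
    pearson_r: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PairingResult:
    response: str
    predictor: str
    delta_aicc: float  # linear AICc minus logistic AICc; > 0 favours logistic
    logistic: LogisticFit
    linear: LinearFit


@dataclass(frozen=True)
class Step4Report:
    pairings: tuple[PairingResult, ...]
    temps: AnnualSeries
    seedfall: AnnualSeries
    quarterly: QuarterlyAbundanceSeries
    seed: int

    @property
    def min_delta_aicc(self) -> float:
        return min(p.delta_aicc for p in self.pairings)


def spring_peak_series(q: QuarterlyAbundanceSeries) -> AnnualSeries:
    """Per-year August abundance; years with no August record are omitted."""
    mask = q.quarters == "Aug"
    if not np.any(mask):
        raise ValueError("no August records")
    years = q.years[mask]
    values = q.values[mask]
    if np.any(np.diff(years) != 1):
        # keep the longest gap-free run from the start; callers with sparse
        # records should slice beforehand
        keep = np.concatenate([[True], np.diff(years) == 1])
        stop = int(np.argmin(keep)) if not keep.all() else years.size
        years, values = years[:stop], values[:stop]
    return AnnualSeries(years, values, name="spring_peak")


def winter_increase_series(
    q: QuarterlyAbundanceSeries, floor: float = 0.1
) -> AnnualSeries:
    """Finite rate of increase Feb -> Aug per year: M_Aug / max(M_Feb, floor).

    The floor guards against zero February abundance in observed index
    data; years missing either record are omitted.
    """
    feb = {int(y): v for y, qq, v in zip(q.years, q.quarters, q.values) if qq == "Feb"}
    aug = {int(y): v for y, qq, v in zip(q.years, q.quarters, q.values) if qq == "Aug"}
    years = sorted(set(feb) & set(aug))
    if not years:
        raise ValueError("no years with both February and August records")
    vals = np.array([aug[y] / max(feb[y], floor) for y in years])
    return AnnualSeries(np.array(years), vals, name="winter_increase")


def _logistic(x, A, B, x0, s):
    # clip the exponent for numerical safety at extreme slopes
    z = np.clip(-s * (x - x0), -500.0, 500.0)
    return A + (B - A) / (1.0 + np.exp(z))


def fit_logistic(x, y, n_starts: int = 12, seed: int = 0) -> LogisticFit:
    """Least-squares 4-parameter logistic with seeded multi-start.

    Starts combine data-driven anchors (asymptotes at the y extremes,
    midpoints at x quantiles) with seeded jitter; each is polished by
    trust-region least squares and the lowest-RSS solution is returned.
    Degenerate (near-constant) responses yield B ~ A without error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 8:
        raise ValueError("need >= 8 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    rng = np.random.default_rng(seed)
    xr = np.ptp(x)
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    quantiles = np.quantile(x, [0.25, 0.5, 0.75])
    base_slopes = np.array([1.0, 4.0, 20.0, 100.0]) / xr

    def residuals(theta):
        return _logistic(x, *theta) - y

    best = None
    for i in range(n_starts):
        x0 = quantiles[i % 3]
        s0 = base_slopes[(i // 3) % 4]
        theta0 = np.array([y_lo, y_hi, x0, s0])
        if i >= 3 * 4:
            theta0 = theta0 * (1 + 0.2 * rng.standard_normal(4))
        try:
            res = scipy.optimize.least_squares(
                residuals, theta0, method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("logistic fit failed from all starts")
    A, B, x0, s = best.x
    # canonical orientation: positive slope, A = lower asymptote
    if s < 0:
        A, B, s = B, A, -s
    fitted = _logistic(x, A, B, x0, s)
    rss = float(np.sum((fitted - y) ** 2))
    r = _safe_pearson(fitted, y)
    return LogisticFit(
        A=float(A), B=float(B), x0=float(x0), s=float(s),
        rss=rss, aicc=_rss_aicc(rss, x.size, 4), pearson_r=r, n=x.size,
    )


def _rss_aicc(rss: float, n: int, k_params: int) -> float:
    rmse = np.sqrt(max(rss, 1e-300) / n)
    return aicc(rmse, n, k_params)


def _safe_pearson(a, b) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(a, b).statistic)


def fit_linear(x, y) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    rss = float(np.sum((fitted - y) ** 2))
    return LinearFit(
        intercept=float(intercept), slope=float(slope), rss=rss,
        aicc=_rss_aicc(rss, x.size, 2), pearson_r=_safe_pearson(fitted, y), n=x.size,
    )


def compare_logistic_linear(
    x, y, n_starts: int = 12, seed: int = 0
) -> tuple[float, LogisticFit, LinearFit]:
    """AICc difference (linear minus logistic) plus both fits.

    Positive values favour the logistic; by the AICc parameter penalty an
    exactly linear relationship gives a difference <= ~2.
    """
    logi = fit_logistic(x, y, n_starts=n_starts, seed=seed)
    line = fit_linear(x, y)
    return line.aicc - logi.aicc, logi, line


def correlation_triplet(model_x, model_y, data_x, data_y, seed: int = 0):
    """(r_mm, r_dd, r_dm) correlations between fitted curves and points.

    ``r_mm``: model points vs the logistic fitted to the model output;
    ``r_dd``: data points vs the logistic fitted to the data;
    ``r_dm``: data points vs the model's logistic evaluated at the data's
    predictor values (how well the model curve transfers to the data).
    """
    model_fit = fit_logistic(model_x, model_y, seed=seed)
    data_fit = fit_logistic(data_x, data_y, seed=seed)
    model_curve_at_data = model_fit.predict(data_x)
    if np.ptp(model_curve_at_data) == 0:
        raise ValueError("constant predictor: model curve is flat over the data range")
    r_mm = model_fit.pearson_r
    r_dd = data_fit.pearson_r
    r_dm = _safe_pearson(model_curve_at_data, np.asarray(data_y, dtype=float))
    return r_mm, r_dd, r_dm


def run_step4(
    params: ConsumerParams,
    reg: RegressionResult,
    horizon: int = 1000,
    temp_mean: float = 16.4,
    temp_sd: float = 0.7,
    seed: int = 0,
    m0: float = 1.0,
    dt: float = DEFAULT_DT,
    floor: float = 0.1,
) -> Step4Report:
    """Long-horizon simulation and threshold analysis, deterministic per seed.

    Draws ``horizon + 2`` i.i.d. normal summer temperatures (two extra
    years so every simulated year has its dT predictor), converts them to
    seedfall through the fitted regression, forward-simulates the
    consumer model, and fits logistic-vs-linear comparisons for the four
    pairings of {spring peak, winter increase} against {dT,
    log10 seedfall}.
    """
    if horizon < 100:
        raise ValueError("horizon must be >= 100 years")
    temps = gen_temperatures(horizon + 2, temp_mean, temp_sd, seed)
    seedfall = predict_seedfall(reg, temps)
    seedfall = AnnualSeries(
        seedfall.years[: horizon], seedfall.values[: horizon], name="seedfall"
    )
    sim = simulate(params, seedfall, m0=m0, dt=dt)
    q = sim.quarterly
    peak = spring_peak_series(q)
    incr = winter_increase_series(q, floor=floor)
    dtemp = compute_delta_t(temps)
    dt_map = {int(y): v for y, v in zip(dtemp.years, dtemp.values)}
    logf_map = {
        int(y): np.log10(v + reg.log_offset)
        for y, v in zip(seedfall.years, seedfall.values)
    }
    pairings = []
    for resp_name, resp in (("spring_peak", peak), ("winter_increase", incr)):
        for pred_name, pmap in (("delta_t", dt_map), ("log10_seedfall", logf_map)):
            years = [int(y) for y in resp.years if int(y) in pmap]
            x = np.array([pmap[y] for y in years])
            y_resp = np.array([resp.value_for(y) for y in years])
            delta, logi, line = compare_logistic_linear(x, y_resp, seed=seed)
            pairings.append(
                PairingResult(
                    response=resp_name, predictor=pred_name,
                    delta_aicc=delta, logistic=logi, linear=line,
                )
            )
    return Step4Report(
        pairings=tuple(pairings), temps=temps, seedfall=seedfall, quarterly=q, seed=seed
    )
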