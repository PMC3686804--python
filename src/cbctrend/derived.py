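"""Derived quantities: abundance indices, trends, cumulative change and
the abundance-weighted latitudinal centre of occurrence.

The abundance index for a region-year is the posterior predicted mean
count per circle at standardized conditions — mean survey effort
(f = 0), no boat, over-dispersion noise at its zero mean — averaged
over every circle of the region whether or not it was surveyed that
year, so missing surveys are imputed through the model.  Trends are the
geometric mean of proportional index changes between the first and last
modeled years, expressed as annual percent change, computed per
posterior draw so that credible intervals propagate all uncertainty.
The centre of occurrence is the count-weighted mean latitude of all
circles; its between-year difference, converted at 111.195 km per
degree of latitude, measures the range shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ExtrapolationError

#: Meridian arc length of one degree of latitude on the mean-radius sphere.
KM_PER_DEGREE_LAT = 111.195

CONTINENTAL = "continental"


@dataclass
class AbundanceIndex:
    """Effort-standardized predicted mean count per circle."""

    region: str
    year: int
    mean: float
    lower95: float
    upper95: float


@dataclass
class TrendEstimate:
    """Annual percent change with 95% credible interval."""

    region: str
    annual_percent: float
    lower95: float
    upper95: float
    significant: bool

    @classmethod
    def from_draws(cls, region: str, annual_pct: np.ndarray) -> "TrendEstimate":
        lo, hi = np.percentile(annual_pct, [2.5, 97.5])
        return cls(region, float(np.mean(annual_pct)), float(lo), float(hi),
                   significant=bool(lo > 0 or hi < 0))


@dataclass
class RangeCentre:
    """Abundance-weighted mean latitude of the surveyed circles."""

    year: int | None
    latitude_cm: float
    lower95: float | None = None
    upper95: float | None = None
    shift_partner_year: int | None = None
    shift_km: float | None = None


def geometric_mean_trend(series, region: str = "",
                         method: str = "endpoints") -> TrendEstimate:
    """Annualized percent change of a positive index series.

    ``series`` is either one index series (length T) or a matrix of
    per-draw series (draws, T).  The default estimator is the geometric
    mean of successive proportional changes, which depends only on the
    series endpoints: 100 * ((I_T / I_1)^(1/(T-1)) - 1).  The
    non-default ``method="regression"`` fits a least-squares line to
    the log index through all years instead.  With per-draw input the
    95% interval is the central interval of the per-draw rates and the
    trend is flagged significant when that interval excludes zero.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if arr.shape[1] < 2:
        raise ValueError("need at least two time points for a trend")
    if np.any(arr <= 0):
        raise ValueError("index series must be strictly positive")
    if method == "endpoints":
        rate = 100.0 * (np.power(arr[:, -1] / arr[:, 0],
                                 1.0 / (arr.shape[1] - 1)) - 1.0)
    elif method == "regression":
        t = np.arange(arr.shape[1], dtype=float)
        t -= t.mean()
        slope = np.log(arr) @ t / (t @ t)
        rate = 100.0 * np.expm1(slope)
    else:
        raise ValueError(f"unknown trend method {method!r}")
    return TrendEstimate.from_draws(region, rate)


def cumulative_change(annual_percent: float, n_intervals: int) -> float:
    """Total percent change after compounding an annual rate.

    ``cumulative_change(-2.07, 35)`` -> about -51.9 (a 52% decline over
    the 35 year-to-year intervals of a 36-year series).
    """
    if annual_percent <= -100:
        raise ValueError("annual percent change must exceed -100")
    return 100.0 * ((1.0 + annual_percent / 100.0) ** n_intervals - 1.0)


def centre_of_latitude(counts, latitudes, year: int | None = None) -> RangeCentre:
    """Count-weighted mean latitude: sum(m_i y_i) / sum(m_i)."""
    m = np.asarray(counts, dtype=float)
    y = np.asarray(latitudes, dtype=float)
    if m.shape != y.shape:
        raise ValueError("counts and latitudes must align")
    if np.any(m < 0):
        raise ValueError("counts must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("centre of latitude undefined for all-zero counts")
    return RangeCentre(year, float(np.dot(m, y) / total))


def latitudinal_shift_km(centre_a: float, centre_b: float) -> float:
    """Absolute north-south displacement between two latitudes, in km."""
    return abs(centre_a - centre_b) * KM_PER_DEGREE_LAT


# -- posterior-draw plumbing (operates on TrendResults) ------------------

def index_draws(results) -> np.ndarray:
    """Per-draw regional abundance index, shape (draws, regions, years).

    index_{r,t} = mean over circles i of region r of
    exp(beta0_r + beta1_r * tau_t + gamma_i + delta_t), i.e. predicted
    counts at mean effort, boat off, noise at zero, including circles
    with missing surveys.
    """
    d = results.draws
    beta0 = d.stacked("beta0")          # (S, R)
    beta1 = d.stacked("beta1")
    gamma = d.stacked("gamma")          # (S, I)
    delta = d.stacked("delta")          # (S, T)
    tau = results.model.tau_years       # (T,)
    reg = results.model.circle_region_idx
    R = results.model.n_regions
    n_per = np.bincount(reg, minlength=R).astype(float)
    eg = np.exp(gamma)
    mean_eg = np.stack([eg[:, reg == r].mean(axis=1) for r in range(R)],
                       axis=1)          # (S, R)
    core = np.exp(beta0[:, :, None] + beta1[:, :, None] * tau[None, None, :]
                  + delta[:, None, :])
    return core * mean_eg[:, :, None]


def continental_index_draws(results) -> np.ndarray:
    """Per-draw predicted mean count per circle over all circles, (S, T)."""
    idx = index_draws(results)
    reg = results.model.circle_region_idx
    w = np.bincount(reg, minlength=results.model.n_regions).astype(float)
    return np.tensordot(idx, w, axes=([1], [0])) / w.sum()


def abundance_index_table(results) -> pd.DataFrame:
    """Tidy index table (region, year, mean, lower95, upper95)."""
    idx = index_draws(results)
    lo, hi = np.percentile(idx, [2.5, 97.5], axis=0)
    mean = idx.mean(axis=0)
    rows = []
    for r, region in enumerate(results.model.regions):
        for t, year in enumerate(results.model.years):
            rows.append((region, int(year), mean[r, t], lo[r, t], hi[r, t]))
    cont = continental_index_draws(results)
    clo, chi = np.percentile(cont, [2.5, 97.5], axis=0)
    for t, year in enumerate(results.model.years):
        rows.append((CONTINENTAL, int(year), cont[:, t].mean(), clo[t], chi[t]))
    return pd.DataFrame(rows, columns=["region", "year", "mean",
                                       "lower95", "upper95"])


def abundance_index(results, region: str, year: int) -> AbundanceIndex:
    """Index of one region-year (posterior mean and central 95% interval)."""
    model = results.model
    if region != CONTINENTAL and region not in model.regions:
        raise ExtrapolationError(f"region {region!r} not in the fitted model")
    if not model.year_range[0] <= year <= model.year_range[1]:
        raise ExtrapolationError(
            f"year {year} outside fitted range {model.year_range}")
    t = int(year - model.years[0])
    if region == CONTINENTAL:
        draws = continental_index_draws(results)[:, t]
    else:
        draws = index_draws(results)[:, model.regions.index(region), t]
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return AbundanceIndex(region, year, float(draws.mean()), float(lo),
                          float(hi))


def trend_table(results) -> pd.DataFrame:
    """Geometric-mean annual trend per region plus the continental trend."""
    idx = index_draws(results)
    rows = []
    for r, region in enumerate(results.model.regions):
        est = geometric_mean_trend(idx[:, r, :], region)
        rows.append((region, est.annual_percent, est.lower95, est.upper95,
                     est.significant))
    est = geometric_mean_trend(continental_index_draws(results), CONTINENTAL)
    rows.append((CONTINENTAL, est.annual_percent, est.lower95, est.upper95,
                 est.significant))
    return pd.DataFrame(rows, columns=["region", "annual_percent",
                                       "lower95", "upper95", "significant"])


def circle_count_draws(results, year: int) -> np.ndarray:
    """Per-draw standardized predicted count of every circle, (S, I)."""
    model = results.model
    if not model.year_range[0] <= year <= model.year_range[1]:
        raise ExtrapolationError(
            f"year {year} outside fitted range {model.year_range}")
    t = int(year - model.years[0])
    d = results.draws
    beta0 = d.stacked("beta0")
    beta1 = d.stacked("beta1")
    gamma = d.stacked("gamma")
    delta_t = d.stacked("delta")[:, t]
    reg = model.circle_region_idx
    tau_t = float(model.tau_years[t])
    return np.exp(beta0[:, reg] + beta1[:, reg] * tau_t + gamma
                  + delta_t[:, None])


def range_centre(results, year: int) -> RangeCentre:
    """Posterior centre of occurrence for one year, with 95% interval."""
    counts = circle_count_draws(results, year)
    lats = results.model.circle_latitudes
    centres = counts @ lats / counts.sum(axis=1)
    lo, hi = np.percentile(centres, [2.5, 97.5])
    return RangeCentre(year, float(centres.mean()), float(lo), float(hi))


def range_shift(results, year_a: int, year_b: int) -> dict:
    """Centre-of-occurrence shift between two years (posterior summary)."""
    ca = range_centre(results, year_a)
    cb = range_centre(results, year_b)
    shift_deg = cb.latitude_cm - ca.latitude_cm
    return {"year_a": year_a, "year_b": year_b,
            "centre_a": ca.latitude_cm, "centre_b": cb.latitude_cm,
            "shift_degrees": shift_deg,
            "shift_km": latitudinal_shift_km(ca.latitude_cm, cb.latitude_cm),
            "direction": "north" if shift_deg > 0 else "south"}
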