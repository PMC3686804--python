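"""Hierarchical over-dispersed Poisson trend model for count surveys.

The observed count C_it on circle *i* (region *r(i)*) in year *t* is
Poisson with log-mean

    log mu_it = beta0_r + beta1_r * (t - t_mid) + beta2 * boat_it
                + gamma_i + delta_t + f(zeta_it) + eps_it

where gamma are circle effects, delta are year effects beyond trend
(shared across regions), eps is per-observation over-dispersion noise
and f is the nonlinear effort adjustment

    f(zeta) = B * ((zeta / zeta_m)^p - 1) / p,   p > 0,

with zeta_m the mean survey hours across the dataset; as p -> 0 the
adjustment tends to B * log(zeta / zeta_m).  A single (B, p) pair is
shared by all regions.  Missing surveys contribute nothing to the
likelihood; their counts are recovered later as derived statistics.

Priors: all fixed coefficients (region intercepts/trends via their
hyper-means when several regions are fitted, the boat coefficient, B)
are N(0, 10^3); variance components take inverse-gamma(0.001, 0.001)
priors; log p is N(0, 1.5^2) to keep the power bounded.  With a single
region the across-region hyperdistribution is unidentified and the
region coefficients take the flat N(0, 10^3) prior directly.

Fitting is by a vectorised adaptive Metropolis-within-Gibbs sampler
(:mod:`cbctrend.sampler`): conjugate Gibbs updates for every variance
and hyper-mean, elementwise random-walk Metropolis for each block of
random effects, run as two or more independent chains with Gelman-Rubin
and Monte-Carlo-error checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import SurveyDataset
from .errors import UnidentifiableModelError

_SMALL_P = 1e-4
COEF_VARIANCE = 1.0e3


def effort_effect(zeta, B, p, zeta_m):
    """Nonlinear influence of survey hours on the log expected count.

    ``B * ((zeta/zeta_m)^p - 1) / p``; continuous in p, with the p -> 0
    logarithmic limit ``B * log(zeta/zeta_m)`` evaluated by series
    expansion below ``p = 1e-4``.  ``zeta`` may be an array.

    Raises
    ------
    ValueError
        If any effort value or the standardisation point is not positive.
    """
    zeta = np.asarray(zeta, dtype=float)
    if np.any(zeta <= 0):
        raise ValueError("effort hours must be positive")
    if not zeta_m > 0:
        raise ValueError("zeta_m must be positive")
    if not p > 0:
        raise ValueError("effort exponent p must be positive")
    L = np.log(zeta / zeta_m)
    if p < _SMALL_P:
        # ((e^{pL} - 1)/p) = L + p L^2/2 + O(p^2)
        out = B * (L + 0.5 * p * L * L)
    else:
        out = B * np.expm1(np.minimum(p * L, 60.0)) / p
    return out if out.ndim else float(out)


@dataclass
class Hyperpriors:
    """Fixed prior constants, serialized with every fit for provenance."""

    coef_variance: float = COEF_VARIANCE       # N(0, 10^3) coefficients
    ig_shape: float = 0.001                    # inverse-gamma on variances
    ig_scale: float = 0.001
    log_p_sd: float = 1.5                      # N(0, sd^2) on log p

    def to_dict(self) -> dict:
        return {"coef_variance": self.coef_variance,
                "ig_shape": self.ig_shape, "ig_scale": self.ig_scale,
                "log_p_sd": self.log_p_sd}


@dataclass
class MCMCConfig:
    """Sampler settings: two chains and a long burn-in by default."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_samples: int = 5_000
    thinning: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least two chains for convergence checks")
        if self.burn_in < 0 or self.n_samples < 1 or self.thinning < 1:
            raise ValueError("invalid MCMC sizes")


@dataclass
class ModelParams:
    """One full parameter point of the count model."""

    beta0: np.ndarray           # (R,) region intercepts, log scale
    beta1: np.ndarray           # (R,) region trends, log scale per year
    beta2: float                # boat effect
    circle_effects: np.ndarray  # (I,)
    year_effects: np.ndarray    # (T,)
    noise: np.ndarray           # (n_obs,) aligned with the model's rows
    effort_B: float
    effort_p: float
    var_circle: float
    var_year: float
    var_noise: float
    hyper_mean_beta0: float = 0.0
    hyper_var_beta0: float = 1.0
    hyper_mean_beta1: float = 0.0
    hyper_var_beta1: float = 1.0

    def is_valid(self) -> bool:
        return (self.var_circle > 0 and self.var_year > 0
                and self.var_noise > 0 and self.effort_p > 0
                and self.hyper_var_beta0 > 0 and self.hyper_var_beta1 > 0)


class CircleCountModel:
    """Hierarchical Poisson trend model bound to one filtered dataset.

    Parameters
    ----------
    dataset : SurveyDataset
        Filtered, region-assigned survey data.  Species rows are summed
        per circle-year (total *Aechmophorus* count) before fitting.

    Build with the constructor or :meth:`from_dataframe`; call
    :meth:`fit` for a :class:`~cbctrend.results.TrendResults`.
    """

    def __init__(self, dataset: SurveyDataset):
        self.dataset = dataset
        obs = dataset.aggregate()
        if obs["region"].isna().any():
            raise UnidentifiableModelError(
                "all circles need a region assignment before fitting")
        if dataset.n_circles < 2 or obs["year"].nunique() < 2:
            raise UnidentifiableModelError(
                "model needs at least two circles and two survey years")

        self.regions = sorted(obs["region"].unique())
        self.circle_ids = dataset.circles["circle_id"].tolist()
        self.years = dataset.years
        self.t_mid = float(self.years.mean())
        circ = dataset.circles.set_index("circle_id")
        self.circle_region_idx = np.array(
            [self.regions.index(circ.loc[c, "region"]) for c in self.circle_ids])
        self.circle_latitudes = circ["latitude"].reindex(self.circle_ids).to_numpy()

        cidx = {c: k for k, c in enumerate(self.circle_ids)}
        yidx = {int(y): k for k, y in enumerate(self.years)}
        self.obs = obs
        self.y = obs["count"].to_numpy(dtype=np.int64)
        self.circle_idx = obs["circle_id"].map(cidx).to_numpy()
        self.year_idx = obs["year"].map(yidx).to_numpy()
        self.region_idx = self.circle_region_idx[self.circle_idx]
        self.tau = (obs["year"].to_numpy(dtype=float) - self.t_mid)
        self.boat = obs["boat_used"].to_numpy(dtype=float)
        self.effort = obs["effort_hours"].to_numpy(dtype=float)
        self.zeta_m = float(self.effort.mean())
        self.log_effort_ratio = np.log(self.effort / self.zeta_m)
        self.has_boat_variation = obs["boat_used"].nunique() > 1

        # Data-derived magnitude constants used by the sampler to set
        # curvature-matched proposal scales (never updated during a run).
        ybar_region = np.array([
            self.y[self.region_idx == r].mean() for r in range(self.n_regions)])
        self.log_count_region = np.log(ybar_region + 0.5)
        ybar_circle = np.array([
            self.y[self.circle_idx == i].mean() for i in range(self.n_circles)])
        self.log_count_circle_rel = (np.log(ybar_circle + 0.5)
                                     - self.log_count_region[self.circle_region_idx])

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, circles: pd.DataFrame,
                       year_range=None) -> "CircleCountModel":
        return cls(SurveyDataset(records, circles, year_range))

    # -- dimensions -----------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_circles(self) -> int:
        return len(self.circle_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def year_range(self) -> tuple:
        return self.dataset.year_range

    @property
    def tau_years(self) -> np.ndarray:
        return self.years - self.t_mid

    # -- likelihood pieces ----------------------------------------------
    def log_mu(self, params: ModelParams) -> np.ndarray:
        """Log expected count for every observed circle-year row."""
        f = effort_effect(self.effort, params.effort_B, params.effort_p,
                          self.zeta_m)
        return (params.beta0[self.region_idx]
                + params.beta1[self.region_idx] * self.tau
                + params.beta2 * self.boat
                + params.circle_effects[self.circle_idx]
                + params.year_effects[self.year_idx]
                + f + params.noise)

    def log_expected_count(self, params: ModelParams, row: int) -> float:
        """Log expected count of one observation row (bounds-checked)."""
        if not 0 <= row < self.n_obs:
            raise LookupError(f"observation row {row} out of range")
        return float(self.log_mu(params)[row])

    def log_posterior(self, params: ModelParams,
                      priors: Hyperpriors | None = None) -> float:
        """Joint log density of data and parameters (up to no constant).

        The density is taken with respect to log p for the effort
        exponent.  Parameter points violating the positivity invariants
        return ``-inf`` rather than raising, so samplers can reject them.
        """
        if priors is None:
            priors = Hyperpriors()
        if not params.is_valid():
            return -np.inf
        logmu = self.log_mu(params)
        mu = np.exp(np.minimum(logmu, 700.0))
        lp = float(np.sum(self.y * logmu - mu - gammaln(self.y + 1.0)))
        lp += _normal_logpdf_sum(params.circle_effects, 0.0, params.var_circle)
        lp += _normal_logpdf_sum(params.year_effects, 0.0, params.var_year)
        lp += _normal_logpdf_sum(params.noise, 0.0, params.var_noise)
        if self.n_regions > 1:
            lp += _normal_logpdf_sum(params.beta0, params.hyper_mean_beta0,
                                     params.hyper_var_beta0)
            lp += _normal_logpdf_sum(params.beta1, params.hyper_mean_beta1,
                                     params.hyper_var_beta1)
            lp += _normal_logpdf_sum(
                np.array([params.hyper_mean_beta0, params.hyper_mean_beta1]),
                0.0, priors.coef_variance)
            lp += _invgamma_logpdf(params.hyper_var_beta0, priors)
            lp += _invgamma_logpdf(params.hyper_var_beta1, priors)
        else:
            lp += _normal_logpdf_sum(params.beta0, 0.0, priors.coef_variance)
            lp += _normal_logpdf_sum(params.beta1, 0.0, priors.coef_variance)
        lp += _normal_logpdf_sum(np.array([params.beta2, params.effort_B]),
                                 0.0, priors.coef_variance)
        lp += _normal_logpdf_sum(np.array([np.log(params.effort_p)]), 0.0,
                                 priors.log_p_sd**2)
        for v in (params.var_circle, params.var_year, params.var_noise):
            lp += _invgamma_logpdf(v, priors)
        return lp

    # -- fitting ---------------------------------------------------------
    def fit(self, mcmc: MCMCConfig | None = None,
            priors: Hyperpriors | None = None, *, store_noise: bool = True,
            fix_effort: bool = False, progress: bool = False):
        """Run the MCMC sampler and return a :class:`TrendResults`.

        Parameters
        ----------
        mcmc : MCMCConfig
            Chain count, burn-in, draws, thinning and seed.
        priors : Hyperpriors
            Prior constants (defaults are the vague priors above).
        store_noise : bool
            Keep per-observation noise draws (needed for posterior
            predictive checks).
        fix_effort : bool
            Fix B = 0, switching the effort adjustment off.
        """
        from .results import TrendResults
        from .sampler import run_chains

        mcmc = mcmc or MCMCConfig()
        priors = priors or Hyperpriors()
        mcmc.validate()
        draws = run_chains(self, mcmc, priors, store_noise=store_noise,
                           fix_effort=fix_effort, progress=progress)
        return TrendResults(self, draws, mcmc, priors)


def _normal_logpdf_sum(x, mean, var) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * x.size * np.log(2.0 * np.pi * var)
                 - 0.5 * np.sum((x - mean) ** 2) / var)


def _invgamma_logpdf(v: float, priors: Hyperpriors) -> float:
    a, b = priors.ig_shape, priors.ig_scale
    return float(a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(v) - b / v)
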