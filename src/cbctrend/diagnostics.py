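"""Convergence diagnostics and posterior predictive checking.

Convergence follows the two-chain protocol: per-parameter potential
scale reduction (split R-hat) and the ratio of Monte Carlo error to
posterior standard deviation.  A fit is flagged non-converged when any
monitored parameter has R-hat > 1.1 or MC error/sd > 0.05.

The posterior predictive check draws a replicated dataset at every
retained iteration, compares it with the observed data through a
sums-of-squared-error discrepancy, and reports the Bayesian p-value:
the fraction of draws whose replicated discrepancy is at least the
observed one.  Values near 0.5 indicate a well-fitting model; values
near 0 or 1 indicate misfit.  The discrepancy defaults to squared
Pearson residuals (obs - mu)^2 / mu, the variance-scaled form standard
for Poisson checks; plain squared error is available via ``scaled``.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .errors import DiagnosticError

RHAT_THRESHOLD = 1.1
MC_ERROR_SD_THRESHOLD = 0.05


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor with chain halves (split R-hat).

    ``draws`` has shape (chains, iterations).  Each chain is split in
    half; with m half-chains of length n, R-hat is
    sqrt(((n-1)/n * W + B/n) / W) for within-variance W and
    between-variance B.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise DiagnosticError("expected draws with shape (chains, iterations)")
    n_chains, n_iter = draws.shape
    if n_chains < 2:
        raise DiagnosticError("R-hat needs at least two chains")
    if n_iter < 4:
        raise DiagnosticError("R-hat needs at least four draws per chain")
    half = n_iter // 2
    halves = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    n = half
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def mc_error_sd_ratio(draws: np.ndarray) -> float:
    """Monte Carlo standard error over posterior sd, i.e. 1/sqrt(ESS)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 1:
        raise DiagnosticError("expected draws with shape (chains, iterations)")
    if draws.std() == 0:
        return 0.0
    ess = float(az.ess(draws, method="bulk"))
    return 1.0 / np.sqrt(ess) if ess > 0 else np.inf


def convergence_diagnostics(draws, params=None) -> pd.DataFrame:
    """Per-parameter R-hat and MC error/sd table for monitored parameters.

    ``draws`` is a :class:`~cbctrend.results.PosteriorDraws`.  Vector
    parameters are expanded into one row per element.

    Raises
    ------
    DiagnosticError
        With fewer than two chains or fewer than ten draws per chain.
    """
    if draws.n_chains < 2:
        raise DiagnosticError("convergence diagnostics need at least 2 chains")
    if draws.n_draws < 10:
        raise DiagnosticError("convergence diagnostics need at least 10 draws")
    rows = []
    for name in (params or draws.monitored):
        arr = draws.get(name)
        labels = draws.element_labels(name)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        for j, lab in enumerate(labels):
            x = arr[:, :, j]
            rows.append((lab, split_rhat(x), mc_error_sd_ratio(x)))
    out = pd.DataFrame(rows, columns=["parameter", "rhat", "mc_error_sd"])
    return out


def is_converged(table: pd.DataFrame) -> bool:
    return bool((table["rhat"] <= RHAT_THRESHOLD).all()
                and (table["mc_error_sd"] <= MC_ERROR_SD_THRESHOLD).all())


# -- posterior predictive checking --------------------------------------

def replicate_counts(mu: np.ndarray, rng) -> np.ndarray:
    """One Poisson replicate of the observed cells at mean ``mu``.

    Missing surveys never appear here: ``mu`` covers observed cells only.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return rng.poisson(np.asarray(mu, dtype=float))


def discrepancy(observed, expected, scaled: bool = True) -> float:
    """Sums-of-squared-error discrepancy between counts and their means.

    ``scaled=True`` (default) uses squared Pearson residuals
    sum((obs - mu)^2 / mu); ``scaled=False`` uses plain sum((obs - mu)^2).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError(
            f"observed {observed.shape} and expected {expected.shape} differ")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    resid2 = (observed - expected) ** 2
    return float(np.sum(resid2 / expected) if scaled else np.sum(resid2))


@dataclass
class PosteriorPredictiveResult:
    """Per-draw discrepancy pairs and the Bayesian p-value."""

    d_obs: np.ndarray
    d_rep: np.ndarray
    bayesian_p: float
    scaled: bool = True

    def pairs(self) -> pd.DataFrame:
        """Scatter table for the 1:1-line visual check."""
        return pd.DataFrame({"draw": np.arange(len(self.d_obs)),
                             "d_obs": self.d_obs, "d_rep": self.d_rep})

    def save(self, path) -> None:
        df = self.pairs()
        df.to_csv(path, index=False)


def posterior_predictive(results, seed: int = 0, scaled: bool = True,
                         thin: int = 1) -> PosteriorPredictiveResult:
    """Run the replicate-data check over the retained posterior draws.

    For every (thinned) draw, the realised Poisson means mu (including
    the draw's noise terms) generate one replicated dataset; observed
    and replicated discrepancies are compared, counting ties toward the
    numerator of the Bayesian p-value.
    """
    rng = np.random.default_rng(seed)
    y = results.model.y
    mu = results.mu_draws(include_noise=True)[::thin]
    reps = rng.poisson(mu)
    d_obs = np.array([discrepancy(y, m, scaled) for m in mu])
    d_rep = np.array([discrepancy(r, m, scaled) for r, m in zip(reps, mu)])
    p = float(np.mean(d_rep >= d_obs))
    return PosteriorPredictiveResult(d_obs, d_rep, p, scaled)


def bayesian_p_value(results, seed: int = 0, scaled: bool = True,
                     thin: int = 1) -> float:
    return posterior_predictive(results, seed, scaled, thin).bayesian_p
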