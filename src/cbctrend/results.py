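"""Posterior draw container and the fitted-model results object."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import derived, diagnostics


@dataclass
class PosteriorDraws:
    """MCMC samples indexed by (chain, draw), with element labels.

    ``params`` maps a parameter name to an array of shape
    (chains, draws) for scalars or (chains, draws, k) for vectors;
    ``coords`` names the elements of the vector parameters.
    """

    params: dict
    monitored: list
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {v.shape[:2] for v in self.params.values()}
        if len(shapes) != 1:
            raise ValueError("unequal draw counts across parameters")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains concatenated: (chains*draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def element_labels(self, name: str) -> list:
        arr = self.params[name]
        if arr.ndim == 2:
            return [name]
        dim = {"beta0": "region", "beta1": "region", "gamma": "circle",
               "delta": "year"}.get(name)
        labels = self.coords.get(dim, range(arr.shape[2]))
        return [f"{name}[{lab}]" for lab in labels]

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` posterior group."""
        import arviz as az

        data = {k: v for k, v in self.params.items() if k != "noise"}
        dims = {"beta0": ["region"], "beta1": ["region"],
                "gamma": ["circle"], "delta": ["year"]}
        return az.from_dict(posterior=data,
                            dims={k: v for k, v in dims.items() if k in data},
                            coords=self.coords)

    def to_frame(self, include_noise: bool = False) -> pd.DataFrame:
        """Long-format table (parameter, chain, draw, value)."""
        frames = []
        for name, arr in self.params.items():
            if name == "noise" and not include_noise:
                continue
            labels = self.element_labels(name)
            a = arr if arr.ndim == 3 else arr[:, :, None]
            for j, lab in enumerate(labels if arr.ndim == 3
                                    else [name]):
                for c in range(a.shape[0]):
                    frames.append(pd.DataFrame({
                        "parameter": lab, "chain": c,
                        "draw": np.arange(a.shape[1]), "value": a[c, :, j]}))
        return pd.concat(frames, ignore_index=True)


class TrendResults:
    """Posterior results of a :class:`~cbctrend.model.CircleCountModel` fit.

    Carries the draws, convergence table and the derived-quantity
    surface: abundance indices, geometric-mean trends, posterior
    predictive checks and range-centre statistics.
    """

    def __init__(self, model, draws: PosteriorDraws, mcmc, priors):
        self.model = model
        self.draws = draws
        self.mcmc = mcmc
        self.priors = priors
        self._convergence = None

    # -- convergence -----------------------------------------------------
    @property
    def convergence(self) -> pd.DataFrame:
        if self._convergence is None:
            self._convergence = diagnostics.convergence_diagnostics(self.draws)
        return self._convergence

    @property
    def converged(self) -> bool:
        return diagnostics.is_converged(self.convergence)

    # -- posterior means -------------------------------------------------
    def mu_draws(self, include_noise: bool = True) -> np.ndarray:
        """Per-draw Poisson means of the observed cells, (S, n_obs)."""
        m, d = self.model, self.draws
        beta0 = d.stacked("beta0")[:, m.region_idx]
        beta1 = d.stacked("beta1")[:, m.region_idx]
        gamma = d.stacked("gamma")[:, m.circle_idx]
        delta = d.stacked("delta")[:, m.year_idx]
        B = d.stacked("effort_B")
        logp = d.stacked("log_effort_p")
        from .sampler import _effort_vector

        f = np.stack([_effort_vector(b, lp, m.log_effort_ratio)
                      for b, lp in zip(B, logp)])
        eta = (beta0 + beta1 * m.tau + d.stacked("beta2")[:, None] * m.boat
               + gamma + delta + f)
        if include_noise:
            eta = eta + d.stacked("noise")
        return np.exp(np.minimum(eta, 500.0))

    # -- derived quantities ----------------------------------------------
    def abundance_index(self, region: str | None = None,
                        year: int | None = None):
        """Full tidy index table, or one region-year when both are given."""
        if region is None and year is None:
            return derived.abundance_index_table(self)
        return derived.abundance_index(self, region, year)

    def trend(self, region: str = derived.CONTINENTAL) -> derived.TrendEstimate:
        table = derived.index_draws(self)
        if region == derived.CONTINENTAL:
            series = derived.continental_index_draws(self)
        else:
            series = table[:, self.model.regions.index(region), :]
        return derived.geometric_mean_trend(series, region)

    def trend_table(self) -> pd.DataFrame:
        return derived.trend_table(self)

    def range_centre(self, year: int) -> derived.RangeCentre:
        return derived.range_centre(self, year)

    def range_shift(self, year_a: int, year_b: int) -> dict:
        return derived.range_shift(self, year_a, year_b)

    def ppc(self, seed: int = 0, scaled: bool = True, thin: int = 1):
        return diagnostics.posterior_predictive(self, seed, scaled, thin)

    # -- reporting ---------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per monitored scalar."""
        rows = []
        for name in self.draws.monitored:
            arr = self.draws.get(name)
            a = arr if arr.ndim == 3 else arr[:, :, None]
            for j, lab in enumerate(self.draws.element_labels(name)):
                x = a[:, :, j].ravel()
                lo, hi = np.percentile(x, [2.5, 97.5])
                rows.append((lab, x.mean(), x.std(ddof=1), lo, hi))
        df = pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                         "lower95", "upper95"])
        conv = self.convergence.set_index("parameter")
        df["rhat"] = df["parameter"].map(conv["rhat"]).to_numpy()
        df["mc_error_sd"] = df["parameter"].map(conv["mc_error_sd"]).to_numpy()
        return df

    def summary(self) -> str:
        """Human-readable fit summary with trends in percent per year."""
        lines = ["Hierarchical count trend model"
                 f" — {self.model.n_regions} region(s),"
                 f" {self.model.n_circles} circles,"
                 f" {self.model.n_years} years,"
                 f" {self.model.n_obs} observed surveys",
                 f"chains: {self.draws.n_chains}, draws/chain: "
                 f"{self.draws.n_draws}, converged: {self.converged}", ""]
        tt = self.trend_table()
        lines.append("Annual trend (geometric mean, % per year):")
        for row in tt.itertuples(index=False):
            star = "*" if row.significant else " "
            lines.append(f"  {row.region:<32} {row.annual_percent:+7.2f} "
                         f"[{row.lower95:+7.2f}, {row.upper95:+7.2f}] {star}")
        lines.append("")
        lines.append("Parameters (posterior mean [95% CI]):")
        sf = self.summary_frame()
        for row in sf.itertuples(index=False):
            lines.append(f"  {row.parameter:<24} {row.mean:9.4f} "
                         f"[{row.lower95:9.4f}, {row.upper95:9.4f}]  "
                         f"rhat={row.rhat:6.3f}  mc/sd={row.mc_error_sd:5.3f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def manifest(self) -> dict:
        return {
            "mcmc": {"n_chains": self.mcmc.n_chains,
                     "burn_in": self.mcmc.burn_in,
                     "n_samples": self.mcmc.n_samples,
                     "thinning": self.mcmc.thinning,
                     "seed": self.mcmc.seed},
            "priors": self.priors.to_dict(),
            "regions": self.model.regions,
            "year_range": list(self.model.year_range),
            "n_circles": self.model.n_circles,
            "n_obs": self.model.n_obs,
            "zeta_m": self.model.zeta_m,
            "converged": bool(self.converged),
            "max_rhat": float(self.convergence["rhat"].max()),
            "max_mc_error_sd": float(self.convergence["mc_error_sd"].max()),
        }

    def save(self, draws_path, manifest_path=None,
             include_noise: bool = False) -> None:
        """Write draws as a long CSV and, optionally, a YAML run manifest."""
        self.draws.to_frame(include_noise=include_noise).to_csv(
            draws_path, index=False)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                yaml.safe_dump(self.manifest(), fh, sort_keys=False)
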