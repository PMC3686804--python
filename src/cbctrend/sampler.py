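"""Vectorised adaptive Metropolis-within-Gibbs sampler for the count model.

Update scheme per sweep (one sweep = one model-equivalent iteration):

* per-observation noise eps: elementwise random-walk Metropolis, all
  sites proposed and accepted independently in one vector operation
  (their full conditionals are mutually independent given the rest);
* circle effects, year effects, region intercepts and region trends:
  blockwise-independent random-walk Metropolis with per-group
  accept/reject, aggregated with ``bincount``;
* boat coefficient: scalar random-walk Metropolis (skipped and pinned
  to 0 when the boat flag never varies);
* effort parameters (B, log p): joint 2-d random-walk Metropolis;
* the three variance components and, with several regions, the
  hyper-means/variances of the region coefficients: conjugate Gibbs
  (normal / inverse-gamma).

Proposal scales adapt by Robbins-Monro during burn-in only (targets
0.44 for componentwise blocks, 0.25 for the 2-d effort block), leaving
a fixed, valid Markov kernel for the retained draws.  Each chain runs
on its own deterministic substream of the fit seed.
"""

from __future__ import annotations

import numpy as np

from .model import CircleCountModel, Hyperpriors, MCMCConfig, _SMALL_P

_TARGET_1D = 0.44
_TARGET_2D = 0.25
_ETA_CAP = 500.0  # exp() guard; proposals beyond this are effectively rejected


def _effort_vector(B: float, logp: float, L: np.ndarray) -> np.ndarray:
    p = np.exp(logp)
    if p < _SMALL_P:
        return B * (L + 0.5 * p * L * L)
    return B * np.expm1(np.minimum(p * L, 60.0)) / p


def _exp(eta: np.ndarray) -> np.ndarray:
    return np.exp(np.minimum(eta, _ETA_CAP))


class _ChainState:
    """Mutable parameter state of one chain."""

    def __init__(self, model: CircleCountModel, rng: np.random.Generator):
        R, I, T, n = (model.n_regions, model.n_circles, model.n_years,
                      model.n_obs)
        counts = np.maximum(model.y, 0.5)
        mean_by_region = np.array([
            counts[model.region_idx == r].mean() for r in range(R)])
        self.beta0 = np.log(mean_by_region) + 0.2 * rng.standard_normal(R)
        self.beta1 = 0.005 * rng.standard_normal(R)
        self.beta2 = 0.0
        self.gamma = 0.1 * rng.standard_normal(I)
        self.delta = 0.05 * rng.standard_normal(T)
        self.eps = 0.1 * rng.standard_normal(n)
        self.B = 0.1 * rng.standard_normal()
        self.logp = 0.2 * rng.standard_normal()
        self.s2c, self.s2y, self.s2n = 0.5, 0.05, 0.1
        self.mu0 = float(self.beta0.mean())
        self.s20 = 1.0
        self.mu1, self.s21 = 0.0, 0.01
        self.f = _effort_vector(self.B, self.logp, model.log_effort_ratio)

    def eta(self, model: CircleCountModel) -> np.ndarray:
        return (self.beta0[model.region_idx]
                + self.beta1[model.region_idx] * model.tau
                + self.beta2 * model.boat
                + self.gamma[model.circle_idx]
                + self.delta[model.year_idx]
                + self.f + self.eps)


def _mh_group(y, eta, idx, size, cur, scale, prior_mean, prior_prec, rng,
              mult=None, curv_w=None):
    """Random-walk MH on a block of conditionally independent group effects.

    ``curv_w`` gives per-observation curvature weights (a proxy for the
    Poisson information, independent of the block being updated so the
    proposal stays symmetric); per-group proposal scales are then
    ``scale / sqrt(prior_prec + curvature)``.
    """
    if curv_w is None:
        prop_sd = np.full(size, scale)
    else:
        curv = np.bincount(idx, weights=curv_w, minlength=size)
        prop_sd = scale / np.sqrt(prior_prec + curv)
    step = prop_sd * rng.standard_normal(size)
    d = step[idx] if mult is None else step[idx] * mult
    dll_obs = y * d - (_exp(eta + d) - _exp(eta))
    dll = np.bincount(idx, weights=dll_obs, minlength=size)
    prop = cur + step
    dll -= 0.5 * prior_prec * ((prop - prior_mean) ** 2 - (cur - prior_mean) ** 2)
    accept = np.log(rng.random(size)) < dll
    return np.where(accept, prop, cur), float(accept.mean())


def _invgamma_draw(rng, shape: float, scale: float) -> float:
    return max(scale / rng.gamma(shape), 1e-12)


def _sweep(model, st, priors, scales, rng, fix_effort):
    y, L = model.y, model.log_effort_ratio
    acc = {}

    # Noise eps: elementwise MH with per-site proposal scales matched to
    # the local conditional curvature 1/s2n + mu.  The curvature proxy
    # exp(eta - eps) excludes eps itself, keeping the proposal symmetric.
    eta = st.eta(model)
    sd_site = 1.0 / np.sqrt(1.0 / st.s2n + _exp(eta - st.eps))
    for _ in range(2):
        step = scales["eps"] * sd_site * rng.standard_normal(model.n_obs)
        dll = (y * step - (_exp(eta + step) - _exp(eta))
               - ((st.eps + step) ** 2 - st.eps ** 2) / (2.0 * st.s2n))
        ok = np.log(rng.random(model.n_obs)) < dll
        st.eps = np.where(ok, st.eps + step, st.eps)
        eta = eta + np.where(ok, step, 0.0)
        acc["eps"] = float(ok.mean())

    # circle effects
    eta = st.eta(model)
    curv = _exp(eta - st.gamma[model.circle_idx]
                + model.log_count_circle_rel[model.circle_idx])
    st.gamma, acc["gamma"] = _mh_group(
        y, eta, model.circle_idx, model.n_circles, st.gamma, scales["gamma"],
        0.0, 1.0 / st.s2c, rng, curv_w=curv)

    # year effects
    eta = st.eta(model)
    curv = _exp(eta - st.delta[model.year_idx])
    st.delta, acc["delta"] = _mh_group(
        y, eta, model.year_idx, model.n_years, st.delta, scales["delta"],
        0.0, 1.0 / st.s2y, rng, curv_w=curv)

    # region intercepts and trends
    if model.n_regions > 1:
        m0, v0 = st.mu0, st.s20
        m1, v1 = st.mu1, st.s21
    else:
        m0 = m1 = 0.0
        v0 = v1 = priors.coef_variance
    eta = st.eta(model)
    curv = _exp(eta - st.beta0[model.region_idx]
                + model.log_count_region[model.region_idx])
    st.beta0, acc["beta0"] = _mh_group(
        y, eta, model.region_idx, model.n_regions, st.beta0, scales["beta0"],
        m0, 1.0 / v0, rng, curv_w=curv)
    eta = st.eta(model)
    curv = (_exp(eta - st.beta1[model.region_idx] * model.tau
                 + model.log_count_region[model.region_idx] - st.beta0[model.region_idx])
            * model.tau ** 2)
    st.beta1, acc["beta1"] = _mh_group(
        y, eta, model.region_idx, model.n_regions, st.beta1, scales["beta1"],
        m1, 1.0 / v1, rng, mult=model.tau, curv_w=curv)

    # Boat coefficient, proposed jointly with a compensating per-region
    # intercept shift (same ridge-move construction as the effort block).
    if model.has_boat_variation:
        if model.n_regions > 1:
            m0e, v0e = st.mu0, st.s20
        else:
            m0e, v0e = 0.0, priors.coef_variance
        n_per_reg = np.bincount(model.region_idx, minlength=model.n_regions)
        mean_boat = (np.bincount(model.region_idx, weights=model.boat,
                                 minlength=model.n_regions) / n_per_reg)
        eta = st.eta(model)
        step = scales["beta2"] * rng.standard_normal()
        shift = -step * mean_boat
        d = step * model.boat + shift[model.region_idx]
        dll = float(np.sum(y * d - (_exp(eta + d) - _exp(eta))))
        prop = st.beta2 + step
        dll -= 0.5 * (prop ** 2 - st.beta2 ** 2) / priors.coef_variance
        b0p = st.beta0 + shift
        dll -= float(np.sum((b0p - m0e) ** 2 - (st.beta0 - m0e) ** 2)
                     / (2.0 * v0e))
        ok = np.log(rng.random()) < dll
        if ok:
            st.beta2 = prop
            st.beta0 = b0p
        acc["beta2"] = float(ok)

    # Rescaling moves: multiply a whole random-effect field by c to let
    # it trade scale with its variance component (log-normal proposal on
    # c; the c^n Jacobian enters as n log c).
    for name, field_attr, idx, s2_attr in (
            ("scale_eps", "eps", None, "s2n"),
            ("scale_gamma", "gamma", model.circle_idx, "s2c"),
            ("scale_delta", "delta", model.year_idx, "s2y")):
        x = getattr(st, field_attr)
        c = np.exp(scales[name] * rng.standard_normal())
        d = (c - 1.0) * (x if idx is None else x[idx])
        eta = st.eta(model)
        dll = float(np.sum(y * d - (_exp(eta + d) - _exp(eta))))
        s2 = getattr(st, s2_attr)
        dll += (-(c * c - 1.0) * float(np.sum(x * x)) / (2.0 * s2)
                + x.size * np.log(c))
        if np.log(rng.random()) < dll:
            setattr(st, field_attr, c * x)
            acc[name] = 1.0
        else:
            acc[name] = 0.0

    # Effort parameters (B, log p): joint proposal that also shifts each
    # region intercept by the negative per-region mean change in f, so
    # the move travels along the intercept/effort ridge (symmetric
    # proposal with unit Jacobian; only priors and the residual
    # likelihood change enter the ratio).
    if not fix_effort:
        if model.n_regions > 1:
            m0e, v0e = st.mu0, st.s20
        else:
            m0e, v0e = 0.0, priors.coef_variance
        n_per_reg = np.bincount(model.region_idx, minlength=model.n_regions)
        chol = scales.get("eff_chol")
        eff_acc = 0.0
        for _ in range(3):
            eta = st.eta(model)
            z = rng.standard_normal(2)
            if chol is not None:
                step = scales["eff_mult"] * (chol @ z)
            else:
                step = np.array([scales["B"] * z[0], scales["logp"] * z[1]])
            Bp = st.B + step[0]
            lpp = st.logp + step[1]
            f_new = _effort_vector(Bp, lpp, L)
            df = f_new - st.f
            mshift = (np.bincount(model.region_idx, weights=df,
                                  minlength=model.n_regions) / n_per_reg)
            d = df - mshift[model.region_idx]
            dll = float(np.sum(y * d - (_exp(eta + d) - _exp(eta))))
            dll -= 0.5 * (Bp ** 2 - st.B ** 2) / priors.coef_variance
            dll -= 0.5 * (lpp ** 2 - st.logp ** 2) / priors.log_p_sd ** 2
            b0p = st.beta0 - mshift
            dll -= float(np.sum((b0p - m0e) ** 2 - (st.beta0 - m0e) ** 2)
                         / (2.0 * v0e))
            if np.log(rng.random()) < dll:
                st.B, st.logp, st.f = Bp, lpp, f_new
                st.beta0 = b0p
                eff_acc += 1.0
        acc["effort"] = eff_acc / 3.0

        # Transport move along the curved (B, p) ridge: random-walk log p
        # while rescaling B to keep the effort effect at one sd of log
        # effort fixed; the deterministic B map contributes a Jacobian
        # |dB'/dB| = h(p)/h(p').
        l0 = max(float(np.std(L)), 1e-3)

        def _h(logp_val):
            pv = np.exp(logp_val)
            return np.expm1(min(pv * l0, 60.0)) / pv if pv >= _SMALL_P \
                else l0 * (1.0 + 0.5 * pv * l0)

        curve_acc = 0.0
        for _ in range(3):
            eta = st.eta(model)
            lpp = st.logp + scales["curve"] * rng.standard_normal()
            hp, hpp = _h(st.logp), _h(lpp)
            Bp = st.B * hp / hpp
            f_new = _effort_vector(Bp, lpp, L)
            df = f_new - st.f
            mshift = (np.bincount(model.region_idx, weights=df,
                                  minlength=model.n_regions) / n_per_reg)
            d = df - mshift[model.region_idx]
            dll = float(np.sum(y * d - (_exp(eta + d) - _exp(eta))))
            dll += np.log(hp) - np.log(hpp)
            dll -= 0.5 * (Bp ** 2 - st.B ** 2) / priors.coef_variance
            dll -= 0.5 * (lpp ** 2 - st.logp ** 2) / priors.log_p_sd ** 2
            b0p = st.beta0 - mshift
            dll -= float(np.sum((b0p - m0e) ** 2 - (st.beta0 - m0e) ** 2)
                         / (2.0 * v0e))
            if np.log(rng.random()) < dll:
                st.B, st.logp, st.f = Bp, lpp, f_new
                st.beta0 = b0p
                curve_acc += 1.0
        acc["curve"] = curve_acc / 3.0

    # Likelihood-invariant translation moves along the ridges that
    # confound fixed and random effects: (a) region intercept vs its
    # circle effects, (b) all intercepts vs the year-effect mean,
    # (c) all trends vs a linear drift in the year effects.  Each move
    # leaves eta unchanged, so only prior terms enter the ratio.
    R = model.n_regions
    reg_of_circle = model.circle_region_idx
    n_per_region = np.bincount(reg_of_circle, minlength=R)
    tau_y = model.tau_years
    if model.n_regions > 1:
        m0, v0 = st.mu0, st.s20
        m1, v1 = st.mu1, st.s21
    else:
        m0 = m1 = 0.0
        v0 = v1 = priors.coef_variance

    shift = scales["shift_g"] * rng.standard_normal(R)
    sum_g = np.bincount(reg_of_circle, weights=st.gamma, minlength=R)
    dll = (-(2.0 * shift * (st.beta0 - m0) + shift ** 2) / (2.0 * v0)
           + (2.0 * shift * sum_g - n_per_region * shift ** 2) / (2.0 * st.s2c))
    ok = np.log(rng.random(R)) < dll
    st.beta0 = np.where(ok, st.beta0 + shift, st.beta0)
    st.gamma = st.gamma - (shift * ok)[reg_of_circle]
    acc["shift_g"] = float(ok.mean())

    a_sh = scales["shift_d0"] * rng.standard_normal()
    dll = (-np.sum(2.0 * a_sh * (st.beta0 - m0) + a_sh ** 2) / (2.0 * v0)
           + (2.0 * a_sh * st.delta.sum() - model.n_years * a_sh ** 2)
           / (2.0 * st.s2y))
    if np.log(rng.random()) < dll:
        st.beta0 = st.beta0 + a_sh
        st.delta = st.delta - a_sh
        acc["shift_d0"] = 1.0
    else:
        acc["shift_d0"] = 0.0

    b_sh = scales["shift_d1"] * rng.standard_normal()
    dll = (-np.sum(2.0 * b_sh * (st.beta1 - m1) + b_sh ** 2) / (2.0 * v1)
           + (2.0 * b_sh * float(st.delta @ tau_y)
              - b_sh ** 2 * float(tau_y @ tau_y)) / (2.0 * st.s2y))
    if np.log(rng.random()) < dll:
        st.beta1 = st.beta1 + b_sh
        st.delta = st.delta - b_sh * tau_y
        acc["shift_d1"] = 1.0
    else:
        acc["shift_d1"] = 0.0

    # Noise-absorbing translation moves: shift a coefficient (or field)
    # and subtract the induced change in eta from the noise field, so
    # the likelihood is untouched and only Gaussian priors enter the
    # ratio.  These let the tightly likelihood-pinned coefficients
    # explore their marginal posteriors at the noise-field scale.
    tobs, cobs, robs = model.year_idx, model.circle_idx, model.region_idx
    s2n = st.s2n

    # (i) year effects vs noise, independent across years
    step = scales["t_delta"] * rng.standard_normal(model.n_years)
    sum_eps = np.bincount(tobs, weights=st.eps, minlength=model.n_years)
    n_t = np.bincount(tobs, minlength=model.n_years)
    dll = (2.0 * step * sum_eps - step ** 2 * n_t) / (2.0 * s2n)
    dll -= ((st.delta + step) ** 2 - st.delta ** 2) / (2.0 * st.s2y)
    ok = np.log(rng.random(model.n_years)) < dll
    st.delta = np.where(ok, st.delta + step, st.delta)
    st.eps = st.eps - (step * ok)[tobs]
    acc["t_delta"] = float(ok.mean())

    # (i-b) circle effects vs noise, independent across circles
    step = scales["t_gamma"] * rng.standard_normal(model.n_circles)
    sum_eps = np.bincount(cobs, weights=st.eps, minlength=model.n_circles)
    n_c = np.bincount(cobs, minlength=model.n_circles)
    dll = (2.0 * step * sum_eps - step ** 2 * n_c) / (2.0 * s2n)
    dll -= ((st.gamma + step) ** 2 - st.gamma ** 2) / (2.0 * st.s2c)
    ok = np.log(rng.random(model.n_circles)) < dll
    st.gamma = np.where(ok, st.gamma + step, st.gamma)
    st.eps = st.eps - (step * ok)[cobs]
    acc["t_gamma"] = float(ok.mean())

    # (ii) region intercepts vs noise
    step = scales["t_beta0"] * rng.standard_normal(R)
    sum_eps = np.bincount(robs, weights=st.eps, minlength=R)
    n_r = np.bincount(robs, minlength=R)
    dll = (2.0 * step * sum_eps - step ** 2 * n_r) / (2.0 * s2n)
    dll -= ((st.beta0 + step - m0) ** 2 - (st.beta0 - m0) ** 2) / (2.0 * v0)
    ok = np.log(rng.random(R)) < dll
    st.beta0 = np.where(ok, st.beta0 + step, st.beta0)
    st.eps = st.eps - (step * ok)[robs]
    acc["t_beta0"] = float(ok.mean())

    # (iii) region trends vs noise
    step = scales["t_beta1"] * rng.standard_normal(R)
    sum_eps_tau = np.bincount(robs, weights=st.eps * model.tau, minlength=R)
    sum_tau2 = np.bincount(robs, weights=model.tau ** 2, minlength=R)
    dll = (2.0 * step * sum_eps_tau - step ** 2 * sum_tau2) / (2.0 * s2n)
    dll -= ((st.beta1 + step - m1) ** 2 - (st.beta1 - m1) ** 2) / (2.0 * v1)
    ok = np.log(rng.random(R)) < dll
    st.beta1 = np.where(ok, st.beta1 + step, st.beta1)
    st.eps = st.eps - ((step * ok)[robs]) * model.tau
    acc["t_beta1"] = float(ok.mean())

    # (iv) boat coefficient vs noise
    if model.has_boat_variation:
        step = scales["t_beta2"] * rng.standard_normal()
        d = step * model.boat
        dll = float((2.0 * step * np.sum(st.eps * model.boat)
                     - step ** 2 * np.sum(model.boat ** 2)) / (2.0 * s2n))
        dll -= 0.5 * ((st.beta2 + step) ** 2 - st.beta2 ** 2) / priors.coef_variance
        if np.log(rng.random()) < dll:
            st.beta2 = st.beta2 + step
            st.eps = st.eps - d
            acc["t_beta2"] = 1.0
        else:
            acc["t_beta2"] = 0.0

    # (v) effort parameters vs noise
    if not fix_effort:
        chol = scales.get("eff_chol")
        t_acc = 0.0
        for _ in range(2):
            z = rng.standard_normal(2)
            if chol is not None:
                step = scales["t_eff"] * (chol @ z)
            else:
                step = scales["t_eff"] * 0.1 * z
            Bp, lpp = st.B + step[0], st.logp + step[1]
            df = _effort_vector(Bp, lpp, L) - st.f
            dll = float((2.0 * np.sum(st.eps * df) - np.sum(df ** 2))
                        / (2.0 * s2n))
            dll -= 0.5 * (Bp ** 2 - st.B ** 2) / priors.coef_variance
            dll -= 0.5 * (lpp ** 2 - st.logp ** 2) / priors.log_p_sd ** 2
            if np.log(rng.random()) < dll:
                st.B, st.logp = Bp, lpp
                st.f = st.f + df
                st.eps = st.eps - df
                t_acc += 1.0
        acc["t_eff"] = t_acc / 2.0

    # conjugate variance updates
    a, b = priors.ig_shape, priors.ig_scale
    st.s2n = _invgamma_draw(rng, a + 0.5 * model.n_obs,
                            b + 0.5 * float(np.sum(st.eps ** 2)))
    st.s2c = _invgamma_draw(rng, a + 0.5 * model.n_circles,
                            b + 0.5 * float(np.sum(st.gamma ** 2)))
    st.s2y = _invgamma_draw(rng, a + 0.5 * model.n_years,
                            b + 0.5 * float(np.sum(st.delta ** 2)))

    # Interweaving: move a variance together with its field, holding the
    # standardized field fixed (non-centered step).  The field's own
    # Gaussian prior is invariant; the inverse-gamma prior, the
    # likelihood and the c^n Jacobian decide acceptance.
    def _ig_logpdf(v):
        return -(a + 1.0) * np.log(v) - b / v

    for name, field_attr, idx, s2_attr in (
            ("iw_eps", "eps", None, "s2n"),
            ("iw_gamma", "gamma", cobs, "s2c"),
            ("iw_delta", "delta", tobs, "s2y")):
        s2 = getattr(st, s2_attr)
        lc = scales[name] * rng.standard_normal()
        s2p = s2 * np.exp(lc)
        c = np.exp(0.5 * lc)
        x = getattr(st, field_attr)
        d = (c - 1.0) * (x if idx is None else x[idx])
        eta = st.eta(model)
        dll = float(np.sum(y * d - (_exp(eta + d) - _exp(eta))))
        dll += _ig_logpdf(s2p) - _ig_logpdf(s2) + x.size * np.log(c)
        if np.log(rng.random()) < dll:
            setattr(st, field_attr, c * x)
            setattr(st, s2_attr, s2p)
            acc[name] = 1.0
        else:
            acc[name] = 0.0

    # hyper-mean / hyper-variance of the region coefficients
    if model.n_regions > 1:
        R = model.n_regions
        for attr_c, attr_m, attr_v in (("beta0", "mu0", "s20"),
                                       ("beta1", "mu1", "s21")):
            coef = getattr(st, attr_c)
            s2 = getattr(st, attr_v)
            prec = R / s2 + 1.0 / priors.coef_variance
            mean = (coef.sum() / s2) / prec
            mu = rng.normal(mean, np.sqrt(1.0 / prec))
            setattr(st, attr_m, float(mu))
            setattr(st, attr_v, _invgamma_draw(
                rng, a + 0.5 * R, b + 0.5 * float(np.sum((coef - mu) ** 2))))
    return acc


def _adapt(scales, acc, it):
    kappa = (it + 1.0) ** -0.6
    for name, rate in acc.items():
        target = _TARGET_2D if name == "effort" else _TARGET_1D
        factor = np.exp(kappa * (rate - target))
        if name == "effort":
            scales["B"] *= factor
            scales["logp"] *= factor
            scales["eff_mult"] *= factor
        else:
            scales[name] *= factor


def _run_chain(model, mcmc, priors, rng, store_noise, fix_effort):
    st = _ChainState(model, rng)
    if fix_effort:
        st.B, st.logp = 0.0, 0.0
        st.f = np.zeros(model.n_obs)
    scales = {"eps": 1.5, "gamma": 1.5, "delta": 1.5, "beta0": 1.5,
              "beta1": 1.5, "beta2": 0.05, "B": 0.1, "logp": 0.1,
              "shift_g": 0.3, "shift_d0": 0.2, "shift_d1": 0.02,
              "scale_eps": 0.1, "scale_gamma": 0.1, "scale_delta": 0.1,
              "eff_mult": 1.0, "curve": 0.4, "t_delta": 0.05, "t_gamma": 0.05,
              "t_beta0": 0.05, "t_beta1": 0.005, "t_beta2": 0.02,
              "t_eff": 1.0, "iw_eps": 0.2, "iw_gamma": 0.2, "iw_delta": 0.2}
    # Welford running covariance of (B, log p) preconditions their joint
    # proposal (Haario-style) once enough burn-in history exists.
    eff_n, eff_mean, eff_m2 = 0, np.zeros(2), np.zeros((2, 2))
    for it in range(mcmc.burn_in):
        acc = _sweep(model, st, priors, scales, rng, fix_effort)
        _adapt(scales, acc, it)
        if not fix_effort:
            x = np.array([st.B, st.logp])
            eff_n += 1
            dx = x - eff_mean
            eff_mean += dx / eff_n
            eff_m2 += np.outer(dx, x - eff_mean)
            if eff_n > 300 and eff_n % 100 == 0:
                cov = eff_m2 / (eff_n - 1) * (2.38 ** 2 / 2.0)
                cov[np.diag_indices(2)] += 1e-8
                scales["eff_chol"] = np.linalg.cholesky(cov)
                scales["eff_mult"] = 1.0

    n_keep = mcmc.n_samples
    out = {
        "beta0": np.empty((n_keep, model.n_regions)),
        "beta1": np.empty((n_keep, model.n_regions)),
        "beta2": np.empty(n_keep),
        "effort_B": np.empty(n_keep),
        "log_effort_p": np.empty(n_keep),
        "gamma": np.empty((n_keep, model.n_circles)),
        "delta": np.empty((n_keep, model.n_years)),
        "var_circle": np.empty(n_keep),
        "var_year": np.empty(n_keep),
        "var_noise": np.empty(n_keep),
    }
    if model.n_regions > 1:
        for nm in ("hyper_mean_beta0", "hyper_var_beta0",
                   "hyper_mean_beta1", "hyper_var_beta1"):
            out[nm] = np.empty(n_keep)
    if store_noise:
        out["noise"] = np.empty((n_keep, model.n_obs))

    reg_of_circle = model.circle_region_idx
    tau_y = model.tau_years
    for k in range(n_keep):
        for _ in range(mcmc.thinning):
            _sweep(model, st, priors, scales, rng, fix_effort)
        # Store with identifiability centering: circle effects sum to
        # zero within region; year effects sum to zero and are
        # orthogonal to the trend; the swept-out mean and linear drift
        # move into the intercepts and trends (eta is unchanged).
        gmean = np.bincount(reg_of_circle, weights=st.gamma,
                            minlength=model.n_regions)
        gmean /= np.bincount(reg_of_circle, minlength=model.n_regions)
        dmean = st.delta.mean()
        dslope = float(st.delta @ tau_y) / float(tau_y @ tau_y)
        out["beta0"][k] = st.beta0 + gmean + dmean
        out["beta1"][k] = st.beta1 + dslope
        out["beta2"][k] = st.beta2
        out["effort_B"][k] = st.B
        out["log_effort_p"][k] = st.logp
        out["gamma"][k] = st.gamma - gmean[reg_of_circle]
        out["delta"][k] = st.delta - dmean - dslope * tau_y
        out["var_circle"][k] = st.s2c
        out["var_year"][k] = st.s2y
        out["var_noise"][k] = st.s2n
        if model.n_regions > 1:
            out["hyper_mean_beta0"][k] = st.mu0
            out["hyper_var_beta0"][k] = st.s20
            out["hyper_mean_beta1"][k] = st.mu1
            out["hyper_var_beta1"][k] = st.s21
        if store_noise:
            out["noise"][k] = st.eps
    return out


def run_chains(model: CircleCountModel, mcmc: MCMCConfig,
               priors: Hyperpriors, *, store_noise: bool = True,
               fix_effort: bool = False, progress: bool = False):
    """Run independent chains and stack their draws.

    Returns a :class:`cbctrend.results.PosteriorDraws`.
    """
    from .results import PosteriorDraws

    root = np.random.SeedSequence(mcmc.seed)
    chains = []
    for c, child in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(model, mcmc, priors, rng, store_noise,
                                 fix_effort))
        if progress:
            print(f"chain {c + 1}/{mcmc.n_chains} done")
    params = {name: np.stack([ch[name] for ch in chains])
              for name in chains[0]}
    monitored = ["beta0", "beta1", "var_circle", "var_year", "var_noise"]
    if model.has_boat_variation:
        monitored.append("beta2")
    if not fix_effort:
        monitored += ["effort_B", "log_effort_p"]
    if model.n_regions > 1:
        monitored += ["hyper_mean_beta0", "hyper_var_beta0",
                      "hyper_mean_beta1", "hyper_var_beta1"]
    return PosteriorDraws(params, monitored=monitored,
                          coords={"region": model.regions,
                                  "circle": model.circle_ids,
                                  "year": [int(y) for y in model.years]})
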