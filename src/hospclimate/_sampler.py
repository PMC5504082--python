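"""MCMC engine for the pooled hierarchical mortality model.

The posterior is sampled with a blocked, vectorized scheme tailored to
the model's conditional-independence structure:

* hospital effects ``u_h``, measure intercepts ``alpha_m`` and climate
  effects ``gamma_c`` partition the observation cells, so each block is
  updated with one simultaneous random-walk Metropolis step per
  component (per-component adaptive scales, tuned during warmup only);
* covariate coefficients ``beta`` touch every cell and are updated
  coordinate-wise;
* the additive aliasing between the intercepts and each random-effect
  block (only contrasts are likelihood-identified) is resolved by exact
  Gibbs "translation" moves that shift mass between ``alpha`` and
  ``u``/``gamma`` under their Gaussian priors without changing the
  likelihood;
* the hierarchical scales are updated by univariate slice sampling on
  the log scale.

Everything is driven by a single ``numpy`` Generator per chain, so a
given (seed, config) reproduces draws exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["SamplerSpec", "run_chain"]

_TARGET_ACCEPT = 0.44  # scalar random-walk optimum


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class SamplerSpec:
    """Fixed data and prior constants handed to each chain."""

    y: np.ndarray            # deaths per cell
    n: np.ndarray            # denominators per cell
    hidx: np.ndarray         # cell -> hospital
    midx: np.ndarray         # cell -> measure
    cidx: np.ndarray | None  # cell -> climate (None: no climate block)
    xcell: np.ndarray        # P x cells, covariate columns expanded to cells
    n_hospitals: int
    n_measures: int
    n_climates: int
    xhosp: np.ndarray | None = None  # n_hospitals x P covariate matrix
    hclim: np.ndarray | None = None  # hospital -> climate
    prior_scale_fixed: float = 2.5   # Normal sd on alpha, beta
    prior_scale_sigma: float = 1.0   # half-Normal sd on sigma_u, sigma_gamma
    pooled_climate: bool = True      # gamma ~ N(0, sigma_gamma) vs fixed N(0, prior_scale_fixed)
    likelihood: str = "binomial-logit"
    # Normal variant: logit of the continuity-corrected observed rate
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.likelihood not in ("binomial-logit", "normal-on-logit-rate"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.likelihood == "normal-on-logit-rate" and self.z is None:
            zr = (self.y + 0.5) / (self.n + 1.0)
            self.z = np.log(zr / (1.0 - zr))
        # constant part of the binomial log-pmf (needed for honest elpd)
        self._const = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)

    def loglik_cells(self, eta: np.ndarray, sigma_e: float = 1.0) -> np.ndarray:
        if self.likelihood == "binomial-logit":
            return self._const + self.y * eta - self.n * _softplus(eta)
        r = self.z - eta
        return -0.5 * np.log(2.0 * np.pi) - np.log(sigma_e) - 0.5 * (r / sigma_e) ** 2


def _slice_sample(x0: float, logf, rng: np.random.Generator,
                  w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    L = x0 - w * rng.random()
    R = L + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(L) > y:
        L -= w
        j -= 1
    while k > 0 and logf(R) > y:
        R += w
        k -= 1
    while True:
        x1 = rng.uniform(L, R)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1


@dataclass
class _State:
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    u: np.ndarray
    sigma_u: float
    sigma_g: float
    sigma_e: float
    eta: np.ndarray = field(init=False)
    ll: np.ndarray = field(init=False)


def _mh_partition_block(values, idx, scales, prior_sd, state, spec, rng):
    """Parallel MH for a block whose components partition the cells."""
    delta = scales * rng.standard_normal(values.size)
    prop = values + delta
    ll_prop = spec.loglik_cells(state.eta + delta[idx], state.sigma_e)
    d_ll = np.bincount(idx, weights=ll_prop - state.ll, minlength=values.size)
    d_ll += (values**2 - prop**2) / (2.0 * prior_sd**2)
    accept = np.log(rng.random(values.size)) < d_ll
    acc_cells = accept[idx]
    state.eta = np.where(acc_cells, state.eta + delta[idx], state.eta)
    state.ll = np.where(acc_cells, ll_prop, state.ll)
    return np.where(accept, prop, values), accept.astype(float)


def _adapt(scales, acc, t):
    gain = min(0.25, (t + 1.0) ** -0.6)
    return scales * np.exp(gain * (acc - _TARGET_ACCEPT))


def _rescale_move(values, idx, sigma, step, state, spec, rng, prior_scale_sigma):
    """Joint multiplicative move on (sigma, effect block).

    Proposes ``sigma' = sigma e^eps`` and scales every effect by the
    same factor.  The Gaussian prior of the block and the Jacobian of
    the map cancel, so the acceptance ratio is the likelihood ratio
    times the half-Normal prior ratio on sigma (plus the log-scale
    Jacobian term).  This traverses the narrow-`sigma` funnel that
    per-component walks cannot.
    """
    eps = step * rng.standard_normal()
    s_new = sigma * np.exp(eps)
    # same bounded log-domain as the slice updates; without it the move
    # can random-walk sigma into underflow when the block is ~zero
    if not -12.0 < np.log(s_new) < 4.0:
        return values, sigma, 0.0
    factor = np.exp(eps)
    delta = values * (factor - 1.0)
    eta_p = state.eta + delta[idx]
    ll_p = spec.loglik_cells(eta_p, state.sigma_e)
    d = float(np.sum(ll_p - state.ll))
    d += -(s_new**2 - sigma**2) / (2.0 * prior_scale_sigma**2) + eps
    if np.log(rng.random()) < d:
        state.eta, state.ll = eta_p, ll_p
        return values * factor, s_new, 1.0
    return values, sigma, 0.0


def run_chain(spec: SamplerSpec, iterations: int, warmup: int,
              rng: np.random.Generator, store_loglik: bool = False) -> dict[str, np.ndarray]:
    """Run one chain; returns post-warmup draws for every block."""
    H, M, C = spec.n_hospitals, spec.n_measures, spec.n_climates
    P = spec.xcell.shape[0]
    has_climate = spec.cidx is not None
    s_fix = spec.prior_scale_fixed

    # empirical-logit start for the intercepts, jittered per chain
    pooled = np.bincount(spec.midx, weights=spec.y, minlength=M) / np.maximum(
        np.bincount(spec.midx, weights=spec.n, minlength=M), 1.0)
    pooled = np.clip(pooled, 1e-4, 1 - 1e-4)
    st = _State(
        alpha=np.log(pooled / (1 - pooled)) + 0.1 * rng.standard_normal(M),
        beta=0.05 * rng.standard_normal(P),
        gamma=0.05 * rng.standard_normal(C) if has_climate else np.zeros(0),
        u=0.05 * rng.standard_normal(H),
        sigma_u=float(np.exp(rng.normal(np.log(0.3), 0.2))),
        sigma_g=float(np.exp(rng.normal(np.log(0.3), 0.2))),
        sigma_e=1.0,
    )

    def recompute_eta():
        eta = st.alpha[spec.midx] + st.u[spec.hidx] + st.beta @ spec.xcell
        if has_climate:
            eta = eta + st.gamma[spec.cidx]
        return eta

    st.eta = recompute_eta()
    st.ll = spec.loglik_cells(st.eta, st.sigma_e)

    sc_u = np.full(H, 0.2)
    sc_a = np.full(M, 0.05)
    sc_g = np.full(C, 0.1)
    sc_b = np.full(P, 0.05)
    sc_ru = 0.3  # rescale-move step sizes
    sc_rg = 0.3
    # adaptive-Metropolis state for the joint beta proposal (the
    # coordinates are posterior-correlated through shared county
    # covariate structure, so per-coordinate walks mix slowly)
    am_start = min(200, warmup // 2)
    am_lam = 1.0
    am_mean = np.zeros(P)
    am_m2 = np.zeros((P, P))
    am_count = 0

    kept = iterations - warmup
    draws = {
        "alpha": np.empty((kept, M)),
        "beta": np.empty((kept, P)),
        "u": np.empty((kept, H)),
        "sigma_u": np.empty(kept),
    }
    if has_climate:
        draws["gamma"] = np.empty((kept, C))
        draws["sigma_gamma"] = np.empty(kept)
    if spec.likelihood == "normal-on-logit-rate":
        draws["sigma_e"] = np.empty(kept)
    if store_loglik:
        draws["log_lik"] = np.empty((kept, spec.y.size))

    for t in range(iterations):
        adapting = t < warmup

        st.u, acc = _mh_partition_block(st.u, spec.hidx, sc_u, st.sigma_u, st, spec, rng)
        if adapting:
            sc_u = _adapt(sc_u, acc, t)

        st.alpha, acc = _mh_partition_block(st.alpha, spec.midx, sc_a, s_fix, st, spec, rng)
        if adapting:
            sc_a = _adapt(sc_a, acc, t)

        if has_climate:
            g_sd = st.sigma_g if spec.pooled_climate else s_fix
            st.gamma, acc = _mh_partition_block(st.gamma, spec.cidx, sc_g, g_sd, st, spec, rng)
            if adapting:
                sc_g = _adapt(sc_g, acc, t)

        # beta: coordinate walks early in warmup, then joint adaptive
        # Metropolis with the running posterior covariance
        if P > 0:
            if t < am_start:
                for j in range(P):
                    db = sc_b[j] * rng.standard_normal()
                    eta_p = st.eta + db * spec.xcell[j]
                    ll_p = spec.loglik_cells(eta_p, st.sigma_e)
                    d = float(np.sum(ll_p - st.ll))
                    d += (st.beta[j] ** 2 - (st.beta[j] + db) ** 2) / (2.0 * s_fix**2)
                    ok = np.log(rng.random()) < d
                    if ok:
                        st.beta[j] += db
                        st.eta, st.ll = eta_p, ll_p
                    if adapting:
                        sc_b[j] = float(_adapt(sc_b[j:j + 1], np.array([float(ok)]), t)[0])
            else:
                cov = am_m2 / max(am_count - 1, 1)
                cov = cov + np.diag(np.maximum(1e-8 - np.diag(cov), 0.0)) + 1e-12 * np.eye(P)
                L = np.linalg.cholesky(cov)
                db = am_lam * (2.38 / np.sqrt(P)) * (L @ rng.standard_normal(P))
                prop = st.beta + db
                eta_p = st.eta + db @ spec.xcell
                ll_p = spec.loglik_cells(eta_p, st.sigma_e)
                d = float(np.sum(ll_p - st.ll))
                d += float(np.sum(st.beta**2 - prop**2)) / (2.0 * s_fix**2)
                ok = np.log(rng.random()) < d
                if ok:
                    st.beta = prop
                    st.eta, st.ll = eta_p, ll_p
                if adapting:
                    gain = min(0.25, (t + 1.0) ** -0.6)
                    am_lam *= float(np.exp(gain * (float(ok) - 0.23)))
            if adapting:
                am_count += 1
                delta = st.beta - am_mean
                am_mean = am_mean + delta / am_count
                am_m2 = am_m2 + np.outer(delta, st.beta - am_mean)

        # exact Gibbs translations along the likelihood-invariant
        # (aliased) directions.  The intercepts absorb any constant
        # shift of u or gamma; the hospital effects can absorb a
        # climate shift (u_h - d for every hospital in the climate) or
        # a covariate shift (u - X d against beta + d).  Each move
        # leaves eta untouched and samples the shift from its exact
        # Gaussian conditional under the priors.
        prec = H / st.sigma_u**2 + M / s_fix**2
        mean = (st.u.sum() / st.sigma_u**2 - st.alpha.sum() / s_fix**2) / prec
        d = rng.normal(mean, 1.0 / np.sqrt(prec))
        st.alpha += d
        st.u -= d
        if has_climate and spec.pooled_climate:
            prec = C / st.sigma_g**2 + M / s_fix**2
            mean = (st.gamma.sum() / st.sigma_g**2 - st.alpha.sum() / s_fix**2) / prec
            d = rng.normal(mean, 1.0 / np.sqrt(prec))
            st.alpha += d
            st.gamma -= d
        if has_climate and spec.hclim is not None:
            g_sd = st.sigma_g if spec.pooled_climate else s_fix
            n_c = np.bincount(spec.hclim, minlength=C).astype(float)
            sum_u = np.bincount(spec.hclim, weights=st.u, minlength=C)
            prec_c = n_c / st.sigma_u**2 + 1.0 / g_sd**2
            mean_c = (sum_u / st.sigma_u**2 - st.gamma / g_sd**2) / prec_c
            dvec = mean_c + rng.standard_normal(C) / np.sqrt(prec_c)
            st.gamma += dvec
            st.u -= dvec[spec.hclim]
        if P > 0 and spec.xhosp is not None:
            X = spec.xhosp
            A = (X.T @ X) / st.sigma_u**2 + np.eye(P) / s_fix**2
            b = (X.T @ st.u) / st.sigma_u**2 - st.beta / s_fix**2
            L = np.linalg.cholesky(A)
            mean_v = np.linalg.solve(A, b)
            dvec = mean_v + np.linalg.solve(L.T, rng.standard_normal(P))
            st.beta = st.beta + dvec
            st.u -= X @ dvec

        # funnel traversal: joint rescaling of (sigma, block)
        st.u, st.sigma_u, acc_su = _rescale_move(
            st.u, spec.hidx, st.sigma_u, sc_ru, st, spec, rng, spec.prior_scale_sigma)
        if adapting:
            sc_ru = float(_adapt(np.array([sc_ru]), np.array([acc_su]), t)[0])
        if has_climate and spec.pooled_climate:
            st.gamma, st.sigma_g, acc_sg = _rescale_move(
                st.gamma, spec.cidx, st.sigma_g, sc_rg, st, spec, rng, spec.prior_scale_sigma)
            if adapting:
                sc_rg = float(_adapt(np.array([sc_rg]), np.array([acc_sg]), t)[0])

        # hierarchical scales: slice sampling on the log scale
        ssq_u = float(st.u @ st.u)

        def logf_u(x, _ssq=ssq_u):
            if not -12.0 < x < 4.0:  # numerical guard, far outside any posterior mass
                return -np.inf
            s = np.exp(x)
            return -H * x - _ssq / (2 * s**2) - s**2 / (2 * spec.prior_scale_sigma**2) + x

        st.sigma_u = float(np.exp(_slice_sample(
            float(np.clip(np.log(st.sigma_u), -11.9, 3.9)), logf_u, rng)))

        if has_climate and spec.pooled_climate:
            ssq_g = float(st.gamma @ st.gamma)

            def logf_g(x, _ssq=ssq_g):
                if not -12.0 < x < 4.0:
                    return -np.inf
                s = np.exp(x)
                return -C * x - _ssq / (2 * s**2) - s**2 / (2 * spec.prior_scale_sigma**2) + x

            st.sigma_g = float(np.exp(_slice_sample(
                float(np.clip(np.log(st.sigma_g), -11.9, 3.9)), logf_g, rng)))

        if spec.likelihood == "normal-on-logit-rate":
            resid = float(np.sum((spec.z - st.eta) ** 2))
            N = spec.y.size

            def logf_e(x, _r=resid):
                if not -12.0 < x < 4.0:
                    return -np.inf
                s = np.exp(x)
                return -N * x - _r / (2 * s**2) - s**2 / (2 * spec.prior_scale_sigma**2) + x

            st.sigma_e = float(np.exp(_slice_sample(
                float(np.clip(np.log(st.sigma_e), -11.9, 3.9)), logf_e, rng)))
            st.ll = spec.loglik_cells(st.eta, st.sigma_e)

        if t >= warmup:
            i = t - warmup
            draws["alpha"][i] = st.alpha
            draws["beta"][i] = st.beta
            draws["u"][i] = st.u
            draws["sigma_u"][i] = st.sigma_u
            if has_climate:
                draws["gamma"][i] = st.gamma
                draws["sigma_gamma"][i] = st.sigma_g
            if spec.likelihood == "normal-on-logit-rate":
                draws["sigma_e"][i] = st.sigma_e
            if store_loglik:
                draws["log_lik"][i] = st.ll

    return draws
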