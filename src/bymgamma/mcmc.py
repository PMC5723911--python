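"""Metropolis-within-Gibbs posterior computation for the hierarchical model.

Update scheme per sweep:

* fixed effects — joint random-walk Metropolis, preconditioned by the
  Cholesky factor of ``(X'X)^{-1}``;
* structured intercepts ``u`` — single-site random-walk Metropolis, executed
  in vectorised batches over the colour classes of a proper graph colouring
  (regions of one colour share no edge, so their full conditionals are
  mutually independent); after the sweep each connected component is
  re-centred and the mean shift is absorbed into the intercept;
* unstructured intercepts ``v`` and random slopes ``b`` — single-site
  Metropolis, vectorised across regions (their full conditionals factorise
  exactly);
* translation moves — the level of ``v`` trades off against the intercept,
  and the level of ``b`` against the exposure slope, along directions that
  leave the linear predictor exactly invariant; a scalar Metropolis step
  along each such direction (accepted on the prior ratio alone) moves these
  otherwise nearly-unidentified combinations, which single-site updates mix
  very slowly;
* precisions ``tau_u, tau_v, tau_b`` — conjugate Gibbs draws from
  ``Gamma(a + r/2, c + S/2)``;
* likelihood shape ``alpha`` — random-walk Metropolis on the log scale with
  the log-Jacobian correction.

Proposal scales adapt by Robbins–Monro during burn-in only (targets 0.44 for
scalar/site updates, 0.23 for the fixed-effect block) and are frozen
afterwards so the retained chain satisfies detailed balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import SpatialGammaModel, log_prior
from .spatial import ICARStructure, greedy_coloring, icar_quadratic_form

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "gibbs_update_precision",
    "mh_update",
    "mh_update_positive",
    "run_sampler",
    "diagnostics",
]


@dataclass(frozen=True)
class SamplerConfig:
    n_iter: int = 10_000
    n_burnin: int = 5_000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0
    target_accept_scalar: float = 0.44
    target_accept_block: float = 0.23
    constraint_tol: float = 1e-8
    adapt: bool = True

    def __post_init__(self):
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, indexed (chain, draw, ...)."""

    coef_names: tuple
    region_ids: tuple
    beta: np.ndarray        # (chains, draws, n_coef)
    u: np.ndarray           # (chains, draws, n_regions)
    v: np.ndarray
    b: np.ndarray
    tau_u: np.ndarray       # (chains, draws)
    tau_v: np.ndarray
    tau_b: np.ndarray
    alpha: np.ndarray
    log_posterior: np.ndarray
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def beta_draws(self, coef: str) -> np.ndarray:
        return self.stacked("beta")[:, self.coef_names.index(coef)]

    def to_inference_data(self):
        import arviz as az

        post = {
            **{f"beta_{n}": self.beta[:, :, i] for i, n in enumerate(self.coef_names)},
            "tau_u": self.tau_u, "tau_v": self.tau_v, "tau_b": self.tau_b,
            "alpha": self.alpha,
            "u": self.u, "v": self.v, "b": self.b,
        }
        return az.from_dict(
            posterior=post,
            coords={"region": list(self.region_ids)},
            dims={"u": ["region"], "v": ["region"], "b": ["region"]},
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        ch, dr = np.meshgrid(np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij")
        rows["chain"], rows["draw"] = ch.ravel(), dr.ravel()
        for i, n in enumerate(self.coef_names):
            rows[f"beta_{n}"] = self.beta[:, :, i].ravel()
        for n in ("tau_u", "tau_v", "tau_b", "alpha", "log_posterior"):
            rows[n] = getattr(self, n).ravel()
        for j, r in enumerate(self.region_ids):
            rows[f"u[{r}]"] = self.u[:, :, j].ravel()
            rows[f"v[{r}]"] = self.v[:, :, j].ravel()
            rows[f"b[{r}]"] = self.b[:, :, j].ravel()
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorSamples":
        coef_names = tuple(c[5:] for c in df.columns if c.startswith("beta_"))
        region_ids = tuple(c[2:-1] for c in df.columns if c.startswith("u["))
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1
        df = df.sort_values(["chain", "draw"])

        def grab(cols):
            a = df[cols].to_numpy(dtype=float)
            return a.reshape(n_chains, n_draws, len(cols))

        return cls(
            coef_names, region_ids,
            beta=grab([f"beta_{n}" for n in coef_names]),
            u=grab([f"u[{r}]" for r in region_ids]),
            v=grab([f"v[{r}]" for r in region_ids]),
            b=grab([f"b[{r}]" for r in region_ids]),
            tau_u=grab(["tau_u"])[:, :, 0], tau_v=grab(["tau_v"])[:, :, 0],
            tau_b=grab(["tau_b"])[:, :, 0], alpha=grab(["alpha"])[:, :, 0],
            log_posterior=grab(["log_posterior"])[:, :, 0],
        )


def gibbs_update_precision(effects, structure, prior_shape, prior_rate, rng) -> float:
    """Conjugate draw for a random-effect precision.

    Posterior is ``Gamma(a + r/2, c + S/2)`` where for iid effects ``r`` is the
    vector length and ``S = sum(e^2)``; for ICAR effects ``r`` is the precision
    rank (n minus number of components) and ``S = u'Qu``.
    """
    effects = np.asarray(effects, dtype=float)
    if isinstance(structure, ICARStructure):
        r = structure.rank
        S = icar_quadratic_form(structure, effects)
    elif structure == "iid":
        r = effects.size
        S = float(np.sum(effects**2))
    else:
        raise ValueError("structure must be 'iid' or an ICARStructure")
    return float(rng.gamma(prior_shape + 0.5 * r, 1.0 / (prior_rate + 0.5 * S)))


def mh_update(current, log_target, scale, rng, current_logp=None):
    """One random-walk Metropolis step on a scalar or vector block.

    Returns ``(value, accepted, log_target(value))``.
    """
    current = np.asarray(current, dtype=float)
    if current_logp is None:
        current_logp = float(log_target(current))
    if not np.isfinite(current_logp):
        raise ValueError("log target is not finite at the current value")
    prop = current + scale * rng.standard_normal(current.shape)
    logp_prop = float(log_target(prop))
    if np.log(rng.uniform()) < logp_prop - current_logp:
        return prop, True, logp_prop
    return current, False, current_logp


def mh_update_positive(current, log_target, scale, rng, current_logp=None):
    """Metropolis step for a positive scalar via a log-scale random walk.

    The proposal ``x' = x * exp(scale * z)`` needs the Jacobian correction
    ``log(x') - log(x)`` in the acceptance ratio.
    """
    current = float(current)
    if current <= 0:
        raise ValueError("current value must be positive")
    if current_logp is None:
        current_logp = float(log_target(current))
    prop = current * np.exp(scale * rng.standard_normal())
    logp_prop = float(log_target(prop))
    log_ratio = logp_prop - current_logp + np.log(prop) - np.log(current)
    if np.log(rng.uniform()) < log_ratio:
        return prop, True, logp_prop
    return current, False, current_logp


class _Adapt:
    """Robbins–Monro adaptation of a log proposal scale during burn-in."""

    def __init__(self, scale, target):
        self.log_scale = np.log(scale)
        self.target = target
        self.t = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, acc_rate):
        self.t += 1
        gamma = min(0.25, self.t ** -0.6)
        self.log_scale += gamma * (acc_rate - self.target)


def _run_chain(model: SpatialGammaModel, config: SamplerConfig, chain: int,
               fixed: dict, prior_only: bool) -> dict:
    rng = np.random.default_rng([config.seed, chain])
    spec, icar = model.spec, model.icar
    X, y, ridx = model.exog, model.y, model.region_index
    xc = model.x - model.x_center      # random slopes act on exposure deviations
    n_obs, n_reg, k = model.n_obs, model.n_regions, model.exog.shape[1]
    labels = icar.component_labels
    comp_sizes = np.bincount(labels)
    deg = icar.degrees()
    adj = -(icar.precision - np.diag(deg))        # 0/1 adjacency
    colors = greedy_coloring(model.graph)
    color_classes = []
    for c in range(colors.max() + 1):
        regs = np.where(colors == c)[0]
        rows = np.where(np.isin(ridx, regs))[0]
        color_classes.append((regs, rows))
    sum_log_y = float(np.sum(np.log(y)))

    state = model.initial_state()
    for name, val in fixed.items():
        if name in ("u", "v", "b"):
            setattr(state, name, np.asarray(val, dtype=float).copy())
        elif name in ("tau_u", "tau_v", "tau_b", "alpha"):
            setattr(state, name, float(val))
        else:
            raise KeyError(f"cannot fix unknown parameter {name!r}")

    eta = model.eta(state)

    # region-sum helper for per-row log-likelihood deltas
    def region_delta(rows, d_eta_rows, eta_rows, y_rows):
        with np.errstate(over="ignore"):
            d = -state.alpha * (d_eta_rows + y_rows * (np.exp(-(eta_rows + d_eta_rows)) - np.exp(-eta_rows)))
        return d

    # preconditioner for the fixed-effect block
    try:
        L = np.linalg.cholesky(np.linalg.inv(X.T @ X + 1e-10 * np.eye(k)))
    except np.linalg.LinAlgError:
        L = np.eye(k) / np.sqrt(n_obs)

    ad_beta = _Adapt(1.0, config.target_accept_block)
    ad_u = _Adapt(0.1, config.target_accept_scalar)
    ad_v = _Adapt(0.1, config.target_accept_scalar)
    ad_b = _Adapt(0.02, config.target_accept_scalar)
    ad_alpha = _Adapt(0.3, config.target_accept_scalar)
    ad_shift_v = _Adapt(0.1, config.target_accept_scalar)
    ad_shift_b = _Adapt(0.02, config.target_accept_scalar)
    ad_swap = _Adapt(0.1, config.target_accept_scalar)
    ad_swap2 = _Adapt(0.1, config.target_accept_scalar)

    n_draws = config.n_draws
    out = {
        "beta": np.empty((n_draws, k)), "u": np.empty((n_draws, n_reg)),
        "v": np.empty((n_draws, n_reg)), "b": np.empty((n_draws, n_reg)),
        "tau_u": np.empty(n_draws), "tau_v": np.empty(n_draws),
        "tau_b": np.empty(n_draws), "alpha": np.empty(n_draws),
        "log_posterior": np.empty(n_draws),
    }
    acc_totals = {"beta": [], "u": [], "v": [], "b": [], "alpha": []}
    like = 0.0 if prior_only else 1.0
    save_i = 0

    for it in range(config.n_iter):
        adapting = config.adapt and it < config.n_burnin
        post_burn = it >= config.n_burnin

        # ---- fixed effects (joint block) --------------------------------
        dbeta = ad_beta.scale * (L @ rng.standard_normal(k))
        d_eta = X @ dbeta
        with np.errstate(over="ignore"):
            d_ll = -state.alpha * np.sum(d_eta + y * (np.exp(-(eta + d_eta)) - np.exp(-eta)))
        d_prior = -0.5 * spec.fixed_effect_precision * (
            np.sum((state.beta + dbeta) ** 2) - np.sum(state.beta**2)
        )
        log_r = like * d_ll + d_prior
        acc = np.log(rng.uniform()) < log_r
        if acc:
            state.beta = state.beta + dbeta
            eta = eta + d_eta
        if adapting:
            ad_beta.update(float(acc))
        if post_burn:
            acc_totals["beta"].append(float(acc))

        # ---- structured intercepts u (colour classes) -------------------
        if "u" not in fixed:
            accs = []
            for regs, rows in color_classes:
                du = ad_u.scale * rng.standard_normal(regs.size)
                d_eta_rows = du[np.searchsorted(regs, ridx[rows])]
                d = region_delta(rows, d_eta_rows, eta[rows], y[rows])
                dll_reg = np.bincount(ridx[rows], weights=d, minlength=n_reg)[regs]
                Au = adj @ state.u
                u_old = state.u[regs]
                u_new = u_old + du
                d_prior = -0.5 * state.tau_u * (
                    deg[regs] * (u_new**2 - u_old**2) - 2.0 * du * Au[regs]
                )
                log_r = like * dll_reg + d_prior
                acc_mask = np.log(rng.uniform(size=regs.size)) < log_r
                if acc_mask.any():
                    state.u[regs[acc_mask]] += du[acc_mask]
                    acc_rows = acc_mask[np.searchsorted(regs, ridx[rows])]
                    eta[rows[acc_rows]] += d_eta_rows[acc_rows]
                accs.append(acc_mask.mean())
            # re-centre per component; absorb the mean shift into the intercept
            m = np.bincount(labels, weights=state.u) / comp_sizes
            state.u -= m[labels]
            shift = float(np.mean(m[labels[ridx]]))
            state.beta[0] += shift
            eta += shift - m[labels[ridx]]
            if adapting:
                ad_u.update(float(np.mean(accs)))
            if post_burn:
                acc_totals["u"].append(float(np.mean(accs)))

        if "tau_u" not in fixed:
            state.tau_u = gibbs_update_precision(
                state.u, icar, spec.precision_prior_shape, spec.precision_prior_rate, rng
            )

        # ---- unstructured intercepts v (factorised across regions) ------
        if "v" not in fixed:
            dv = ad_v.scale * rng.standard_normal(n_reg)
            d_eta_all = dv[ridx]
            d = region_delta(None, d_eta_all, eta, y)
            dll_reg = np.bincount(ridx, weights=d, minlength=n_reg)
            d_prior = -0.5 * state.tau_v * ((state.v + dv) ** 2 - state.v**2)
            acc_mask = np.log(rng.uniform(size=n_reg)) < like * dll_reg + d_prior
            if acc_mask.any():
                state.v[acc_mask] += dv[acc_mask]
                rows_acc = acc_mask[ridx]
                eta[rows_acc] += d_eta_all[rows_acc]
            if adapting:
                ad_v.update(float(acc_mask.mean()))
            if post_burn:
                acc_totals["v"].append(float(acc_mask.mean()))

        if "tau_v" not in fixed:
            state.tau_v = gibbs_update_precision(
                state.v, "iid", spec.precision_prior_shape, spec.precision_prior_rate, rng
            )

        # ---- random slopes b --------------------------------------------
        if "b" not in fixed:
            db = ad_b.scale * rng.standard_normal(n_reg)
            d_eta_all = db[ridx] * xc
            d = region_delta(None, d_eta_all, eta, y)
            dll_reg = np.bincount(ridx, weights=d, minlength=n_reg)
            d_prior = -0.5 * state.tau_b * ((state.b + db) ** 2 - state.b**2)
            acc_mask = np.log(rng.uniform(size=n_reg)) < like * dll_reg + d_prior
            if acc_mask.any():
                state.b[acc_mask] += db[acc_mask]
                rows_acc = acc_mask[ridx]
                eta[rows_acc] += d_eta_all[rows_acc]
            if adapting:
                ad_b.update(float(acc_mask.mean()))
            if post_burn:
                acc_totals["b"].append(float(acc_mask.mean()))

        if "tau_b" not in fixed:
            state.tau_b = gibbs_update_precision(
                state.b, "iid", spec.precision_prior_shape, spec.precision_prior_rate, rng
            )

        # ---- eta-invariant translation moves ----------------------------
        # v_i -> v_i - c, b0 -> b0 + c leaves eta unchanged; ratio is prior-only
        if "v" not in fixed:
            c = ad_shift_v.scale * rng.standard_normal()
            d_prior = (
                -0.5 * state.tau_v * (np.sum((state.v - c) ** 2) - np.sum(state.v**2))
                - 0.5 * spec.fixed_effect_precision
                * ((state.beta[0] + c) ** 2 - state.beta[0] ** 2)
            )
            acc = np.log(rng.uniform()) < d_prior
            if acc:
                state.v -= c
                state.beta[0] += c
            if adapting:
                ad_shift_v.update(float(acc))
        # u -> a*u, v -> v + (1-a)*u, tau_u -> tau_u / a^2 rescales the
        # structured/unstructured split of the intercept while leaving both
        # eta and the ICAR kernel exactly invariant (a funnel-escaping joint
        # move); the ratio collects the tau_u prior, the v prior and the
        # Jacobian a^rank * a^{-2}
        if "u" not in fixed and "v" not in fixed and "tau_u" not in fixed:
            a = float(np.exp(ad_swap.scale * rng.standard_normal()))
            v_new = state.v + (1.0 - a) * state.u
            tau_u_new = state.tau_u / a**2
            d_prior = (
                (spec.precision_prior_shape - 1.0) * np.log(tau_u_new / state.tau_u)
                - spec.precision_prior_rate * (tau_u_new - state.tau_u)
                - 0.5 * state.tau_v * (np.sum(v_new**2) - np.sum(state.v**2))
                - 2.0 * np.log(a)
            )
            acc = np.log(rng.uniform()) < d_prior
            if acc:
                state.u *= a
                state.v = v_new
                state.tau_u = tau_u_new
            if adapting:
                ad_swap.update(float(acc))

        # symmetric counterpart: v -> a*v, u -> u + (1-a)*(v - v_bar),
        # b0 -> b0 + (1-a)*v_bar, tau_v -> tau_v / a^2 (connected graphs
        # only, where absorbing the mean shift into the intercept is exact)
        if ("u" not in fixed and "v" not in fixed and "tau_v" not in fixed
                and icar.n_components == 1):
            a = float(np.exp(ad_swap2.scale * rng.standard_normal()))
            v_bar = float(state.v.mean())
            u_new = state.u + (1.0 - a) * (state.v - v_bar)
            tau_v_new = state.tau_v / a**2
            dS_u = float(u_new @ (icar.precision @ u_new)
                         - state.u @ (icar.precision @ state.u))
            b0_new = state.beta[0] + (1.0 - a) * v_bar
            d_prior = (
                (spec.precision_prior_shape - 1.0) * np.log(tau_v_new / state.tau_v)
                - spec.precision_prior_rate * (tau_v_new - state.tau_v)
                - 0.5 * state.tau_u * dS_u
                - 0.5 * spec.fixed_effect_precision * (b0_new**2 - state.beta[0] ** 2)
                - 2.0 * np.log(a)
            )
            acc = np.log(rng.uniform()) < d_prior
            if acc:
                state.u = u_new
                state.v = a * state.v
                state.tau_v = tau_v_new
                state.beta[0] = b0_new
            if adapting:
                ad_swap2.update(float(acc))

        # b_i -> b_i - c, beta_x -> beta_x + c, b0 -> b0 - c * x_center
        if "b" not in fixed:
            c = ad_shift_b.scale * rng.standard_normal()
            b0n = state.beta[0] - c * model.x_center
            bxn = state.beta[1] + c
            d_prior = (
                -0.5 * state.tau_b * (np.sum((state.b - c) ** 2) - np.sum(state.b**2))
                - 0.5 * spec.fixed_effect_precision
                * (b0n**2 - state.beta[0] ** 2 + bxn**2 - state.beta[1] ** 2)
            )
            acc = np.log(rng.uniform()) < d_prior
            if acc:
                state.b -= c
                state.beta[0] = b0n
                state.beta[1] = bxn
            if adapting:
                ad_shift_b.update(float(acc))

        # ---- likelihood shape alpha (log-scale walk) --------------------
        if "alpha" not in fixed:
            a_old = state.alpha
            a_new = a_old * np.exp(ad_alpha.scale * rng.standard_normal())
            with np.errstate(over="ignore"):
                s_eta_resid = float(np.sum(eta + y * np.exp(-eta)))

            def full_ll(a):
                return (
                    n_obs * (a * np.log(a) - gammaln(a))
                    - a * s_eta_resid + (a - 1.0) * sum_log_y
                )

            d_prior = (
                (spec.shape_prior_shape - 1.0) * (np.log(a_new) - np.log(a_old))
                - spec.shape_prior_rate * (a_new - a_old)
            )
            log_r = like * (full_ll(a_new) - full_ll(a_old)) + d_prior + np.log(a_new) - np.log(a_old)
            acc = np.log(rng.uniform()) < log_r
            if acc:
                state.alpha = a_new
            if adapting:
                ad_alpha.update(float(acc))
            if post_burn:
                acc_totals["alpha"].append(float(acc))

        # ---- store -------------------------------------------------------
        if post_burn and (it - config.n_burnin) % config.thin == 0:
            out["beta"][save_i] = state.beta
            out["u"][save_i] = state.u
            out["v"][save_i] = state.v
            out["b"][save_i] = state.b
            out["tau_u"][save_i] = state.tau_u
            out["tau_v"][save_i] = state.tau_v
            out["tau_b"][save_i] = state.tau_b
            out["alpha"][save_i] = state.alpha
            lp = log_prior(state, spec, icar)
            if not prior_only:
                lp += model.loglike(state)
            out["log_posterior"][save_i] = lp
            save_i += 1

    out["acceptance"] = {kk: float(np.mean(vv)) if vv else np.nan for kk, vv in acc_totals.items()}
    return out


def run_sampler(model: SpatialGammaModel, config: SamplerConfig,
                fixed: dict | None = None, prior_only: bool = False) -> PosteriorSamples:
    """Draw from the posterior; identical (seed, config, data) give identical draws.

    ``prior_only=True`` drops the likelihood so the sampler targets the prior —
    a validity check, not a user-facing fit.
    """
    fixed = dict(fixed or {})
    lp0 = None
    state0 = model.initial_state()
    for name, val in fixed.items():
        if name in ("u", "v", "b"):
            setattr(state0, name, np.asarray(val, dtype=float))
        else:
            setattr(state0, name, float(val))
    lp0 = model.log_posterior(state0) if not prior_only else 0.0
    if not np.isfinite(lp0):
        raise RuntimeError(
            f"log posterior not finite at initialization: {lp0}; state={state0}"
        )

    chains = [_run_chain(model, config, c, fixed, prior_only) for c in range(config.n_chains)]
    stack = lambda name: np.stack([c[name] for c in chains])
    acc = {}
    for name in chains[0]["acceptance"]:
        vals = [c["acceptance"][name] for c in chains]
        acc[name] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    samples = PosteriorSamples(
        coef_names=model.coef_names,
        region_ids=model.graph.region_ids,
        beta=stack("beta"), u=stack("u"), v=stack("v"), b=stack("b"),
        tau_u=stack("tau_u"), tau_v=stack("tau_v"), tau_b=stack("tau_b"),
        alpha=stack("alpha"), log_posterior=stack("log_posterior"),
        acceptance=acc,
    )
    if not np.all(np.isfinite(samples.log_posterior)):
        raise RuntimeError("non-finite log posterior among retained draws")
    return samples


def diagnostics(samples: PosteriorSamples, rhat_warn: float = 1.05,
                ess_warn: float = 100.0) -> dict:
    """Split-R̂ and effective sample size per scalar parameter (via ArviZ).

    With a single chain R̂ is omitted (a notice is included); degenerate
    (constant) chains are flagged instead of producing spurious numbers.
    """
    import arviz as az

    if samples.n_draws < 100:
        raise ValueError("need at least 100 retained draws for diagnostics")
    idata = samples.to_inference_data()
    report = {"parameters": {}, "warnings": [], "acceptance": samples.acceptance}
    ess = az.ess(idata)
    rhat = az.rhat(idata) if samples.n_chains >= 2 else None
    if rhat is None:
        report["warnings"].append("single chain: R-hat omitted")

    def walk(ds):
        for name, da in ds.data_vars.items():
            if da.ndim == 0:
                yield name, float(da)
            else:
                for i, val in enumerate(np.asarray(da).ravel()):
                    yield f"{name}[{i}]", float(val)

    # a constant chain has no meaningful ESS, whatever the estimator returns
    variances = {}
    for name, da in idata.posterior.data_vars.items():
        arr = np.asarray(da)          # (chain, draw, ...)
        flat_var = arr.reshape(arr.shape[0] * arr.shape[1], -1).var(axis=0)
        if arr.ndim == 2:
            variances[name] = float(flat_var[0])
        else:
            for i, v in enumerate(flat_var):
                variances[f"{name}[{i}]"] = float(v)

    ess_map = dict(walk(ess))
    rhat_map = dict(walk(rhat)) if rhat is not None else {}
    for name, e in ess_map.items():
        entry = {"ess": e}
        if np.isnan(e) or variances.get(name, 1.0) == 0.0:
            entry["degenerate"] = True
            report["warnings"].append(f"{name}: degenerate (constant) chain")
        elif e < ess_warn:
            report["warnings"].append(f"{name}: ESS {e:.0f} < {ess_warn:.0f}")
        r = rhat_map.get(name)
        if r is not None:
            entry["rhat"] = r
            if np.isfinite(r) and r > rhat_warn:
                report["warnings"].append(f"{name}: R-hat {r:.3f} > {rhat_warn}")
        report["parameters"][name] = entry
    report["max_rhat"] = (
        float(np.nanmax([p.get("rhat", np.nan) for p in report["parameters"].values()]))
        if rhat_map else None
    )
    return report
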