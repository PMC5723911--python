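"""Hierarchical gamma regression with a BYM spatial intercept and random slopes.

Model
-----
For region *i* and year *t* the standardized prevalence (in percent) is

    y_it ~ Gamma(shape = alpha, mean = mu_it),        mu_it = exp(eta_it)
    eta_it = b0 + bx * x_it + b_bmi * bmi_it + b_drk * drink_it
             + b_yr * (year_t - year_bar) + u_i + v_i + s_i * (x_it - x_bar)

where ``x`` is one smoking exposure (%), ``u`` is the spatially structured
(ICAR) intercept, ``v`` the unstructured intercept and ``s_i`` a region random
slope on the exposure.  The region slope on the exposure is ``bx + s_i``
either way; applying ``s_i`` to the deviation from the sample mean exposure
``x_bar`` (rather than to raw ``x``) is a reparameterisation that keeps the
random intercepts on their natural scale and decorrelates ``v_i`` from
``s_i``, which single-site samplers need.  The fixed exposure effect stays in
natural percent units, so the national relative risk per 5 points is
``exp(5 * bx)`` and region *i*'s is ``exp(5 * (bx + s_i))``.  The gamma distribution is parameterised by shape
``alpha`` and mean, i.e. rate ``alpha / mu``, so ``E[y] = mu`` and
``Var[y] = mu^2 / alpha``.

Priors: fixed effects are independent zero-mean normals (precision 0.001 by
default); ``u`` carries the improper ICAR prior with a per-component
sum-to-zero constraint; ``v_i`` and ``s_i`` are iid zero-mean normals; every
random-effect precision has a Gamma(1, 5e-5) prior, and the likelihood shape
``alpha`` a Gamma(1, 0.01) prior.  The exposure enters in natural percentage
units so the relative risk per a 5-point increase is ``exp(5 * bx)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import gammaln

from .spatial import ICARStructure, SpatialGraph, build_icar_structure, icar_quadratic_form
from .standardize import RegionYearPanel

__all__ = [
    "ModelSpec",
    "ModelState",
    "gamma_loglik",
    "linear_predictor",
    "log_prior",
    "log_prior_components",
    "SpatialGammaModel",
]


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one outcome × exposure hierarchical fit."""

    outcome: str = "stroke"
    exposure: str = "smoking_rate"
    confounders: tuple = ("mean_bmi", "drinking_rate")
    year_term: bool = True
    #: precision of the independent zero-mean normal prior on each fixed effect
    fixed_effect_precision: float = 0.001
    #: Gamma(shape, rate) prior shared by every random-effect precision
    precision_prior_shape: float = 1.0
    precision_prior_rate: float = 5e-5
    #: Gamma(shape, rate) prior on the gamma likelihood shape alpha
    shape_prior_shape: float = 1.0
    shape_prior_rate: float = 0.01
    #: tolerance on the per-component mean of the structured intercept
    constraint_tol: float = 1e-8
    #: what to do with nonpositive prevalence cells: "drop" or "half_min"
    nonpositive_policy: str = "drop"

    def __post_init__(self):
        if self.exposure in self.confounders:
            raise ValueError("exposure must appear exactly once in the linear predictor")
        if self.nonpositive_policy not in ("drop", "half_min"):
            raise ValueError("nonpositive_policy must be 'drop' or 'half_min'")

    @property
    def coef_names(self) -> tuple:
        names = ["intercept", self.exposure, *self.confounders]
        if self.year_term:
            names.append("year_centered")
        return tuple(names)

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "confounders" in d:
            d["confounders"] = tuple(d["confounders"])
        return cls(**d)

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass
class ModelState:
    """One point in parameter space (a single MCMC state)."""

    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    b: np.ndarray
    tau_u: float
    tau_v: float
    tau_b: float
    alpha: float

    def copy(self) -> "ModelState":
        return ModelState(
            self.beta.copy(), self.u.copy(), self.v.copy(), self.b.copy(),
            self.tau_u, self.tau_v, self.tau_b, self.alpha,
        )


def gamma_loglik(y, mu, alpha):
    """Log density of Gamma(shape ``alpha``, mean ``mu``) at ``y``.

    Uses the mean parameterisation (rate = alpha / mu).  Broadcasts; all
    arguments must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(y <= 0) or np.any(mu <= 0) or np.any(alpha <= 0):
        raise ValueError("gamma_loglik requires y, mu, alpha > 0")
    out = (
        alpha * (np.log(alpha) - np.log(mu))
        - gammaln(alpha)
        + (alpha - 1.0) * np.log(y)
        - alpha * y / mu
    )
    return float(out) if out.ndim == 0 else out


def linear_predictor(panel_row: dict, coefficients: dict, random_effects: dict) -> float:
    """Evaluate eta for one observation from name-keyed pieces.

    ``panel_row`` supplies the covariates (exposure, confounders,
    ``year_centered``); ``coefficients`` maps coefficient name -> value with
    ``"intercept"`` for b0; ``random_effects`` supplies ``u``, ``v`` and the
    random slope ``b`` for the row's region (missing entries default to 0).
    """
    eta = float(coefficients.get("intercept", 0.0))
    exposure_value = None
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        if name not in panel_row:
            raise KeyError(f"covariate {name!r} missing from panel row")
        eta += float(coef) * float(panel_row[name])
    eta += float(random_effects.get("u", 0.0)) + float(random_effects.get("v", 0.0))
    slope = float(random_effects.get("b", 0.0))
    if slope != 0.0:
        exposure = random_effects.get("exposure_name")
        if exposure is None or exposure not in panel_row:
            raise KeyError("random slope supplied without an exposure value in the row")
        eta += slope * float(panel_row[exposure])
    return eta


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - gammaln(shape)


def log_prior_components(state: ModelState, spec: ModelSpec, icar: ICARStructure) -> dict:
    """Additive blocks of the log prior; ``log_prior`` is their sum.

    The ICAR block is the kernel ``(rank/2) log tau_u - (tau_u/2) u'Qu`` (the
    pseudo-determinant of Q, a constant, is dropped); it raises if any
    component mean of ``u`` exceeds the constraint tolerance.
    """
    if state.tau_u <= 0 or state.tau_v <= 0 or state.tau_b <= 0 or state.alpha <= 0:
        raise ValueError("precisions and alpha must be strictly positive")
    labels = icar.component_labels
    comp_means = np.bincount(labels, weights=state.u) / np.bincount(labels)
    if np.any(np.abs(comp_means) > spec.constraint_tol):
        raise ValueError(
            "structured intercept violates per-component sum-to-zero constraint "
            f"(max |component mean| = {np.abs(comp_means).max():.3e})"
        )
    n = icar.n_regions
    quad = icar_quadratic_form(icar, state.u)
    prec = spec.fixed_effect_precision
    k = len(state.beta)
    comps = {
        "icar_u": 0.5 * icar.rank * np.log(state.tau_u) - 0.5 * state.tau_u * quad,
        "iid_v": 0.5 * n * (np.log(state.tau_v) - np.log(2 * np.pi))
        - 0.5 * state.tau_v * np.sum(state.v**2),
        "iid_b": 0.5 * n * (np.log(state.tau_b) - np.log(2 * np.pi))
        - 0.5 * state.tau_b * np.sum(state.b**2),
        "fixed": 0.5 * k * (np.log(prec) - np.log(2 * np.pi))
        - 0.5 * prec * np.sum(state.beta**2),
        "tau_u": _gamma_logpdf(state.tau_u, spec.precision_prior_shape, spec.precision_prior_rate),
        "tau_v": _gamma_logpdf(state.tau_v, spec.precision_prior_shape, spec.precision_prior_rate),
        "tau_b": _gamma_logpdf(state.tau_b, spec.precision_prior_shape, spec.precision_prior_rate),
        "alpha": _gamma_logpdf(state.alpha, spec.shape_prior_shape, spec.shape_prior_rate),
    }
    return {k_: float(v_) for k_, v_ in comps.items()}


def log_prior(state: ModelState, spec: ModelSpec, icar: ICARStructure) -> float:
    return float(sum(log_prior_components(state, spec, icar).values()))


class SpatialGammaModel:
    """Bayesian hierarchical gamma regression on a region-year panel.

    Parameters
    ----------
    panel : RegionYearPanel
        Observation table from the standardization stage (or the synthetic
        generator).
    graph : SpatialGraph
        Region adjacency; must cover every region in the panel.
    spec : ModelSpec
        Outcome, exposure, confounders and priors.

    Examples
    --------
    >>> model = SpatialGammaModel(panel, graph, ModelSpec(outcome="stroke"))
    >>> res = model.fit(SamplerConfig(n_iter=4000, n_burnin=2000, seed=1))
    >>> res.rr_national()
    """

    def __init__(self, panel: RegionYearPanel, graph: SpatialGraph, spec: ModelSpec):
        self.spec = spec
        self.graph = graph
        self.icar = build_icar_structure(graph)
        obs = panel.observations(spec.outcome).copy()
        missing_regions = set(obs["region_id"].astype(str)) - set(graph.region_ids)
        if missing_regions:
            raise ValueError(f"panel regions absent from graph: {sorted(missing_regions)[:5]}")
        if obs["region_id"].nunique() < 2:
            raise ValueError("model needs at least 2 regions")
        for c in (spec.exposure, *spec.confounders):
            if c not in obs.columns:
                raise KeyError(f"covariate {c!r} missing from panel")
            if obs[c].isna().any():
                raise ValueError(f"covariate {c!r} has missing values")

        nonpos = obs["prevalence"] <= 0
        if nonpos.any():
            if spec.nonpositive_policy == "drop":
                warnings.warn(
                    f"dropping {int(nonpos.sum())} nonpositive prevalence cells "
                    f"for outcome {spec.outcome!r}", stacklevel=2,
                )
                obs = obs[~nonpos]
            else:
                half_min = 0.5 * obs.loc[~nonpos, "prevalence"].min()
                obs.loc[nonpos, "prevalence"] = half_min
        if obs.empty:
            raise ValueError("no positive prevalence observations remain")

        obs = obs.sort_values(["region_id", "year"]).reset_index(drop=True)
        self.data = obs
        self.year_center = float(np.mean(sorted(obs["year"].unique())))
        ridx_map = {r: i for i, r in enumerate(graph.region_ids)}
        self.region_index = obs["region_id"].astype(str).map(ridx_map).to_numpy(dtype=np.intp)
        self.y = obs["prevalence"].to_numpy(dtype=float)
        self.x = obs[spec.exposure].to_numpy(dtype=float)
        self.x_center = float(self.x.mean())
        cols = [np.ones(len(obs)), self.x]
        cols += [obs[c].to_numpy(dtype=float) for c in spec.confounders]
        if spec.year_term:
            cols.append(obs["year"].to_numpy(dtype=float) - self.year_center)
        self.exog = np.column_stack(cols)
        self.coef_names = spec.coef_names
        self.n_obs = len(obs)
        self.n_regions = graph.n_regions

    # -- densities ---------------------------------------------------------
    def eta(self, state: ModelState) -> np.ndarray:
        re = (state.u + state.v)[self.region_index] + state.b[self.region_index] * (
            self.x - self.x_center
        )
        return self.exog @ state.beta + re

    def loglike(self, state: ModelState) -> float:
        mu = np.exp(self.eta(state))
        return float(np.sum(gamma_loglik(self.y, mu, state.alpha)))

    def log_posterior(self, state: ModelState) -> float:
        return self.loglike(state) + log_prior(state, self.spec, self.icar)

    # -- initialisation ----------------------------------------------------
    def initial_state(self) -> ModelState:
        """Deterministic start: log-linear least squares for the fixed effects,
        random effects at zero, precisions at 1, alpha at a method-of-moments
        estimate from the least-squares residuals."""
        beta, *_ = np.linalg.lstsq(self.exog, np.log(self.y), rcond=None)
        resid = np.log(self.y) - self.exog @ beta
        # for log Gamma(alpha, mean mu): Var(log y) ~ trigamma(alpha) ~ 1/alpha
        alpha = float(np.clip(1.0 / max(np.var(resid), 1e-6), 0.5, 1e4))
        n = self.n_regions
        return ModelState(
            beta=beta.astype(float),
            u=np.zeros(n), v=np.zeros(n), b=np.zeros(n),
            tau_u=1.0, tau_v=1.0, tau_b=1.0, alpha=alpha,
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, config=None, fixed: dict | None = None):
        """Run the Metropolis-within-Gibbs sampler and wrap the draws.

        ``fixed`` maps parameter names (``"tau_u"``, ``"tau_v"``, ``"tau_b"``,
        ``"alpha"``, ``"u"``, ``"v"``, ``"b"``) to values held constant during
        sampling — used for oracle comparisons and degenerate-limit checks.
        """
        from .mcmc import SamplerConfig, run_sampler
        from .results import SpatialGammaResults

        if config is None:
            config = SamplerConfig()
        samples = run_sampler(self, config, fixed=fixed)
        return SpatialGammaResults(self, samples, config)
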