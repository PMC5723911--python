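"""Posterior summaries: relative risks per exposure increase, rankings, export.

The effect scale is the relative risk (RR) of the outcome prevalence per a
``delta``-percentage-point increase in the exposure: with a log link,
``RR = exp(delta * beta_x)`` nationally and ``exp(delta * (beta_x + b_i))``
for region *i* with random slope ``b_i``.  Summaries are the posterior mean
of the RR draws (the median is available via ``point="median"``) and the
equal-tailed 95% credibility interval from the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RRSummary",
    "RegionRanking",
    "rr_from_slope",
    "regional_rr",
    "rank_regions",
    "export_region_table",
    "SpatialGammaResults",
]

DEFAULT_DELTA = 5.0


@dataclass(frozen=True)
class RRSummary:
    """Relative risk with 95% equal-tailed credibility interval."""

    level: str                 # "national" or a region id
    rr_mean: float
    rr_ci_low: float
    rr_ci_high: float
    delta: float = DEFAULT_DELTA

    def __post_init__(self):
        if not (0 < self.rr_ci_low <= self.rr_ci_high):
            raise ValueError("require 0 < ci_low <= ci_high")

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes 1 (the no-association value)."""
        return self.rr_ci_low > 1.0 or self.rr_ci_high < 1.0


@dataclass(frozen=True)
class RegionRanking:
    """Regions ordered by RR point estimate (descending, ties by id)."""

    ordered: tuple        # of (region_id, rr_mean), descending
    top: tuple
    bottom: tuple
    k: int


def _summarize(rr_draws: np.ndarray, level: str, delta: float, point: str) -> RRSummary:
    lo, hi = np.percentile(rr_draws, [2.5, 97.5])
    est = float(np.mean(rr_draws) if point == "mean" else np.median(rr_draws))
    return RRSummary(level, est, float(lo), float(hi), delta)


def rr_from_slope(beta_draws, delta: float = DEFAULT_DELTA, level: str = "national",
                  point: str = "mean") -> RRSummary:
    """RR summary from posterior slope draws: per-draw ``RR = exp(delta * beta)``."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.size == 0:
        raise ValueError("empty draw vector")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return _summarize(np.exp(delta * beta_draws), level, delta, point)


def regional_rr(samples, delta: float = DEFAULT_DELTA, point: str = "mean") -> list:
    """Per-region RR summaries from ``exp(delta * (beta_x + b_i))`` draws.

    ``samples`` is a :class:`~bymgamma.mcmc.PosteriorSamples`; the exposure
    slope is the second fixed-effect coordinate by construction.
    """
    beta_x = samples.stacked("beta")[:, 1]
    b = samples.stacked("b")
    out = []
    for j, region in enumerate(samples.region_ids):
        draws = np.exp(delta * (beta_x + b[:, j]))
        out.append(_summarize(draws, str(region), delta, point))
    return out


def rank_regions(summaries, k: int) -> RegionRanking:
    """Top-k and bottom-k regions by RR point estimate (ties broken by id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(summaries):
        raise ValueError(f"k={k} exceeds number of regions ({len(summaries)})")
    ordered = tuple(
        (s.level, s.rr_mean)
        for s in sorted(summaries, key=lambda s: (-s.rr_mean, s.level))
    )
    return RegionRanking(ordered, ordered[:k], ordered[-k:][::-1], k)


def export_region_table(summaries, path, outcome: str = "", exposure: str = "") -> pd.DataFrame:
    """Write per-region RR summaries to CSV (joinable to boundary files)."""
    if not summaries:
        warnings.warn("exporting an empty region RR table", stacklevel=2)
    df = pd.DataFrame(
        [
            {
                "region_id": s.level, "outcome": outcome, "exposure": exposure,
                "rr_mean": s.rr_mean, "rr_ci_low": s.rr_ci_low,
                "rr_ci_high": s.rr_ci_high, "delta": s.delta,
            }
            for s in summaries
        ],
        columns=["region_id", "outcome", "exposure", "rr_mean", "rr_ci_low",
                 "rr_ci_high", "delta"],
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return df


class SpatialGammaResults:
    """Fit results: posterior draws plus summary, effect and diagnostic views."""

    def __init__(self, model, samples, config):
        self.model = model
        self.samples = samples
        self.config = config

    # -- parameter summaries ----------------------------------------------
    def posterior_table(self) -> pd.DataFrame:
        """Posterior mean, sd and 95% CI for fixed effects and hyperparameters."""
        rows = []
        for i, name in enumerate(self.samples.coef_names):
            draws = self.samples.stacked("beta")[:, i]
            rows.append(self._row(f"beta[{name}]", draws))
        for name in ("tau_u", "tau_v", "tau_b", "alpha"):
            rows.append(self._row(name, self.samples.stacked(name)))
        return pd.DataFrame(rows).set_index("parameter")

    @staticmethod
    def _row(name, draws):
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return {
            "parameter": name, "mean": float(np.mean(draws)), "sd": float(np.std(draws)),
            "ci_2.5%": float(lo), "ci_97.5%": float(hi),
        }

    def summary(self, delta: float = DEFAULT_DELTA) -> str:
        spec = self.model.spec
        tab = self.posterior_table()
        rr = self.rr_national(delta)
        lines = [
            "Bayesian hierarchical gamma regression (BYM intercept + random slopes)",
            f"outcome: {spec.outcome}   exposure: {spec.exposure}",
            f"regions: {self.model.n_regions}   observations: {self.model.n_obs}   "
            f"chains: {self.samples.n_chains}   draws/chain: {self.samples.n_draws}",
            "",
            tab.to_string(float_format=lambda v: f"{v:10.4f}"),
            "",
            f"national RR per {delta:g}-point {spec.exposure} increase: "
            f"{rr.rr_mean:.3f} (95% CI {rr.rr_ci_low:.3f}, {rr.rr_ci_high:.3f})"
            + ("  *" if rr.significant else ""),
        ]
        return "\n".join(lines)

    # -- effects -----------------------------------------------------------
    def rr_national(self, delta: float = DEFAULT_DELTA, point: str = "mean") -> RRSummary:
        return rr_from_slope(self.samples.beta_draws(self.model.spec.exposure),
                             delta=delta, point=point)

    def rr_regional(self, delta: float = DEFAULT_DELTA, point: str = "mean") -> list:
        return regional_rr(self.samples, delta=delta, point=point)

    def rank_regions(self, k: int = 5, delta: float = DEFAULT_DELTA) -> RegionRanking:
        return rank_regions(self.rr_regional(delta), k)

    def export_region_table(self, path, delta: float = DEFAULT_DELTA) -> pd.DataFrame:
        return export_region_table(
            self.rr_regional(delta), path,
            outcome=self.model.spec.outcome, exposure=self.model.spec.exposure,
        )

    # -- diagnostics & plots ------------------------------------------------
    def diagnostics(self, **kw) -> dict:
        from .mcmc import diagnostics

        return diagnostics(self.samples, **kw)

    def to_inference_data(self):
        return self.samples.to_inference_data()

    def plot_trace(self, var_names=None):
        """Trace plot of fixed effects and hyperparameters (matplotlib axes)."""
        import arviz as az

        if var_names is None:
            var_names = [f"beta_{n}" for n in self.samples.coef_names] + [
                "tau_u", "tau_v", "tau_b", "alpha"
            ]
        return az.plot_trace(self.to_inference_data(), var_names=var_names)
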