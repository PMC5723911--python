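"""Direct sex/age standardization of survey prevalence into a region-year panel.

Direct standardization removes demographic composition differences between
regions: the standardized rate is ``100 * sum_s w_s * r_s`` where ``r_s`` is
the stratum-specific mean of a binary indicator (complete-case within the
sex × age-group stratum) and ``w_s`` the stratum share of a standard
population.  Disease prevalence is computed on an outcome-specific
age-restricted subset (hypertension ≥30, stroke ≥50, myocardial infarction
and angina ≥40 years); smoking exposures and the drinking rate are
standardized over all adults, and BMI enters as a plain arithmetic mean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AGE_CUTOFFS",
    "DEFAULT_AGE_BANDS",
    "OUTCOMES",
    "EXPOSURES",
    "StandardPopulation",
    "RegionYearPanel",
    "age_restrict",
    "direct_standardize",
    "build_panel",
    "normality_screen",
]

OUTCOMES = ("hypertension", "stroke", "myocardial_infarction", "angina")
#: minimum age (years) at which each disease outcome is assessed
AGE_CUTOFFS = {"hypertension": 30, "stroke": 50, "myocardial_infarction": 40, "angina": 40}
EXPOSURES = ("smoking_rate", "passive_home_rate", "passive_work_rate")
#: survey record column holding each exposure indicator
EXPOSURE_FLAGS = {
    "smoking_rate": "current_smoker",
    "passive_home_rate": "passive_home",
    "passive_work_rate": "passive_work",
}

DEFAULT_AGE_BANDS = (
    "19-24", "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

_BAND_RE = re.compile(r"^(\d+)\s*(?:-\s*(\d+)|\+)$")


def band_bounds(band: str) -> tuple[int, float]:
    """Parse an age-band label like ``"30-34"`` or ``"80+"`` into (low, high)."""
    m = _BAND_RE.match(str(band).strip())
    if not m:
        raise ValueError(f"unparseable age band label: {band!r}")
    lo = int(m.group(1))
    hi = float(m.group(2)) if m.group(2) is not None else np.inf
    if hi < lo:
        raise ValueError(f"age band upper bound below lower bound: {band!r}")
    return lo, hi


class StandardPopulation:
    """Sex × age-group weights defining the standard population.

    Weights are normalized to sum to one on construction.
    """

    def __init__(self, weights: dict):
        w = {(str(s), str(a)): float(x) for (s, a), x in weights.items()}
        if any(x < 0 for x in w.values()):
            raise ValueError("standard population weights must be nonnegative")
        total = sum(w.values())
        if total <= 0:
            raise ValueError("at least one stratum must have positive weight")
        self.weights = {k: v / total for k, v in w.items()}

    def __contains__(self, stratum):
        return tuple(map(str, stratum)) in self.weights

    def weight(self, sex, age_group) -> float:
        return self.weights.get((str(sex), str(age_group)), 0.0)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "StandardPopulation":
        """Empirical sex × age distribution of a record set."""
        counts = records.groupby(["sex", "age_group"], observed=True).size()
        return cls({k: float(v) for k, v in counts.items()})

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        df = pd.read_csv(path)
        need = {"sex", "age_group", "weight"}
        if not need <= set(df.columns):
            raise ValueError(f"standard population file needs columns {sorted(need)}")
        return cls({(r.sex, r.age_group): r.weight for r in df.itertuples()})

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, a, w) for (s, a), w in sorted(self.weights.items())]
        return pd.DataFrame(rows, columns=["sex", "age_group", "weight"])


@dataclass
class RegionYearPanel:
    """Observation table for the hierarchical model.

    ``prevalence``: one row per (region_id, year, outcome) with the
    standardized prevalence in percent, the respondent count of the
    age-restricted cell, and flags for nonpositive values / small cells.
    ``covariates``: one row per (region_id, year) with standardized exposure
    rates (%), mean BMI (kg/m^2) and the standardized monthly drinking rate (%).
    """

    prevalence: pd.DataFrame
    covariates: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        dup = self.prevalence.duplicated(["region_id", "year", "outcome"])
        if dup.any():
            raise ValueError("duplicate (region, year, outcome) rows in panel")

    @property
    def region_ids(self) -> tuple:
        return tuple(sorted(self.covariates["region_id"].astype(str).unique()))

    @property
    def years(self) -> tuple:
        return tuple(sorted(self.covariates["year"].unique()))

    def observations(self, outcome: str) -> pd.DataFrame:
        """Merged response + covariate rows for one outcome."""
        prev = self.prevalence[self.prevalence["outcome"] == outcome]
        if prev.empty:
            raise KeyError(f"outcome {outcome!r} not present in panel")
        return prev.merge(self.covariates, on=["region_id", "year"], validate="1:1")

    def to_csv(self, prevalence_path, covariates_path) -> None:
        self.prevalence.to_csv(prevalence_path, index=False)
        self.covariates.to_csv(covariates_path, index=False)

    @classmethod
    def from_csv(cls, prevalence_path, covariates_path) -> "RegionYearPanel":
        prev = pd.read_csv(prevalence_path, dtype={"region_id": str})
        cov = pd.read_csv(covariates_path, dtype={"region_id": str})
        return cls(prev, cov)


def age_restrict(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Subset records to the outcome's assessment ages (30/50/40/40 and up).

    Raises if any age band present straddles the cutoff, since such a band
    cannot be assigned unambiguously.
    """
    if outcome not in AGE_CUTOFFS:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    cutoff = AGE_CUTOFFS[outcome]
    keep = []
    for band in records["age_group"].unique():
        lo, hi = band_bounds(band)
        if lo >= cutoff:
            keep.append(band)
        elif hi >= cutoff:
            raise ValueError(
                f"age band {band!r} straddles the {outcome} cutoff of {cutoff} years; "
                "reconfigure bands so every band lies entirely on one side"
            )
    return records[records["age_group"].isin(keep)]


def direct_standardize(
    records: pd.DataFrame,
    variable: str,
    standard: StandardPopulation,
    redistribute_empty: bool = True,
) -> float:
    """Directly standardized rate of a binary indicator, in percent.

    Stratum rates use complete cases within the stratum; strata with no
    non-missing observation carry no rate, and by default their standard
    weight is redistributed proportionally over the observed strata (set
    ``redistribute_empty=False`` to drop that weight instead).
    """
    if records.empty:
        raise ValueError("cannot standardize an empty record set")
    if variable not in records.columns:
        raise KeyError(f"variable {variable!r} not in records")
    vals = pd.to_numeric(records[variable], errors="coerce")
    grp = vals.groupby(
        [records["sex"].astype(str), records["age_group"].astype(str)], observed=True
    )
    rates = grp.mean()
    rates = rates.dropna()
    if rates.empty:
        raise ValueError(f"all records missing on {variable!r}")
    w = np.array([standard.weight(s, a) for s, a in rates.index])
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("no positive standard weight on any observed stratum")
    if redistribute_empty:
        w = w / total_w
    return float(100.0 * np.sum(w * rates.values))


def build_panel(
    records: pd.DataFrame,
    standard_by_year: dict | None = None,
    min_cell_size: int = 10,
    redistribute_empty: bool = True,
) -> RegionYearPanel:
    """Standardize survey records into a :class:`RegionYearPanel`.

    ``standard_by_year`` maps year -> :class:`StandardPopulation`; when omitted,
    each year's pooled sample demography serves as that year's standard (the
    default reference population; see package docs).
    """
    records = records.copy()
    records["region_id"] = records["region_id"].astype(str)
    years = sorted(records["year"].unique())
    if standard_by_year is None:
        standard_by_year = {
            y: StandardPopulation.from_records(records[records["year"] == y]) for y in years
        }
    missing = [y for y in years if y not in standard_by_year]
    if missing:
        raise ValueError(f"no standard population supplied for years {missing}")

    prev_rows, cov_rows = [], []
    for (region, year), cell in records.groupby(["region_id", "year"], observed=True):
        std = standard_by_year[year]
        for outcome in OUTCOMES:
            sub = age_restrict(cell, outcome)
            n = int(sub[outcome].notna().sum()) if outcome in sub else 0
            if n == 0:
                continue
            p = direct_standardize(sub, outcome, std, redistribute_empty)
            prev_rows.append(
                {
                    "region_id": region,
                    "year": year,
                    "outcome": outcome,
                    "prevalence": p,
                    "n_respondents": n,
                    "nonpositive": p <= 0.0,
                    "low_n": n < min_cell_size,
                }
            )
        cov = {"region_id": region, "year": year}
        for rate_name, flag in EXPOSURE_FLAGS.items():
            cov[rate_name] = (
                direct_standardize(cell, flag, std, redistribute_empty)
                if cell[flag].notna().any()
                else np.nan
            )
        cov["mean_bmi"] = float(pd.to_numeric(cell["bmi"], errors="coerce").mean())
        cov["drinking_rate"] = (
            direct_standardize(cell, "drinks_monthly", std, redistribute_empty)
            if cell["drinks_monthly"].notna().any()
            else np.nan
        )
        cov["n_respondents"] = int(len(cell))
        cov_rows.append(cov)

    panel = RegionYearPanel(
        pd.DataFrame(prev_rows),
        pd.DataFrame(cov_rows),
        meta={"min_cell_size": min_cell_size, "years": years},
    )
    return panel


def normality_screen(panel: RegionYearPanel, outcome: str, alpha: float = 0.05) -> dict:
    """Shapiro–Wilk screen of the pooled standardized prevalence values.

    Informational only: a "non-normal" verdict motivates the gamma response
    family but never gates model fitting.
    """
    vals = panel.prevalence.loc[
        panel.prevalence["outcome"] == outcome, "prevalence"
    ].to_numpy(dtype=float)
    if len(vals) < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 values")
    if len(vals) > 5000:
        raise ValueError("Shapiro–Wilk is unreliable above 5000 values; subsample first")
    if np.ptp(vals) == 0:
        return {"statistic": np.nan, "p_value": np.nan, "verdict": "degenerate"}
    stat, p = stats.shapiro(vals)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "verdict": "non-normal" if p < alpha else "normal",
    }
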