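"""Posterior summaries of the family-planning indicators.

All summaries transform first, then summarize: every posterior draw of the
latent logit field is pushed through the inverse logit (or through the
demand-satisfied / annual-change arithmetic) before medians and 2.5/97.5
percentiles are taken, so the reported intervals are genuine posterior
intervals of the reported quantity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .smoother import PosteriorDraws

SUMMARY_COLUMNS = (
    "area", "year", "subgroup", "outcome",
    "median", "ci_lower", "ci_upper", "n_draws",
)
CHANGE_COLUMNS = (
    "area", "year_from", "year_to",
    "median", "ci_lower", "ci_upper", "prob_positive", "n_draws",
)

OUTCOME_LABELS = {
    "modern": "mCPR",
    "traditional": "traditional CPR",
    "unmet": "unmet need",
}


def _summarize_grid(values: np.ndarray, areas, years, subgroup, outcome) -> pd.DataFrame:
    """Median and central 95% interval per cell of a (draws, areas, years) array."""
    med = np.median(values, axis=0)
    lo = np.percentile(values, 2.5, axis=0)
    hi = np.percentile(values, 97.5, axis=0)
    rows = []
    for i, a in enumerate(areas):
        for j, yr in enumerate(years):
            rows.append({
                "area": a, "year": int(yr), "subgroup": subgroup,
                "outcome": outcome, "median": float(med[i, j]),
                "ci_lower": float(lo[i, j]), "ci_upper": float(hi[i, j]),
                "n_draws": values.shape[0],
            })
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def summarize_indicator(
    draws: PosteriorDraws, outcome: str = "modern", subgroup: str = "all"
) -> pd.DataFrame:
    """Posterior median and 95% interval of the prevalence per area-year."""
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    p = expit(draws.eta)
    return _summarize_grid(
        p, draws.areas, draws.years, subgroup, OUTCOME_LABELS.get(outcome, outcome)
    )


def _matched_prob_draws(
    draws_m: PosteriorDraws, draws_t: PosteriorDraws, draws_u: PosteriorDraws
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for other, name in ((draws_t, "traditional"), (draws_u, "unmet")):
        if other.areas != draws_m.areas or other.years != draws_m.years:
            raise ValueError(f"draw grids differ between modern and {name} fits")
        if other.n_draws != draws_m.n_draws:
            raise ValueError(
                f"draw counts differ between modern ({draws_m.n_draws}) and "
                f"{name} ({other.n_draws}) fits; fit with matched configs"
            )
    return expit(draws_m.eta), expit(draws_t.eta), expit(draws_u.eta)


def demand_satisfied(
    draws_m: PosteriorDraws, draws_t: PosteriorDraws, draws_u: PosteriorDraws
) -> pd.DataFrame:
    """Demand for family planning satisfied by modern methods (SDG 3.7.1).

    Per draw and cell: DS = m / (m + t + u), combining the three outcome fits
    draw-by-draw (matched by draw index) so the ratio's uncertainty is
    propagated.  A draw with m + t + u = 0 contributes DS = 0 (and is logged).
    """
    m, t, u = _matched_prob_draws(draws_m, draws_t, draws_u)
    denom = m + t + u
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} draw-cells with zero total demand; DS set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ds = np.where(zero, 0.0, m / np.where(zero, 1.0, denom))
    return _summarize_grid(ds, draws_m.areas, draws_m.years, "all", "demand satisfied")


def annual_rate_of_change(
    draws: PosteriorDraws, year_from: int = 2012, year_to: int = 2017
) -> pd.DataFrame:
    """Average annual change of the prevalence, in percentage points per year.

    Per draw and area: (p_to - p_from) / (year_to - year_from) * 100 on the
    probability scale; the summary reports the posterior median, 95% interval
    and the posterior probability that the change is positive.
    """
    for yr in (year_from, year_to):
        if yr not in draws.years:
            raise ValueError(f"year {yr} not on the fitted grid {draws.years}")
    if year_to <= year_from:
        raise ValueError("year_to must exceed year_from")
    i_from = draws.years.index(year_from)
    i_to = draws.years.index(year_to)
    p = expit(draws.eta)
    slope = (p[:, :, i_to] - p[:, :, i_from]) / (year_to - year_from) * 100.0
    rows = []
    for i, a in enumerate(draws.areas):
        s = slope[:, i]
        rows.append({
            "area": a, "year_from": int(year_from), "year_to": int(year_to),
            "median": float(np.median(s)),
            "ci_lower": float(np.percentile(s, 2.5)),
            "ci_upper": float(np.percentile(s, 97.5)),
            "prob_positive": float((s > 0).mean()),
            "n_draws": len(s),
        })
    return pd.DataFrame(rows, columns=list(CHANGE_COLUMNS))


def count_significant_increases(changes: pd.DataFrame) -> dict[str, int]:
    """How many areas changed significantly / had positive medians.

    "Significant" means the 95% credible interval excludes zero from below.
    Both counts are reported separately; a positive median with an interval
    straddling zero is suggestive, not significant.
    """
    if len(changes) == 0:
        raise ValueError("no change summaries")
    return {
        "significant_increases": int((changes["ci_lower"] > 0).sum()),
        "positive_medians": int((changes["median"] > 0).sum()),
    }


def aggregate_national(draws: PosteriorDraws, populations: pd.DataFrame,
                       outcome: str = "modern") -> pd.DataFrame:
    """Population-weighted national prevalence per year.

    ``populations`` needs columns area, year, women_15_49 covering every
    area on the grid (years missing from the table reuse the nearest
    available year's counts).
    """
    req = {"area", "year", "women_15_49"}
    if not req <= set(populations.columns):
        raise ValueError(f"populations table needs columns {sorted(req)}")
    if (populations["women_15_49"] <= 0).any():
        raise ValueError("populations must be positive")
    missing = set(draws.areas) - set(populations["area"])
    if missing:
        raise ValueError(f"missing population for areas: {sorted(missing)}")
    p = expit(draws.eta)  # (D, n, T)
    rows = []
    for j, yr in enumerate(draws.years):
        sub = populations[populations["year"] == yr]
        if len(sub) == 0:
            nearest = populations.loc[(populations["year"] - yr).abs().idxmin(), "year"]
            sub = populations[populations["year"] == nearest]
        pops = sub.set_index("area")["women_15_49"]
        if not set(draws.areas) <= set(pops.index):
            missing = sorted(set(draws.areas) - set(pops.index))
            raise ValueError(f"missing population for areas: {missing} in year {yr}")
        w = pops.loc[list(draws.areas)].to_numpy(float)
        w = w / w.sum()
        nat = p[:, :, j] @ w  # (D,)
        rows.append({
            "area": "national", "year": int(yr), "subgroup": "all",
            "outcome": OUTCOME_LABELS.get(outcome, outcome),
            "median": float(np.median(nat)),
            "ci_lower": float(np.percentile(nat, 2.5)),
            "ci_upper": float(np.percentile(nat, 97.5)),
            "n_draws": p.shape[0],
        })
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
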