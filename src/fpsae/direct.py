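"""Design-based direct estimation from individual survey records.

Stage 1 of the two-stage small-area workflow: for every (area, survey,
subgroup, outcome) cell compute the Hájek weighted prevalence and its
with-replacement Taylor-linearization variance, then move to the logit scale
with the delta method.  The resulting table — logit estimates with known
design-based variances — is the pseudo-likelihood the smoothing model treats
as Gaussian observations of the latent rates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

OUTCOME_COLUMNS = {
    "modern": "uses_modern",
    "traditional": "uses_traditional",
    "unmet": "unmet_need",
}

SUBGROUP_ALL = "all"
AGE_PARITY_SUBGROUPS = (
    "nulliparous 15-24",
    "parous 15-24",
    "nulliparous 25+",
    "parous 25+",
)

ESTIMATE_COLUMNS = (
    "area", "survey_id", "instrument_type", "year", "subgroup", "outcome",
    "p_hat", "var_p", "n", "n_psu", "y_logit", "v_logit", "adjusted",
)


class NoDataError(ValueError):
    """Raised when an estimator is asked for a cell with no records."""


def weighted_prevalence(records: pd.DataFrame, outcome: str) -> tuple[float, float]:
    """Hájek ratio estimate p_hat = sum(w*y) / sum(w) and the weight total.

    Scale-invariant in the weights, so it is indifferent to whether released
    weights are normalized.
    """
    if len(records) == 0:
        raise NoDataError(f"no records for outcome {outcome!r}")
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    if col not in records.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    w = records["weight"].to_numpy(float)
    if (w <= 0).any():
        raise ValueError("all weights must be positive")
    y = records[col].to_numpy(float)
    W = w.sum()
    return float((w * y).sum() / W), float(W)


def _collapse_lone_strata(records: pd.DataFrame) -> tuple[pd.Series, bool]:
    """Merge single-PSU strata with the adjacent stratum in sort order.

    Returns the (possibly relabelled) stratum assignment and whether any
    collapse happened.  Strata are merged left-to-right within the cell;
    repeated until no mergeable lone stratum remains.
    """
    strata = records["stratum"].astype(str).copy()
    collapsed = False
    while True:
        psu_counts = records.groupby(strata)["cluster"].nunique()
        lone = psu_counts[psu_counts < 2].index.tolist()
        if not lone or len(psu_counts) < 2:
            break
        order = sorted(psu_counts.index)
        target = lone[0]
        pos = order.index(target)
        partner = order[pos - 1] if pos > 0 else order[pos + 1]
        merged = f"{min(target, partner)}+{max(target, partner)}"
        strata = strata.replace({target: merged, partner: merged})
        collapsed = True
    return strata, collapsed


def design_variance(
    records: pd.DataFrame,
    outcome: str = "modern",
    lone_psu: str = "collapse",
) -> tuple[float, bool]:
    """With-replacement between-PSU linearization variance of the Hájek ratio.

    Within each stratum h the weighted score totals of its PSUs are
    contrasted against their stratum mean and scaled by n_h/(n_h-1); strata
    contributions add, and everything is normalized by the squared weight
    total.  Collapses to the usual with-replacement SRS formula when every
    observation is its own PSU with equal weights.

    ``lone_psu`` picks the rule for single-PSU strata: "collapse" (merge with
    the neighbouring stratum in sort order; default), "certainty" (contributes
    zero variance), or "fail".

    Returns (variance, adjusted_flag); the flag records that a lone-PSU rule
    fired.
    """
    if len(records) == 0:
        raise NoDataError("no records")
    if lone_psu not in ("collapse", "certainty", "fail"):
        raise ValueError(f"unknown lone_psu rule {lone_psu!r}")
    col = OUTCOME_COLUMNS.get(outcome, outcome)
    p_hat, W = weighted_prevalence(records, outcome)
    w = records["weight"].to_numpy(float)
    y = records[col].to_numpy(float)
    z = w * (y - p_hat) / W  # linearized score contributions

    strata = records["stratum"].astype(str)
    adjusted = False
    if lone_psu == "collapse":
        strata, adjusted = _collapse_lone_strata(records)

    df = pd.DataFrame({
        "stratum": strata.to_numpy(),
        "cluster": records["cluster"].astype(str).to_numpy(),
        "z": z,
    })
    psu_totals = df.groupby(["stratum", "cluster"], sort=True)["z"].sum()
    var = 0.0
    lone_strata = []
    for stratum, zh in psu_totals.groupby(level=0, sort=True):
        n_h = len(zh)
        if n_h < 2:
            lone_strata.append(stratum)
            continue
        var += n_h / (n_h - 1) * float(((zh - zh.mean()) ** 2).sum())
    if lone_strata:
        if lone_psu == "fail":
            raise ValueError(f"single-PSU strata with no variance contribution: {lone_strata}")
        adjusted = True  # certainty rule, or an uncollapsible lone stratum
    return float(var), adjusted


def boundary_adjust(p_hat: float, n_eff: float) -> tuple[float, bool]:
    """Pull estimates off the {0, 1} boundary before the logit transform.

    Adds half a pseudo-observation per effective sample:
    ``(p_hat * n_eff + 0.5) / (n_eff + 1)``.  Off the boundary the estimate
    passes through untouched.
    """
    if n_eff <= 0:
        raise ValueError(f"n_eff must be positive, got {n_eff}")
    if p_hat < 0 or p_hat > 1:
        raise ValueError(f"p_hat outside [0, 1]: {p_hat}")
    if p_hat == 0.0 or p_hat == 1.0:
        return (p_hat * n_eff + 0.5) / (n_eff + 1.0), True
    return float(p_hat), False


def logit_transform(p_hat: float, var_p: float) -> tuple[float, float]:
    """Logit of the estimate with its delta-method variance.

    y = log(p/(1-p)); v = var_p / (p(1-p))^2.  The transformed pair is the
    Gaussian pseudo-observation the smoothing model consumes.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError(
            f"p_hat={p_hat} is on the boundary; apply boundary_adjust first"
        )
    if var_p < 0:
        raise ValueError("var_p must be >= 0")
    y = float(np.log(p_hat / (1.0 - p_hat)))
    v = float(var_p / (p_hat * (1.0 - p_hat)) ** 2)
    return y, v


def _subgroup_label(age_group: str, parity: str) -> str:
    return f"{parity} {age_group}"


def _cell_estimate(cell: pd.DataFrame, outcome: str, lone_psu: str) -> dict:
    p_hat, _ = weighted_prevalence(cell, outcome)
    var_p, var_adj = design_variance(cell, outcome, lone_psu=lone_psu)
    n = int(len(cell))
    n_eff = p_hat * (1 - p_hat) / var_p if var_p > 0 else float(n)
    p_adj, bnd_adj = boundary_adjust(p_hat, n_eff)
    floor = p_adj * (1 - p_adj) / n_eff
    var_adj_p = var_p
    if bnd_adj or var_p <= 0:
        var_adj_p = max(var_p, floor)
    y, v = logit_transform(p_adj, var_adj_p)
    return {
        "p_hat": p_hat,
        "var_p": var_p,
        "n": n,
        "n_psu": int(cell["cluster"].nunique()),
        "y_logit": y,
        "v_logit": v,
        "adjusted": bool(bnd_adj or var_adj or var_p <= 0),
    }


def direct_estimates_table(
    records: pd.DataFrame,
    grouping: str = SUBGROUP_ALL,
    outcomes: tuple[str, ...] = tuple(OUTCOME_COLUMNS),
    n_min: int = 10,
    lone_psu: str = "collapse",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct estimates for every (area, survey, subgroup, outcome) cell.

    ``grouping`` is "all" (all women pooled) or "age-parity" (the four
    age x parity subgroups).  Cells with fewer than ``n_min`` records are
    dropped and reported in the second return value (the drop log); a tiny
    cell's logit-scale asymptotics would be meaningless, not just noisy.
    """
    if grouping not in (SUBGROUP_ALL, "age-parity"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rows, dropped = [], []
    if grouping == SUBGROUP_ALL:
        groups = [(SUBGROUP_ALL, records)]
    else:
        groups = [
            (_subgroup_label(ag, par), records[
                (records["age_group"] == ag) & (records["parity"] == par)
            ])
            for par in ("nulliparous", "parous")
            for ag in ("15-24", "25+")
        ]
    for subgroup, sub in groups:
        for (area, survey_id), cell in sub.groupby(["area", "survey_id"], sort=True):
            meta = {
                "area": area,
                "survey_id": survey_id,
                "instrument_type": cell["instrument_type"].iloc[0],
                "year": int(cell["year"].iloc[0]),
                "subgroup": subgroup,
            }
            if len(cell) < n_min:
                dropped.append({**meta, "n": int(len(cell)), "reason": f"n < {n_min}"})
                continue
            for outcome in outcomes:
                rows.append({**meta, "outcome": outcome,
                             **_cell_estimate(cell, outcome, lone_psu)})
    est = pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))
    drop_log = pd.DataFrame(
        dropped, columns=["area", "survey_id", "instrument_type", "year",
                          "subgroup", "n", "reason"],
    )
    return est, drop_log


class DirectEstimator(TransformerMixin, BaseEstimator):
    """Transformer from individual records to the direct-estimate table.

    Parameters
    ----------
    grouping : {"all", "age-parity"}
        Whether to pool all women or split into the four age-parity groups.
    outcomes : tuple of str
        Which binary outcomes to estimate.
    n_min : int
        Minimum unweighted cell size; smaller cells are dropped and logged.
    lone_psu : {"collapse", "certainty", "fail"}
        Handling of single-PSU strata in the variance estimator.

    Attributes
    ----------
    estimates_ : DataFrame
        One row per retained (area, survey, subgroup, outcome) cell.
    dropped_ : DataFrame
        Log of cells below ``n_min``.
    """

    def __init__(
        self,
        grouping: str = SUBGROUP_ALL,
        outcomes: tuple[str, ...] = tuple(OUTCOME_COLUMNS),
        n_min: int = 10,
        lone_psu: str = "collapse",
    ):
        self.grouping = grouping
        self.outcomes = outcomes
        self.n_min = n_min
        self.lone_psu = lone_psu

    def fit(self, X: pd.DataFrame, y=None) -> "DirectEstimator":
        if len(X) == 0:
            raise NoDataError("no records")
        self.estimates_, self.dropped_ = direct_estimates_table(
            X, grouping=self.grouping, outcomes=tuple(self.outcomes),
            n_min=self.n_min, lone_psu=self.lone_psu,
        )
        if len(self.dropped_):
            warnings.warn(
                f"dropped {len(self.dropped_)} cells below n_min={self.n_min}",
                stacklevel=2,
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        # stateless transform: estimates are a pure function of the records
        return direct_estimates_table(
            X, grouping=self.grouping, outcomes=tuple(self.outcomes),
            n_min=self.n_min, lone_psu=self.lone_psu,
        )[0]

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).estimates_
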