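"""Model comparison from posterior draws: DIC, WAIC and the log CPO sum.

All three criteria are computed from the same draws x observations matrix of
pointwise log-likelihoods, where one observation is one direct-estimate row
(an area-survey-subgroup cell on the logit scale).  No composite score is
formed: the criteria are reported side by side and ranked per column, since
they penalize complexity differently and need not agree.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .smoother import PosteriorDraws


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    n_obs: int
    lcpo_sum: float
    dic: float
    p_dic: float
    waic: float
    p_waic: float
    warnings: int  # observations with unstable CPO importance weights


def compute_dic(loglik: np.ndarray, loglik_at_mean: np.ndarray) -> tuple[float, float]:
    """Deviance information criterion with a plug-in at the posterior mean.

    D_bar is the posterior mean deviance; the plug-in deviance is evaluated
    at the posterior mean of the latent linear predictor (the observations
    are Gaussian in the predictor, so the plug-in is well defined).
    p_DIC = D_bar - D(mean); DIC = D_bar + p_DIC.
    """
    loglik = np.atleast_2d(np.asarray(loglik, float))
    loglik_at_mean = np.asarray(loglik_at_mean, float)
    if not (np.all(np.isfinite(loglik)) and np.all(np.isfinite(loglik_at_mean))):
        raise ValueError("non-finite log-likelihood input")
    d_bar = -2.0 * float(loglik.sum(axis=1).mean())
    d_hat = -2.0 * float(loglik_at_mean.sum())
    p_dic = d_bar - d_hat
    return d_bar + p_dic, p_dic


def compute_waic(loglik: np.ndarray) -> tuple[float, float]:
    """Watanabe-Akaike criterion: -2 (lppd - p_waic).

    lppd is the log pointwise predictive density (log of the draw-averaged
    density, via log-sum-exp); p_waic the sum of pointwise draw variances of
    the log-likelihood.
    """
    loglik = np.atleast_2d(np.asarray(loglik, float))
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite log-likelihood input")
    D = loglik.shape[0]
    lppd = float((logsumexp(loglik, axis=0) - np.log(D)).sum())
    if D < 2:
        import warnings as _w
        _w.warn("single posterior draw: p_waic forced to 0", stacklevel=2)
        p_waic = 0.0
    else:
        p_waic = float(loglik.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), p_waic


def compute_lcpo(loglik: np.ndarray, weight_share_limit: float = 0.5) -> tuple[float, np.ndarray, int]:
    """Sum of log conditional predictive ordinates via the harmonic-mean identity.

    CPO_i = 1 / mean over draws of 1/p(y_i | draw), evaluated in log space.
    Observations whose importance weights are dominated by a single draw
    (max weight share above ``weight_share_limit``) are counted as unstable.

    Returns (lcpo_sum, per-observation log CPO, unstable count).
    """
    loglik = np.atleast_2d(np.asarray(loglik, float))
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite log-likelihood input")
    D = loglik.shape[0]
    neg = -loglik
    log_mean_inv = logsumexp(neg, axis=0) - np.log(D)
    log_cpo = -log_mean_inv
    # weight share of the dominant draw in the harmonic-mean estimator
    max_share = np.exp(neg.max(axis=0) - logsumexp(neg, axis=0))
    unstable = int((max_share > weight_share_limit).sum()) if D > 1 else 0
    if not np.all(np.isfinite(log_cpo)):
        raise ValueError("CPO overflow: non-finite log CPO")
    return float(log_cpo.sum()), log_cpo, unstable


def score_model(draws: PosteriorDraws, model_id: str = "model") -> ModelScore:
    """All three criteria from one fit's pointwise log-likelihood matrix."""
    loglik = draws.loglik
    mean_pred = draws.predictor.mean(axis=0)
    loglik_at_mean = (
        -0.5 * np.log(2 * np.pi * draws.v_obs)
        - 0.5 * (draws.y_obs - mean_pred) ** 2 / draws.v_obs
    )
    dic, p_dic = compute_dic(loglik, loglik_at_mean)
    waic, p_waic = compute_waic(loglik)
    lcpo_sum, _, unstable = compute_lcpo(loglik)
    return ModelScore(
        model_id=model_id, n_obs=loglik.shape[1], lcpo_sum=lcpo_sum,
        dic=dic, p_dic=p_dic, waic=waic, p_waic=p_waic, warnings=unstable,
    )


def rank_models(scores: list[ModelScore]) -> pd.DataFrame:
    """Side-by-side table with per-criterion ranks (1 = preferred).

    DIC and WAIC rank ascending, LCPO descending.  Ties share the minimum
    rank and are flagged.
    """
    if len(scores) < 2:
        raise ValueError("need at least two models to rank")
    n_obs = {s.n_obs for s in scores}
    if len(n_obs) > 1:
        raise ValueError(f"scores computed on different observation sets: {sorted(n_obs)}")
    df = pd.DataFrame([asdict(s) for s in scores])
    df["rank_dic"] = df["dic"].rank(method="min").astype(int)
    df["rank_waic"] = df["waic"].rank(method="min").astype(int)
    df["rank_lcpo"] = (-df["lcpo_sum"]).rank(method="min").astype(int)
    df["tied"] = (
        df.duplicated("dic", keep=False)
        | df.duplicated("waic", keep=False)
        | df.duplicated("lcpo_sum", keep=False)
    )
    order = df["rank_waic"] + df["rank_dic"] + df["rank_lcpo"]
    return df.iloc[np.argsort(order.to_numpy(), kind="stable")].reset_index(drop=True)
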