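"""Blocked Gibbs sampler and the SpaceTimeSmoother estimator.

The joint posterior factorizes conveniently: given the block precisions
``tau`` the latent field is exactly Gaussian (see
:func:`fpsae.model.conditional_field_posterior`), and given the field each
``tau_b`` depends on the data only through the quadratic form
``x_b' Q_b x_b``.  The sampler therefore alternates

  1. ``x | tau, y`` — one exact draw from the constrained Gaussian
     conditional (dense Cholesky of the sparse-assembled precision;
     constraints by conditioning-by-kriging);
  2. ``tau_b | x`` — a conjugate Gamma draw under Gamma hyperpriors, or a
     random-walk Metropolis step on ``log tau_b`` targeting the penalized
     complexity prior ``P(sigma_b > u) = alpha``.

Forecast years carry prior structure but no likelihood rows, so their
posterior spread grows with the horizon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .graphs import AdjacencyGraph
from .model import (
    ConstrainedGaussian,
    LatentModel,
    ModelSpec,
    assemble_latent_model,
)


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout and hyperparameter-move tuning."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    step_size: float = 1.0     # global scale on the per-block log-tau proposals
    ess_floor: float = 50.0    # warn (not fail) below this effective sample size

    def validate(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples of the latent field and hyperparameters.

    ``eta`` holds the latent logit-scale field on the full area x year grid
    (instrument effects excluded), shape (draws, areas, years).  ``loglik``
    and ``predictor`` are draws x observations matrices feeding model
    selection; ``x`` is the full latent vector per draw.
    """

    areas: tuple[str, ...]
    years: tuple[int, ...]
    eta: np.ndarray
    hyper: dict[str, np.ndarray]      # effect name -> sigma draws
    loglik: np.ndarray
    predictor: np.ndarray
    x: np.ndarray
    obs_meta: pd.DataFrame
    y_obs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v_obs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0]

    def check_invariants(self) -> None:
        for name, arr in (("eta", self.eta), ("loglik", self.loglik)):
            if not np.all(np.isfinite(arr)):
                raise AssertionError(f"non-finite values in posterior {name}")
        if self.eta.shape != (self.n_draws, len(self.areas), len(self.years)):
            raise AssertionError("eta dimensions inconsistent with grid")

    def eta_cell(self, area: str, year: int) -> np.ndarray:
        return self.eta[:, self.areas.index(area), self.years.index(year)]

    # -- persistence --------------------------------------------------------

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        D, n, T = self.eta.shape
        grid = pd.MultiIndex.from_product(
            [range(D), self.areas, self.years], names=["draw", "area", "year"]
        )
        pd.DataFrame({"value": self.eta.ravel()}, index=grid).reset_index().to_csv(
            path / "eta.csv", index=False
        )
        hyper_rows = [
            {"draw": d, "effect": name, "sigma": float(vals[d])}
            for name, vals in self.hyper.items()
            for d in range(len(vals))
        ]
        pd.DataFrame(hyper_rows, columns=["draw", "effect", "sigma"]).to_csv(
            path / "hyper.csv", index=False
        )
        for name, arr in (("loglik", self.loglik), ("predictor", self.predictor)):
            pd.DataFrame(arr).to_csv(path / f"{name}.csv", index=False)
        obs = self.obs_meta.copy()
        obs["y_logit"] = self.y_obs
        obs["v_logit"] = self.v_obs
        obs.to_csv(path / "obs_meta.csv", index=False)
        (path / "meta.json").write_text(json.dumps(
            {**self.meta, "areas": list(self.areas), "years": list(self.years)},
            indent=2, default=str,
        ))

    @classmethod
    def from_dir(cls, path) -> "PosteriorDraws":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        areas = tuple(meta.pop("areas"))
        years = tuple(int(y) for y in meta.pop("years"))
        eta_long = pd.read_csv(path / "eta.csv")
        D = int(eta_long["draw"].max()) + 1
        eta = eta_long["value"].to_numpy().reshape(D, len(areas), len(years))
        hyper_long = pd.read_csv(path / "hyper.csv")
        hyper = {
            name: g.sort_values("draw")["sigma"].to_numpy()
            for name, g in hyper_long.groupby("effect")
        }
        loglik = pd.read_csv(path / "loglik.csv").to_numpy()
        predictor = pd.read_csv(path / "predictor.csv").to_numpy()
        obs_meta = pd.read_csv(path / "obs_meta.csv")
        y_obs = obs_meta.pop("y_logit").to_numpy(float)
        v_obs = obs_meta.pop("v_logit").to_numpy(float)
        return cls(areas=areas, years=years, eta=eta, hyper=hyper, loglik=loglik,
                   predictor=predictor, x=np.zeros((D, 0)), obs_meta=obs_meta,
                   y_obs=y_obs, v_obs=v_obs, meta=meta)


def effective_sample_size(chain: np.ndarray) -> float:
    """Autocorrelation-time ESS (Geyer initial positive sequence)."""
    x = np.asarray(chain, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s, t = 0.0, 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(n / max(1.0, 1.0 + 2.0 * s))


class _PcPrior:
    """Penalized-complexity prior on sigma = tau^{-1/2}: exponential(lam)."""

    def __init__(self, u: float, alpha: float):
        self.lam = -np.log(alpha) / u

    def log_density_tau(self, log_tau: float) -> float:
        # log p(tau) + log |dtau/dlog tau|
        return -1.5 * log_tau - self.lam * np.exp(-0.5 * log_tau) + log_tau


class _GammaPrior:
    """Gamma(shape, rate) prior on the precision tau."""

    def __init__(self, shape: float, rate: float):
        self.shape = shape
        self.rate = rate

    def log_density_tau(self, log_tau: float) -> float:
        # log p(tau) + log |dtau/dlog tau|
        return self.shape * log_tau - self.rate * np.exp(log_tau)


class _GibbsEngine:
    """Precomputed pieces for fast repeated field updates."""

    def __init__(self, model: LatentModel):
        self.model = model
        Vinv = 1.0 / model.v
        AtVinv = model.A.T.multiply(Vinv)
        self.data_P = np.asarray((AtVinv @ model.A).todense())
        self.b = np.asarray(AtVinv @ model.y).ravel()
        self.block_dense = {
            blk.name: np.asarray(blk.structure.todense())
            for blk in model.tau_blocks
        }

    def field_conditional(self, taus: Mapping[str, float]) -> ConstrainedGaussian:
        P = self.data_P.copy()
        for blk in self.model.tau_blocks:
            sl = blk.sl
            P[sl, sl] += float(taus[blk.name]) * self.block_dense[blk.name]
        return ConstrainedGaussian(P, self.b, self.model.C)

    def quad_form(self, name: str, x: np.ndarray) -> float:
        blk = self.model.block(name)
        xb = x[blk.sl]
        return float(xb @ (self.block_dense[name] @ xb))


def sample_posterior(
    model: LatentModel,
    config: McmcConfig | None = None,
    fixed_taus: Mapping[str, float] | None = None,
) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and collect retained draws.

    ``fixed_taus`` freezes the named precisions (all of them, typically) and
    skips their updates — used both for oracle-equivalence tests and for
    conditional runs.
    """
    config = config or McmcConfig()
    config.validate()
    spec = model.spec
    engine = _GibbsEngine(model)
    if spec.hyperprior == "pc":
        prior = _PcPrior(spec.pc_u, spec.pc_alpha)
    else:
        prior = _GammaPrior(spec.gamma_shape, spec.gamma_rate)
    fixed = dict(fixed_taus or {})
    A_cols = {b.name: model.A[:, b.sl].tocsc() for b in model.tau_blocks}
    Vinv_vec = 1.0 / model.v
    # precision cap (sigma >= 1e-3): the PC prior's tau tail is polynomial,
    # and tau ~ 1e8 numerically swamps the flat (trend) directions in the
    # joint factorization
    LOG_TAU_MAX, LOG_TAU_MIN = np.log(1e6), np.log(1e-8)

    n, T = len(model.areas), len(model.years)
    G = model.eta_map()
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    kept_x, kept_tau = [], {b.name: [] for b in model.tau_blocks}

    # the conditional of log tau_b has sd ~ sqrt(2/rank), so a fixed global
    # proposal scale would freeze the high-rank blocks; scale per block
    steps = {
        b.name: config.step_size * float(np.clip(2.4 * np.sqrt(2.0 / max(b.rank, 1)), 0.15, 1.2))
        for b in model.tau_blocks
    }

    # initialize free precisions at the hyperprior's centre of mass
    if spec.hyperprior == "pc":
        lam = -np.log(spec.pc_alpha) / spec.pc_u
        tau_init = (lam / np.log(2.0)) ** 2  # sigma at the prior median
    else:
        tau_init = spec.gamma_shape / spec.gamma_rate

    for chain, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        taus = {b.name: float(fixed.get(b.name, tau_init)) for b in model.tau_blocks}
        log_taus = {k: np.log(v) for k, v in taus.items()}
        for it in range(config.iterations):
            cond = engine.field_conditional(taus)
            x = cond.sample(rng, 1)[0]
            if not np.all(np.isfinite(x)):
                raise RuntimeError(
                    f"sampler diverged (non-finite state) at chain {chain}, iteration {it}"
                )
            # centered update: tau_b | x
            for blk in model.tau_blocks:
                if blk.name in fixed:
                    continue
                q = engine.quad_form(blk.name, x)
                if spec.hyperprior == "gamma":
                    shape = spec.gamma_shape + 0.5 * blk.rank
                    rate = spec.gamma_rate + 0.5 * q
                    tau = float(np.clip(rng.gamma(shape, 1.0 / rate),
                                        np.exp(LOG_TAU_MIN), np.exp(LOG_TAU_MAX)))
                    taus[blk.name] = tau
                    log_taus[blk.name] = np.log(tau)
                else:
                    lt = log_taus[blk.name]
                    prop = lt + steps[blk.name] * rng.standard_normal()
                    if not LOG_TAU_MIN < prop < LOG_TAU_MAX:
                        continue

                    def logpost(theta: float) -> float:
                        return (0.5 * blk.rank * theta
                                - 0.5 * q * np.exp(theta)
                                + prior.log_density_tau(theta))

                    if np.log(rng.uniform()) < logpost(prop) - logpost(lt):
                        log_taus[blk.name] = prop
                        taus[blk.name] = float(np.exp(prop))
            # interweaved non-centered update: rescale the block with its
            # whitened coordinates fixed.  The centered update alone mixes
            # very slowly for high-dimensional blocks (the x <-> tau coupling
            # acts like a random walk); the rescaling move lets sigma_b make
            # large likelihood-informed jumps.
            pred = np.asarray(model.A @ x).ravel()
            resid = model.y - pred
            for blk in model.tau_blocks:
                if blk.name in fixed:
                    continue
                lt = log_taus[blk.name]
                prop = lt + 0.8 * config.step_size * rng.standard_normal()
                if not LOG_TAU_MIN < prop < LOG_TAU_MAX:
                    continue
                scale = np.exp(-0.5 * (prop - lt))  # sigma' / sigma
                xb = x[blk.sl]
                dpred = np.asarray(A_cols[blk.name] @ ((scale - 1.0) * xb)).ravel()
                new_resid = resid - dpred
                dloglik = -0.5 * float(
                    Vinv_vec @ (new_resid**2) - Vinv_vec @ (resid**2)
                )
                dlogprior = prior.log_density_tau(prop) - prior.log_density_tau(lt)
                if np.log(rng.uniform()) < dloglik + dlogprior:
                    x[blk.sl] = scale * xb
                    resid = new_resid
                    log_taus[blk.name] = prop
                    taus[blk.name] = float(np.exp(prop))
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                kept_x.append(x)
                for name in kept_tau:
                    kept_tau[name].append(taus[name])

    X = np.asarray(kept_x)
    pred = X @ np.asarray(model.A.todense()).T
    loglik = (
        -0.5 * np.log(2 * np.pi * model.v)[None, :]
        - 0.5 * (model.y[None, :] - pred) ** 2 / model.v[None, :]
    )
    eta = np.asarray((G @ X.T).T).reshape(len(X), n, T)
    hyper = {name: 1.0 / np.sqrt(np.asarray(vals)) for name, vals in kept_tau.items()}

    draws = PosteriorDraws(
        areas=model.areas, years=model.years, eta=eta, hyper=hyper,
        loglik=loglik, predictor=pred, x=X, obs_meta=model.obs_meta,
        y_obs=model.y.copy(), v_obs=model.v.copy(),
        meta={"config": asdict(config), "spec": asdict(spec),
              "fixed_taus": {k: float(v) for k, v in fixed.items()}},
    )
    draws.check_invariants()

    free = [nm for nm in kept_tau if nm not in fixed]
    if free and config.ess_floor > 0:
        ess = min(effective_sample_size(hyper[nm]) for nm in free)
        if ess < config.ess_floor:
            warnings.warn(
                f"minimum hyperparameter effective sample size {ess:.0f} below "
                f"floor {config.ess_floor:.0f}; consider longer chains",
                stacklevel=2,
            )
    return draws


class SpaceTimeSmoother(BaseEstimator):
    """Bayesian space-time smoother over logit-scale direct estimates.

    Fits the two-stage small-area model: Gaussian pseudo-likelihood for the
    logit direct estimates with known design-based variances, and a latent
    field composed of a national RW2 trend, yearly shocks, ICAR + iid area
    effects, an area-specific RW2 interaction, and instrument (survey type /
    type-year / type-area) effects, inferred by blocked Gibbs MCMC.

    Parameters mirror :class:`fpsae.model.ModelSpec` and
    :class:`McmcConfig`; see those for semantics.

    Attributes
    ----------
    model_ : LatentModel
        The assembled joint model.
    draws_ : PosteriorDraws
        Retained posterior samples of the latent field and hyperparameters.
    """

    def __init__(
        self,
        rw2_time: bool = True,
        iid_time: bool = True,
        icar_space: bool = True,
        iid_space: bool = True,
        spacetime_interaction: bool = True,
        survey_type: bool = True,
        survey_time: bool = True,
        survey_space: bool = True,
        hyperprior: str = "pc",
        pc_u: float = 1.0,
        pc_alpha: float = 0.01,
        gamma_shape: float = 0.5,
        gamma_rate: float = 5e-4,
        forecast_horizon: int = 1,
        interaction_type: str = "II",
        scale_icar: bool = True,
        chains: int = 4,
        iterations: int = 5000,
        burn_in: int = 2500,
        thin: int = 1,
        seed: int = 0,
        step_size: float = 1.0,
        ess_floor: float = 50.0,
        fixed_taus: dict | None = None,
    ):
        self.rw2_time = rw2_time
        self.iid_time = iid_time
        self.icar_space = icar_space
        self.iid_space = iid_space
        self.spacetime_interaction = spacetime_interaction
        self.survey_type = survey_type
        self.survey_time = survey_time
        self.survey_space = survey_space
        self.hyperprior = hyperprior
        self.pc_u = pc_u
        self.pc_alpha = pc_alpha
        self.gamma_shape = gamma_shape
        self.gamma_rate = gamma_rate
        self.forecast_horizon = forecast_horizon
        self.interaction_type = interaction_type
        self.scale_icar = scale_icar
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.step_size = step_size
        self.ess_floor = ess_floor
        self.fixed_taus = fixed_taus

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            rw2_time=self.rw2_time, iid_time=self.iid_time,
            icar_space=self.icar_space, iid_space=self.iid_space,
            spacetime_interaction=self.spacetime_interaction,
            survey_type=self.survey_type, survey_time=self.survey_time,
            survey_space=self.survey_space, hyperprior=self.hyperprior,
            pc_u=self.pc_u, pc_alpha=self.pc_alpha,
            gamma_shape=self.gamma_shape, gamma_rate=self.gamma_rate,
            forecast_horizon=self.forecast_horizon,
            scale_icar=self.scale_icar, interaction_type=self.interaction_type,
        )

    def _mcmc_config(self) -> McmcConfig:
        return McmcConfig(
            chains=self.chains, iterations=self.iterations,
            burn_in=self.burn_in, thin=self.thin, seed=self.seed,
            step_size=self.step_size, ess_floor=self.ess_floor,
        )

    def fit(self, X: pd.DataFrame, y=None, *, graph: AdjacencyGraph) -> "SpaceTimeSmoother":
        """Fit to a direct-estimate table (single outcome and subgroup)."""
        self.model_ = assemble_latent_model(X, graph, self._model_spec())
        self.draws_ = sample_posterior(
            self.model_, self._mcmc_config(), fixed_taus=self.fixed_taus
        )
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "draws_")
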