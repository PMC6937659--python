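"""Canned multi-survey scenarios for validation experiments.

A "Nigeria-like" world: 37 areas on a planar adjacency, a 15-year grid,
and ten survey rounds from four instrument types — three DHS-like and three
MICS-like national rounds, two NNHS-like rounds, and two PMA-like rounds
covering six areas.  The survey design (2 strata per area, 15 sampled
clusters per stratum, 25 women per cluster) matches the order of the real
instruments' state-level samples.

Calibration experiments here are *generative*: each replicate draws the
component standard deviations from the model's own hyperprior, which is the
regime in which Bayesian credible intervals have exact frequentist coverage.
At any fixed sigma the intervals inherit the usual shrinkage trade-off and
no nominal-coverage guarantee exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .direct import DirectEstimator
from .graphs import AdjacencyGraph, synthetic_graph
from .synthetic import (
    OUTCOMES,
    BiasProfile,
    SamplingFrame,
    SigmaConfig,
    SurveySpec,
    TruePrevalenceSurface,
    build_sampling_frame,
    frame_prevalence,
    generate_true_surface,
    simulate_survey,
)

#: survey rounds: (survey_id, instrument_type, fieldwork year)
DEFAULT_PLAN = (
    ("dhs1", "DHS", 2004), ("mics1", "MICS", 2006), ("dhs2", "DHS", 2009),
    ("nnhs1", "NNHS", 2011), ("mics2", "MICS", 2012), ("dhs3", "DHS", 2014),
    ("nnhs2", "NNHS", 2015), ("pma1", "PMA", 2015), ("pma2", "PMA", 2016),
    ("mics3", "MICS", 2017),
)

DEFAULT_YEARS = range(2003, 2018)
N_AREAS = 37
PMA_AREAS = 6  # PMA-like rounds cover a handful of areas, not the country


@dataclass
class ScenarioWorld:
    """One simulated world plus everything needed to score a fit against it."""

    graph: AdjacencyGraph
    years: tuple[int, ...]
    surfaces: dict[str, TruePrevalenceSurface]
    frame: SamplingFrame
    records: pd.DataFrame
    sigmas: SigmaConfig
    bias_mode: str
    injected_bias: float = 0.0
    injected_instrument: str = "DHS"
    truth_logit: pd.DataFrame = field(default=None)  # area x year, estimand scale

    def truth(self, area: str, year: int) -> float:
        return float(self.truth_logit.loc[area, year])


def draw_sigmas_from_pc_prior(rng: np.random.Generator,
                              u: float = 1.0, alpha: float = 0.01) -> SigmaConfig:
    """One draw of all component sds from the PC prior P(sigma > u) = alpha."""
    lam = -np.log(alpha) / u
    names = ("alpha", "e", "s", "v", "delta", "phi", "psi", "xi")
    return SigmaConfig(**{n: float(rng.exponential(1.0 / lam)) for n in names})


def _estimand_truth(
    surfaces: dict[str, TruePrevalenceSurface],
    frame: SamplingFrame,
    years,
    outcome: str = "modern",
) -> pd.DataFrame:
    """Population truth on the logit scale: logit of the frame prevalence
    (the size-weighted cluster average of inverse-logit rates — what
    design-unbiased estimators converge to)."""
    rows = {}
    for yr in years:
        fp = frame_prevalence(surfaces, frame, yr)
        rows[yr] = logit(fp[outcome])
    return pd.DataFrame(rows)  # area x year


def draw_support_biases(
    surfaces: dict[str, TruePrevalenceSurface],
    plan,
    graph: AdjacencyGraph,
    sigmas: SigmaConfig,
    rng: np.random.Generator,
) -> dict[str, dict[str, BiasProfile]]:
    """Instrument biases drawn from the model's constrained prior.

    The smoothing model lets instrument-year and instrument-area effects
    exist only on the cells an instrument actually fielded, centered within
    instrument; the generated biases live on exactly that support, so the
    instrument-averaged estimand is the plain population truth.  Returns
    ``{outcome: {survey_id: BiasProfile}}``.
    """
    instruments = sorted({inst for _, inst, _ in plan})
    inst_years = {k: sorted({yr for _, i, yr in plan if i == k}) for k in instruments}
    inst_areas = {
        k: (graph.areas if k != "PMA" else graph.areas[:PMA_AREAS])
        for k in instruments
    }
    out: dict[str, dict[str, BiasProfile]] = {}
    for o in OUTCOMES:
        phi = {k: surfaces[o].components["phi_survey_type"][k] for k in instruments}
        psi, xi = {}, {}
        for k in instruments:
            vals = rng.normal(0.0, sigmas.psi, size=len(inst_years[k]))
            vals -= vals.mean()
            psi[k] = dict(zip(inst_years[k], vals))
            vals = rng.normal(0.0, sigmas.xi, size=len(inst_areas[k]))
            vals -= vals.mean()
            xi[k] = dict(zip(inst_areas[k], vals))
        out[o] = {
            sid: BiasProfile(
                type_bias=float(phi[inst]),
                time_bias=float(psi[inst][yr]),
                space_bias={a: float(v) for a, v in xi[inst].items()},
            )
            for sid, inst, yr in plan
        }
    return out


def simulate_world(
    rep_seed: int,
    bias_mode: str = "drawn",
    sigmas: SigmaConfig | str = "pc-prior",
    injected_bias: float = 0.0,
    injected_instrument: str = "DHS",
    plan=DEFAULT_PLAN,
    years=DEFAULT_YEARS,
    n_areas: int = N_AREAS,
    clusters_per_stratum: int = 15,
    women_per_cluster: int = 25,
) -> ScenarioWorld:
    """Simulate one replicate world and its survey records.

    ``bias_mode``:
      - "none": surveys carry no instrument biases;
      - "drawn": biases come from the surfaces' own phi/psi/xi draws;
      - "injected": a fixed mean-zero type-bias contrast whose
        ``injected_instrument`` coordinate equals ``injected_bias`` (the
        other instruments get ``-injected_bias/(K-1)``), nothing else.

    ``sigmas="pc-prior"`` draws the component sds from the model's PC
    hyperprior (generative self-consistency); pass a :class:`SigmaConfig`
    for a fixed-sigma world.
    """
    if bias_mode not in ("none", "drawn", "injected"):
        raise ValueError(f"unknown bias_mode {bias_mode!r}")
    years = tuple(years)
    base = 100_000 * rep_seed
    rng = np.random.default_rng(base)
    graph = synthetic_graph(n_areas, seed=1)  # the map is fixed across replicates
    if isinstance(sigmas, str):
        if sigmas != "pc-prior":
            raise ValueError(f"unknown sigma rule {sigmas!r}")
        sigmas = draw_sigmas_from_pc_prior(rng)
    surfaces = {
        o: generate_true_surface(graph, years, sigmas, seed=base + i, outcome=o)
        for i, o in enumerate(OUTCOMES)
    }
    frame = build_sampling_frame(graph, clusters_per_stratum=40, seed=base + 50)
    instruments = tuple(sorted({inst for _, inst, _ in plan}))
    K = len(instruments)
    drawn = (draw_support_biases(surfaces, plan, graph, sigmas, rng)
             if bias_mode == "drawn" else None)

    def profiles(sid: str, inst: str):
        if bias_mode == "none":
            return {}
        if bias_mode == "drawn":
            return {o: drawn[o][sid] for o in OUTCOMES}
        b = (injected_bias if inst == injected_instrument
             else -injected_bias / (K - 1))
        return {o: BiasProfile(type_bias=b) for o in OUTCOMES}

    recs = []
    for i, (sid, inst, yr) in enumerate(plan):
        areas = graph.areas if inst != "PMA" else graph.areas[:PMA_AREAS]
        spec = SurveySpec(
            sid, inst, yr, areas,
            clusters_per_stratum=clusters_per_stratum,
            women_per_cluster=women_per_cluster,
            bias_profiles=profiles(sid, inst),
        )
        recs.append(simulate_survey(surfaces, frame, spec, seed=base + 100 + i))
    records = pd.concat(recs, ignore_index=True)
    truth = _estimand_truth(surfaces, frame, years)
    return ScenarioWorld(
        graph=graph, years=years, surfaces=surfaces, frame=frame,
        records=records, sigmas=sigmas, bias_mode=bias_mode,
        injected_bias=injected_bias, injected_instrument=injected_instrument,
        truth_logit=truth,
    )


def draw_model_prior_latents(model, sigmas: dict, rng: np.random.Generator,
                             mu: float = -2.0) -> np.ndarray:
    """One draw of the latent vector from the model's own prior.

    Each block is sampled on its constraint manifold with covariance
    ``sigma_b^2 Q_b^+`` (flat directions — the overall level and the free
    trend directions — are set to 0, with the level at ``mu``); this is the
    reference prior under which the model's credible intervals are exactly
    calibrated.
    """
    from scipy.linalg import null_space as dense_null

    x = np.zeros(model.dim)
    x[model.block("mu").sl] = mu
    for blk in model.tau_blocks:
        Cb = model.C[:, blk.sl]
        Cb = Cb[np.abs(Cb).sum(axis=1) > 0]
        U = dense_null(Cb) if len(Cb) else np.eye(blk.size)
        if U.shape[1] == 0:
            continue
        M = U.T @ np.asarray(blk.structure.todense()) @ U
        w, V = np.linalg.eigh(M)
        keep = w > 1e-9 * max(1.0, w.max())
        z = rng.normal(size=int(keep.sum())) / np.sqrt(w[keep])
        x[blk.sl] = float(sigmas[blk.name]) * (U @ (V[:, keep] @ z))
    return x


def simulate_model_consistent_world(
    rep_seed: int,
    model_spec=None,
    plan=DEFAULT_PLAN,
    years=DEFAULT_YEARS,
    n_areas: int = N_AREAS,
    clusters_per_stratum: int = 15,
    women_per_cluster: int = 25,
    pc_u: float = 1.0,
    pc_alpha: float = 0.01,
    mu_by_outcome: dict | None = None,
) -> ScenarioWorld:
    """A replicate world drawn from the smoothing model's own joint prior.

    Component sds come from the PC hyperprior, the latent field and the
    instrument effects from the model's constrained priors, and surveys are
    then simulated through the full two-stage design.  This is the regime in
    which the model's 95% intervals are exactly calibrated, so coverage
    measured here tests the whole pipeline (simulator, direct estimation,
    assembly, MCMC, summaries) rather than any shrinkage trade-off.
    """
    from .model import ModelSpec, assemble_latent_model

    years = tuple(years)
    base = 100_000 * rep_seed
    rng = np.random.default_rng(base)
    graph = synthetic_graph(n_areas, seed=1)
    spec = model_spec or ModelSpec(survey_time=False, pc_u=pc_u, pc_alpha=pc_alpha)
    mu_by_outcome = mu_by_outcome or {"modern": -2.0, "traditional": -3.0,
                                      "unmet": -1.4}
    lam = -np.log(pc_alpha) / pc_u

    # a template estimates table fixes the observation design (areas, years,
    # instruments) the model will see, which defines its constraint windows
    template_rows = []
    for sid, inst, yr in plan:
        areas = graph.areas if inst != "PMA" else graph.areas[:PMA_AREAS]
        for a in areas:
            template_rows.append(dict(area=a, survey_id=sid, instrument_type=inst,
                                      year=yr, subgroup="all", outcome="modern",
                                      y_logit=0.0, v_logit=1.0))
    template = pd.DataFrame(template_rows)
    model = assemble_latent_model(template, graph, spec)

    sig_names = [b.name for b in model.tau_blocks]
    sigmas = {nm: float(rng.exponential(1.0 / lam)) for nm in sig_names}
    G = model.eta_map()
    T, n = len(model.years), len(model.areas)
    years = model.years  # the model grid, incl. the forecast year

    surfaces, profiles = {}, {}
    for o in OUTCOMES:
        x = draw_model_prior_latents(model, sigmas, rng, mu=mu_by_outcome[o])
        eta = np.asarray(G @ x).reshape(n, T)
        surfaces[o] = TruePrevalenceSurface(
            areas=graph.areas, years=years, outcome=o, eta_true=eta,
            components={"model_prior_draw": True}, sigma=SigmaConfig(),
        )
        phi_blk = model.block("phi") if spec.survey_type else None
        xi_blk = model.block("xi") if spec.survey_space else None
        prof = {}
        for sid, inst, yr in plan:
            k = model.instruments.index(inst)
            type_bias = float(x[phi_blk.sl][k]) if phi_blk else 0.0
            if xi_blk:
                xi_vals = x[xi_blk.sl].reshape(len(model.instruments), n)
                space_bias = {a: float(xi_vals[k, graph.index(a)])
                              for a in graph.areas}
            else:
                space_bias = {}
            prof[sid] = BiasProfile(type_bias=type_bias, space_bias=space_bias)
        profiles[o] = prof

    frame = build_sampling_frame(graph, clusters_per_stratum=40, seed=base + 50)
    recs = []
    for i, (sid, inst, yr) in enumerate(plan):
        areas = graph.areas if inst != "PMA" else graph.areas[:PMA_AREAS]
        svy = SurveySpec(
            sid, inst, yr, areas,
            clusters_per_stratum=clusters_per_stratum,
            women_per_cluster=women_per_cluster,
            bias_profiles={o: profiles[o][sid] for o in OUTCOMES},
        )
        recs.append(simulate_survey(surfaces, frame, svy, seed=base + 100 + i))
    records = pd.concat(recs, ignore_index=True)
    truth = _estimand_truth(surfaces, frame, years)
    return ScenarioWorld(
        graph=graph, years=years, surfaces=surfaces, frame=frame,
        records=records, sigmas=SigmaConfig(**{
            k: sigmas.get(k, 0.0) for k in SigmaConfig().__dict__
        }), bias_mode="model-prior", truth_logit=truth,
    )


def direct_estimates_for(world: ScenarioWorld, outcome: str = "modern") -> pd.DataFrame:
    est = DirectEstimator(outcomes=(outcome,)).fit_transform(world.records)
    return est[est["outcome"] == outcome].reset_index(drop=True)


def coverage_of_truth(draws, world: ScenarioWorld, outcome: str = "modern") -> float:
    """Share of area-year cells whose 95% interval covers the world's truth."""
    hits = []
    for i, a in enumerate(draws.areas):
        for j, yr in enumerate(draws.years):
            if yr not in world.years:
                continue  # forecast years have no defined truth row
            lo, hi = np.percentile(draws.eta[:, i, j], [2.5, 97.5])
            tr = world.truth(a, yr)
            hits.append(lo <= tr <= hi)
    return float(np.mean(hits))


def recovered_type_bias(smoother, instrument: str) -> float:
    """Posterior mean of the survey-type effect for one instrument."""
    blk = smoother.model_.block("phi")
    k = smoother.model_.instruments.index(instrument)
    return float(smoother.draws_.x[:, blk.sl].mean(axis=0)[k])
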