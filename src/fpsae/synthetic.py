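"""Synthetic multi-survey worlds with known truth.

Real inputs to this kind of analysis (DHS/MICS-style microdata) are access
gated, so every downstream stage is exercised against simulated surveys drawn
from a known latent prevalence surface.  The generator mirrors the structure
the smoothing model assumes: a national logit-scale level, a second-order
random walk trend, iid yearly shocks, structured (intrinsic CAR) plus
unstructured area effects, an area-specific temporal interaction, and
additive instrument biases — and then emulates a two-stage stratified
cluster survey (PPS-with-replacement clusters, fixed takes of women) with
design weights, so design-based estimation has something real to chew on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .graphs import AdjacencyGraph
from .gmrf import rw2_structure, icar_structure, constrained_intrinsic_sample

OUTCOMES = ("modern", "traditional", "unmet")
INSTRUMENTS = ("DHS", "MICS", "NNHS", "PMA")

RECORD_COLUMNS = (
    "survey_id", "instrument_type", "area", "year", "stratum", "cluster",
    "weight", "age_group", "parity", "uses_modern", "uses_traditional",
    "unmet_need",
)

AGE_GROUPS = ("15-24", "25+")
PARITIES = ("nulliparous", "parous")


@dataclass(frozen=True)
class SigmaConfig:
    """Standard deviations of the latent components (logit scale).

    Defaults describe a country with strong, persistent spatial contrasts
    (the structured area effect dominates), a slow national trend, modest
    area-specific trend departures, and instrument effects small relative to
    the spatial signal.
    """

    alpha: float = 0.05   # RW2 innovation sd, national trend
    e: float = 0.05       # iid yearly shocks
    s: float = 0.5        # structured (ICAR) area effect, marginal sd
    v: float = 0.3        # unstructured area effect
    delta: float = 0.08   # space-time interaction (RW2 innovations per area)
    phi: float = 0.15     # survey-type bias
    psi: float = 0.10     # survey-type x year bias
    xi: float = 0.20      # survey-type x area bias

    def validate(self) -> None:
        for name, val in self.__dict__.items():
            if val < 0:
                raise ValueError(f"sigma {name} must be >= 0, got {val}")


@dataclass(frozen=True)
class TruePrevalenceSurface:
    """Latent logit-scale truth over the full area x year grid.

    ``eta_true[a, t]`` excludes instrument effects: it is the
    instrument-averaged truth the smoothing model targets.  Realized
    instrument-effect draws are stored in ``components`` so survey scenarios
    can build bias profiles from them.
    """

    areas: tuple[str, ...]
    years: tuple[int, ...]
    outcome: str
    eta_true: np.ndarray  # (n_areas, n_years)
    components: dict
    sigma: SigmaConfig

    def eta(self, area: str, year: int) -> float:
        return float(self.eta_true[self.areas.index(area), self.years.index(year)])

    def check_invariants(self, atol: float = 1e-10) -> None:
        c = self.components
        recon = (
            c["mu"]
            + c["alpha_rw2"][None, :]
            + c["e_iid_time"][None, :]
            + c["s_icar"][:, None]
            + c["v_iid_area"][:, None]
            + c["delta_interaction"]
        )
        if not np.allclose(recon, self.eta_true, atol=atol, rtol=0):
            raise AssertionError("eta_true does not equal the sum of its components")
        t = np.arange(len(self.years), dtype=float)
        t_c = t - t.mean()
        a = c["alpha_rw2"]
        if abs(a.sum()) > 1e-8 or abs(a @ t_c) > 1e-8:
            raise AssertionError("alpha_rw2 violates its sum / linear-trend constraints")


@dataclass(frozen=True)
class SamplingFrame:
    """Area -> stratum -> cluster population structure.

    ``clusters`` has one row per cluster: area, stratum, cluster, size
    (women of reproductive age) and a logit offset capturing within-area
    heterogeneity between communities.
    """

    clusters: pd.DataFrame
    sigma_cluster: float

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.clusters["area"]))

    def check_invariants(self) -> None:
        df = self.clusters
        if (df["size"] <= 0).any() or not np.issubdtype(df["size"].dtype, np.integer):
            raise AssertionError("cluster sizes must be positive integers")
        if df.groupby("cluster")["stratum"].nunique().gt(1).any():
            raise AssertionError("a cluster belongs to more than one stratum")
        if df.groupby("stratum")["area"].nunique().gt(1).any():
            raise AssertionError("a stratum belongs to more than one area")


@dataclass(frozen=True)
class BiasProfile:
    """Additive logit-scale instrument biases for one survey and outcome."""

    type_bias: float = 0.0
    time_bias: float = 0.0
    space_bias: Mapping[str, float] = field(default_factory=dict)

    def total(self, area: str) -> float:
        return self.type_bias + self.time_bias + float(self.space_bias.get(area, 0.0))


@dataclass(frozen=True)
class SurveySpec:
    """One cross-sectional survey round: design shape and bias profile."""

    survey_id: str
    instrument_type: str
    year: int
    areas_covered: tuple[str, ...]
    clusters_per_stratum: int = 4
    women_per_cluster: int = 20
    first_stage: str = "pps"  # "pps" (with replacement) or "srs"
    bias_profiles: Mapping[str, BiasProfile] = field(default_factory=dict)

    def bias(self, outcome: str) -> BiasProfile:
        return self.bias_profiles.get(outcome, BiasProfile())


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_true_surface(
    graph: AdjacencyGraph,
    years: range | tuple[int, ...] | list[int],
    sigmas: SigmaConfig | None = None,
    seed: int = 0,
    mu: float = -2.0,
    outcome: str = "modern",
    instruments: tuple[str, ...] = INSTRUMENTS,
) -> TruePrevalenceSurface:
    """Draw one latent truth surface from the model's own priors.

    The RW2 trend is sampled in the orthogonal complement of its null space,
    so the realized trend has zero sum and zero linear contrast; the ICAR
    effect likewise sums to zero within each connected component.  Instrument
    effects (phi/psi/xi) are drawn mean-zero and stored in ``components``
    without entering ``eta_true``.
    """
    years = tuple(int(y) for y in years)
    if len(years) < 3:
        raise ValueError(f"need at least 3 years for an order-2 random walk, got {len(years)}")
    if sorted(years) != list(years) or len(set(years)) != len(years):
        raise ValueError("years must be strictly increasing")
    sigmas = sigmas or SigmaConfig()
    sigmas.validate()

    rng = np.random.default_rng(seed)
    n, T = graph.n_areas, len(years)
    R_t = rw2_structure(T)
    Q_s = icar_structure(graph, scaled=True)
    K = len(instruments)

    alpha = sigmas.alpha * constrained_intrinsic_sample(R_t, rng)
    e = rng.normal(0.0, sigmas.e, size=T)
    s = sigmas.s * constrained_intrinsic_sample(Q_s, rng)
    v = rng.normal(0.0, sigmas.v, size=n)
    delta = np.vstack(
        [sigmas.delta * constrained_intrinsic_sample(R_t, rng) for _ in range(n)]
    )

    phi = rng.normal(0.0, sigmas.phi, size=K)
    phi -= phi.mean()  # identifiable contrasts only
    psi = rng.normal(0.0, sigmas.psi, size=(K, T))
    xi = rng.normal(0.0, sigmas.xi, size=(K, n))

    eta = mu + alpha[None, :] + e[None, :] + s[:, None] + v[:, None] + delta
    components = {
        "mu": mu,
        "alpha_rw2": alpha,
        "e_iid_time": e,
        "s_icar": s,
        "v_iid_area": v,
        "delta_interaction": delta,
        "phi_survey_type": dict(zip(instruments, phi)),
        "psi_survey_time": {
            (k, y): float(psi[i, j])
            for i, k in enumerate(instruments)
            for j, y in enumerate(years)
        },
        "xi_survey_space": {
            (k, a): float(xi[i, j])
            for i, k in enumerate(instruments)
            for j, a in enumerate(graph.areas)
        },
    }
    return TruePrevalenceSurface(
        areas=graph.areas, years=years, outcome=outcome,
        eta_true=eta, components=components, sigma=sigmas,
    )


def bias_from_surface(surface: TruePrevalenceSurface, instrument: str, year: int) -> BiasProfile:
    """Assemble a survey's bias profile from the surface's stored draws."""
    c = surface.components
    return BiasProfile(
        type_bias=float(c["phi_survey_type"][instrument]),
        time_bias=float(c["psi_survey_time"][(instrument, year)]),
        space_bias={a: c["xi_survey_space"][(instrument, a)] for a in surface.areas},
    )


def build_sampling_frame(
    graph: AdjacencyGraph,
    strata_per_area: int = 2,
    clusters_per_stratum: int = 10,
    cluster_size_range: tuple[int, int] = (100, 300),
    sigma_cluster: float = 0.3,
    seed: int = 0,
) -> SamplingFrame:
    """Enumerate strata and clusters with sizes and iid logit offsets."""
    if strata_per_area <= 0 or clusters_per_stratum <= 0:
        raise ValueError("strata_per_area and clusters_per_stratum must be positive")
    lo, hi = cluster_size_range
    if lo <= 0 or lo > hi:
        raise ValueError(f"invalid cluster_size_range {cluster_size_range}")
    if sigma_cluster < 0:
        raise ValueError("sigma_cluster must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for area in graph.areas:
        for h in range(strata_per_area):
            stratum = f"{area}/S{h}"
            for c in range(clusters_per_stratum):
                rows.append({
                    "area": area,
                    "stratum": stratum,
                    "cluster": f"{stratum}/C{c}",
                    "size": int(rng.integers(lo, hi + 1)),
                    "offset": rng.normal(0.0, sigma_cluster) if sigma_cluster > 0 else 0.0,
                })
    frame = SamplingFrame(pd.DataFrame(rows), sigma_cluster)
    frame.check_invariants()
    return frame


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------

def _outcome_probs(eta_m, eta_t, eta_u):
    """Hierarchical decomposition into 4 exclusive categories.

    Modern use is resolved first, traditional among non-modern users, unmet
    need among non-users; this guarantees the exclusivity the indicators obey
    (a woman is classified by her most effective method).
    """
    p_m = expit(eta_m)
    p_t = (1.0 - p_m) * expit(eta_t)
    p_u = (1.0 - p_m - p_t) * expit(eta_u)
    return p_m, p_t, p_u


def simulate_survey(
    surfaces: Mapping[str, TruePrevalenceSurface],
    frame: SamplingFrame,
    spec: SurveySpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one survey's individual records from the truth surfaces.

    Two stages per stratum: ``clusters_per_stratum`` cluster draws, PPS with
    replacement (each hit is an independent PSU) or SRS-with-replacement,
    then a fixed take of ``women_per_cluster`` women per hit.  The design
    weight is the inverse overall inclusion probability per draw,
    ``1 / (m * z_j) * N_j / wpc`` with ``z_j`` the single-draw selection
    probability.

    Returns a DataFrame with exactly the canonical record columns.
    """
    missing = [o for o in OUTCOMES if o not in surfaces]
    if missing:
        raise ValueError(f"surfaces missing outcomes: {missing}")
    ref = surfaces["modern"]
    if spec.year not in ref.years:
        raise ValueError(
            f"survey year {spec.year} outside surface grid {ref.years[0]}..{ref.years[-1]}"
        )
    if not spec.areas_covered:
        raise ValueError("survey covers no areas")
    unknown = set(spec.areas_covered) - set(frame.areas)
    if unknown:
        raise ValueError(f"areas not in sampling frame: {sorted(unknown)}")
    for o, surf in surfaces.items():
        if surf.areas != ref.areas or surf.years != ref.years:
            raise ValueError(f"surface grids disagree for outcome {o!r}")

    rng = np.random.default_rng(seed)
    t_ix = ref.years.index(spec.year)
    m = spec.clusters_per_stratum
    wpc = spec.women_per_cluster
    rows: list[dict] = []

    for area in spec.areas_covered:
        a_ix = ref.areas.index(area)
        eta = {o: surfaces[o].eta_true[a_ix, t_ix] + spec.bias(o).total(area)
               for o in OUTCOMES}
        sub = frame.clusters[frame.clusters["area"] == area]
        for stratum, clus in sub.groupby("stratum", sort=True):
            sizes = clus["size"].to_numpy(float)
            if spec.first_stage == "pps":
                z = sizes / sizes.sum()
            elif spec.first_stage == "srs":
                z = np.full(len(clus), 1.0 / len(clus))
            else:
                raise ValueError(f"unknown first_stage {spec.first_stage!r}")
            draws = rng.choice(len(clus), size=m, replace=True, p=z)
            for d, j in enumerate(draws):
                crow = clus.iloc[j]
                weight = crow["size"] / (m * z[j] * wpc)
                p_m, p_t, p_u = _outcome_probs(
                    eta["modern"] + crow["offset"],
                    eta["traditional"] + crow["offset"],
                    eta["unmet"] + crow["offset"],
                )
                u = rng.uniform(size=wpc)
                modern = u < p_m
                trad = (~modern) & (u < p_m + p_t)
                unmet = (~modern) & (~trad) & (u < p_m + p_t + p_u)
                young = rng.uniform(size=wpc) < 0.35
                p_parous = np.where(young, 0.30, 0.85)
                parous = rng.uniform(size=wpc) < p_parous
                for i in range(wpc):
                    rows.append({
                        "survey_id": spec.survey_id,
                        "instrument_type": spec.instrument_type,
                        "area": area,
                        "year": spec.year,
                        "stratum": stratum,
                        "cluster": f"{crow['cluster']}|{d}",
                        "weight": weight,
                        "age_group": AGE_GROUPS[0] if young[i] else AGE_GROUPS[1],
                        "parity": PARITIES[1] if parous[i] else PARITIES[0],
                        "uses_modern": int(modern[i]),
                        "uses_traditional": int(trad[i]),
                        "unmet_need": int(unmet[i]),
                    })
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def frame_prevalence(
    surfaces: Mapping[str, TruePrevalenceSurface],
    frame: SamplingFrame,
    year: int,
    bias_profiles: Mapping[str, BiasProfile] | None = None,
) -> pd.DataFrame:
    """Population-frame prevalence per area and outcome at one year.

    Size-weighted average over clusters of the category probabilities —
    the estimand the design-based estimator targets.
    """
    ref = surfaces["modern"]
    t_ix = ref.years.index(year)
    bias_profiles = bias_profiles or {}
    out = []
    for area in frame.areas:
        a_ix = ref.areas.index(area)
        clus = frame.clusters[frame.clusters["area"] == area]
        sizes = clus["size"].to_numpy(float)
        offs = clus["offset"].to_numpy(float)
        eta = {
            o: surfaces[o].eta_true[a_ix, t_ix]
            + bias_profiles.get(o, BiasProfile()).total(area)
            for o in OUTCOMES
        }
        p_m, p_t, p_u = _outcome_probs(
            eta["modern"] + offs, eta["traditional"] + offs, eta["unmet"] + offs
        )
        w = sizes / sizes.sum()
        out.append({
            "area": area,
            "modern": float(w @ p_m),
            "traditional": float(w @ p_t),
            "unmet": float(w @ p_u),
        })
    return pd.DataFrame(out).set_index("area")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_records(records: pd.DataFrame, path) -> None:
    records.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "year": int, "uses_modern": int, "uses_traditional": int,
            "unmet_need": int, "weight": float,
        },
    )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df.loc[:, list(RECORD_COLUMNS)]
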