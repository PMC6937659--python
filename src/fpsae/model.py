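"""Assembly of the latent space-time smoothing model.

The logit-scale direct estimates ``y_i`` with design-based variances ``v_i``
are treated as Gaussian observations of a latent linear predictor

    y_i ~ N( (A x)_i , v_i ),   v_i known,

where the latent vector ``x`` stacks an overall level ``mu``, a national
RW2 trend ``alpha``, iid yearly shocks ``e``, structured (ICAR) and
unstructured area effects ``s`` and ``v``, an area-specific RW2 interaction
``delta``, and instrument effects: type ``phi``, type-by-year ``psi`` and
type-by-area ``xi``.  Each block carries a precision ``tau_b`` times a fixed
structure matrix; intrinsic and exchangeable blocks that would be confounded
with ``mu`` (or with the main effects, for the interaction) get exact linear
constraints ``C x = 0``.

The conditional of ``x`` given hyperparameters is Gaussian and available in
closed form; :func:`conditional_field_posterior` computes it exactly (with
constraints handled by conditioning-by-kriging) and doubles as the Gibbs
field update and the oracle the sampler is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .gmrf import icar_structure, interaction_structure, rw2_structure
from .graphs import AdjacencyGraph


@dataclass(frozen=True)
class ModelSpec:
    """Which random effects to include, hyperprior family, forecast horizon."""

    rw2_time: bool = True
    iid_time: bool = True
    icar_space: bool = True
    iid_space: bool = True
    spacetime_interaction: bool = True
    survey_type: bool = True
    survey_time: bool = True
    survey_space: bool = True
    hyperprior: str = "pc"        # "pc": P(sigma > pc_u) = pc_alpha; or "gamma"
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    gamma_shape: float = 0.5
    gamma_rate: float = 5e-4
    forecast_horizon: int = 1
    scale_icar: bool = True
    interaction_type: str = "II"  # "II": RW2 x iid areas; "IV": RW2 x ICAR

    def validate(self) -> None:
        if self.hyperprior not in ("pc", "gamma"):
            raise ValueError(f"unknown hyperprior family {self.hyperprior!r}")
        if self.spacetime_interaction and not self.rw2_time:
            raise ValueError("the space-time interaction requires the RW2 time structure")
        if self.spacetime_interaction and not (self.icar_space or self.iid_space):
            raise ValueError("the space-time interaction requires a spatial main effect")
        if self.interaction_type not in ("II", "IV"):
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")
        if self.forecast_horizon < 0:
            raise ValueError("forecast_horizon must be >= 0")


@dataclass(frozen=True)
class Block:
    """One latent sub-vector: its position, structure matrix and rank.

    ``rank`` is the exponent entering the tau updates: the rank of the
    structure matrix restricted to the constraint manifold (the structure
    rank for intrinsic blocks; size minus constraint count for exchangeable
    ones).
    """

    name: str
    start: int
    size: int
    structure: sp.csr_matrix | None  # None = flat prior (no precision term)
    rank: int
    has_tau: bool
    intrinsic: bool = False

    @property
    def sl(self) -> slice:
        return slice(self.start, self.start + self.size)


@dataclass
class LatentModel:
    """Assembled joint model: blocks, observation map, constraints, data."""

    areas: tuple[str, ...]
    years: tuple[int, ...]
    instruments: tuple[str, ...]
    blocks: tuple[Block, ...]
    A: sp.csr_matrix          # n_obs x dim observation map
    C: np.ndarray             # n_con x dim, constraints C x = 0
    y: np.ndarray             # logit-scale direct estimates
    v: np.ndarray             # their design-based variances (known)
    obs_meta: pd.DataFrame
    spec: ModelSpec
    _block_ix: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._block_ix = {b.name: b for b in self.blocks}

    @property
    def dim(self) -> int:
        return self.blocks[-1].start + self.blocks[-1].size

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def block(self, name: str) -> Block:
        return self._block_ix[name]

    @property
    def tau_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.has_tau)

    def prior_precision(self, taus: Mapping[str, float]) -> sp.csr_matrix:
        """Sum of tau_b * Q_b placed on the block diagonal."""
        parts = []
        for b in self.blocks:
            if b.structure is None:
                parts.append(sp.csr_matrix((b.size, b.size)))
            else:
                parts.append(float(taus[b.name]) * b.structure)
        return sp.block_diag(parts, format="csr")

    def eta_map(self) -> sp.csr_matrix:
        """Map x -> latent field eta on the full area x year grid.

        Instrument effects are excluded: eta is the instrument-averaged truth.
        Grid cells are ordered area-major ((a0,y0), (a0,y1), ...).
        """
        n, T = len(self.areas), len(self.years)
        G = sp.lil_matrix((n * T, self.dim))
        rows = np.arange(n * T)
        a_ix = rows // T
        t_ix = rows % T
        for b in self.blocks:
            if b.name == "mu":
                G[rows, b.start] = 1.0
            elif b.name in ("alpha", "e"):
                G[rows, b.start + t_ix] = 1.0
            elif b.name in ("s", "v"):
                G[rows, b.start + a_ix] = 1.0
            elif b.name == "delta":
                G[rows, b.start + a_ix * T + t_ix] = 1.0
        return G.tocsr()


def _year_grid(estimates: pd.DataFrame, horizon: int) -> tuple[int, ...]:
    y0, y1 = int(estimates["year"].min()), int(estimates["year"].max())
    return tuple(range(y0, y1 + horizon + 1))


def assemble_latent_model(
    estimates: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec | None = None,
) -> LatentModel:
    """Build the joint latent model from a direct-estimate table.

    The table must concern a single outcome and subgroup (each indicator and
    demographic group gets its own fit).  The year grid spans the earliest to
    the latest survey year plus ``forecast_horizon``; forecast years have
    prior structure but no likelihood rows, which is what produces growing
    forecast uncertainty.
    """
    spec = spec or ModelSpec()
    spec.validate()
    if len(estimates) == 0:
        raise ValueError("no direct estimates supplied")
    for col in ("outcome", "subgroup"):
        if estimates[col].nunique() > 1:
            raise ValueError(
                f"estimates mix several {col}s ({sorted(estimates[col].unique())}); "
                "fit one model per outcome and subgroup"
            )
    bad = sorted(set(estimates["area"]) - set(graph.areas))
    if bad:
        raise ValueError(f"estimates reference areas absent from the graph: {bad}")
    if (estimates["v_logit"] <= 0).any():
        raise ValueError("every estimate entering the model needs v_logit > 0")

    years = _year_grid(estimates, spec.forecast_horizon)
    T, n = len(years), graph.n_areas
    if spec.rw2_time and T < 3:
        raise ValueError(f"RW2 needs at least 3 grid years, got {T}")
    instruments = tuple(sorted(estimates["instrument_type"].unique()))
    K = len(instruments)

    eye = lambda m: sp.identity(m, format="csr")
    blocks: list[Block] = []
    pos = 0

    def add(name: str, size: int, structure, rank: int,
            has_tau: bool = True, intrinsic: bool = False) -> None:
        nonlocal pos
        blocks.append(Block(name, pos, size, structure, rank, has_tau, intrinsic))
        pos += size

    add("mu", 1, None, 0, has_tau=False)
    if spec.rw2_time:
        add("alpha", T, rw2_structure(T), T - 2, intrinsic=True)
    if spec.iid_time:
        add("e", T, eye(T), T)
    if spec.icar_space:
        add("s", n, icar_structure(graph, scaled=spec.scale_icar),
            n - graph.n_components, intrinsic=True)
    if spec.iid_space:
        add("v", n, eye(n), n)
    if spec.spacetime_interaction:
        R_t = rw2_structure(T)
        if spec.interaction_type == "II":
            add("delta", n * T, interaction_structure(R_t, n), n * (T - 2),
                intrinsic=True)
        else:  # type IV: RW2 in time crossed with ICAR in space
            Q_s = icar_structure(graph, scaled=spec.scale_icar)
            Q = sp.kron(Q_s, R_t, format="csr")
            rank = (n - graph.n_components) * (T - 2)
            add("delta", n * T, Q, rank, intrinsic=True)
    if spec.survey_type:
        add("phi", K, eye(K), K)
    if spec.survey_time:
        add("psi", K * T, eye(K * T), K * T)
    if spec.survey_space:
        add("xi", K * n, eye(K * n), K * n)

    blocks_t = tuple(blocks)
    dim = pos

    # observation map
    a_of = {a: i for i, a in enumerate(graph.areas)}
    t_of = {y: i for i, y in enumerate(years)}
    k_of = {k: i for i, k in enumerate(instruments)}
    A = sp.lil_matrix((len(estimates), dim))
    rows = np.arange(len(estimates))
    a_ix = estimates["area"].map(a_of).to_numpy()
    t_ix = estimates["year"].map(t_of).to_numpy()
    k_ix = estimates["instrument_type"].map(k_of).to_numpy()
    for b in blocks_t:
        if b.name == "mu":
            A[rows, b.start] = 1.0
        elif b.name in ("alpha", "e"):
            A[rows, b.start + t_ix] = 1.0
        elif b.name in ("s", "v"):
            A[rows, b.start + a_ix] = 1.0
        elif b.name == "delta":
            A[rows, b.start + a_ix * T + t_ix] = 1.0
        elif b.name == "phi":
            A[rows, b.start + k_ix] = 1.0
        elif b.name == "psi":
            A[rows, b.start + k_ix * T + t_ix] = 1.0
        elif b.name == "xi":
            A[rows, b.start + k_ix * n + a_ix] = 1.0

    # constraints: remove every direction confounded with mu / the main
    # effects.  Time-block constraints are supported on the observed years
    # only — that removes the same flat directions but leaves forecast years
    # free, so forecast uncertainty grows with the horizon instead of being
    # artificially tied back by a grid-wide contrast.
    obs_mask = np.isin(np.array(years), estimates["year"].unique()).astype(float)
    if obs_mask.sum() < 2:
        obs_mask = np.ones(T)
    t_idx = np.arange(T, dtype=float)
    t_bar = (t_idx * obs_mask).sum() / obs_mask.sum()
    t_cen = obs_mask * (t_idx - t_bar)
    con_rows: list[np.ndarray] = []
    con_count: dict[str, int] = {}

    def crow(block: str, values: np.ndarray, offset: int = 0) -> None:
        row = np.zeros(dim)
        b = next(bb for bb in blocks_t if bb.name == block)
        row[b.start + offset : b.start + offset + len(values)] = values
        con_rows.append(row)
        con_count[block] = con_count.get(block, 0) + 1

    # Linear trends are flat (unpenalized) directions of the RW2 blocks and
    # must be *representable*, not pinned: the national trend lives in alpha
    # and area-specific trends in delta.  When the type II interaction is on,
    # its free per-area trend directions span the common trend too, so
    # alpha's trend direction is then constrained away to avoid a doubly
    # flat (singular) direction; without the interaction alpha keeps its
    # trend free.
    free_area_trends = spec.spacetime_interaction and spec.interaction_type == "II"
    if spec.rw2_time:
        crow("alpha", obs_mask)
        if free_area_trends:
            crow("alpha", t_cen)
    if spec.iid_time:
        crow("e", obs_mask)
    if spec.icar_space:
        for comp in graph.components:
            ind = np.zeros(n)
            for a in comp:
                ind[a_of[a]] = 1.0
            crow("s", ind)
    if spec.iid_space:
        crow("v", np.ones(n))
    if spec.spacetime_interaction:
        if spec.interaction_type == "II":
            for a in range(n):
                crow("delta", obs_mask, offset=a * T)
        else:
            # type IV: the Kronecker null space mixes spatial and temporal flat
            # directions; use an orthonormal numerical basis so C keeps full
            # row rank
            from .gmrf import null_space

            d_blk = next(b for b in blocks_t if b.name == "delta")
            for vec in null_space(d_blk.structure).T:
                crow("delta", vec)
    if spec.survey_type:
        crow("phi", np.ones(K))
    # instrument-year and instrument-area effects exist only where that
    # instrument actually collected data: a cell never fielded is pinned to
    # zero, otherwise it would absorb field variance for free (a year shock
    # can hide in psi by compensating on data-free cells).  Within each
    # instrument the observed cells are centered, so phi keeps the
    # instrument-level mean and the field keeps shocks common to all
    # instruments.
    obs_kt = set(zip(k_ix, t_ix))
    obs_ka = set(zip(k_ix, a_ix))
    if spec.survey_time:
        for k in range(K):
            observed = np.array([(k, t) in obs_kt for t in range(T)])
            if observed.any():
                crow("psi", observed.astype(float), offset=k * T)
            for t in np.flatnonzero(~observed):
                crow("psi", np.ones(1), offset=k * T + int(t))
    if spec.survey_space:
        for k in range(K):
            observed = np.array([(k, a) in obs_ka for a in range(n)])
            if observed.any():
                crow("xi", observed.astype(float), offset=k * n)
            for a in np.flatnonzero(~observed):
                crow("xi", np.ones(1), offset=k * n + int(a))

    C = np.vstack(con_rows) if con_rows else np.zeros((0, dim))

    # degrees of freedom driving the tau updates: intrinsic blocks keep the
    # structure rank (their flat directions contribute nothing to x'Qx
    # whether constrained or left free); exchangeable blocks lose one df per
    # constraint
    blocks_t = tuple(
        Block(b.name, b.start, b.size, b.structure,
              b.rank if (b.intrinsic or not b.has_tau)
              else b.size - con_count.get(b.name, 0),
              b.has_tau, b.intrinsic)
        for b in blocks_t
    )

    obs_meta = estimates.loc[
        :, ["area", "survey_id", "instrument_type", "year", "subgroup", "outcome"]
    ].reset_index(drop=True)

    return LatentModel(
        areas=graph.areas, years=years, instruments=instruments,
        blocks=blocks_t, A=A.tocsr(), C=C,
        y=estimates["y_logit"].to_numpy(float),
        v=estimates["v_logit"].to_numpy(float),
        obs_meta=obs_meta, spec=spec,
    )


class ConstrainedGaussian:
    """Exact Gaussian conditional of x | y, tau under the constraints C x = 0.

    The unconstrained precision ``P = sum_b tau_b Q_b + A' V^-1 A`` can be
    singular along directions the constraints remove, so the factorized
    matrix is ``P + kappa C'C`` — on the constraint manifold the extra term
    vanishes identically, so the constrained law is untouched.  Draws are
    produced by conditioning-by-kriging: sample from the regularized
    unconstrained Gaussian, then project the constraint residual out using
    the posterior covariance metric.
    """

    def __init__(self, P, b: np.ndarray, C: np.ndarray):
        dim = P.shape[0]
        self.C = np.asarray(C, dtype=float).reshape(-1, dim)
        P_r = np.asarray(P.todense()) if sp.issparse(P) else np.array(P, dtype=float)
        scale = max(float(np.mean(np.diagonal(P_r))), 1.0)
        if len(self.C):
            P_r = P_r + scale * (self.C.T @ self.C)
        try:
            self._L = cholesky(P_r, lower=True)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "constrained precision is singular: some latent directions are "
                "unidentified even under the constraints"
            ) from err
        m_star = cho_solve((self._L, True), b)
        if len(self.C):
            W = cho_solve((self._L, True), self.C.T)       # Sigma C'
            S = self.C @ W                                  # C Sigma C'
            self._S_chol = cholesky(S, lower=True)
            self._W = W
            self.mean = m_star - W @ cho_solve((self._S_chol, True), self.C @ m_star)
        else:
            self._W = None
            self.mean = m_star
        self._dim = dim

    def _correct(self, x: np.ndarray) -> np.ndarray:
        if self._W is None:
            return x
        resid = self.C @ x
        return x - self._W @ cho_solve((self._S_chol, True), resid)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draws from the constrained conditional, shape (size, dim)."""
        z = rng.standard_normal((self._dim, size))
        x = self.mean[:, None] + solve_triangular(self._L.T, z, lower=False)
        out = np.empty_like(x.T)
        for i in range(size):
            out[i] = self._correct(x[:, i])
        return out

    def covariance(self) -> np.ndarray:
        """Dense constrained covariance (small models / tests only)."""
        Sigma = cho_solve((self._L, True), np.eye(self._dim))
        if self._W is not None:
            Sigma = Sigma - self._W @ cho_solve((self._S_chol, True), self._W.T)
        return Sigma


def conditional_field_posterior(
    model: LatentModel, taus: Mapping[str, float]
) -> ConstrainedGaussian:
    """Closed-form Gaussian conditional of the latent field at fixed precisions.

    This is simultaneously the blocked-Gibbs field update and the oracle the
    sampler is validated against.
    """
    for b in model.tau_blocks:
        if taus[b.name] <= 0:
            raise ValueError(f"precision for block {b.name!r} must be > 0")
    Vinv = 1.0 / model.v
    AtVinv = model.A.T.multiply(Vinv)          # dim x n_obs
    P = model.prior_precision(taus) + (AtVinv @ model.A).tocsr()
    b = np.asarray(AtVinv @ model.y).ravel()
    return ConstrainedGaussian(P, b, model.C)
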