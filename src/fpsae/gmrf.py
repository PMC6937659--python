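"""Intrinsic Gaussian Markov random field structure matrices.

All smoothing components are intrinsic GMRFs: a density proportional to
``exp(-tau/2 * x' R x)`` with a rank-deficient structure matrix ``R`` whose
null space (flat directions) is removed by explicit linear constraints.

- second-order random walk over T time points: rank T-2, null space spanned
  by the constant and linear vectors;
- intrinsic CAR over an adjacency graph: rank n - (number of connected
  components), null space spanned by the component indicators;
- space-time interaction of Knorr-Held type II: an independent RW2 per area
  (Kronecker of the RW2 structure with the identity over areas), null space
  of dimension 2 * n_areas.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .graphs import AdjacencyGraph


def rw2_structure(T: int) -> sp.csr_matrix:
    """Structure matrix R = D'D of a second-order random walk.

    D is the (T-2) x T second-difference operator, so x'Rx is the sum of
    squared second differences.
    """
    if T < 3:
        raise ValueError(f"an order-2 random walk needs at least 3 time points, got T={T}")
    D = sp.diags([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(T - 2, T), format="csr")
    return (D.T @ D).tocsr()


def icar_structure(graph: AdjacencyGraph, scaled: bool = True) -> sp.csr_matrix:
    """Intrinsic CAR structure: degree on the diagonal, -1 between neighbours.

    With ``scaled=True`` the matrix is multiplied by the generalized variance
    of the constrained prior (geometric mean of the marginal variances), so a
    unit precision corresponds to a typical marginal variance of 1 regardless
    of graph topology — one prior on sigma then means the same thing across
    graphs.
    """
    n = graph.n_areas
    if n < 2:
        raise ValueError("ICAR needs at least 2 areas")
    deg = graph.degrees().astype(float)
    Q = sp.lil_matrix((n, n))
    Q.setdiag(deg)
    for e in graph.edges:
        a, b = (graph.index(x) for x in e)
        Q[a, b] = -1.0
        Q[b, a] = -1.0
    Q = Q.tocsr()
    if scaled:
        Q = Q * _generalized_variance(Q)
    return Q


def interaction_structure(R_time: sp.spmatrix, n_areas: int) -> sp.csr_matrix:
    """Type II space-time interaction: independent RW2 per area.

    Under area-major ordering (all years of area 0, then area 1, ...) this is
    ``I_n (x) R_time`` — block diagonal with one RW2 block per area.  The null
    space has dimension 2 * n_areas (a constant and a linear trend per area),
    which the model removes with per-area constraints because those directions
    are already carried by the main effects.
    """
    R_time = sp.csr_matrix(R_time)
    T = R_time.shape[0]
    if R_time.shape != (T, T):
        raise ValueError("R_time must be square")
    if T < 3 or abs(R_time[0, 0] - 1.0) > 1e-12:
        raise ValueError("R_time does not look like an RW2 structure matrix")
    if n_areas < 1:
        raise ValueError("n_areas must be positive")
    return sp.kron(sp.identity(n_areas, format="csr"), R_time, format="csr")


def null_space(R: sp.spmatrix, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the (numerical) null space, columns as vectors."""
    w, V = np.linalg.eigh(np.asarray(R.todense()))
    return V[:, w < tol * max(1.0, w.max())]


def structure_rank(R: sp.spmatrix, tol: float = 1e-9) -> int:
    w = np.linalg.eigvalsh(np.asarray(R.todense()))
    return int((w >= tol * max(1.0, w.max())).sum())


def _generalized_variance(R: sp.spmatrix, tol: float = 1e-9) -> float:
    """Geometric mean of the constrained prior's marginal variances.

    Computed from the spectral pseudo-inverse of R restricted to the
    complement of its null space (the constrained intrinsic covariance).
    """
    w, V = np.linalg.eigh(np.asarray(R.todense()))
    keep = w >= tol * max(1.0, w.max())
    cov_diag = (V[:, keep] ** 2 / w[keep]).sum(axis=1)
    # isolated nodes (singleton components) sit entirely in the null space
    # and have zero constrained variance; they carry no information about
    # the scaling
    positive = cov_diag > tol
    if not positive.any():
        return 1.0
    return float(np.exp(np.mean(np.log(cov_diag[positive]))))


def constrained_intrinsic_sample(R: sp.spmatrix, rng: np.random.Generator) -> np.ndarray:
    """One unit-precision draw from the intrinsic GMRF, null space removed.

    Sampling along the positive eigenvectors with variance 1/eigenvalue keeps
    the draw exactly orthogonal to every flat direction, so RW2 draws have
    zero sum and zero linear contrast and ICAR draws sum to zero within each
    connected component.
    """
    w, V = np.linalg.eigh(np.asarray(R.todense()))
    keep = w >= 1e-9 * max(1.0, w.max())
    z = rng.normal(size=int(keep.sum())) / np.sqrt(w[keep])
    return V[:, keep] @ z
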