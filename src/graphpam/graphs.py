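"""Weighted graphs and Laplacian spectra.

The dynamical model lives on an undirected weighted graph with coupling
matrix ``W`` (symmetric, nonnegative, zero diagonal).  The graph Laplacian
``L = D - W`` with ``D = diag(k)``, ``k_i = sum_j W_ij`` drives the
diffusive part of the dynamics; every exact propagator downstream is built
from its eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

__all__ = [
    "WeightedGraph",
    "LaplacianSpectrum",
    "build_laplacian",
    "generate_mean_field",
    "generate_torus",
    "generate_regular",
    "generate_separable",
    "torus_eigenvalues",
]

#: default numerical tolerance for structural invariants
TOL = 1e-10


@dataclass(frozen=True)
class WeightedGraph:
    """A weighted graph given by its coupling matrix.

    Parameters
    ----------
    weights
        ``(N, N)`` coupling matrix ``W``.  Symmetric with zero diagonal and
        nonnegative entries unless ``directed`` is set (the separable model
        ``W_ij = b_j k_i`` is the only directed case supported).
    directed
        Whether the weights are allowed to be asymmetric.
    """

    weights: np.ndarray
    directed: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Row sums ``k_i = sum_j W_ij``."""
        return self.weights.sum(axis=1)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    def laplacian(self) -> np.ndarray:
        """``L = diag(k) - W`` (zero row sums by construction)."""
        return np.diag(self.degrees) - self.weights

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if W.shape[0] < 1:
            raise ValueError("graph needs at least one node")
        if not np.all(np.isfinite(W)):
            raise ValueError("weights must be finite")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.abs(np.diag(W)) > TOL):
            raise ValueError("self loops are not allowed (nonzero diagonal)")
        if not self.directed and not np.allclose(W, W.T, atol=TOL, rtol=0):
            raise ValueError(
                "weight matrix is asymmetric; pass directed=True only for "
                "the separable model"
            )


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Eigendecomposition of a graph Laplacian.

    ``eigenvalues`` are sorted ascending; ``eigenvectors`` holds the
    corresponding orthonormal eigenvectors as columns.  For a connected
    graph the zero mode is the uniform vector with entries ``1/sqrt(N)``.
    """

    laplacian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_components: int = 1
    graph: WeightedGraph | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1


def build_laplacian(graph: WeightedGraph, *, component_tol: float = 1e-8) -> LaplacianSpectrum:
    """Diagonalize the Laplacian of an undirected weighted graph.

    Rejects directed (separable-model) graphs: the spectral machinery
    assumes an orthonormal eigenbasis, which only the symmetric Laplacian
    guarantees.  Disconnected graphs succeed with ``n_components > 1`` and
    a warning.
    """
    if graph.directed:
        raise ValueError(
            "build_laplacian requires an undirected graph; the directed "
            "separable model is supported only by the SDE simulator and the "
            "second-moment dynamics"
        )
    if graph.n_nodes > 2000:
        raise ValueError(
            "dense eigendecomposition is capped at N = 2000; use closed-form "
            "spectra (torus_eigenvalues) or smaller graphs for spectral work"
        )
    L = graph.laplacian()
    lam, phi = scipy.linalg.eigh(L)
    lam = np.clip(lam, 0.0, None) if lam.min() > -1e-9 else lam
    scale = max(abs(lam[-1]), 1.0)
    n_components = int(np.sum(lam < component_tol * scale))
    n_components = max(n_components, 1)
    if n_components > 1:
        warnings.warn(
            f"graph has {n_components} connected components", stacklevel=2
        )
    return LaplacianSpectrum(
        laplacian=L,
        eigenvalues=lam,
        eigenvectors=phi,
        n_components=n_components,
        graph=graph,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_mean_field(n_nodes: int) -> WeightedGraph:
    """Fully connected graph with per-pair weight ``1/N``.

    With this normalization the interaction drift is ``J (mbar - m_i)`` up
    to ``O(1/N)``, the convention under which the mean-field critical point
    sits at ``J/sigma^2 = 1`` and the Pareto exponent is
    ``mu = 1 + 2J/sigma^2``.  The nonzero Laplacian eigenvalues all equal 1.
    """
    if n_nodes < 2:
        raise ValueError("mean-field graph needs at least 2 nodes")
    W = np.full((n_nodes, n_nodes), 1.0 / n_nodes)
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W)


def generate_torus(dimension: int, side: int) -> WeightedGraph:
    """Periodic d-dimensional lattice with unit nearest-neighbour weights.

    Every node has degree ``2 * dimension``.  ``side >= 3`` is required so
    the periodic wrap does not create multi-edges.
    """
    if dimension not in (1, 2, 3, 4):
        raise ValueError("dimension must be in {1, 2, 3, 4}")
    if side < 3:
        raise ValueError("side must be >= 3 (smaller sides create multi-edges)")
    n = side**dimension
    W = np.zeros((n, n))
    coords = np.stack(
        np.unravel_index(np.arange(n), (side,) * dimension), axis=1
    )
    for axis in range(dimension):
        nbr = coords.copy()
        nbr[:, axis] = (nbr[:, axis] + 1) % side
        j = np.ravel_multi_index(tuple(nbr.T), (side,) * dimension)
        W[np.arange(n), j] = 1.0
        W[j, np.arange(n)] = 1.0
    return WeightedGraph(W)


def torus_eigenvalues(dimension: int, side: int) -> np.ndarray:
    """Closed-form (circulant) Laplacian spectrum of the periodic lattice.

    ``lambda(a_1..a_d) = sum_axis (2 - 2 cos(2 pi a_axis / side))``,
    returned sorted ascending.  Lets generating-function sums over very
    large lattices bypass the dense eigensolve.
    """
    if dimension not in (1, 2, 3, 4):
        raise ValueError("dimension must be in {1, 2, 3, 4}")
    if side < 3:
        raise ValueError("side must be >= 3")
    one_d = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(side) / side)
    lam = one_d
    for _ in range(dimension - 1):
        lam = (lam[:, None] + one_d[None, :]).ravel()
    return np.sort(lam)


def generate_regular(n_nodes: int, degree: int, seed: int) -> WeightedGraph:
    """Simple random d-regular graph with unit weights, reproducible from seed."""
    if (n_nodes * degree) % 2 != 0:
        raise ValueError("n_nodes * degree must be even for a regular graph")
    if degree >= n_nodes:
        raise ValueError("degree must be smaller than n_nodes")
    last_err: Exception | None = None
    for attempt in range(10):
        try:
            g = nx.random_regular_graph(degree, n_nodes, seed=seed + attempt)
            break
        except nx.NetworkXError as err:  # pragma: no cover - rare retry path
            last_err = err
    else:  # pragma: no cover
        raise ValueError(
            f"regular-graph generation failed after retries (seed={seed}): {last_err}"
        )
    W = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=float)
    return WeightedGraph(W)


def generate_separable(b_weights: np.ndarray, k_values: np.ndarray) -> WeightedGraph:
    """Separable (directed) model ``W_ij = b_j k_i`` with ``sum_j b_j = 1``.

    The resulting graph is asymmetric, so it is flagged directed and only
    usable by the SDE simulator and the second-moment dynamics.  Row sums
    (with the diagonal zeroed) equal ``k_i (1 - b_i)``.
    """
    b = np.asarray(b_weights, dtype=float)
    k = np.asarray(k_values, dtype=float)
    if b.ndim != 1 or k.ndim != 1 or b.size != k.size:
        raise ValueError("b_weights and k_values must be 1-D of equal length")
    if abs(b.sum() - 1.0) > 1e-8:
        raise ValueError("b_weights must sum to 1")
    if np.any(b <= 0) or np.any(k <= 0):
        raise ValueError("b_weights and k_values must be positive")
    W = np.outer(k, b)
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W, directed=True)
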