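"""Adjacency graphs, structure matrices and intrinsic-CAR primitives.

An intrinsic conditional autoregressive (CAR) prior on an area-level field
``phi`` has the improper Gaussian kernel ``exp(-(tau/2) * phi' K phi)`` where
``K`` is the graph Laplacian of the area contiguity graph (degree matrix minus
adjacency matrix).  Its full conditionals are the textbook ones: given all
neighbours, ``phi_i`` is normal with mean the neighbour average and precision
``n_i * tau``.  The kernel is flat along per-component constants, so sampling
and identification work on the orthogonal complement of that null space.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

StructureRole = Literal["spatial", "identity", "interaction"]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Adjacency graphs
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AdjacencyGraph:
    """Area contiguity structure.

    Parameters
    ----------
    area_ids
        Ordered area labels; index in this list is the area index everywhere.
    neighbors
        ``neighbors[i]`` is the frozenset of indices contiguous to area ``i``.
    """

    area_ids: tuple[str, ...]
    neighbors: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if len(self.neighbors) != n:
            raise ValidationError("neighbors length does not match area_ids")
        if len(set(self.area_ids)) != n:
            raise ValidationError("duplicate area ids")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValidationError(f"area {self.area_ids[i]!r} lists itself as a neighbor")
            for j in nb:
                if not 0 <= j < n:
                    raise ValidationError(f"neighbor index {j} of area {self.area_ids[i]!r} out of range")
                if i not in self.neighbors[j]:
                    raise ValidationError(
                        f"asymmetric neighbor pair: {self.area_ids[i]!r} lists "
                        f"{self.area_ids[j]!r} but not vice versa"
                    )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_i(self) -> np.ndarray:
        """Neighbor count per area."""
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nb if j > i)
        return g

    def connected_components(self) -> list[np.ndarray]:
        """Index arrays of the connected components, in first-seen order."""
        comps = nx.connected_components(self.to_networkx())
        out = [np.array(sorted(c), dtype=int) for c in comps]
        out.sort(key=lambda c: c[0])
        return out

    def component_labels(self) -> np.ndarray:
        """Component id per area (0-based, first-seen order)."""
        lab = np.empty(self.n_areas, dtype=int)
        for k, comp in enumerate(self.connected_components()):
            lab[comp] = k
        return lab

    def coloring(self) -> np.ndarray:
        """Greedy proper coloring; areas of equal color are never contiguous."""
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        return np.array([colors[i] for i in range(self.n_areas)], dtype=int)


def graph_from_neighbors(area_ids: Sequence[str], neighbors: Iterable[Iterable[int]]) -> AdjacencyGraph:
    return AdjacencyGraph(
        area_ids=tuple(str(a) for a in area_ids),
        neighbors=tuple(frozenset(int(j) for j in nb) for nb in neighbors),
    )


def graph_from_edges(area_ids: Sequence[str], edges: Iterable[tuple[str, str]]) -> AdjacencyGraph:
    """Build a graph from an edge list over labels; edges are symmetrised."""
    ids = [str(a) for a in area_ids]
    idx = {a: i for i, a in enumerate(ids)}
    nb: list[set[int]] = [set() for _ in ids]
    for a, b in edges:
        a, b = str(a), str(b)
        if a not in idx or b not in idx:
            missing = [x for x in (a, b) if x not in idx]
            raise ValidationError(f"edge references unknown area id(s): {missing}")
        i, j = idx[a], idx[b]
        if i == j:
            raise ValidationError(f"self-edge on area {a!r}")
        nb[i].add(j)
        nb[j].add(i)
    return graph_from_neighbors(ids, nb)


def read_gal(path) -> AdjacencyGraph:
    """Read a GAL-style neighbor list.

    Format: a header line whose last token is the number of areas; then for
    each area a line ``<id> <n_neighbors>`` followed by a line of neighbor ids
    (empty or absent when ``n_neighbors`` is 0).
    """
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise ValidationError("empty GAL file")
    header = tokens_by_line[0]
    n = int(header[-1])
    ids: list[str] = []
    raw: list[list[str]] = []
    pos = 1
    for _ in range(n):
        if pos >= len(tokens_by_line):
            raise ValidationError("GAL file truncated")
        aid, k = tokens_by_line[pos][0], int(tokens_by_line[pos][1])
        pos += 1
        if k > 0:
            nbrs = tokens_by_line[pos]
            if len(nbrs) != k:
                raise ValidationError(f"area {aid!r}: expected {k} neighbors, found {len(nbrs)}")
            pos += 1
        else:
            nbrs = []
        ids.append(aid)
        raw.append(nbrs)
    idx = {a: i for i, a in enumerate(ids)}
    try:
        neighbors = [[idx[b] for b in nbrs] for nbrs in raw]
    except KeyError as exc:
        raise ValidationError(f"unknown neighbor id {exc.args[0]!r}") from None
    return graph_from_neighbors(ids, neighbors)


def write_gal(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, aid in enumerate(graph.area_ids):
            nb = sorted(graph.neighbors[i])
            fh.write(f"{aid} {len(nb)}\n")
            if nb:
                fh.write(" ".join(graph.area_ids[j] for j in nb) + "\n")


def read_edge_csv(path) -> AdjacencyGraph:
    """Two-column edge-list CSV (``area_a,area_b`` header optional)."""
    import pandas as pd

    df = pd.read_csv(path, header=None, dtype=str)
    if df.iloc[0, 0].lstrip("-").replace(".", "").isalpha() and str(df.iloc[0, 0]).lower() in (
        "area_a",
        "source",
        "from",
    ):
        df = df.iloc[1:]
    edges = [(a, b) for a, b in df.itertuples(index=False)]
    ids = sorted({x for e in edges for x in e})
    return graph_from_edges(ids, edges)


# ---------------------------------------------------------------------------
# Structure matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StructureMatrix:
    """Symmetric PSD precision-structure matrix with a role tag."""

    matrix: sp.csr_matrix
    role: StructureRole

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def quad_form(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).ravel()
        return float(x @ (self.matrix @ x))

    def write_coo_csv(self, path) -> None:
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write("row,col,value\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r},{c},{v:.17g}\n")


def build_structure_matrix(graph: AdjacencyGraph) -> StructureMatrix:
    """Spatial structure matrix: graph Laplacian (degree minus adjacency).

    Entries are -1 for contiguous pairs, the neighbor count on the diagonal,
    0 elsewhere; rows sum to zero and the matrix is PSD with null-space
    dimension equal to the number of connected components.
    """
    n = graph.n_areas
    rows, cols, vals = [], [], []
    for i, nb in enumerate(graph.neighbors):
        if nb:
            rows.append(i)
            cols.append(i)
            vals.append(float(len(nb)))
        for j in nb:
            rows.append(i)
            cols.append(j)
            vals.append(-1.0)
    k = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return StructureMatrix(matrix=k, role="spatial")


def identity_structure(n: int) -> StructureMatrix:
    return StructureMatrix(matrix=sp.identity(n, format="csr"), role="identity")


def rw1_structure_matrix(T: int) -> sp.csr_matrix:
    """First-order random-walk structure matrix on ``T`` ordered points."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    if T == 1:
        return sp.csr_matrix((1, 1))
    main = np.full(T, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(T - 1, -1.0)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def build_interaction_structure(
    k_u: StructureMatrix, T: int, variant: str = "rw1-time"
) -> StructureMatrix:
    """Space-cohort interaction structure ``K_u ⊗ R``.

    ``variant='identity-time'`` uses R = I_T (cohorts exchangeable);
    ``variant='rw1-time'`` (default) uses the RW1 structure matrix, giving the
    single-site conditional precisions ``n_i`` at the boundary cohorts and
    ``2 n_i`` at interior cohorts (times the field precision).  The vec
    ordering is area-major: entry ``i*T + t`` is area ``i``, cohort ``t``.
    """
    if T < 2:
        raise ValidationError("interaction structure needs T >= 2")
    if variant == "identity-time":
        r = sp.identity(T, format="csr")
    elif variant == "rw1-time":
        r = rw1_structure_matrix(T)
    else:
        raise ValidationError(f"unknown interaction variant {variant!r}")
    return StructureMatrix(matrix=sp.kron(k_u.matrix, r, format="csr"), role="interaction")


# ---------------------------------------------------------------------------
# Constrained omega covariance
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OmegaCovariance:
    """Singular covariance of the cohort log-scalings, rank T-1.

    The shared-field scalings ``omega_t`` satisfy ``sum_t log omega_t = 0``;
    jointly the logs are normal with variance ``sigma2_omega`` each and
    constant negative correlation ``-1/(T-1)``, i.e. an isotropic normal on
    the sum-to-zero subspace with variance ``sigma2_omega * T/(T-1)``.
    """

    T: int
    sigma2_omega: float
    matrix: np.ndarray

    def subspace_variance(self) -> float:
        """Variance along each direction of the sum-to-zero subspace."""
        return self.sigma2_omega * self.T / (self.T - 1)


def build_omega_covariance(T: int, sigma2: float) -> OmegaCovariance:
    if T < 2:
        raise ValidationError("omega constraint degenerate for T < 2")
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    m = np.full((T, T), -sigma2 / (T - 1))
    np.fill_diagonal(m, sigma2)
    return OmegaCovariance(T=T, sigma2_omega=float(sigma2), matrix=m)


def sum_zero_basis(T: int) -> np.ndarray:
    """Orthonormal T×(T-1) basis of the sum-to-zero subspace (Helmert).

    For T = 2 the single column is exactly ``(c, -c)`` so that the summed
    constraint is bitwise zero for any coefficient.
    """
    b = np.zeros((T, T - 1))
    for k in range(1, T):
        col = np.zeros(T)
        col[:k] = 1.0
        col[k] = -float(k)
        col /= np.sqrt(k * (k + 1.0))
        b[:, k - 1] = col
    return b


# ---------------------------------------------------------------------------
# Full conditionals and exact prior sampling
# ---------------------------------------------------------------------------


def car_full_conditional(
    field: np.ndarray, i: int, tau: float, graph: AdjacencyGraph
) -> tuple[float, float]:
    """Intrinsic-CAR full conditional of area ``i``: (mean, precision).

    Mean is the neighbour average of ``field``; precision is ``n_i * tau``.
    Undefined for isolated areas (no neighbours).
    """
    nb = graph.neighbors[i]
    if not nb:
        raise ValidationError(
            f"area {graph.area_ids[i]!r} has no neighbors; the intrinsic-CAR "
            "conditional is undefined for islands"
        )
    field = np.asarray(field, dtype=float)
    idx = np.fromiter(nb, dtype=int)
    return float(field[idx].mean()), float(len(nb) * tau)


def car_rank(graph: AdjacencyGraph) -> int:
    """Rank of the spatial structure matrix: I minus #components."""
    return graph.n_areas - len(graph.connected_components())


def _car_spectral_cache(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray]:
    k = build_structure_matrix(graph).dense()
    evals, evecs = np.linalg.eigh(k)
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    return evals[keep], evecs[:, keep]


def sample_intrinsic_car(
    graph: AdjacencyGraph, tau: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Exact draw from the intrinsic CAR prior, sum-zero per component.

    The draw lives in the span of the structure matrix's non-null
    eigenvectors, with variance ``1/(tau * eigenvalue)`` along each; isolated
    areas receive 0.  Used by the synthetic-data generator and as an oracle.
    """
    if tau <= 0:
        raise ValidationError("tau must be positive")
    rng = np.random.default_rng(rng)
    evals, evecs = _car_spectral_cache(graph)
    z = rng.standard_normal(evals.shape[0]) / np.sqrt(tau * evals)
    return evecs @ z
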