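"""The ISOMAP core: neighbour graph, geodesics, classical MDS and the
residual-variance dimensionality criterion.

The working definition of collective behaviour implemented here is the
existence of a low-dimensional manifold on which the group's video frames —
viewed as points in pixel space — can be embedded.  The pipeline is:

1. build a nu-nearest-neighbour graph over the frames, with ambient
   (pixel-space) Euclidean edge weights and non-edges set to infinity so
   shortest paths cannot jump between manifold branches;
2. approximate on-manifold geodesic distances by all-pairs shortest paths
   (Floyd-Warshall by default; repeated Dijkstra as an equivalent,
   often faster, solver);
3. embed with classical multidimensional scaling (double-centred squared
   distances, eigendecomposition);
4. for each candidate dimension d compute the residual variance
   R(d) = 1 - rho^2, where rho is the linear correlation between geodesic
   distances and pairwise Euclidean distances among the first d embedding
   coordinates; the estimated dimensionality is the smallest d with
   R(d) below a threshold (default 0.05).

Trials where R never drops below the threshold within d_max dimensions are
*censored*: they carry the value d_max + 1 downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "GeodesicMatrix",
    "EmbeddingResult",
    "build_knn_graph",
    "largest_component",
    "geodesic_matrix",
    "classical_mds",
    "residual_variances",
    "embedding_dimensionality",
    "isomap",
]

_SOLVERS = {"floyd": "FW", "dijkstra": "D", "auto": "auto"}


@dataclass
class NeighborGraph:
    """Symmetric nu-NN graph; ``weights[i, j]`` is the ambient Euclidean
    distance for connected pairs and infinity otherwise (zero diagonal)."""

    weights: np.ndarray
    nu: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    def finite_mask(self) -> np.ndarray:
        mask = np.isfinite(self.weights)
        np.fill_diagonal(mask, False)
        return mask


@dataclass
class GeodesicMatrix:
    """All-pairs shortest-path lengths over a neighbour graph; infinity
    between distinct connected components."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass
class EmbeddingResult:
    """MDS coordinates, residual-variance scree and estimated dimensionality.

    ``dimensionality`` equals ``d_max + 1`` for censored trials (no R(d)
    below the threshold); check :attr:`censored`.
    """

    coordinates: np.ndarray
    residuals: np.ndarray
    dimensionality: int
    d_max: int
    threshold: float
    nu: int | None = None
    retained_fraction: float = 1.0
    retained_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def censored(self) -> bool:
        return self.dimensionality > self.d_max


def build_knn_graph(Z: np.ndarray, nu: int) -> NeighborGraph:
    """Symmetric union nu-nearest-neighbour graph in ambient Euclidean
    distance.

    An edge {i, j} exists when j is among the nu closest points to i *or*
    vice versa; distance ties are broken by ascending index.  Duplicate rows
    are allowed (edge weight 0).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if not 1 <= nu < n:
        raise ValueError(f"need 1 <= nu < n, got nu={nu}, n={n}")
    dist = squareform(pdist(Z))
    # stable argsort on (distance, index); exclude self via inf diagonal
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    nearest = order[:, :nu]
    weights = np.full((n, n), np.inf)
    rows = np.repeat(np.arange(n), nu)
    cols = nearest.ravel()
    weights[rows, cols] = dist[rows, cols]
    weights[cols, rows] = dist[cols, rows]  # union symmetrization
    np.fill_diagonal(weights, 0.0)
    return NeighborGraph(weights=weights, nu=nu)


def largest_component(
    graph: NeighborGraph, min_fraction: float = 0.0
) -> tuple[NeighborGraph, np.ndarray]:
    """Restrict to the largest connected component.

    Returns the induced subgraph and the retained vertex indices.  Ties in
    component size are resolved in favour of the component containing the
    lowest-index vertex.  If the retained fraction falls below
    ``min_fraction`` the data are considered too sparse and an error is
    raised.
    """
    mask = graph.finite_mask()
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # labels are assigned in order of first occurrence, so argmax's
    # first-winner rule retains the lowest-index component on ties
    keep_label = int(np.argmax(sizes))
    idx = np.flatnonzero(labels == keep_label)
    fraction = idx.size / graph.n_vertices
    if fraction < min_fraction:
        raise ValueError(
            f"largest component retains only {fraction:.1%} of points "
            f"(floor {min_fraction:.0%}): data too sparse for a connected "
            "neighbour graph"
        )
    sub = NeighborGraph(weights=graph.weights[np.ix_(idx, idx)], nu=graph.nu)
    return sub, idx


def geodesic_matrix(graph: NeighborGraph, method: str = "floyd") -> GeodesicMatrix:
    """All-pairs shortest paths over the neighbour graph.

    ``method`` is ``"floyd"`` (Floyd-Warshall, the reference solver),
    ``"dijkstra"`` (per-source Dijkstra, faster on sparse graphs) or
    ``"auto"``.  Vertices in different components end up at infinite
    distance.
    """
    if method not in _SOLVERS:
        raise ValueError(f"unknown solver {method!r}; choose from {sorted(_SOLVERS)}")
    mask = graph.finite_mask()
    # csr with explicit zeros so duplicate points (distance 0) stay connected
    n = graph.n_vertices
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(mask.sum(axis=1), out=indptr[1:])
    indices = np.flatnonzero(mask.ravel()) % n
    data = graph.weights[mask]
    csg = csr_matrix((data, indices, indptr), shape=(n, n))
    D = shortest_path(csg, method=_SOLVERS[method], directed=False)
    return GeodesicMatrix(D=D)


def classical_mds(D: GeodesicMatrix | np.ndarray, d_max: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a finite symmetric distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns the
    ``n x d_max`` coordinate matrix (columns ordered by descending
    eigenvalue, scaled by the square root of the eigenvalue).  Directions
    with non-positive eigenvalues contribute zero coordinates.  Each
    column's sign is fixed so its largest-magnitude entry is positive,
    making coordinates reproducible across runs and libraries.
    """
    Dm = D.D if isinstance(D, GeodesicMatrix) else np.asarray(D, dtype=float)
    if not np.all(np.isfinite(Dm)):
        raise ValueError(
            "distance matrix has non-finite entries; restrict to the "
            "largest connected component first"
        )
    n = Dm.shape[0]
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    sq = Dm ** 2
    row_mean = sq.mean(axis=1, keepdims=True)
    B = -0.5 * (sq - row_mean - row_mean.T + sq.mean())
    B = 0.5 * (B + B.T)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:d_max]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    coords = np.zeros((n, d_max))
    pos = vals > 0
    coords[:, pos] = vecs[:, pos] * np.sqrt(vals[pos])
    # deterministic sign convention
    for j in range(d_max):
        col = coords[:, j]
        if col.any():
            k = int(np.argmax(np.abs(col)))
            if col[k] < 0:
                coords[:, j] = -col
    return coords


def residual_variances(D: GeodesicMatrix | np.ndarray, coordinates: np.ndarray) -> np.ndarray:
    """Residual variance R(d) = 1 - rho^2 for d = 1..d_max.

    ``rho`` is the Pearson correlation between the upper-triangle geodesic
    distances and the pairwise Euclidean distances computed from the first
    ``d`` coordinate columns.  R is 0 for a perfect embedding, 1 for the
    worst; if either distance vector is constant the correlation is
    undefined and R(d) is reported as 1 with a warning.
    """
    Dm = D.D if isinstance(D, GeodesicMatrix) else np.asarray(D, dtype=float)
    coordinates = np.asarray(coordinates, dtype=float)
    n, d_max = coordinates.shape
    if Dm.shape != (n, n):
        raise ValueError("distance matrix and coordinates disagree on n")
    iu = np.triu_indices(n, k=1)
    g = Dm[iu]
    R = np.empty(d_max)
    for d in range(1, d_max + 1):
        e = pdist(coordinates[:, :d])
        if g.std() == 0 or e.std() == 0:
            warnings.warn(
                f"constant distance vector at d={d}; residual variance "
                "undefined, reporting 1",
                stacklevel=2,
            )
            R[d - 1] = 1.0
            continue
        rho = np.corrcoef(g, e)[0, 1]
        R[d - 1] = 1.0 - rho ** 2
    # numerical guard: correlation rounding can push R marginally outside [0, 1]
    np.clip(R, 0.0, 1.0, out=R)
    if np.any(np.diff(R) > 1e-9):
        logger.debug("residual-variance scree is not monotone: %s", R)
    return R


def embedding_dimensionality(R: np.ndarray, threshold: float = 0.05,
                             d_max: int | None = None) -> int:
    """Smallest d with R(d) < threshold; ``d_max + 1`` when censored."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty residual-variance vector")
    if d_max is None:
        d_max = R.size
    below = np.flatnonzero(R[:d_max] < threshold)
    if below.size:
        return int(below[0]) + 1
    return d_max + 1


def isomap(
    Z: np.ndarray,
    nu: int = 11,
    d_max: int = 11,
    threshold: float = 0.05,
    component_floor: float = 0.90,
    solver: str = "auto",
) -> EmbeddingResult:
    """Full ISOMAP dimensionality estimate of a data matrix ``Z`` (rows are
    frames or points, columns are ambient coordinates).

    Composes the neighbour graph, largest-component restriction, geodesic
    matrix, classical MDS, residual variances and the threshold criterion.
    Defaults (nu=11, d_max=11, threshold=0.05) are the standard analysis
    profile; the estimate is insensitive to nu over roughly 7..15 on
    well-sampled manifolds.
    """
    Z = np.asarray(Z, dtype=float)
    graph = build_knn_graph(Z, nu=nu)
    sub, idx = largest_component(graph, min_fraction=component_floor)
    geo = geodesic_matrix(sub, method=solver)
    coords = classical_mds(geo, d_max=d_max)
    R = residual_variances(geo, coords)
    dim = embedding_dimensionality(R, threshold=threshold, d_max=d_max)
    return EmbeddingResult(
        coordinates=coords,
        residuals=R,
        dimensionality=dim,
        d_max=d_max,
        threshold=threshold,
        nu=nu,
        retained_fraction=idx.size / Z.shape[0],
        retained_indices=idx,
    )
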