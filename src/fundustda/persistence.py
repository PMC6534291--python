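"""Lower-star filtration persistent homology of 2D scalar fields.

The field ``z(x, y)`` is filtered by its sub-level sets ``{z < l}`` as the
level ``l`` sweeps from below the minimum to above the maximum.  The grid is
triangulated with a uniform Freudenthal split (one diagonal per unit square,
from ``(i, j)`` to ``(i+1, j+1)``) and each simplex enters the filtration at
the maximum of its vertex values — the lower-star rule.  Connected
components (dimension 0) are born at local minima and die when they merge
into an older component (elder rule); holes (dimension 1) are born when an
edge closes a loop and die at the local maximum that fills them.

Two independent engines are provided:

* :func:`compute_persistence` — fast union-find for dimension 0 and a dual
  (Alexander-duality) union-find over triangles for dimension 1; linear
  memory, near-linear time, used for full-size images.
* :func:`brute_force_persistence` — textbook boundary-matrix reduction over
  GF(2), restricted to small complexes; the verification oracle.

Births and deaths are recorded as field values.  Zero-persistence pairs
(birth equal to death) are discarded.  The single essential component of a
connected grid is reported with its death capped at the maximum field value
and flagged ``essential``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Filtration",
    "PersistenceDiagram",
    "InvalidFieldError",
    "OracleSizeError",
    "build_lower_star_filtration",
    "compute_persistence",
    "sublevel_betti",
    "brute_force_persistence",
    "write_diagrams_csv",
]


class InvalidFieldError(ValueError):
    """Field contains non-finite values or has an unusable shape."""


class OracleSizeError(ValueError):
    """Complex too large for the brute-force reduction oracle."""


@dataclass(frozen=True)
class PersistenceDiagram:
    """Birth/death pairs of one homology dimension.

    Attributes
    ----------
    dimension
        Homology dimension, 0 (components) or 1 (holes).
    pairs
        ``(n, 2)`` float array of (birth, death) field values, death >= birth.
    essential
        Boolean flag per pair; an essential class never dies inside the
        filtration and its death is capped at the maximum field value.
    """

    dimension: int
    pairs: np.ndarray
    essential: np.ndarray

    def __post_init__(self) -> None:
        pairs = np.atleast_2d(np.asarray(self.pairs, dtype=np.float64))
        if pairs.size == 0:
            pairs = pairs.reshape(0, 2)
        ess = np.asarray(self.essential, dtype=bool).reshape(-1)
        if pairs.shape[1] != 2 or len(ess) != len(pairs):
            raise ValueError("pairs must be (n, 2) with one essential flag per pair")
        if np.any(pairs[:, 1] < pairs[:, 0]):
            raise ValueError("death must be >= birth")
        order = np.lexsort((ess, pairs[:, 1], pairs[:, 0]))
        object.__setattr__(self, "pairs", pairs[order])
        object.__setattr__(self, "essential", ess[order])

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def births(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.pairs[:, 1]

    @property
    def lifetimes(self) -> np.ndarray:
        return self.pairs[:, 1] - self.pairs[:, 0]

    def without_essential(self) -> "PersistenceDiagram":
        keep = ~self.essential
        return PersistenceDiagram(self.dimension, self.pairs[keep], self.essential[keep])

    def equals(self, other: "PersistenceDiagram") -> bool:
        return (
            self.dimension == other.dimension
            and self.pairs.shape == other.pairs.shape
            and np.array_equal(self.pairs, other.pairs)
            and np.array_equal(self.essential, other.essential)
        )


@dataclass
class Filtration:
    """Freudenthal triangulation of a grid with lower-star values.

    Vertices are grid points indexed in row-major order; ``edges`` and
    ``triangles`` hold vertex-index rows sorted ascending within each
    simplex.  Each simplex carries the maximum of its vertex values.
    """

    shape: tuple[int, int]
    vertex_values: np.ndarray  # (V,)
    edges: np.ndarray  # (E, 2) int
    edge_values: np.ndarray  # (E,)
    triangles: np.ndarray  # (T, 3) int
    triangle_values: np.ndarray  # (T,)
    # dual adjacency: for each edge, indices of the <=2 incident triangles
    # (-1 marks the outer face)
    edge_cofaces: np.ndarray = dataclass_field(repr=False, default=None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_values)

    @property
    def n_simplices(self) -> int:
        return self.n_vertices + len(self.edges) + len(self.triangles)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + len(self.triangles)

    def simplex_order(self) -> list[tuple[tuple[float, int, int, tuple[int, ...]], int, tuple[int, ...]]]:
        """Total order of all simplices as (sort_key, dimension, vertices).

        Key is (value, dimension, max vertex index, vertex tuple): faces
        always precede cofaces, and ties are broken deterministically by
        row-major vertex index (simulation of simplicity).
        """
        items = []
        for v in range(self.n_vertices):
            items.append(((float(self.vertex_values[v]), 0, v, (v,)), 0, (v,)))
        for e, val in zip(self.edges, self.edge_values):
            tup = tuple(int(x) for x in e)
            items.append(((float(val), 1, tup[-1], tup), 1, tup))
        for t, val in zip(self.triangles, self.triangle_values):
            tup = tuple(int(x) for x in t)
            items.append(((float(val), 2, tup[-1], tup), 2, tup))
        items.sort(key=lambda it: it[0])
        return items


def build_lower_star_filtration(field: np.ndarray) -> Filtration:
    """Triangulate a grid field and assign lower-star filtration values.

    Every unit square is split along its (i, j)-(i+1, j+1) diagonal, giving
    ``V = HW`` vertices, ``E = H(W-1) + W(H-1) + (H-1)(W-1)`` edges and
    ``T = 2(H-1)(W-1)`` triangles (Euler characteristic 1).  Degenerate
    strips (H == 1 or W == 1) yield a path graph with no triangles.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2 or field.size < 2:
        raise InvalidFieldError(f"expected a 2D field with >= 2 pixels, got shape {field.shape}")
    if not np.all(np.isfinite(field)):
        raise InvalidFieldError("field contains non-finite values")
    h, w = field.shape
    vals = field.ravel()
    idx = np.arange(h * w).reshape(h, w)

    edge_list = []
    if w > 1:  # horizontal
        edge_list.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    if h > 1:  # vertical
        edge_list.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    if h > 1 and w > 1:  # diagonal (i, j) - (i+1, j+1)
        edge_list.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
    edges = np.concatenate(edge_list, axis=0)
    edges.sort(axis=1)

    if h > 1 and w > 1:
        # upper triangle {(i,j), (i,j+1), (i+1,j+1)}, lower {(i,j), (i+1,j), (i+1,j+1)}
        a = idx[:-1, :-1].ravel()
        b = idx[:-1, 1:].ravel()
        c = idx[1:, :-1].ravel()
        d = idx[1:, 1:].ravel()
        upper = np.stack([a, b, d], axis=1)
        lower = np.stack([a, c, d], axis=1)
        triangles = np.concatenate([upper, lower], axis=0)
        triangles.sort(axis=1)
    else:
        triangles = np.empty((0, 3), dtype=np.int64)

    edge_values = vals[edges].max(axis=1)
    triangle_values = vals[triangles].max(axis=1) if len(triangles) else np.empty(0)

    edge_cofaces = _edge_cofaces(h, w)
    return Filtration((h, w), vals, edges, edge_values, triangles, triangle_values, edge_cofaces)


def _edge_cofaces(h: int, w: int) -> np.ndarray:
    """Map each edge (in build order) to its incident triangle indices.

    Triangles are indexed in build order: the ``(h-1)(w-1)`` upper triangles
    of each unit square first, then the lower triangles.  ``-1`` denotes the
    outer face of the plane.
    """
    n_sq = (h - 1) * (w - 1)
    sq = np.arange(n_sq).reshape(h - 1, w - 1) if n_sq else np.empty((0, 0), dtype=np.int64)
    cof = []
    if w > 1:
        # horizontal edge (i, j)-(i, j+1): upper triangle of square (i, j),
        # lower triangle of square (i-1, j)
        up = np.full((h, w - 1), -1, dtype=np.int64)
        lo = np.full((h, w - 1), -1, dtype=np.int64)
        if h > 1:
            up[:-1, :] = sq
            lo[1:, :] = sq + n_sq
        cof.append(np.stack([up.ravel(), lo.ravel()], axis=1))
    if h > 1:
        # vertical edge (i, j)-(i+1, j): lower triangle of square (i, j),
        # upper triangle of square (i, j-1)
        lo = np.full((h - 1, w), -1, dtype=np.int64)
        up = np.full((h - 1, w), -1, dtype=np.int64)
        if w > 1:
            lo[:, :-1] = sq + n_sq
            up[:, 1:] = sq
        cof.append(np.stack([lo.ravel(), up.ravel()], axis=1))
    if h > 1 and w > 1:
        # diagonal edge: both triangles of its own square
        cof.append(np.stack([sq.ravel(), sq.ravel() + n_sq], axis=1))
    return np.concatenate(cof, axis=0)


class _UnionFind:
    """Union-find with elder rule: the root with the smaller key survives."""

    __slots__ = ("parent", "birth_key")

    def __init__(self, keys: list) -> None:
        self.parent = list(range(len(keys)))
        self.birth_key = keys

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> tuple[int, int] | None:
        """Merge components of a and b; return (survivor, dying) roots."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if self.birth_key[rb] < self.birth_key[ra]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return ra, rb


def _edge_sort_order(filtration: Filtration, descending: bool = False) -> np.ndarray:
    """Edge processing order by (value, max vertex index, min vertex index)."""
    e = filtration.edges
    keys = (filtration.edge_values, e[:, 1], e[:, 0])
    order = np.lexsort((keys[2], keys[1], keys[0]))
    return order[::-1] if descending else order


def compute_persistence(filtration: Filtration) -> tuple[PersistenceDiagram, PersistenceDiagram]:
    """Persistence diagrams in dimensions 0 and 1 by twin union-finds.

    Dimension 0 runs the elder rule directly: edges are processed in
    filtration order, and when two components merge the younger one (larger
    birth value, ties by vertex index) dies at the edge value.

    Dimension 1 uses planar duality: a hole born at edge value ``b`` and
    filled at triangle value ``d`` corresponds, in the reversed filtration
    of the dual graph (triangles plus the outer face), to a component born
    at the triangle and absorbed at the edge.  Processing dual edges in
    decreasing filtration order with the reversed elder rule therefore
    yields exactly the dimension-1 pairing of the boundary-matrix reduction.
    """
    vals = filtration.vertex_values
    n = filtration.n_vertices

    # --- dimension 0 ---
    uf = _UnionFind([(float(vals[v]), v) for v in range(n)])
    pairs0 = []
    for ei in _edge_sort_order(filtration):
        u, v = filtration.edges[ei]
        merged = uf.union(int(u), int(v))
        if merged is not None:
            _, dying = merged
            birth = uf.birth_key[dying][0]
            death = float(filtration.edge_values[ei])
            if death > birth:
                pairs0.append((birth, death))
    global_min = float(vals.min())
    global_max = float(vals.max())
    pairs0.append((global_min, global_max))
    ess0 = np.zeros(len(pairs0), dtype=bool)
    ess0[-1] = True
    dgm0 = PersistenceDiagram(0, np.array(pairs0), ess0)

    # --- dimension 1 via the dual graph ---
    pairs1 = []
    nt = len(filtration.triangles)
    if nt:
        tri_keys: list = [
            (float(filtration.triangle_values[t]), int(filtration.triangles[t][2]), t)
            for t in range(nt)
        ]
        # outer face: eldest in the reversed order
        keys = [(-k[0], -k[1], -k[2]) for k in tri_keys]  # negate: reversed elder rule
        keys.append((-np.inf, 0, 0))
        outer = nt
        duf = _UnionFind(keys)
        for ei in _edge_sort_order(filtration, descending=True):
            t1, t2 = filtration.edge_cofaces[ei]
            a = outer if t1 < 0 else int(t1)
            b = outer if t2 < 0 else int(t2)
            merged = duf.union(a, b)
            if merged is not None:
                _, dying = merged
                death = -duf.birth_key[dying][0]
                birth = float(filtration.edge_values[ei])
                if death > birth:
                    pairs1.append((birth, death))
    dgm1 = PersistenceDiagram(1, np.array(pairs1).reshape(-1, 2), np.zeros(len(pairs1), dtype=bool))
    return dgm0, dgm1


def sublevel_betti(field: np.ndarray, level: float) -> tuple[int, int]:
    """Betti numbers (beta0, beta1) of the strict sub-level complex {z < l}.

    Computed independently of the persistence pairing: beta0 by sparse
    connected-component labelling of the included vertices and edges, beta1
    from the Euler relation ``beta0 - beta1 = V - E + T``.
    """
    filtration = build_lower_star_filtration(field)
    vkeep = filtration.vertex_values < level
    nv = int(vkeep.sum())
    if nv == 0:
        return 0, 0
    ekeep = filtration.edge_values < level
    tkeep = filtration.triangle_values < level if len(filtration.triangles) else np.zeros(0, dtype=bool)
    ne, ntri = int(ekeep.sum()), int(tkeep.sum())

    vidx = np.flatnonzero(vkeep)
    remap = -np.ones(filtration.n_vertices, dtype=np.int64)
    remap[vidx] = np.arange(nv)
    sub_edges = remap[filtration.edges[ekeep]]
    graph = coo_matrix(
        (np.ones(ne), (sub_edges[:, 0], sub_edges[:, 1])), shape=(nv, nv)
    )
    beta0 = connected_components(graph, directed=False)[0]
    beta1 = beta0 - nv + ne - ntri
    return int(beta0), int(beta1)


def brute_force_persistence(
    filtration: Filtration, max_simplices: int = 2000
) -> tuple[PersistenceDiagram, PersistenceDiagram]:
    """Reference diagrams by full boundary-matrix reduction over GF(2).

    The standard column algorithm: simplices are sorted by the filtration
    total order, each column holds its facet indices, and columns are added
    (symmetric difference) until their lowest entry is a fresh pivot.  A
    column that empties creates a class; a surviving pivot (i, j) pairs the
    birth simplex i with the death simplex j.  Intended for small grids
    only; use :func:`compute_persistence` for real images.
    """
    if filtration.n_simplices > max_simplices:
        raise OracleSizeError(
            f"{filtration.n_simplices} simplices exceed the oracle limit of {max_simplices}"
        )
    order = filtration.simplex_order()
    position = {verts: i for i, (_, _, verts) in enumerate(order)}
    columns: list[set[int] | None] = []
    for _, dim, verts in order:
        if dim == 0:
            columns.append(set())
        else:
            facets = [verts[:k] + verts[k + 1 :] for k in range(len(verts))]
            columns.append({position[f] for f in facets})

    pivot_of: dict[int, int] = {}
    pairs_by_dim: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    unpaired = set(range(len(order)))
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            if low not in pivot_of:
                pivot_of[low] = j
                birth = order[low][0][0]
                death = order[j][0][0]
                dim = order[low][1]
                if dim <= 1 and death > birth:
                    pairs_by_dim[dim].append((birth, death))
                unpaired.discard(low)
                unpaired.discard(j)
                break
            col ^= columns[pivot_of[low]]

    global_max = float(filtration.vertex_values.max())
    ess_pairs = []
    for i in sorted(unpaired):
        key, dim, _ = order[i]
        if dim == 0:
            ess_pairs.append((key[0], global_max))
        elif dim == 1:
            raise AssertionError("unexpected essential 1-cycle on a disk complex")
    pairs0 = pairs_by_dim[0] + ess_pairs
    ess0 = np.zeros(len(pairs0), dtype=bool)
    ess0[len(pairs_by_dim[0]) :] = True
    dgm0 = PersistenceDiagram(0, np.array(pairs0).reshape(-1, 2), ess0)
    dgm1 = PersistenceDiagram(
        1, np.array(pairs_by_dim[1]).reshape(-1, 2), np.zeros(len(pairs_by_dim[1]), dtype=bool)
    )
    return dgm0, dgm1


def write_diagrams_csv(path, diagrams: list[PersistenceDiagram]) -> None:
    """Write diagrams to CSV with columns dimension,birth,death,essential."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dimension", "birth", "death", "essential"])
        for dgm in diagrams:
            for (b, d), ess in zip(dgm.pairs, dgm.essential):
                writer.writerow([dgm.dimension, repr(float(b)), repr(float(d)), int(ess)])
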