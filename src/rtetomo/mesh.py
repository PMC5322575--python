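"""Triangulated disk domains, boundary sources/detectors, and upwind element ordering.

Meshes are generated by a deterministic concentric-ring construction: ring m of
M carries about ``c*m`` nodes (c chosen so the element count hits the requested
target), annuli are triangulated by an angular zipper merge, and interior nodes
receive a small seeded jitter so that two meshes with different seeds or ring
counts are genuinely different discretizations (used to avoid the inverse
crime: data are synthesized on a finer mesh than the one used for inversion).

Units are millimetres; the domain center is at the origin.  Element and node
indices are 0-based in memory and 1-based in the exported text format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "TriMesh",
    "SourceSpec",
    "DetectorSpec",
    "build_trimesh",
    "mesh_disk",
    "place_boundary_units",
    "upwind_order",
    "transfer_piecewise_constant",
]

# An edge with |omega . n| below this is treated as non-coupling when ordering
# elements along a transport direction (unit vectors, so the scale is absolute).
_DEG_TOL = 1e-12


@dataclass
class TriMesh:
    """Conforming triangulation of a disk with precomputed DG geometry.

    Core fields
    -----------
    nodes : (V, 2) float array, mm
    triangles : (T, 3) int array, counterclockwise node triples

    Derived (filled by :func:`build_trimesh`)
    -----------------------------------------
    areas : (T,) element areas, mm^2
    grads : (T, 3, 2) constant gradients of the three linear hat functions
    neighbor : (T, 3) adjacent element across local edge l (-1 on the boundary);
        local edge l joins local nodes l and (l+1) % 3
    neighbor_edge : (T, 3) local edge index of the shared edge in the neighbor
    normals : (T, 3, 2) outward unit edge normals
    edge_len : (T, 3) edge lengths, mm
    boundary_edges : (B, 2) (element, local edge) pairs ordered as the CCW
        boundary loop
    bedge_id : (T, 3) boundary-edge index or -1
    interior_edges : (E_i, 4) (t1, l1, t2, l2) one record per interior edge
    radius : disk radius when generated by :func:`mesh_disk`, else None
    """

    nodes: np.ndarray
    triangles: np.ndarray
    areas: np.ndarray = field(default=None, repr=False)
    grads: np.ndarray = field(default=None, repr=False)
    neighbor: np.ndarray = field(default=None, repr=False)
    neighbor_edge: np.ndarray = field(default=None, repr=False)
    normals: np.ndarray = field(default=None, repr=False)
    edge_len: np.ndarray = field(default=None, repr=False)
    boundary_edges: np.ndarray = field(default=None, repr=False)
    bedge_id: np.ndarray = field(default=None, repr=False)
    interior_edges: np.ndarray = field(default=None, repr=False)
    radius: float | None = None

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class BoundaryUnit:
    """A boundary node with its two adjacent boundary edges and the values of
    the piecewise-linear hat (peaked at the node) on each edge's endpoints.

    ``edges`` holds (edge_id, element, local_edge, h_start, h_end) per edge,
    where h_start/h_end are the hat values at the edge's start/end node in the
    CCW boundary orientation.  ``support`` is the total arc length of the two
    edges; the hat has unit peak, so its integral is support / 2.
    """

    index: int
    node: int
    position: np.ndarray  # node coordinates on the boundary, mm
    edges: list[tuple[int, int, int, float, float]]
    support: float


@dataclass
class SourceSpec(BoundaryUnit):
    """Collimated boundary source: hat profile peaked at a boundary node,
    injected in the single grid direction nearest the inward radial direction
    of the node's nominal angle.

    ``amplitude`` scales the hat; with power normalization (the default in
    :func:`place_boundary_units`) amplitude = 2 / support so every source
    injects unit power regardless of local edge lengths — essential when
    data synthesized on one mesh are inverted on another.
    """

    direction_index: int | None = None
    direction: np.ndarray | None = None
    amplitude: float = 1.0


@dataclass
class DetectorSpec(BoundaryUnit):
    """Detector reading the hat-weighted average of the outgoing flux density
    around its boundary node (weight integral = support / 2)."""


def _signed_area(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                  - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))


def build_trimesh(nodes: np.ndarray, triangles: np.ndarray,
                  radius: float | None = None) -> TriMesh:
    """Assemble all derived geometry/adjacency; validates the triangulation."""
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    sa = _signed_area(nodes, triangles)
    flip = sa < 0
    if flip.any():
        triangles = triangles.copy()
        triangles[flip] = triangles[flip][:, [0, 2, 1]]
        sa = np.abs(sa)
    if np.any(sa <= 0):
        raise ValueError("degenerate (zero-area) triangle in mesh")
    areas = sa

    T = len(triangles)
    p = nodes[triangles]  # (T,3,2)
    # hat-function gradients: grad phi_i = rot90(opposite edge vector)/(2A)
    grads = np.empty((T, 3, 2))
    for i in range(3):
        e = p[:, (i + 2) % 3] - p[:, (i + 1) % 3]  # opposite edge
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= (2.0 * areas)[:, None, None]

    # local edge l: from local node l to (l+1)%3
    edge_vec = p[:, [1, 2, 0]] - p[:, [0, 1, 2]]  # (T,3,2)
    edge_len = np.linalg.norm(edge_vec, axis=2)
    normals = np.stack([edge_vec[..., 1], -edge_vec[..., 0]], axis=-1)
    normals /= edge_len[..., None]

    neighbor = np.full((T, 3), -1, dtype=np.int64)
    neighbor_edge = np.full((T, 3), -1, dtype=np.int64)
    seen: dict[tuple[int, int], tuple[int, int]] = {}
    interior = []
    for t in range(T):
        tri = triangles[t]
        for l in range(3):
            a, b = int(tri[l]), int(tri[(l + 1) % 3])
            key = (min(a, b), max(a, b))
            if key in seen:
                t2, l2 = seen.pop(key)
                neighbor[t, l] = t2
                neighbor[t2, l2] = t
                neighbor_edge[t, l] = l2
                neighbor_edge[t2, l2] = l
                interior.append((t2, l2, t, l))
            else:
                seen[key] = (t, l)
    interior_edges = np.array(interior, dtype=np.int64).reshape(-1, 4)

    # remaining edges are the boundary; order them into the CCW loop
    b_list = list(seen.values())
    if not b_list:
        raise ValueError("mesh has no boundary edges")
    start_node: dict[int, tuple[int, int]] = {}
    for t, l in b_list:
        start_node[int(triangles[t, l])] = (t, l)
    t0, l0 = b_list[0]
    loop = [(t0, l0)]
    nxt = int(triangles[t0, (l0 + 1) % 3])
    while nxt != int(triangles[t0, l0]):
        t, l = start_node[nxt]
        loop.append((t, l))
        nxt = int(triangles[t, (l + 1) % 3])
    if len(loop) != len(b_list):
        raise ValueError("boundary edges do not form a single closed loop")
    boundary_edges = np.array(loop, dtype=np.int64)
    bedge_id = np.full((T, 3), -1, dtype=np.int64)
    for k, (t, l) in enumerate(boundary_edges):
        bedge_id[t, l] = k

    return TriMesh(nodes=nodes, triangles=triangles, areas=areas, grads=grads,
                   neighbor=neighbor, neighbor_edge=neighbor_edge,
                   normals=normals, edge_len=edge_len,
                   boundary_edges=boundary_edges, bedge_id=bedge_id,
                   interior_edges=interior_edges, radius=radius)


def _ring_layout(target_elements: int) -> tuple[int, list[int]]:
    """Choose ring count M and per-ring node counts summing to ~target elements.

    With counts n_1..n_M the element total is n_1 + sum_{m>=2}(n_{m-1}+n_m)
    = 2*sum_{m<M} n_m + n_M; the outer ring count absorbs the rounding
    remainder so the target is hit exactly whenever the correction is mild.
    """
    best = None
    m0 = max(1, round(np.sqrt(target_elements / (2.0 * np.pi))))
    for M in {max(1, m0 - 1), m0, m0 + 1}:
        c = target_elements / M**2
        counts = [max(3, round(c * m)) for m in range(1, M + 1)]
        total = 2 * sum(counts[:-1]) + counts[-1]
        adj = target_elements - total
        adj = int(np.clip(adj, -counts[-1] // 3, counts[-1] // 3))
        counts[-1] += adj
        total += adj
        score = (abs(total - target_elements), abs(c - 2 * np.pi))
        if best is None or score < best[0]:
            best = (score, M, counts)
    return best[1], best[2]


def mesh_disk(radius: float, target_elements: int, seed: int = 0,
              jitter: float = 0.15, boundary_multiple: int | None = None) -> TriMesh:
    """Triangulate the disk of the given radius with ~target_elements elements.

    Deterministic for a fixed seed.  Interior nodes are jittered by a fraction
    of the local spacing (halved automatically if a triangle would invert);
    boundary nodes stay exactly on the circle.

    If ``boundary_multiple`` is given, the outer ring carries a multiple of
    that many equispaced nodes starting at angle 0, so the nominal positions
    of k equispaced (or half-spacing offset) boundary units are exact boundary
    nodes on every such mesh — e.g. ``boundary_multiple=24`` for the 12-source
    / 12-detector layout.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if target_elements < 16:
        raise ValueError(f"target_elements must be >= 16, got {target_elements}")
    M, counts = _ring_layout(target_elements)
    if boundary_multiple is not None:
        want = max(boundary_multiple,
                   boundary_multiple * round(counts[-1] / boundary_multiple))
        if M > 1:  # keep the element total by shifting the remainder inward
            counts[-2] = max(3, counts[-2] - (want - counts[-1]) // 2)
        counts[-1] = want
    nodes = [np.zeros(2)]
    ring_slices = []
    for m, n_m in enumerate(counts, start=1):
        r = radius * m / M
        off = 0.5 * ((M - m) % 2)  # outer ring starts exactly at angle 0
        th = 2.0 * np.pi * (np.arange(n_m) + off) / n_m
        start = len(nodes)
        nodes.extend(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        ring_slices.append((start, start + n_m, th))
    nodes = np.asarray(nodes)

    tris = []
    s0, e0, _ = ring_slices[0]
    for j in range(counts[0]):  # center fan
        tris.append((0, s0 + j, s0 + (j + 1) % counts[0]))
    for m in range(1, M):  # zipper merge of consecutive rings
        sa, ea, tha = ring_slices[m - 1]
        sb, eb, thb = ring_slices[m]
        na, nb = ea - sa, eb - sb
        exta = np.concatenate([tha, [tha[0] + 2 * np.pi]])
        extb = np.concatenate([thb, [thb[0] + 2 * np.pi]])
        i = j = 0
        while i < na or j < nb:
            take_inner = i < na and (j >= nb or exta[i + 1] <= extb[j + 1])
            if take_inner:
                tris.append((sa + i % na, sb + j % nb, sa + (i + 1) % na))
                i += 1
            else:
                tris.append((sa + i % na, sb + j % nb, sb + (j + 1) % nb))
                j += 1
    tris = np.asarray(tris, dtype=np.int64)

    rng = np.random.default_rng(seed)
    interior = np.arange(1, ring_slices[-1][0])  # all but center and outer ring
    h = radius / M
    disp = rng.normal(size=(len(interior), 2))
    disp *= (rng.uniform(0, 1, len(interior)) ** 0.5 / np.maximum(
        np.linalg.norm(disp, axis=1), 1e-300))[:, None]
    amp = jitter
    while amp > 1e-4:
        pts = nodes.copy()
        pts[interior] += amp * h * disp
        if np.all(_signed_area(pts, tris) != 0) and np.all(
                np.abs(_signed_area(pts, tris)) > 1e-12 * h * h):
            break
        amp *= 0.5
    else:
        pts = nodes
    try:
        mesh = build_trimesh(pts, tris, radius=radius)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ValueError(
            f"disk meshing failed (radius={radius}, target_elements="
            f"{target_elements}, seed={seed}): {exc}") from exc
    logger.debug("mesh_disk: target=%d actual=%d nodes=%d rings=%d",
                 target_elements, mesh.n_elements, mesh.n_nodes, M)
    return mesh


def _circ_dist(a, b):
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def _boundary_node_unit(mesh: TriMesh, k: int, index: int, cls, **extra):
    """Build a node-anchored boundary unit at boundary-loop position k.

    The hat peaks (value 1) at boundary node k and falls to 0 at the two
    neighboring boundary nodes, so its support is edge k-1 plus edge k of the
    CCW boundary loop.
    """
    B = len(mesh.boundary_edges)
    e_prev, e_next = (k - 1) % B, k
    recs = []
    support = 0.0
    for eid, (h_s, h_e) in ((e_prev, (0.0, 1.0)), (e_next, (1.0, 0.0))):
        t, l = map(int, mesh.boundary_edges[eid])
        recs.append((eid, t, l, h_s, h_e))
        support += float(mesh.edge_len[t, l])
    t, l = map(int, mesh.boundary_edges[k])
    node = int(mesh.triangles[t, l])  # start node of edge k
    return cls(index=index, node=node, position=mesh.nodes[node].copy(),
               edges=recs, support=support, **extra)


def place_boundary_units(mesh: TriMesh, n_src: int, n_det: int, grid=None,
                         normalization: str = "power"):
    """Equispaced sources and (half-spacing offset) detectors on the boundary.

    Nominal source angles are 2*pi*i/n_src and detector angles
    2*pi*(j+1/2)/n_det, each snapped to the nearest *boundary node* (meshes
    from :func:`mesh_disk` carry those nominal angles as exact boundary nodes
    whenever the outer ring count is a multiple of lcm(n_src, 2*n_det), so
    the same physical unit positions are shared across meshes of different
    resolution).  Each source's incident direction is the grid direction
    nearest to the inward radial direction at its nominal angle.

    normalization : "power" scales each source hat to unit injected power
    (amplitude 2/support), making measurements comparable across meshes;
    "peak" keeps unit peak value.
    """
    if n_src < 1 or n_det < 1:
        raise ValueError("need at least one source and one detector")
    if normalization not in ("power", "peak"):
        raise ValueError(f"unknown normalization {normalization!r}")
    B = len(mesh.boundary_edges)
    if n_src + n_det > B:
        raise ValueError(f"more units ({n_src + n_det}) than boundary edges ({B})")
    t_idx, l_idx = mesh.boundary_edges[:, 0], mesh.boundary_edges[:, 1]
    bnodes = mesh.nodes[mesh.triangles[t_idx, l_idx]]
    node_angles = np.arctan2(bnodes[:, 1], bnodes[:, 0]) % (2 * np.pi)

    def snap(nominal, taken):
        d = _circ_dist(node_angles, nominal)
        for k in np.argsort(d):
            if k not in taken:
                return int(k)
        return int(np.argmin(d))

    taken: set[int] = set()
    sources = []
    for i in range(n_src):
        nominal = 2 * np.pi * i / n_src
        k = snap(nominal, taken)
        taken.add(k)
        spec = _boundary_node_unit(mesh, k, i, SourceSpec)
        if normalization == "power":
            spec.amplitude = 2.0 / spec.support
        if grid is not None:
            inward = -np.array([np.cos(nominal), np.sin(nominal)])
            di = int(np.argmax(grid.directions @ inward))
            spec.direction_index = di
            spec.direction = grid.directions[di]
        sources.append(spec)
    detectors = []
    for j in range(n_det):
        k = snap(2 * np.pi * (j + 0.5) / n_det, taken)
        taken.add(k)
        detectors.append(_boundary_node_unit(mesh, k, j, DetectorSpec))
    return sources, detectors


def upwind_order(mesh: TriMesh, direction: np.ndarray) -> np.ndarray:
    """Topological order of elements along a transport direction.

    Every element appears after all neighbors whose shared edge carries inflow
    into it (omega . n_outward < 0 seen from the element).  Ties/degenerate
    edges (|omega . n| <= 1e-12) do not couple; should a cycle remain, it is
    broken at the unprocessed element with smallest centroid projection onto
    the direction.
    """
    w = np.asarray(direction, dtype=float)
    T = mesh.n_elements
    an = mesh.normals @ w  # (T,3)
    indeg = np.zeros(T, dtype=np.int64)
    out: list[list[int]] = [[] for _ in range(T)]
    ie = mesh.interior_edges
    a_up = an[ie[:, 0], ie[:, 1]]  # omega . n as seen from t1 (outward of t1)
    for (t1, _l1, t2, _l2), s in zip(ie, a_up):
        if s > _DEG_TOL:      # flow from t1 into t2
            out[t1].append(t2)
            indeg[t2] += 1
        elif s < -_DEG_TOL:   # flow from t2 into t1
            out[t2].append(t1)
            indeg[t1] += 1
    proj = mesh.centroids() @ w
    order = np.empty(T, dtype=np.int64)
    import heapq
    ready = [(proj[t], t) for t in range(T) if indeg[t] == 0]
    heapq.heapify(ready)
    done = np.zeros(T, dtype=bool)
    pos = 0
    while pos < T:
        if not ready:  # cycle: break at smallest projection
            t = int(np.argmin(np.where(done, np.inf, proj)))
            indeg[t] = 0
            heapq.heappush(ready, (proj[t], t))
        _, t = heapq.heappop(ready)
        if done[t]:
            continue
        done[t] = True
        order[pos] = t
        pos += 1
        for t2 in out[t]:
            indeg[t2] -= 1
            if indeg[t2] == 0 and not done[t2]:
                heapq.heappush(ready, (proj[t2], t2))
    return order


def transfer_piecewise_constant(values: np.ndarray, mesh_a: TriMesh,
                                mesh_b: TriMesh) -> np.ndarray:
    """Transfer a per-element field from mesh A to mesh B by centroid lookup.

    Each target element takes the value of the source element containing its
    centroid; centroids that fall outside every source element (boundary
    rounding) take the nearest source element's value, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != mesh_a.n_elements:
        raise ValueError("field length does not match source mesh")
    ca = mesh_a.centroids()
    cb = mesh_b.centroids()
    tree = cKDTree(ca)
    k = min(16, mesh_a.n_elements)
    _, cand = tree.query(cb, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty(mesh_b.n_elements)
    pa = mesh_a.nodes[mesh_a.triangles]
    n_fallback = 0
    for i, pt in enumerate(cb):
        found = -1
        for t in cand[i]:
            v0, v1, v2 = pa[t]
            d = ((v1[0] - v0[0]) * (v2[1] - v0[1]) - (v2[0] - v0[0]) * (v1[1] - v0[1]))
            l1 = ((pt[0] - v0[0]) * (v2[1] - v0[1]) - (v2[0] - v0[0]) * (pt[1] - v0[1])) / d
            l2 = ((v1[0] - v0[0]) * (pt[1] - v0[1]) - (pt[0] - v0[0]) * (v1[1] - v0[1])) / d
            if l1 >= -1e-12 and l2 >= -1e-12 and l1 + l2 <= 1 + 1e-12:
                found = t
                break
        if found < 0:
            found = cand[i][0]
            n_fallback += 1
        out[i] = values[found]
    if n_fallback:
        logger.warning("transfer_piecewise_constant: %d centroids outside the "
                       "source mesh, assigned from nearest element", n_fallback)
    return out
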