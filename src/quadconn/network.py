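"""Ground-truth network of the synthetic multimodal phantom.

The phantom's latent truth is a sparse weighted graph: nodes are small
gray-matter patches, edges carry a coupling weight in (0, 1] and a fiber
bundle (a 26-connected voxel polyline) joining the two patches.  Every
simulated modality derives its signal from one shared latent quantity, the
*path strength* between two nodes: the maximum over graph paths of the
product of edge weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigError, PlacementError
from .grid import VolumeGrid


@dataclass(frozen=True)
class Node:
    node_id: int
    center: tuple[int, int, int]  # voxel index
    radius: int = 1  # Chebyshev patch radius in voxels


@dataclass
class Edge:
    node_a: int
    node_b: int
    weight: float
    bundle: np.ndarray  # (L, 3) int voxel polyline, 26-connected

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ConfigError(f"edge weight must be in (0, 1], got {self.weight}")
        self.bundle = np.asarray(self.bundle, dtype=int)
        if self.bundle.ndim != 2 or self.bundle.shape[1] != 3:
            raise ConfigError("bundle must be an (L, 3) voxel polyline")
        step = np.abs(np.diff(self.bundle, axis=0))
        if step.size and step.max() > 1:
            raise ConfigError("bundle polyline must be 26-connected")


@dataclass
class GroundTruthNetwork:
    nodes: list[Node]
    edges: list[Edge] = field(default_factory=list)

    def node(self, node_id: int) -> Node:
        return self.nodes[node_id]

    def patch_voxels(self, node_id: int, grid: VolumeGrid) -> np.ndarray:
        """Voxel indices of a node's patch (Chebyshev ball clipped to the grid)."""
        n = self.nodes[node_id]
        r = n.radius
        rng = [np.arange(max(0, c - r), min(s, c + r + 1))
               for c, s in zip(n.center, grid.shape)]
        ii, jj, kk = np.meshgrid(*rng, indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    def node_containing(self, voxel) -> int | None:
        """Id of the node whose patch contains the voxel, else None."""
        v = np.asarray(voxel)
        for n in self.nodes:
            if np.abs(v - np.asarray(n.center)).max() <= n.radius:
                return n.node_id
        return None

    def _graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.node_id for n in self.nodes)
        for e in self.edges:
            # parallel paths: keep the stronger edge
            if g.has_edge(e.node_a, e.node_b):
                if g[e.node_a][e.node_b]["weight"] >= e.weight:
                    continue
            g.add_edge(e.node_a, e.node_b, weight=e.weight, cost=-np.log(e.weight))
        return g

    def path_strength(self, a: int, b: int) -> float:
        """Max over paths of the product of edge weights (1.0 for a == b)."""
        if a == b:
            return 1.0
        g = self._graph()
        try:
            cost = nx.shortest_path_length(g, a, b, weight="cost")
        except nx.NetworkXNoPath:
            return 0.0
        return float(np.exp(-cost))

    def path_hops(self, a: int, b: int) -> int:
        """Number of edges on the strongest path between two nodes (0 if a==b)."""
        if a == b:
            return 0
        g = self._graph()
        try:
            path = nx.shortest_path(g, a, b, weight="cost")
        except nx.NetworkXNoPath:
            return -1
        return len(path) - 1

    def strength_matrix(self) -> np.ndarray:
        """Symmetric matrix of pairwise path strengths (diagonal 1)."""
        n = len(self.nodes)
        g = self._graph()
        m = np.zeros((n, n))
        np.fill_diagonal(m, 1.0)
        for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="cost"):
            for dst, cost in lengths.items():
                m[src, dst] = np.exp(-cost)
        return m

    # -- serialization ---------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {"id": n.node_id, "center": list(n.center), "radius": n.radius}
                for n in self.nodes
            ],
            "edges": [
                {"a": e.node_a, "b": e.node_b, "weight": e.weight,
                 "bundle": e.bundle.tolist()}
                for e in self.edges
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthNetwork":
        payload = json.loads(text)
        nodes = [Node(d["id"], tuple(d["center"]), d["radius"]) for d in payload["nodes"]]
        edges = [Edge(d["a"], d["b"], d["weight"], np.asarray(d["bundle"]))
                 for d in payload["edges"]]
        return cls(nodes, edges)


# Satellite nodes are placed along lattice directions, one per *antipodal
# class* so no two hub bundles share an FOD axis at the hub.  Edge-class
# directions come first: all 12 are equivalent under the cube symmetry group,
# so networks with up to 6 satellites get fully lattice-symmetric bundle
# geometry; face (3 classes) and corner (4 classes) directions extend the
# capacity to 13 satellites at the cost of mixing geometry classes.
_EDGE_CLASSES = [(1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1)]
_FACE_CLASSES = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_CORNER_CLASSES = [(1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]
PLACEMENT_CLASSES = _EDGE_CLASSES + _FACE_CLASSES + _CORNER_CLASSES


def _digitize_segment(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """26-connected straight voxel line from a to b (inclusive)."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    steps = int(np.abs(b - a).max())
    if steps == 0:
        return a[None, :]
    t = np.linspace(0.0, 1.0, steps + 1)
    pts = np.rint(a[None, :] + t[:, None] * (b - a)[None, :]).astype(int)
    # drop consecutive duplicates (possible only through rounding ties)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.abs(np.diff(pts, axis=0)).max(axis=1) > 0)
    return pts[keep]


def generate_network(
    n_nodes: int,
    n_edges: int,
    weight_range: tuple[float, float],
    grid: VolumeGrid,
    rng: np.random.Generator,
    hub_distance: int = 6,
    patch_radius: int = 1,
    weight_spacing: str = "even",
    hub_jitter: int = 0,
) -> GroundTruthNetwork:
    """Place a hub-and-spokes network with lattice-aligned straight bundles.

    Node 0 (the hub, where the stimulating pair sits) goes at the grid
    center, displaced by a uniform random offset of up to ``hub_jitter``
    voxels per axis (the implantation site varies between sessions); the
    remaining nodes are placed along randomly chosen lattice directions at
    equal lattice (Chebyshev) distance ``hub_distance``, so every hub bundle
    has the same number of tracking steps.  The first ``n_nodes - 1`` edges
    form the star from the hub; any extra edges join random non-hub pairs
    with straight digitized bundles.

    Edge weights are evenly spaced over ``weight_range`` and assigned to
    edges in random order (``weight_spacing="even"``), or drawn iid uniform
    (``"uniform"``).
    """
    if n_nodes < 2:
        raise ConfigError("need at least 2 nodes")
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ConfigError("more edges than node pairs")
    lo, hi = weight_range
    if not (0 < lo <= hi <= 1):
        raise ConfigError("weight_range must satisfy 0 < lo <= hi <= 1")

    center = np.asarray(grid.shape) // 2
    if hub_jitter > 0:
        center = center + rng.integers(-hub_jitter, hub_jitter + 1, size=3)
    margin = hub_distance + patch_radius
    if (center - margin < 0).any() or (center + margin >= np.asarray(grid.shape)).any():
        raise PlacementError(
            f"grid {grid.shape} too small to place node 1 at lattice distance "
            f"{hub_distance} from the hub"
        )
    if n_nodes - 1 > len(PLACEMENT_CLASSES):
        raise PlacementError(
            f"cannot place node {len(PLACEMENT_CLASSES) + 1}: only "
            f"{len(PLACEMENT_CLASSES)} antipodal direction classes available"
        )

    # one direction per antipodal class (random class subset, random sign)
    n_sat = n_nodes - 1
    dirs: list[tuple[int, int, int]] = []
    for group in (_EDGE_CLASSES, _FACE_CLASSES, _CORNER_CLASSES):
        take = min(len(group), n_sat - len(dirs))
        if take > 0:
            picks = rng.choice(len(group), size=take, replace=False)
            signs = rng.choice([-1, 1], size=take)
            dirs.extend(tuple(int(s) * c for c in group[i])
                        for i, s in zip(picks, signs))
    nodes = [Node(0, tuple(int(c) for c in center), patch_radius)]
    for i, d in enumerate(dirs, start=1):
        offset = np.asarray(d) * hub_distance  # equal Chebyshev distance
        pos = center + offset
        if not bool(grid.contains(pos)) or (pos - patch_radius < 0).any() or (
            pos + patch_radius >= np.asarray(grid.shape)
        ).any():
            raise PlacementError(f"cannot place node {i}: patch leaves the grid")
        nodes.append(Node(i, tuple(int(c) for c in pos), patch_radius))
    net = GroundTruthNetwork(nodes)

    # patches must be pairwise disjoint
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            gap = np.abs(np.asarray(nodes[a].center) - np.asarray(nodes[b].center)).max()
            if gap <= 2 * patch_radius:
                raise PlacementError(f"cannot place node {b}: patch overlaps node {a}")

    if n_edges == 0:
        return net

    pairs = [(0, i) for i in range(1, min(n_nodes, n_edges + 1))]
    if n_edges > len(pairs):
        extra_pool = [(a, b) for a in range(1, n_nodes) for b in range(a + 1, n_nodes)]
        picks = rng.choice(len(extra_pool), size=n_edges - len(pairs), replace=False)
        pairs.extend(extra_pool[i] for i in picks)

    if weight_spacing == "even":
        if n_edges == 1:
            weights = np.array([(lo + hi) / 2.0])
        else:
            weights = np.linspace(lo, hi, n_edges)
        weights = weights[rng.permutation(n_edges)]
    elif weight_spacing == "uniform":
        weights = rng.uniform(lo, hi, size=n_edges)
    else:
        raise ConfigError(f"unknown weight_spacing {weight_spacing!r}")

    patch_centers = {n.node_id: np.asarray(n.center) for n in nodes}
    for (a, b), w in zip(pairs, weights):
        obstacles = [m for m in nodes if m.node_id not in (a, b)]
        bundle = _route_bundle(patch_centers[a], patch_centers[b], obstacles, grid)
        if bundle is None:
            raise PlacementError(
                f"bundle {a}-{b} cannot avoid the other node patches"
            )
        net.edges.append(Edge(a, b, float(w), bundle))
    return net


def _clear_of(bundle: np.ndarray, obstacles: list[Node]) -> bool:
    for m in obstacles:
        d = np.abs(bundle - np.asarray(m.center)).max(axis=1)
        if (d <= m.radius).any():
            return False
    return True


def _route_bundle(
    a: np.ndarray, b: np.ndarray, obstacles: list[Node], grid: VolumeGrid
) -> np.ndarray | None:
    """Straight digitized bundle a->b, detouring via a waypoint if it would
    cross another node's patch.  Deterministic candidate order."""
    direct = _digitize_segment(a, b)
    if _clear_of(direct, obstacles):
        return direct
    ab = (b - a).astype(float)
    ab /= max(np.linalg.norm(ab), 1e-12)
    # orthogonal detour directions, fixed order for determinism
    for base in ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)):
        perp = np.asarray(base, dtype=float) - (np.asarray(base) @ ab) * ab
        nrm = np.linalg.norm(perp)
        if nrm < 1e-6:
            continue
        perp /= nrm
        for sign in (1.0, -1.0):
            for dist in (3, 4, 5):
                way = np.rint((a + b) / 2.0 + sign * dist * perp).astype(int)
                if not bool(grid.contains(way)):
                    continue
                seg1 = _digitize_segment(a, way)
                seg2 = _digitize_segment(way, b)
                cand = np.vstack([seg1, seg2[1:]])
                if _clear_of(cand, obstacles):
                    return cand
    return None
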