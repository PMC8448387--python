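"""3-D astroglial morphometrics: segmentation, volume, skeleton, density.

Each segmented cell is reduced to a medial-axis voxel skeleton, the
skeleton is converted to a graph (26-connectivity), and branches are the
paths between terminals — endpoints (degree 1) and junction clusters
(connected groups of degree >= 3 voxels).  Short terminal spurs produced by
thinning are pruned.  Reported per cell: volume (voxel count x voxel
volume), branchpoint count (junction clusters), branch count, and branch
length, both mean-per-branch (the default per-cell value) and total.

Soma density is counted in fixed 50 x 200 um visual fields with half-open
bounds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_OFFSETS26 = [o for o in itertools.product((-1, 0, 1), repeat=3)
              if o != (0, 0, 0)]


@dataclass
class Branch:
    path: list[tuple[int, int, int]]     # voxel coordinates along the branch
    length: float                        # um
    is_spur: bool                        # touches one endpoint + one junction


@dataclass
class SkeletonGraph:
    """Voxel-path skeleton of one cell as a graph, with branch decomposition."""

    graph: nx.Graph
    branches: list[Branch]
    branchpoints: list[tuple[int, int, int]]   # one representative per cluster
    endpoints: list[tuple[int, int, int]]
    volume: float                        # um^3 of the source component

    @property
    def n_branchpoints(self) -> int:
        return len(self.branchpoints)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def branch_lengths(self) -> list[float]:
        return [b.length for b in self.branches]


@dataclass
class BranchMetrics:
    n_branchpoints: int
    n_branches: int
    mean_branch_length: float            # um; per-cell default
    total_branch_length: float           # um


@dataclass
class DensityField:
    """Soma count in one 50 x 200 um visual field."""

    count: int
    field_origin: tuple[float, float]    # (x, y) um
    field_size: tuple[float, float] = (50.0, 200.0)


# ---------------------------------------------------------------------------
# segmentation and volume


def segment_cells(zstack: np.ndarray, intensity_threshold: float | None = None,
                  min_voxels: int = 0) -> tuple[np.ndarray, int]:
    """Label 26-connected components above threshold; drop tiny ones.

    ``intensity_threshold`` defaults to Otsu on the stack.  Components with
    fewer than ``min_voxels`` voxels are discarded; surviving components are
    relabeled 1..n in scan order, so labels are deterministic.  Touching
    cells merge into one component (a known limitation of connectivity-based
    segmentation).
    """
    zstack = np.asarray(zstack)
    if zstack.size == 0 or zstack.max() == zstack.min() == 0:
        return np.zeros(zstack.shape, dtype=np.int32), 0
    if intensity_threshold is None:
        intensity_threshold = threshold_otsu(zstack)
    binary = zstack > intensity_threshold
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return labels.astype(np.int32), 0
    if min_voxels > 0:
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_voxels)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
        n = len(keep)
    return labels.astype(np.int32), int(n)


def cell_volume(cell_mask: np.ndarray, voxel_size) -> float:
    """Voxel count times voxel volume (um^3); supports anisotropic voxels."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n = int(cell_mask.sum())
    if n == 0:
        raise ValueError("empty component has no volume")
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return n * float(np.prod(vox))


# ---------------------------------------------------------------------------
# skeleton graph


def _voxel_graph(skel: np.ndarray, voxel_size: np.ndarray) -> nx.Graph:
    coords = [tuple(c) for c in np.argwhere(skel)]
    present = set(coords)
    G = nx.Graph()
    G.add_nodes_from(coords)
    for c in coords:
        for off in _OFFSETS26:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in present and nb > c:     # each pair once
                step = math.sqrt(sum((o * v) ** 2
                                     for o, v in zip(off, voxel_size)))
                G.add_edge(c, nb, weight=step)
    return G


def _path_length(path, voxel_size: np.ndarray, window: int = 3) -> float:
    """Length of a voxel path by chord sampling (um).

    Summing raw inter-voxel steps overestimates oblique straight paths by
    up to ~8% (digital zig-zag); summing chords between every ``window``-th
    voxel removes most of that bias while following genuine curvature.
    """
    pts = np.asarray(path, dtype=float) * voxel_size
    if len(pts) < 2:
        return 0.0
    if len(pts) <= window + 1:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    anchors = list(range(0, len(pts), window))
    if anchors[-1] != len(pts) - 1:
        anchors.append(len(pts) - 1)
    a = pts[anchors]
    return float(np.linalg.norm(np.diff(a, axis=0), axis=1).sum())


def _decompose(G: nx.Graph, voxel_size: np.ndarray):
    """Branches, junction clusters, endpoints of a skeleton voxel graph."""
    deg = dict(G.degree)
    junctions = {n for n, d in deg.items() if d >= 3}
    clusters = [set(c) for c in
                nx.connected_components(G.subgraph(junctions))] if junctions else []
    node2cluster: dict = {}
    for i, cl in enumerate(clusters):
        for n in cl:
            node2cluster[n] = i
    endpoints = [n for n, d in deg.items() if d == 1]
    terminals = set(endpoints) | junctions
    visited: set[frozenset] = set()
    branches: list[Branch] = []

    def ekey(a, b):
        return frozenset((a, b))

    for start in sorted(terminals):
        for nbr in sorted(G.neighbors(start)):
            if start in node2cluster and node2cluster.get(nbr) == node2cluster[start]:
                continue                       # intra-cluster hop, not a branch
            if ekey(start, nbr) in visited:
                continue
            path = [start, nbr]
            length = G.edges[start, nbr]["weight"]
            visited.add(ekey(start, nbr))
            prev, cur = start, nbr
            while cur not in terminals:
                nxts = [m for m in G.neighbors(cur) if m != prev]
                if not nxts:
                    break
                nxt = nxts[0]
                if ekey(cur, nxt) in visited:
                    break
                visited.add(ekey(cur, nxt))
                length += G.edges[cur, nxt]["weight"]
                path.append(nxt)
                prev, cur = cur, nxt
            ends = (path[0], path[-1])
            n_end = sum(1 for e in ends if deg.get(e, 0) == 1)
            n_junc = sum(1 for e in ends if e in node2cluster)
            branches.append(Branch(path, _path_length(path, voxel_size),
                                   is_spur=(n_end == 1 and n_junc == 1)))
    # a pure cycle (all degree 2) has no terminals: one closed branch
    if not terminals and G.number_of_edges() > 0:
        for comp in nx.connected_components(G):
            sub = G.subgraph(comp)
            length = sum(d["weight"] for _, _, d in sub.edges(data=True))
            branches.append(Branch(list(comp), length, is_spur=False))
    return branches, clusters, endpoints


def skeletonize_cell(cell_mask: np.ndarray, voxel_size,
                     prune_length: float | None = None,
                     volume: float | None = None) -> SkeletonGraph:
    """Medial-axis skeleton of one component, as a pruned branch graph.

    Branch lengths accumulate inter-voxel steps (1, sqrt(2), sqrt(3) times
    the voxel size, scaled per axis for anisotropic voxels).  Terminal
    spurs shorter than ``prune_length`` (default 2 voxels) are removed and
    the topology recomputed, which collapses thinning artifacts without
    deleting real branches.  A component thinner than one voxel everywhere
    yields a single-node graph with no branches.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if prune_length is None:
        prune_length = 2.0 * float(vox.mean())
    if volume is None:
        volume = cell_volume(cell_mask, vox) if cell_mask.any() else 0.0
    skel = skeletonize(cell_mask) if cell_mask.any() else cell_mask
    G = _voxel_graph(skel, vox)
    for _ in range(10):
        branches, clusters, endpoints = _decompose(G, vox)
        spurs = [b for b in branches if b.is_spur and b.length < prune_length]
        if not spurs:
            break
        junction_nodes = set().union(*clusters) if clusters else set()
        drop = {n for b in spurs for n in b.path if n not in junction_nodes}
        if not drop:
            break
        G.remove_nodes_from(drop)
    branches, clusters, endpoints = _decompose(G, vox)
    reps = [min(cl) for cl in clusters]
    return SkeletonGraph(graph=G, branches=branches, branchpoints=reps,
                         endpoints=endpoints, volume=float(volume))


def branch_metrics(skel: SkeletonGraph) -> BranchMetrics:
    """Branchpoint count, branch count, and mean/total branch length (um)."""
    lengths = skel.branch_lengths
    if not lengths:
        return BranchMetrics(0, 0, 0.0, 0.0)
    return BranchMetrics(skel.n_branchpoints, len(lengths),
                         float(np.mean(lengths)), float(np.sum(lengths)))


# ---------------------------------------------------------------------------
# soma density


def soma_centroids(labels: np.ndarray, pixel_size: float) -> np.ndarray:
    """(x, y) centroids in um of a labeled 2-D soma image."""
    n = int(labels.max())
    if n == 0:
        return np.empty((0, 2))
    cms = ndimage.center_of_mass(labels > 0, labels, index=range(1, n + 1))
    return np.array([(c[1] * pixel_size, c[0] * pixel_size) for c in cms])


def count_density(somas: np.ndarray, field_origin=(0.0, 0.0),
                  field_size=(50.0, 200.0),
                  image_extent: tuple[float, float] | None = None) -> DensityField:
    """Count soma centroids inside a half-open visual field rectangle.

    ``somas`` is an (n, 2) array of (x, y) centroids in um.  A centroid on
    the field's max edge is excluded (half-open bounds).  When
    ``image_extent`` is given, the field must lie inside it.
    """
    ox, oy = field_origin
    fx, fy = field_size
    if image_extent is not None:
        if ox < 0 or oy < 0 or ox + fx > image_extent[0] or oy + fy > image_extent[1]:
            raise ValueError("visual field lies outside the image bounds")
    somas = np.asarray(somas, dtype=float).reshape(-1, 2)
    inside = ((somas[:, 0] >= ox) & (somas[:, 0] < ox + fx) &
              (somas[:, 1] >= oy) & (somas[:, 1] < oy + fy))
    return DensityField(count=int(inside.sum()), field_origin=(ox, oy),
                        field_size=(fx, fy))
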