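"""Skeletonization of vessel masks and extraction of rooted skeleton graphs.

A traced vascular network arrives as a binary raster.  This module thins it
to a 1-pixel skeleton, classifies skeleton pixels into end points (one
8-neighbor) and branch candidates (three or more 8-neighbors), merges
junction clusters produced by thinning into single branch nodes, traces the
degree-2 pixel chains between nodes into vessel segments, roots the graph at
the node nearest the umbilical-cord insertion, and measures per-segment arc
length, chord length and thickness.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``;
* 8-connectivity throughout;
* arc length accumulates 1 per axial step and sqrt(2) per diagonal step
  (general Euclidean distance for the rare non-adjacent hops through a
  junction cluster);
* all lengths are reported in cm via ``scale_px_per_cm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

logger = logging.getLogger(__name__)

_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: Chebyshev radius within which thinning junction pixels merge into one node.
BRANCH_CLUSTER_RADIUS = 2

#: Default spur threshold in px.  Thinning leaves junction spurs up to about
#: one stroke half-width (~5 px for the thickest vessels at 35 px/cm), so the
#: default sits just above that and well below any real terminal branch.
DEFAULT_SPUR_PX = 6.0


@dataclass
class VesselMask:
    """A binary vessel raster with its physical context.

    ``cord_xy`` is the umbilical-cord insertion in ``(row, col)`` pixels;
    ``boundary`` is the chorionic-disc mask in the same frame (or ``None``).
    """

    grid: np.ndarray
    scale_px_per_cm: float = 35.0
    cord_xy: Tuple[int, int] = (0, 0)
    boundary: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.size == 0:
            raise ValueError("vessel mask grid is empty")
        if self.scale_px_per_cm <= 0:
            raise ValueError("scale_px_per_cm must be positive")
        r, c = int(self.cord_xy[0]), int(self.cord_xy[1])
        if not (0 <= r < self.grid.shape[0] and 0 <= c < self.grid.shape[1]):
            raise ValueError("cord_xy lies outside the grid")


@dataclass
class SkeletonNode:
    id: int
    rc: Tuple[int, int]
    kind: str  # 'end' | 'branch' | 'internal'
    generation: int = 0


@dataclass
class VesselSegment:
    """One inter-node vessel.

    ``arc_length_cm`` is the paper's per-vessel curve length c_i,
    ``chord_cm`` the end-to-end distance entering the tortuosity ratio, and
    ``thickness_cm`` the vessel diameter d_i.  The source overloads one
    symbol for all three; they are kept apart here.
    """

    pixel_path: np.ndarray  # (L, 2) int array, oriented parent -> child
    arc_length_cm: float
    chord_cm: float
    thickness_cm: Optional[float] = None
    parent_node: int = -1
    child_node: int = -1

    @property
    def tortuosity(self) -> float:
        return self.arc_length_cm / self.chord_cm if self.chord_cm > 0 else np.nan


class SkeletonGraph:
    """Rooted tree of branch/end nodes and pixel-path segments."""

    def __init__(self, scale_px_per_cm: float) -> None:
        self.scale_px_per_cm = float(scale_px_per_cm)
        self.nodes: Dict[int, SkeletonNode] = {}
        self.segments: Dict[int, VesselSegment] = {}
        self.root_id: int = -1
        self.repair_log: List[str] = []

    # -- structure queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    def end_nodes(self) -> List[SkeletonNode]:
        return [nd for nd in self.nodes.values() if nd.kind == "end"]

    def branch_nodes(self) -> List[SkeletonNode]:
        return [nd for nd in self.nodes.values() if nd.kind == "branch"]

    def children_of(self, node_id: int) -> List[VesselSegment]:
        return [s for s in self.segments.values() if s.parent_node == node_id]

    def parent_segment(self, node_id: int) -> Optional[VesselSegment]:
        for s in self.segments.values():
            if s.child_node == node_id:
                return s
        return None

    def degree(self, node_id: int) -> int:
        return sum(
            1
            for s in self.segments.values()
            if node_id in (s.parent_node, s.child_node)
        )

    # -- maintenance -------------------------------------------------------
    def _refresh_kinds(self) -> None:
        for nid, nd in self.nodes.items():
            d = self.degree(nid)
            if d <= 1:
                nd.kind = "end"
            elif d == 2:
                nd.kind = "end" if nid == self.root_id else "internal"
            else:
                nd.kind = "branch"
        # a degree-2 root is neither an end nor a branch point
        if self.root_id in self.nodes and self.degree(self.root_id) == 2:
            self.nodes[self.root_id].kind = "internal"

    def _assign_generations(self) -> None:
        if self.root_id not in self.nodes:
            return
        adj: Dict[int, List[int]] = {nid: [] for nid in self.nodes}
        for s in self.segments.values():
            adj[s.parent_node].append(s.child_node)
            adj[s.child_node].append(s.parent_node)
        depth = {self.root_id: 0}
        frontier = [self.root_id]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in depth:
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            frontier = nxt
        for nid, nd in self.nodes.items():
            nd.generation = depth.get(nid, 0)

    def dissolve_degree2(self) -> None:
        """Merge the two segments incident to any degree-2 non-root node."""
        changed = True
        while changed:
            changed = False
            for nid in list(self.nodes):
                if nid == self.root_id or self.degree(nid) != 2:
                    continue
                inc = [
                    (sid, s)
                    for sid, s in self.segments.items()
                    if nid in (s.parent_node, s.child_node)
                ]
                if len(inc) != 2:
                    continue
                (sid1, s1), (sid2, s2) = inc
                merged = _merge_segments(s1, s2, nid, self.scale_px_per_cm)
                del self.segments[sid1]
                del self.segments[sid2]
                del self.nodes[nid]
                self.segments[sid1] = merged
                changed = True
                break
        self._refresh_kinds()

    def to_json_dict(self) -> dict:
        return {
            "scale_px_per_cm": self.scale_px_per_cm,
            "root_id": self.root_id,
            "nodes": [
                {
                    "id": nd.id,
                    "rc": list(map(int, nd.rc)),
                    "kind": nd.kind,
                    "generation": int(nd.generation),
                }
                for nd in self.nodes.values()
            ],
            "segments": [
                {
                    "parent_node": int(s.parent_node),
                    "child_node": int(s.child_node),
                    "arc_length_cm": float(s.arc_length_cm),
                    "chord_cm": float(s.chord_cm),
                    "thickness_cm": (
                        None if s.thickness_cm is None else float(s.thickness_cm)
                    ),
                    "pixel_path": [[int(r), int(c)] for r, c in s.pixel_path],
                }
                for s in self.segments.values()
            ],
            "repair_log": list(self.repair_log),
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def skeletonize(mask) -> np.ndarray:
    """Thin a binary vessel mask to a 1-px-wide skeleton.

    Accepts a :class:`VesselMask` or a bare boolean array.  An empty mask
    yields an empty skeleton.
    """
    grid = mask.grid if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    if not grid.any():
        return np.zeros_like(grid, dtype=bool)
    return _sk_skeletonize(grid)


def _path_metrics(path: np.ndarray, scale: float) -> Tuple[float, float]:
    """Arc length (axial 1, diagonal sqrt(2), Euclidean otherwise) and chord, in cm."""
    if len(path) < 2:
        return 0.0, 0.0
    diffs = np.diff(path.astype(float), axis=0)
    steps = np.hypot(diffs[:, 0], diffs[:, 1])
    arc = float(steps.sum()) / scale
    chord = float(np.hypot(*(path[-1] - path[0]).astype(float))) / scale
    return arc, chord


def _merge_segments(
    s1: VesselSegment, s2: VesselSegment, junction: int, scale: float
) -> VesselSegment:
    """Concatenate two segments meeting at a dissolved degree-2 junction."""

    def oriented(s: VesselSegment, start_is_junction: bool) -> np.ndarray:
        # return path running away from the junction
        if (s.parent_node == junction) == start_is_junction:
            return s.pixel_path
        return s.pixel_path[::-1]

    # run s1 from its far node into the junction, then s2 out of it
    p1 = oriented(s1, start_is_junction=False)
    p2 = oriented(s2, start_is_junction=True)
    path = np.vstack([p1, p2[1:]]) if len(p2) > 1 else p1
    arc, chord = _path_metrics(path, scale)
    a = s1.parent_node if s1.parent_node != junction else s1.child_node
    b = s2.child_node if s2.child_node != junction else s2.parent_node
    thickness = None
    if s1.thickness_cm is not None and s2.thickness_cm is not None:
        w1, w2 = max(s1.arc_length_cm, 1e-9), max(s2.arc_length_cm, 1e-9)
        thickness = (s1.thickness_cm * w1 + s2.thickness_cm * w2) / (w1 + w2)
    return VesselSegment(
        pixel_path=path,
        arc_length_cm=arc,
        chord_cm=chord,
        thickness_cm=thickness,
        parent_node=a,
        child_node=b,
    )


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant") * skel


def _cluster_branch_pixels(cands: np.ndarray) -> List[np.ndarray]:
    """Group branch-candidate pixels lying within Chebyshev distance 2."""
    if len(cands) == 0:
        return []
    tree = cKDTree(cands.astype(float))
    pairs = tree.query_pairs(r=BRANCH_CLUSTER_RADIUS, p=np.inf)
    parent = list(range(len(cands)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: Dict[int, List[int]] = {}
    for i in range(len(cands)):
        groups.setdefault(find(i), []).append(i)
    return [cands[idx] for idx in groups.values()]


def build_graph(
    skeleton: np.ndarray,
    cord_xy: Tuple[int, int],
    scale: float,
    edt: Optional[np.ndarray] = None,
) -> SkeletonGraph:
    """Turn a 1-px skeleton into a rooted :class:`SkeletonGraph`.

    Pixel kinds follow 8-connectivity neighbor counts (1 -> end, >=3 ->
    branch candidate); adjacent branch candidates merge into one node.
    Cycles left by the tracing are repaired by removing, per cycle, the edge
    with the smallest mean width (``2*edt - 1``) when a distance transform is
    supplied, else the shortest edge; disconnected components other than the
    root's are discarded.  Both repairs are logged on ``graph.repair_log``.
    """
    skel = np.asarray(skeleton, bool)
    g = SkeletonGraph(scale)
    if not skel.any():
        return g

    counts = _neighbor_counts(skel)
    end_px = np.argwhere(skel & (counts <= 1))
    branch_px = np.argwhere(skel & (counts >= 3))

    node_of: Dict[Tuple[int, int], int] = {}
    rep: Dict[int, Tuple[int, int]] = {}
    nid = 0
    for cluster in _cluster_branch_pixels(branch_px):
        centroid = cluster.mean(axis=0)
        k = int(np.argmin(((cluster - centroid) ** 2).sum(axis=1)))
        rep[nid] = tuple(int(v) for v in cluster[k])
        for px in cluster:
            node_of[tuple(int(v) for v in px)] = nid
        g.nodes[nid] = SkeletonNode(nid, rep[nid], "branch")
        nid += 1
    for px in end_px:
        key = tuple(int(v) for v in px)
        if key in node_of:
            continue
        rep[nid] = key
        node_of[key] = nid
        g.nodes[nid] = SkeletonNode(nid, key, "end")
        nid += 1

    if not g.nodes:
        # a pure cycle with no distinguished pixels; nothing to root
        return g

    # trace degree-2 chains between node pixels
    used_chain: set = set()
    seen_direct: set = set()
    raw_segments: List[Tuple[int, int, np.ndarray]] = []

    def neighbors(p: Tuple[int, int]) -> Iterable[Tuple[int, int]]:
        r, c = p
        for dr, dc in _NB8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                yield (rr, cc)

    for start_nid in list(g.nodes):
        members = [px for px, i in node_of.items() if i == start_nid]
        for m in members:
            for nb in neighbors(m):
                if nb in node_of:
                    other = node_of[nb]
                    if other == start_nid:
                        continue  # internal cluster adjacency
                    key = frozenset((m, nb))
                    if key in seen_direct:
                        continue
                    seen_direct.add(key)
                    path = _assemble_path(rep[start_nid], m, [], nb, rep[other])
                    raw_segments.append((start_nid, other, path))
                    continue
                if nb in used_chain:
                    continue
                chain = []
                prev, cur = m, nb
                while cur not in node_of:
                    chain.append(cur)
                    used_chain.add(cur)
                    nxt = [q for q in neighbors(cur) if q != prev and q not in used_chain]
                    nxt = [q for q in nxt if q not in chain]
                    if not nxt:
                        break
                    prev, cur = cur, nxt[0]
                if cur in node_of:
                    other = node_of[cur]
                    path = _assemble_path(rep[start_nid], m, chain, cur, rep[other])
                    raw_segments.append((start_nid, other, path))
                else:
                    # dangling chain (should not occur: its tip would be an
                    # end pixel); keep as a stub to the last chain pixel
                    path = _assemble_path(rep[start_nid], m, chain, None, None)
                    end_key = tuple(chain[-1]) if chain else m
                    g.nodes[nid] = SkeletonNode(nid, end_key, "end")
                    rep[nid] = end_key
                    node_of[end_key] = nid
                    raw_segments.append((start_nid, nid, path))
                    nid += 1

    # assemble a multigraph for component filtering and cycle repair
    G = nx.MultiGraph()
    G.add_nodes_from(g.nodes)
    for idx, (a, b, path) in enumerate(raw_segments):
        G.add_edge(a, b, key=idx, path=path)

    cord = (int(cord_xy[0]), int(cord_xy[1]))
    root = min(
        g.nodes, key=lambda i: (g.nodes[i].rc[0] - cord[0]) ** 2 + (g.nodes[i].rc[1] - cord[1]) ** 2
    )
    g.root_id = root

    keep = nx.node_connected_component(G, root)
    dropped = set(G.nodes) - keep
    if dropped:
        g.repair_log.append(f"discarded {len(dropped)} node(s) outside the root component")
        logger.info("build_graph: %s", g.repair_log[-1])
        G.remove_nodes_from(dropped)
        for i in dropped:
            del g.nodes[i]

    def edge_width(path: np.ndarray) -> float:
        if edt is not None:
            vals = 2.0 * edt[path[:, 0], path[:, 1]] - 1.0
            return float(vals.mean()) if len(vals) else 0.0
        return float(len(path))  # fall back: shortest edge is the likeliest artifact

    while G.number_of_edges() >= G.number_of_nodes():
        cyc = nx.find_cycle(G)
        edges = [(u, v, k) for u, v, k in cyc]
        widths = [edge_width(G.edges[u, v, k]["path"]) for u, v, k in edges]
        u, v, k = edges[int(np.argmin(widths))]
        g.repair_log.append(
            f"cycle repaired: removed edge {u}-{v} (width proxy {min(widths):.2f})"
        )
        logger.info("build_graph: %s", g.repair_log[-1])
        G.remove_edge(u, v, key=k)

    # orient from the root and materialize segments
    sid = 0
    for a, b in nx.bfs_edges(G, root):
        k = next(iter(G[a][b]))
        path = G.edges[a, b, k]["path"]
        if tuple(path[0]) != g.nodes[a].rc:
            path = path[::-1]
        arc, chord = _path_metrics(path, scale)
        g.segments[sid] = VesselSegment(
            pixel_path=path,
            arc_length_cm=arc,
            chord_cm=chord,
            parent_node=a,
            child_node=b,
        )
        sid += 1

    g._refresh_kinds()
    g.dissolve_degree2()
    g._assign_generations()
    return g


def _assemble_path(rep_a, attach_a, chain, attach_b, rep_b) -> np.ndarray:
    pts: List[Tuple[int, int]] = [rep_a]
    if attach_a != rep_a:
        pts.append(attach_a)
    pts.extend(chain)
    if attach_b is not None and (not pts or pts[-1] != attach_b):
        pts.append(attach_b)
    if rep_b is not None and pts[-1] != rep_b:
        pts.append(rep_b)
    # drop accidental duplicates
    dedup = [pts[0]]
    for p in pts[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return np.array(dedup, dtype=int)


def measure_thickness(
    mask,
    graph: SkeletonGraph,
    caliber_map: Optional[np.ndarray] = None,
) -> SkeletonGraph:
    """Attach per-segment thickness (cm) to a graph.

    Geometric route: thickness at a skeleton pixel is ``2*EDT - 1`` px, the
    width of a symmetric stroke around the medial axis (a bar spanning w
    rows has EDT (w+1)/2 at its center row); the segment thickness is the
    mean over its path pixels.  When ``caliber_map`` (cm per pixel, from a
    color-tracing palette) is given it takes precedence.
    """
    grid = mask.grid if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    scale = graph.scale_px_per_cm
    edt = ndimage.distance_transform_edt(grid)
    for s in graph.segments.values():
        rr, cc = s.pixel_path[:, 0], s.pixel_path[:, 1]
        inside = grid[rr, cc]
        if not inside.any():
            raise ValueError(
                "segment lies entirely outside the mask foreground; "
                "mask and graph are inconsistent"
            )
        if caliber_map is not None:
            vals = caliber_map[rr[inside], cc[inside]]
            s.thickness_cm = float(np.mean(vals[vals > 0])) if (vals > 0).any() else float(
                np.mean(vals)
            )
        else:
            w = 2.0 * edt[rr[inside], cc[inside]] - 1.0
            s.thickness_cm = float(w.mean()) / scale
    return graph


def prune_spurs(graph: SkeletonGraph, min_length_cm: float) -> SkeletonGraph:
    """Remove terminal segments shorter than ``min_length_cm``.

    Degree-2 junctions left behind are dissolved (their segments merged) so
    the end/branch-node identities stay valid.  The root is never pruned.
    """
    if min_length_cm < 0:
        raise ValueError("min_length_cm must be >= 0")
    if min_length_cm == 0 or not graph.segments:
        return graph
    changed = True
    while changed:
        changed = False
        for sid, s in list(graph.segments.items()):
            leaf = s.child_node
            if leaf == graph.root_id:
                continue
            if graph.degree(leaf) == 1 and s.arc_length_cm < min_length_cm:
                del graph.segments[sid]
                del graph.nodes[leaf]
                changed = True
        if changed:
            graph.dissolve_degree2()
    graph._refresh_kinds()
    graph._assign_generations()
    return graph
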