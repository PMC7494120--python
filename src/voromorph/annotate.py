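"""Graph annotation: sides, vertex roles, per-boundary subgraphs, root paths.

The global Voronoi graph is split into the *in-graph* (foreground) and
*out-graph* (background), and partitioned into per-boundary subgraphs:
the portion of each side owned by one boundary, bounded by the boundary
itself on one side and by its *root path* — the chain of bridges (vertices
equidistant to exactly two boundaries), hubs (three or more) and
connectors — on the other.  A subgraph with no bridges (an isolated
object's interior, an empty hole) is a tree rooted at its maximal-clearance
vertex, and the root path is the longest leaf-to-leaf path through that
root, restricted to vertices of positive clearance.

Conventions (see the methods note for rationale):

* r=0 boundary-contact vertices sit exactly on a boundary and join the two
  sides; their side label is that of their convex-wedge bisector edge
  (computable from the boundary's turn direction).
* edges generated by two frame sites get side ``frame`` and are excluded
  from subgraphs and features; mixed content/frame bisector edges are
  genuine out-graph root-path edges (the frame acts as the outermost
  boundary).
* inter-boundary edges are owned by the lower boundary id for the edge
  partition, but participate in both adjacent subgraphs' root paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import FRAME_BOUNDARY
from .voronoi import RZERO, GraphEdge, ShapeGraph

__all__ = [
    "SubGraph",
    "Annotation",
    "split_in_out",
    "classify_vertices",
    "partition_subgraphs",
    "root_path",
    "annotate",
]


@dataclass
class SubGraph:
    """The part of one side of the graph owned by one boundary."""

    boundary_id: int
    side: str  # "in" | "out"
    graph: ShapeGraph
    vertex_ids: np.ndarray
    edge_ids: list[int]  # edges owned by this subgraph (partition)
    path_edge_ids: list[int]  # owned + shared root-path edges
    root_path: list[int] = field(default_factory=list)
    root_cyclic: bool = False
    bridged: bool = False  # root path built from inter-boundary bridges
    root_vertex: int = -1  # max-clearance root (bridgeless subgraphs)

    def nx_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(int(v) for v in self.vertex_ids)
        for eid in self.path_edge_ids:
            e = self.graph.edges[eid]
            g.add_edge(e.v1, e.v2, key=eid, length=e.length)
        return g


def _foreground_prepared(boundaries):
    """Prepared shapely geometry of the foreground (shells minus holes)."""
    from shapely import prepare
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    exteriors = [b for b in boundaries if b.kind == "exterior"]
    interiors = [b for b in boundaries if b.kind == "interior"]
    polys = []
    for ext in exteriors:
        holes = [h.points for h in interiors if h.owner_object == ext.owner_object]
        if len(exteriors) > 1 and holes:
            # owner labels are shared across one object only; guard against
            # label collisions between boundary sets by containment
            shell = Polygon(ext.points)
            holes = [h for h in holes if shell.contains(Polygon(h).representative_point())]
            polys.append(Polygon(ext.points, holes))
        else:
            polys.append(Polygon(ext.points, holes))
    if not polys:
        return None
    merged = unary_union(polys)
    prepare(merged)
    return merged


def _boundary_turns(graph: ShapeGraph) -> dict[int, float]:
    """Cross product of the two segment directions at every corner point site."""
    ss = graph.sites
    turns: dict[int, float] = {}
    for i, sprev, snext in ss.corner_triples():
        d1 = ss.seg_dir[sprev - ss.npts]
        d2 = ss.seg_dir[snext - ss.npts]
        turns[i] = float(d1[0] * d2[1] - d1[1] * d2[0])
    return turns


def split_in_out(graph: ShapeGraph, boundaries) -> ShapeGraph:
    """Label every vertex and edge 'in', 'out' or 'frame' (in place).

    Vertices are located against the foreground polygons; boundary-contact
    (r=0) vertices are assigned the side of their convex wedge, frame
    corners the side 'frame'.  Edges take 'frame' when both generating
    sites are frame sites, otherwise the side of their midpoint.
    """
    import shapely

    fg = _foreground_prepared(boundaries)
    ss = graph.sites
    n = graph.n_vertices
    side = np.array([""] * n, dtype=object)

    contact = graph.clearance <= RZERO
    turns = _boundary_turns(graph)
    for v in np.nonzero(contact)[0]:
        tang = graph.tangent_sites[v]
        pts_in_tang = [s for s in tang if s < ss.npts]
        if any(ss.boundary_of[s] == FRAME_BOUNDARY for s in tang):
            side[v] = "frame"
            continue
        # convex wedge is on the material side iff the boundary turns left
        # (positive cross) at this corner; boundaries are traced with the
        # material on the left
        tv = 0.0
        for s in pts_in_tang:
            if s in turns:
                tv = turns[s]
                break
        side[v] = "in" if tv > 0 else "out"

    free = ~contact
    if fg is None:
        side[free] = "out"
    else:
        pts = shapely.points(graph.positions[free])
        inside = shapely.contains(fg, pts)
        side[free] = np.where(inside, "in", "out")
    graph.vertex_side = side

    # Edge side from the chord midpoint: an edge never crosses a boundary
    # (its interior keeps positive clearance), and the parabolic sagitta
    # cannot push the chord midpoint across either.
    mids = []
    which = []
    for eid, e in enumerate(graph.edges):
        b1, b2 = graph.edge_boundaries(e)
        if b1 == FRAME_BOUNDARY and b2 == FRAME_BOUNDARY:
            e.side = "frame"
            continue
        mids.append(0.5 * (graph.positions[e.v1] + graph.positions[e.v2]))
        which.append(eid)
    if which:
        if fg is None:
            for eid in which:
                graph.edges[eid].side = "out"
        else:
            inside = shapely.contains(fg, shapely.points(np.array(mids)))
            for eid, ins in zip(which, inside):
                graph.edges[eid].side = "in" if ins else "out"
    return graph


def classify_vertices(graph: ShapeGraph) -> np.ndarray:
    """Role per vertex: 'bridge', 'hub' or 'branch' ('connector' is assigned
    during root-path extraction)."""
    n = graph.n_vertices
    roles = np.array(["branch"] * n, dtype=object)
    for v in range(n):
        nb = len(graph.vertex_boundaries(v))
        if nb == 2:
            roles[v] = "bridge"
        elif nb >= 3:
            roles[v] = "hub"
    graph.vertex_role = roles
    return roles


def _edge_side_ok(e: GraphEdge, side: str) -> bool:
    return e.side == side


def partition_subgraphs(graph: ShapeGraph, boundaries) -> dict[tuple[int, str], SubGraph]:
    """Partition non-frame edges into per-(boundary, side) subgraphs.

    Each edge is owned by the boundary generating it; inter-boundary
    (root-path) edges are owned by the lower id but shared with the other
    subgraph's path edges.  The frame never owns a subgraph.
    """
    if graph.vertex_side is None:
        raise ValueError("run split_in_out first")
    if graph.vertex_role is None:
        classify_vertices(graph)

    members: dict[tuple[int, str], dict] = {}

    def slot(bid: int, side: str) -> dict:
        key = (bid, side)
        if key not in members:
            members[key] = {"own": [], "path": [], "verts": set()}
        return members[key]

    for eid, e in enumerate(graph.edges):
        if e.side == "frame":
            continue
        b1, b2 = graph.edge_boundaries(e)
        owners = {b for b in (b1, b2) if b != FRAME_BOUNDARY}
        if not owners:
            continue
        own = min(owners)
        e.owner = own
        slot(own, e.side)["own"].append(eid)
        for b in owners:
            s = slot(b, e.side)
            s["path"].append(eid)
            s["verts"].update((e.v1, e.v2))

    out: dict[tuple[int, str], SubGraph] = {}
    for (bid, side), m in sorted(members.items()):
        out[(bid, side)] = SubGraph(
            boundary_id=bid,
            side=side,
            graph=graph,
            vertex_ids=np.array(sorted(m["verts"]), dtype=np.int64),
            edge_ids=sorted(set(m["own"])),
            path_edge_ids=sorted(set(m["path"])),
        )
    for sub in out.values():
        root_path(sub)
    return out


def root_path(sub: SubGraph) -> list[int]:
    """Compute and store the subgraph's root path.

    With root vertices (bridges/hubs against other boundaries or the
    frame): the chain of inter-boundary edges, ordered; disconnected root
    chains are joined through shortest connector paths (vertices promoted
    to role 'connector').  Without roots: the longest path through the
    maximal-clearance vertex over positive-clearance vertices.
    """
    g = sub.graph
    bid = sub.boundary_id
    nxg = sub.nx_graph()
    if nxg.number_of_nodes() == 0:
        raise ValueError("empty subgraph")

    chain = nx.Graph()
    for eid in sub.path_edge_ids:
        e = g.edges[eid]
        b1, b2 = g.edge_boundaries(e)
        if b1 != b2:  # inter-boundary bisector edge
            chain.add_edge(e.v1, e.v2, length=e.length, eid=eid)

    if chain.number_of_nodes() == 0:
        sub.root_path, sub.root_cyclic = _tree_root_path(sub, nxg)
        sub.bridged = False
        return sub.root_path
    sub.bridged = True

    comps = [sorted(c) for c in nx.connected_components(chain)]
    comps.sort()
    if len(comps) > 1:
        # connect root components through the subgraph (connector vertices)
        wg = nx.Graph()
        for u, v, d in nxg.edges(data=True):
            w = d.get("length", 0.0)
            if not wg.has_edge(u, v) or wg[u][v]["length"] > w:
                wg.add_edge(u, v, length=w)
        anchor = comps[0]
        for other in comps[1:]:
            best = None
            try:
                dist, path = nx.multi_source_dijkstra(
                    wg, set(anchor) & set(wg.nodes), weight="length"
                )
            except ValueError:
                break
            reach = [v for v in other if v in dist]
            if not reach:
                continue
            tgt = min(reach, key=lambda v: (dist[v], v))
            p = path[tgt]
            for u, v in zip(p, p[1:]):
                chain.add_edge(u, v, length=wg[u][v]["length"])
            for v in p[1:-1]:
                if g.vertex_role is not None and g.vertex_role[v] == "branch":
                    g.vertex_role[v] = "connector"
            anchor = sorted(set(anchor) | set(other) | set(p))

    # order the (now connected, within reach) chain
    nodes = sorted(chain.nodes)
    degs = dict(chain.degree())
    cyclic = all(d == 2 for d in degs.values()) and nx.is_connected(chain)
    if cyclic:
        start = max(nodes, key=lambda v: (g.clearance[v], -v))
        order = [start]
        prev = None
        cur = start
        while True:
            nbrs = sorted(n for n in chain.neighbors(cur) if n != prev)
            if not nbrs:
                break
            nxt = nbrs[0]
            if nxt == start:
                break
            order.append(nxt)
            prev, cur = cur, nxt
        # canonical counter-clockwise traversal (positive signed area)
        pts = g.positions[order]
        area = 0.5 * float(
            np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
        )
        if area < 0:
            order = [order[0]] + order[:0:-1]
        sub.root_path, sub.root_cyclic = order, True
    else:
        # path or branched chain: deterministic DFS traversal from the
        # maximal-clearance endpoint
        ends = sorted((v for v, d in degs.items() if d == 1), key=lambda v: (-g.clearance[v], v))
        start = ends[0] if ends else max(nodes, key=lambda v: (g.clearance[v], -v))
        order = list(nx.dfs_preorder_nodes(chain, source=start))
        sub.root_path, sub.root_cyclic = order, False
    return sub.root_path


def _tree_root_path(sub: SubGraph, nxg: nx.MultiGraph) -> tuple[list[int], bool]:
    """Longest positive-clearance path through the max-clearance root."""
    g = sub.graph
    verts = [int(v) for v in sub.vertex_ids]
    root = max(verts, key=lambda v: (g.clearance[v], -v))
    sub.root_vertex = root
    keep = {v for v in verts if g.clearance[v] > RZERO}
    keep.add(root)
    h = nx.Graph()
    h.add_nodes_from(keep)
    for u, v, d in nxg.edges(data=True):
        if u in keep and v in keep:
            w = d.get("length", 0.0)
            if not h.has_edge(u, v) or h[u][v]["length"] > w:
                h.add_edge(u, v, length=w)
    if root not in h or h.number_of_edges() == 0:
        return [root], False
    dist, paths = nx.single_source_dijkstra(h, root, weight="length")
    # two deepest branches leaving the root through different first steps
    best: dict[int, tuple[float, int]] = {}
    for v, d in dist.items():
        if v == root or len(paths[v]) < 2:
            continue
        first = paths[v][1]
        if first not in best or d > best[first][0] or (d == best[first][0] and v < best[first][1]):
            best[first] = (d, v)
    branches = sorted(best.values(), key=lambda t: (-t[0], t[1]))
    if not branches:
        return [root], False
    leg1 = paths[branches[0][1]]
    if len(branches) > 1:
        leg2 = paths[branches[1][1]]
        path = leg2[::-1] + leg1[1:]
    else:
        path = leg1
    return [int(v) for v in path], False


@dataclass
class Annotation:
    graph: ShapeGraph
    boundaries: list
    subgraphs: dict[tuple[int, str], SubGraph]


def annotate(graph: ShapeGraph, boundaries) -> Annotation:
    """Run the full annotation pipeline on a constructed graph."""
    split_in_out(graph, boundaries)
    classify_vertices(graph)
    subs = partition_subgraphs(graph, boundaries)
    return Annotation(graph=graph, boundaries=list(boundaries), subgraphs=subs)
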