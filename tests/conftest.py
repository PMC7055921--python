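"""Shared fixtures and independent brute-force oracles.

The oracles re-derive quantities from first principles (circumcenter by
linear solve, components by flood fill, per-edge label counting) so that
they share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import tlograph as tg
from tlograph.cells import CellMap, CellRecord


# ---------------------------------------------------------------------------
# point-set / cell-map helpers


def make_cell_map(points, phenotypes=None, roi_id="roi", resolution=1.0) -> CellMap:
    points = np.asarray(points, dtype=float)
    if phenotypes is None:
        phenotypes = ["T"] * len(points)
    cells = [
        CellRecord(cell_id=f"c{i:04d}", x=float(x), y=float(y), phenotype=p)
        for i, ((x, y), p) in enumerate(zip(points, phenotypes))
    ]
    return CellMap(roi_id=roi_id, cells=cells, resolution_um_per_px=resolution)


@pytest.fixture
def square_map() -> CellMap:
    """Four cells at the corners of an axis-aligned 10 px square."""
    return make_cell_map([(0, 0), (10, 0), (10, 10), (0, 10)])


def random_point_map(rng: np.random.Generator, n: int, scale: float = 100.0) -> CellMap:
    pts = rng.random((n, 2)) * scale
    phen = rng.choice(["T", "B"], size=n)
    return make_cell_map(pts, list(phen), roi_id=f"rand{n}")


# ---------------------------------------------------------------------------
# brute-force oracles


def circumcenter_radius_solve(p1, p2, p3) -> float:
    """Circumradius via the circumcenter as solution of a linear system
    (perpendicular-bisector intersection) — independent of the R=abc/4A
    route used by the implementation."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = 2.0 * np.array([p2 - p1, p3 - p1])
    b = np.array([p2 @ p2 - p1 @ p1, p3 @ p3 - p1 @ p1])
    try:
        center = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.inf
    if not np.all(np.isfinite(center)):
        return np.inf
    return float(np.linalg.norm(center - p1))


def brute_force_filtered_edges(cell_map: CellMap, threshold: float) -> set:
    """Union of the sides of every Delaunay triangle whose independently
    recomputed circumradius is below the threshold."""
    from scipy.spatial import Delaunay

    pts = np.array([(c.x, c.y) for c in cell_map.cells])
    ids = [c.cell_id for c in cell_map.cells]
    edges = set()
    for s in Delaunay(pts).simplices:
        r = circumcenter_radius_solve(pts[s[0]], pts[s[1]], pts[s[2]])
        if r < threshold:
            for u, v in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
                edges.add(frozenset((ids[u], ids[v])))
    return edges


def flood_fill_components(nodes, edges) -> list[set]:
    """Connected components by explicit BFS over an adjacency map."""
    adj = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_force_kappa(graph, a: int, type_a: str = "B") -> float:
    """κ(a) as the fraction of inter-type edges whose A-endpoint has more
    than a A–A edges, counted edge by edge."""
    g = graph.graph
    inter = [
        (u, v)
        for u, v in g.edges
        if g.nodes[u]["phenotype"] != g.nodes[v]["phenotype"]
    ]
    if not inter:
        return 0.0
    n_hi = 0
    for u, v in inter:
        a_end = u if g.nodes[u]["phenotype"] == type_a else v
        aa = sum(1 for nb in g.neighbors(a_end) if g.nodes[nb]["phenotype"] == type_a)
        if aa > a:
            n_hi += 1
    return n_hi / len(inter)


def brute_force_clustering(graph) -> float:
    """Mean local clustering via exhaustive neighbor-pair enumeration."""
    g = graph.graph
    total = 0.0
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        if len(nbrs) < 2:
            continue
        pairs = [(x, y) for i, x in enumerate(nbrs) for y in nbrs[i + 1 :]]
        links = sum(1 for x, y in pairs if g.has_edge(x, y))
        total += links / len(pairs)
    return total / g.number_of_nodes()


# ---------------------------------------------------------------------------
# hand-built labelled graphs


def build_graph(node_phenotypes: dict, edges: list, type_a: str = "B"):
    """NeighborhoodGraph from explicit nodes/edges with dummy coordinates."""
    import networkx as nx

    g = nx.Graph()
    for i, (name, phen) in enumerate(node_phenotypes.items()):
        g.add_node(name, x=float(i % 17), y=float(i // 17), phenotype=phen)
    g.add_edges_from(edges)
    return tg.NeighborhoodGraph(graph=g, threshold_px=45.0, designated_type_a=type_a)


@pytest.fixture(scope="session")
def cohort_features():
    """Features + labels for a balanced 50/class synthetic cohort (seed 1).

    Session-scoped: the same cohort backs the SVM-recovery, permutation and
    PCA checks.
    """
    from tlograph.io import features_to_dataframe

    maps, labels = tg.generate_labeled_cohort(50, seed=1)
    vecs, labs = [], []
    for cm, lab in zip(maps, labels):
        infs = tg.build_neighborhood_graphs(cm)
        assert infs, f"pattern {cm.roi_id} produced no infiltrate"
        g = max(infs, key=lambda x: x.n_nodes)
        vecs.append(tg.compute_feature_vector(g, resolution_um_per_px=0.253))
        labs.append(lab)
    return features_to_dataframe(vecs), labs
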