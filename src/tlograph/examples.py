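"""A small worked-example graph for the κ score.

``worked_example_graph`` builds a synthetic two-phenotype graph (a
reconstruction of the kind of toy infiltrate used to illustrate edge
labelling): a B-cell cluster around a hub, two stray B cells, and 20 T
cells each linked to one B cell.  Its γ-label spectrum is

    {0: 6, 2: 6, 3: 4, 4: 3, 6: 1}

over 20 inter-type edges and 12 B–B α edges, so κ(2) = 8/20 = 0.4 and
κ(5) = 1/20 = 0.05.
"""

from __future__ import annotations

import networkx as nx

from .graphs import NeighborhoodGraph

# B-B edges: a hub 'h' of degree 6, a 4-cycle with one chord among a1..a4,
# and the pair a5-a6; b1/b2 carry no B-B edge at all.
_BB_EDGES = [
    ("h", "a1"),
    ("h", "a2"),
    ("h", "a3"),
    ("h", "a4"),
    ("h", "a5"),
    ("h", "a6"),
    ("a1", "a2"),
    ("a2", "a3"),
    ("a3", "a4"),
    ("a4", "a1"),
    ("a1", "a3"),
    ("a5", "a6"),
]

# B-B degrees: h=6, a1=4, a2=3, a3=4, a4=3, a5=2, a6=2, b1=0, b2=0.
# One T cell per inter-type edge; the B endpoint sets the gamma index.
_TB_ATTACHMENTS = (
    ["h"]  # gamma_6
    + ["a1", "a1", "a3"]  # gamma_4 x3
    + ["a2", "a2", "a4", "a4"]  # gamma_3 x4
    + ["a5", "a5", "a5", "a6", "a6", "a6"]  # gamma_2 x6
    + ["b1", "b1", "b1", "b2", "b2", "b2"]  # gamma_0 x6
)


def worked_example_graph() -> NeighborhoodGraph:
    """The worked-example graph, ready for edge labelling."""
    g = nx.Graph()
    b_nodes = ["h", "a1", "a2", "a3", "a4", "a5", "a6", "b1", "b2"]
    for i, name in enumerate(b_nodes):
        g.add_node(name, x=float(i), y=0.0, phenotype="B")
    for j, b_end in enumerate(_TB_ATTACHMENTS):
        t_name = f"t{j:02d}"
        g.add_node(t_name, x=float(j), y=10.0, phenotype="T")
        g.add_edge(t_name, b_end)
    g.add_edges_from(_BB_EDGES)
    return NeighborhoodGraph(graph=g, threshold_px=45.0, designated_type_a="B")
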