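"""Per-infiltrate features: edge labels, the κ organization score, and
classical graph statistics.

Edges between same-phenotype cells are labelled α.  Each remaining
(inter-type) edge is labelled γᵢ where i is the number of A–A edges incident
to the edge's endpoint of designated type A (B cells by default).  The
TLO-organization score

    κ(a) = (|E| − |Eα| − Σ_{j=0..a} |Eγⱼ|) / (|E| − |Eα|)

is the fraction of inter-type edges whose A-endpoint sits in an A-cell
cluster of more than ``a`` A–A links: high when B cells form compact zones
bordered by T cells (the TLO geometry), near zero for well-mixed or
T-dominated infiltrates.  Single T cells dispersed inside a B-cell core —
a frequent feature of real TLOs — raise rather than destroy the score,
which is what distinguishes κ from plain homogeneity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .graphs import InfiltrateGraph, NeighborhoodGraph

ALPHA = "alpha"

#: Exact all-pairs mean distance up to this many nodes; sampled above.
PAIRWISE_EXACT_CAP = 5000
PAIRWISE_SAMPLE_PAIRS = 1_000_000


class MultiTypeError(ValueError):
    """More than two phenotypes: the γ label is then ill-defined."""


class EdgelessGraphError(ValueError):
    """Operation undefined on a graph with no edges."""


@dataclass
class EdgeLabelSummary:
    """Counts of α and γᵢ edge labels for one graph.

    Partition identity: ``n_alpha + sum(gamma_counts.values()) == n_edges``.
    ``n_alpha_a`` counts the α edges joining two cells of the designated
    type A (a subset of all α edges).
    """

    n_edges: int
    n_alpha: int
    n_alpha_a: int
    gamma_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_alpha + sum(self.gamma_counts.values()) != self.n_edges:
            raise ValueError("edge label counts do not partition the edge set")
        if self.n_alpha_a > self.n_alpha:
            raise ValueError("n_alpha_a exceeds n_alpha")

    @property
    def n_inter(self) -> int:
        return self.n_edges - self.n_alpha


def label_edges(graph: NeighborhoodGraph, designated_type_a: str = "B") -> EdgeLabelSummary:
    """Assign α/γᵢ labels to every edge and return the label counts.

    Labels are stored on the graph's edges under the ``label`` key: the
    string ``"alpha"`` for same-type edges, the integer γ index otherwise.
    """
    g = graph.graph
    phenotypes = {d["phenotype"] for _, d in g.nodes(data=True)}
    if len(phenotypes) > 2:
        raise MultiTypeError(
            f"multi-type not supported: found phenotypes {sorted(phenotypes)}"
        )
    a_type = designated_type_a
    # A–A degree of each A node = number of alpha_A edges incident to it
    aa_degree = {
        n: sum(1 for nb in g.neighbors(n) if g.nodes[nb]["phenotype"] == a_type)
        for n, d in g.nodes(data=True)
        if d["phenotype"] == a_type
    }
    n_alpha = 0
    n_alpha_a = 0
    gamma_counts: Counter[int] = Counter()
    for u, v in g.edges:
        pu, pv = g.nodes[u]["phenotype"], g.nodes[v]["phenotype"]
        if pu == pv:
            g.edges[u, v]["label"] = ALPHA
            n_alpha += 1
            if pu == a_type:
                n_alpha_a += 1
        else:
            a_end = u if pu == a_type else v
            i = aa_degree[a_end]
            g.edges[u, v]["label"] = i
            gamma_counts[i] += 1
    return EdgeLabelSummary(
        n_edges=g.number_of_edges(),
        n_alpha=n_alpha,
        n_alpha_a=n_alpha_a,
        gamma_counts=dict(gamma_counts),
    )


def kappa(summary: EdgeLabelSummary, a: int) -> float:
    """TLO-like organization κ(a): fraction of inter-type edges with γ index > a.

    Defined as 0 when the graph has no inter-type edges (a pure single-type
    region exposes no T/B interface to score).
    """
    if a < 0:
        raise ValueError("order a must be non-negative")
    n_inter = summary.n_inter
    if n_inter == 0:
        return 0.0
    low = sum(cnt for i, cnt in summary.gamma_counts.items() if i <= a)
    return (n_inter - low) / n_inter


def homogeneity(summary: EdgeLabelSummary) -> float:
    """H = |Eα| / |E|: fraction of edges joining same-phenotype cells."""
    if summary.n_edges == 0:
        raise EdgelessGraphError("homogeneity undefined on an edgeless graph")
    return summary.n_alpha / summary.n_edges


def clustering_coefficient(graph: NeighborhoodGraph) -> float:
    """Global clustering coefficient C (mean of local coefficients).

    C = (1/|V|) Σ_l 2·n_l / (|N_l|(|N_l|−1)), where n_l counts edges among
    the neighbors of node l.  Nodes with fewer than two neighbors contribute
    zero to the sum but remain in |V|.
    """
    g = graph.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    total = 0.0
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if g.has_edge(nbrs[i], nbrs[j])
        )
        total += 2.0 * links / (k * (k - 1))
    return total / n


def degree_statistics(graph: NeighborhoodGraph) -> tuple[dict[int, float], float]:
    """Degree distribution P(k) = n_k/|V| and average degree ⟨K⟩ = 2|E|/|V|."""
    g = graph.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    counts = Counter(dict(g.degree).values())
    p_k = {k: c / n for k, c in sorted(counts.items())}
    avg = 2.0 * g.number_of_edges() / n
    return p_k, avg


def mean_pairwise_distance(
    graph: NeighborhoodGraph,
    resolution_um_per_px: float,
    exact_cap: int = PAIRWISE_EXACT_CAP,
    sample_pairs: int = PAIRWISE_SAMPLE_PAIRS,
    seed: int = 0,
) -> tuple[float, bool]:
    """Mean Euclidean distance over all unordered node pairs, in μm.

    Exact up to ``exact_cap`` nodes; above that, a seeded random sample of
    ``sample_pairs`` pairs is averaged instead.  Returns ``(value,
    subsampled)`` so downstream outputs can flag the approximation.
    """
    pts = graph.coordinates()
    n = len(pts)
    if n < 2:
        raise ValueError("mean pairwise distance undefined for fewer than 2 nodes")
    if n <= exact_cap:
        mean_px = float(pdist(pts).mean())
        return mean_px * resolution_um_per_px, False
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=sample_pairs)
    j = rng.integers(0, n - 1, size=sample_pairs)
    j = np.where(j >= i, j + 1, j)  # exclude self-pairs without rejection
    d = np.linalg.norm(pts[i] - pts[j], axis=1)
    return float(d.mean()) * resolution_um_per_px, True


@dataclass
class FeatureVector:
    """The full per-infiltrate feature set."""

    roi_id: str
    infiltrate_id: str
    n_nodes: int
    frac_a: float
    n_edges: int
    n_alpha: int
    frac_alpha_a: float
    homogeneity: float
    kappa: dict[int, float]
    clustering_c: float
    degree_distribution: dict[int, float]
    avg_degree: float
    mean_pairwise_dist_um: float
    pairwise_subsampled: bool = False

    def as_row(self) -> dict:
        """Flat dict for tabular output (designated type reported as B)."""
        row = {
            "roi_id": self.roi_id,
            "infiltrate_id": self.infiltrate_id,
            "n_nodes": self.n_nodes,
            "frac_B": self.frac_a,
            "n_edges": self.n_edges,
            "n_alpha": self.n_alpha,
            "frac_alpha_B": self.frac_alpha_a,
            "homogeneity": self.homogeneity,
        }
        for a, val in sorted(self.kappa.items()):
            row[f"kappa_{a}"] = val
        row.update(
            {
                "clustering_C": self.clustering_c,
                "avg_degree": self.avg_degree,
                "mean_pairwise_dist_um": self.mean_pairwise_dist_um,
            }
        )
        return row


DEFAULT_KAPPA_ORDERS = (2, 5)


def compute_feature_vector(
    infiltrate: InfiltrateGraph,
    kappa_orders: tuple[int, ...] = DEFAULT_KAPPA_ORDERS,
    resolution_um_per_px: float = 1.0,
    distance_seed: int = 0,
) -> FeatureVector:
    """Assemble every feature for one infiltrate."""
    summary = label_edges(infiltrate, infiltrate.designated_type_a)
    g = infiltrate.graph
    n_nodes = g.number_of_nodes()
    n_a = sum(
        1 for _, d in g.nodes(data=True) if d["phenotype"] == infiltrate.designated_type_a
    )
    p_k, avg_k = degree_statistics(infiltrate)
    dist_um, subsampled = mean_pairwise_distance(
        infiltrate, resolution_um_per_px, seed=distance_seed
    )
    return FeatureVector(
        roi_id=infiltrate.roi_id,
        infiltrate_id=infiltrate.infiltrate_id,
        n_nodes=n_nodes,
        frac_a=n_a / n_nodes,
        n_edges=summary.n_edges,
        n_alpha=summary.n_alpha,
        frac_alpha_a=summary.n_alpha_a / summary.n_edges if summary.n_edges else 0.0,
        homogeneity=homogeneity(summary),
        kappa={a: kappa(summary, a) for a in kappa_orders},
        clustering_c=clustering_coefficient(infiltrate),
        degree_distribution=p_k,
        avg_degree=avg_k,
        mean_pairwise_dist_um=dist_um,
        pairwise_subsampled=subsampled,
    )
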