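"""Composite node-importance scoring, critical response network extraction,
baseline centralities and target categorization.

The importance of node *i* in the C-T-P network ``Net_ctp = {N, E}`` is

    W_i = [ (n - 1) / sum_k d(i, k) ]  x  [ sum_{j<k, j!=i!=k} t_jk(i)/t_jk ] / [ n(n-1)/2 ]

the product of a closeness factor (the "leadership" of the node — how short
its distances to everyone else are) and a bridging factor (the fraction of
shortest paths between other node pairs that transit through it, i.e.
betweenness normalized by the number of unordered pairs). The graph is treated
as undirected, unweighted and simple; node weights (relevance scores) and edge
relations play no part.

Nodes scoring strictly above the network mean W_avg form the critical response
network (CRN, the induced subgraph on those nodes); its non-component nodes
are the *effective proteins* that downstream component selection must cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._brandes import adjacency_csr, shortest_path_stats
from .networks import ROLE_COMPONENT, TypedNetwork

BASELINE_METHODS = ("degree", "betweenness", "clustering")
#: Method labels accepted by the model-comparison layer.
ALL_METHODS = ("composite",) + BASELINE_METHODS


def _as_graph(net: TypedNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, TypedNetwork) else net


def _above_mean_mask(values: np.ndarray, mean: float) -> np.ndarray:
    """Strictly-above-the-mean with a round-off guard.

    Scores that are equal in exact arithmetic (e.g. on a vertex-transitive
    graph) can differ from their mean by a few ulps after floating-point
    accumulation; a relative epsilon keeps the strict rule strict there.
    """
    eps = 1e-9 * max(abs(mean), np.max(np.abs(values), initial=0.0))
    return values > mean + eps


@dataclass
class ImportanceScores:
    """Per-node composite scores plus the network mean.

    Invariants: ``wi = closeness_factor * bridging_factor`` elementwise,
    ``wavg`` is the arithmetic mean of ``wi`` over all ``n`` scored nodes,
    and every ``wi`` is nonnegative with ``bridging_factor`` in [0, 1].
    """

    nodes: tuple[str, ...]
    closeness_factor: np.ndarray
    bridging_factor: np.ndarray
    wi: np.ndarray
    wavg: float
    n: int
    roles: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, node: str) -> float:
        return float(self.wi[self.nodes.index(node)])

    @property
    def values(self) -> np.ndarray:
        return self.wi

    @property
    def mean(self) -> float:
        return self.wavg

    def above_mean(self) -> set[str]:
        """Nodes with score strictly above the network mean."""
        mask = _above_mean_mask(self.wi, self.wavg)
        return {v for v, keep in zip(self.nodes, mask) if keep}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.nodes,
                "role": [self.roles.get(v, "") for v in self.nodes],
                "closeness_factor": self.closeness_factor,
                "bridging_factor": self.bridging_factor,
                "wi": self.wi,
                "above_mean": _above_mean_mask(self.wi, self.wavg),
            }
        )


@dataclass
class ScoreVector:
    """A plain centrality vector (baseline methods) with the same above-mean
    interface as :class:`ImportanceScores`."""

    nodes: tuple[str, ...]
    values: np.ndarray
    method: str
    roles: dict[str, str] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def above_mean(self) -> set[str]:
        mask = _above_mean_mask(self.values, self.mean)
        return {v for v, keep in zip(self.nodes, mask) if keep}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.nodes,
                "role": [self.roles.get(v, "") for v in self.nodes],
                self.method: self.values,
                "above_mean": _above_mean_mask(self.values, self.mean),
            }
        )


def importance_scores(
    net: TypedNetwork | nx.Graph, componentwise: bool = False
) -> ImportanceScores:
    """Score every node of ``net`` with the composite importance measure.

    Isolated nodes are removed before scoring. By default the remaining graph
    must be connected (shortest-path quantities are otherwise ill-defined
    under the printed formula) and have at least 3 nodes; with
    ``componentwise=True`` a disconnected graph is accepted — unreachable
    pairs contribute zero to the bridging numerator and are excluded from the
    closeness denominator, while both normalizations keep the global ``n``.
    """
    g = _as_graph(net)
    g = g.subgraph([v for v in g if g.degree(v) > 0])
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError(
            f"importance scores need >= 3 non-isolated nodes, got {n} "
            "(the bridging factor is undefined below that)"
        )
    if not componentwise and not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected; pass componentwise=True to score "
            "per-component with unreachable pairs contributing zero"
        )

    nodes = tuple(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(index[u], index[v]) for u, v in g.edges], dtype=np.int64)
    adj = adjacency_csr(n, edges)
    farness, reach, btw = shortest_path_stats(adj)

    with np.errstate(divide="ignore", invalid="ignore"):
        closeness = np.where(farness > 0, (n - 1) / farness, 0.0)
    bridging = btw / (n * (n - 1) / 2.0)
    wi = closeness * bridging

    roles = net.roles() if isinstance(net, TypedNetwork) else {}
    return ImportanceScores(
        nodes=nodes,
        closeness_factor=closeness,
        bridging_factor=bridging,
        wi=wi,
        wavg=float(wi.mean()),
        n=n,
        roles=roles,
    )


@dataclass
class CRNResult:
    """Critical response network: the above-mean nodes, their induced
    subgraph, and the effective proteins (the kept non-component nodes)."""

    kept_nodes: frozenset[str]
    network: TypedNetwork
    effective_proteins: frozenset[str]


def extract_crn(
    net: TypedNetwork, scores: ImportanceScores | ScoreVector
) -> CRNResult:
    """Keep nodes scoring strictly above the mean; induce their subgraph.

    Single pass by contract: scores are not recomputed on the reduced graph.
    An all-equal score vector (e.g. any vertex-transitive graph) therefore
    yields an empty CRN, which is a legal result.
    """
    kept = frozenset(scores.above_mean())
    sub = net.induced_subgraph(kept)
    effective = frozenset(
        v for v in kept if net.role(v) != ROLE_COMPONENT
    )
    return CRNResult(kept_nodes=kept, network=sub, effective_proteins=effective)


def baseline_scores(
    net: TypedNetwork | nx.Graph, method: str, componentwise: bool = False
) -> ScoreVector:
    """Standard centralities used as comparison models.

    ``degree`` is the raw degree count, ``betweenness`` the unnormalized
    interior pair-dependency sum (same quantity as the bridging numerator),
    and ``clustering`` the local clustering coefficient (0 for degree < 2).
    The same strict above-mean rule applies downstream.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {BASELINE_METHODS}"
        )
    g = _as_graph(net)
    g = g.subgraph([v for v in g if g.degree(v) > 0])
    if g.number_of_nodes() < 3:
        raise ValueError("baseline scores need >= 3 non-isolated nodes")
    if not componentwise and not nx.is_connected(g):
        raise ValueError("graph is disconnected; pass componentwise=True")
    nodes = tuple(g.nodes)
    if method == "degree":
        vals = np.array([g.degree(v) for v in nodes], dtype=float)
    elif method == "betweenness":
        bc = nx.betweenness_centrality(g, normalized=False)
        vals = np.array([bc[v] for v in nodes])
    else:
        cc = nx.clustering(g)
        vals = np.array([cc[v] for v in nodes])
    roles = net.roles() if isinstance(net, TypedNetwork) else {}
    return ScoreVector(nodes=nodes, values=vals, method=method, roles=roles)


def score_network(
    net: TypedNetwork | nx.Graph, method: str = "composite", componentwise: bool = False
) -> ImportanceScores | ScoreVector:
    """Dispatch between the composite measure and the baseline centralities."""
    if method == "composite":
        return importance_scores(net, componentwise=componentwise)
    return baseline_scores(net, method, componentwise=componentwise)


@dataclass(frozen=True)
class TargetCategories:
    """Disjoint partition of protein nodes by provenance."""

    essential_common: frozenset[str]
    disease_specific: frozenset[str]
    component_specific: frozenset[str]


def categorize_targets(
    ct_targets: set[str] | frozenset[str],
    disease_genes: set[str] | frozenset[str],
    all_proteins: set[str] | frozenset[str],
) -> TargetCategories:
    """Split proteins into essential-common (component target AND pathogenic
    gene), component-specific and disease-specific sets."""
    ct_targets, disease_genes = frozenset(ct_targets), frozenset(disease_genes)
    if not ct_targets <= frozenset(all_proteins):
        raise ValueError("ct_targets must be a subset of all_proteins")
    if not disease_genes <= frozenset(all_proteins):
        raise ValueError("disease_genes must be a subset of all_proteins")
    return TargetCategories(
        essential_common=ct_targets & disease_genes,
        component_specific=ct_targets - disease_genes,
        disease_specific=disease_genes - ct_targets,
    )
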