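"""Assembly of the disease-gene, component-target (C-T) and merged C-T-P networks.

The pipeline works on a single graph type, :class:`TypedNetwork`: an undirected
simple graph whose nodes carry a *role* (chemical component, predicted protein
target, disease/pathogenic gene, or both) and an optional weight (the
disease-relevance score), and whose edges carry a *relation* (protein-protein
interaction or component-target association).

Builders in this module enforce the simple-graph invariants everywhere:
no self-loops, no duplicate edges, component nodes only ever touch
component-target edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

#: Legal node roles.
ROLE_COMPONENT = "component"
ROLE_TARGET = "target"
ROLE_DISEASE = "disease_gene"
ROLE_BOTH = "target_and_disease_gene"
ROLES = frozenset({ROLE_COMPONENT, ROLE_TARGET, ROLE_DISEASE, ROLE_BOTH})

#: Legal edge relations.
REL_PPI = "ppi"
REL_CT = "component_target"
RELATIONS = frozenset({REL_PPI, REL_CT})

#: Roles that denote a protein (non-component) node.
PROTEIN_ROLES = frozenset({ROLE_TARGET, ROLE_DISEASE, ROLE_BOTH})


@dataclass(frozen=True)
class DiseaseGene:
    """A pathogenic gene with its disease-relevance score.

    The score is the database-assigned association weight (e.g. the GeneCards
    relevance score); it is attached to the node as a weight and used only for
    the relevance threshold, never inside the importance formula.
    """

    symbol: str
    relevance_score: float

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("disease gene symbol must be nonempty")
        if not self.relevance_score >= 0:
            raise ValueError(
                f"relevance score must be >= 0, got {self.relevance_score!r}"
            )


class TypedNetwork:
    """Undirected simple graph with node roles and edge relations.

    Thin wrapper over :class:`networkx.Graph` that validates the invariants the
    pipeline relies on. Node identifiers are strings; gene symbols are expected
    to be normalized (trimmed, uppercased) upstream, component identifiers keep
    their own namespace and case.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, node: str, role: str, weight: float | None = None) -> None:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        self.graph.add_node(node, role=role, weight=weight)

    def add_edge(self, u: str, v: str, relation: str) -> None:
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        if u not in self.graph or v not in self.graph:
            raise ValueError(f"edge endpoints must be added as nodes first: {u!r}-{v!r}")
        self.graph.add_edge(u, v, relation=relation)

    # -- accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def weight(self, node: str) -> float | None:
        return self.graph.nodes[node].get("weight")

    def roles(self) -> dict[str, str]:
        return {n: d["role"] for n, d in self.graph.nodes(data=True)}

    def nodes_with_role(self, *roles: str) -> set[str]:
        want = set(roles)
        return {n for n, d in self.graph.nodes(data=True) if d["role"] in want}

    def protein_nodes(self) -> set[str]:
        """All non-component nodes."""
        return self.nodes_with_role(*PROTEIN_ROLES)

    def summary(self) -> dict:
        """Node/edge counts broken down by role and relation."""
        by_role: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            by_role[d["role"]] = by_role.get(d["role"], 0) + 1
        by_rel: dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            by_rel[d["relation"]] = by_rel.get(d["relation"], 0) + 1
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_by_role": by_role,
            "edges_by_relation": by_rel,
        }

    # -- transformations ----------------------------------------------

    def induced_subgraph(self, nodes: Iterable[str]) -> "TypedNetwork":
        return TypedNetwork(nx.Graph(self.graph.subgraph(nodes)))

    def remove_isolated(self) -> None:
        self.graph.remove_nodes_from(list(nx.isolates(self.graph)))

    def copy(self) -> "TypedNetwork":
        return TypedNetwork(self.graph.copy())

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        """Assert every structural invariant; raise ``ValueError`` on breach."""
        for n, d in self.graph.nodes(data=True):
            if d.get("role") not in ROLES:
                raise ValueError(f"node {n!r} has invalid role {d.get('role')!r}")
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            rel = d.get("relation")
            if rel not in RELATIONS:
                raise ValueError(f"edge {u!r}-{v!r} has invalid relation {rel!r}")
            u_comp = self.graph.nodes[u]["role"] == ROLE_COMPONENT
            v_comp = self.graph.nodes[v]["role"] == ROLE_COMPONENT
            if (u_comp or v_comp) and rel != REL_CT:
                raise ValueError(
                    f"component node on non component_target edge {u!r}-{v!r}"
                )
            if u_comp and v_comp:
                raise ValueError(f"edge between two components {u!r}-{v!r}")

    def graph_equal(self, other: "TypedNetwork") -> bool:
        """Equality of node set (with role/weight) and edge set (with relation)."""
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            a, b = self.graph.nodes[n], other.graph.nodes[n]
            if a["role"] != b["role"] or a.get("weight") != b.get("weight"):
                return False
        mine = {frozenset((u, v)): d["relation"] for u, v, d in self.graph.edges(data=True)}
        theirs = {frozenset((u, v)): d["relation"] for u, v, d in other.graph.edges(data=True)}
        return mine == theirs


def normalize_symbol(symbol: str) -> str:
    """Gene-symbol normalization used at every ingest point: trim + uppercase."""
    return symbol.strip().upper()


def merge_ppi(edge_lists: Sequence[Sequence[tuple[str, str]]]) -> TypedNetwork:
    """Merge several PPI edge lists into one deduplicated undirected network.

    ``(A, B)`` and ``(B, A)`` collapse to a single edge. Self-loops are dropped,
    and a node appearing only in self-loops is dropped with them (shortest-path
    quantities are loop-insensitive). All nodes get role ``target`` by default;
    the disease builder reassigns roles later.
    """
    if not edge_lists:
        raise ValueError("merge_ppi requires at least one edge list")
    net = TypedNetwork()
    for edges in edge_lists:
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                continue
            for n in (a, b):
                if n not in net.graph:
                    net.add_node(n, ROLE_TARGET)
            net.add_edge(a, b, REL_PPI)
    return net


def build_disease_network(
    ppi: TypedNetwork,
    genes: Sequence[DiseaseGene],
    min_score: float = 5.0,
) -> TypedNetwork:
    """Weighted disease-gene network: threshold, map onto the PPI, prune.

    Keeps genes with relevance score strictly greater than ``min_score`` that
    are present in the PPI, induces the PPI subgraph on them, and removes
    isolated nodes. Node weight is the relevance score. Mapping is exact symbol
    match after normalization; no alias resolution.
    """
    selected = {
        normalize_symbol(g.symbol): g.relevance_score
        for g in genes
        if g.relevance_score > min_score
    }
    mapped = [s for s in selected if s in ppi.graph]
    if not mapped:
        warnings.warn(
            "no disease gene above the relevance threshold maps onto the PPI; "
            "returning an empty network",
            stacklevel=2,
        )
        return TypedNetwork()
    net = ppi.induced_subgraph(mapped)
    net.remove_isolated()
    if net.n_nodes == 0:
        warnings.warn(
            "every mapped disease gene was isolated after induction; "
            "returning an empty network",
            stacklevel=2,
        )
    for n in net.graph.nodes:
        net.graph.nodes[n]["role"] = ROLE_DISEASE
        net.graph.nodes[n]["weight"] = selected[n]
    return net


def build_ct_network(
    associations: Sequence[tuple[str, str]],
) -> TypedNetwork:
    """Bipartite component-target network from (component id, target symbol) pairs.

    Duplicate associations collapse. Component ids live in their own namespace
    and are kept verbatim; a component id equal to a (normalized) target symbol
    in the same table is a namespace collision and an error.
    """
    pairs = [(c, normalize_symbol(t)) for c, t in associations]
    comp_ids = {c for c, _ in pairs}
    targets = {t for _, t in pairs}
    clash = comp_ids & targets
    if clash:
        raise ValueError(
            f"component ids collide with target symbols: {sorted(clash)[:5]}"
        )
    net = TypedNetwork()
    for c, t in pairs:
        if c not in net.graph:
            net.add_node(c, ROLE_COMPONENT)
        if t not in net.graph:
            net.add_node(t, ROLE_TARGET)
        net.add_edge(c, t, REL_CT)
    return net


def component_degrees(ct: TypedNetwork) -> dict[str, int]:
    """Per-component target counts in a C-T network."""
    return {n: ct.graph.degree(n) for n in ct.nodes_with_role(ROLE_COMPONENT)}


def target_degrees(ct: TypedNetwork) -> dict[str, int]:
    """Per-target component counts in a C-T network."""
    return {n: ct.graph.degree(n) for n in ct.nodes_with_role(ROLE_TARGET)}


def build_ctp_network(
    ct: TypedNetwork,
    disease: TypedNetwork,
    ppi: TypedNetwork,
) -> TypedNetwork:
    """Merge the C-T and disease networks over the PPI into the C-T-P network.

    Protein nodes present in both layers take the combined role
    ``target_and_disease_gene`` (keeping the disease weight). Edges are the
    union of C-T edges, disease-network edges, and every PPI edge between two
    included protein nodes. Isolated nodes are removed at the end.
    """
    if ct.n_nodes == 0:
        raise ValueError("C-T network must be nonempty")
    net = TypedNetwork()
    ct_targets = ct.nodes_with_role(ROLE_TARGET)
    disease_nodes = set(disease.graph.nodes)

    for c in ct.nodes_with_role(ROLE_COMPONENT):
        net.add_node(c, ROLE_COMPONENT)
    for p in ct_targets | disease_nodes:
        if p in ct_targets and p in disease_nodes:
            net.add_node(p, ROLE_BOTH, weight=disease.weight(p))
        elif p in disease_nodes:
            net.add_node(p, ROLE_DISEASE, weight=disease.weight(p))
        else:
            net.add_node(p, ROLE_TARGET)

    for u, v, d in ct.graph.edges(data=True):
        net.add_edge(u, v, d["relation"])
    for u, v in disease.graph.edges:
        net.add_edge(u, v, REL_PPI)
    proteins = ct_targets | disease_nodes
    for u, v in ppi.graph.edges:
        if u in proteins and v in proteins:
            net.add_edge(u, v, REL_PPI)

    net.remove_isolated()
    net.validate()
    return net
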