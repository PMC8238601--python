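"""Seeded generators for every input the pipeline reads, plus a planted
ground-truth fixture for end-to-end recovery tests.

Three generators cover the three input layers: a scale-free PPI graph
(preferential attachment), disease genes with log-normal relevance scores
straddling the selection threshold, and component records whose ADME
properties straddle the screening cutoffs with a controlled pass rate and
whose target sets overlap the disease genes by a controlled fraction.

The planted fixture builds a network whose importance structure is known by
construction: the designated effective proteins sit on a cycle of cut
vertices ("bridges"), each gating its own leaf periphery, so every shortest
path between peripheries transits them — their bridging factor is large and
their composite score is far above the network mean. Two kinds of decoys are
planted. Decoy components anchor on one bridge and otherwise target only
leaves of that same bridge; since the anchor route is always at least as
short, the leaves stay off every inter-node shortest path and keep a
near-zero bridging factor. A dense clique module hangs off one bridge with
every member also wired to that bridge, giving its members high degree and
clustering coefficient but exactly zero betweenness — a trap that degree-
and clustering-based node selection falls into while the composite score
does not. A planted core of components tiles the bridge set disjointly,
making the greedy coverage optimum unique.

All generators are pure functions of the configuration: the same config gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .adme import ComponentRecord
from .enrichment import GeneSetCollection
from .networks import (
    ROLE_TARGET,
    REL_PPI,
    DiseaseGene,
    TypedNetwork,
    build_ct_network,
    build_ctp_network,
    build_disease_network,
)

HERB_CODES = ("ZM", "XM", "HB", "BJT", "YYH", "DG")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults are sized so a desk-scale run exercises every pipeline stage in
    seconds: ~10^2 proteins, a few dozen components with 3-10 targets each,
    relevance scores log-normal around the selection threshold, and a 60%
    ADME pass rate (property distributions straddle every cutoff).
    """

    seed: int = 0
    n_proteins: int = 120
    ppi_attachment: int = 3
    n_disease: int = 60
    relevance_mu: float = 2.0
    relevance_sigma: float = 0.6
    n_components: int = 24
    adme_pass_fraction: float = 0.6
    targets_per_component: tuple[int, int] = (3, 10)
    disease_overlap_fraction: float = 0.5
    n_terms: int = 30
    term_size_range: tuple[int, int] = (6, 15)
    planted_core_size: int = 4

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        for name in ("n_proteins", "n_disease", "n_components", "n_terms",
                     "planted_core_size", "ppi_attachment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("adme_pass_fraction", "disease_overlap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("targets_per_component", "term_size_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an increasing positive range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream ``stream`` of the config's seed."""
        return np.random.default_rng([self.seed, stream])


def _protein_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(cfg: SyntheticConfig) -> TypedNetwork:
    """Connected scale-free PPI layer via preferential attachment.

    The growth model attaches each new node with ``ppi_attachment`` edges, so
    the edge count is exactly ``(n_proteins - m) * m``.
    """
    if cfg.n_proteins < cfg.ppi_attachment + 1:
        raise ValueError("n_proteins must exceed ppi_attachment")
    g = nx.barabasi_albert_graph(
        cfg.n_proteins, cfg.ppi_attachment, seed=int(cfg.rng(0).integers(2**31))
    )
    net = TypedNetwork()
    for i in g.nodes:
        net.add_node(_protein_name(i), ROLE_TARGET)
    for u, v in g.edges:
        net.add_edge(_protein_name(u), _protein_name(v), REL_PPI)
    return net


def generate_disease_genes(
    cfg: SyntheticConfig, ppi: TypedNetwork
) -> list[DiseaseGene]:
    """Disease genes drawn from the PPI with log-normal relevance scores.

    With the default (mu=2.0, sigma=0.6) about a quarter of scores fall under
    the relevance threshold of 5, so threshold filtering is always exercised.
    """
    rng = cfg.rng(1)
    nodes = sorted(ppi.graph.nodes)
    chosen = rng.choice(len(nodes), size=min(cfg.n_disease, len(nodes)), replace=False)
    scores = np.exp(rng.normal(cfg.relevance_mu, cfg.relevance_sigma, size=len(chosen)))
    return [
        DiseaseGene(symbol=nodes[i], relevance_score=float(s))
        for i, s in zip(sorted(chosen), scores)
    ]


def _draw_adme(rng: np.random.Generator, passing: bool) -> dict[str, float]:
    """ADME properties on the requested side of the screening thresholds.

    Passing records clear every cutoff with margin; failing records break
    between one and four properties.
    """
    vals = {
        "ob": float(rng.uniform(32, 90)),
        "mw": float(rng.uniform(200, 480)),
        "caco2": float(rng.uniform(0.5, 1.6)),
        "dl": float(rng.uniform(0.18, 0.95)),
    }
    if not passing:
        fail = {
            "ob": lambda: float(rng.uniform(2, 28)),
            "mw": lambda: float(rng.uniform(520, 900)),
            "caco2": lambda: float(rng.uniform(-1.5, 0.3)),
            "dl": lambda: float(rng.uniform(0.01, 0.12)),
        }
        broken = rng.choice(4, size=int(rng.integers(1, 5)), replace=False)
        for idx in broken:
            key = ("ob", "mw", "caco2", "dl")[idx]
            vals[key] = fail[key]()
    return vals


def generate_components_and_targets(
    cfg: SyntheticConfig,
    ppi: TypedNetwork,
    disease_genes: Sequence[DiseaseGene] | None = None,
) -> tuple[list[ComponentRecord], list[tuple[str, str]]]:
    """Component records plus their component-target association table.

    Each component passes the ADME screen with probability
    ``adme_pass_fraction``; targets are sampled from the PPI proteins with a
    ``disease_overlap_fraction`` share drawn from the disease-gene list.
    """
    if disease_genes is None:
        disease_genes = generate_disease_genes(cfg, ppi)
    rng = cfg.rng(2)
    nodes = sorted(ppi.graph.nodes)
    disease = sorted({g.symbol for g in disease_genes} & set(nodes))
    background = sorted(set(nodes) - set(disease))
    records: list[ComponentRecord] = []
    associations: list[tuple[str, str]] = []
    lo, hi = cfg.targets_per_component
    for i in range(cfg.n_components):
        cid = f"CMP{i + 1:03d}"
        passing = bool(rng.random() < cfg.adme_pass_fraction)
        herbs = rng.choice(
            len(HERB_CODES), size=int(rng.integers(1, 4)), replace=False
        )
        records.append(
            ComponentRecord(
                id=cid,
                name=f"component-{i + 1:03d}",
                herbs=frozenset(HERB_CODES[h] for h in herbs),
                include_listed=False,
                **_draw_adme(rng, passing),
            )
        )
        n_t = int(rng.integers(lo, hi + 1))
        n_dis = min(len(disease), int(round(cfg.disease_overlap_fraction * n_t)))
        n_bg = min(len(background), n_t - n_dis)
        picks = [disease[j] for j in rng.choice(len(disease), n_dis, replace=False)]
        picks += [background[j] for j in rng.choice(len(background), n_bg, replace=False)]
        associations.extend((cid, t) for t in sorted(picks))
    return records, associations


# -- planted ground-truth fixture --------------------------------------


@dataclass(frozen=True)
class PlantedTruth:
    """What the fixture guarantees by construction."""

    effective_proteins: frozenset[str]
    core_components: tuple[str, ...]
    tiles: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class PlantedFixture:
    """Full input bundle plus ground truth for recovery tests."""

    config: SyntheticConfig
    ppi: TypedNetwork
    disease_genes: list[DiseaseGene]
    components: list[ComponentRecord]
    associations: list[tuple[str, str]]
    gene_sets: GeneSetCollection
    truth: PlantedTruth

    def assemble(self) -> tuple[TypedNetwork, TypedNetwork, TypedNetwork]:
        """Build (disease network, C-T network, C-T-P network) with the
        production builders."""
        disease = build_disease_network(self.ppi, self.disease_genes)
        ct = build_ct_network(self.associations)
        ctp = build_ctp_network(ct, disease, self.ppi)
        return disease, ct, ctp


class InfeasibleFixtureError(ValueError):
    """The requested configuration cannot be tiled into a planted fixture."""


def make_planted_fixture(cfg: SyntheticConfig | None = None) -> PlantedFixture:
    """Build the planted-ground-truth fixture.

    Topology: ``planted_core_size * tile`` bridge proteins on a cycle, each
    the sole gateway to its own leaves; a dense clique module hanging off one
    bridge (high degree/clustering, zero betweenness); decoy components
    targeting only leaves and clique members. The planted core components
    tile the bridge set disjointly, so greedy coverage selection must pick
    exactly the core, and the bridges are the designed effective proteins.
    """
    cfg = cfg or SyntheticConfig()
    rng = cfg.rng(3)
    m = cfg.planted_core_size
    tile = cfg.targets_per_component[0]
    if tile < 2:
        raise InfeasibleFixtureError("tile size (min targets per component) must be >= 2")
    n_bridges = m * tile
    clique_size = max(8, round(0.6 * cfg.n_proteins))
    n_leaves = cfg.n_proteins - n_bridges - clique_size
    if n_leaves < 2 * n_bridges:
        raise InfeasibleFixtureError(
            f"n_proteins={cfg.n_proteins} too small for {n_bridges} bridges "
            f"with >= 2 leaves each plus a {clique_size}-clique"
        )
    if cfg.n_components <= m:
        raise InfeasibleFixtureError("n_components must exceed planted_core_size")

    bridges = [f"G{i:04d}" for i in range(n_bridges)]
    leaves = [f"G{i:04d}" for i in range(n_bridges, n_bridges + n_leaves)]
    clique = [
        f"G{i:04d}"
        for i in range(n_bridges + n_leaves, n_bridges + n_leaves + clique_size)
    ]

    ppi = TypedNetwork()
    for p in bridges + leaves + clique:
        ppi.add_node(p, ROLE_TARGET)
    for i, b in enumerate(bridges):
        ppi.add_edge(b, bridges[(i + 1) % n_bridges], REL_PPI)
    leaves_of: dict[str, list[str]] = {b: [] for b in bridges}
    for j, leaf in enumerate(leaves):
        owner = bridges[j % n_bridges]
        leaves_of[owner].append(leaf)
        ppi.add_edge(leaf, owner, REL_PPI)
    for a_i in range(clique_size):
        for b_i in range(a_i + 1, clique_size):
            ppi.add_edge(clique[a_i], clique[b_i], REL_PPI)
        ppi.add_edge(clique[a_i], bridges[0], REL_PPI)

    # Disease layer: bridges and leaves are always pathogenic, plus half the
    # clique — the disease query stays a strict subset of the annotation
    # universe, so enrichment against it is informative.
    disease_symbols = bridges + leaves + clique[::2]
    disease_genes = [
        DiseaseGene(symbol=s, relevance_score=float(rng.uniform(6, 50)))
        for s in disease_symbols
    ]

    # Core components tile the bridges; each decoy anchors on one bridge and
    # otherwise targets leaves of that same bridge, so the anchor route keeps
    # every decoy target off the inter-node shortest paths.
    components: list[ComponentRecord] = []
    associations: list[tuple[str, str]] = []
    tiles: dict[str, frozenset[str]] = {}
    for i in range(m):
        cid = f"CORE{i + 1:02d}"
        tile_set = frozenset(bridges[i * tile:(i + 1) * tile])
        tiles[cid] = tile_set
        components.append(_fixture_component(cid, f"core-{i + 1:02d}", rng))
        associations.extend((cid, t) for t in sorted(tile_set))
    for i in range(cfg.n_components - m):
        cid = f"DEC{i + 1:03d}"
        components.append(_fixture_component(cid, f"decoy-{i + 1:03d}", rng))
        anchor = bridges[int(rng.integers(n_bridges))]
        pool = leaves_of[anchor]
        n_t = min(len(pool), int(rng.integers(2, 4)))
        picks = rng.choice(len(pool), size=n_t, replace=False)
        associations.append((cid, anchor))
        associations.extend((cid, pool[j]) for j in sorted(picks))

    gene_sets = _planted_gene_sets(cfg, rng, bridges, leaves, clique)

    return PlantedFixture(
        config=cfg,
        ppi=ppi,
        disease_genes=disease_genes,
        components=components,
        associations=associations,
        gene_sets=gene_sets,
        truth=PlantedTruth(
            effective_proteins=frozenset(bridges),
            core_components=tuple(sorted(tiles)),
            tiles=tiles,
        ),
    )


def _fixture_component(
    cid: str, name: str, rng: np.random.Generator
) -> ComponentRecord:
    herbs = rng.choice(len(HERB_CODES), size=int(rng.integers(1, 4)), replace=False)
    return ComponentRecord(
        id=cid,
        name=name,
        herbs=frozenset(HERB_CODES[h] for h in herbs),
        include_listed=False,
        **_draw_adme(rng, passing=True),
    )


def _planted_gene_sets(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    bridges: list[str],
    leaves: list[str],
    clique: list[str],
) -> GeneSetCollection:
    """A third of the terms concentrate on the bridge set (the planted
    enrichment signal); the rest are background. The annotation universe
    includes extra background-only symbols beyond the network, as real
    annotation collections always cover far more genes than any one study.
    """
    lo, hi = cfg.term_size_range
    extras = [f"X{i:04d}" for i in range(cfg.n_proteins // 2)]
    universe = bridges + leaves + clique + extras
    background_pool = leaves + clique + extras
    sets: dict[str, list[str]] = {}
    n_planted = max(2, cfg.n_terms // 3)
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < n_planted:
            n_b = min(len(bridges), max(3, round(0.8 * size)))
            picks = [bridges[j] for j in rng.choice(len(bridges), n_b, replace=False)]
            n_rest = min(len(leaves), size - n_b)
            if n_rest > 0:
                picks += [leaves[j] for j in rng.choice(len(leaves), n_rest, replace=False)]
            sets[f"PLT{t + 1:03d}"] = picks
        else:
            size = min(size, len(background_pool))
            picks = rng.choice(len(background_pool), size, replace=False)
            sets[f"BKG{t + 1:03d}"] = [background_pool[j] for j in picks]
    return GeneSetCollection.from_sets(sets, universe=universe)
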