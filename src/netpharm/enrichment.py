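"""Hypergeometric gene-set enrichment and coverage-based model validation.

Enrichment of a query gene set against a collection (KEGG pathways, GO terms,
or any GMT-style flat sets) uses the one-sided upper-tail hypergeometric test:
the probability of observing at least the seen overlap when drawing the query
from the universe. *Intervention terms* are the intersection of the terms
enriched for the drug-target set and for the pathogenic-gene set; a scoring
model is validated by the proportion of intervention terms its effective
proteins recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .importance import ALL_METHODS, extract_crn, score_network
from .networks import TypedNetwork

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Every set must be nonempty and contained in the universe; the universe
    defaults to the union of all sets when not supplied (the standard fallback
    when no explicit background is stated).
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            if not genes <= self.universe:
                raise ValueError(f"gene set {term!r} is not within the universe")

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        built = {
            term: ((descriptions or {}).get(term, term), frozenset(genes))
            for term, genes in sets.items()
        }
        if universe is None:
            uni: frozenset[str] = frozenset().union(
                *(g for _, g in built.values())
            ) if built else frozenset()
        else:
            uni = frozenset(universe)
        return cls(sets=built, universe=uni)

    def terms(self) -> list[str]:
        return list(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    description: str
    overlap_count: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float | None
    enriched: bool


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment of ``query`` against every term.

    For a term of size K in a universe of size M, with the query restricted
    to the universe of size N and overlap k, the p-value is
    P[X >= k], X ~ Hypergeom(M, K, N). Terms with raw p < ``alpha`` are
    flagged enriched (the significance gate is the raw p-value by design;
    a Benjamini-Hochberg column is added when ``adjust=True``). Rows come
    back sorted by p ascending, ties by term id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = frozenset(query) & collection.universe
    if not q:
        raise ValueError("query does not intersect the collection universe")
    M, N = len(collection.universe), len(q)
    rows = []
    for term, (desc, genes) in collection.sets.items():
        k = len(q & genes)
        p = float(hypergeom.sf(k - 1, M, len(genes), N))
        p = min(p, 1.0)
        rows.append((term, desc, k, len(genes), p))
    rows.sort(key=lambda r: (r[4], r[0]))
    if adjust and rows:
        adj = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    else:
        adj = [None] * len(rows)
    return [
        EnrichmentRow(
            term=term,
            description=desc,
            overlap_count=k,
            query_size=N,
            set_size=ks,
            universe_size=M,
            p_value=p,
            adjusted_p=None if a is None else float(a),
            enriched=p < alpha,
        )
        for (term, desc, k, ks, p), a in zip(rows, adj)
    ]


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def enriched_terms(rows: Sequence[EnrichmentRow]) -> frozenset[str]:
    return frozenset(r.term for r in rows if r.enriched)


def intervention_terms(
    targets_enriched: Iterable[str], disease_enriched: Iterable[str]
) -> frozenset[str]:
    """Terms enriched for both the drug targets and the pathogenic genes."""
    return frozenset(targets_enriched) & frozenset(disease_enriched)


@dataclass(frozen=True)
class CoverageReport:
    """How much of a denominator term set the numerator set recovers."""

    numerator_terms: frozenset[str]
    denominator_terms: frozenset[str]
    proportion: float

    @property
    def percent(self) -> float:
        return round(100.0 * self.proportion, 2)


def coverage_proportion(
    numerator: Iterable[str], denominator: Iterable[str]
) -> CoverageReport:
    num, den = frozenset(numerator), frozenset(denominator)
    if not den:
        raise ValueError("denominator term set must be nonempty")
    return CoverageReport(
        numerator_terms=num,
        denominator_terms=den,
        proportion=len(num & den) / len(den),
    )


def compare_models(
    net: TypedNetwork,
    methods: Sequence[str],
    collection: GeneSetCollection,
    disease_genes: Iterable[str],
    target_genes: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    componentwise: bool = False,
) -> pd.DataFrame:
    """Benchmark scoring models by intervention-term coverage.

    For each method (the composite importance measure or a baseline
    centrality): score the network, keep the strictly-above-mean nodes, take
    their non-component members as effective proteins, enrich those against
    the collection, and report what proportion of the intervention terms
    (terms enriched for both ``target_genes`` and ``disease_genes``) the
    effective proteins recover. One row per method; an effective-protein set
    disjoint from the universe scores zero coverage.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    disease_hits = enriched_terms(enrich(disease_genes, collection, alpha))
    target_hits = enriched_terms(enrich(target_genes, collection, alpha))
    intervention = intervention_terms(target_hits, disease_hits)
    records = []
    for method in methods:
        scores = score_network(net, method, componentwise=componentwise)
        crn = extract_crn(net, scores)
        eff = crn.effective_proteins
        if eff & collection.universe:
            hits = enriched_terms(enrich(eff, collection, alpha))
        else:
            hits = frozenset()
        report = coverage_proportion(hits, intervention)
        records.append(
            {
                "method": method,
                "n_effective": len(eff),
                "n_enriched": len(hits),
                "n_intervention": len(intervention),
                "covered": len(hits & intervention),
                "coverage_percent": report.percent,
            }
        )
    return pd.DataFrame(records, columns=[
        "method", "n_effective", "n_enriched", "n_intervention",
        "covered", "coverage_percent",
    ])
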