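"""End-to-end orchestration: tables in, core active component group out.

Chains the pipeline stages in their canonical order — ADME screen, disease
network, C-T network, C-T-P merge, composite importance scoring, critical
response network, target-coverage selection — and returns every intermediate
product so callers (CLI, tests, validation) can inspect any stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .adme import AdmeThresholds, ComponentRecord, filter_active_components
from .importance import (
    CRNResult,
    ImportanceScores,
    categorize_targets,
    extract_crn,
    importance_scores,
    TargetCategories,
)
from .networks import (
    DiseaseGene,
    TypedNetwork,
    build_ct_network,
    build_ctp_network,
    build_disease_network,
)
from .tcc import CACGResult, TCCSelection, cacg_at, tcc_select


@dataclass
class PipelineResult:
    active_components: list[ComponentRecord]
    disease_network: TypedNetwork
    ct_network: TypedNetwork
    ctp_network: TypedNetwork
    scores: ImportanceScores
    crn: CRNResult
    categories: TargetCategories
    selection: TCCSelection | None
    cacg: CACGResult | None


def run_pipeline(
    ppi: TypedNetwork,
    disease_genes: Sequence[DiseaseGene],
    components: Sequence[ComponentRecord],
    associations: Sequence[tuple[str, str]],
    min_score: float = 5.0,
    thresholds: AdmeThresholds | None = None,
    coverage_target: float = 1.0,
    componentwise: bool = False,
) -> PipelineResult:
    """Run the full formula-optimization pipeline.

    Associations of components rejected by the ADME screen are dropped before
    network construction. When the critical response network retains no
    protein (legal on degenerate inputs), selection and CACG are ``None``.
    """
    active = filter_active_components(components, thresholds)
    active_ids = {c.id for c in active}
    assoc = [(c, t) for c, t in associations if c in active_ids]
    if not assoc:
        raise ValueError("no associations left after the ADME screen")

    disease_net = build_disease_network(ppi, disease_genes, min_score)
    ct = build_ct_network(assoc)
    ctp = build_ctp_network(ct, disease_net, ppi)

    scores = importance_scores(ctp, componentwise=componentwise)
    crn = extract_crn(ctp, scores)

    ct_targets = {t for _, t in assoc} & set(ctp.graph.nodes)
    disease_set = set(disease_net.graph.nodes) & set(ctp.graph.nodes)
    categories = categorize_targets(
        ct_targets, disease_set, ctp.protein_nodes()
    )

    selection: TCCSelection | None = None
    cacg: CACGResult | None = None
    if crn.effective_proteins:
        per_component: dict[str, set[str]] = {}
        for c, t in assoc:
            per_component.setdefault(c, set()).add(t)
        selection = tcc_select(per_component, crn.effective_proteins)
        cacg = cacg_at(selection, coverage_target)

    return PipelineResult(
        active_components=active,
        disease_network=disease_net,
        ct_network=ct,
        ctp_network=ctp,
        scores=scores,
        crn=crn,
        categories=categories,
        selection=selection,
        cacg=cacg,
    )
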