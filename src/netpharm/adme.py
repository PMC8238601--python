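"""ADME screening of herbal components and cross-herb overlap counting.

Active components are selected by four absorption/distribution/metabolism/
excretion properties — oral bioavailability (OB, %), molecular weight (MW, Da),
Caco-2 permeability (log-scale, unitless) and drug-likeness (DL, unitless) —
with strict thresholds, unioned with a literature include-list of
high-concentration components that bypass the property filter entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentRecord:
    """A chemical component with herb membership and ADME properties.

    Properties may be missing (``None``) for components absent from the
    property database; such records fail the screen unless include-listed.
    """

    id: str
    name: str
    herbs: frozenset[str]
    mw: float | None = None
    ob: float | None = None
    caco2: float | None = None
    dl: float | None = None
    include_listed: bool = False

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"component {self.id!r} must belong to >=1 herb")
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"component {self.id!r}: MW must be > 0")
        if self.ob is not None and not (0 <= self.ob <= 100):
            raise ValueError(f"component {self.id!r}: OB must be in [0, 100]")


@dataclass(frozen=True)
class AdmeThresholds:
    """Screening cutoffs; defaults are the standard OB/MW/Caco-2/DL criteria."""

    ob: float = 30.0
    mw: float = 500.0
    caco2: float = 0.4
    dl: float = 0.14


def passes_adme(record: ComponentRecord, thresholds: AdmeThresholds) -> bool:
    """All four properties present and strictly inside the cutoffs:
    OB > ob, MW < mw, Caco-2 > caco2, DL > dl."""
    if None in (record.ob, record.mw, record.caco2, record.dl):
        return False
    return (
        record.ob > thresholds.ob
        and record.mw < thresholds.mw
        and record.caco2 > thresholds.caco2
        and record.dl > thresholds.dl
    )


def filter_active_components(
    records: Sequence[ComponentRecord],
    thresholds: AdmeThresholds | None = None,
) -> list[ComponentRecord]:
    """Select potential active components.

    A record is kept when it passes all four strict ADME inequalities, or when
    it is include-listed (literature-documented high-concentration components
    join by set union, regardless of properties). Input order is preserved.
    Records with missing properties fail closed unless include-listed; the
    rejection is logged with a reason.
    """
    thresholds = thresholds or AdmeThresholds()
    kept: list[ComponentRecord] = []
    for rec in records:
        if rec.include_listed:
            kept.append(rec)
            continue
        if None in (rec.ob, rec.mw, rec.caco2, rec.dl):
            missing = [
                k for k in ("ob", "mw", "caco2", "dl") if getattr(rec, k) is None
            ]
            logger.warning(
                "component %s rejected: missing ADME propert%s %s",
                rec.id,
                "y" if len(missing) == 1 else "ies",
                ",".join(missing),
            )
            continue
        if passes_adme(rec, thresholds):
            kept.append(rec)
    return kept


def herb_overlap_counts(
    records: Sequence[ComponentRecord],
) -> dict[frozenset[str], int]:
    """Exact-subset (UpSet-style) partition of components over herb sets.

    Each component is counted once, under its exact herb membership set, so the
    counts over all subsets sum to the number of records and the bins are
    disjoint by construction. Shared components are the bins of size >= 2.
    """
    return dict(Counter(rec.herbs for rec in records))


def dedup_by_name(records: Sequence[ComponentRecord]) -> list[ComponentRecord]:
    """Collapse records sharing a (case-insensitive) name across herbs.

    The merged record carries the union of herb memberships and the first
    record's id and properties. Provided for cross-herb tallies where one
    chemical collected from several herb tables should count once.
    """
    merged: dict[str, ComponentRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.name.strip().lower()
        if key not in merged:
            merged[key] = rec
            order.append(key)
        else:
            old = merged[key]
            merged[key] = ComponentRecord(
                id=old.id,
                name=old.name,
                herbs=old.herbs | rec.herbs,
                mw=old.mw,
                ob=old.ob,
                caco2=old.caco2,
                dl=old.dl,
                include_listed=old.include_listed or rec.include_listed,
            )
    return [merged[k] for k in order]
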