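"""Target-coverage-contribution (TCC) selection of a core active component group.

Given the effective-protein universe extracted from the critical response
network and each component's target set, the selection ranks components by
their cumulative contribution to covering the universe. The default mode is
greedy maximum coverage: repeatedly pick the component covering the most
still-uncovered effective proteins, stopping when no pick adds coverage. An
exact mode (exhaustive subset search, feasible up to 20 components) finds, for
every subset size k, a size-k subset of maximal coverage; it doubles as the
optimality oracle for the greedy curve. The core active component group (CACG)
is the shortest selection prefix reaching a requested coverage level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

EXACT_MAX_COMPONENTS = 20


@dataclass
class TCCSelection:
    """Ordered component picks with marginal and cumulative coverage.

    ``order`` is the pick sequence; ``target_counts`` maps each picked
    component to its effective-target count; ``marginal_coverage`` holds the
    pairwise-disjoint sets of newly covered effective proteins per pick;
    ``cumulative_coverage`` is nondecreasing with last value
    ``|covered| / |universe|``.
    """

    order: tuple[str, ...]
    target_counts: dict[str, int]
    marginal_coverage: tuple[frozenset[str], ...]
    cumulative_coverage: tuple[float, ...]
    universe: frozenset[str]

    @property
    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.marginal_coverage:
            out |= s
        return frozenset(out)


def _restrict(
    component_targets: Mapping[str, set[str] | frozenset[str]],
    effective: frozenset[str],
) -> dict[str, frozenset[str]]:
    return {c: frozenset(t) & effective for c, t in component_targets.items()}


def _greedy_order(
    sets: dict[str, frozenset[str]], universe: frozenset[str]
) -> tuple[list[str], list[frozenset[str]]]:
    """Greedy max coverage. Ties on marginal gain break toward the larger
    total effective-target count, then the lexicographically smaller id."""
    uncovered = set(universe)
    order: list[str] = []
    marginals: list[frozenset[str]] = []
    remaining = dict(sets)
    while uncovered and remaining:
        best_id: str | None = None
        best_key: tuple[int, int] | None = None
        for cid in sorted(remaining):
            gain = len(remaining[cid] & uncovered)
            key = (gain, len(sets[cid]))
            if best_key is None or key > best_key:
                best_key, best_id = key, cid
        assert best_id is not None and best_key is not None
        if best_key[0] == 0:
            break
        newly = frozenset(remaining.pop(best_id) & uncovered)
        uncovered -= newly
        order.append(best_id)
        marginals.append(newly)
    return order, marginals


def exact_coverage_by_k(
    component_targets: Mapping[str, set[str] | frozenset[str]],
    effective: set[str] | frozenset[str],
) -> dict[int, tuple[int, tuple[str, ...]]]:
    """For every subset size k, the maximal number of effective proteins
    coverable by k components, with one witness subset.

    Exhaustive over all 2^m subsets via bitmask union DP; gated to
    m <= ``EXACT_MAX_COMPONENTS``. Serves as the optimality oracle for the
    greedy selection.
    """
    effective = frozenset(effective)
    sets = _restrict(component_targets, effective)
    comps = sorted(sets)
    m = len(comps)
    if m > EXACT_MAX_COMPONENTS:
        raise ValueError(
            f"exact search is limited to {EXACT_MAX_COMPONENTS} components, got {m}"
        )
    prot_index = {p: i for i, p in enumerate(sorted(effective))}
    masks = [
        sum(1 << prot_index[p] for p in sets[c]) for c in comps
    ]
    best: dict[int, tuple[int, int]] = {0: (0, 0)}  # k -> (coverage, subset bits)
    cover = [0] * (1 << m)
    for bits in range(1, 1 << m):
        low = bits & -bits
        cover[bits] = cover[bits ^ low] | masks[low.bit_length() - 1]
        k = bits.bit_count()
        c = cover[bits].bit_count()
        if k not in best or c > best[k][0]:
            best[k] = (c, bits)
    return {
        k: (c, tuple(comps[i] for i in range(m) if bits >> i & 1))
        for k, (c, bits) in sorted(best.items())
    }


def tcc_select(
    component_targets: Mapping[str, set[str] | frozenset[str]],
    effective: set[str] | frozenset[str],
    mode: str = "greedy",
) -> TCCSelection:
    """Select components by target-coverage contribution.

    Target sets are intersected with the effective-protein universe before
    selection; components with zero marginal gain are never picked. In
    ``exact`` mode the minimal-size subset achieving the maximal attainable
    coverage is found exhaustively and ordered internally by the same greedy
    rule, so the cumulative curve is comparable across modes.
    """
    effective = frozenset(effective)
    if not effective:
        raise ValueError("effective-protein universe must be nonempty")
    sets = _restrict(component_targets, effective)
    if not sets:
        return TCCSelection((), {}, (), (), effective)

    if mode == "greedy":
        order, marginals = _greedy_order(sets, effective)
    elif mode == "exact":
        by_k = exact_coverage_by_k(component_targets, effective)
        attainable = max(c for c, _ in by_k.values())
        k_min = min(k for k, (c, _) in by_k.items() if c == attainable)
        subset = by_k[k_min][1]
        order, marginals = _greedy_order(
            {c: sets[c] for c in subset}, effective
        )
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'greedy' or 'exact'")

    covered = 0
    cumulative: list[float] = []
    for s in marginals:
        covered += len(s)
        cumulative.append(covered / len(effective))
    return TCCSelection(
        order=tuple(order),
        target_counts={c: len(sets[c]) for c in order},
        marginal_coverage=tuple(marginals),
        cumulative_coverage=tuple(cumulative),
        universe=effective,
    )


def coverage_curve(sel: TCCSelection) -> pd.DataFrame:
    """Tabulate the accumulative coverage curve, one row per pick.

    Columns: rank (1-based), component, marginal (newly covered count),
    cumulative_percent (to two decimals).
    """
    return pd.DataFrame(
        {
            "rank": range(1, len(sel.order) + 1),
            "component": sel.order,
            "marginal": [len(s) for s in sel.marginal_coverage],
            "cumulative_percent": [
                round(100.0 * v, 2) for v in sel.cumulative_coverage
            ],
        }
    )


@dataclass(frozen=True)
class CACGResult:
    """Core active component group: the selection prefix reaching the
    requested coverage, flagged if the target is unreachable."""

    components: tuple[str, ...]
    reached: bool


def cacg_at(sel: TCCSelection, coverage_target: float = 1.0) -> CACGResult:
    """Shortest prefix of the selection whose cumulative coverage meets
    ``coverage_target``; the full order with ``reached=False`` otherwise."""
    if not 0 < coverage_target <= 1:
        raise ValueError("coverage_target must be in (0, 1]")
    for i, v in enumerate(sel.cumulative_coverage):
        if v >= coverage_target:
            return CACGResult(components=sel.order[: i + 1], reached=True)
    return CACGResult(components=sel.order, reached=False)
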