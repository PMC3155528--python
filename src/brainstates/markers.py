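"""Regional marker gene candidates from the multi-state table.

A multi-state probe marks a region when its highest (or lowest) state
contains exactly that single region.  High and low calls are independent:
a probe whose extreme states are both singletons yields one of each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .multistate import MultiStateTable, StateModel


@dataclass(frozen=True)
class MarkerCall:
    probe_id: str
    gene: str
    region: str
    direction: str  # "high" or "low"
    expression_range: float  # max - min of state means, log2
    n_states: int


def _extreme_singleton(model: StateModel, which: str) -> str | None:
    state = model.n_states - 1 if which == "high" else 0
    regions = model.regions_of_state(state)
    if len(regions) == 1:
        return next(iter(regions))
    return None


def find_markers(table: MultiStateTable) -> list[MarkerCall]:
    """Scan every multi-state probe for singleton extreme states.

    Output order follows probe ID order and is invariant to the order
    probes were fit in.
    """
    calls: list[MarkerCall] = []
    for pid in sorted(table.multi_state_probes):
        model = table.models[pid]
        gene = table.probes.at[pid, "gene"]
        rng = model.expression_range
        for direction in ("high", "low"):
            region = _extreme_singleton(model, direction)
            if region is not None:
                calls.append(
                    MarkerCall(pid, gene, region, direction, rng, model.n_states)
                )
    return calls


def markers_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.probe_id, c.gene, c.region, c.direction, c.expression_range,
             c.n_states)
            for c in calls
        ],
        columns=["probe_id", "gene", "region", "direction", "range", "n_states"],
    )


def top_markers(
    calls: Sequence[MarkerCall],
    k: int = 3,
    regions: Sequence[str] | None = None,
) -> list[str]:
    """Up to ``k`` high-direction probes per region by descending range.

    Ties break on probe ID for determinism.  The union is deduplicated by
    gene; ``regions`` restricts the regions considered (e.g. dropping
    spinal cord / retina / pituitary / pineal).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    high = [c for c in calls if c.direction == "high"]
    if regions is not None:
        wanted = set(regions)
        high = [c for c in high if c.region in wanted]
    by_region: dict[str, list[MarkerCall]] = {}
    for c in high:
        by_region.setdefault(c.region, []).append(c)
    genes: list[str] = []
    seen: set[str] = set()
    for region in sorted(by_region):
        ranked = sorted(
            by_region[region], key=lambda c: (-c.expression_range, c.probe_id)
        )
        for c in ranked[:k]:
            if c.gene not in seen:
                seen.add(c.gene)
                genes.append(c.gene)
    return genes
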