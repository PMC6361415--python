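"""Consensus taxonomy assignment from precomputed alignment hit tables.

The rules mirror common practice for 16S reference mapping: hits below a 60%
identity floor are discarded; if any hit is a perfect (100%) match, only the
perfect matches vote; otherwise all hits within 5 percentage points of the
best hit vote.  The assigned taxonomy is the deepest rank prefix shared by
all voting hits; a query with no qualifying hits, or whose voting hits do not
even agree at the domain level, is left unidentified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Hit, HitTable

__all__ = [
    "ConsensusAssignment",
    "select_hits",
    "consensus_taxonomy",
    "assign_all",
    "distance_histogram",
]

IDENTITY_FLOOR = 60.0
BAND_WIDTH = 5.0
_EPS = 1e-9  # tolerance for the 100% and 60% identity gates


@dataclass
class ConsensusAssignment:
    query_id: str
    path: tuple[str, ...]          # empty when unidentified
    identified: bool
    n_selected: int
    best_identity: float | None

    @property
    def status(self) -> str:
        return "identified" if self.identified else "unidentified"


def select_hits(hits: list[Hit], floor: float = IDENTITY_FLOOR,
                band: float = BAND_WIDTH) -> list[Hit]:
    """Choose the hits that vote on the consensus.

    Perfect (100%) hits preempt everything else; otherwise, with best identity
    s >= floor, all hits with identity >= s - band are kept (inclusive at
    exactly s - band); below the floor nothing qualifies.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: -h.percent_identity)
    best = ordered[0].percent_identity
    if best >= 100.0 - _EPS:
        return [h for h in ordered if h.percent_identity >= 100.0 - _EPS]
    if best < floor - _EPS:
        return []
    return [h for h in ordered if h.percent_identity >= best - band - _EPS]


def consensus_taxonomy(query_id: str, selected: list[Hit]) -> ConsensusAssignment:
    """Deepest shared taxonomy prefix of the selected hits.

    Ranks are compared positionally on the semicolon-split paths; a missing
    rank never matches.  No shared domain => unidentified.
    """
    if not selected:
        return ConsensusAssignment(query_id, (), False, 0, None)
    best = max(h.percent_identity for h in selected)
    paths = [h.taxonomy for h in selected]
    depth = min(len(p) for p in paths)
    shared: list[str] = []
    for level in range(depth):
        names = {p[level] for p in paths}
        if len(names) == 1:
            shared.append(next(iter(names)))
        else:
            break
    if not shared:  # no agreement even at the domain rank
        return ConsensusAssignment(query_id, (), False, len(selected), best)
    return ConsensusAssignment(query_id, tuple(shared), True, len(selected), best)


def assign_all(table: HitTable) -> list[ConsensusAssignment]:
    """Run hit selection + consensus for every query in a hit table."""
    return [
        consensus_taxonomy(q, select_hits(hits)) for q, hits in table.groups.items()
    ]


def distance_histogram(best_identities, bin_width: float = 2.0):
    """Histogram of distances (100 - identity) to the closest reference entry.

    Returns ``(edges, counts)`` with equal-width bins starting at 0; the bin
    width defaults to 2 percentage points.  Empty input yields empty arrays.
    """
    ident = np.asarray(list(best_identities), dtype=float)
    if ident.size == 0:
        return np.array([]), np.array([], dtype=np.int64)
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("identities must lie in [0, 100]")
    dist = 100.0 - ident
    n_bins = int(np.ceil((dist.max() + 1e-12) / bin_width))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist, bins=edges)
    return edges, counts.astype(np.int64)
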