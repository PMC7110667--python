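"""Per-base mapping coverage of repeat instances over a family consensus.

Coverage counts chains (one per instance), so the profile directly shows
which consensus regions are present in which copies: 5'-truncated LINE
families give coverage rising toward the 3' end, and a fixed deletion in a
sub-lineage appears as a sharp coverage drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .chains import ChainSet

__all__ = ["CoverageTrack", "compute_coverage", "coverage_by_species"]


@dataclass(frozen=True)
class CoverageTrack:
    """Integer per-base coverage over one consensus."""

    consensus_name: str
    values: np.ndarray
    n_instances: int

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("coverage values must be >= 0")
        if self.n_instances and self.values.size and self.values.max() > self.n_instances:
            raise ValueError("coverage exceeds the number of instances")

    def __len__(self) -> int:
        return int(self.values.size)


def compute_coverage(cs: ChainSet, cons_len: int) -> CoverageTrack:
    """Count, per consensus base, the chains with an aligned block covering it.

    All chains must target the same consensus; chain gaps (dq) contribute
    nothing.  Input order is irrelevant by construction.
    """
    names = cs.consensus_names()
    if len(names) > 1:
        raise ValueError(f"chains target multiple consensuses: {names}")
    diffs = np.zeros(cons_len + 1, dtype=np.int64)
    for chain in cs:
        if chain.q_size != cons_len:
            raise ValueError(
                f"chain {chain.id}: q_size {chain.q_size} != consensus length {cons_len}"
            )
        for qs, qe in chain.q_blocks_plus():
            if qs < 0 or qe > cons_len:
                raise ValueError(f"chain {chain.id}: block outside consensus")
            diffs[qs] += 1
            diffs[qe] -= 1
    values = np.cumsum(diffs[:-1])
    name = names[0] if names else "consensus"
    return CoverageTrack(name, values, n_instances=len(cs))


def coverage_by_species(
    groups: Mapping[str, ChainSet], cons_len: int
) -> Dict[str, CoverageTrack]:
    """Coverage per species group on a shared consensus coordinate system."""
    tracks: Dict[str, CoverageTrack] = {}
    names = set()
    for species, cs in groups.items():
        tracks[species] = compute_coverage(cs, cons_len)
        names.update(cs.consensus_names())
    if len(names) > 1:
        raise ValueError(f"groups target different consensuses: {sorted(names)}")
    return tracks
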