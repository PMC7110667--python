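"""Escape-deletion analysis: coverage-drop windows, genotyping, ordering.

Retrotransposon lineages escape KRAB zinc finger repression by deleting the
repressor's binding site; on a family consensus this leaves a sharp drop in
instance mapping coverage.  This module finds such drop windows, genotypes
every instance as carrier / non-carrier / not-spanning, and infers the
relative age of two deletions from their co-occurrence pattern: if nearly
all carriers of deletion B also carry deletion A but not vice versa, A
predates B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .chains import ChainSet
from .coverage import CoverageTrack
from .io_formats import RmskRecord

__all__ = [
    "FullLengthFilter",
    "DeletionWindow",
    "DeletionStatusMatrix",
    "ContingencyResult",
    "filter_full_length",
    "detect_deletion_windows",
    "genotype_instances",
    "cooccurrence",
]

CARRIER = "carrier"
NON_CARRIER = "non-carrier"
NOT_SPANNING = "not-spanning"


@dataclass(frozen=True)
class FullLengthFilter:
    """Keep elements at least this long (6000 nt ~ an intact LINE-1)."""

    min_length: int = 6000

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class DeletionWindow:
    """A consensus interval where instance coverage collapses."""

    consensus_name: str
    start: int
    end: int
    drop_fraction_observed: float
    n_spanning: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def wid(self) -> str:
        return f"{self.consensus_name}:{self.start}-{self.end}"


# rows: instance ids; columns: window ids; cells in {carrier, non-carrier, not-spanning}
DeletionStatusMatrix = pd.DataFrame


@dataclass(frozen=True)
class ContingencyResult:
    """Carrier co-occurrence of two deletion windows and an ordering call."""

    window_a: str
    window_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    p_a_given_b: float
    p_b_given_a: float
    ordering_call: str  # "A_first", "B_first" or "unresolved"


def filter_full_length(
    records: Sequence[RmskRecord], f: FullLengthFilter = FullLengthFilter()
) -> Tuple[List[RmskRecord], Dict[str, int]]:
    """Keep near full-length elements; "less than min_length" is excluded,
    so an element of exactly min_length is kept.  Per-family counts of the
    kept elements are returned alongside."""
    kept = [r for r in records if len(r.interval) >= f.min_length]
    counts: Dict[str, int] = {}
    for r in kept:
        counts[r.family] = counts.get(r.family, 0) + 1
    return kept, counts


def _windowed_medians(values: np.ndarray, flank: int) -> Tuple[np.ndarray, np.ndarray]:
    """left[i] = median over [i-flank, i); right[i] = median over (i, i+flank]."""
    n = values.size
    left = np.zeros(n)
    right = np.zeros(n)
    if n > flank:
        sw = np.lib.stride_tricks.sliding_window_view(values, flank)
        med = np.median(sw, axis=1)  # med[k] = median(values[k:k+flank])
        left[flank:] = med[: n - flank]
        right[: n - flank - 1] = med[1 : n - flank]
    for i in range(min(flank, n)):
        if i:
            left[i] = np.median(values[:i])
    for i in range(max(0, n - flank - 1), n):
        if i + 1 < n:
            right[i] = np.median(values[i + 1 :])
    return left, right


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _outer_baselines(
    values: np.ndarray, s: int, e: int, flank: int, prev_end: int, next_start: int
) -> Tuple[float, float]:
    lo = max(prev_end, s - flank)
    hi = min(next_start, e + flank)
    left = float(np.median(values[lo:s])) if s > lo else 0.0
    right = float(np.median(values[e:hi])) if hi > e else 0.0
    return left, right


def detect_deletion_windows(
    track: CoverageTrack,
    drop_fraction: float = 0.5,
    flank_win: int = 100,
    min_width: int = 5,
    min_spanning: int = 10,
) -> List[DeletionWindow]:
    """Find consensus windows where coverage drops below a local baseline.

    A base is initially marked dropped when its coverage falls below
    ``drop_fraction`` times the larger of the two flanking medians (windows
    of ``flank_win`` bases) and that baseline reaches ``min_spanning``.
    Because the interior of a drop wider than ``flank_win`` sees only its
    own depressed flanks, marked runs are then iteratively merged whenever
    every base between them stays below the threshold set by baselines
    measured *outside* the candidate windows, and each window's boundaries
    are refined against those outer baselines.  Windows narrower than
    ``min_width`` (or separated by less than it) are filtered or merged.
    """
    values = track.values.astype(float)
    n = values.size
    if n == 0:
        return []
    left, right = _windowed_medians(values, flank_win)
    base = np.maximum(left, right)
    mask = (base >= min_spanning) & (values < drop_fraction * base)
    wins = _runs(mask)
    if not wins:
        return []

    # merge runs across still-depressed interiors (wide deletions fragment the
    # initial mask because their own interior drags the local medians down)
    changed = True
    while changed:
        changed = False
        merged: List[Tuple[int, int]] = []
        i = 0
        while i < len(wins):
            s, e = wins[i]
            while i + 1 < len(wins):
                s2, e2 = wins[i + 1]
                l_out, r_out = _outer_baselines(
                    values, s, e2, flank_win,
                    wins[i - 1][1] if i > 0 else 0,
                    wins[i + 2][0] if i + 2 < len(wins) else n,
                )
                gap = values[e:s2]
                if (
                    min(l_out, r_out) >= min_spanning
                    and gap.size
                    and np.all(gap < drop_fraction * max(l_out, r_out))
                ):
                    e = e2
                    i += 1
                    changed = True
                elif gap.size == 0 and i + 1 < len(wins):
                    e = e2
                    i += 1
                    changed = True
                else:
                    break
            merged.append((s, e))
            i += 1
        wins = merged

    # boundary refinement against outer baselines
    refined: List[Tuple[int, int]] = []
    for idx, (s, e) in enumerate(wins):
        prev_end = wins[idx - 1][1] if idx > 0 else 0
        next_start = wins[idx + 1][0] if idx + 1 < len(wins) else n
        # a genuine deletion has solid coverage on BOTH sides; a 5' truncation
        # ramp (or a window at the array edge) does not and is rejected here.
        # The drop threshold uses the higher flank: the lower one is itself
        # depressed by the rising truncation profile.
        l_out, r_out = _outer_baselines(values, s, e, flank_win, prev_end, next_start)
        if min(l_out, r_out) < min_spanning:
            continue
        thr = drop_fraction * max(l_out, r_out)
        while s > prev_end and values[s - 1] < thr:
            s -= 1
        while e < next_start and values[e] < thr:
            e += 1
        while s < e and values[s] >= thr:
            s += 1
        while e > s and values[e - 1] >= thr:
            e -= 1
        if e > s:
            refined.append((s, e))

    # merge windows separated by less than min_width, then drop narrow ones
    final: List[Tuple[int, int]] = []
    for s, e in refined:
        if final and s - final[-1][1] < min_width:
            final[-1] = (final[-1][0], e)
        else:
            final.append((s, e))
    out: List[DeletionWindow] = []
    for idx, (s, e) in enumerate(final):
        if e - s < min_width:
            continue
        prev_end = final[idx - 1][1] if idx > 0 else 0
        next_start = final[idx + 1][0] if idx + 1 < len(final) else n
        l_out, r_out = _outer_baselines(values, s, e, flank_win, prev_end, next_start)
        bases = [b for b in (l_out, r_out) if b > 0]
        bg = float(np.mean(bases)) if bases else 0.0
        drop = 1.0 - (float(values[s:e].mean()) / bg if bg > 0 else 0.0)
        out.append(
            DeletionWindow(
                consensus_name=track.consensus_name,
                start=s,
                end=e,
                drop_fraction_observed=float(np.clip(drop, 0.0, 1.0)),
                n_spanning=int(round(bg)),
            )
        )
    return out


def genotype_instances(
    cs: ChainSet,
    windows: Sequence[DeletionWindow],
    span_margin: int = 20,
    covered_max: float = 0.2,
) -> DeletionStatusMatrix:
    """Per-instance deletion status for every detected window.

    An instance *spans* a window when its alignment covers at least one base
    within ``span_margin`` on each side; a spanning instance is a *carrier*
    when its aligned bases cover less than ``covered_max`` of the window.
    """
    rows = {}
    for chain in cs:
        inst = cs.instance_of.get(chain.id, str(chain.id))
        blocks = list(chain.q_blocks_plus())
        statuses = {}
        for w in windows:
            lflank = (max(0, w.start - span_margin), w.start)
            rflank = (w.end, w.end + span_margin)
            covers_l = any(qs < lflank[1] and qe > lflank[0] for qs, qe in blocks)
            covers_r = any(qs < rflank[1] and qe > rflank[0] for qs, qe in blocks)
            if not (covers_l and covers_r):
                statuses[w.wid] = NOT_SPANNING
                continue
            inside = sum(
                max(0, min(qe, w.end) - max(qs, w.start)) for qs, qe in blocks
            )
            statuses[w.wid] = CARRIER if inside < covered_max * w.width else NON_CARRIER
        rows[inst] = statuses
    cols = [w.wid for w in windows]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def cooccurrence(
    m: DeletionStatusMatrix,
    a: str,
    b: str,
    tau_high: float = 0.9,
    tau_margin: float = 0.2,
) -> ContingencyResult:
    """Carrier contingency of windows ``a`` and ``b`` over doubly-spanning rows.

    The call is ``A_first`` when P(A|B) >= tau_high and exceeds P(B|A) by at
    least tau_margin (symmetrically ``B_first``); otherwise ``unresolved``.
    An old deletion shows up in (almost) every carrier of a younger one.
    """
    both = m[(m[a] != NOT_SPANNING) & (m[b] != NOT_SPANNING)]
    if both.empty:
        raise ValueError("no instance spans both windows")
    ca = both[a] == CARRIER
    cb = both[b] == CARRIER
    n11 = int((ca & cb).sum())
    n10 = int((ca & ~cb).sum())
    n01 = int((~ca & cb).sum())
    n00 = int((~ca & ~cb).sum())
    p_a_b = n11 / (n11 + n01) if (n11 + n01) else float("nan")
    p_b_a = n11 / (n11 + n10) if (n11 + n10) else float("nan")
    call = "unresolved"
    if np.isfinite(p_a_b) and np.isfinite(p_b_a):
        if p_a_b >= tau_high and p_a_b - p_b_a >= tau_margin:
            call = "A_first"
        elif p_b_a >= tau_high and p_b_a - p_a_b >= tau_margin:
            call = "B_first"
    return ContingencyResult(a, b, n11, n10, n01, n00, p_a_b, p_b_a, call)
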