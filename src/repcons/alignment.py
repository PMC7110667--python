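"""Fit ("glocal") affine-gap alignment of an instance against a consensus.

The aligner consumes the query end-to-end while end gaps on the target are
free, which is the right model for repeat instances: most copies are
5'-truncated fragments of the family consensus, and a global alignment
would penalize the truncation itself.

Two execution paths share one dynamic-programming kernel:

* **full DP** over the whole rectangle, used for short sequence pairs and as
  the reference mode in tests;
* **anchored banded DP** for long pairs: maximal exact shared k-mers are
  chained co-linearly, the chain defines a per-row diagonal track, and the
  DP is confined to a band around that track.  A single-anchor chain
  degenerates to the classic one-diagonal band.

Scores are integers.  Among co-optimal alignments the kernel prefers fewer
gap openings, then the leftmost target end (ties inside the DP are broken
by a composite integer objective, so the result is fully deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .io_formats import SeqRecord

__all__ = [
    "AlignScoring",
    "AlignmentBlocks",
    "UnalignableError",
    "fit_align",
    "score_from_blocks",
]

# full-DP fallback is refused above this many matrix cells
_FULL_DP_MAX_CELLS = 4_000_000
_ANCHOR_K = 12
_COMPOSITE_SHIFT = 32  # composite = score << 32  minus one per gap opening


class UnalignableError(RuntimeError):
    """No k-mer anchor exists and the pair is too large for full DP."""


@dataclass(frozen=True)
class AlignScoring:
    """Integer alignment scores; a gap of length L costs gap_open + L*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")


@dataclass(frozen=True)
class AlignmentBlocks:
    """Ungapped co-linear segments of one query/target alignment.

    Blocks are (q_start, q_end, t_start, t_end) half-open pairs, strictly
    increasing in both coordinates; mismatches live inside blocks, gaps
    between them.
    """

    query_name: str
    target_name: str
    blocks: Tuple[Tuple[int, int, int, int], ...]
    score: float

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment has no blocks")
        prev_q = prev_t = -1
        for qs, qe, ts, te in self.blocks:
            if qe - qs != te - ts or qe <= qs:
                raise ValueError(f"malformed block {(qs, qe, ts, te)}")
            if qs < prev_q or ts < prev_t:
                raise ValueError("blocks must be strictly increasing")
            prev_q, prev_t = qe, te

    @property
    def q_span(self) -> Tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def t_span(self) -> Tuple[int, int]:
        return self.blocks[0][2], self.blocks[-1][3]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def score_from_blocks(
    blocks: Sequence[Tuple[int, int, int, int]],
    query: str,
    target: str,
    s: AlignScoring,
    query_len: Optional[int] = None,
) -> int:
    """Recompute the alignment score from its blocks (additivity check).

    Unaligned query bases outside the outermost blocks are charged as end
    gaps in the target (query must be consumed end-to-end); target overhangs
    are free.
    """
    total = 0
    for qs, qe, ts, te in blocks:
        for a, b in zip(query[qs:qe], target[ts:te]):
            total += s.match if a == b else s.mismatch
    for (_q1s, q1e, _t1s, t1e), (q2s, _q2e, t2s, _t2e) in zip(blocks, blocks[1:]):
        gap = (q2s - q1e) + (t2s - t1e)
        total += s.gap_open + gap * s.gap_extend
    # leading/trailing unaligned query bases are gaps in the target
    n = len(query) if query_len is None else query_len
    lead = blocks[0][0]
    trail = n - blocks[-1][1]
    for g in (lead, trail):
        if g > 0:
            total += s.gap_open + g * s.gap_extend
    return total


# ---------------------------------------------------------------------------
# DP kernel


@njit(cache=True)
def _fit_dp(q, t, lo, W, match, mismatch, go, ge):  # pragma: no cover - jitted
    """Banded affine fit DP along a per-row diagonal track.

    Row i (0..n) holds cells j = lo[i] + b for b in [0, W); lo[0..n] is the
    leftmost target column per row.  Returns (blocks, nblocks, score).
    """
    n = q.shape[0]
    m = t.shape[0]
    NEG = np.int64(-(1 << 60))
    S1 = np.int64(1) << _COMPOSITE_SHIFT
    open_cost = np.int64(go + ge) * S1 - 1
    ext_cost = np.int64(ge) * S1

    M = np.full((n + 1, W), NEG, np.int64)
    X = np.full((n + 1, W), NEG, np.int64)
    Y = np.full((n + 1, W), NEG, np.int64)
    pM = np.zeros((n + 1, W), np.uint8)
    pX = np.zeros((n + 1, W), np.uint8)
    pY = np.zeros((n + 1, W), np.uint8)

    for b in range(W):
        j = lo[0] + b
        if 0 <= j <= m:
            M[0, b] = 0  # free target prefix: start before consuming any query

    for i in range(1, n + 1):
        qc = q[i - 1]
        base = lo[i]
        shift = base - lo[i - 1]
        for b in range(W):
            j = base + b
            if j < 0 or j > m:
                continue
            # X: consume query base against a target gap; pred (i-1, j)
            bx = b + shift
            bestx = NEG
            px = np.uint8(0)
            if 0 <= bx < W:
                vm = M[i - 1, bx]
                if vm != NEG:
                    bestx = vm + open_cost
                vx = X[i - 1, bx]
                if vx != NEG and vx + ext_cost > bestx:
                    bestx = vx + ext_cost
                    px = 1
            X[i, b] = bestx
            pX[i, b] = px
            # M: diagonal move; pred (i-1, j-1)
            bm = b + shift - 1
            bestm = NEG
            pm = np.uint8(0)
            if j >= 1 and 0 <= bm < W:
                sub = np.int64(match if qc == t[j - 1] else mismatch) * S1
                vm = M[i - 1, bm]
                if vm != NEG:
                    bestm = vm + sub
                vx = X[i - 1, bm]
                if vx != NEG and vx + sub > bestm:
                    bestm = vx + sub
                    pm = 1
                vy = Y[i - 1, bm]
                if vy != NEG and vy + sub > bestm:
                    bestm = vy + sub
                    pm = 2
            M[i, b] = bestm
            pM[i, b] = pm
            # Y: consume target base against a query gap; pred (i, j-1)
            besty = NEG
            py = np.uint8(0)
            if j >= 1 and b >= 1:
                vm = M[i, b - 1]
                if vm != NEG:
                    besty = vm + open_cost
                vy = Y[i, b - 1]
                if vy != NEG and vy + ext_cost > besty:
                    besty = vy + ext_cost
                    py = 1
            Y[i, b] = besty
            pY[i, b] = py

    # best end: max composite over last row, M or X; ties -> leftmost j
    best = NEG
    bend = -1
    send = np.uint8(0)
    for b in range(W):
        j = lo[n] + b
        if j < 0 or j > m:
            continue
        if M[n, b] > best:
            best = M[n, b]
            bend = b
            send = 0
        if X[n, b] > best:
            best = X[n, b]
            bend = b
            send = 1
    blocks = np.zeros((n + 1, 4), np.int64)
    if bend < 0 or best == NEG:
        return blocks, 0, np.int64(0)

    # traceback, collecting maximal diagonal runs as blocks
    nb = 0
    i = n
    b = bend
    state = send
    run_len = 0
    run_qe = 0
    run_te = 0
    while i > 0:
        j = lo[i] + b
        if state == 0:  # M: diagonal
            if run_len == 0:
                run_qe = i
                run_te = j
            run_len += 1
            nxt = pM[i, b]
            b = b + (lo[i] - lo[i - 1]) - 1
            i -= 1
            state = nxt
        else:
            if run_len > 0:
                blocks[nb, 0] = i - 0  # q_start of finished run is current i
                blocks[nb, 1] = run_qe
                blocks[nb, 2] = j - 0
                blocks[nb, 3] = run_te
                nb += 1
                run_len = 0
            if state == 1:  # X: gap in target, consume query
                nxt = pX[i, b]  # 0 = from M, 1 = from X
                b = b + (lo[i] - lo[i - 1])
                i -= 1
                state = np.uint8(0) if nxt == 0 else np.uint8(1)
            else:  # Y: gap in query, consume target
                nxt = pY[i, b]  # 0 = from M, 1 = from Y
                b -= 1
                state = np.uint8(0) if nxt == 0 else np.uint8(2)
    if run_len > 0:
        j = lo[i] + b
        blocks[nb, 0] = i
        blocks[nb, 1] = run_qe
        blocks[nb, 2] = j
        blocks[nb, 3] = run_te
        nb += 1

    # blocks were collected walking backwards; caller reverses them
    return blocks[:nb], nb, best


# ---------------------------------------------------------------------------
# anchoring


def _chain_anchors(q: str, t: str, k: int = _ANCHOR_K, max_occ: int = 8):
    """Chain maximal shared k-mer runs co-linearly; returns list of segments.

    Segments are (q_start, t_start, length) exact matches, strictly
    increasing in q and t along the selected chain (maximum total matched
    length; ties broken toward smaller diagonal shifts).
    """
    n, m = len(q), len(t)
    if n < k or m < k:
        return []
    index: dict = {}
    for j in range(m - k + 1):
        index.setdefault(t[j : j + k], []).append(j)
    # raw anchors merged into maximal same-diagonal runs
    segs: List[Tuple[int, int, int]] = []
    open_run: dict = {}  # diag -> [q_start, q_end)
    for i in range(n - k + 1):
        hits = index.get(q[i : i + k])
        if not hits or len(hits) > max_occ:
            continue
        for j in hits:
            d = j - i
            run = open_run.get(d)
            if run is not None and i <= run[1]:
                run[1] = max(run[1], i + k)
            else:
                if run is not None:
                    segs.append((run[0], run[0] + d, run[1] - run[0]))
                open_run[d] = [i, i + k]
    for d, run in open_run.items():
        segs.append((run[0], run[0] + d, run[1] - run[0]))
    if not segs:
        return []
    segs.sort(key=lambda s: (s[0], s[1]))
    if len(segs) > 4000:
        segs = sorted(segs, key=lambda s: -s[2])[:4000]
        segs.sort(key=lambda s: (s[0], s[1]))
    # O(s^2) colinear chaining on matched length with a mild shift penalty
    ns = len(segs)
    score = [0.0] * ns
    prev = [-1] * ns
    for a in range(ns):
        qa, ta, la = segs[a]
        score[a] = float(la)
        for b in range(a):
            qb, tb, lb = segs[b]
            if qb >= qa or tb >= ta:
                continue
            # segment ends may overrun the true junction by a few bases
            # (a k-mer can straddle it by chance); allow trimmed overlaps
            overlap = max(qb + lb - qa, tb + lb - ta, 0)
            if overlap >= min(la, lb):
                continue
            shift = abs((ta - qa) - (tb - qb))
            cand = score[b] + la - overlap - 0.01 * shift
            if cand > score[a]:
                score[a] = cand
                prev[a] = b
    best = int(np.argmax(score))
    chain = []
    while best >= 0:
        chain.append(segs[best])
        best = prev[best]
    chain.reverse()
    return chain


def _diag_track(chain, n: int, half: int) -> Tuple[np.ndarray, int]:
    """Per-row band origin lo[i] following the anchor chain's diagonals."""
    d = np.empty(n + 1, dtype=np.int64)
    (q0, t0, _l0) = chain[0]
    d[: q0 + 1] = t0 - q0
    for (qa, ta, la), (qb, tb, _lb) in zip(chain, chain[1:]):
        da, db = ta - qa, tb - qb
        d[qa : qa + la + 1] = da
        span = qb - (qa + la)
        if span > 0:
            # interpolate across the unanchored stretch
            d[qa + la : qb + 1] = np.round(
                np.linspace(da, db, span + 1)
            ).astype(np.int64)
        else:
            d[qb] = db
    qz, tz, _lz = chain[-1]
    d[qz:] = tz - qz
    lo = np.arange(n + 1, dtype=np.int64) + d - half
    return lo, 2 * half + 1


def fit_align(
    query: SeqRecord,
    target: SeqRecord,
    scoring: Optional[AlignScoring] = None,
    band: Optional[int] = 200,
) -> AlignmentBlocks:
    """Optimal fit alignment: query end-to-end, target substring, end gaps free.

    ``band=None`` forces full DP (refused above the size cap).  Otherwise
    k-mer anchors define a diagonal track and the DP runs in a band of
    half-width up to ``band`` around it; the half-width shrinks automatically
    when the chained anchors show no large diagonal jumps.
    """
    s = scoring or AlignScoring()
    q, t = query.seq, target.seq
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        raise ValueError("cannot align empty sequences")
    qa, ta = _encode(q), _encode(t)

    full_cells = (n + 1) * (m + 1)
    use_full = band is None or full_cells <= min(_FULL_DP_MAX_CELLS, (2 * band + 1) * (n + 1))
    if use_full:
        if full_cells > _FULL_DP_MAX_CELLS:
            raise UnalignableError(
                f"pair of sizes {n} x {m} exceeds the full-DP cell cap"
            )
        lo = np.zeros(n + 1, dtype=np.int64)
        W = m + 1
    else:
        chain = _chain_anchors(q, t)
        if not chain:
            if full_cells <= _FULL_DP_MAX_CELLS:
                lo = np.zeros(n + 1, dtype=np.int64)
                W = m + 1
                chain = None
            else:
                raise UnalignableError(
                    f"no shared {_ANCHOR_K}-mer between {query.name!r} and "
                    f"{target.name!r} and pair too large for full DP"
                )
        if chain:
            jumps = [
                abs((tb - qb) - (ta_ - qa_))
                for (qa_, ta_, la_), (qb, tb, _lb) in zip(chain, chain[1:])
            ]
            half = min(band, 24 + (max(jumps) if jumps else 0))
            lo, W = _diag_track(chain, n, half)

    raw_blocks, nb, composite = _fit_dp(
        qa, ta, lo, W, s.match, s.mismatch, s.gap_open, s.gap_extend
    )
    if nb == 0:
        # the optimum aligned no bases at all (gap-only) — representable only
        # as "no alignment"; happens for tiny or unrelated pairs
        raise UnalignableError(
            f"optimal alignment of {query.name!r} vs {target.name!r} aligns no bases"
        )
    blocks = tuple(
        (int(b[0]), int(b[1]), int(b[2]), int(b[3])) for b in raw_blocks[:nb][::-1]
    )
    score = score_from_blocks(blocks, q, t, s)
    return AlignmentBlocks(query.name, target.name, blocks, score)
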