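"""Genome -> consensus liftOver chains and interval lifting.

A chain's target (``t``) side is the genome and its query (``q``) side the
consensus, matching the UCSC "over.chain" orientation for lifting data FROM
the genome TO the consensus.  Minus-strand instances yield ``qStrand=-``
chains whose q coordinates follow the UCSC reverse-strand convention;
``tStrand`` is always ``+``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .alignment import AlignmentBlocks
from .io_formats import Chain, ChainBlock, GenomeInterval

__all__ = [
    "ChainSet",
    "build_chain",
    "lift_interval",
    "lift_bed",
    "LiftParams",
    "Unmapped",
]


@dataclass(frozen=True)
class LiftParams:
    """Lifting policy: minimum aligned fraction and multi-chain behaviour."""

    min_match: float = 0.95
    multiple: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")


@dataclass(frozen=True)
class Unmapped:
    """An interval that failed to lift, with a reason code."""

    interval: GenomeInterval
    reason: str  # "deleted" (no chain) or "partial" (aligned fraction too low)


class ChainSet:
    """Chains indexed by genomic chromosome for fast overlap lookup."""

    def __init__(self, chains: Iterable[Chain] = ()) -> None:
        self.chains: Dict[int, Chain] = {}
        self.instance_of: Dict[int, str] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for c in chains:
            self.add(c)

    def add(self, chain: Chain, instance_id: Optional[str] = None) -> None:
        if chain.id in self.chains:
            raise ValueError(f"duplicate chain id {chain.id}")
        self.chains[chain.id] = chain
        if instance_id is not None:
            self.instance_of[chain.id] = instance_id
        self._trees.setdefault(chain.t_name, IntervalTree()).addi(
            chain.t_start, chain.t_end, chain.id
        )

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self):
        return iter(self.chains.values())

    def overlapping(self, chrom: str, start: int, end: int) -> List[Chain]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: iv.data)
        return [self.chains[iv.data] for iv in hits]

    def consensus_names(self) -> List[str]:
        return sorted({c.q_name for c in self.chains.values()})


def build_chain(
    aln: AlignmentBlocks,
    locus: GenomeInterval,
    genome_size: int,
    cons_len: int,
    chain_id: int,
) -> Chain:
    """Turn one instance-vs-consensus alignment into a genome->consensus chain.

    ``aln`` must align the instance sequence extracted from ``locus``
    (reverse-complemented first when ``locus.strand`` is ``-``) as query
    against the consensus as target.  The chain's t side is expressed on the
    forward genome strand; for minus-strand instances the block order is
    reversed and q coordinates are given on the consensus minus strand.
    """
    inst_len = len(locus)
    if aln.blocks[-1][1] > inst_len:
        raise ValueError(
            f"alignment spans {aln.blocks[-1][1]} query bases but locus "
            f"{locus.name!r} is only {inst_len} long"
        )
    if aln.blocks[-1][3] > cons_len:
        raise ValueError("alignment exceeds consensus length")

    if locus.strand == "+":
        # genome position = locus.start + query index; consensus on + strand
        pairs = [
            (locus.start + qs, locus.start + qe, ts, te)
            for qs, qe, ts, te in aln.blocks
        ]
        q_strand = "+"
    else:
        # query index q maps to genome position locus.end - 1 - q; walking the
        # genome forward walks the consensus backwards -> minus-strand q side
        pairs = [
            (locus.end - qe, locus.end - qs, cons_len - te, cons_len - ts)
            for qs, qe, ts, te in reversed(aln.blocks)
        ]
        q_strand = "-"

    t_start, q_start = pairs[0][0], pairs[0][2]
    t_end, q_end = pairs[-1][1], pairs[-1][3]
    blocks: List[ChainBlock] = []
    for idx, (ts, te, qs, qe) in enumerate(pairs):
        if idx + 1 < len(pairs):
            nts, _nte, nqs, _nqe = pairs[idx + 1][0], 0, pairs[idx + 1][2], 0
            blocks.append((te - ts, nts - te, nqs - qe))
        else:
            blocks.append((te - ts, 0, 0))
    return Chain(
        id=chain_id,
        score=aln.score,
        t_name=locus.chrom,
        t_size=genome_size,
        t_start=t_start,
        t_end=t_end,
        q_name=aln.target_name,
        q_size=cons_len,
        q_strand=q_strand,
        q_start=q_start,
        q_end=q_end,
        blocks=tuple(blocks),
    )


def _map_through_chain(
    iv: GenomeInterval, chain: Chain
) -> Tuple[int, Optional[Tuple[int, int]]]:
    """Aligned base count and the minimal consensus span covering iv's mapping.

    The span is in plus-strand consensus coordinates; None when no base maps.
    """
    aligned = 0
    lo = None
    hi = None
    q = chain.q_start
    t = chain.t_start
    for size, dt, dq in chain.blocks:
        s = max(iv.start, t)
        e = min(iv.end, t + size)
        if s < e:
            aligned += e - s
            if chain.q_strand == "+":
                c_lo = q + (s - t)
                c_hi = q + (e - t)
            else:
                c_hi = chain.q_size - (q + (s - t))
                c_lo = chain.q_size - (q + (e - t))
            lo = c_lo if lo is None else min(lo, c_lo)
            hi = c_hi if hi is None else max(hi, c_hi)
        t += size + dt
        q += size + dq
    return aligned, (None if lo is None else (lo, hi))


def lift_interval(
    iv: GenomeInterval,
    cs: ChainSet,
    params: LiftParams = LiftParams(),
) -> Tuple[List[GenomeInterval], List[Unmapped]]:
    """Lift one genomic interval to consensus coordinates through chains.

    For each overlapping chain the aligned fraction of ``iv`` must reach
    ``min_match``; the lifted interval is the minimal consensus span covering
    all mapped bases.  With ``multiple`` unset only the best-supported chain
    (highest aligned fraction, then lowest chain id) is reported.  Output
    order follows chain ids.
    """
    hits = cs.overlapping(iv.chrom, iv.start, iv.end)
    if not hits:
        return [], [Unmapped(iv, "deleted")]
    candidates: List[Tuple[float, int, GenomeInterval]] = []
    for chain in hits:
        aligned, span = _map_through_chain(iv, chain)
        frac = aligned / len(iv)
        if span is None or frac < params.min_match:
            continue
        strand = iv.strand if chain.q_strand == "+" else ("-" if iv.strand == "+" else "+")
        lifted = GenomeInterval(
            chain.q_name, span[0], span[1], iv.name, iv.score, strand
        )
        candidates.append((frac, chain.id, lifted))
    if not candidates:
        return [], [Unmapped(iv, "partial")]
    if params.multiple:
        return [c[2] for c in sorted(candidates, key=lambda c: c[1])], []
    best = max(candidates, key=lambda c: (c[0], -c[1]))
    return [best[2]], []


def lift_bed(
    bed: Sequence[GenomeInterval],
    cs: ChainSet,
    params: LiftParams = LiftParams(),
) -> Tuple[List[GenomeInterval], List[Unmapped]]:
    """Element-wise lift; input order is preserved within the lifted list."""
    lifted: List[GenomeInterval] = []
    unmapped: List[Unmapped] = []
    for iv in bed:
        ok, bad = lift_interval(iv, cs, params)
        lifted.extend(ok)
        unmapped.extend(bad)
    return lifted, unmapped
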