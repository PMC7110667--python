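"""Build a family consensus from genomic instances.

The procedure mirrors how repeat reference sequences are built for families
without a curated model: drop the longest 1% of copies (they tend to be
recombination or misannotation artifacts), align the 50 longest remaining
copies, and call a majority-rule consensus.

The multiple alignment is a deterministic center-star: the longest sequence
is the center, every other sequence is fit-aligned to it, and the pairwise
alignments are merged under "once a gap, always a gap".  For consensus
calling this is entirely adequate — columns are dominated by the center's
coordinate system — and it is reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .alignment import AlignScoring, fit_align
from .io_formats import SeqRecord

__all__ = [
    "SelectParams",
    "MSA",
    "Consensus",
    "select_representatives",
    "center_star_msa",
    "call_consensus",
    "build_family_consensus",
]

GAP = "-"


@dataclass(frozen=True)
class SelectParams:
    """Representative selection: remove the longest fraction, keep the next n."""

    top_frac_removed: float = 0.01
    n_keep: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.top_frac_removed < 1):
            raise ValueError("top_frac_removed must be in [0, 1)")
        if self.n_keep < 2:
            raise ValueError("n_keep must be >= 2")


@dataclass(frozen=True)
class MSA:
    """A gapped multiple alignment; ungapping any row reproduces its input."""

    rows: Tuple[Tuple[str, str], ...]  # (instance_id, gapped sequence)
    ncol: int

    def __post_init__(self) -> None:
        for name, row in self.rows:
            if len(row) != self.ncol:
                raise ValueError(f"row {name!r} has length {len(row)} != {self.ncol}")

    def ungapped(self, name: str) -> str:
        for n, row in self.rows:
            if n == name:
                return row.replace(GAP, "")
        raise KeyError(name)


@dataclass(frozen=True)
class Consensus:
    """A gap-free, N-free consensus sequence with build provenance."""

    name: str
    seq: str
    select_params: Optional[SelectParams] = None
    row_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if GAP in self.seq or "N" in self.seq:
            raise ValueError("consensus must be gap-free and N-free")

    def as_record(self) -> SeqRecord:
        return SeqRecord(self.name, self.seq)


def parse_aligned_fasta(text: str) -> MSA:
    """Read a gapped (aligned) FASTA, e.g. from an external MSA tool."""
    rows: List[Tuple[str, str]] = []
    name: Optional[str] = None
    buf: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                rows.append((name, "".join(buf).upper()))
            name = line[1:].split()[0]
            buf = []
        else:
            buf.append(line)
    if name is not None:
        rows.append((name, "".join(buf).upper()))
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0][1])
    return MSA(tuple(rows), ncol)


def select_representatives(
    seqs: Sequence[SeqRecord], p: SelectParams = SelectParams()
) -> List[SeqRecord]:
    """Drop the ceil(top_frac_removed * n) longest, keep the n_keep longest rest.

    Output is in decreasing length; equal lengths are ordered by name.  At
    least one sequence is removed whenever top_frac_removed > 0.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to select representatives")
    ranked = sorted(seqs, key=lambda r: (-len(r.seq), r.name))
    n_drop = math.ceil(p.top_frac_removed * len(ranked))
    remaining = ranked[n_drop:]
    return remaining[: p.n_keep]


def center_star_msa(
    seqs: Sequence[SeqRecord],
    scoring: Optional[AlignScoring] = None,
    band: Optional[int] = 200,
) -> MSA:
    """Merge fit alignments of every sequence against the longest one.

    The center is the longest sequence (ties broken by name).  Insertions
    relative to the center open gap columns in all other rows ("once a gap,
    always a gap"); insertions from different rows that attach at the same
    center position share left-aligned columns.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for an MSA")
    for rec in seqs:
        if not rec.seq:
            raise ValueError(f"empty sequence {rec.name!r}")
    center = min(seqs, key=lambda r: (-len(r.seq), r.name))
    others = [r for r in seqs if r is not center]
    L = len(center.seq)

    # per-row: aligned blocks plus insertion segments keyed by center position
    # insertion at center position p = query bases emitted between center
    # columns p-1 and p (p in 0..L)
    aligned: Dict[str, List[Tuple[int, int, int, int]]] = {}
    insertions: Dict[str, Dict[int, Tuple[int, int]]] = {}
    ins_len = [0] * (L + 1)
    for rec in others:
        aln = fit_align(rec, center, scoring, band)
        aligned[rec.name] = list(aln.blocks)
        ins: Dict[int, Tuple[int, int]] = {}
        first = aln.blocks[0]
        if first[0] > 0:
            ins[first[2]] = (0, first[0])
        for (q1s, q1e, t1s, t1e), (q2s, q2e, t2s, t2e) in zip(
            aln.blocks, aln.blocks[1:]
        ):
            if q2s > q1e:  # query insertion attaches before center column t2s
                ins[t2s] = (q1e, q2s)
        last = aln.blocks[-1]
        if last[1] < len(rec.seq):
            ins[last[3]] = (last[1], len(rec.seq))
        insertions[rec.name] = ins
        for p, (qs, qe) in ins.items():
            ins_len[p] = max(ins_len[p], qe - qs)

    ncol = L + sum(ins_len)
    # column offset of center position p, after all insertion slots before it
    offset = [0] * (L + 1)
    acc = 0
    for p in range(L + 1):
        acc += ins_len[p]
        offset[p] = p + acc  # first column at/after center col p's slot end
    # center column p sits at offset[p] - 1 ... careful: define col_of(p)
    col_of = [offset[p] for p in range(L)]  # column index of center base p
    # insertion slot for position p occupies columns [offset[p]-ins_len[p], offset[p])

    rows: List[Tuple[str, str]] = []
    center_row = [GAP] * ncol
    for p in range(L):
        center_row[col_of[p]] = center.seq[p]
    rows.append((center.name, "".join(center_row)))

    for rec in others:
        row = [GAP] * ncol
        for qs, qe, ts, te in aligned[rec.name]:
            for off in range(qe - qs):
                row[col_of[ts + off]] = rec.seq[qs + off]
        for p, (qs, qe) in insertions[rec.name].items():
            # the slot for position p is the ins_len[p] columns before center col p
            slot_start = (col_of[p] if p < L else ncol) - ins_len[p]
            for off in range(qe - qs):
                row[slot_start + off] = rec.seq[qs + off]
        rows.append((rec.name, "".join(row)))

    msa = MSA(tuple(rows), ncol)
    for rec in seqs:  # ungapping invariant, checked eagerly
        if msa.ungapped(rec.name) != rec.seq:
            raise AssertionError(f"MSA ungapping failed for {rec.name!r}")
    return msa


def call_consensus(
    msa: MSA,
    name: str = "consensus",
    gap_majority: float = 0.5,
    min_base_count: int = 2,
    select_params: Optional[SelectParams] = None,
) -> Consensus:
    """Majority-rule consensus over MSA columns.

    A column is omitted when its gap fraction exceeds ``gap_majority`` or
    when the winning base is seen fewer than ``min_base_count`` times; ties
    between bases are broken alphabetically (A < C < G < T).
    """
    nrow = len(msa.rows)
    out: List[str] = []
    for c in range(msa.ncol):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        gaps = 0
        for _name, row in msa.rows:
            ch = row[c]
            if ch == GAP or ch == "N":
                gaps += 1
            else:
                counts[ch] += 1
        if gaps / nrow > gap_majority:
            continue
        base = max("ACGT", key=lambda b: counts[b])  # max is stable: ties -> A<C<G<T
        if counts[base] < min_base_count:
            continue
        out.append(base)
    if not out:
        raise ValueError("no consensus: all columns omitted")
    return Consensus(
        name, "".join(out), select_params, tuple(n for n, _ in msa.rows)
    )


def build_family_consensus(
    seqs: Sequence[SeqRecord],
    name: str,
    params: SelectParams = SelectParams(),
    scoring: Optional[AlignScoring] = None,
    gap_majority: float = 0.5,
    min_base_count: int = 2,
    msa: Optional[MSA] = None,
) -> Tuple[Consensus, MSA]:
    """Select representatives, align, and call the consensus in one step.

    An externally computed alignment (e.g. from a standalone MSA tool) may be
    supplied via ``msa``, in which case selection and alignment are skipped.
    """
    if msa is None:
        reps = select_representatives(seqs, params)
        msa = center_star_msa(reps, scoring)
    cons = call_consensus(
        msa, name, gap_majority, min_base_count, select_params=params
    )
    return cons, msa
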