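"""Readers and writers for the plain-text formats the toolkit speaks.

Coordinate conventions, enforced at every boundary:

* BED, bedGraph and all in-memory intervals are 0-based, half-open.
* RepeatMasker ``.out`` coordinates are 1-based, inclusive on disk and are
  converted on input (see :func:`rmsk_to_halfopen`).
* UCSC chain files follow the standard convention: target (``t``) is the
  genome, query (``q``) the consensus; a ``qStrand`` of ``-`` gives q
  coordinates on the reverse-complemented query. ``tStrand`` is always ``+``.

All writers end files with a trailing newline; all parsers accept ``\\n``
and ``\\r\\n`` line endings.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, List, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "GenomeInterval",
    "RmskRecord",
    "Chain",
    "ChainBlock",
    "FormatError",
    "parse_fasta",
    "write_fasta",
    "parse_bed",
    "write_bed",
    "parse_chain",
    "write_chain",
    "parse_rmsk_out",
    "rmsk_to_halfopen",
    "write_bedgraph",
    "revcomp",
]

_DNA_OK = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.name!r} is empty")
        bad = set(self.seq) - _DNA_OK
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open stranded interval — the universal coordinate currency."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RmskRecord:
    """One RepeatMasker annotation: a genomic interval tagged with its family."""

    interval: GenomeInterval
    family: str
    instance_id: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be nonempty")


# chain block: size of ungapped segment, then gap on target (dt) and on
# query (dq) before the next block.  The final block has dt == dq == 0.
ChainBlock = Tuple[int, int, int]


@dataclass(frozen=True)
class Chain:
    """A UCSC chain: block-structured pairwise alignment genome -> consensus."""

    id: int
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: Tuple[ChainBlock, ...]
    t_strand: str = "+"

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValueError("tStrand must be '+'")
        if self.q_strand not in ("+", "-"):
            raise ValueError(f"invalid qStrand {self.q_strand!r}")
        if not self.blocks:
            raise ValueError(f"chain {self.id} has no blocks")
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if any(b[0] <= 0 for b in self.blocks):
            raise ValueError(f"chain {self.id}: block sizes must be positive")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ValueError(f"chain {self.id}: final block must have dt=dq=0")
        if sizes + dts != self.t_end - self.t_start:
            raise FormatError(
                f"chain {self.id}: target span {self.t_end - self.t_start} != "
                f"sum of sizes+dt {sizes + dts}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise FormatError(
                f"chain {self.id}: query span {self.q_end - self.q_start} != "
                f"sum of sizes+dq {sizes + dqs}"
            )

    def t_blocks(self) -> Iterator[Tuple[int, int]]:
        """Ungapped segments in target (genome) coordinates, ascending."""
        t = self.t_start
        for size, dt, _dq in self.blocks:
            yield t, t + size
            t += size + dt

    def q_blocks_strand(self) -> Iterator[Tuple[int, int]]:
        """Ungapped segments in q-strand coordinates (reversed if qStrand=-)."""
        q = self.q_start
        for size, _dt, dq in self.blocks:
            yield q, q + size
            q += size + dq

    def q_blocks_plus(self) -> Iterator[Tuple[int, int]]:
        """Ungapped segments in plus-strand query (consensus) coordinates."""
        for qs, qe in self.q_blocks_strand():
            if self.q_strand == "+":
                yield qs, qe
            else:
                yield self.q_size - qe, self.q_size - qs


# ---------------------------------------------------------------------------
# FASTA


def _as_text(stream: Union[IO, str]) -> IO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_fasta(stream: Union[IO, str], n_policy: str = "keep") -> List[SeqRecord]:
    """Read a (multi-)FASTA into :class:`SeqRecord` objects, uppercased.

    ``n_policy`` controls non-ACGTN characters: ``"keep"`` rejects them,
    ``"mask"`` maps them to N.  Order is preserved; duplicate names and empty
    files are errors.
    """
    records: List[SeqRecord] = []
    seen = set()
    for rec in SeqIO.parse(_as_text(stream), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if n_policy == "mask":
            seq = re.sub(r"[^ACGTN]", "N", seq)
        records.append(SeqRecord(rec.id, seq))
    if not records:
        raise FormatError("empty FASTA input")
    return records


def write_fasta(records: Iterable[SeqRecord], stream: IO, width: int = 60) -> None:
    for rec in records:
        stream.write(f">{rec.name}\n")
        for i in range(0, len(rec.seq), width):
            stream.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def parse_bed(stream: Union[IO, str]) -> List[GenomeInterval]:
    """Parse BED3..BED6 lines into intervals (0-based half-open).

    Missing columns default to name ".", score 0, strand "+".  Malformed
    lines raise :class:`FormatError` naming the line number.
    """
    out: List[GenomeInterval] = []
    for lineno, raw in enumerate(_as_text(stream), start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise FormatError(f"BED line {lineno}: fewer than 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: non-integer coordinate") from exc
        name = cols[3] if len(cols) > 3 else "."
        try:
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: non-numeric score") from exc
        strand = cols[5] if len(cols) > 5 else "+"
        try:
            out.append(GenomeInterval(cols[0], start, end, name, score, strand))
        except ValueError as exc:
            raise FormatError(f"BED line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomeInterval], stream: IO) -> None:
    for iv in intervals:
        score = int(iv.score) if float(iv.score).is_integer() else iv.score
        stream.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
        )


# ---------------------------------------------------------------------------
# UCSC chain


def parse_chain(stream: Union[IO, str]) -> List[Chain]:
    """Parse a UCSC chain file; block arithmetic is validated per chain."""
    chains: List[Chain] = []
    lines = _as_text(stream).read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith("chain"):
            raise FormatError(f"expected chain header, got {line!r}")
        f = line.split()
        if len(f) != 13:
            raise FormatError(f"malformed chain header: {line!r}")
        (score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, cid) = (
            float(f[1]), f[2], int(f[3]), f[4], int(f[5]), int(f[6]),
            f[7], int(f[8]), f[9], int(f[10]), int(f[11]), int(f[12]))
        blocks: List[ChainBlock] = []
        while i < len(lines):
            bl = lines[i].strip()
            i += 1
            if not bl:
                break
            parts = bl.split()
            if len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
                break
            else:
                raise FormatError(f"chain {cid}: malformed block line {bl!r}")
        try:
            chains.append(
                Chain(cid, score, t_name, t_size, t_start, t_end,
                      q_name, q_size, q_strand, q_start, q_end,
                      tuple(blocks), t_strand)
            )
        except ValueError as exc:
            raise FormatError(f"chain {cid}: {exc}") from exc
    return chains


def write_chain(chains: Iterable[Chain], stream: IO) -> None:
    """Write chains in canonical UCSC form (round-trips bit-exactly)."""
    for c in chains:
        score = int(c.score) if float(c.score).is_integer() else c.score
        stream.write(
            f"chain {score} {c.t_name} {c.t_size} {c.t_strand} "
            f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
            f"{c.q_start} {c.q_end} {c.id}\n"
        )
        for size, dt, dq in c.blocks[:-1]:
            stream.write(f"{size}\t{dt}\t{dq}\n")
        stream.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out


def rmsk_to_halfopen(begin_1based: int, end_inclusive: int) -> Tuple[int, int]:
    """Convert RepeatMasker 1-based inclusive coordinates to 0-based half-open."""
    return begin_1based - 1, end_inclusive


def parse_rmsk_out(stream: Union[IO, str]) -> List[RmskRecord]:
    """Parse the whitespace-delimited RepeatMasker ``.out`` dialect.

    Both the classic 15-column layout (``score div del ins chrom begin end
    (left) strand family class ...``) and a minimal 9-column layout without
    the ``(left)`` column are accepted; only genomic chrom/begin/end, strand
    (``+`` or ``C``) and the repeat family name are interpreted.  Strand
    ``C`` maps to ``-``.  Instance ids are synthesized as ``family#ordinal``
    in file order.  A header-only file yields an empty list.
    """
    records: List[RmskRecord] = []
    per_family: dict = {}
    strands = ("+", "C", "-")
    for lineno, raw in enumerate(_as_text(stream), start=1):
        cols = raw.split()
        if not cols or not cols[0].lstrip("-").isdigit():
            continue  # header or blank line
        if len(cols) >= 10 and cols[8] in strands:
            chrom, begin, end, strand_col, family = cols[4], cols[5], cols[6], cols[8], cols[9]
        elif len(cols) >= 9 and cols[7] in strands:
            chrom, begin, end, strand_col, family = cols[4], cols[5], cols[6], cols[7], cols[8]
        else:
            raise FormatError(f".out line {lineno}: unrecognized column layout")
        try:
            start, stop = rmsk_to_halfopen(int(begin), int(end))
        except ValueError as exc:
            raise FormatError(f".out line {lineno}: malformed coordinate") from exc
        strand = "-" if strand_col in ("C", "-") else "+"
        per_family[family] = per_family.get(family, 0) + 1
        instance_id = f"{family}#{per_family[family]}"
        try:
            iv = GenomeInterval(chrom, start, stop, instance_id, 0, strand)
        except ValueError as exc:
            raise FormatError(f".out line {lineno}: {exc}") from exc
        records.append(RmskRecord(iv, family, instance_id))
    return records


def write_rmsk_out(records: Iterable[RmskRecord], stream: IO) -> None:
    """Write a classic-layout ``.out`` table (1-based inclusive, C for minus)."""
    stream.write(
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n\n"
    )
    for i, rec in enumerate(records, start=1):
        iv = rec.interval
        strand = "C" if iv.strand == "-" else "+"
        stream.write(
            f" 1000  0.0  0.0  0.0  {iv.chrom} {iv.start + 1} {iv.end} (0) "
            f"{strand} {rec.family} LINE/L1 1 {len(iv)} (0) {i}\n"
        )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    values: Sequence[int],
    name: str,
    stream: IO,
    include_zero: bool = False,
) -> None:
    """Run-length encode a per-base track as bedGraph (0-based half-open).

    Zero-valued runs are omitted unless ``include_zero``; negative values are
    rejected.
    """
    arr = np.asarray(values)
    if arr.size == 0:
        return
    if (arr < 0).any():
        raise ValueError("bedGraph values must be >= 0")
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v == 0 and not include_zero:
            continue
        v_out = int(v) if float(v).is_integer() else float(v)
        stream.write(f"{name}\t{s}\t{e}\t{v_out}\n")


def parse_bedgraph(stream: Union[IO, str], length: int, name: str | None = None) -> np.ndarray:
    """Expand a bedGraph back into a per-base array of the given length."""
    arr = np.zeros(length, dtype=float)
    for lineno, raw in enumerate(_as_text(stream), start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split()
        if len(cols) < 4:
            raise FormatError(f"bedGraph line {lineno}: fewer than 4 columns")
        if name is not None and cols[0] != name:
            continue
        s, e, v = int(cols[1]), int(cols[2]), float(cols[3])
        if not (0 <= s < e <= length):
            raise FormatError(f"bedGraph line {lineno}: interval outside track")
        arr[s:e] = v
    return arr
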