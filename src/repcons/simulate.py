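"""Synthetic repeat families with known truth.

The generator emulates the statistical structure of a young LINE-1 family:

* copies are 5'-truncated — the start offset on the consensus follows a
  geometric law, so short 3' fragments dominate and mapping coverage rises
  toward the 3' end;
* sub-lineages carry fixed deletions (repressor-escape events), optionally
  nested: a younger deletion arises almost exclusively on the background of
  an older one;
* instances accumulate i.i.d. point substitutions;
* a repressor binding site at a fixed consensus position contributes one
  noisy ChIP-seq summit per bound instance.

Instances are planted in a random genome with spacer DNA and annotated in
RepeatMasker ``.out`` style; the ``SimTruth`` record keeps every generated
fact so downstream calls can be scored exactly.  All randomness flows from
the spec seed: identical specs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .deletions import CARRIER, NON_CARRIER, NOT_SPANNING, DeletionWindow
from .io_formats import GenomeInterval, RmskRecord, SeqRecord, revcomp

__all__ = [
    "DeletionSpec",
    "BindingSiteSpec",
    "FamilySimSpec",
    "InstanceTruth",
    "SimTruth",
    "make_consensus",
    "simulate_family",
    "plant_genome",
    "simulate_summits",
    "truth_status_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_INSTANCE = 200  # shortest simulated fragment


@dataclass(frozen=True)
class DeletionSpec:
    """A planted fixed deletion carried by a fraction of the family.

    ``requires`` names an older deletion: carriers of this one are drawn
    with probability ``carrier_fraction`` among carriers of the required
    deletion and with probability ``leak_fraction`` elsewhere (the small
    leak models homoplasy / annotation noise).
    """

    id: str
    start: int
    width: int
    carrier_fraction: float
    requires: Optional[str] = None
    leak_fraction: float = 0.0

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class BindingSiteSpec:
    """A repressor binding site: bound instances emit one summit each."""

    consensus_pos: int
    bound_fraction: float = 1.0
    jitter_sd: float = 2.0


@dataclass(frozen=True)
class FamilySimSpec:
    """Generative description of one synthetic repeat family."""

    name: str = "L1PA_SYN"
    consensus_len: int = 6000
    n_instances: int = 300
    truncation_geom_p: float = 1.0 / 3000.0
    mut_rate: float = 0.02
    deletions: Tuple[DeletionSpec, ...] = ()
    binding_site: Optional[BindingSiteSpec] = None
    minus_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.consensus_len < _MIN_INSTANCE:
            raise ValueError("consensus too short")
        if not (0 < self.truncation_geom_p <= 1):
            raise ValueError("truncation_geom_p must be in (0, 1]")
        for frac in (self.mut_rate, self.minus_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        seen = set()
        for d in self.deletions:
            if not (0 <= d.start < d.end <= self.consensus_len):
                raise ValueError(f"deletion {d.id} outside consensus")
            if not (0 <= d.carrier_fraction <= 1 and 0 <= d.leak_fraction <= 1):
                raise ValueError(f"deletion {d.id}: fractions must be in [0, 1]")
            seen.add(d.id)
        for d in self.deletions:
            if d.requires is not None and d.requires not in seen:
                raise ValueError(f"deletion {d.id} requires unknown {d.requires}")
        order = {d.id: i for i, d in enumerate(self.deletions)}
        for d in self.deletions:
            if d.requires is not None and order[d.requires] >= order[d.id]:
                raise ValueError("deletions must be listed in dependency order")
        if self.binding_site is not None:
            if not (0 <= self.binding_site.consensus_pos < self.consensus_len):
                raise ValueError("binding site outside consensus")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FamilySimSpec":
        raw = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        raw["deletions"] = tuple(DeletionSpec(**d) for d in raw.get("deletions", ()))
        if raw.get("binding_site") is not None:
            raw["binding_site"] = BindingSiteSpec(**raw["binding_site"])
        return cls(**raw)


@dataclass
class InstanceTruth:
    """Everything generated about one instance (locus filled at planting)."""

    instance_id: str
    cons_start: int
    strand: str
    carried: Tuple[str, ...]  # deletions that removed >= 1 base
    bound: bool
    site_offset: Optional[int]  # offset of the binding site within the instance
    locus: Optional[GenomeInterval] = None


@dataclass
class SimTruth:
    spec: FamilySimSpec
    consensus_name: str
    instances: List[InstanceTruth] = field(default_factory=list)

    def by_id(self) -> Dict[str, InstanceTruth]:
        return {t.instance_id: t for t in self.instances}


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(_BASES, size=n, p=p)
    return codes.tobytes().decode("ascii")


def make_consensus(length: int, gc: float = 0.42, seed: int = 0) -> SeqRecord:
    """I.i.d. random consensus at the given GC content (LINE-1s are AT-rich)."""
    if length < _MIN_INSTANCE:
        raise ValueError(f"consensus length must be >= {_MIN_INSTANCE}")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return SeqRecord("consensus", _random_dna(rng, length, gc))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != codes[i]]
        codes[i] = rng.choice(choices)
    return codes.tobytes().decode("ascii")


def simulate_family(
    spec: FamilySimSpec, consensus: SeqRecord
) -> Tuple[List[SeqRecord], SimTruth]:
    """Draw truncated, deleted, mutated instances from a consensus.

    Sequences are returned in consensus (forward) orientation; the strand
    flag in the truth record is realized when the genome is planted.
    """
    if len(consensus.seq) != spec.consensus_len:
        raise ValueError("consensus length does not match the spec")
    rng = np.random.default_rng(spec.seed)
    L = spec.consensus_len
    instances: List[SeqRecord] = []
    truth = SimTruth(spec=spec, consensus_name=consensus.name)
    site = spec.binding_site
    for i in range(spec.n_instances):
        start = min(int(rng.geometric(spec.truncation_geom_p)) - 1, L - _MIN_INSTANCE)
        assigned: Dict[str, bool] = {}
        for d in spec.deletions:
            if d.requires is None:
                p = d.carrier_fraction
            else:
                p = d.carrier_fraction if assigned.get(d.requires) else d.leak_fraction
            assigned[d.id] = bool(rng.random() < p)
        # build the surviving sequence: consensus[start:] minus carried deletions
        removed = sorted(
            (max(d.start, start), d.end)
            for d in spec.deletions
            if assigned[d.id] and d.end > start
        )
        carried = tuple(
            d.id for d in spec.deletions if assigned[d.id] and d.end > start
        )
        pieces: List[str] = []
        pos = start
        for rs, re_ in removed:
            if rs > pos:
                pieces.append(consensus.seq[pos:rs])
            pos = max(pos, re_)
        pieces.append(consensus.seq[pos:])
        raw = "".join(pieces)
        seq = _mutate(rng, raw, spec.mut_rate)
        strand = "-" if rng.random() < spec.minus_fraction else "+"

        bound = site is not None and bool(rng.random() < site.bound_fraction)
        site_offset: Optional[int] = None
        if site is not None:
            p = site.consensus_pos
            alive = start <= p and all(not (rs <= p < re_) for rs, re_ in removed)
            if alive:
                deleted_before = sum(
                    min(re_, p) - rs for rs, re_ in removed if rs < p
                )
                site_offset = p - start - deleted_before
            else:
                bound = False
        iid = f"{spec.name}#{i + 1}"
        instances.append(SeqRecord(iid, seq))
        truth.instances.append(
            InstanceTruth(iid, start, strand, carried, bound, site_offset)
        )
    return instances, truth


def plant_genome(
    instances: Sequence[SeqRecord],
    truth: SimTruth,
    spacer_len: int = 2000,
    seed: int = 1,
    chrom: str = "chrSim",
    gc: float = 0.42,
) -> Tuple[SeqRecord, List[RmskRecord]]:
    """Concatenate instances with random spacers into an annotated genome.

    Minus-strand instances are inserted reverse-complemented; annotations
    carry forward-genome coordinates so that extracting each interval (and
    reverse-complementing on minus) reproduces the instance sequence
    exactly.  Truth loci are filled in.
    """
    if not instances:
        raise ValueError("no instances to plant")
    rng = np.random.default_rng(seed)
    by_id = truth.by_id()
    parts: List[str] = []
    annotations: List[RmskRecord] = []
    pos = 0
    for rec in instances:
        spacer = _random_dna(rng, spacer_len, gc)
        parts.append(spacer)
        pos += spacer_len
        t = by_id[rec.name]
        inserted = revcomp(rec.seq) if t.strand == "-" else rec.seq
        parts.append(inserted)
        iv = GenomeInterval(chrom, pos, pos + len(rec.seq), rec.name, 0, t.strand)
        t.locus = iv
        family = rec.name.split("#")[0]
        annotations.append(RmskRecord(iv, family, rec.name))
        pos += len(rec.seq)
    parts.append(_random_dna(rng, spacer_len, gc))
    return SeqRecord(chrom, "".join(parts)), annotations


def simulate_summits(
    truth: SimTruth, jitter_sd: float = 2.0, seed: int = 2
) -> List[GenomeInterval]:
    """One 1-bp summit per bound instance whose binding site survived.

    The summit sits at the genomic base homologous to the consensus site
    plus integer-rounded Gaussian jitter applied along the consensus
    direction (so it lifts back with symmetric error on either strand).
    """
    if truth.spec.binding_site is None:
        raise ValueError("simulation spec has no binding site")
    rng = np.random.default_rng(seed)
    out: List[GenomeInterval] = []
    for t in truth.instances:
        if not t.bound or t.site_offset is None:
            continue
        if t.locus is None:
            raise ValueError("plant_genome must run before simulate_summits")
        jitter = int(np.round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        if t.strand == "+":
            g = t.locus.start + t.site_offset + jitter
        else:
            g = t.locus.end - 1 - t.site_offset - jitter
        g = max(t.locus.start, min(g, t.locus.end - 1))
        out.append(
            GenomeInterval(t.locus.chrom, g, g + 1, f"summit_{t.instance_id}", 0, "+")
        )
    return out


def truth_status_matrix(
    truth: SimTruth, windows: Sequence[DeletionWindow], span_margin: int = 20
) -> pd.DataFrame:
    """Deletion status per instance derived from the simulation truth.

    The analog of genotyping from alignments, but computed from generated
    facts: an instance spans a window when its surviving sequence reaches
    both flanks, and carries it when the window lies in a carried deletion.
    """
    del_by_id = {d.id: d for d in truth.spec.deletions}
    L = truth.spec.consensus_len
    rows = {}
    for t in truth.instances:
        gaps = [(max(del_by_id[i].start, t.cons_start), del_by_id[i].end) for i in t.carried]
        statuses = {}
        for w in windows:
            lpos, rpos = max(0, w.start - span_margin), min(L, w.end + span_margin)
            def covered(a: int, b: int) -> int:
                if b <= t.cons_start:
                    return 0
                a = max(a, t.cons_start)
                missing = sum(max(0, min(b, ge) - max(a, gs)) for gs, ge in gaps)
                return (b - a) - missing
            if covered(lpos, w.start) == 0 or covered(w.end, rpos) == 0:
                statuses[w.wid] = NOT_SPANNING
            elif covered(w.start, w.end) < 0.2 * w.width:
                statuses[w.wid] = CARRIER
            else:
                statuses[w.wid] = NON_CARRIER
        rows[t.instance_id] = statuses
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[w.wid for w in windows]
    )
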