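"""End-to-end workflows: simulate, chain, and analyze a repeat family.

These functions glue the modules into the two standard workflows — the
browser build (consensus -> chains -> coverage) and the analysis pass
(lift -> meta-summits -> deletion windows) — and are what the command-line
interface and the reproduction script drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .alignment import AlignScoring, fit_align
from .chains import ChainSet, LiftParams, build_chain, lift_bed
from .io_formats import GenomeInterval, RmskRecord, SeqRecord, revcomp
from .metasummits import (
    MetaSummit,
    SummitParams,
    call_metasummits,
    extend_summits,
    pileup_intervals,
)
from .simulate import (
    FamilySimSpec,
    SimTruth,
    make_consensus,
    plant_genome,
    simulate_family,
    simulate_summits,
)

__all__ = [
    "SimDataset",
    "simulate_dataset",
    "extract_instance",
    "align_family",
    "metasummits_from_genomic_summits",
]


@dataclass
class SimDataset:
    """One simulated family with its genome, annotations and ground truth."""

    spec: FamilySimSpec
    consensus: SeqRecord
    instances: List[SeqRecord]
    truth: SimTruth
    genome: SeqRecord
    annotations: List[RmskRecord]
    summits: Optional[List[GenomeInterval]]


def _subseed(seed: int, k: int) -> int:
    return (seed * 7 + k) % (2**31 - 1)


def simulate_dataset(spec: FamilySimSpec, gc: float = 0.42) -> SimDataset:
    """Generate consensus, instances, planted genome, annotations and summits."""
    consensus = make_consensus(spec.consensus_len, gc, seed=_subseed(spec.seed, 0))
    consensus = SeqRecord(spec.name, consensus.seq)
    instances, truth = simulate_family(spec, consensus)
    genome, annotations = plant_genome(
        instances, truth, seed=_subseed(spec.seed, 1), gc=gc
    )
    summits = None
    if spec.binding_site is not None:
        summits = simulate_summits(
            truth, jitter_sd=spec.binding_site.jitter_sd, seed=_subseed(spec.seed, 2)
        )
    return SimDataset(spec, consensus, instances, truth, genome, annotations, summits)


def extract_instance(genome: SeqRecord, rec: RmskRecord) -> SeqRecord:
    """Pull an annotated instance out of the genome, forward-oriented."""
    iv = rec.interval
    seq = genome.seq[iv.start : iv.end]
    if iv.strand == "-":
        seq = revcomp(seq)
    return SeqRecord(rec.instance_id, seq)


def align_family(
    consensus: SeqRecord,
    genome: SeqRecord,
    annotations: Sequence[RmskRecord],
    scoring: Optional[AlignScoring] = None,
    band: Optional[int] = 200,
) -> ChainSet:
    """Fit-align every annotated instance to the consensus and build chains."""
    cs = ChainSet()
    for chain_id, rec in enumerate(annotations, start=1):
        inst = extract_instance(genome, rec)
        aln = fit_align(inst, consensus, scoring, band)
        chain = build_chain(
            aln, rec.interval, len(genome.seq), len(consensus.seq), chain_id
        )
        cs.add(chain, instance_id=rec.instance_id)
    return cs


def metasummits_from_genomic_summits(
    summits: Sequence[GenomeInterval],
    cs: ChainSet,
    cons_len: int,
    params: SummitParams = SummitParams(),
    lift_params: Optional[LiftParams] = None,
) -> Tuple[List[MetaSummit], List[GenomeInterval]]:
    """Extend genomic summits, lift them to the consensus, and call peaks.

    The lift threshold defaults to 0.5 (not the usual 0.95) because an
    11-nt extended summit sitting near a chain gap should still lift on its
    mapped half.  Returns the called meta-summits and the lifted intervals.
    """
    lp = lift_params or LiftParams(min_match=0.5)
    extended = extend_summits(summits, params.flank)
    lifted, _unmapped = lift_bed(extended, cs, lp)
    pileup = pileup_intervals(lifted, cons_len)
    return call_metasummits(pileup, params), lifted
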