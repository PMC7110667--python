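"""Synthetic family generator: determinism, truth consistency, statistics."""

import pytest

from repcons.io_formats import revcomp
from repcons.pipeline import simulate_dataset
from repcons.simulate import (
    BindingSiteSpec,
    DeletionSpec,
    FamilySimSpec,
    make_consensus,
    plant_genome,
    simulate_family,
    simulate_summits,
)


class TestMakeConsensus:
    def test_seed_determinism(self):
        a = make_consensus(1000, 0.5, seed=1)
        b = make_consensus(1000, 0.5, seed=1)
        assert a.seq == b.seq

    def test_gc_one_gives_only_gc(self):
        rec = make_consensus(500, gc=1.0, seed=3)
        assert set(rec.seq) <= {"G", "C"}

    def test_empirical_gc_within_binomial_bound(self):
        rec = make_consensus(100_000, gc=0.42, seed=5)
        gc = sum(c in "GC" for c in rec.seq) / len(rec.seq)
        assert abs(gc - 0.42) < 0.01  # ~6 sigma for n = 100k


def _spec(**kw):
    defaults = dict(
        name="FAM", consensus_len=1000, n_instances=50,
        truncation_geom_p=1.0, mut_rate=0.0, seed=9,
    )
    defaults.update(kw)
    return FamilySimSpec(**defaults)


class TestSimulateFamily:
    def test_no_noise_full_length_equals_consensus(self):
        spec = _spec(n_instances=3)
        cons = make_consensus(1000, seed=1)
        instances, truth = simulate_family(spec, cons)
        for rec, t in zip(instances, truth.instances):
            assert t.cons_start == 0
            assert rec.seq == cons.seq

    def test_carrier_count_within_binomial_bound(self):
        spec = _spec(
            n_instances=1000,
            deletions=(DeletionSpec("d", 100, 50, 0.7),),
        )
        cons = make_consensus(1000, seed=1)
        _instances, truth = simulate_family(spec, cons)
        carriers = sum("d" in t.carried for t in truth.instances)
        # binomial 99% interval around 700 for n=1000, p=0.7
        assert 662 <= carriers <= 738

    def test_nested_requirement_is_subset(self):
        spec = _spec(
            n_instances=800,
            deletions=(
                DeletionSpec("old", 100, 50, 0.6),
                DeletionSpec("new", 300, 20, 0.5, requires="old"),
            ),
        )
        cons = make_consensus(1000, seed=1)
        _instances, truth = simulate_family(spec, cons)
        for t in truth.instances:
            if "new" in t.carried:
                assert "old" in t.carried

    def test_truncated_instance_loses_deletion(self):
        spec = _spec(
            truncation_geom_p=1e-4,
            n_instances=300,
            deletions=(DeletionSpec("d", 50, 30, 1.0),),
        )
        cons = make_consensus(1000, seed=1)
        instances, truth = simulate_family(spec, cons)
        for rec, t in zip(instances, truth.instances):
            if t.cons_start >= 80:
                assert "d" not in t.carried
                assert rec.seq == cons.seq[t.cons_start :]

    def test_requires_must_be_declared_earlier(self):
        with pytest.raises(ValueError):
            _spec(deletions=(DeletionSpec("b", 10, 5, 0.5, requires="a"),
                             DeletionSpec("a", 100, 5, 0.5)))

    def test_unknown_spec_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            FamilySimSpec.from_json('{"n_copies": 5}')

    def test_spec_json_roundtrip(self):
        spec = _spec(
            deletions=(DeletionSpec("d", 100, 50, 0.7),),
            binding_site=BindingSiteSpec(400, 0.9, 2.0),
        )
        assert FamilySimSpec.from_json(spec.to_json()) == spec


class TestPlantGenome:
    def test_genome_length_single_plus_instance(self):
        spec = _spec(n_instances=1, minus_fraction=0.0)
        cons = make_consensus(1000, seed=1)
        instances, truth = simulate_family(spec, cons)
        genome, ann = plant_genome(instances, truth, spacer_len=2000, seed=4)
        assert len(genome.seq) == 2 * 2000 + len(instances[0].seq)
        assert len(ann) == 1 and ann[0].interval.strand == "+"

    def test_extraction_roundtrip_both_strands(self):
        spec = _spec(n_instances=40, minus_fraction=0.5, truncation_geom_p=0.002)
        cons = make_consensus(1000, seed=1)
        instances, truth = simulate_family(spec, cons)
        genome, ann = plant_genome(instances, truth, seed=4)
        strands = set()
        for rec, a in zip(instances, ann):
            seq = genome.seq[a.interval.start : a.interval.end]
            if a.interval.strand == "-":
                seq = revcomp(seq)
            strands.add(a.interval.strand)
            assert seq == rec.seq
        assert strands == {"+", "-"}


class TestSimulateSummits:
    def _bound_dataset(self, jitter_sd):
        spec = _spec(
            n_instances=60,
            truncation_geom_p=0.005,
            binding_site=BindingSiteSpec(600, bound_fraction=1.0, jitter_sd=jitter_sd),
        )
        cons = make_consensus(1000, seed=1)
        instances, truth = simulate_family(spec, cons)
        plant_genome(instances, truth, seed=4)
        return truth

    def test_zero_jitter_sits_on_homologous_base(self):
        truth = self._bound_dataset(0.0)
        summits = simulate_summits(truth, jitter_sd=0.0, seed=5)
        by_id = truth.by_id()
        assert summits  # some instances survive truncation
        for s in summits:
            iid = s.name.removeprefix("summit_")
            t = by_id[iid]
            if t.strand == "+":
                assert s.start == t.locus.start + t.site_offset
            else:
                assert s.start == t.locus.end - 1 - t.site_offset

    def test_truncated_site_emits_no_summit(self):
        truth = self._bound_dataset(2.0)
        summits = simulate_summits(truth, seed=5)
        with_site = [t for t in truth.instances if t.bound]
        assert len(summits) == len(with_site)
        for t in truth.instances:
            if t.cons_start > 600:
                assert t.site_offset is None and not t.bound

    def test_site_inside_carried_deletion_silenced(self):
        spec = _spec(
            n_instances=200,
            deletions=(DeletionSpec("d", 580, 40, 0.5),),
            binding_site=BindingSiteSpec(600, 1.0, 0.0),
        )
        cons = make_consensus(1000, seed=1)
        _instances, truth = simulate_family(spec, cons)
        for t in truth.instances:
            if "d" in t.carried:
                assert not t.bound

    def test_bound_fraction_zero_no_summits(self):
        spec = _spec(binding_site=BindingSiteSpec(600, 0.0, 2.0), n_instances=30)
        cons = make_consensus(1000, seed=1)
        _instances, truth = simulate_family(spec, cons)
        plant_genome(_instances, truth, seed=4)
        assert simulate_summits(truth, seed=5) == []


def test_dataset_fully_deterministic():
    spec = FamilySimSpec(
        consensus_len=1500, n_instances=30, mut_rate=0.01,
        deletions=(DeletionSpec("d", 300, 25, 0.5),),
        binding_site=BindingSiteSpec(700), seed=77,
    )
    a = simulate_dataset(spec)
    b = simulate_dataset(spec)
    assert a.genome.seq == b.genome.seq
    assert [r.seq for r in a.instances] == [r.seq for r in b.instances]
    assert [s.start for s in a.summits] == [s.start for s in b.summits]
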