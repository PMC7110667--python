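"""Full-length filtering, deletion-window detection, genotyping, ordering."""

import numpy as np
import pandas as pd
import pytest

from repcons.alignment import AlignmentBlocks
from repcons.chains import ChainSet, build_chain
from repcons.coverage import CoverageTrack
from repcons.deletions import (
    CARRIER,
    NON_CARRIER,
    NOT_SPANNING,
    DeletionWindow,
    cooccurrence,
    detect_deletion_windows,
    filter_full_length,
    genotype_instances,
)
from repcons.io_formats import GenomeInterval, RmskRecord


def _rmsk(length, family="L1PA3", start=1000, n=1):
    return RmskRecord(
        GenomeInterval("chr1", start, start + length, f"{family}#{n}"),
        family,
        f"{family}#{n}",
    )


class TestFullLengthFilter:
    def test_boundary_exactly_6000_kept(self):
        records = [_rmsk(5999, n=1), _rmsk(6000, start=10_000, n=2),
                   _rmsk(6500, start=20_000, n=3)]
        kept, counts = filter_full_length(records)
        assert len(kept) == 2 and counts == {"L1PA3": 2}
        assert all(len(r.interval) >= 6000 for r in kept)

    def test_empty_input(self):
        assert filter_full_length([]) == ([], {})

    def test_counts_keyed_per_family(self):
        records = [
            _rmsk(6100, "L1PA3", 0, 1),
            _rmsk(6100, "L1PA4", 10_000, 1),
            _rmsk(6100, "L1PA4", 20_000, 2),
        ]
        _, counts = filter_full_length(records)
        assert counts == {"L1PA3": 1, "L1PA4": 2}

    def test_conservation(self):
        records = [_rmsk(5000 + 100 * i, start=10_000 * i, n=i) for i in range(1, 30)]
        kept, _ = filter_full_length(records)
        removed = [r for r in records if len(r.interval) < 6000]
        assert len(kept) + len(removed) == len(records)


def _track(values):
    return CoverageTrack("cons", np.asarray(values, dtype=int), int(max(values)))


class TestDetectDeletionWindows:
    def test_wide_drop_recovered_exactly(self):
        values = np.full(6000, 100)
        values[500:629] = 30
        (w,) = detect_deletion_windows(_track(values))
        assert (w.start, w.end, w.width) == (500, 629, 129)
        assert w.drop_fraction_observed == pytest.approx(0.7)
        assert w.n_spanning == 100

    def test_flat_coverage_no_windows(self):
        assert detect_deletion_windows(_track(np.full(2000, 50))) == []

    def test_two_narrow_drops_detected_separately(self):
        values = np.full(4000, 80)
        values[1000:1020] = 10
        values[2000:2011] = 10
        wins = detect_deletion_windows(_track(values))
        assert [(w.start, w.end) for w in wins] == [(1000, 1020), (2000, 2011)]
        assert [w.width for w in wins] == [20, 11]

    def test_shallow_dip_below_threshold_ignored(self):
        values = np.full(2000, 100)
        values[800:850] = 60  # 40% drop < default 50% threshold
        assert detect_deletion_windows(_track(values)) == []

    def test_low_coverage_region_not_called(self):
        values = np.full(2000, 4)  # below min_spanning everywhere
        values[900:950] = 0
        assert detect_deletion_windows(_track(values), min_spanning=10) == []

    def test_width_below_min_width_dropped(self):
        values = np.full(2000, 100)
        values[700:703] = 10
        assert detect_deletion_windows(_track(values), min_width=5) == []

    def test_drop_on_sloped_truncation_profile(self):
        # coverage rising toward 3' as in a truncated family, drop at 500
        base = np.linspace(20, 100, 6000).astype(int)
        values = base.copy()
        values[500:629] = (base[500:629] * 0.25).astype(int)
        (w,) = detect_deletion_windows(_track(values))
        assert (w.start, w.end) == (500, 629)


def _chain_for(blocks, cid, locus_len, locus_start=0):
    aln = AlignmentBlocks(f"i{cid}", "cons", blocks, 0)
    locus = GenomeInterval("chr1", locus_start, locus_start + locus_len, f"i{cid}")
    return build_chain(aln, locus, 10_000_000, 1000, cid)


class TestGenotypeInstances:
    WINDOW = DeletionWindow("cons", 500, 629, 0.7, 100)

    def _cs(self):
        cs = ChainSet()
        # carrier: gap exactly over [500, 629)
        cs.add(
            _chain_for(((0, 500, 0, 500), (500, 871, 629, 1000)), 1, 871, 0),
            instance_id="carrier",
        )
        # non-carrier: full-length exact
        cs.add(
            _chain_for(((0, 1000, 0, 1000),), 2, 1000, 5000), instance_id="full"
        )
        # 5'-truncated instance starting at consensus 700: cannot span
        cs.add(
            _chain_for(((0, 300, 700, 1000),), 3, 300, 10_000),
            instance_id="trunc",
        )
        return cs

    def test_statuses(self):
        m = genotype_instances(self._cs(), [self.WINDOW])
        col = m[self.WINDOW.wid]
        assert col["carrier"] == CARRIER
        assert col["full"] == NON_CARRIER
        assert col["trunc"] == NOT_SPANNING

    def test_every_cell_defined(self):
        w2 = DeletionWindow("cons", 800, 820, 0.5, 100)
        m = genotype_instances(self._cs(), [self.WINDOW, w2])
        assert m.shape == (3, 2) and not m.isna().any().any()


def _matrix(n11, n10, n01, n00, extra_nonspanning=0):
    rows = (
        [{"A": CARRIER, "B": CARRIER}] * n11
        + [{"A": CARRIER, "B": NON_CARRIER}] * n10
        + [{"A": NON_CARRIER, "B": CARRIER}] * n01
        + [{"A": NON_CARRIER, "B": NON_CARRIER}] * n00
        + [{"A": NOT_SPANNING, "B": CARRIER}] * extra_nonspanning
    )
    return pd.DataFrame(rows, index=[f"i{k}" for k in range(len(rows))])


class TestCooccurrence:
    def test_worked_example(self):
        r = cooccurrence(_matrix(95, 40, 5, 60), "A", "B")
        assert (r.n11, r.n10, r.n01, r.n00) == (95, 40, 5, 60)
        assert r.p_a_given_b == pytest.approx(0.95)
        assert r.p_b_given_a == pytest.approx(95 / 135)
        assert r.ordering_call == "A_first"

    def test_perfect_nesting_calls_a_first(self):
        r = cooccurrence(_matrix(50, 30, 0, 40), "A", "B")
        assert r.p_a_given_b == 1.0 and r.ordering_call == "A_first"

    def test_symmetric_case_b_first(self):
        r = cooccurrence(_matrix(95, 5, 40, 60), "A", "B")
        assert r.ordering_call == "B_first"

    def test_independent_statuses_unresolved(self):
        r = cooccurrence(_matrix(25, 25, 25, 25), "A", "B")
        assert r.ordering_call == "unresolved"

    def test_not_spanning_rows_excluded(self):
        r = cooccurrence(_matrix(10, 5, 1, 4, extra_nonspanning=7), "A", "B")
        assert r.n11 + r.n10 + r.n01 + r.n00 == 20

    def test_no_doubly_spanning_rows_is_an_error(self):
        m = pd.DataFrame(
            [{"A": NOT_SPANNING, "B": CARRIER}, {"A": CARRIER, "B": NOT_SPANNING}],
            index=["x", "y"],
        )
        with pytest.raises(ValueError, match="spans both"):
            cooccurrence(m, "A", "B")


class TestEndToEndPlantedRecovery:
    def test_noiseless_window_and_genotypes_match_truth(self, small_family):
        from repcons.coverage import compute_coverage

        ds, cs = small_family
        track = compute_coverage(cs, ds.spec.consensus_len)
        (w,) = detect_deletion_windows(track)
        planted = ds.spec.deletions[0]
        assert (w.start, w.end) == (planted.start, planted.end)
        m = genotype_instances(cs, [w])
        truth = ds.truth.by_id()
        for iid, status in m[w.wid].items():
            t = truth[iid]
            if status == NOT_SPANNING:
                continue
            assert (status == CARRIER) == (planted.id in t.carried)
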