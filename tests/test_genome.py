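"""Interval algebra against brute-force per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ervdyn.errors import ParameterError
from ervdyn.genome import (
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    assign_by_largest_overlap,
    make_bins,
    merge_intervals,
    overlap_counts,
    overlap_length,
    shuffle_matched,
)
from conftest import paint, random_interval_set


def iv(chrom, start, end, name="."):
    return GenomicInterval(chrom, start, end, name)


class TestGenomeModel:
    def test_effective_size_defaults_to_total(self, toy_genome):
        assert toy_genome.effective_genome_size == 18_000

    @pytest.mark.parametrize(
        "lengths,egs",
        [({"chr1": 0}, None), ({"chr1": 100}, 200), ({"chr1": 100}, 0)],
    )
    def test_invalid_models_rejected(self, lengths, egs):
        with pytest.raises(ParameterError):
            GenomeModel(lengths, egs)


class TestMakeBins:
    def test_truncated_tiling(self):
        g = GenomeModel({"chr1": 12_000})
        bins = make_bins(g, 5000)
        assert [(b.start, b.end) for b in bins] == [(0, 5000), (5000, 10000), (10000, 12000)]

    def test_exact_fit_single_bin(self):
        g = GenomeModel({"chr1": 5000})
        bins = make_bins(g, 5000)
        assert len(bins) == 1 and bins[0].end == 5000

    def test_covers_every_base_exactly_once(self):
        g = GenomeModel({"chrA": 7000, "chrB": 3000})
        bins = make_bins(g, 5000)
        assert len(bins) == 3
        for chrom, length in g.lengths.items():
            cov = paint(bins, length, chrom)
            assert (cov == 1).all()

    def test_zero_width_rejected(self, toy_genome):
        with pytest.raises(ParameterError):
            make_bins(toy_genome, 0)


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (iv("chr1", 0, 10), iv("chr1", 10, 20), 0),  # half-open abutment
            (iv("chr1", 0, 10), iv("chr1", 5, 20), 5),
            (iv("chr1", 0, 10), iv("chr2", 0, 10), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_length(a, b) == expected

    def test_matches_per_base_membership(self, rng, toy_genome):
        for _ in range(200):
            a = random_interval_set(rng, toy_genome, 1)[0]
            b = random_interval_set(rng, toy_genome, 1)[0]
            expected = 0
            if a.chrom == b.chrom:
                base_a = set(range(a.start, a.end))
                expected = len(base_a & set(range(b.start, b.end)))
            assert overlap_length(a, b) == expected


def merge_oracle(intervals, length, chrom, max_gap):
    """Merged runs via painting and gap-bridging (independent route)."""
    cov = paint(intervals, length, chrom) > 0
    runs = []
    start = None
    for i, c in enumerate(cov):
        if c and start is None:
            start = i
        elif not c and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, length])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [tuple(r) for r in merged]


class TestMergeIntervals:
    def test_abutting_merge_and_one_bp_gap(self):
        merged = merge_intervals(IntervalSet([iv("chr1", 0, 10), iv("chr1", 10, 20)]))
        assert [(m.start, m.end) for m in merged] == [(0, 20)]
        kept = merge_intervals(IntervalSet([iv("chr1", 0, 10), iv("chr1", 11, 20)]))
        assert [(m.start, m.end) for m in kept] == [(0, 10), (11, 20)]

    @pytest.mark.parametrize("max_gap", [0, 1, 25])
    def test_matches_paint_and_scan_oracle(self, rng, toy_genome, max_gap):
        ivs = random_interval_set(rng, toy_genome, 1000, max_len=300)
        merged = merge_intervals(ivs, max_gap=max_gap)
        for chrom, length in toy_genome.lengths.items():
            got = [(m.start, m.end) for m in merged if m.chrom == chrom]
            assert got == merge_oracle(ivs, length, chrom, max_gap)

    def test_idempotent_and_union_preserving(self, rng, toy_genome):
        ivs = random_interval_set(rng, toy_genome, 300, max_len=500)
        merged = merge_intervals(ivs)
        again = merge_intervals(merged)
        assert [m.key for m in merged] == [m.key for m in again]
        for chrom, length in toy_genome.lengths.items():
            assert (
                (paint(ivs, length, chrom) > 0) == (paint(merged, length, chrom) > 0)
            ).all()

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 9500), st.integers(1, 500)), min_size=1, max_size=40
        ),
        st.integers(0, 10),
    )
    def test_merge_properties_hold_on_arbitrary_inputs(self, spans, max_gap):
        ivs = IntervalSet([iv("chr1", s, s + l) for s, l in spans])
        merged = merge_intervals(ivs, max_gap=max_gap)
        # idempotence
        assert [m.key for m in merge_intervals(merged, max_gap=max_gap)] == [
            m.key for m in merged
        ]
        # union preservation
        assert ((paint(ivs, 10_000, "chr1") > 0) == (paint(merged, 10_000, "chr1") > 0)).all()
        # pairwise separation by more than max_gap
        for a, b in zip(merged, list(merged)[1:]):
            assert b.start - a.end > max_gap
        # member lists partition the input
        assert sorted(
            m.key for members in merged.attrs["members"] for m in members
        ) == sorted(x.key for x in ivs.sorted())

    def test_members_retained(self):
        merged = merge_intervals(IntervalSet([iv("chr1", 0, 10), iv("chr1", 5, 30)]))
        assert len(merged.attrs["members"][0]) == 2


class TestAssignByLargestOverlap:
    def test_largest_overlap_wins(self):
        bins = IntervalSet([iv("chr1", 0, 5000, "bin")])
        anns = IntervalSet([iv("chr1", 0, 3000, "IAP"), iv("chr1", 4000, 5000, "ETn")])
        assert assign_by_largest_overlap(bins, anns) == ["IAP"]

    def test_contained_query_and_unassigned(self):
        anns = IntervalSet([iv("chr1", 0, 1000, "A")])
        queries = IntervalSet([iv("chr1", 100, 200), iv("chr2", 0, 50)])
        assert assign_by_largest_overlap(queries, anns) == ["A", "unassigned"]

    def test_matches_brute_force_argmax(self, rng, toy_genome):
        queries = random_interval_set(rng, toy_genome, 150)
        anns = random_interval_set(rng, toy_genome, 60)
        got = assign_by_largest_overlap(queries, anns)
        sorted_anns = sorted(anns, key=lambda a: (a.chrom, a.start, a.end, a.name))
        for q, label in zip(queries, got):
            best, best_len = "unassigned", 0
            for a in sorted_anns:
                ov = overlap_length(q, a)
                if ov > best_len:
                    best, best_len = a.name, ov
            assert label == best


class TestShuffleMatched:
    def test_length_multiset_conserved(self, toy_genome):
        src = IntervalSet([iv("chr1", 0, 340), iv("chr1", 1000, 3000), iv("chr2", 0, 6500)])
        out = shuffle_matched(src, toy_genome, seed=3)
        assert sorted(o.length for o in out) == [340, 2000, 6500]

    def test_seed_determinism(self, toy_genome):
        src = IntervalSet([iv("chr1", 100, 500), iv("chr2", 0, 700)])
        a = shuffle_matched(src, toy_genome, seed=9)
        b = shuffle_matched(src, toy_genome, seed=9)
        assert [x.key for x in a] == [x.key for x in b]

    def test_respects_exclusion(self, toy_genome):
        src = IntervalSet([iv("chr1", 0, 500)])
        exclude = IntervalSet(
            [iv("chr1", 0, 9000), iv("chr2", 0, 4000)]
        )
        for seed in range(30):
            out = shuffle_matched(src, toy_genome, seed=seed, exclude=exclude)
            for o in out:
                assert not exclude.overlapping(o.chrom, o.start, o.end)

    def test_start_positions_uniform(self):
        genome = GenomeModel({"chr1": 10_000})
        src = IntervalSet([iv("chr1", 4000, 4100)])
        starts = []
        none = IntervalSet([])
        for seed in range(10_000):
            starts.append(shuffle_matched(src, genome, seed=seed, exclude=none)[0].start)
        counts, _ = np.histogram(starts, bins=20, range=(0, 9901))
        p = sps.chisquare(counts).pvalue
        assert p > 0.01

    def test_placement_failure_names_interval(self):
        genome = GenomeModel({"chr1": 1000})
        src = IntervalSet([iv("chr1", 0, 900, "big")])
        exclude = IntervalSet([iv("chr1", 0, 1000)])
        from ervdyn.errors import PlacementError

        with pytest.raises(PlacementError, match="big"):
            shuffle_matched(src, genome, seed=1, exclude=exclude, max_attempts=20)


class TestOverlapCounts:
    def test_pairwise_example(self):
        res = overlap_counts(
            {"A": IntervalSet([iv("chr1", 0, 10)]), "B": IntervalSet([iv("chr1", 5, 15)])}
        )
        assert res["A"][("A", "B")] == 1
        assert res["B"][("A", "B")] == 1

    def test_disjoint_sets(self):
        res = overlap_counts(
            {"A": IntervalSet([iv("chr1", 0, 10)]), "B": IntervalSet([iv("chr1", 20, 30)])}
        )
        assert res["A"] == {("A",): 1}
        assert res["B"] == {("B",): 1}

    def test_three_sets_match_enumeration(self, rng, toy_genome):
        sets = {
            name: random_interval_set(rng, toy_genome, 40) for name in ("A", "B", "C")
        }
        res = overlap_counts(sets)
        for name, ivset in sets.items():
            expected = {}
            for member in ivset:
                combo = {name}
                for other, oset in sets.items():
                    if other != name and any(
                        overlap_length(member, o) > 0 for o in oset
                    ):
                        combo.add(other)
                key = tuple(sorted(combo))
                expected[key] = expected.get(key, 0) + 1
            assert res[name] == expected
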