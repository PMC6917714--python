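"""Interval arithmetic, panel statistics and GI coverage accounting."""

import pytest
from hypothesis import given, settings, strategies as st

from bacpanel import (
    GeneFeature,
    GenomeRecord,
    GenomeStats,
    IntervalSet,
    Replicon,
    covered_bp,
    gi_coverage,
    merge_intervals,
    rank_gi_percent,
    summarize_stats,
)
from bacpanel.model import features_overlapping

intervals_strategy = st.lists(
    st.tuples(st.integers(0, 10_000), st.integers(0, 10_000)).map(
        lambda t: (min(t), max(t))
    ),
    max_size=30,
)


def brute_force_bp(intervals, size=10_001):
    """Per-bp scan oracle for covered length."""
    hit = [False] * size
    for s, e in intervals:
        for i in range(s, e):
            hit[i] = True
    return sum(hit)


class TestIntervalMerge:
    @settings(max_examples=60, deadline=None)
    @given(intervals_strategy)
    def test_merge_idempotent_and_matches_per_bp_oracle(self, intervals):
        merged = merge_intervals(intervals)
        assert merge_intervals(merged) == merged
        assert all(s < e for s, e in merged)
        assert all(merged[i][1] <= merged[i + 1][0] for i in range(len(merged) - 1))
        assert covered_bp(intervals) == brute_force_bp(intervals)

    @settings(max_examples=30, deadline=None)
    @given(intervals_strategy)
    def test_covered_bp_invariant_under_input_order(self, intervals):
        assert covered_bp(intervals) == covered_bp(list(reversed(intervals)))

    def test_overlapping_intervals_merge(self):
        assert merge_intervals([(0, 100), (50, 150)]) == [(0, 150)]
        assert covered_bp([(0, 100), (50, 150)]) == 150


def _one_replicon_genome(gid="g1", length=1_000):
    return GenomeRecord(
        genome_id=gid, replicons=[Replicon(f"{gid}.chr", length)]
    )


class TestGICoverage:
    def test_single_island_percent(self):
        g = _one_replicon_genome()
        cov = gi_coverage(g, [], [IntervalSet(f"{g.genome_id}.chr", [(0, 100)])])
        assert cov.gi_bp == 100
        assert cov.gi_percent == pytest.approx(10.0)

    def test_overlapping_islands_merged_before_counting(self):
        g = _one_replicon_genome()
        cov = gi_coverage(
            g, [], [IntervalSet(f"{g.genome_id}.chr", [(0, 100), (50, 150)])]
        )
        assert cov.gi_bp == 150

    def test_island_outside_replicon_is_error(self):
        g = _one_replicon_genome(length=100)
        with pytest.raises(ValueError, match="outside replicon"):
            gi_coverage(g, [], [IntervalSet(f"{g.genome_id}.chr", [(50, 200)])])

    def test_disjoint_island_sets_add_percentages(self):
        g = _one_replicon_genome(length=2_000)
        a = [IntervalSet(f"{g.genome_id}.chr", [(0, 100)])]
        b = [IntervalSet(f"{g.genome_id}.chr", [(500, 700)])]
        both = [IntervalSet(f"{g.genome_id}.chr", [(0, 100), (500, 700)])]
        assert gi_coverage(g, [], both).gi_percent == pytest.approx(
            gi_coverage(g, [], a).gi_percent + gi_coverage(g, [], b).gi_percent
        )

    def test_gene_in_gi_requires_one_bp_overlap(self):
        g = _one_replicon_genome()
        rep = f"{g.genome_id}.chr"
        feats = [
            GeneFeature("in", rep, 90, 120),     # 10 bp overlap
            GeneFeature("out", rep, 100, 200),   # touches boundary, no overlap
            GeneFeature("bio", rep, 10, 50),
        ]
        cov = gi_coverage(
            g, feats, [IntervalSet(rep, [(0, 100)])],
            biosynthetic_gene_ids={"bio", "absent"},
        )
        assert set(cov.gene_ids_in_gi) == {"in", "bio"}
        assert cov.biosynthetic_genes_in_gi == 1
        assert cov.biosynthetic_genes_in_gi <= cov.genes_in_gi

    def test_min_overlap_fraction_tightens_membership(self):
        feats = [GeneFeature("f", "r", 90, 190)]  # 10% overlap with (0, 100)
        assert features_overlapping(feats, {"r": [(0, 100)]}) == feats
        assert features_overlapping(feats, {"r": [(0, 100)]}, 0.5) == []


class TestPanelSummary:
    def test_single_genome_identity(self):
        s = GenomeStats("g", 4_000_000, 4_000, 30)
        out = summarize_stats([s])
        assert out.mean_genome_size == out.min_genome_size == 4_000_000
        assert out.mean_orf_count == 4_000 and out.mean_rrna_count == 30

    def test_empty_panel_is_error(self):
        with pytest.raises(ValueError):
            summarize_stats([])

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 8_000_000), st.integers(0, 9_000), st.integers(0, 60)
            ),
            min_size=1,
            max_size=32,
        )
    )
    def test_means_match_naive_resummation(self, rows):
        stats = [GenomeStats(f"g{i}", *row) for i, row in enumerate(rows)]
        out = summarize_stats(stats)
        n = len(rows)
        assert out.mean_genome_size == pytest.approx(sum(r[0] for r in rows) / n)
        assert out.mean_orf_count == pytest.approx(sum(r[1] for r in rows) / n)
        assert out.mean_rrna_count == pytest.approx(sum(r[2] for r in rows) / n)
        assert out.min_genome_size <= out.mean_genome_size <= out.max_genome_size


class TestQuartileRanking:
    def test_four_strains_one_per_quartile(self):
        r = rank_gi_percent([("a", 1.0), ("b", 2.0), ("c", 3.0), ("d", 4.0)])
        assert r.quartile_of == {"a": 1, "b": 2, "c": 3, "d": 4}

    def test_requires_four_strains(self):
        with pytest.raises(ValueError):
            rank_gi_percent([("a", 1.0), ("b", 2.0), ("c", 3.0)])

    def test_ties_broken_by_strain_id_lower_quartile_first(self):
        r = rank_gi_percent([("b", 1.0), ("a", 1.0), ("c", 1.0), ("d", 1.0)])
        assert r.quartile_of["a"] == 1 and r.quartile_of["d"] == 4

    def test_reference_mean_count_restricted_to_subgroup(self):
        vals = [("a", 1.0), ("b", 6.0), ("c", 7.0), ("d", 8.0)]
        r = rank_gi_percent(vals, reference_mean=5.6, subgroup={"a", "b"})
        assert r.n_above_reference == 1

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=30))
    def test_quartiles_partition_the_panel(self, values):
        vals = [(f"s{i:02d}", v) for i, v in enumerate(values)]
        r = rank_gi_percent(vals)
        assert sorted(r.quartile_of) == sorted(s for s, _ in vals)
        sizes = sorted(r.counts)
        assert sizes[-1] - sizes[0] <= 1 and sum(sizes) == len(vals)


class TestPanelGeneOverlap:
    def _features(self, n):
        return [GeneFeature(f"g{i:02d}", "r", 10 * i + 1, 10 * i + 9) for i in range(n)]

    def test_empty_reference_set_gives_empty_result(self):
        from bacpanel import HomologyHit, panel_gene_overlap

        feats = self._features(3)
        hits = {"g00": [HomologyHit("g00", "NP_1", 120.0, 1e-30)]}
        assert panel_gene_overlap(feats, hits, set()) == []

    def test_planted_orthologs_found_among_decoys(self):
        from bacpanel import HomologyHit, panel_gene_overlap

        feats = self._features(50)
        planted = {"g03", "g17", "g42"}
        hits = {
            f.feature_id: [
                HomologyHit(
                    f.feature_id,
                    "NP_ref" if f.feature_id in planted else "NP_other",
                    150.0,
                    1e-40,
                )
            ]
            for f in feats
        }
        assert panel_gene_overlap(feats, hits, {"NP_ref"}) == sorted(planted)

    def test_duplicate_hits_not_double_counted(self):
        from bacpanel import HomologyHit, panel_gene_overlap

        feats = self._features(1)
        hits = {
            "g00": [
                HomologyHit("g00", "NP_ref", 150.0, 1e-40),
                HomologyHit("g00", "NP_ref", 140.0, 1e-38),
            ]
        }
        assert panel_gene_overlap(feats, hits, {"NP_ref", "NP_ref"}) == ["g00"]


class TestModelInvariants:
    def test_genome_needs_exactly_one_chromosome(self):
        with pytest.raises(ValueError, match="chromosome"):
            GenomeRecord(
                genome_id="g",
                replicons=[Replicon("a", 10), Replicon("b", 10)],
            )
        with pytest.raises(ValueError, match="replicon"):
            GenomeRecord(genome_id="g", replicons=[])

    def test_feature_interval_must_be_valid(self):
        with pytest.raises(ValueError):
            GeneFeature("f", "r", 10, 10)
        with pytest.raises(ValueError):
            GeneFeature("f", "r", -1, 5)
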