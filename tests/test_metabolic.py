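"""Reaction matrices, clustering, binomial enrichment and concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bacpanel import (
    CladePartition,
    ReactionMatrix,
    binomial_enrichment,
    clade_tree_concordance,
    cluster_species,
    compare_groups,
    cut_to_clades,
    group_specific_reactions,
    pathway_rollup,
)
from bacpanel.homology import Reaction, ReactionCatalog
from bacpanel.metabolic import EnrichmentRecord
from bacpanel.simulate import SimulationConfig, simulate_matrix


def binomial_tail_oracle(k, n, p):
    """Exact pmf summation: (P(X >= k), P(X <= k))."""
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    return sum(pmf[k:]), sum(pmf[: k + 1])


def _matrix_from_rows(rows, species=None):
    species = species or [f"s{i:02d}" for i in range(len(rows))]
    cols = [f"R{j}" for j in range(len(rows[0]))]
    return ReactionMatrix(pd.DataFrame(rows, index=species, columns=cols))


class TestBinomialEnrichment:
    def test_matches_pmf_summation_oracle_small_panels(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((8, 12)) < 0.4).tolist()
        m = _matrix_from_rows(rows)
        part = CladePartition(
            clade_of={s: 1 if i < 3 else 2 for i, s in enumerate(m.species_ids)},
            excluded={},
        )
        for rec in binomial_enrichment(m, part):
            want_over, want_under = binomial_tail_oracle(rec.k, rec.n, rec.p_bg)
            assert rec.p_over == pytest.approx(want_over, abs=1e-12)
            assert rec.p_under == pytest.approx(want_under, abs=1e-12)
            assert rec.p_over + rec.p_under >= 1.0 - 1e-12

    def test_known_tail_values(self):
        # all-present clade of 5 against a fair background
        m = _matrix_from_rows([[True]] * 5 + [[True], [False]] * 2)
        part = CladePartition(
            clade_of={s: 1 if i < 5 else 2 for i, s in enumerate(m.species_ids)},
            excluded={},
        )
        rec = [r for r in binomial_enrichment(m, part) if r.clade_id == 1][0]
        assert (rec.k, rec.n, rec.p_bg) == (5, 5, 0.5)
        assert rec.p_over == pytest.approx(0.03125)
        assert rec.call == "none"  # far from the 1e-5 threshold
        assert binomial_tail_oracle(6, 7, 0.2)[0] == pytest.approx(3.712e-4, rel=1e-3)

    def test_degenerate_background_handled_exactly(self):
        m = _matrix_from_rows([[True]] * 5 + [[False]] * 5)
        part = CladePartition(
            clade_of={s: 1 if i < 5 else 2 for i, s in enumerate(m.species_ids)},
            excluded={},
        )
        recs = {r.clade_id: r for r in binomial_enrichment(m, part)}
        assert recs[1].p_bg == 0.0 and recs[1].p_over == 0.0
        assert recs[1].call == "over"
        assert recs[2].p_bg == 1.0 and recs[2].p_under == 0.0
        assert recs[2].call == "under"

    def test_excluded_species_contribute_nothing(self):
        rows = [[True]] * 3 + [[False]] * 3 + [[True]] * 2
        m = _matrix_from_rows(rows)
        sp = m.species_ids
        part = CladePartition(
            clade_of={**{s: 1 for s in sp[:3]}, **{s: 2 for s in sp[3:6]}},
            excluded={sp[6]: "low quality", sp[7]: "too distant"},
        )
        rec = [r for r in binomial_enrichment(m, part) if r.clade_id == 1][0]
        assert rec.p_bg == 0.0  # the two excluded carriers are ignored

    def test_background_empty_is_error(self):
        m = _matrix_from_rows([[True], [True]])
        part = CladePartition(clade_of={s: 1 for s in m.species_ids}, excluded={})
        with pytest.raises(ValueError, match="background"):
            binomial_enrichment(m, part)


class TestClustering:
    def test_identical_rows_merge_at_distance_zero(self):
        m = _matrix_from_rows([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        d = cluster_species(m)
        assert d.linkage[0, 2] == 0.0

    def test_complementary_rows_merge_last(self):
        m = _matrix_from_rows([[1, 1, 0, 0], [1, 1, 0, 1], [0, 0, 1, 1]])
        d = cluster_species(m)
        assert d.linkage[-1, 2] == max(d.linkage[:, 2])

    def test_planted_three_block_matrix_recovered_exactly(self):
        cfg = SimulationConfig(seed=5, clade_sizes=(4, 4, 4))
        df, _ = simulate_matrix(cfg)
        m = ReactionMatrix(df)
        part = cut_to_clades(cluster_species(m), 3)
        found = {frozenset(part.members(c)) for c in part.clade_ids}
        want_sets = {}
        for s, c in cfg.clade_of().items():
            want_sets.setdefault(c, set()).add(s)
        assert found == {frozenset(v) for v in want_sets.values()}

    def test_invariant_to_species_input_order(self):
        rng = np.random.default_rng(8)
        rows = (rng.random((6, 15)) < 0.5).tolist()
        m = _matrix_from_rows(rows)
        shuffled = ReactionMatrix(m.presence.iloc[[3, 1, 5, 0, 4, 2]])
        d1, d2 = cluster_species(m), cluster_species(shuffled)
        assert d1.labels == d2.labels
        assert np.allclose(d1.linkage, d2.linkage)

    def test_cut_extremes_and_range_check(self):
        m = _matrix_from_rows([[1, 0], [0, 1], [1, 1]])
        d = cluster_species(m)
        assert len(set(cut_to_clades(d, 1).clade_of.values())) == 1
        singletons = cut_to_clades(d, 3)
        assert sorted(singletons.clade_of.values()) == [1, 2, 3]
        with pytest.raises(ValueError):
            cut_to_clades(d, 4)
        with pytest.raises(ValueError):
            cluster_species(_matrix_from_rows([[1, 0]]))


class TestGroupSpecific:
    def test_inclusive_fraction_boundaries(self):
        # focal: 8/10 present (>= 0.75); others: 2/22 present (absence ~0.909)
        rows = [[True]] * 8 + [[False]] * 2 + [[True]] * 2 + [[False]] * 20
        m = _matrix_from_rows(rows)
        focal = m.species_ids[:10]
        assert group_specific_reactions(m, focal) == ["R0"]
        # 7/10 focal presence drops below 0.75
        rows[7] = [False]
        m2 = _matrix_from_rows(rows)
        assert group_specific_reactions(m2, focal) == []

    def test_strict_thresholds_select_exclusive_universal_reactions(self):
        rows = [[1, 1], [1, 1], [0, 1], [0, 0]]
        m = _matrix_from_rows(rows)
        focal = m.species_ids[:2]
        assert group_specific_reactions(m, focal, 1.0, 1.0) == ["R0"]

    def test_zero_thresholds_return_all_reactions(self):
        m = _matrix_from_rows([[1, 0, 1], [0, 0, 1]])
        assert group_specific_reactions(m, [m.species_ids[0]], 0.0, 0.0) == [
            "R0", "R1", "R2",
        ]

    @settings(max_examples=25, deadline=None)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.integers(0, 10_000),
    )
    def test_monotone_in_both_thresholds(self, p_min, a_min, seed):
        rng = np.random.default_rng(seed)
        m = _matrix_from_rows((rng.random((8, 10)) < 0.5).tolist())
        focal = m.species_ids[:3]
        base = set(group_specific_reactions(m, focal, p_min, a_min))
        tighter_p = min(1.0, p_min + 0.2)
        tighter_a = min(1.0, a_min + 0.2)
        assert set(group_specific_reactions(m, focal, tighter_p, a_min)) <= base
        assert set(group_specific_reactions(m, focal, p_min, tighter_a)) <= base

    def test_focal_equal_to_panel_is_error(self):
        m = _matrix_from_rows([[1], [1]])
        with pytest.raises(ValueError):
            group_specific_reactions(m, m.species_ids)


class TestGroupComparison:
    def test_clone_groups_have_zero_difference(self):
        m = _matrix_from_rows([[1, 1, 0]] * 4)
        cmp = compare_groups(m, m.species_ids[:2], m.species_ids[2:])
        assert cmp.reaction_difference == 0.0

    def test_planted_reaction_surplus_recovered(self):
        rows = [[True] * 10] * 3 + [[True] * 6 + [False] * 4] * 3
        m = _matrix_from_rows(rows)
        cmp = compare_groups(m, m.species_ids[:3], m.species_ids[3:])
        assert cmp.reaction_difference == pytest.approx(4.0)

    def test_overlapping_groups_rejected(self):
        m = _matrix_from_rows([[1], [1], [1]])
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(m, m.species_ids[:2], m.species_ids[1:])


class TestPathwayRollup:
    def _catalog(self):
        return ReactionCatalog(
            reactions={
                f"R{i}": Reaction(f"R{i}", ("e",), frozenset({"m"}),
                                  pathway_id="pw-ectoine" if i < 3 else "pw-other")
                for i in range(5)
            },
            enzyme_seqs={"e": "MKV"},
        )

    def test_no_calls_empty_table(self):
        assert pathway_rollup([], self._catalog()).empty

    def test_shared_pathway_counts_aggregate(self):
        recs = [
            EnrichmentRecord(f"R{i}", 1, 4, 4, 0.0, 0.0, 1.0, "over")
            for i in range(3)
        ] + [EnrichmentRecord("R3", 1, 0, 4, 0.9, 1.0, 0.4, "none")]
        table = pathway_rollup(recs, self._catalog())
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.pathway, row.clade, row.call, row.n_reactions) == (
            "pw-ectoine", 1, "over", 3,
        )


class TestTreeConcordance:
    TREE = "(((s1,s2),(s3,s4)),((s5,s6),(s7,s8)));"

    def _partition(self, mapping):
        return CladePartition(clade_of=mapping, excluded={})

    def test_full_subtree_is_concordant(self):
        part = self._partition(
            {"s1": 1, "s2": 1, "s3": 1, "s4": 1, "s5": 2, "s6": 2, "s7": 2, "s8": 2}
        )
        assert clade_tree_concordance(part, self.TREE) == {1: True, 2: True}

    def test_clade_mixing_distant_subtrees_is_discordant(self):
        part = self._partition(
            {"s1": 1, "s8": 1, "s2": 2, "s3": 2, "s4": 2, "s5": 2, "s6": 2, "s7": 2}
        )
        out = clade_tree_concordance(part, self.TREE)
        assert out[1] is False

    def test_singleton_clade_concordant_and_pruning_of_extra_leaves(self):
        part = self._partition({"s1": 1, "s3": 2, "s4": 2})
        out = clade_tree_concordance(part, self.TREE)
        assert out == {1: True, 2: True}

    def test_missing_species_named_in_error(self):
        part = self._partition({"s1": 1, "sX": 1})
        with pytest.raises(ValueError, match="sX"):
            clade_tree_concordance(part, self.TREE)
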