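"""SMGC similarity, family formation, product assignment, co-localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bacpanel import (
    SMGC,
    SMGCFamily,
    assign_products,
    build_families,
    classify_colocalization,
    cluster_similarity,
    family_census,
    normalized_position,
)
from bacpanel.scoring import HitTableProvider
from bacpanel.simulate import _mutate, _random_protein


def _smgc(smgc_id, genome, genes, start=1000, end=2000):
    return SMGC(
        smgc_id=smgc_id, genome_id=genome, replicon_id=f"{genome}.chr",
        start=start, end=end, gene_ids=tuple(genes),
    )


def _hits(pairs, bit=200.0):
    """Hit-table provider scoring listed (query, subject) pairs symmetrically."""
    rows = []
    for q, s in pairs:
        rows.append((q, s, bit, 1e-50))
        rows.append((s, q, bit, 1e-50))
    return HitTableProvider(
        pd.DataFrame(rows, columns=["query", "subject", "bit_score", "e_value"])
    )


class TestNormalizedPosition:
    def test_midpoint_over_length(self):
        c = _smgc("c", "g", ["x"], start=1_000_000, end=1_050_000)
        assert normalized_position(c, 4_100_000) == pytest.approx(0.25)

    def test_centered_cluster_is_half(self):
        c = _smgc("c", "g", ["x"], start=400, end=600)
        assert normalized_position(c, 1000) == pytest.approx(0.5)

    def test_cluster_at_end_stays_below_one(self):
        c = _smgc("c", "g", ["x"], start=900, end=1000)
        assert normalized_position(c, 1000) < 1.0

    def test_out_of_bounds_rejected(self):
        c = _smgc("c", "g", ["x"], start=900, end=1200)
        with pytest.raises(ValueError):
            normalized_position(c, 1000)


class TestClusterSimilarity:
    def test_identity_is_one(self):
        a = _smgc("a", "g1", ["x1", "x2"])
        provider = _hits([("x1", "x1"), ("x2", "x2")])
        seqs = {"x1": "", "x2": ""}
        assert cluster_similarity(a, a, seqs, provider) == 1.0

    def test_disjoint_gene_sets_are_zero(self):
        a = _smgc("a", "g1", ["x1", "x2"])
        b = _smgc("b", "g2", ["y1", "y2"])
        provider = _hits([])
        seqs = {g: "" for g in ("x1", "x2", "y1", "y2")}
        assert cluster_similarity(a, b, seqs, provider) == 0.0

    def test_three_of_five_shared_gives_boundary_similarity(self):
        a = _smgc("a", "g1", [f"x{i}" for i in range(5)])
        b = _smgc("b", "g2", [f"y{i}" for i in range(5)])
        provider = _hits([(f"x{i}", f"y{i}") for i in range(3)])
        seqs = {g: "" for g in (*a.gene_ids, *b.gene_ids)}
        sim = cluster_similarity(a, b, seqs, provider)
        assert sim == pytest.approx(0.6)

    def test_symmetric_with_real_scorer(self, scorer):
        rng = np.random.default_rng(21)
        anc = [_random_protein(rng, 160) for _ in range(3)]
        seqs = {f"a{i}": _mutate(anc[i], rng, 0.05) for i in range(3)}
        seqs.update({f"b{i}": _mutate(anc[i], rng, 0.05) for i in range(2)})
        seqs["b2"] = _random_protein(rng, 160)
        a = _smgc("a", "g1", ["a0", "a1", "a2"])
        b = _smgc("b", "g2", ["b0", "b1", "b2"])
        s_ab = cluster_similarity(a, b, seqs, scorer)
        s_ba = cluster_similarity(b, a, seqs, scorer)
        assert s_ab == s_ba
        assert s_ab == pytest.approx(4 / 6)

    def test_missing_gene_sequence_named(self, scorer):
        a = _smgc("a", "g1", ["x1"])
        with pytest.raises(KeyError, match="x1"):
            cluster_similarity(a, a, {}, scorer)


class TestBuildFamilies:
    def test_no_edges_every_cluster_alone(self):
        clusters = [_smgc(f"c{i}", f"g{i}", [f"z{i}"]) for i in range(4)]
        seqs = {f"z{i}": "" for i in range(4)}
        fams = build_families(clusters, seqs, _hits([]))
        assert len(fams) == 4
        assert all(len(f.members) == 1 for f in fams)

    def test_chain_connects_by_single_linkage(self):
        a = _smgc("a", "g1", ["a1", "a2"])
        b = _smgc("b", "g2", ["b1", "b2"])
        c = _smgc("c", "g3", ["c1", "c2"])
        provider = _hits([("a1", "b1"), ("a2", "b2"), ("b1", "c1"), ("b2", "c2")])
        seqs = {g: "" for g in ("a1", "a2", "b1", "b2", "c1", "c2")}
        fams = build_families([a, b, c], seqs, provider)
        assert len(fams) == 1 and len(fams[0].members) == 3

    def test_partition_invariant_to_input_order(self):
        a = _smgc("a", "g1", ["a1"])
        b = _smgc("b", "g2", ["b1"])
        c = _smgc("c", "g3", ["c1"])
        provider = _hits([("a1", "b1")])
        seqs = {"a1": "", "b1": "", "c1": ""}
        f1 = build_families([a, b, c], seqs, provider)
        f2 = build_families([c, b, a], seqs, provider)
        as_sets = lambda fams: {frozenset(m.smgc_id for m in f.members) for f in fams}
        assert as_sets(f1) == as_sets(f2)
        all_ids = [m.smgc_id for f in f1 for m in f.members]
        assert sorted(all_ids) == ["a", "b", "c"]  # exhaustive and disjoint

    def test_planted_families_recovered_exactly(self, small_panel, scorer):
        fams = build_families(
            small_panel.smgcs, small_panel.gene_sequences, scorer
        )
        got = {frozenset(m.smgc_id for m in f.members) for f in fams}
        want = {frozenset(v) for v in small_panel.truth.family_members.values()}
        assert got == want


class TestAssignProducts:
    def test_empty_reference_catalog_all_unknown(self):
        fam = SMGCFamily("f1", [_smgc("a", "g1", ["a1"])])
        assign_products([fam], [], {}, {"a1": ""}, _hits([]))
        assert fam.known_product == ""

    def test_identical_member_gets_reference_product(self):
        member = _smgc("a", "g1", ["a1", "a2"])
        ref = SMGC("ref", "mibig", "mibig", 0, 100, ("r1", "r2"), product="bacitracin")
        fam = SMGCFamily("f1", [member])
        provider = _hits([("a1", "r1"), ("a2", "r2")])
        seqs = {"a1": "", "a2": ""}
        assign_products([fam], [ref], {"r1": "", "r2": ""}, seqs, provider)
        assert fam.known_product == "bacitracin"

    def test_below_threshold_match_stays_unknown(self):
        # 5+5 genes, 2 reciprocal matches -> similarity 0.4 < 0.6
        member = _smgc("a", "g1", [f"a{i}" for i in range(5)])
        ref = SMGC("ref", "mibig", "mibig", 0, 100,
                   tuple(f"r{i}" for i in range(5)), product="decoy")
        fam = SMGCFamily("f1", [member])
        provider = _hits([("a0", "r0"), ("a1", "r1")])
        seqs = {f"a{i}": "" for i in range(5)}
        assign_products([fam], [ref], {f"r{i}": "" for i in range(5)}, seqs, provider)
        assert fam.known_product == ""


def _family_at(positions, length=1_000_000):
    # width-1 clusters: midpoint/length tracks the requested position to 1e-6
    members = [
        _smgc(f"c{g}", g, [f"{g}.x"], start=int(p * length),
              end=int(p * length) + 1)
        for g, p in positions.items()
    ]
    return SMGCFamily("fam", members)


def _info(genomes, circular=True):
    return {g: (1_000_000, circular) for g in genomes}


class TestColocalization:
    def test_tight_positions_are_strict(self):
        fam = _family_at({"g1": 0.41, "g2": 0.43, "g3": 0.39})
        call = classify_colocalization(fam, _info(["g1", "g2", "g3"]))
        assert call.classification == "strict"

    def test_one_outlier_is_partial(self):
        fam = _family_at({"g1": 0.41, "g2": 0.43, "g3": 0.90})
        call = classify_colocalization(fam, _info(["g1", "g2", "g3"]))
        assert call.classification == "partial"

    def test_spread_positions_are_random_with_circular_distance(self):
        fam = _family_at({"g1": 0.10, "g2": 0.50, "g3": 0.90})
        call = classify_colocalization(fam, _info(["g1", "g2", "g3"]))
        assert call.classification == "random"  # 0.10 vs 0.90 is 0.2 circularly

    def test_wraparound_pair_is_strict_on_circular_chromosome(self):
        fam = _family_at({"g1": 0.01, "g2": 0.99})
        assert (
            classify_colocalization(fam, _info(["g1", "g2"])).classification
            == "strict"
        )
        assert (
            classify_colocalization(
                fam, _info(["g1", "g2"], circular=False)
            ).classification
            == "random"
        )

    def test_single_species_class(self):
        fam = _family_at({"g1": 0.5})
        assert classify_colocalization(fam, _info(["g1"])).classification == "single"

    def test_members_without_chromosome_info_excluded(self):
        fam = _family_at({"g1": 0.41, "g2": 0.43, "g9": 0.9})
        call = classify_colocalization(fam, _info(["g1", "g2"]))
        assert call.classification == "strict"
        assert set(call.positions) == {"g1", "g2"}

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0, 1, exclude_max=True))
    def test_rotation_invariance_on_circular_chromosomes(self, shift):
        base = {"g1": 0.41, "g2": 0.43, "g3": 0.90}
        rotated = {g: (p + shift) % 1.0 for g, p in base.items()}
        f1, f2 = _family_at(base), _family_at(rotated)
        info = _info(["g1", "g2", "g3"])
        assert (
            classify_colocalization(f1, info).classification
            == classify_colocalization(f2, info).classification
        )

    def test_zero_tolerance_degenerates_to_random(self, small_panel, scorer):
        from bacpanel import build_families

        fams = build_families(small_panel.smgcs, small_panel.gene_sequences, scorer)
        info = {
            g.genome_id: (g.chromosome.length, g.chromosome.circular)
            for g in small_panel.genomes
        }
        for fam in fams:
            call = classify_colocalization(fam, info, tolerance=0.0)
            if call and len(call.positions) > 1:
                assert call.classification == "random"


class TestCensus:
    def test_small_family_counts(self):
        fam = SMGCFamily("f1", [_smgc(f"c{i}", f"g{i}", ["x"]) for i in range(3)])
        census = family_census([fam], {f"g{i}": "reference" for i in range(3)})
        assert census.total_occurrences == 3
        assert census.distinct_families == 1
        assert census.shared_families == 1 and census.unique_families == 0

    def test_conservation_shared_plus_unique_is_distinct(self, pipeline_result):
        result, _ = pipeline_result
        c = result.census
        assert c["shared_families"] + c["unique_families"] == c["distinct_families"]
        multi = {
            k: v for k, v in c["coloc_class_counts"].items() if k != "single"
        }
        assert sum(multi.values()) == c["multi_species_classified"]

    def test_planted_census_recovered(self, pipeline_result, small_panel):
        result, _ = pipeline_result
        c = result.census
        truth = small_panel.truth
        classes = list(truth.family_classes.values())
        assert c["distinct_families"] == len(truth.family_members)
        assert c["unique_families"] == classes.count("single")
        assert c["shared_families"] == len(classes) - classes.count("single")
        assert c["group_exclusive_families"] == len(truth.exclusive_families)
        assert c["known_families"] == len(truth.known_products)
        for klass in ("strict", "partial", "random"):
            assert c["coloc_class_counts"].get(klass, 0) == classes.count(klass)

    def test_unlabelled_genome_is_error(self):
        fam = SMGCFamily("f1", [_smgc("c", "g1", ["x"])])
        with pytest.raises(KeyError, match="g1"):
            family_census([fam], {})
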