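"""Secondary-metabolite gene cluster (SMGC) families and co-localization.

Predicted gene clusters (antiSMASH-style intervals with their gene lists)
are grouped into families: two clusters are similar if the symmetric
shared-gene fraction

    sim(A, B) = (h_AB + h_BA) / (|A| + |B|)

is at least 0.60, where h_XY counts genes of X with a homolog in Y above the
homology bit-score threshold; families are the connected components of the
similarity graph (single-linkage semantics). Families are annotated with a
known product when any member reaches the same similarity against a
characterized reference cluster, and classified by genomic placement using
the normalized chromosomal position of each member (cluster midpoint over
chromosome length): strict when all species' positions coincide within a
tolerance (circular distance on circular chromosomes), partial when some
but not all do, random when none do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .homology import DEFAULT_BIT_MIN
from .scoring import ScoreProvider

DEFAULT_SIM_MIN = 0.60
DEFAULT_COLOC_TOLERANCE = 0.05


@dataclass(frozen=True)
class SMGC:
    """One predicted secondary-metabolite gene cluster (0-based half-open)."""

    smgc_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    gene_ids: tuple[str, ...]
    predicted_class: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"SMGC {self.smgc_id}: invalid interval")
        if not self.gene_ids:
            raise ValueError(f"SMGC {self.smgc_id}: needs >= 1 gene")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def normalized_position(smgc: SMGC, replicon_length: int) -> float:
    """Cluster midpoint over chromosome length, in [0, 1)."""
    if not (0 < smgc.end <= replicon_length):
        raise ValueError(
            f"SMGC {smgc.smgc_id}: outside replicon of length {replicon_length}"
        )
    return smgc.midpoint / replicon_length


def cluster_similarity(
    a: SMGC,
    b: SMGC,
    sequences: Mapping[str, str],
    provider: ScoreProvider,
    bit_min: float = DEFAULT_BIT_MIN,
) -> float:
    """Symmetric shared-gene fraction between two clusters, in [0, 1]."""
    for g in (*a.gene_ids, *b.gene_ids):
        if g not in sequences:
            raise KeyError(f"gene sequence missing: {g}")

    def hits(x: SMGC, y: SMGC) -> int:
        n = 0
        for gx in x.gene_ids:
            for gy in y.gene_ids:
                bit, _ = provider.pair_score(gx, sequences[gx], gy, sequences[gy])
                if bit >= bit_min:
                    n += 1
                    break
        return n

    return (hits(a, b) + hits(b, a)) / (len(a.gene_ids) + len(b.gene_ids))


@dataclass
class SMGCFamily:
    """A connected component of >= sim_min-similar clusters."""

    family_id: str
    members: list[SMGC]
    known_product: str = ""

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(m.genome_id for m in self.members)

    @property
    def is_shared(self) -> bool:
        return len(self.species_set) >= 2


def build_families(
    smgcs: Sequence[SMGC],
    sequences: Mapping[str, str],
    provider: ScoreProvider,
    sim_min: float = DEFAULT_SIM_MIN,
    bit_min: float = DEFAULT_BIT_MIN,
) -> list[SMGCFamily]:
    """Partition clusters into families: connected components of the graph
    with an edge wherever pairwise similarity >= sim_min (inclusive)."""
    g = nx.Graph()
    g.add_nodes_from(c.smgc_id for c in smgcs)
    by_id = {c.smgc_id: c for c in smgcs}
    ordered = sorted(smgcs, key=lambda c: c.smgc_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if cluster_similarity(a, b, sequences, provider, bit_min) >= sim_min:
                g.add_edge(a.smgc_id, b.smgc_id)
    families = []
    components = sorted(nx.connected_components(g), key=min)
    for idx, comp in enumerate(components, start=1):
        members = [by_id[c] for c in sorted(comp)]
        families.append(SMGCFamily(family_id=f"fam{idx:03d}", members=members))
    return families


def assign_products(
    families: Sequence[SMGCFamily],
    reference_clusters: Sequence[SMGC],
    reference_sequences: Mapping[str, str],
    sequences: Mapping[str, str],
    provider: ScoreProvider,
    sim_min: float = DEFAULT_SIM_MIN,
    bit_min: float = DEFAULT_BIT_MIN,
) -> None:
    """Annotate families with the product of the best-matching characterized
    reference cluster at similarity >= sim_min; otherwise leave unknown.
    Modifies families in place."""
    seqs = {**sequences, **reference_sequences}
    for fam in families:
        best_sim, best_product = 0.0, ""
        for member in fam.members:
            for ref in reference_clusters:
                sim = cluster_similarity(member, ref, seqs, provider, bit_min)
                if sim > best_sim or (sim == best_sim and ref.product < best_product):
                    best_sim, best_product = sim, ref.product
        fam.known_product = best_product if best_sim >= sim_min else ""


def circular_distance(x: float, y: float, circular: bool = True) -> float:
    d = abs(x - y)
    return min(d, 1.0 - d) if circular else d


@dataclass(frozen=True)
class ColocalizationCall:
    family_id: str
    positions: dict[str, float]  # genome -> normalized position
    classification: str  # strict / partial / random / single
    tolerance: float


def classify_colocalization(
    family: SMGCFamily,
    replicon_info: Mapping[str, tuple[int, bool]],  # genome -> (chrom length, circular)
    tolerance: float = DEFAULT_COLOC_TOLERANCE,
    computable_genomes: Iterable[str] | None = None,
) -> ColocalizationCall | None:
    """Classify a family by the positional agreement of its members.

    ``replicon_info`` maps each genome to its complete chromosome's length
    and circularity; members of genomes not listed (or not in
    ``computable_genomes`` when given) have no computable normalized position
    and are excluded. When a species carries several members, its position is
    the member minimizing the summed distance to the other species' members.

    strict: all pairwise distances <= tolerance; partial: at least one pair
    within tolerance and at least one species outside; random: no pair within
    tolerance; single: only one species has a computable position. Returns
    None when no member has a computable position.
    """
    allowed = set(computable_genomes) if computable_genomes is not None else None
    by_genome: dict[str, list[float]] = {}
    circ: dict[str, bool] = {}
    for m in family.members:
        if m.genome_id not in replicon_info:
            continue
        if allowed is not None and m.genome_id not in allowed:
            continue
        length, circular = replicon_info[m.genome_id]
        by_genome.setdefault(m.genome_id, []).append(normalized_position(m, length))
        circ[m.genome_id] = circular
    if not by_genome:
        return None

    def dist(g1: str, x: float, g2: str, y: float) -> float:
        return circular_distance(x, y, circ[g1] and circ[g2])

    # one position per species: nearest-member convention for multi-member species
    positions: dict[str, float] = {}
    for g in sorted(by_genome):
        candidates = by_genome[g]
        if len(candidates) == 1:
            positions[g] = candidates[0]
            continue
        others = [
            (g2, p) for g2 in sorted(by_genome) if g2 != g for p in by_genome[g2]
        ]
        if not others:
            positions[g] = min(candidates)
            continue
        positions[g] = min(
            candidates, key=lambda x: (sum(dist(g, x, g2, p) for g2, p in others), x)
        )

    genomes = sorted(positions)
    if len(genomes) == 1:
        classification = "single"
    else:
        pair_dists = [
            dist(g1, positions[g1], g2, positions[g2])
            for i, g1 in enumerate(genomes)
            for g2 in genomes[i + 1 :]
        ]
        if all(d <= tolerance for d in pair_dists):
            classification = "strict"
        elif any(d <= tolerance for d in pair_dists):
            classification = "partial"
        else:
            classification = "random"
    return ColocalizationCall(
        family_id=family.family_id,
        positions=positions,
        classification=classification,
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class FamilyCensus:
    """Counts describing a family collection, mirroring a shared/unique,
    known/unknown and co-localization-class breakdown."""

    total_occurrences: int
    distinct_families: int
    shared_families: int
    unique_families: int
    known_families: int
    unknown_families: int
    group_exclusive_families: int
    group_exclusive_unknown: int
    coloc_class_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "total_occurrences": self.total_occurrences,
            "distinct_families": self.distinct_families,
            "shared_families": self.shared_families,
            "unique_families": self.unique_families,
            "known_families": self.known_families,
            "unknown_families": self.unknown_families,
            "group_exclusive_families": self.group_exclusive_families,
            "group_exclusive_unknown": self.group_exclusive_unknown,
            "coloc_class_counts": dict(self.coloc_class_counts),
        }


def family_census(
    families: Sequence[SMGCFamily],
    group_labels: Mapping[str, str],
    focal_group: str = "red_sea",
    coloc_calls: Sequence[ColocalizationCall] = (),
) -> FamilyCensus:
    """Census of a family collection.

    Every member genome must carry a group label. Group-exclusive families
    are those whose species set lies entirely in the focal group.
    Co-localization class counts cover the supplied calls for multi-species
    families (single-species calls are tallied under "single").
    """
    for fam in families:
        for g in fam.species_set:
            if g not in group_labels:
                raise KeyError(f"genome {g} has no group label")
    shared = sum(1 for f in families if f.is_shared)
    unique = sum(1 for f in families if not f.is_shared)
    known = sum(1 for f in families if f.known_product)
    exclusive = [
        f
        for f in families
        if all(group_labels[g] == focal_group for g in f.species_set)
    ]
    class_counts: dict[str, int] = {}
    for call in coloc_calls:
        class_counts[call.classification] = class_counts.get(call.classification, 0) + 1
    return FamilyCensus(
        total_occurrences=sum(len(f.members) for f in families),
        distinct_families=len(families),
        shared_families=shared,
        unique_families=unique,
        known_families=known,
        unknown_families=len(families) - known,
        group_exclusive_families=len(exclusive),
        group_exclusive_unknown=sum(1 for f in exclusive if not f.known_product),
        coloc_class_counts=class_counts,
    )


# ---------------------------------------------------------------------------
# TSV interchange (antiSMASH-derived exports)

def read_smgc_tsv(path: str | Path) -> list[SMGC]:
    """Read (smgc_id, genome, replicon, start, end, class, product, gene_ids)
    rows; gene_ids comma-separated; coordinates 0-based half-open."""
    df = pd.read_csv(path, sep="\t", comment="#").fillna("")
    return [
        SMGC(
            smgc_id=str(r.smgc_id),
            genome_id=str(r.genome),
            replicon_id=str(r.replicon),
            start=int(r.start),
            end=int(r.end),
            gene_ids=tuple(str(r.gene_ids).split(",")),
            predicted_class=str(getattr(r, "predicted_class", "")),
            product=str(getattr(r, "product", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_smgc_tsv(path: str | Path, smgcs: Sequence[SMGC]) -> None:
    pd.DataFrame(
        [
            (
                c.smgc_id,
                c.genome_id,
                c.replicon_id,
                c.start,
                c.end,
                c.predicted_class,
                c.product,
                ",".join(c.gene_ids),
            )
            for c in smgcs
        ],
        columns=[
            "smgc_id", "genome", "replicon", "start", "end",
            "predicted_class", "product", "gene_ids",
        ],
    ).to_csv(path, sep="\t", index=False)


def family_table(families: Sequence[SMGCFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for m in fam.members:
            rows.append(
                (fam.family_id, m.smgc_id, m.genome_id, m.predicted_class,
                 fam.known_product)
            )
    return pd.DataFrame(
        rows, columns=["family", "smgc", "genome", "predicted_class", "known_product"]
    )


def colocalization_table(calls: Sequence[ColocalizationCall]) -> pd.DataFrame:
    rows = [
        (c.family_id, g, pos, c.classification, c.tolerance)
        for c in calls
        for g, pos in sorted(c.positions.items())
    ]
    return pd.DataFrame(
        rows, columns=["family", "genome", "normalized_position", "class", "tolerance"]
    )
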