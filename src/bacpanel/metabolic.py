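"""Species x reaction presence/absence matrices and their comparative analysis.

The reaction repertoire of each species is inferred by enzyme-sequence
homology against a reaction catalog (see :mod:`bacpanel.homology`), giving a
boolean species x reaction matrix. Species are clustered on these binary
profiles (Jaccard distance, average linkage by default) into "metabolic
clades"; each (reaction, clade) pair is then tested for over- and
under-representation with an exact one-sided binomial test against the
presence fraction among the other included species, at a raw significance
threshold (default 1e-5, no multiple-testing correction — an optional
Bonferroni factor is available). Group-specific reactions, group mean
comparisons, pathway roll-ups and clade-vs-phylogeny concordance complete
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import binom

from .homology import DEFAULT_BIT_MIN, ReactionCatalog, call_reaction_presence
from .scoring import ScoreProvider

DEFAULT_ALPHA = 1e-5


@dataclass(frozen=True)
class NetworkSummary:
    """Per-species metabolic network summary."""

    species_id: str
    n_reactions: int
    n_metabolites: int
    n_genes_used: int


@dataclass
class ReactionMatrix:
    """Boolean species x reaction matrix with per-species summaries."""

    presence: pd.DataFrame  # bool, index=species, columns=reactions
    summaries: dict[str, NetworkSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)

    @property
    def species_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.presence.columns)

    def row_sum(self, species_id: str) -> int:
        return int(self.presence.loc[species_id].sum())

    def prune_absent(self) -> "ReactionMatrix":
        """Drop reactions absent from every species."""
        keep = self.presence.any(axis=0)
        return ReactionMatrix(self.presence.loc[:, keep], dict(self.summaries))

    def to_tsv(self, path: str | Path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReactionMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="species")
        return cls(df.astype(bool))


def build_matrix(
    proteomes: Mapping[str, Mapping[str, str]],
    catalog: ReactionCatalog,
    provider: ScoreProvider,
    bit_min: float = DEFAULT_BIT_MIN,
    prune_absent: bool = False,
) -> ReactionMatrix:
    """Call every reaction of the catalog in every proteome.

    Summaries count, per species, the present reactions, the union of their
    metabolite sets, and the distinct proteome sequences supporting at least
    one present reaction.
    """
    if not catalog.reactions:
        raise ValueError("empty reaction catalog")
    species = sorted(proteomes)
    reactions = catalog.reaction_ids
    data = np.zeros((len(species), len(reactions)), dtype=bool)
    summaries: dict[str, NetworkSummary] = {}
    for i, sp in enumerate(species):
        if not proteomes[sp]:
            raise ValueError(f"species {sp}: empty proteome")
        metabolites: set[str] = set()
        genes_used: set[str] = set()
        for j, rid in enumerate(reactions):
            present, hit = call_reaction_presence(
                rid, catalog, proteomes[sp], provider, bit_min=bit_min
            )
            data[i, j] = present
            if present:
                metabolites |= catalog.reactions[rid].metabolite_ids
                if hit is not None:
                    genes_used.add(hit.subject_id)
        summaries[sp] = NetworkSummary(
            species_id=sp,
            n_reactions=int(data[i].sum()),
            n_metabolites=len(metabolites),
            n_genes_used=len(genes_used),
        )
    matrix = ReactionMatrix(
        pd.DataFrame(data, index=species, columns=reactions), summaries
    )
    return matrix.prune_absent() if prune_absent else matrix


def summarize_networks(
    matrix: ReactionMatrix, catalog: ReactionCatalog
) -> dict[str, NetworkSummary]:
    """Recompute per-species summaries from a bare matrix and a catalog
    (gene counts unavailable without the supporting hits: reported as 0)."""
    out = {}
    for sp in matrix.species_ids:
        present = matrix.presence.loc[sp]
        mets: set[str] = set()
        for rid in matrix.reaction_ids:
            if present[rid] and rid in catalog.reactions:
                mets |= catalog.reactions[rid].metabolite_ids
        out[sp] = NetworkSummary(sp, int(present.sum()), len(mets), 0)
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Deterministic agglomerative clustering of species on binary profiles."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def cluster_species(
    matrix: ReactionMatrix,
    distance: str = "jaccard",
    linkage: str = "average",
    exclude: Iterable[str] = (),
) -> Dendrogram:
    """Hierarchical clustering of species by reaction presence/absence.

    Species order is canonicalized (sorted ids) before computing distances,
    so the dendrogram is invariant to input order. Excluded species are left
    out of the clustering entirely.
    """
    excluded = set(exclude)
    labels = tuple(s for s in sorted(matrix.species_ids) if s not in excluded)
    if len(labels) < 2:
        raise ValueError("clustering requires >= 2 included species")
    X = matrix.presence.loc[list(labels)].to_numpy(dtype=bool)
    dists = pdist(X, metric=distance)
    Z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(linkage=Z, labels=labels)


@dataclass(frozen=True)
class CladePartition:
    """Assignment of included species to metabolic clades."""

    clade_of: dict[str, int]  # species -> clade id (1..k)
    excluded: dict[str, str]  # species -> reason

    @property
    def clade_ids(self) -> list[int]:
        return sorted(set(self.clade_of.values()))

    def members(self, clade_id: int) -> list[str]:
        return sorted(s for s, c in self.clade_of.items() if c == clade_id)


def cut_to_clades(
    dendrogram: Dendrogram,
    k: int,
    exclusions: Mapping[str, str] | None = None,
) -> CladePartition:
    """Cut the dendrogram into exactly k clades.

    Clade ids are renumbered 1..k in order of each clade's smallest species
    id, so the partition is stable across scipy versions. ``exclusions``
    documents species deliberately left out of the clustering.
    """
    n = len(dendrogram.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(
            f"dendrogram does not admit a cut into exactly {k} clades "
            f"(got {len(set(raw))})"
        )
    groups: dict[int, list[str]] = {}
    for label, c in zip(dendrogram.labels, raw):
        groups.setdefault(int(c), []).append(label)
    order = sorted(groups, key=lambda c: min(groups[c]))
    clade_of = {
        s: new_id
        for new_id, c in enumerate(order, start=1)
        for s in groups[c]
    }
    exclusions = dict(exclusions or {})
    overlap = set(exclusions) & set(clade_of)
    if overlap:
        raise ValueError(f"excluded species present in dendrogram: {sorted(overlap)}")
    return CladePartition(clade_of=clade_of, excluded=exclusions)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One reaction x clade binomial test."""

    reaction_id: str
    clade_id: int
    k: int  # presences in the clade
    n: int  # clade size
    p_bg: float  # presence fraction among included non-clade species
    p_over: float  # P(X >= k), X ~ Binomial(n, p_bg)
    p_under: float  # P(X <= k)
    call: str  # over / under / none


def binomial_enrichment(
    matrix: ReactionMatrix,
    partition: CladePartition,
    alpha: float = DEFAULT_ALPHA,
    bonferroni: bool = False,
) -> list[EnrichmentRecord]:
    """Exact one-sided binomial tests for every (reaction, clade) pair.

    The background rate is the presence fraction among the *included*
    non-clade species; excluded species contribute nothing. Degenerate
    backgrounds (0 or 1) are handled exactly, without pseudocounts. With
    ``bonferroni`` the threshold is divided by the number of tests.
    """
    included = sorted(partition.clade_of)
    sub = matrix.presence.loc[included]
    records: list[EnrichmentRecord] = []
    clades = partition.clade_ids
    threshold = alpha / (len(clades) * len(matrix.reaction_ids)) if bonferroni else alpha
    for clade_id in clades:
        members = partition.members(clade_id)
        others = [s for s in included if partition.clade_of[s] != clade_id]
        if not others:
            raise ValueError(f"clade {clade_id}: empty background group")
        n = len(members)
        in_clade = sub.loc[members].to_numpy(dtype=bool)
        in_bg = sub.loc[others].to_numpy(dtype=bool)
        k_vec = in_clade.sum(axis=0)
        p_bg_vec = in_bg.mean(axis=0)
        p_over_vec = binom.sf(k_vec - 1, n, p_bg_vec)
        p_under_vec = binom.cdf(k_vec, n, p_bg_vec)
        for rid, k, p_bg, p_over, p_under in zip(
            matrix.reaction_ids, k_vec, p_bg_vec, p_over_vec, p_under_vec
        ):
            if p_over <= threshold:
                call = "over"
            elif p_under <= threshold:
                call = "under"
            else:
                call = "none"
            records.append(
                EnrichmentRecord(
                    reaction_id=rid,
                    clade_id=clade_id,
                    k=int(k),
                    n=n,
                    p_bg=float(p_bg),
                    p_over=float(p_over),
                    p_under=float(p_under),
                    call=call,
                )
            )
    return records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.reaction_id, r.clade_id, r.k, r.n, r.p_bg, r.p_over, r.p_under, r.call)
            for r in records
        ],
        columns=["reaction", "clade", "k", "n", "p_bg", "p_over", "p_under", "call"],
    )


def group_specific_reactions(
    matrix: ReactionMatrix,
    focal_group: Iterable[str],
    presence_min: float = 0.75,
    absence_min: float = 0.90,
) -> list[str]:
    """Reactions present in >= presence_min of the focal group and absent in
    >= absence_min of the complement (inclusive comparisons)."""
    focal = sorted(set(focal_group))
    others = sorted(set(matrix.species_ids) - set(focal))
    if not others:
        raise ValueError("focal group must be a proper subset of the panel")
    unknown = set(focal) - set(matrix.species_ids)
    if unknown:
        raise ValueError(f"focal species not in matrix: {sorted(unknown)}")
    pres = matrix.presence.loc[focal].mean(axis=0)
    absent = 1.0 - matrix.presence.loc[others].mean(axis=0)
    keep = (pres >= presence_min) & (absent >= absence_min)
    return [rid for rid in matrix.reaction_ids if keep[rid]]


@dataclass(frozen=True)
class GroupComparison:
    mean_reactions_a: float
    mean_reactions_b: float
    mean_metabolites_a: float | None
    mean_metabolites_b: float | None

    @property
    def reaction_difference(self) -> float:
        return self.mean_reactions_a - self.mean_reactions_b

    @property
    def metabolite_difference(self) -> float | None:
        if self.mean_metabolites_a is None or self.mean_metabolites_b is None:
            return None
        return self.mean_metabolites_a - self.mean_metabolites_b


def compare_groups(
    matrix: ReactionMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> GroupComparison:
    """Mean reaction (and, when summaries exist, metabolite) counts of two
    disjoint species groups and their differences."""
    a, b = sorted(set(group_a)), sorted(set(group_b))
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")

    def mean_reactions(group: list[str]) -> float:
        return float(matrix.presence.loc[group].sum(axis=1).mean())

    def mean_metabolites(group: list[str]) -> float | None:
        if not all(s in matrix.summaries for s in group):
            return None
        return float(np.mean([matrix.summaries[s].n_metabolites for s in group]))

    return GroupComparison(
        mean_reactions_a=mean_reactions(a),
        mean_reactions_b=mean_reactions(b),
        mean_metabolites_a=mean_metabolites(a),
        mean_metabolites_b=mean_metabolites(b),
    )


def pathway_rollup(
    records: Sequence[EnrichmentRecord], catalog: ReactionCatalog
) -> pd.DataFrame:
    """Roll called reactions up to pathways: counts per (pathway, clade,
    direction), sorted by clade, descending count, pathway id."""
    rows = []
    for r in records:
        if r.call == "none":
            continue
        if r.reaction_id not in catalog.reactions:
            raise KeyError(f"reaction {r.reaction_id} absent from catalog")
        rows.append((catalog.reactions[r.reaction_id].pathway_id, r.clade_id, r.call))
    if not rows:
        return pd.DataFrame(columns=["pathway", "clade", "call", "n_reactions"])
    df = pd.DataFrame(rows, columns=["pathway", "clade", "call"])
    out = (
        df.groupby(["pathway", "clade", "call"], sort=False)
        .size()
        .reset_index(name="n_reactions")
    )
    return out.sort_values(
        ["clade", "n_reactions", "pathway", "call"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def clade_tree_concordance(
    partition: CladePartition,
    tree: "str | dendropy.Tree",
) -> dict[int, bool]:
    """Monophyly of each metabolic clade on a species tree.

    The tree is pruned to the included species first; a clade is concordant
    iff its members form a monophyletic group in the pruned tree. Species
    missing from the tree are a hard error (named).
    """
    if isinstance(tree, str):
        if tree.lstrip().startswith("("):
            t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
        else:
            t = dendropy.Tree.get(path=tree, schema="newick", preserve_underscores=True)
    else:
        t = tree
    t.is_rooted = True  # monophyly is evaluated on the rooted topology
    leaf_labels = {x.taxon.label for x in t.leaf_node_iter()}
    included = set(partition.clade_of)
    missing = included - leaf_labels
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    pruned = t.extract_tree_with_taxa_labels(labels=included)
    result: dict[int, bool] = {}
    for clade_id in partition.clade_ids:
        members = set(partition.members(clade_id))
        if len(members) == 1:
            result[clade_id] = True
            continue
        mrca = pruned.mrca(taxon_labels=members)
        under = {x.taxon.label for x in mrca.leaf_iter()}
        result[clade_id] = under == members
    return result
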