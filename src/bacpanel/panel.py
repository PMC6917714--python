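"""Panel-level statistics: size/ORF/rRNA summaries, GI coverage, quartile ranking.

These are the operations behind the panel summary table (strain, genome size,
ORF and rRNA counts) and the genomic-island accounting table (GI %, genes in
GIs, biosynthetic genes in GIs) of a multi-strain comparative study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    GenomeStats,
    GICoverage,
    IntervalSet,
    PanelSummary,
    features_overlapping,
    merge_intervals,
)


def genome_stats(genome: GenomeRecord, features: Sequence[GeneFeature]) -> GenomeStats:
    """Per-genome statistics: size = summed replicon length, ORFs = CDS count."""
    return GenomeStats(
        genome_id=genome.genome_id,
        size_bp=genome.size,
        n_orfs=sum(f.kind is FeatureKind.CDS for f in features),
        n_rrna=sum(f.kind is FeatureKind.rRNA for f in features),
    )


def summarize_stats(stats: Sequence[GenomeStats]) -> PanelSummary:
    """Arithmetic means and ranges over per-genome statistics."""
    if not stats:
        raise ValueError("empty panel")
    sizes = [s.size_bp for s in stats]
    orfs = [s.n_orfs for s in stats]
    rrnas = [s.n_rrna for s in stats]
    n = len(stats)
    return PanelSummary(
        n_genomes=n,
        mean_genome_size=sum(sizes) / n,
        mean_orf_count=sum(orfs) / n,
        mean_rrna_count=sum(rrnas) / n,
        min_genome_size=min(sizes),
        max_genome_size=max(sizes),
        min_orf_count=min(orfs),
        max_orf_count=max(orfs),
        min_rrna_count=min(rrnas),
        max_rrna_count=max(rrnas),
    )


def summarize_panel(
    panel: Sequence[tuple[GenomeRecord, Sequence[GeneFeature]]],
) -> PanelSummary:
    """Summary statistics over a panel of annotated genomes."""
    if not panel:
        raise ValueError("empty panel")
    return summarize_stats([genome_stats(g, feats) for g, feats in panel])


def gi_coverage(
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    islands: Sequence[IntervalSet],
    biosynthetic_gene_ids: frozenset[str] | set[str] = frozenset(),
    min_overlap_fraction: float = 0.0,
) -> GICoverage:
    """Genomic-island coverage for one genome.

    gi_bp is the bp covered by the merged islands over all replicons;
    gi_percent relates it to the summed replicon length. A gene is "in a GI"
    iff it overlaps any island by >= 1 bp (tighten with
    ``min_overlap_fraction``). ``biosynthetic_gene_ids`` marks the subset of
    features belonging to biosynthetic gene clusters.
    """
    by_replicon: dict[str, list[tuple[int, int]]] = {}
    for iset in islands:
        rep = genome.replicon(iset.replicon_id)
        iset.check_bounds(rep)
        by_replicon.setdefault(iset.replicon_id, []).extend(iset.intervals)

    gi_bp = sum(
        e - s for ivs in by_replicon.values() for s, e in merge_intervals(ivs)
    )
    in_gi = features_overlapping(features, by_replicon, min_overlap_fraction)
    gene_ids = tuple(sorted(f.feature_id for f in in_gi))
    bio = frozenset(biosynthetic_gene_ids)
    n_genes = len(features)
    return GICoverage(
        genome_id=genome.genome_id,
        gi_bp=gi_bp,
        gi_percent=100.0 * gi_bp / genome.size,
        genes_in_gi=len(in_gi),
        pct_genes_in_gi=(100.0 * len(in_gi) / n_genes) if n_genes else 0.0,
        biosynthetic_genes_in_gi=len(set(gene_ids) & bio),
        gene_ids_in_gi=gene_ids,
    )


@dataclass(frozen=True)
class QuartileRanking:
    """Quartile split of a panel by GI percentage."""

    quartile_of: dict[str, int]  # strain -> 1..4 (1 = lowest GI %)
    counts: tuple[int, int, int, int]
    n_above_reference: int | None = None

    def strains_in(self, *quartiles: int) -> list[str]:
        return sorted(s for s, q in self.quartile_of.items() if q in quartiles)


def rank_gi_percent(
    panel_values: Sequence[tuple[str, float]],
    reference_mean: float | None = None,
    subgroup: Iterable[str] | None = None,
) -> QuartileRanking:
    """Rank strains by GI percentage into four near-equal quartile groups.

    Strains are sorted ascending by value (ties broken by strain id, the
    lexicographically smaller id landing in the lower quartile) and split into
    four groups whose sizes differ by at most one. If ``reference_mean`` is
    given, also counts how many strains of ``subgroup`` (default: all) lie
    strictly above it.
    """
    if len(panel_values) < 4:
        raise ValueError("quartile ranking requires >= 4 strains")
    order = sorted(panel_values, key=lambda sv: (sv[1], sv[0]))
    n = len(order)
    base, extra = divmod(n, 4)
    sizes = [base + (1 if q < extra else 0) for q in range(4)]
    quartile_of: dict[str, int] = {}
    i = 0
    for q, size in enumerate(sizes, start=1):
        for strain, _ in order[i : i + size]:
            quartile_of[strain] = q
        i += size
    n_above = None
    if reference_mean is not None:
        group = set(subgroup) if subgroup is not None else {s for s, _ in panel_values}
        n_above = sum(1 for s, v in panel_values if s in group and v > reference_mean)
    return QuartileRanking(
        quartile_of=quartile_of, counts=tuple(sizes), n_above_reference=n_above
    )


def panel_gene_overlap(
    features: Sequence[GeneFeature],
    homology_hits: Mapping[str, Sequence],
    reference_gene_ids: Iterable[str],
) -> list[str]:
    """Feature ids with a qualifying homology hit to any reference gene.

    ``homology_hits`` maps feature id -> hits (objects with a ``subject_id``);
    a feature qualifies if any hit's subject is in the reference set. Result
    is sorted (deterministic) and duplicate-free.
    """
    ref = set(reference_gene_ids)
    matched = {
        f.feature_id
        for f in features
        if any(h.subject_id in ref for h in homology_hits.get(f.feature_id, ()))
    }
    return sorted(matched)
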