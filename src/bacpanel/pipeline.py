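"""End-to-end orchestration over an on-disk panel directory.

A "panel directory" holds the inputs the pipeline consumes — per-genome
GFF3/FASTA/proteome files, island interval calls, SMGC interval+gene-list
exports, a reaction catalog with enzyme sequences, a trait-gene panel with
its reference proteome, optionally a species tree and a planted-truth
record. :func:`simulate_panel` writes exactly this layout. Each ``stage_*``
function is a thin, typed wrapper over the library; :func:`run_all` chains
them and writes the report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .homology import (
    DEFAULT_BIT_MIN,
    DEFAULT_E_MAX,
    ReactionCatalog,
    TraitPanel,
    TraitProfile,
    trait_profile,
)
from .metabolic import (
    DEFAULT_ALPHA,
    CladePartition,
    Dendrogram,
    EnrichmentRecord,
    ReactionMatrix,
    binomial_enrichment,
    build_matrix,
    clade_tree_concordance,
    cluster_species,
    cut_to_clades,
    enrichment_table,
    group_specific_reactions,
)
from .model import GeneFeature, GenomeRecord, IntervalSet, GICoverage
from .panel import genome_stats, gi_coverage, summarize_panel
from .scoring import LocalAlignmentScorer, ScoreProvider
from .simulate import SyntheticTruth, truth_check
from .smgc import (
    DEFAULT_COLOC_TOLERANCE,
    DEFAULT_SIM_MIN,
    SMGC,
    ColocalizationCall,
    SMGCFamily,
    assign_products,
    build_families,
    classify_colocalization,
    colocalization_table,
    family_census,
    family_table,
    read_smgc_tsv,
)


@dataclass
class Thresholds:
    """The pipeline's threshold set, recorded in every output header."""

    bit_min: float = DEFAULT_BIT_MIN
    e_max: float = DEFAULT_E_MAX
    alpha: float = DEFAULT_ALPHA
    sim_min: float = DEFAULT_SIM_MIN
    presence_min: float = 0.75
    absence_min: float = 0.90
    coloc_tolerance: float = DEFAULT_COLOC_TOLERANCE
    k_clades: int = 3

    def header(self) -> list[str]:
        return [
            f"bit_min={self.bit_min} e_max={self.e_max} alpha={self.alpha}",
            f"sim_min={self.sim_min} presence_min={self.presence_min} "
            f"absence_min={self.absence_min} coloc_tolerance={self.coloc_tolerance} "
            f"k_clades={self.k_clades}",
        ]


@dataclass
class LoadedPanel:
    genomes: list[GenomeRecord]
    features: dict[str, list[GeneFeature]]
    proteomes: dict[str, dict[str, str]]
    group_labels: dict[str, str]
    islands: dict[str, list[IntervalSet]]
    smgcs: list[SMGC]
    reference_clusters: list[SMGC]
    reference_cluster_seqs: dict[str, str]
    catalog: ReactionCatalog
    trait_panel: TraitPanel
    reference_proteome: dict[str, str]
    tree_newick: str | None = None
    truth: SyntheticTruth | None = None

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def genome(self, gid: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == gid:
                return g
        raise KeyError(gid)

    @property
    def gene_sequences(self) -> dict[str, str]:
        merged: dict[str, str] = {}
        for prot in self.proteomes.values():
            merged.update(prot)
        return merged

    @property
    def biosynthetic_gene_ids(self) -> set[str]:
        return {g for c in self.smgcs for g in c.gene_ids}

    def replicon_info(self) -> dict[str, tuple[int, bool]]:
        """genome -> (chromosome length, circular) for co-localization."""
        return {
            g.genome_id: (g.chromosome.length, g.chromosome.circular)
            for g in self.genomes
        }


def load_panel(panel_dir: str | Path) -> LoadedPanel:
    """Read a panel directory (the layout :func:`simulate_panel` writes)."""
    d = Path(panel_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"panel directory not found: {d}")
    meta = pd.read_csv(d / "panel.tsv", sep="\t")
    genomes, features, proteomes, group_labels = [], {}, {}, {}
    for row in meta.itertuples(index=False):
        gid = str(row.genome)
        genome, feats = pio.read_genome(
            d / f"{gid}.gff3", d / f"{gid}.fna", genome_id=gid,
            species_label=str(row.species),
        )
        genomes.append(genome)
        features[gid] = feats
        proteomes[gid] = pio.read_fasta(d / f"{gid}.faa")
        group_labels[gid] = str(row.group)
    islands = pio.read_interval_tsv(d / "islands.tsv") if (d / "islands.tsv").exists() else {}
    smgcs = read_smgc_tsv(d / "smgc.tsv") if (d / "smgc.tsv").exists() else []
    ref_clusters, ref_seqs = [], {}
    if (d / "reference_clusters.tsv").exists():
        ref_clusters = read_smgc_tsv(d / "reference_clusters.tsv")
        ref_seqs = pio.read_fasta(d / "reference_clusters.faa")
    catalog = ReactionCatalog.from_tsv(
        d / "catalog.tsv", pio.read_fasta(d / "enzymes.faa")
    )
    tp_df = pd.read_csv(d / "trait_panel.tsv", sep="\t")
    trait_panel = TraitPanel(
        panel_name="panel",
        genes=tuple(
            (str(r.gene_name), str(r.reference_protein_id))
            for r in tp_df.itertuples(index=False)
        ),
        required_genes=frozenset(
            str(r.gene_name) for r in tp_df.itertuples(index=False)
            if str(r.required) == "yes"
        ),
    )
    reference_proteome = pio.read_fasta(d / "reference_proteome.faa")
    tree = (d / "tree.nwk").read_text().strip() if (d / "tree.nwk").exists() else None
    truth = (
        SyntheticTruth.from_dict(pio.read_json(d / "truth.json"))
        if (d / "truth.json").exists()
        else None
    )
    return LoadedPanel(
        genomes=genomes,
        features=features,
        proteomes=proteomes,
        group_labels=group_labels,
        islands=islands,
        smgcs=smgcs,
        reference_clusters=ref_clusters,
        reference_cluster_seqs=ref_seqs,
        catalog=catalog,
        trait_panel=trait_panel,
        reference_proteome=reference_proteome,
        tree_newick=tree,
        truth=truth,
    )


# --------------------------------------------------------------------------
# stages

def stage_summarize(panel: LoadedPanel) -> tuple[pd.DataFrame, dict]:
    stats = [genome_stats(g, panel.features[g.genome_id]) for g in panel.genomes]
    summary = summarize_panel(
        [(g, panel.features[g.genome_id]) for g in panel.genomes]
    )
    df = pd.DataFrame(
        [(s.genome_id, s.size_bp, s.n_orfs, s.n_rrna) for s in stats],
        columns=["genome", "size_bp", "n_orfs", "n_rrna"],
    )
    return df, summary.__dict__


def stage_gi(panel: LoadedPanel) -> list[GICoverage]:
    bio = panel.biosynthetic_gene_ids
    out = []
    for g in panel.genomes:
        out.append(
            gi_coverage(
                g,
                panel.features[g.genome_id],
                panel.islands.get(g.genome_id, []),
                biosynthetic_gene_ids=bio,
            )
        )
    return out


def gi_table(coverages: Sequence[GICoverage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.genome_id, c.gi_bp, round(c.gi_percent, 4), c.genes_in_gi,
             round(c.pct_genes_in_gi, 4), c.biosynthetic_genes_in_gi)
            for c in coverages
        ],
        columns=["genome", "gi_bp", "gi_percent", "genes_in_gi",
                 "pct_genes_in_gi", "biosynthetic_genes_in_gi"],
    )


def stage_matrix(
    panel: LoadedPanel, provider: ScoreProvider, thresholds: Thresholds
) -> ReactionMatrix:
    return build_matrix(
        panel.proteomes, panel.catalog, provider, bit_min=thresholds.bit_min
    )


def stage_clades(
    matrix: ReactionMatrix,
    thresholds: Thresholds,
    exclusions: Mapping[str, str] | None = None,
) -> tuple[Dendrogram, CladePartition]:
    dendro = cluster_species(matrix, exclude=exclusions or {})
    partition = cut_to_clades(dendro, thresholds.k_clades, exclusions)
    return dendro, partition


def stage_enrich(
    matrix: ReactionMatrix, partition: CladePartition, thresholds: Thresholds
) -> list[EnrichmentRecord]:
    return binomial_enrichment(matrix, partition, alpha=thresholds.alpha)


def stage_specific(
    matrix: ReactionMatrix, panel: LoadedPanel, thresholds: Thresholds,
    focal_group: str = "red_sea",
) -> list[str]:
    focal = [g for g, lbl in panel.group_labels.items() if lbl == focal_group]
    return group_specific_reactions(
        matrix, focal,
        presence_min=thresholds.presence_min, absence_min=thresholds.absence_min,
    )


def stage_smgc(
    panel: LoadedPanel, provider: ScoreProvider, thresholds: Thresholds
) -> list[SMGCFamily]:
    families = build_families(
        panel.smgcs, panel.gene_sequences, provider,
        sim_min=thresholds.sim_min, bit_min=thresholds.bit_min,
    )
    if panel.reference_clusters:
        assign_products(
            families, panel.reference_clusters, panel.reference_cluster_seqs,
            panel.gene_sequences, provider,
            sim_min=thresholds.sim_min, bit_min=thresholds.bit_min,
        )
    return families


def stage_coloc(
    families: Sequence[SMGCFamily], panel: LoadedPanel, thresholds: Thresholds
) -> list[ColocalizationCall]:
    info = panel.replicon_info()
    calls = []
    for fam in families:
        call = classify_colocalization(fam, info, tolerance=thresholds.coloc_tolerance)
        if call is not None:
            calls.append(call)
    return calls


def stage_traits(
    panel: LoadedPanel, provider: ScoreProvider, thresholds: Thresholds
) -> dict[str, TraitProfile]:
    return {
        gid: trait_profile(
            gid, panel.proteomes[gid], panel.trait_panel,
            panel.reference_proteome, provider, e_max=thresholds.e_max,
        )
        for gid in panel.genome_ids
    }


def traits_table(profiles: Mapping[str, TraitProfile]) -> pd.DataFrame:
    rows = []
    for gid in sorted(profiles):
        p = profiles[gid]
        for gene, _ in sorted(p.presence.items()):
            rows.append(
                (gid, gene, int(p.presence[gene]), round(p.coverage[gene], 4),
                 round(p.completeness, 4),
                 int(gene in p.missing_required))
            )
    return pd.DataFrame(
        rows,
        columns=["genome", "gene", "present", "coverage", "completeness",
                 "missing_required"],
    )


def stage_concord(
    partition: CladePartition, panel: LoadedPanel
) -> dict[int, bool]:
    if panel.tree_newick is None:
        raise ValueError("panel has no species tree")
    return clade_tree_concordance(partition, panel.tree_newick)


# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    summary_table: pd.DataFrame
    panel_summary: dict
    gi_coverages: list[GICoverage]
    matrix: ReactionMatrix
    dendrogram: Dendrogram
    partition: CladePartition
    enrichment: list[EnrichmentRecord]
    specific_reactions: list[str]
    families: list[SMGCFamily]
    coloc_calls: list[ColocalizationCall]
    trait_profiles: dict[str, TraitProfile]
    concordance: dict[int, bool] | None
    census: dict
    recovery: dict | None = None


def run_all(
    panel_dir: str | Path,
    out_dir: str | Path,
    thresholds: Thresholds | None = None,
    provider: ScoreProvider | None = None,
    exclusions: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on a panel directory and write the report tables."""
    thresholds = thresholds or Thresholds()
    provider = provider or LocalAlignmentScorer()
    panel = load_panel(panel_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = thresholds.header()

    summary_df, summary = stage_summarize(panel)
    pio.write_table(out / "panel_summary.tsv", summary_df, hdr)
    covs = stage_gi(panel)
    pio.write_table(out / "gi_coverage.tsv", gi_table(covs), hdr)
    matrix = stage_matrix(panel, provider, thresholds)
    matrix.presence.astype(int).to_csv(out / "matrix.tsv", sep="\t",
                                       index_label="species")
    dendro, partition = stage_clades(matrix, thresholds, exclusions)
    records = stage_enrich(matrix, partition, thresholds)
    pio.write_table(out / "enrichment.tsv", enrichment_table(records), hdr)
    specific = stage_specific(matrix, panel, thresholds)
    pio.write_table(
        out / "group_specific.tsv",
        pd.DataFrame({"reaction": specific}), hdr,
    )
    families = stage_smgc(panel, provider, thresholds)
    pio.write_table(out / "families.tsv", family_table(families), hdr)
    calls = stage_coloc(families, panel, thresholds)
    pio.write_table(out / "colocalization.tsv", colocalization_table(calls), hdr)
    profiles = stage_traits(panel, provider, thresholds)
    pio.write_table(out / "traits.tsv", traits_table(profiles), hdr)
    concordance = None
    if panel.tree_newick is not None:
        concordance = stage_concord(partition, panel)
        pio.write_table(
            out / "concordance.tsv",
            pd.DataFrame(
                sorted(concordance.items()), columns=["clade", "monophyletic"]
            ),
            hdr,
        )
    multi_calls = [c for c in calls if c.classification != "single"]
    census = family_census(
        families, panel.group_labels, focal_group="red_sea",
        coloc_calls=calls,
    ).to_dict()
    census["multi_species_classified"] = len(multi_calls)
    pio.write_json(out / "census.json", census)

    recovery = None
    if panel.truth is not None:
        recovery = truth_check(
            panel.truth,
            matrix=matrix,
            partition=partition,
            enrichment_records=records,
            families=families,
            coloc_calls=calls,
            trait_profiles=profiles,
            gi_coverages=covs,
        )
        pio.write_json(out / "recovery.json", recovery)

    return PipelineResult(
        summary_table=summary_df,
        panel_summary=summary,
        gi_coverages=covs,
        matrix=matrix,
        dendrogram=dendro,
        partition=partition,
        enrichment=records,
        specific_reactions=specific,
        families=families,
        coloc_calls=calls,
        trait_profiles=profiles,
        concordance=concordance,
        census=census,
        recovery=recovery,
    )
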