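"""Seeded synthetic-panel generator with planted ground truth.

Generates a panel of bacterial genomes with the statistical structure the
pipeline is designed to detect: clade-specific reaction repertoires on top
of a shared core, secondary-metabolite gene-cluster families placed at
controlled normalized chromosome positions (strict / partial / random
co-localization classes, with margins around the classification tolerance),
genomic islands overlapping biosynthetic genes, and trait-gene deletions
(e.g. the sporulation phosphorelay gene spo0B). Proteome homologs are
derived from ancestral sequences by uniform point mutation at a rate chosen
so that true homologs clear the bit-score threshold of the built-in scorer
by a wide margin while unrelated sequences stay far below it.

All randomness flows from one seeded generator; the same config and seed
produce byte-identical output files. Every planted signal is recorded in a
:class:`SyntheticTruth` so recovery can be asserted stage by stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import Reaction, ReactionCatalog, TraitPanel
from .io import write_fasta, write_gff3, write_interval_tsv, write_json
from .model import (
    FeatureKind,
    GeneFeature,
    GenomeRecord,
    IntervalLabel,
    IntervalSet,
    Replicon,
    SourceEnv,
    features_overlapping,
)
from .smgc import SMGC, write_smgc_tsv

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))

# SMGC blocks are confined to this normalized arc so they never collide with
# the linear gene run at the start of the chromosome
SAFE_ARC = (0.35, 0.97)
MIN_BLOCK_SEPARATION = 0.03

TRAIT_GENES = (
    "tatAd", "tatAy", "tatAc", "tatCd", "tatCy",
    "secA", "secY", "secE", "secG", "secDF",
    "spo0A", "spo0B",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel.

    Defaults emulate the study conditions the pipeline targets: clades with
    fully penetrant private reaction repertoires over a 5% background rate, a
    family census of 12 gene-cluster families (5 shared across species, 7
    unique, 3 exclusive to the focal group) with strict/partial/random
    placement classes at a 0.05 co-localization tolerance, and two genomes
    lacking spo0B.
    """

    seed: int = 0
    clade_sizes: tuple[int, ...] = (4, 4, 4)
    n_core_reactions: int = 12
    enriched_per_clade: int = 10
    n_noise_reactions: int = 15
    background_presence: float = 0.05
    enrichment_margin_alpha: float = 1e-5
    # SMGC families
    shared_family_classes: tuple[str, ...] = (
        "strict", "strict", "strict", "partial", "random"
    )
    n_unique_families: int = 7
    n_group_exclusive: int = 3
    genes_per_family: int = 4
    members_per_shared_family: int = 3
    coloc_tolerance: float = 0.05
    coloc_jitter: float = 0.012
    coloc_margin: float = 0.03
    # genome layout
    chromosome_length: int = 300_000
    gi_per_genome: int = 2
    gi_length: tuple[int, int] = (4_000, 10_000)
    n_rrna_per_genome: int = 3
    n_decoy_proteins: int = 8
    protein_length: tuple[int, int] = (120, 240)
    mutation_rate: float = 0.05
    # traits / tree
    trait_deletions: tuple[tuple[str, tuple[str, ...]], ...] | None = None
    discordant_clade_pairs: tuple[tuple[int, int], ...] = ((2, 3),)
    focal_clade: int = 1  # genomes of this clade carry the focal group label

    @property
    def n_species(self) -> int:
        return sum(self.clade_sizes)

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def clade_of(self) -> dict[str, int]:
        out, i = {}, 0
        for clade, size in enumerate(self.clade_sizes, start=1):
            for _ in range(size):
                out[f"sp{i + 1:02d}"] = clade
                i += 1
        return out

    def resolved_trait_deletions(self) -> dict[str, tuple[str, ...]]:
        if self.trait_deletions is not None:
            return {g: tuple(genes) for g, genes in self.trait_deletions}
        sp = self.species_ids()
        return {sp[-2]: ("spo0B",), sp[-1]: ("spo0B",)}

    def validate(self) -> None:
        if not self.clade_sizes or any(s < 1 for s in self.clade_sizes):
            raise ValueError("clade sizes must all be >= 1")
        if not (0.0 <= self.background_presence <= 1.0):
            raise ValueError("background_presence must be a probability")
        if self.coloc_jitter >= self.coloc_tolerance / 2:
            raise ValueError("coloc_jitter must be < tolerance/2 (margin guarantee)")
        arc = SAFE_ARC[1] - SAFE_ARC[0]
        step = self.coloc_tolerance + self.coloc_margin
        if self.members_per_shared_family * step >= arc:
            raise ValueError(
                "random-class placement infeasible: tolerance+margin too large "
                "for the usable arc"
            )
        n_blocks_worst = len(self.shared_family_classes) + self.n_unique_families
        if n_blocks_worst * MIN_BLOCK_SEPARATION >= arc:
            raise ValueError("too many gene-cluster blocks for the usable arc")
        for c1, c2 in self.discordant_clade_pairs:
            if not (1 <= c1 <= len(self.clade_sizes) and 1 <= c2 <= len(self.clade_sizes)):
                raise ValueError(f"discordant pair ({c1},{c2}) out of clade range")

    @classmethod
    def small(cls, seed: int = 0) -> "SimulationConfig":
        """Scaled-down panel for full sequence-level runs."""
        return cls(
            seed=seed,
            clade_sizes=(3, 3, 3),
            n_core_reactions=8,
            enriched_per_clade=5,
            n_noise_reactions=8,
            n_decoy_proteins=5,
        )

    @classmethod
    def panel32(cls, seed: int = 0) -> "SimulationConfig":
        """32-species panel (matrix-level analyses)."""
        return cls(
            seed=seed,
            clade_sizes=(5, 5, 5, 5, 4, 4, 4),
            n_core_reactions=40,
            enriched_per_clade=10,
            n_noise_reactions=60,
        )


@dataclass
class SyntheticTruth:
    """The planted ground truth of a synthetic panel."""

    clade_of: dict[str, int]
    group_labels: dict[str, str]
    enriched_reactions: dict[int, list[str]]  # clade -> reaction ids
    presence: dict[str, list[str]]  # species -> present reaction ids
    family_members: dict[str, list[str]]  # planted family -> smgc ids
    family_classes: dict[str, str]  # planted family -> strict/partial/random/single
    exclusive_families: list[str]
    known_products: dict[str, str]
    gi_biosynthetic_gene_ids: dict[str, list[str]]
    deleted_trait_genes: dict[str, list[str]]
    concordant_clades: dict[int, bool]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enriched_reactions"] = {str(k): v for k, v in d["enriched_reactions"].items()}
        d["concordant_clades"] = {str(k): v for k, v in d["concordant_clades"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            clade_of=dict(d["clade_of"]),
            group_labels=dict(d["group_labels"]),
            enriched_reactions={int(k): list(v) for k, v in d["enriched_reactions"].items()},
            presence={k: list(v) for k, v in d["presence"].items()},
            family_members={k: list(v) for k, v in d["family_members"].items()},
            family_classes=dict(d["family_classes"]),
            exclusive_families=list(d["exclusive_families"]),
            known_products=dict(d["known_products"]),
            gi_biosynthetic_gene_ids={k: list(v) for k, v in d["gi_biosynthetic_gene_ids"].items()},
            deleted_trait_genes={k: list(v) for k, v in d["deleted_trait_genes"].items()},
            concordant_clades={int(k): bool(v) for k, v in d["concordant_clades"].items()},
        )


@dataclass
class SyntheticPanel:
    """In-memory synthetic panel; :func:`write_panel` serializes it."""

    config: SimulationConfig
    genomes: list[GenomeRecord]
    features: dict[str, list[GeneFeature]]
    chromosomes: dict[str, str]
    proteomes: dict[str, dict[str, str]]
    catalog: ReactionCatalog
    presence: pd.DataFrame
    islands: dict[str, list[IntervalSet]]
    smgcs: list[SMGC]
    reference_clusters: list[SMGC]
    reference_cluster_seqs: dict[str, str]
    trait_panel: TraitPanel
    reference_proteome: dict[str, str]
    tree_newick: str
    truth: SyntheticTruth

    @property
    def gene_sequences(self) -> dict[str, str]:
        """All gene/protein sequences of the panel, keyed by feature id."""
        merged: dict[str, str] = {}
        for prot in self.proteomes.values():
            merged.update(prot)
        return merged


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        repl = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=int(hit.sum()))]
        arr[hit] = repl
    return "".join(arr)


def simulate_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Plant a presence/absence matrix directly (no sequences).

    Core reactions are present everywhere; each clade's enriched reactions
    are present in every clade member and, in background species, with
    probability ``background_presence`` — truncated so the background
    fraction keeps the exact binomial tail below ``enrichment_margin_alpha``
    (the margin that makes planted enrichments recoverable by construction);
    noise reactions are iid Bernoulli(background) everywhere.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    species = config.species_ids()
    clade_of = config.clade_of()
    n_clades = len(config.clade_sizes)

    core = [f"Rcore{i + 1:04d}" for i in range(config.n_core_reactions)]
    enriched = {
        c: [f"Rclade{c}e{i + 1:03d}" for i in range(config.enriched_per_clade)]
        for c in range(1, n_clades + 1)
    }
    noise = [f"Rnoise{i + 1:04d}" for i in range(config.n_noise_reactions)]
    reactions = core + [r for c in sorted(enriched) for r in enriched[c]] + noise

    df = pd.DataFrame(False, index=species, columns=reactions)
    df.loc[:, core] = True
    bg = config.background_presence
    for c in sorted(enriched):
        members = [s for s in species if clade_of[s] == c]
        others = [s for s in species if clade_of[s] != c]
        n_bg = len(others)
        # largest background count that keeps the exact over-representation
        # tail below alpha for a fully penetrant clade
        m_max = int(math.floor(n_bg * config.enrichment_margin_alpha ** (1.0 / len(members))))
        for rid in enriched[c]:
            df.loc[members, rid] = True
            m = min(int(rng.binomial(n_bg, bg)), m_max)
            if m > 0:
                carriers = rng.choice(n_bg, size=m, replace=False)
                df.loc[[others[i] for i in sorted(carriers)], rid] = True
    # noise reactions: iid Bernoulli(background), redrawn when the pattern is
    # wholly confined to one clade — such patterns make the estimated
    # background fraction exactly 0 and the exact binomial tail degenerate-
    # significant at any alpha, so they are excluded by construction (margin
    # guarantee; see the methods note)
    clade_arr = np.array([clade_of[s] for s in species])
    for rid in noise:
        row = rng.random(len(species)) < bg
        for _ in range(100):
            if not row.any() or len(set(clade_arr[row])) > 1:
                break
            row = rng.random(len(species)) < bg
        else:
            private = clade_arr[row][0]
            row[int(np.argmax(clade_arr != private))] = True
        df.loc[:, rid] = row
    return df, enriched


def _build_catalog(
    presence: pd.DataFrame,
    enriched: Mapping[int, Sequence[str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReactionCatalog:
    """Enzyme sequences and pathway/metabolite annotations for all reactions.

    Each clade's enriched reactions share a dedicated pathway (the planted
    pathway-rollup signal); core and noise reactions get generic pathways.
    """
    enriched_pathway = {
        rid: f"pw-clade{c}" for c, rids in enriched.items() for rid in rids
    }
    reactions: dict[str, Reaction] = {}
    enzyme_seqs: dict[str, str] = {}
    lo, hi = config.protein_length
    for j, rid in enumerate(presence.columns):
        n_enz = int(rng.integers(1, 4))  # 1-3 enzyme sequences per reaction
        ids = []
        for e in range(n_enz):
            eid = f"{rid}.enz{e + 1}"
            enzyme_seqs[eid] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            ids.append(eid)
        mets = frozenset(
            f"M{int(m) + 1:05d}" for m in rng.integers(0, 4 * len(presence.columns), size=int(rng.integers(2, 6)))
        )
        if rid in enriched_pathway:
            pathway = enriched_pathway[rid]
        elif rid.startswith("Rcore"):
            pathway = f"pw-core{j % 4 + 1}"
        else:
            pathway = f"pw-noise{j % 6 + 1}"
        reactions[rid] = Reaction(
            reaction_id=rid,
            enzyme_seq_ids=tuple(ids),
            metabolite_ids=mets,
            pathway_id=pathway,
        )
    return ReactionCatalog(reactions=reactions, enzyme_seqs=enzyme_seqs)


def _plant_family_positions(
    config: SimulationConfig,
    rng: np.random.Generator,
    members: Sequence[str],
    klass: str,
    used_positions: Mapping[str, list[float]],
) -> dict[str, float]:
    """Choose a normalized position per member genome, honouring the class
    margins and keeping blocks within one genome apart."""
    lo_arc, hi_arc = SAFE_ARC
    tol, jit, margin = config.coloc_tolerance, config.coloc_jitter, config.coloc_margin

    def ok(genome: str, pos: float) -> bool:
        return all(abs(pos - p) > MIN_BLOCK_SEPARATION for p in used_positions[genome])

    def draw(genome: str, lo: float, hi: float) -> float:
        for _ in range(500):
            pos = float(rng.uniform(lo, hi))
            if ok(genome, pos):
                return pos
        raise ValueError("infeasible config: cannot place gene-cluster block")

    positions: dict[str, float] = {}
    if klass in ("strict", "partial"):
        for _ in range(500):
            base = float(rng.uniform(lo_arc + tol, hi_arc - tol))
            cands = {g: base + float(rng.uniform(-jit, jit)) for g in members}
            if all(ok(g, p) for g, p in cands.items()):
                positions = cands
                break
        else:
            raise ValueError("infeasible config: cannot place co-localized family")
        if klass == "partial":
            outlier = members[-1]
            base = positions[members[0]]
            for _ in range(500):
                pos = draw(outlier, lo_arc, hi_arc)
                if abs(pos - base) > tol + margin and (1 - abs(pos - base)) > tol + margin:
                    positions[outlier] = pos
                    break
            else:
                raise ValueError("infeasible config: cannot displace partial outlier")
    elif klass == "random":
        placed: list[float] = []
        for g in members:
            for _ in range(500):
                pos = draw(g, lo_arc, hi_arc)
                if all(
                    abs(pos - p) > tol + margin and (1 - abs(pos - p)) > tol + margin
                    for p in placed
                ):
                    placed.append(pos)
                    positions[g] = pos
                    break
            else:
                raise ValueError("infeasible config: random-class placement failed")
    elif klass == "single":
        g = members[0]
        positions[g] = draw(g, lo_arc, hi_arc)
    else:
        raise ValueError(f"unknown family class {klass!r}")
    return positions


def synthesize(config: SimulationConfig) -> SyntheticPanel:
    """Generate the full panel in memory. Deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = config.species_ids()
    clade_of = config.clade_of()
    n_clades = len(config.clade_sizes)
    lo, hi = config.protein_length
    mu = config.mutation_rate

    presence, enriched = simulate_matrix(config, rng)
    catalog = _build_catalog(presence, enriched, config, rng)

    # --- reference strain: trait proteins + housekeeping ------------------
    reference_proteome: dict[str, str] = {}
    trait_ref_ids = {}
    for gene in TRAIT_GENES:
        ref_id = f"ref.{gene}"
        reference_proteome[ref_id] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        trait_ref_ids[gene] = ref_id
    for i in range(8):
        rid = f"ref.hk{i + 1:02d}"
        reference_proteome[rid] = _random_protein(rng, int(rng.integers(lo, hi + 1)))
    trait_panel = TraitPanel(
        panel_name="secretion_sporulation",
        genes=tuple((g, trait_ref_ids[g]) for g in TRAIT_GENES),
        required_genes=frozenset({"spo0B"}),
    )
    deletions = config.resolved_trait_deletions()

    # --- SMGC families ----------------------------------------------------
    focal_species = [s for s in species if clade_of[s] == config.focal_clade]
    other_species = [s for s in species if clade_of[s] != config.focal_clade]
    n_fam = len(config.shared_family_classes) + config.n_unique_families
    ancestral_genes: dict[str, list[tuple[str, str]]] = {}
    fam_keys = [f"pf{i + 1:02d}" for i in range(n_fam)]
    for key in fam_keys:
        ancestral_genes[key] = [
            (f"{key}.g{j + 1}", _random_protein(rng, int(rng.integers(max(lo, 150), hi + 1))))
            for j in range(config.genes_per_family)
        ]

    fam_members: dict[str, list[str]] = {}
    fam_class: dict[str, str] = {}
    fam_positions: dict[str, dict[str, float]] = {}
    used_positions: dict[str, list[float]] = {s: [] for s in species}

    shared_keys = fam_keys[: len(config.shared_family_classes)]
    for key, klass in zip(shared_keys, config.shared_family_classes):
        k = min(config.members_per_shared_family, len(species))
        # spread shared families across groups so none is accidentally exclusive
        picks = [focal_species[0]] if focal_species else []
        pool = [s for s in other_species if s not in picks]
        idx = rng.choice(len(pool), size=k - len(picks), replace=False)
        members = sorted(picks + [pool[i] for i in sorted(idx)])
        positions = _plant_family_positions(config, rng, members, klass, used_positions)
        for g, p in positions.items():
            used_positions[g].append(p)
        fam_members[key] = members
        fam_class[key] = klass
        fam_positions[key] = positions

    unique_keys = fam_keys[len(config.shared_family_classes):]
    exclusive_keys = []
    for i, key in enumerate(unique_keys):
        if i < config.n_group_exclusive:
            host = focal_species[i % len(focal_species)]
            exclusive_keys.append(key)
        else:
            host = other_species[(i - config.n_group_exclusive) % len(other_species)]
        positions = _plant_family_positions(config, rng, [host], "single", used_positions)
        used_positions[host].append(positions[host])
        fam_members[key] = [host]
        fam_class[key] = "single"
        fam_positions[key] = positions

    # reference cluster catalog: two characterized products
    known_products = {shared_keys[0]: "bacillibactin", unique_keys[0]: "fengycin"}
    reference_clusters: list[SMGC] = []
    reference_cluster_seqs: dict[str, str] = {}
    for key, product in sorted(known_products.items()):
        gene_ids = []
        for gid, seq in ancestral_genes[key]:
            rid = f"mibig.{gid}"
            reference_cluster_seqs[rid] = _mutate(seq, rng, mu)
            gene_ids.append(rid)
        span = sum(len(reference_cluster_seqs[g]) * 3 + 100 for g in gene_ids)
        reference_clusters.append(
            SMGC(
                smgc_id=f"mibig.{key}",
                genome_id="mibig",
                replicon_id="mibig",
                start=0,
                end=span,
                gene_ids=tuple(gene_ids),
                predicted_class="NRPS",
                product=product,
            )
        )

    # --- genomes: features, proteomes, SMGC blocks, GIs -------------------
    L = config.chromosome_length
    genomes: list[GenomeRecord] = []
    features: dict[str, list[GeneFeature]] = {}
    chromosomes: dict[str, str] = {}
    proteomes: dict[str, dict[str, str]] = {}
    islands: dict[str, list[IntervalSet]] = {}
    smgcs: list[SMGC] = []
    gi_bio_truth: dict[str, list[str]] = {}
    smgc_counter = 0

    source_cycle = [SourceEnv.mangrove_mud, SourceEnv.microbial_mat, SourceEnv.barren_soil]
    for si, sp in enumerate(species):
        rep_id = f"{sp}.chr"
        genome = GenomeRecord(
            genome_id=sp,
            species_label=f"Bacillus syntheticus {sp}",
            source_env=source_cycle[si % 3],
            replicons=[Replicon(rep_id, L, circular=True, is_chromosome=True)],
        )
        feats: list[GeneFeature] = []
        prot: dict[str, str] = {}

        # linear run: enzyme homologs for present reactions, traits, decoys
        cursor = 1_000
        def place_gene(fid: str, seq: str, kind: FeatureKind = FeatureKind.CDS,
                       product: str = "") -> None:
            nonlocal cursor
            glen = len(seq) * 3
            feats.append(GeneFeature(fid, rep_id, cursor, cursor + glen,
                                     strand="+" if len(feats) % 2 == 0 else "-",
                                     kind=kind, product=product))
            prot[fid] = seq
            cursor += glen + 200

        for rid in presence.columns:
            if not presence.at[sp, rid]:
                continue
            eid = catalog.reactions[rid].enzyme_seq_ids[0]
            place_gene(f"{sp}.{eid}", _mutate(catalog.enzyme_seqs[eid], rng, mu))
        deleted_here = set(deletions.get(sp, ()))
        for gene in TRAIT_GENES:
            if gene in deleted_here:
                continue
            place_gene(f"{sp}.{gene}", _mutate(reference_proteome[trait_ref_ids[gene]], rng, mu))
        for d in range(config.n_decoy_proteins):
            place_gene(f"{sp}.decoy{d + 1:02d}", _random_protein(rng, int(rng.integers(lo, hi + 1))))

        if cursor >= int(SAFE_ARC[0] * L) - 20_000:
            raise ValueError(
                "infeasible config: linear gene run collides with the "
                "gene-cluster arc; increase chromosome_length"
            )
        rrna_start = cursor + 5_000
        for r in range(config.n_rrna_per_genome):
            s = rrna_start + r * 4_000
            feats.append(GeneFeature(f"{sp}.rrna{r + 1}", rep_id, s, s + 2_900,
                                     strand="+", kind=FeatureKind.rRNA,
                                     product="ribosomal RNA"))

        # SMGC blocks at planted positions
        sp_smgc_gene_ids: list[str] = []
        first_block: tuple[int, int] | None = None
        for key in fam_keys:
            if sp not in fam_members[key]:
                continue
            pos = fam_positions[key][sp]
            genes = ancestral_genes[key]
            block_len = sum(len(seq) * 3 for _, seq in genes) + 100 * (len(genes) - 1)
            start = int(round(pos * L - block_len / 2))
            gcursor = start
            gene_ids = []
            for gid, seq in genes:
                fid = f"{sp}.{gid}"
                mseq = _mutate(seq, rng, mu)
                glen = len(mseq) * 3
                feats.append(GeneFeature(fid, rep_id, gcursor, gcursor + glen,
                                         strand="+", kind=FeatureKind.CDS,
                                         product="biosynthetic gene"))
                prot[fid] = mseq
                gene_ids.append(fid)
                gcursor += glen + 100
            end = gcursor - 100
            smgc_counter += 1
            smgcs.append(
                SMGC(
                    smgc_id=f"{sp}.smgc{smgc_counter:03d}",
                    genome_id=sp,
                    replicon_id=rep_id,
                    start=start,
                    end=end,
                    gene_ids=tuple(gene_ids),
                    predicted_class="NRPS" if key in known_products else "other",
                )
            )
            sp_smgc_gene_ids.extend(gene_ids)
            if first_block is None:
                first_block = (start, end)

        # genomic islands: the first overlaps the first SMGC block (if any)
        gi_intervals: list[tuple[int, int]] = []
        gmin, gmax = config.gi_length
        if first_block is not None:
            glen = int(rng.integers(gmin, gmax + 1))
            gi_start = max(0, first_block[0] + (first_block[1] - first_block[0]) // 3)
            gi_intervals.append((gi_start, min(L, gi_start + glen)))
        free_lo = rrna_start + config.n_rrna_per_genome * 4_000 + 2_000
        for g in range(config.gi_per_genome - len(gi_intervals)):
            glen = int(rng.integers(gmin, gmax + 1))
            s = free_lo + g * (gmax + 2_000)
            if s + glen >= int(SAFE_ARC[0] * L):
                break
            gi_intervals.append((s, s + glen))
        islands[sp] = [IntervalSet(rep_id, gi_intervals, IntervalLabel.GI)]

        in_gi = features_overlapping(feats, {rep_id: gi_intervals})
        gi_bio_truth[sp] = sorted(
            set(f.feature_id for f in in_gi) & set(sp_smgc_gene_ids)
        )

        seq = "".join(NUCLEOTIDES[rng.integers(0, 4, size=L)])
        genomes.append(genome)
        features[sp] = sorted(feats, key=lambda f: (f.start, f.feature_id))
        chromosomes[sp] = seq
        proteomes[sp] = dict(sorted(prot.items()))

    # --- species tree ------------------------------------------------------
    blocks = {c: [s for s in species if clade_of[s] == c] for c in range(1, n_clades + 1)}
    discordant: set[int] = set()
    for c1, c2 in config.discordant_clade_pairs:
        if c1 == c2 or not blocks[c1] or not blocks[c2]:
            continue
        blocks[c1][0], blocks[c2][0] = blocks[c2][0], blocks[c1][0]
        discordant |= {c1, c2}

    def block_nwk(members: list[str]) -> str:
        return members[0] if len(members) == 1 else "(" + ",".join(members) + ")"

    tree_newick = "(" + ",".join(block_nwk(blocks[c]) for c in sorted(blocks)) + ");"

    truth = SyntheticTruth(
        clade_of=clade_of,
        group_labels={
            s: ("red_sea" if clade_of[s] == config.focal_clade else "reference")
            for s in species
        },
        enriched_reactions={c: list(r) for c, r in enriched.items()},
        presence={
            s: [r for r in presence.columns if presence.at[s, r]] for s in species
        },
        family_members={
            k: sorted(c.smgc_id for c in smgcs if any(
                c.genome_id == m and c.gene_ids[0] == f"{c.genome_id}.{k}.g1"
                for m in fam_members[k]))
            for k in fam_keys
        },
        family_classes=dict(fam_class),
        exclusive_families=sorted(
            k for k in fam_keys
            if all(clade_of[m] == config.focal_clade for m in fam_members[k])
        ),
        known_products=dict(known_products),
        gi_biosynthetic_gene_ids=gi_bio_truth,
        deleted_trait_genes={g: sorted(v) for g, v in deletions.items()},
        concordant_clades={c: c not in discordant for c in range(1, n_clades + 1)},
    )

    return SyntheticPanel(
        config=config,
        genomes=genomes,
        features=features,
        chromosomes=chromosomes,
        proteomes=proteomes,
        catalog=catalog,
        presence=presence,
        islands=islands,
        smgcs=smgcs,
        reference_clusters=reference_clusters,
        reference_cluster_seqs=reference_cluster_seqs,
        trait_panel=trait_panel,
        reference_proteome=reference_proteome,
        tree_newick=tree_newick,
        truth=truth,
    )


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> None:
    """Serialize a panel to the formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for genome in panel.genomes:
        gid = genome.genome_id
        rep = genome.chromosome
        with open(out / f"{gid}.fna", "w") as fh:
            fh.write(f">{rep.replicon_id} circular=true chromosome=true\n")
            seq = panel.chromosomes[gid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        write_gff3(out / f"{gid}.gff3", genome, panel.features[gid])
        write_fasta(out / f"{gid}.faa", panel.proteomes[gid])
    write_interval_tsv(out / "islands.tsv", panel.islands)
    write_smgc_tsv(out / "smgc.tsv", panel.smgcs)
    write_smgc_tsv(out / "reference_clusters.tsv", panel.reference_clusters)
    write_fasta(out / "reference_clusters.faa", panel.reference_cluster_seqs)
    panel.catalog.to_tsv(out / "catalog.tsv")
    write_fasta(out / "enzymes.faa", panel.catalog.enzyme_seqs)
    write_fasta(out / "reference_proteome.faa", panel.reference_proteome)
    pd.DataFrame(
        [
            (g, rid, "yes" if g in panel.trait_panel.required_genes else "no")
            for g, rid in panel.trait_panel.genes
        ],
        columns=["gene_name", "reference_protein_id", "required"],
    ).to_csv(out / "trait_panel.tsv", sep="\t", index=False)
    panel.presence.astype(int).to_csv(out / "matrix.tsv", sep="\t", index_label="species")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(panel.tree_newick + "\n")
    write_json(out / "truth.json", panel.truth.to_dict())
    pd.DataFrame(
        [
            (g.genome_id, g.species_label, g.source_env.value,
             panel.truth.group_labels[g.genome_id])
            for g in panel.genomes
        ],
        columns=["genome", "species", "source", "group"],
    ).to_csv(out / "panel.tsv", sep="\t", index=False)


def simulate_panel(config: SimulationConfig, outdir: str | Path) -> SyntheticPanel:
    """Generate and write a synthetic panel; same seed => identical bytes."""
    panel = synthesize(config)
    write_panel(panel, outdir)
    return panel


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def truth_check(
    truth: SyntheticTruth,
    *,
    matrix=None,
    partition=None,
    enrichment_records=None,
    families=None,
    coloc_calls=None,
    trait_profiles=None,
    gi_coverages=None,
) -> dict:
    """Compare pipeline outputs against the planted truth, stage by stage.

    Any subset of outputs may be supplied; each present stage contributes a
    block of confusion counts plus precision/recall. Species ids must match
    the truth's panel (mismatches are a hard error).
    """
    report: dict = {}

    if matrix is not None:
        if set(matrix.species_ids) != set(truth.presence):
            raise ValueError("matrix species ids do not match the truth panel")
        tp = fp = fn = 0
        for sp in matrix.species_ids:
            called = {r for r in matrix.reaction_ids if matrix.presence.at[sp, r]}
            planted = set(truth.presence[sp])
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        report["matrix"] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": _safe_ratio(tp, tp + fp),
            "recall": _safe_ratio(tp, tp + fn),
        }

    clade_map: dict[int, int] = {}
    if partition is not None:
        unknown = set(partition.clade_of) - set(truth.clade_of)
        if unknown:
            raise ValueError(f"partition species not in truth panel: {sorted(unknown)}")
        for c in partition.clade_ids:
            members = partition.members(c)
            votes: dict[int, int] = {}
            for s in members:
                votes[truth.clade_of[s]] = votes.get(truth.clade_of[s], 0) + 1
            clade_map[c] = max(sorted(votes), key=lambda t: votes[t])
        truth_sets = {}
        for s, c in truth.clade_of.items():
            if s in partition.clade_of:
                truth_sets.setdefault(c, set()).add(s)
        found_sets = {frozenset(partition.members(c)) for c in partition.clade_ids}
        report["partition"] = {
            "exact_match": found_sets == {frozenset(v) for v in truth_sets.values()},
            "n_clades_found": len(partition.clade_ids),
            "n_clades_planted": len(set(truth.clade_of.values())),
        }

    if enrichment_records is not None:
        planted = {
            (c, rid) for c, rids in truth.enriched_reactions.items() for rid in rids
        }
        over_calls = set()
        n_false = 0
        for rec in enrichment_records:
            tclade = clade_map.get(rec.clade_id, rec.clade_id)
            if rec.call == "over":
                over_calls.add((tclade, rec.reaction_id))
            if rec.call != "none" and (tclade, rec.reaction_id) not in planted:
                n_false += 1
        tp = len(planted & over_calls)
        report["enrichment"] = {
            "planted": len(planted),
            "recovered": tp,
            "recall": _safe_ratio(tp, len(planted)),
            "false_calls": n_false,
            "n_tests": len(enrichment_records),
        }

    if families is not None:
        truth_by_members = {
            frozenset(m): key for key, m in truth.family_members.items() if m
        }
        matched: dict[str, str] = {}  # built family id -> truth key
        for fam in families:
            key = truth_by_members.get(frozenset(c.smgc_id for c in fam.members))
            if key is not None:
                matched[fam.family_id] = key
        n_truth = len(truth_by_members)
        fam_block = {
            "planted": n_truth,
            "exactly_recovered": len(matched),
            "recall": _safe_ratio(len(matched), n_truth),
        }
        if coloc_calls is not None:
            call_by_fam = {c.family_id: c.classification for c in coloc_calls}
            n_classified = n_correct = 0
            for fam_id, key in sorted(matched.items()):
                want = truth.family_classes[key]
                got = call_by_fam.get(fam_id)
                if got is None:
                    continue
                n_classified += 1
                n_correct += got == want
            fam_block["class_accuracy"] = _safe_ratio(n_correct, n_classified)
            fam_block["n_classified"] = n_classified
        if truth.exclusive_families is not None:
            want_excl = {
                frozenset(truth.family_members[k]) for k in truth.exclusive_families
            }
            got_excl = {
                frozenset(c.smgc_id for c in fam.members)
                for fam in families
                if all(truth.group_labels.get(g) == "red_sea" for g in fam.species_set)
            }
            fam_block["exclusive_match"] = want_excl == got_excl
        report["families"] = fam_block

    if trait_profiles is not None:
        tp = fn = fp = 0
        for genome, profile in sorted(trait_profiles.items()):
            deleted = set(truth.deleted_trait_genes.get(genome, ()))
            for gene, present in profile.presence.items():
                if gene in deleted:
                    tp += not present
                    fn += present
                else:
                    fp += not present
        report["traits"] = {
            "planted_deletions": sum(len(v) for v in truth.deleted_trait_genes.values()),
            "detected": tp,
            "missed": fn,
            "false_absences": fp,
            "recall": _safe_ratio(tp, tp + fn),
        }

    if gi_coverages is not None:
        tp = fp = fn = 0
        for cov in gi_coverages:
            planted = set(truth.gi_biosynthetic_gene_ids.get(cov.genome_id, ()))
            # generator convention: family genes carry the planted-family tag
            got = {g for g in cov.gene_ids_in_gi if ".pf" in g}
            tp += len(got & planted)
            fp += len(got - planted)
            fn += len(planted - got)
        report["gi_overlap"] = {
            "tp": tp, "fp": fp, "fn": fn,
            "recall": _safe_ratio(tp, tp + fn),
        }
    return report
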