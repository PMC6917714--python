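"""Homology-based calls: best hits, reciprocal best hits, reaction presence,
trait-gene profiles.

Thresholds follow the conventions of homology-based genome annotation:
reaction presence requires a bit score >= 100 against the catalog enzyme (or
enzyme family); orthology between two proteomes is the bidirectional best hit
(BBH) with both e-values <= 1e-5. All threshold comparisons are inclusive.
A trait gene absent from a genome is recorded with coverage 0, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .scoring import ScoreProvider

DEFAULT_BIT_MIN = 100.0
DEFAULT_E_MAX = 1e-5


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    bit_score: float
    e_value: float
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score) or self.bit_score < 0:
            raise ValueError(f"bit_score must be finite and >= 0: {self.bit_score}")


def best_hit(
    query_id: str,
    query_seq: str,
    proteome: Mapping[str, str],
    provider: ScoreProvider,
    with_coverage: bool = False,
) -> HomologyHit | None:
    """Highest-bit-score hit of a query in a proteome.

    Ties are broken by subject id (lexicographically smallest wins). Returns
    None when no subject produces a positive-scoring local alignment.
    """
    if not proteome:
        raise ValueError("empty proteome")
    best: HomologyHit | None = None
    for sid in sorted(proteome):
        bit, e_value = provider.pair_score(query_id, query_seq, sid, proteome[sid])
        if bit <= 0:
            continue
        if best is None or bit > best.bit_score:
            best = HomologyHit(query_id, sid, bit, e_value)
    if best is not None and with_coverage:
        cov = provider.coverage(query_seq, proteome[best.subject_id])
        best = HomologyHit(best.query_id, best.subject_id, best.bit_score,
                           best.e_value, cov)
    return best


def _score_matrix(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    provider: ScoreProvider,
) -> dict[tuple[str, str], tuple[float, float]]:
    return {
        (a, b): provider.pair_score(a, proteome_a[a], b, proteome_b[b])
        for a in proteome_a
        for b in proteome_b
    }


def bbh_pairs(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    provider: ScoreProvider,
    e_max: float = DEFAULT_E_MAX,
) -> set[tuple[str, str]]:
    """Reciprocal best hits between two proteomes.

    (a, b) is kept iff b is a's best hit in B, a is b's best hit in A, and
    both directions have e-value <= e_max (inclusive). Ties broken by subject
    id, matching :func:`best_hit`.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores = _score_matrix(proteome_a, proteome_b, provider)

    def best_of(query: str, subjects: Sequence[str], flip: bool) -> str | None:
        top, top_bit = None, 0.0
        for s in sorted(subjects):
            bit, _ = scores[(s, query) if flip else (query, s)]
            if bit > top_bit:
                top, top_bit = s, bit
        return top

    best_in_b = {a: best_of(a, list(proteome_b), flip=False) for a in proteome_a}
    best_in_a = {b: best_of(b, list(proteome_a), flip=True) for b in proteome_b}
    pairs = set()
    for a, b in best_in_b.items():
        if b is None or best_in_a.get(b) != a:
            continue
        if scores[(a, b)][1] <= e_max:
            pairs.add((a, b))
    return pairs


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    enzyme_seq_ids: tuple[str, ...]
    metabolite_ids: frozenset[str]
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if not self.enzyme_seq_ids:
            raise ValueError(f"reaction {self.reaction_id}: needs >= 1 enzyme sequence")
        if not self.metabolite_ids:
            raise ValueError(f"reaction {self.reaction_id}: empty metabolite set")


@dataclass
class ReactionCatalog:
    """Reaction -> enzyme sequences / metabolites / pathway catalog
    (a MetaCyc-style extract) plus the enzyme sequences themselves."""

    reactions: dict[str, Reaction]
    enzyme_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.reactions.values():
            for eid in r.enzyme_seq_ids:
                if self.enzyme_seqs and eid not in self.enzyme_seqs:
                    raise ValueError(
                        f"reaction {r.reaction_id}: enzyme sequence {eid} missing"
                    )

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    @classmethod
    def from_tsv(cls, path: str | Path, enzyme_seqs: Mapping[str, str]) -> "ReactionCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        reactions = {}
        for row in df.itertuples(index=False):
            reactions[str(row.reaction_id)] = Reaction(
                reaction_id=str(row.reaction_id),
                enzyme_seq_ids=tuple(str(row.enzyme_seq_ids).split(",")),
                metabolite_ids=frozenset(str(row.metabolite_ids).split(",")),
                pathway_id=str(row.pathway_id),
            )
        return cls(reactions=reactions, enzyme_seqs=dict(enzyme_seqs))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (
                r.reaction_id,
                ",".join(r.enzyme_seq_ids),
                ",".join(sorted(r.metabolite_ids)),
                r.pathway_id,
            )
            for r in (self.reactions[rid] for rid in self.reaction_ids)
        ]
        pd.DataFrame(
            rows, columns=["reaction_id", "enzyme_seq_ids", "metabolite_ids", "pathway_id"]
        ).to_csv(path, sep="\t", index=False)


def call_reaction_presence(
    reaction_id: str,
    catalog: ReactionCatalog,
    proteome: Mapping[str, str],
    provider: ScoreProvider,
    bit_min: float = DEFAULT_BIT_MIN,
) -> tuple[bool, HomologyHit | None]:
    """Call a reaction present in a proteome by enzyme-sequence homology.

    Single-enzyme reactions use the best pairwise bit score; multi-enzyme
    reactions use the provider's family score. Present iff score >= bit_min
    (inclusive boundary). Returns the supporting hit for single-enzyme calls.
    """
    if reaction_id not in catalog.reactions:
        raise KeyError(f"reaction {reaction_id!r} absent from catalog")
    reaction = catalog.reactions[reaction_id]
    enzymes = [(eid, catalog.enzyme_seqs[eid]) for eid in reaction.enzyme_seq_ids]
    if len(enzymes) == 1:
        eid, eseq = enzymes[0]
        hit = best_hit(eid, eseq, proteome, provider)
        present = hit is not None and hit.bit_score >= bit_min
        return present, (hit if present else None)
    # family call: best family score over the proteome
    best_bit, best_pid = 0.0, None
    for pid in sorted(proteome):
        bit = provider.family_score(pid, proteome[pid], enzymes)
        if bit > best_bit:
            best_bit, best_pid = bit, pid
    present = best_bit >= bit_min
    # family scores carry no e-value; mark it as not-computed
    hit = (
        HomologyHit(reaction_id, best_pid, best_bit, math.inf)
        if present and best_pid is not None
        else None
    )
    return present, hit


@dataclass(frozen=True)
class TraitPanel:
    """A curated panel of trait genes (e.g. Tat/Sec secretion, sporulation)
    defined by reference proteins of a model strain."""

    panel_name: str
    genes: tuple[tuple[str, str], ...]  # (gene_name, reference_protein_id)
    required_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(names) != len(set(names)):
            raise ValueError(f"panel {self.panel_name}: duplicate gene names")
        unknown = self.required_genes - set(names)
        if unknown:
            raise ValueError(f"panel {self.panel_name}: required genes not in panel: "
                             f"{sorted(unknown)}")


@dataclass(frozen=True)
class TraitProfile:
    genome_id: str
    panel_name: str
    presence: dict[str, bool]  # gene_name -> present
    coverage: dict[str, float]  # gene_name -> coverage (0 when absent)
    completeness: float
    missing_required: tuple[str, ...]


def trait_profile(
    genome_id: str,
    genome_proteome: Mapping[str, str],
    panel: TraitPanel,
    reference_proteome: Mapping[str, str],
    provider: ScoreProvider,
    e_max: float = DEFAULT_E_MAX,
) -> TraitProfile:
    """Presence/absence of a trait-gene panel in a genome via BBH orthology.

    A panel gene is present iff its reference protein has a reciprocal best
    hit in the genome's proteome (e-values <= e_max both ways). Absent genes
    get coverage 0. ``missing_required`` flags absent essential genes, e.g. a
    sporulation phosphorelay gene whose loss arrests sporulation.
    """
    for gene, ref_id in panel.genes:
        if ref_id not in reference_proteome:
            raise ValueError(
                f"panel {panel.panel_name}: reference protein {ref_id} "
                f"(gene {gene}) absent from reference proteome"
            )
    pairs = bbh_pairs(genome_proteome, reference_proteome, provider, e_max=e_max)
    partner_of_ref = {b: a for a, b in pairs}
    presence, coverage = {}, {}
    for gene, ref_id in panel.genes:
        partner = partner_of_ref.get(ref_id)
        presence[gene] = partner is not None
        coverage[gene] = (
            provider.coverage(reference_proteome[ref_id], genome_proteome[partner])
            if partner is not None
            else 0.0
        )
    n = len(panel.genes)
    completeness = sum(presence.values()) / n if n else 1.0
    missing_required = tuple(
        sorted(g for g in panel.required_genes if not presence[g])
    )
    return TraitProfile(
        genome_id=genome_id,
        panel_name=panel.panel_name,
        presence=presence,
        coverage=coverage,
        completeness=completeness,
        missing_required=missing_required,
    )
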