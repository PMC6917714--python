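"""Core data model: genomes, features, interval sets, panel statistics.

All coordinates are internal 0-based half-open ``[start, end)``. GFF3 I/O
(see :mod:`bacpanel.io`) converts to and from the 1-based inclusive
convention at the boundary, so interval arithmetic in this module never
has to think about off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class SourceEnv(str, Enum):
    """Isolation source of a strain."""

    mangrove_mud = "mangrove_mud"
    microbial_mat = "microbial_mat"
    barren_soil = "barren_soil"
    other = "other"


class FeatureKind(str, Enum):
    CDS = "CDS"
    rRNA = "rRNA"
    other = "other"


@dataclass(frozen=True)
class Replicon:
    """A chromosome or plasmid."""

    replicon_id: str
    length: int
    circular: bool = True
    is_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"replicon {self.replicon_id}: length must be > 0")


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature on a replicon (0-based half-open)."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    kind: FeatureKind = FeatureKind.CDS
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class GenomeRecord:
    """One genome of the panel: replicons plus per-strain metadata."""

    genome_id: str
    species_label: str = ""
    source_env: SourceEnv = SourceEnv.other
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"genome {self.genome_id}: at least one replicon required")
        n_chrom = sum(r.is_chromosome for r in self.replicons)
        if n_chrom != 1:
            raise ValueError(
                f"genome {self.genome_id}: exactly one primary chromosome expected, "
                f"found {n_chrom}"
            )

    @property
    def chromosome(self) -> Replicon:
        return next(r for r in self.replicons if r.is_chromosome)

    @property
    def size(self) -> int:
        """Genome size = summed replicon length (chromosome + plasmids)."""
        return sum(r.length for r in self.replicons)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(f"genome {self.genome_id}: no replicon {replicon_id!r}")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Normalize intervals: drop empties, sort, merge overlapping/adjacent-overlap.

    Touching intervals (a, b), (b, c) are NOT merged into one — they cover the
    same bp either way, and keeping them separate preserves the half-open
    semantics; overlapping ones are. Idempotent, order-insensitive.
    """
    cleaned = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in cleaned:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_bp(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a set of (possibly overlapping) intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


class IntervalLabel(str, Enum):
    GI = "GI"
    prophage = "prophage"
    SMGC = "SMGC"
    other = "other"


@dataclass
class IntervalSet:
    """Labelled intervals on one replicon, normalized on construction."""

    replicon_id: str
    intervals: list[tuple[int, int]]
    label: IntervalLabel = IntervalLabel.other

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def check_bounds(self, replicon: Replicon) -> None:
        for s, e in self.intervals:
            if s < 0 or e > replicon.length:
                raise ValueError(
                    f"interval ({s}, {e}) outside replicon "
                    f"{replicon.replicon_id} [0, {replicon.length})"
                )


@dataclass(frozen=True)
class GenomeStats:
    """Per-genome summary statistics (the columns of a panel summary table)."""

    genome_id: str
    size_bp: float
    n_orfs: float
    n_rrna: float


@dataclass(frozen=True)
class PanelSummary:
    n_genomes: int
    mean_genome_size: float
    mean_orf_count: float
    mean_rrna_count: float
    min_genome_size: float
    max_genome_size: float
    min_orf_count: float
    max_orf_count: float
    min_rrna_count: float
    max_rrna_count: float


@dataclass(frozen=True)
class GICoverage:
    """Genomic-island coverage accounting for one genome."""

    genome_id: str
    gi_bp: int
    gi_percent: float
    genes_in_gi: int
    pct_genes_in_gi: float
    biosynthetic_genes_in_gi: int
    gene_ids_in_gi: tuple[str, ...] = ()


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap length between two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def features_overlapping(
    features: Sequence[GeneFeature],
    islands_by_replicon: dict[str, list[tuple[int, int]]],
    min_overlap_fraction: float = 0.0,
) -> list[GeneFeature]:
    """Features overlapping any island on their replicon.

    A gene counts as "in" an island set with any overlap >= 1 bp by default;
    ``min_overlap_fraction`` > 0 additionally requires the overlap to cover at
    least that fraction of the gene.
    """
    hit: list[GeneFeature] = []
    for f in features:
        isl = islands_by_replicon.get(f.replicon_id, [])
        ov = sum(overlap_bp((f.start, f.end), iv) for iv in merge_intervals(isl))
        if ov >= 1 and ov >= min_overlap_fraction * f.length:
            hit.append(f)
    return hit
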