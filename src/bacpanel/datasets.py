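"""Published per-strain values of the ten Red Sea *Bacillus* isolates.

The package ships the printed per-genome sequencing statistics (strain,
genome size, ORF and rRNA counts) and genomic-island table (GI %, prophage
%, biosynthetic genes overlapping GIs) of the ten-strain Red Sea panel as
small TSVs. They are inputs: all derived quantities — panel means, quartile
membership, counts above a reference mean, column totals — are computed by
the package's own operations at run time.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .model import GenomeStats

_DATA = files("bacpanel") / "data"


def red_sea_table1() -> pd.DataFrame:
    """Sequencing features of the ten Red Sea genomes."""
    return pd.read_csv(str(_DATA / "red_sea_table1.tsv"), sep="\t")


def red_sea_stats() -> list[GenomeStats]:
    """Per-genome statistics in the units the panel summary expects (bp)."""
    df = red_sea_table1()
    return [
        GenomeStats(
            genome_id=str(r.strain),
            size_bp=float(r.size_mb) * 1e6,
            n_orfs=float(r.n_orfs),
            n_rrna=float(r.n_rrna),
        )
        for r in df.itertuples(index=False)
    ]


def red_sea_table2() -> pd.DataFrame:
    """Genomic-island / prophage percentages and biosynthetic-gene overlap."""
    return pd.read_csv(str(_DATA / "red_sea_table2.tsv"), sep="\t")


def red_sea_gi_totals() -> dict[str, float]:
    """Panel-level GI totals and the external reference values (28-strain
    GI mean, printed quartile value ranges)."""
    df = pd.read_csv(str(_DATA / "red_sea_gi_totals.tsv"), sep="\t")
    return {str(r.quantity): float(r.value) for r in df.itertuples(index=False)}


def count_in_ranges(
    values: list[tuple[str, float]], ranges: list[tuple[float, float]]
) -> int:
    """How many strains' values fall inside any of the closed ranges."""
    return sum(
        1 for _, v in values if any(lo <= v <= hi for lo, hi in ranges)
    )
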