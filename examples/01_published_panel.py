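"""Panel summary statistics and genomic-island ranking of the ten-strain
Red Sea *Bacillus* panel, from the published per-genome values shipped with
the package.

Prints the panel means (genome size, ORF and rRNA counts), how many strains
exceed the 28-strain reference GI mean, how many fall in the upper GI
quartile ranges, and the total biosynthetic genes overlapping genomic
islands — the package recomputes each from the per-strain inputs.
"""

from bacpanel import rank_gi_percent, summarize_stats
from bacpanel.datasets import (
    count_in_ranges,
    red_sea_gi_totals,
    red_sea_stats,
    red_sea_table2,
)

summary = summarize_stats(red_sea_stats())
print(f"panel of {summary.n_genomes} genomes")
print(f"  mean genome size : {summary.mean_genome_size / 1e3:,.0f} kb "
      f"(range {summary.min_genome_size / 1e6:.2f}-{summary.max_genome_size / 1e6:.2f} Mb)")
print(f"  mean ORF count   : {summary.mean_orf_count:,.1f}")
print(f"  mean rRNA count  : {summary.mean_rrna_count:.1f}")

t2 = red_sea_table2()
totals = red_sea_gi_totals()
values = list(zip(t2.strain, t2.gi_percent))
ranking = rank_gi_percent(values, reference_mean=totals["reference_gi_mean_percent"])
in_upper = count_in_ranges(
    values,
    [(totals["q3_low"], totals["q3_high"]), (totals["q4_low"], totals["q4_high"])],
)
print(f"\ngenomic islands (GI % of genome):")
print(f"  strains above the {totals['reference_gi_mean_percent']}% reference mean: "
      f"{ranking.n_above_reference}")
print(f"  strains inside the upper two quartile ranges: {in_upper}")
print(f"  biosynthetic genes inside GIs, panel total: "
      f"{int(t2.biosynthetic_genes_in_gi.sum())}")
print(f"  mean GI bp per genome: "
      f"{totals['gi_bp_total'] / totals['n_genomes']:,.0f} bp")
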