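# Methods

This note documents the models, conventions and numerical choices behind
`bacpanel`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Coordinates and interval accounting

All internal coordinates are 0-based half-open; GFF3 I/O converts from/to
the 1-based inclusive convention at the boundary and nowhere else.
Interval sets (genomic islands, prophages, SMGCs) are normalized on
construction — empties dropped, sorted, overlapping intervals merged — so
covered-bp accounting is idempotent and order-free. A gene counts as
"inside" an island when it overlaps the merged islands by at least 1 bp;
a `min_overlap_fraction` option tightens this (default 0, the most
inclusive reading of "genes located within predicted GIs"). GI percentage
uses the summed replicon length (chromosome + plasmids) as denominator,
since several panel genomes carry two replicons. Island intervals are
treated as linear even on circular chromosomes, because upstream island
predictors emit linear intervals. Quartile ranking splits the panel into
four rank-based groups whose sizes differ by at most one, ties broken by
strain id with the lexicographically smaller id in the lower quartile —
the published analysis reports quartile value ranges but not its
splitting algorithm, so a deterministic convention was chosen and is
reported with the output.

## Homology scoring

The built-in provider is Smith–Waterman local alignment under BLOSUM62
with affine gaps (open 11, extend 1; a gap of length g costs 11 + g).
Raw scores S convert to bits via the Karlin–Altschul relation
bits = (λS − ln K)/ln 2 with the standard gapped parameters for this
scoring system (λ = 0.267, K = 0.041), and the e-value is m·n·2^(−bits)
over the pairwise search space, clamped below at 1e-300 to keep ranking
stable. This is not a reimplementation of BLAST statistics — it is a
deterministic scorer with the same scale, sufficient for desk-scale
analyses; precomputed hit tables from external aligners can be injected
through `HitTableProvider` wherever the built-in scorer is accepted.

Thresholds are inclusive everywhere (presence at bit ≥ 100, orthology at
e ≤ 1e-5, similarity at ≥ 0.60); strictness at the boundary is not
specified by the thresholds' provenance, and the inclusive reading is the
documented convention. Reaction presence uses only the bit-score rule; no
additional e-value condition is applied. For multi-enzyme reactions the
default family score is the maximum pairwise bit score over family
members — a deliberate simplification of a profile model that is exact
when family members are close homologs, and the provider interface admits
profile-based implementations.

## Enrichment statistics

The background rate p for a (reaction, clade) test is the plug-in
presence fraction among the *included* non-clade species; excluded
species (e.g. low-quality genomes) contribute nothing. Both one-sided
exact binomial tails are computed (scipy's regularized-beta evaluation;
cross-checked against direct pmf summation to ≤ 1e-12 for all n ≤ 32),
and a raw α = 1e-5 threshold makes the call — no multiple-testing
correction by default, matching the analysis the pipeline reproduces; a
Bonferroni option exists. Degenerate backgrounds (p ∈ {0, 1}) are handled
exactly with no pseudocounts: a presence pattern confined to one clade
has P(X ≥ k | p = 0) = 0 and is *always* called. Users should be aware
that the plug-in background makes extreme-background tests
anti-conservative; the generator's margin conventions below exist for
exactly this reason.

Species clustering uses Jaccard distance on the binary reaction profiles
with average linkage (both configurable); species order is canonicalized
before distance computation so the dendrogram is input-order invariant,
and clade ids are renumbered by smallest member id for stability. The
clade count k is a user choice (the reproduced analysis chose its clade
count by manual dendrogram inspection). Clade/tree concordance is
monophyly of each clade on the input tree after pruning to the included
species, evaluated on the rooted topology.

## SMGC families and co-localization

Cluster similarity is the symmetric shared-gene fraction
(h_AB + h_BA)/(|A| + |B|); the upstream analysis used MultiGeneBlast's
(undefined) similarity, and this reproducible, order-free statistic is
the package's stand-in, with the qualifying-homolog bit threshold
configurable. Families are single-linkage connected components at
similarity ≥ 0.60, not cliques. Product assignment takes the
best-matching characterized reference cluster at the same threshold.

Normalized position is the cluster midpoint divided by the chromosome
length, computed only for complete chromosomes; distances between
positions are circular (min(|Δ|, 1 − |Δ|)) on circular replicons and
linear otherwise. The co-localization tolerance defaults to 0.05
normalized units — the underlying analysis does not state one — and is
recorded in every output. When one species carries several members of a
family, the species' position is the member minimizing the summed
distance to the other species' members. No origin-of-replication
normalization is applied to positions.

## Synthetic panels and what passing tests mean

The generator plants, per run: clade-private reactions present in every
clade member over a 5 % background; core reactions present everywhere;
iid background noise reactions; 12 gene-cluster families (5 shared with
strict/partial/random placement, 7 single-species, 3 exclusive to the
focal group) whose genes are point-mutated copies of ancestral proteins;
genomic islands, one per genome overlapping a biosynthetic block; trait
deletions (two genomes lacking *spo0B*); and a species tree concordant
with the clades except one planted discordant pair. Default problem
sizes: 9 species (3 clades of 3) for full sequence-level runs, 32 species
in 7 clades (sizes 5,5,5,5,4,4,4) for matrix-level analyses; protein
lengths 120–240 aa, point-mutation rate 0.05, chosen so true homologs
score far above the bit-100 threshold (typically > 300 bits) and
unrelated proteins far below (< 40 bits).

Margin conventions make planted signals recoverable *by construction*:
strict families are jittered by < tolerance/2 so every pairwise distance
stays within tolerance; partial outliers and random placements are
rejection-sampled beyond tolerance + 0.03; background occurrences of
planted enriched reactions are truncated so the resulting background
fraction keeps the exact tail below α even in the worst draw; and noise
reactions are redrawn if their carriers all fall in a single clade, since
such patterns make the degenerate exact test fire at any α (see above).
Infeasible configurations (jitter too large, tolerance too wide for the
usable arc) raise before anything is written. All randomness flows from
one seeded generator; identical config + seed gives byte-identical files.

Consequently, perfect recovery on these panels demonstrates the
*correctness of the machinery* — calls, tests, clustering, classification
and plumbing — under conditions where the right answer is unambiguous. It
does not demonstrate robustness on real data, where homologs diverge
non-uniformly, gene clusters vary in content and boundaries, island calls
are noisy, and enrichment margins are not guaranteed. The generator makes
no attempt at realistic sequence evolution (no substitution-rate
heterogeneity, no indels, no codon structure: chromosome nucleotides are
random filler and protein sequences are carried alongside), nor at
realistic operon/cluster architecture.

## Known limitations

- The paper-scale census numbers of the reproduced study (417 cluster
  occurrences, 200 families, 38/4/12 placement classes, 2.7 Mbp of GI
  sequence) depend on the original genomes and upstream predictor outputs
  and cannot be regenerated from this repository; the package reproduces
  the published per-strain tables' derived statistics and validates the
  machinery on synthetic panels instead.
- The built-in scorer's e-values are approximate (pairwise search space,
  gapped parameters); rankings and threshold calls are the supported use,
  not absolute e-value accuracy.
- `cut_to_clades` requires the dendrogram to admit a cut into exactly k
  groups; pathological ties can make some k unreachable, which is
  reported as an error rather than silently merged.
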