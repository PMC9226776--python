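# Methods

This note documents the models, numerical conventions and design choices
behind `liposcan`, and what the synthetic fixtures do and do not establish
about behaviour on real metagenomes.

## Profile HMM engine

Each lipolytic family is modelled as a linear profile HMM built from the
family's multiple sequence alignment. Columns whose gap fraction is below
`gap_threshold` (default 0.5) become match states, in order; residues in
the remaining columns are treated as insertions attached to the preceding
match node. The architecture is Plan7-like with per-node states M/I/D and
transitions M→{M,I,D}, I→{M,I}, D→{M,D}; the rarely informative I→D and
D→I edges are omitted.

**Estimation.** Emissions and transitions are Laplace-smoothed relative
frequencies, `(weighted count + pseudocount) / (total + k·pseudocount)`
with pseudocount 1 by default. This is deliberately simpler than the
Dirichlet-mixture priors of full HMMER implementations: every number in a
model is reproducible by hand, at some cost in sensitivity for very small
families. Sequence weights are uniform by default; Henikoff position-based
weighting is available (`sequence_weighting="henikoff"`). The background
is the Robinson–Robinson amino-acid frequency table (uniform 1/20
selectable).

**Scoring.** Scoring is local-mode log₂-odds against the background null:
a path enters at any match state with probability 1/L, exits freely from
any match state, and unaligned flanking residues cost nothing. The engine
is single-hit and local-only — no multihit or glocal modes — because the
screening decision rests on the database content and the E-value cutoff,
not on alignment-mode subtleties. Viterbi and Forward are computed in
log-space with a vectorized Lance-style accumulate for the delete chain;
both are verified against exhaustive path enumeration on small models
(L ≤ 3, sequences ≤ 5, tolerance 1e-9 bits).

**E-values.** Viterbi scores of i.i.d. background decoys (default 200
decoys of length 350, seed 42) are fitted with a Gumbel law by maximum
likelihood; `E = n_comparisons · (1 − exp(−exp(−λ(s − τ))))` with
`n_comparisons` the number of query proteins in the scan (per-scan
convention). The fit's self-consistency is tested by requiring the decoys'
own P-values to be uniform within ±0.05 at the 0.1 quantile. The screening
cutoff defaults to E ≤ 1e-10.

**Serialization.** Profiles round-trip through a documented HMMER3-flavoured
text subset (header, per-node ME/IE/TR lines, `//` terminator); databases
are plain concatenations of profile records, and floats are written at full
precision so scores are bit-identical after a round trip.

## Similarity search

The confirmation search is exact affine-gap Smith–Waterman (BLOSUM62,
gap open 11, extend 1; a gap of length k costs open + k·extend), executed
via Biopython's `PairwiseAligner`. With registry-scale reference sets an
exact search is tractable, and it removes heuristic-seeding artifacts
while keeping BLAST-style decision semantics: E-values use the
Karlin–Altschul form `K·m·n·exp(−λS)` with the published gapped-BLOSUM62
constants (λ = 0.267, K = 0.041); identity is identical pairs over aligned
residue-pair columns (gap columns excluded); query coverage is the aligned
query span over the query length (qcovs-style).

## Annotation rules

Proteins of 200–800 aa are screened; a profile hit (best family = lowest
E-value, ties by bit score then family name) is confirmed against the
reference registry. Rule order for alpha/beta-fold families: no profile
hit → `no_hit`; same family by both routes at identity ≥ 0.60 and coverage
≥ 0.70 → `assigned`; miscellaneous-category, weak, or absent similarity →
`unassigned`; strong similarity to a non-lipolytic family →
`non_lipolytic`. When the two routes each give a strong but *different*
lipolytic family, the protein is left `unassigned`: assignment requires
agreement, and the non-lipolytic clause applies only to non-lipolytic
targets. The registry's coverage gate is intentionally stricter when
composing family reference sets (≥ 0.80) than at annotation (≥ 0.70); both
are separate `Thresholds` fields.

Keyword-route families (GDSL/II, β-lactamase-like/VIII, patatin-like) are
screened with their own profiles and must additionally hit a secondary
functional-family confirmation profile; family VIII is further restricted
to 350–450 aa. A route hit without confirmation (or outside the window) is
`non_lipolytic`. When a protein has evidence on both routes, the
alpha/beta verdict stands unless the route rule assigns it or the
alpha/beta chain ended in `no_hit`. The profile cutoff is applied before
choosing the per-protein best family.

Sequence similarity networks connect sequences whose pairwise alignment
satisfies E ≤ cutoff (1e-10 default; 1e-16 for the stricter
family-verification mode) and raw score ≥ 16. The score threshold is in
raw alignment-score units and configurable, since similarity-network tools
differ in the unit they threshold on.

## Community statistics

`LPGM = count · (1e9 / assembly_bp) · (1e6 / genes)` — lipolytic hits per
gigabase of assembly per million predicted genes; the formula is isolated
in `lpgm_normalize` and linear in counts by construction. Heatmap-style
transforms use log₁₀(x+1), which is monotone and maps absence to zero.

Bray–Curtis dissimilarity (`scipy`) feeds agglomerative Ward clustering in
the **ward.D** convention: the Lance–Williams Ward update applied to the
raw dissimilarities with no pre-squaring, ties broken lexicographically on
the smallest member label. This matches R's `hclust(method="ward.D")`
(verified against frozen R output) and differs from scipy's `'ward'`
linkage, which implements the D2 (squared) convention.

ANOSIM uses midranks over all pairwise distances,
`R = (mean between-group rank − mean within-group rank) / (n(n−1)/4)`,
and a seeded permutation p-value with the add-one convention
`p = (1 + #{R_perm ≥ R_obs}) / (1 + n_permutations)` (default 9,999
permutations). The statistic is checked against scikit-bio, R's vegan, and
full label-permutation enumeration at small n; the null rejection rate at
α = 0.05 calibrates to 0.05 ± 0.02.

Indicator analysis computes, per category, the point-biserial (Pearson)
correlation between its abundance vector and the 0/1 membership vector of
every habitat subset of size 1..3 (never the full set — such a subset
carries no contrast; the powerset is intractable at many habitats), keeps
the best subset, and assigns a permutation p-value (999 permutations,
add-one). Plain point-biserial r is the default and documented semantics;
a group-equalized variant is not currently offered. Only positive
associations with p ≤ α (0.05) are reported. The bipartite network keeps
categories with mean LPGM ≥ 0.5 and flags each as unique- (1 habitat),
pair- (2) or multi-associated (> 2).

## Library hit-rate arithmetic

For activity-plate library screens: hits per million clones
(`hits·1e6/clones`, displayed to the nearest integer), gigabases screened
(`clones·insert_kb·1e3/1e9`, totals to two decimals) and hits per Gb
(one decimal). Totals per sample are sums of parts. Rates are invariant
when clones and hits scale together.

## Synthetic data: what it emulates, and what it does not

Families descend from background-sampled consensus sequences (250–450 aa)
with a G-x-S-x-G catalytic-serine motif embedded in the middle third —
alpha/beta-hydrolase-like in length and motif, not in real secondary
structure. Members differ by i.i.d. point substitutions (rate 0.10) and
rare short indels (rate 0.01, bounded so coverage gates stay intact). The
benchmark set holds 20 positives per family, 80 non-homologous background
decoys, and 40 "twilight" decoys that keep ~22.5% of a target family's
consensus positions — emulating the non-lipolytic homolog problem at the
20–25% identity band, measured against the consensus (not every member) by
global alignment. One family is generated as the keyword-route family with
lengths inside the 350–450 aa window; its confirmation profile is built
from a subset of the family alignment.

Synthetic communities draw per-sample category profiles from
habitat-specific Dirichlet concentrations: 24 core genera (concentration
1.0 everywhere) plus 3 planted indicator genera per habitat (base 0.05,
boosted by the habitat effect, default 3.0, in their own habitat), with
multinomial sampling of 2,000 hits per sample over 4 habitats × 6 samples;
metadata uses a 1 Gb assembly and 1e6 genes per sample so LPGM equals the
raw count. At effect 0 all samples are exchangeable by construction.

Because all between-habitat signal is carried by planted genera with
near-disjoint support, habitat separation is cleaner than in field
surveys: ANOSIM R typically lands at 0.93–1.0, whereas real multi-habitat
gene-profile surveys report R around 0.6–0.8. Passing the recovery tests
therefore shows the statistics recover strong planted structure and stay
calibrated under the null — not that the pipeline resolves the subtler
overlapping community gradients of real metagenomes. Likewise, benchmark
recall/rejection near 1.0 reflects families that are mutually unrelated by
construction; real families share fold-level similarity that makes the
assignment problem harder.

## Numerical and degenerate-input conventions

Non-canonical residues are rejected by default (configurable skip).
Bray–Curtis on an all-zero sample pair is defined as 0 with a warning.
A constant abundance vector has indicator r defined as 0 and is never
significant. Calibration aborts on a zero-variance decoy score
distribution. Scan hit ties break by higher bit score then lexicographic
family name; Ward merge ties break lexicographically. All stochastic
steps take explicit seeds; identical inputs and seeds give byte-identical
outputs.

## Problem sizes

Default test and demo scales: ~300-protein benchmark over 9 families
(~350-state profiles), 200-decoy calibrations, 24-sample communities,
9,999 ANOSIM permutations in demos and 199–999 inside repeated-run
studies. These sizes keep full runs in the minutes range while leaving
every statistic's behaviour (rank distributions, permutation calibration,
Gumbel tails) in its asymptotically meaningful regime.
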