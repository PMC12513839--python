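# Methods

## Dependency model

All computations consume a model satisfying a minimal contract: a pure
function from a sequence over {A, C, G, T} to an N×4 row-stochastic matrix
of per-position base probabilities, computed with the full unmasked
sequence as context, plus declared capabilities (`style`,
`max_context`, `supports_mask`). U is mapped to T at ingest; sequences
containing N or other ambiguity codes are rejected rather than imputed,
because the substitution set underlying the dependency definition has no
principled extension to ambiguous bases.

The dependency of target j on query i is the largest absolute log2
odds-ratio change across the four target bases when the query base is
substituted; the per-pair statistic maximizes over the three alternative
query bases. Odds are `p/(1−p)` per base against all alternatives — the
standard reading, which also makes the signed 3×4 log-odds grid
antisymmetric under swapping reference and alternative. Probabilities are
clipped to `[ε, 1−ε]` with ε = 1e-9 (then renormalized) before any odds
computation, so all log-odds are finite; the clip bound also caps the
largest representable dependency at ≈ 2·log2((1−ε)/ε) ≈ 60. Dependencies
are stored in log2 units. Diagonal entries are NaN in memory and empty
cells in the TSV exchange format: self-dependencies are undefined, and a
zero placeholder would corrupt quantile statistics downstream.

A full substitution map costs exactly 3N+1 model evaluations (one
reference profile, one per position×alternative); the mask-based variant
replaces the three substitutions with a single masked evaluation per
query (N+1 total). For autoregressive models a query cannot influence
targets 5′ of it, so the forward pass fills the upper triangle and a
second pass on the reverse complement — with positions remapped as
p → N−1−p — fills the lower one; an optional mitigation mode takes the
elementwise maximum of the combined map and its transpose.

## Synthetic models as oracles

The test oracle standing in for a trained gLM is a pairwise coupling
model, `P(s) ∝ exp(Σ h_i(s_i) + Σ J_ij(s_i, s_j))`, whose single-position
conditionals have an exact closed form computable in O(degree). Because
the joint is enumerable for small N, three independent routes to the same
quantities exist: closed-form conditionals, full-joint enumeration, and
literal per-pair substitution (the brute-force dependency oracle, kept
free of any shared odds/log code with the production path). Masking is
given exact semantics — the masked profile marginalizes the query base
out of the joint — so the mask-based metric can also be checked against a
direct computation.

Planted-structure generators build coupling models whose dependency maps
carry the field's canonical signatures:

- **Stems**: Watson–Crick reward matrices (strength `s`; G·T wobble at
  `s/2`, on by default, mirroring the weaker wobble preference seen in
  real maps) on antiparallel pair sets with constant i+j. Default
  strength 3 puts the planted-pair dependency at ≈ 7.4, comfortably
  between the zero background and the clipping cap.
- **Motifs**: dense mutual couplings among L positions from the outer
  products of per-position PWM log-enrichment vectors, centered,
  normalized to unit norm and scaled by `strength/(L−1)` so the total
  conditional logit swing stays of order `strength` for any motif length.
  Without that normalization, strong motifs drive probabilities into the
  clip bound and the resulting saturation erases the very dependencies
  the block is supposed to show.
- **Duplications**: two non-overlapping copies of a 2–20-nt duplicate in
  a 100-nt background (composition configurable, default uniform,
  shuffled), with identity couplings between forward copy partners and
  complementarity couplings between inverted partners — producing the
  parallel/antiparallel off-diagonal the duplication profile averages.

All generators are seed-deterministic, and every generator degenerates to
a context-free product model at strength 0 (identically zero maps).

What these emulators deliberately do not capture: trained-model noise
(background dependencies are exactly zero), long-range composition
effects, tokenization artifacts, or epistasis beyond pairwise terms.
Passing tests therefore certify the correctness of the statistics and
detectors given a model's probabilities, not the quality of any
particular gLM's probabilities on real genomes.

## Detectors

**Block score.** For every sliding window of 6 consecutive positions the
within-window dependencies (diagonal excluded: 30 values) are reduced to
their first quartile, using linear interpolation between order statistics
(fixed, for cross-implementation reproducibility); the per-nucleotide
score is the maximum over covering windows. Sliding windows and
max-aggregation privilege fully contained motifs and make the track
covariant under translation; tiled windows and diagonal inclusion remain
available as options since either convention is defensible.

**Stem calling.** 5×5 matched filters with ones on the (anti)diagonal,
mean-centered so any constant patch responds exactly zero, are
cross-correlated with the map (valid region only; NaN diagonal cells are
zero-filled — conservative, since zeros cannot push a window over
threshold). Response cells at or above a threshold are grouped by the
i+j of their window centers; an antidiagonal supported by ≥3 survivors
counts as one candidate stem and ≥2 stems flag a structure candidate.
The support and stem-count defaults (3 and 2) are the procedure's
standard operating point; the response threshold default of 25 is
calibrated to RiNALMo-scale maps and is exposed because synthetic maps
live on a different scale — validation runs anchor it at twice the
smallest planted-pair dependency, a closed-form quantity of the
generator, not a fitted value. A perfect antiparallel stem has constant
i+j, so each planted helix contributes exactly one antidiagonal id, and
any window that picks stem cells up on its own antidiagonal necessarily
shares that id — which is why recovery on clean maps is exact.

**Pair contacts and evaluation.** Contact scores take the maximum of the
two orientations per unordered pair. AUROC is rank-based with midrank
ties (scikit-learn); precision at a threshold is TP/(TP+FP) among calls.
Bootstrap CIs for correlations resample pairs with replacement (default
100 draws) and report r ± 2 bootstrap standard deviations.

## Analyses

**Splice statistics.** The donor–acceptor statistic averages the map
cells between the two donor and two acceptor nucleotides, in both
orientations by default (the definition is orientation-symmetric and both
cells carry information; a single-orientation mode exists). Negatives are
(a) decoy acceptors — the same statistic against every intronic AG that
is not the annotated acceptor — and (b) a matched-distance background of
map entries at exactly the donor–acceptor spacing, sampled without
replacement (with-replacement fallback when fewer eligible pairs exist
than requested), excluding the donor and acceptor positions themselves.
Splice-outlier scoring compares the variant×junction-dinucleotide cells
against the mean of all entries at the same spacing and excludes variants
closer than 5 bp to the junction, where near-diagonal self-interaction
values would dominate.

**Duplication profile.** For each sequence the map cells linking copy-1
position t to its copy-2 partner (same order forward, reversed order
inverted) are averaged over t and over both orientations of each cell
pair, then aggregated by (length, orientation) with a 95% normal
approximation CI across sequences.

**Tiling and the power law.** Long sequences are tiled with square maps
of `window` positions every `stride` (defaults 1000/500; the final
partial window is dropped and the tiling frame is anchored at the
sequence start). Entries mapping to the same genomic (i, j) from
overlapping tiles are averaged first; then a fixed number of entries per
tile is sampled (seeded, without replacement) among pairs at most
`max_dist` apart (default 500, which equalizes the number of reachable
targets on both sides of a query), and values at or below the floor of
0.001 are dropped as numerically unreliable. Averaging before sampling
was chosen over the reverse order because it makes the sampled population
independent of tile phase. The power law is fitted by OLS of log10
dependency on log10 distance; base 10 throughout, so the slope converts
directly to percent decay per tenfold distance, `(1 − 10^slope)·100`, and
the exponentiated intercept is the scaling constant (fitted dependency at
distance 1). Residuals per integer distance (medians, annotated with
distance mod 3) expose periodic deviations such as codon-frame or
nucleosome-repeat enrichment.

**Region categories.** Features of types tRNA, tRNA_pseudogene, rRNA,
snRNA, ribozyme, SRP_RNA, snoRNA, RNase_P_RNA and RNase_MRP_RNA label a
region structured RNA; five_prime_utr, three_prime_utr, intron, CDS and
pseudogene_with_CDS label it protein-coding; transposable_element,
pseudogene and unannotated regions are intergenic. Precedence is
structured RNA > protein-coding > intergenic. The nuclear/mitochondrial
compartment is read from the sequence name.

## Validation conditions

The acceptance computations (`scripts/acceptance.py`, mirrored by the
test suite) use these problem sizes, chosen to exercise every code path
at desk scale: 50 random coupling models with N ∈ [4, 8] for oracle and
enumeration agreement; 100 seeded two-stem models (N = 44, stems of 6
pairs, strength 3) plus 100 null models for stem recovery/specificity;
20 planted-motif models (N = 60, L = 6) at moderate coupling and one at
strong coupling for block-score AUROC; 50 simulations of 10,000 noisy
power-law samples (true decay 78% per tenfold, lognormal noise with
0.3 sd on the log10 scale) for decay recovery; 100 donor–acceptor-coupled
models (N = 40) for the splice statistics; and instrumented models for
the 3N+1 / N+1 evaluation-count contracts.

## Known limitations

- The pairwise oracle cannot represent higher-order epistasis; detectors
  are validated on pairwise-generated maps only.
- Adapters for k-mer tokenizations are exact for the synthetic product
  extensions used in tests; real k-mer models need not be consistent
  across overlapping tokens, in which case the averaged profile is a
  heuristic (the sum-based aggregation variant is provided but off by
  default, as it performs worse in practice).
- Gradient- and attention-based dependency metrics require model
  internals and are out of scope; so is running actual transformer
  weights — user-supplied adapters bridge to those.
- Edge nucleotides under overlapping k-mer tokenization are averaged over
  however many k-mers cover them; this boundary convention is a
  documented choice, not an established standard.
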