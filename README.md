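# nucdep

Nucleotide dependency analysis for genomic language models (gLMs):
compute pairwise dependency maps and variant influence scores from any
model that exposes per-position nucleotide probabilities, then detect the
functional patterns those maps carry — transcription-factor motif blocks,
RNA stem antidiagonals, splice-site element interactions, duplication
diagonals — and fit the global power-law decay of dependency with distance.

The toolkit is aimed at researchers interpreting DNA/RNA language models
(masked, k-mer-tokenized or autoregressive) and at structural/regulatory
genomicists who want unsupervised contact or motif evidence from such
models. It ships **exact synthetic probability models** (pairwise-coupled
Potts-style sequence distributions with closed-form conditionals) so every
operation can be validated against brute-force enumeration — no trained
weights are required to build, test or benchmark the code.

## The core statistic

Given a sequence `n_1 … n_N` and a model that predicts a probability for
each base at each position from the full, unmasked sequence, the
dependency of target `j` on query `i` under the substitution
`n_i: k_ref → k_alt` is

```
e[i,j,k_alt] = max_k | log2( odds(n_j = k | …, n_i = k_alt, …)
                           / odds(n_j = k | …, n_i = k_ref, …) ) |
```

with `odds(p) = p/(1−p)` and `k` ranging over A, C, G, T. The per-pair
dependency `e[i,j]` maximizes over the three alternative query bases;
self-dependencies are undefined (NaN). A full N×N map costs exactly
`3N + 1` model evaluations. Derived quantities include:

- **variant influence score** — mean of `e[i,·,k_alt]` over all other
  positions; an aggregate variant-impact proxy;
- **reconstruction log-ratio** — `log2 P(alt) − log2 P(ref)` at the
  variant itself (the classical gLM baseline);
- **block score** — first quartile of dependencies within 6-nt windows;
  lights up densely interdependent motif instances;
- **stem calls** — mean-centered 5×5 antidiagonal filters, thresholding,
  and grouping of hits by `i+j`;
- **power-law fit** — OLS on log10 dependency vs log10 distance, reported
  as percent decay per tenfold distance and a scaling constant.

k-mer-tokenized models are adapted to per-nucleotide probabilities
(averaging over overlapping k-mers; renormalizing the four matching
k-mers for nonoverlapping grids), and autoregressive models get the
reverse-complement second pass that fills the lower map triangle.

## Worked example

Generate a synthetic two-stem model (its dependency map mimics an RNA
with two helices), compute its map, and call stems:

```sh
nucdep simulate --kind stems --n 60 --seed 7 --out-prefix trna_like
nucdep depmap --fasta trna_like.fa --model trna_like.model.json --out-matrix map.tsv
nucdep stems --matrix map.tsv --threshold 14 --out hits.tsv
cat hits.tsv.json
```

```json
{
  "n_stems": 2,
  "antidiagonal_ids": [22, 96],
  "is_candidate": true,
  "threshold": 14.0,
  "min_support": 3,
  "min_stems": 2
}
```

The planted helices sit at base pairs with constant `i+j` of 22 and 96;
both are recovered, with no spurious antidiagonals, so the map is flagged
as a structure candidate (`n_stems ≥ 2`). The matrix TSV holds the map
itself (planted pairs reach a dependency of ≈7.42 here; the background is
exactly zero), and `hits.tsv` lists each window center whose filter
response clears the threshold, e.g.:

```
center_i  center_j  response
5         17        17.8064
6         16        23.7419
7         15        29.6774
```

Other subcommands: `influence` (VCF SNVs → influence scores and
reconstruction log-ratios), `blocks` (motif block scores), `powerlaw`
(tiled maps → distance power-law fit + residual periodicity profile),
`splice` (donor–acceptor vs decoy/matched-distance statistics) and
`duplications` (forward/inverted duplication diagonal profiles). The same
functionality is available as a library (`nucdep.depcore`,
`nucdep.patterns`, `nucdep.analyses`, …).

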