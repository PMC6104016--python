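# Methods

## The model

Each reference genome *i* is summarised as a k-th-order Markov chain over
{A, C, G, T}. A state is a k-mer; each state can transition to four states
that overlap it in k−1 bases, so a genome is described by 4^(k+1) transition
probabilities:

    P_i(O_n | O_m) = F_i(O_n | O_m) / F_i(O_m)

where F_i(O_n | O_m) counts occurrences of the (k+1)-mer formed by the prefix
state O_m followed by the last base of O_n. We implement the denominator
F_i(O_m) as the number of prefix occurrences *that have a successor*
(equivalently the row sum of the transition counts), so every probability row
normalises exactly; whether the terminal k-mer of a sequence should be
counted in the denominator is otherwise ambiguous, and this convention is the
one that makes the normalisation invariant hold to machine precision.

A read of length l is scored against genome i by its negative
log-likelihood, adjusted by an abundance weight:

    S_i = ( − Σ_{j=0}^{l−k−1} ln p_i(O_{j+1} | O_j) ) · (1 + ω_i)

and the minimum-score genome wins. The sum over a read is a dot product
between the read's (k+1)-mer transition-count vector and the genome's
negative-log-probability vector, so a batch of reads against the whole
database is one dense matrix product (any BLAS-backed backend satisfies the
contract; see Determinism below).

## Smoothing, ambiguity, strand

- **Pseudocount.** Unseen transitions must not produce −ln 0, since every
  read sums ln of the probabilities along its path. Estimation adds an
  additive pseudocount (default 1) per successor:
  P = (F + c) / (F_row + 4c). Prefix states never observed in the genome get
  the uniform row P = 1/4. With pseudocount 0 (useful for hand-checked toy
  models) an unobserved transition is capped at neglogp = 745, the negative
  log of the smallest positive double, so matrices stay finite (0·∞ would
  poison the matrix product) while an impossible transition still dominates
  any realistic score.
- **Ambiguous bases.** Any (k+1)-mer window containing a non-ACGT character
  is skipped, both in model building and read encoding. A read with no valid
  window is UNCLASSIFIED — the only source of unclassified reads in this
  composition-based scheme, by design unlike alignment tools' large
  no-hit fractions.
- **Strand.** Models are built from the given strand only. At classification
  time the default scores each read and its reverse complement against every
  genome and keeps the smaller raw score (`--single-strand` disables this).
- **Multi-record genomes.** All records under one genome id pool into one
  model; windows never span record boundaries.
- **k.** Default 5 (4096 transition probabilities), configurable. Larger k
  sharpens genome discrimination but needs more sequence per state.

## The abundance-weighting loop

The working assumption: when a read scores similarly against several genomes
it is more likely to come from the more abundant one. The loop:

1. Initialise the composition estimate q evenly, q_i = 1/n.
2. Set ω_i = −α·q_i and assign every read to argmin S_raw·(1+ω_i).
3. Re-estimate q from the assignment proportions (classified reads only).
4. Stop when the Bray-Curtis distance Σ|q−q′| / Σ(q+q′) between successive
   estimates drops below `bc_cutoff` (default 1e-3), else repeat, up to
   `max_iter` (default 20) passes.

Weights update once per full pass, never per batch, so `batch_size`
(default 1000) is purely a throughput knob and results are bit-identical for
any batch size.

**Choice of α (default 0.1).** The multiplier (1+ω_i) scales the *whole*
negative log-likelihood, so the implied prior grows with read length and
score magnitude. For a 100 bp read scoring ~130 nats, a spread of
α·(q_max−q_min) = 0.4 (α = 0.5 on a 90/10 community) shifts scores by ~50
nats — far beyond any Bayesian prior log-odds (ln(0.9/0.1) ≈ 2.2 nats) — and
empirically makes the re-estimation loop rich-get-richer unstable: on a
90/10 two-genome mixture the estimate collapses to (0.996, 0.004). We
measured the fixed points of the loop on that fixture across α: the estimate
tracks truth for α ≤ 0.3 and collapses at 0.5. The default α = 0.1 bounds
the prior's score shift at 10% even for a fully dominant genome, enough to
break near-ties toward the abundant organism (a strict inequality asserted
in tests) while staying well inside the stable region. α = 0 disables
weighting and reproduces a single unweighted pass bit-exactly.

**Convergence accounting.** `iterations` counts scoring passes. A
single-genome database converges after the first pass (the initial estimate
already equals the post-pass estimate, BC = 0). Non-convergence at
`max_iter` returns the last pass's result with a warning in the run log.

**Ties.** Exact score ties break to the first genome in canonical database
order — deterministic and recorded here deliberately.

## Clade-exclusion benchmarking

To emulate samples containing unknown organisms, the benchmark removes from
the reference every genome sharing the query's taxon name at a chosen rank
(species, genus, family, order or class; "none" keeps everything), then
classifies and scores. "NA" ranks never cause exclusion and never count as
matches. For each (exclusion level, evaluated rank) cell the report gives:

- sensitivity = TP/ALL, precision = TP/(ALL−UN),
  accuracy = (sensitivity+precision)/2, with TP = reads whose predicted
  taxon at the rank equals the truth taxon, UN = unclassified, ALL = total.
  Reads whose truth lineage is NA at the rank are excluded from ALL (an
  NA = NA match would be vacuous). ALL = UN makes precision undefined; it is
  reported as 0 with a degenerate flag to keep tables numeric.
- over-prediction rate = |predicted taxa ∖ expected taxa| / |predicted
  taxa|, the unclassified sentinel not counting as a taxon. An optional
  minimum-proportion filter (default 0) drops trace taxa before counting.
- cosine consistency = cosine similarity between predicted and expected
  proportion vectors aligned on the union of taxa.
- Shannon index H = −Σ p_i ln p_i of the predicted profile (natural log).

Composition profiles are taken over classified reads; reads whose assigned
lineage is NA at a rank are dropped from that rank's profile and the
proportions renormalise over named taxa.

## The synthetic-data generator

Test inputs are generated, never shipped: genomes sampled from explicit
order-k transition matrices (or Dirichlet-drawn ones; concentration 0.5 by
default, giving strongly distinguishable chains), toy seven-rank taxonomies
in which congeneric species share a genus-level base matrix perturbed by a
divergence knob (0 = identical chains; taxonomic proximity then correlates
with model similarity), communities with uniform or geometric
(mock-community-style) proportions, and single-end reads with uniform start
positions, uniform strand, and i.i.d. substitutions among the three other
bases. Constant-"I" quality strings are written; the classifier ignores
quality. Deliberately not modelled: platform error profiles, indels,
paired ends, coverage and GC bias. Passing tests therefore demonstrate the
method's behaviour under its own model family and a simple error process,
not performance on real sequencers' artefacts or on real genomes' shared
evolutionary structure (real congeners are far closer than independent
Dirichlet chains).

Standard problem sizes in the test suite and the reproduction script:
genomes of 20–30 kb, 2,000 reads of 100 bp, two- to four-genome databases at
k = 5, and a 100 kb order-1 genome for parameter recovery (max per-entry
error ~0.005, comfortably inside the 0.02 regression bound).

## Determinism

Identical inputs and parameters give bit-identical outputs. Raw scoring does
one matrix-vector product per read rather than a single reads×models GEMM:
BLAS blocking differs with matrix shape, which would let results drift
(~1e-14) across batch sizes; fixing the reduction order per read makes
assignments, scores and the Bray-Curtis trajectory bitwise independent of
batching. Database serialization stores negative log-probabilities as
IEEE-754 hex float literals in a versioned single-file text format, so a
save/load round-trip is exact.

## Known limitations

- Composition scoring always returns a nearest genome; it cannot say "no
  hit". Interpret species-level calls under heavy clade exclusion as
  nearest-relative statements, not identifications.
- The weighting loop's fixed point is not guaranteed unique; with very
  similar genomes and large α it can still drift. The default α is chosen
  conservatively (see above).
- Lineages must arrive pre-resolved; there is no taxonomy-dump resolution,
  and no protein-space or interpolated Markov models.
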