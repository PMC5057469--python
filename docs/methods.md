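# Methods

`cpphylo` implements a compact maximum-likelihood phylogenetics engine and,
on top of it, the analyses used to ask *how much chloroplast genome data a
phylogeny needs*: per-gene relative evolutionary rates, rate-category
partitioning, and bootstrap support measured as a function of alignment
size.  Everything runs at desk scale on synthetic data with known ground
truth; this note records the models, the defaults and why, and what the
synthetic results do and do not show.

## Substitution model

Nucleotide evolution follows GTR+Γ: a general time-reversible rate matrix
`Q_ij = s_ij π_j` built from six exchangeabilities `s` (order AC, AG, AT,
CG, CT, GT) and stationary frequencies `π`, with among-site rate variation
modelled by a discrete Gamma distribution.  Conventions:

- **Identifiability** — the GT exchangeability is fixed at 1; `Q` is scaled
  so `-Σ_i π_i Q_ii = 1`, making branch lengths expected substitutions per
  site at mean rate.
- **Discretization** — `n_categories = 4` equal-probability categories;
  each category rate is the mean of its quantile bin of Gamma(α, α)
  (computed from the regularized incomplete gamma function) and the
  category mean is renormalized to exactly 1.  Four categories is the
  common practice default; the count is a parameter.
- **Transition probabilities** — `P(t) = exp(Qt)` via the symmetric
  similarity transform `diag(√π) Q diag(1/√π)`, one `eigh` per model,
  reused for every branch and category.

## Likelihood engine

Felsenstein pruning over compressed site patterns (unique columns of the
bitmask-encoded alignment, with multiplicities).  Gaps and IUPAC ambiguity
codes are partial missing data: a tip's conditional likelihood is 1 for
each compatible state, so a fully gapped column contributes no signal.
Per-node rescaling (dividing by the per-pattern maximum and accumulating
log factors) guards against underflow.  The likelihood is invariant to the
stored rooting; trees are kept arbitrarily rooted (trifurcating root by
convention) and written with children sorted so output is canonical.

**Branch lengths.**  Each branch is optimized by bounded Brent on its
one-dimensional likelihood curve, computed from cached partials on both
sides of the branch (the flanking outer product is precomputed, so one
evaluation is a 16·k × patterns product).  Branches are cycled in rounds;
partials are rebuilt at the start of each round and the round is reverted
if the joint update ever lowers the likelihood, so accepted steps are
non-decreasing.  Convergence: total gain per round < 1e-6 log units,
at most 10 rounds; lengths clamped to [1e-8, 50].

**Model parameters.**  Exchangeabilities (log), frequencies (additive
log-ratio) and α (log, bounded to [0.02, 100]) are optimized jointly by
L-BFGS-B with the tree fixed; if the optimizer fails to improve on the
incoming model the input is returned.  Degenerate single-pattern
alignments return the input model with a warning.

**Search.**  Starting trees come from randomized stepwise addition under
Fitch parsimony (bitwise, vectorized over patterns; ties broken by the
first minimum in postorder so a seed fully determines the tree).  NNI
hill-climbing then evaluates both interchanges around every internal
branch lazily — only the central branch length is re-optimized, using the
four cached flanking partials — applies the best improving move, fully
re-optimizes branch lengths, and repeats until no move gains more than
`tol` (default 1e-4 log units).  `search_ml_tree` takes the best of
`n_starts` independent starts (default 10; the experiment pipeline uses 1
start per bootstrap replicate, a deliberate desk-scale choice since
hundreds of replicate datasets are analysed).

## Relative gene rates

A gene's rate is measured on the fixed reference topology: model
parameters and topology are held at the concatenation's optimum, branch
lengths alone are re-optimized on the gene's alignment, and the gene tree
length is divided by the concatenated tree length.  Values > 1 mean faster
than the genome-wide coding average.  Conventions chosen where the
procedure leaves room:

- Taxa missing from a gene are pruned from the tree first, and the
  denominator is the concatenated tree pruned to the same taxa (tree
  length depends on the taxon set; comparing unequal sets would bias the
  ratio).  Genes with < 4 taxa are flagged uncomputable.
- Genes shorter than 800 nt are excluded from category analyses; the
  remaining genes are slow below 0.75, fast above 1.5, and medium on the
  closed interval [0.75, 1.5] (boundary values are medium).

## Data-requirement experiment

Datasets of fixed sizes (default grid 1,000 / 2,500 / 5,000 / 10,000
columns) are drawn from the source alignment by sampling columns with
replacement.  Each dataset is analysed by ML (one parsimony start + NNI,
model parameters reused from the full-data optimum — re-estimating on
1 kb subsamples is unstable), and support for each internal bipartition of
the reference topology is the percentage of analysed datasets containing
it.  Summaries per replicate: the proportion of reference branches with
support strictly greater than 90%, and at exactly 100%.  The desk-scale
default is 3 replicates × 30 bootstrap datasets per size; the original
cluster-scale design (sizes to 100 k, 5 × 100) is available through the
same functions.  Support is always counted on the known reference
topology's branch set so curves are comparable across sizes and
categories.

## Synthetic data

The generator emulates the shape of a red-algal plastid phylogenomic
dataset:

- **Full-scale defaults** — 22 taxa, 195 genes; gene lengths 90 nt +
  Gamma(shape 1.5, scale 437), mean ≈ 746 nt, so the concatenation is
  ≈ 145 kb; per-gene rate multipliers log-normal with median 1 and
  σ = 0.70, putting the 5th–95th percentile ratio near 10 (the classic
  slow markers sit at the low end of the real distribution, which is
  right-skewed; the symmetric log-scale default is a documented
  simplification and the skew is configurable).
- **Model** — AT-rich (33% GC), transition-biased GTR with α = 0.8,
  typical of plastid coding sequence.
- **Trees** — Yule topologies with exponential waiting times, rescaled to
  a requested total length (default 2.0 substitutions/site for the
  22-taxon scale).  For the support experiment a *designed* variant is
  used: the same Yule topology but internal branches log-spaced over
  0.0008–0.005 substitutions/site (shuffled across internodes) and
  uniform 0.04 terminals.  This mirrors an order-level radiation whose
  internodes are short relative to terminal branches and span an order of
  magnitude, which places the support transition inside the subsampled
  size window — on an easy tree every category saturates at the smallest
  size and the comparison is vacuous.
- Simulation uses the same discrete-Γ machinery as inference (a site draws
  one category tree-wide), so recovery tests are internally consistent.

Study instances used by the test suite and the acceptance script:
rate recovery uses 22 taxa × 40 genes, all ≥ 800 nt at reduced lengths
(mean ≈ 900 nt); the support experiment uses 14 taxa × 60 genes (min
600 nt, mean ≈ 1.1 kb).  These sizes keep the full pipeline in the tens of
minutes on one CPU while leaving every analysis stage non-trivial.

**What the synthetic results do not show.**  The generator draws
independent sites (no codon structure, no indels, no alignment error), a
single stationary model shared by all genes, and complete taxon coverage
by default.  Passing recovery and ordering checks therefore validates the
machinery and the statistical logic of the rate and data-requirement
analyses, not the biological conclusions one would draw from real plastid
genomes.  The category-ordering margin at 2,500 nt (fast and medium above
slow) is Monte-Carlo-thin at desk scale: it holds on the pinned study
conditions but single-replicate category curves can invert by resampling
noise alone.

## Genome comparison

The genome-statistics table (packaged as a TSV transcription of the study
summary: taxon, family, genome length, GC, feature counts) marks draft
entries with `>=`-prefixed values; such records are flagged incomplete,
their counts are lower bounds, and they are excluded from min/max
genome-size summaries.  The parser strips spaces and commas from printed
thousands.  Gene content (copy counts, pseudogene status) attaches to the
same records; presence/absence matrices count pseudogenes as absent and
report them separately.

## Numerical and degenerate-input choices

- Site patterns are compressed once per engine; bootstrap resampling
  always draws original columns, never compressed patterns.
- All randomness descends from one integer seed via
  `SeedSequence(seed, spawn_key=...)` with documented keys per task, so
  any replicate is independently reproducible.
- Percentages are reported half-up-rounded by default; truncation is
  available because published tables are not always consistent about it.
- Zero-length internal branches, all-gap columns, constant alignments and
  empty rate categories are exercised in the tests; each either resolves
  arbitrarily without error or raises an error naming the offender.
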