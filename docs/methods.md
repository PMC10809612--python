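# Methods

## The inference model

Each gene is treated as an independently evolving character on a rooted
species cladogram with states `M` (mitochondrion-encoded), `N`
(nucleus-encoded) and `L` (lost or not detected). The central modelling
assumption is irreversibility: a gene can move from the mitochondrial
genome to the nucleus and can be lost from either location, but
functional re-insertion into the mitochondrial genome — and regain after
loss — are excluded. The transition cost matrix therefore has finite
entries only for `M→N` (transfer, cost `c_t`, default 1), `M→L` and
`N→L` (loss, cost `c_l`, default 1), zero on the diagonal and infinity
elsewhere. Transfer and loss are weighted equally by default because
nothing in the data motivates a weighting; both costs are configurable
and scaling both by a constant provably changes only the reported cost,
not the event counts.

Minimisation uses Sankoff's dynamic program with one twist: node values
are pairs `(cost, transfers)` ordered lexicographically. Because the
lexicographic order on pairs is translation-invariant, sums of
independent minima minimise separately, so the DP is exact; it returns
the minimum cost and, among all minimum-cost labelings, the fewest
transfers. Counts therefore read "at least this many independent
transfers", which is the right semantics for a census in which deeper
losses can hide transfers. Polytomies are handled by summing per-state
child vectors. Tips map to admissible state sets: `M/N/L` to
themselves, `D` (both copies retained) to `{N}` — a transfer has
demonstrably occurred, with the duplication surfaced as a flag — and
`?` to all three states at zero cost, because for transcriptome-only
taxa absence of evidence must not be scored as loss.

A virtual stem edge above the root carries the fixed ancestral state
`M` (the last eukaryotic common ancestor was mitochondrion-encoded for
every gene in scope). Without it, a gene nuclear in all sampled taxa
would count zero or two transfers depending on rooting; with it, it
counts exactly one early transfer.

Backtracing picks one representative labeling, breaking ties by the
state preference `M > N > L` and setting an ambiguity flag whenever any
tie was broken. The preference keeps ancestors mitochondrial at ties,
which places tied events toward the tips (e.g. a node above one `N`
leaf and one `L` leaf stays `M`, giving a tip transfer plus a tip loss
rather than an ancestral transfer plus a loss). Event maps name edges
by the child node's identifier.

`replacement_events` collapses a gene module to a single character per
taxon (`M` if any member gene is mitochondrion-encoded, else `L`, or
`N` where an optional replacement marker — a nuclear heme lyase in the
cytochrome *c* maturation case — is present) and counts module-level
events with the same DP.

State percentages in the per-gene table are over taxa with a
determinate state; `D` counts toward `pct_N` so the three percentages
sum to 100.

## Clustering and summaries

Pairwise taxon distance is the Hamming proportion over genes observed
(non-`?`) in both taxa, with `D` its own category; a pair with no
co-observed genes receives distance 1 with a warning. Hamming is the
minimal metric on categorical retention patterns, and it satisfies the
triangle inequality on fully observed data. Agglomeration is average
linkage (the conventional default for presence/absence profiles),
implemented directly via Lance–Williams updates so that ties in the
minimum inter-cluster distance can be broken deterministically by the
lexicographic order of cluster representatives — making the dendrogram
invariant to input order. Taxa with no observed data should be dropped
first (`taxa_with_data`), mirroring the practice of excluding species
without nuclear genomic or transcriptomic data. The dendrogram is
emitted as Newick with heights encoded as branch lengths. Group
summaries tally state counts and fractions per (group, gene) —
fractions over observed states — and merge taxa with identical
full-row patterns into sectors with multiplicity, the tabular
equivalent of a Coulson plot.

## Presequence consensus

A protein's mitochondrial targeting signal is accepted when at least
`k` of `n` predictors call it (default 2 of 3). Missing calls shrink
the denominator rather than counting as negative — the original
three-tool protocol never faced missing calls, and silently treating
absence as a negative prediction would bias verdicts — and a negative
verdict that enough missing calls could have flipped is flagged
indeterminate. Verdicts are provably monotone in `k`. Joining verdicts
onto the gene-state matrix yields the cross-tabulation of location
state × MTS call that underlies the observation that
mitochondrion-encoded versions lack detectable presequences.

## The burst-upon-drift simulator

The simulator follows a haploid, asexual population of `N` cells; each
cell carries `G` genes in states `M`, `D` (functional copies in both
compartments) or `N`; a gene with no functional copy makes the cell
inviable. Heteroplasmy is deliberately not modelled — the model is
drawn at cell level, and within-cell mitogenome dynamics would add
parameters the theory does not constrain.

Per generation, mutation acts first: each `M` gene gains a functional
nuclear copy with probability `mu_dup`; each functional mitochondrial
copy is inactivated with probability `mu_mt`; each functional nuclear
copy with probability `mu_nuc`. The three per-copy events are
independent within the generation and composed (duplication followed in
the same generation by mitochondrial-copy loss yields `N`), which
reproduces the first-order transitions `M→D` (`mu_dup`), `D→N`
(`mu_mt`), `D→M` (`mu_nuc`), `M→inviable` (`mu_mt`), `N→inviable`
(`mu_nuc`) exactly to first order while keeping simultaneous events
well-defined. Reproduction then draws the next generation by
fitness-weighted multinomial resampling of whole parental genotypes
(mitochondrial and nuclear loci co-transmitted); fitness is
multiplicative across genes with `w_M = 1`, `w_D = 1 − s_dup`,
`w_N = 1 − s_nuc`, clamped at 0. Mutation-before-selection is the
standard Wright–Fisher ordering and keeps generation sizes exact;
inviable cells stay in the census with fitness 0 rather than being
removed mid-generation. A bottleneck window (generations
`start … start+duration−1`, sizes `N_b`) multiplies `mu_mt` by a
factor for its duration. Setting `s_nuc < 0` makes the nuclear-only
state beneficial, recovering the adaptive sweep path without separate
code. Fixation of a gene is recorded at the first generation when
every living cell is `N` for it (absorbing only when `mu_nuc = 0`);
extinction is a recorded outcome.

Two internal engines implement the identical model: an exact
count-based engine, fully vectorised over replicates, for single-gene
runs (used for the large calibration runs), and a per-cell engine for
multi-gene runs where co-transmission correlates genes. Their
statistical agreement is itself under test.

Burst statistics: `window_fraction` is the share of fixations dated
inside the bottleneck window; `burst_index` divides it by the window's
share of total time (≈ 1 under time-homogeneous fixation, ≫ 1 when
transfers cluster in the bottleneck); the index of dispersion is
variance/mean of fixation counts over ten equal time bins. With no
fixations — or no bottleneck, for the window-based statistics — the
values are reported as undefined (`None`), never as numbers.

## Synthetic data

The generator stands in for a real multi-taxon census. Gene states
evolve down the tree as a continuous-time Markov chain whose generator
allows only `M→N`, `M→L`, `N→L`, started from `M` above the root; this
guarantees every simulated history satisfies the irreversibility the
inference assumes, and the returned event log is the ground truth that
inference is scored against. Burst edges multiply the transfer rate,
emulating episodic relocation on particular lineages. Detection noise
is applied last: in transcriptome-evidence taxa a truly encoded gene is
recorded `L` (optionally `?`) with probability `q`, reproducing the
"lost or not detected" conflation of real data. An optional dwell
variant routes transfers through `D` with an exponential dwell time;
it is off by default because dual retention is rare in nature.

Defaults (`rate_transfer = 0.15`, `rate_loss_m = 0.10`,
`rate_loss_n = 0.05` per unit branch length, `q = 0.05`, half the taxa
transcriptome-evidence, 20 genes) are chosen to produce matrices that
look like the real census at a small scale — a handful of transfers
and losses per tree with occasional masking — and to give the test
suite statistical power. No empirical rate estimates exist for these
quantities. What passing tests show is therefore internal consistency
(inference recovers, bounds, or calibrates against the processes the
generator implements), not agreement with any particular empirical
dataset: real data add phylogenetic error, correlated detection
failures across genes, and non-clocklike rate variation that the
generator does not emulate.

The predictor-call generator draws each tool's call as
Bernoulli(sensitivity) for true presequences and Bernoulli(1 −
specificity) otherwise, independently across tools — real predictors
share training biases, so real consensus calls are more correlated
than simulated ones.

## Numerical and design choices

* All randomness flows from one top-level seed; pipeline stages use
  named substreams (`rng.substream`), so runs are reproducible and
  stages are independently perturbable.
* Sankoff values use exact tuple arithmetic (floats enter only through
  user-supplied costs); the root value is asserted finite, which the
  cost matrix guarantees.
* Losses are recovered from `cost = c_t·transfers + c_l·losses`, exact
  for every labeling under this cost matrix.
* The diffusion benchmark for deleterious fixation,
  `(1 − e^{2s}) / (1 − e^{2Ns})` for one initial copy with cost `s`,
  agrees with the exact single-gene Wright–Fisher chain to ≪ 1 % at
  `N = 100`, `s = 0.01`.
* Simulation sizes in the test and acceptance runs (20 000 replicates
  for single-gene calibrations; 150 replicates × 10 genes per arm for
  the bottleneck contrast; 1000 enumeration cases; 500 synthetic
  matrices; 200 clustering replicates) were chosen so that each
  statistical check has comfortable power at its stated tolerance
  while the whole suite runs in minutes on one CPU.
* Yule trees grow from the root split (two lineages at time 0); trees
  conditioned on tip count extend all tips to just before the next
  unrealised split, keeping them ultrametric.

## Known limitations

* Parsimony counts are lower bounds by construction; no likelihood
  model of rate variation is provided, and transfers erased by
  downstream losses (or merged with a sibling transfer under an
  all-nuclear ancestor) are invisible to any tip-pattern method.
* The clustering metric and linkage are conventional choices; exact
  reproduction of any particular published dendrogram is not promised.
* The simulator's cell-level treatment ignores heteroplasmy, sexual
  reproduction and mito-nuclear linkage disequilibrium beyond full
  co-transmission; `D`-state dynamics stop at duplication (no sub- or
  neo-functionalisation).
* tRNA gain/transfer is excluded from the default gene universe; its
  status as transfer is contested.
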