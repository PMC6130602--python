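# Methods

`coevo` clusters gene presence/absence profiles by their evolutionary
history on a reference phylogeny rather than by raw vector distance.
This note records the models, the numerical choices, and the limits of
what the test suite demonstrates.

## The correlated-evolution test

For two binary characters X and Y (presence/absence of two gene
families across genomes at the tips of a rooted tree with branch
lengths), two continuous-time Markov models are contrasted.

**Independent model (4 parameters).** Each character evolves by its own
2-state chain with gain rate α (0→1) and loss rate β (1→0):

    Q = [ -α  α ]
        [  β -β ]

The joint likelihood factorises into the two single-character pruning
likelihoods.

**Dependent model (8 parameters).** The pair evolves as one 4-state
chain over joint states S1=(0,0), S2=(0,1), S3=(1,0), S4=(1,1) with
eight free transition rates q12, q13, q21, q24, q31, q34, q42, q43.
The four "dual" transitions in which both characters change at once
(q14, q23, q32, q41) are structurally zero. The independent model is
the submodel with q12=q34, q13=q24, q21=q43, q31=q42.

The statistic is LR = 2(lnL_dep − lnL_indep), referred (for reference
p-values) to χ² with 8 − 4 = 4 degrees of freedom. Finite trees make
this reference approximate; the package's calibration test measures the
actual null rejection rate by simulation rather than assuming the
asymptotics.

### Likelihood computation

Felsenstein pruning over the tree with per-node rescaling to avoid
underflow. The 2-state transition probabilities use the closed form
P(t) = π + e^{−(α+β)t}(I − π). The 4-state transition matrices are
computed by eigendecomposition of Q — exact for diagonalisable rate
matrices and far cheaper than per-branch Padé exponentials inside an
optimiser loop — with two safeguards: the eigenbasis must reconstruct Q
to 1e-9 (otherwise the evaluation falls back to `scipy.linalg.expm`),
and rows of P are clipped to [0, 1] and renormalised. The eigen route
is validated in the test suite against a truncated-series matrix
exponential to 1e-10 and against brute-force enumeration of internal
states on hundreds of random small trees.

Missing tip states are treated as ambiguous (partial likelihood 1 in
every state). Zero-length branches are floored at 1e-9 inside
likelihood computations only (`FitOptions.length_floor`).

### Root prior

Uniform over states by default (1/2 per state independent, 1/4
dependent); a stationary-distribution prior is available via
`FitOptions.root_prior="stationary"`. With the uniform prior the
likelihood is not exactly invariant to the root position, but the
rooting-robustness test shows the LR vectors are empirically almost
unchanged across rootings (Pearson r > 0.9, typically > 0.99).

### Optimisation

Rates are fitted as log10 values bounded in [1e-7, 1e3] after the tree
is rescaled to mean root-to-tip depth 1 (the LR is invariant to jointly
rescaling rates and branch lengths; the factor is recorded on the tree
table). The independent model factorises, so each character is fitted
separately (2 parameters each). Multi-start strategy: one
data-informed start (tip frequencies for the independent model; the
independence-structured embedding of the fitted independent model for
the dependent model) plus seeded log-uniform random restarts (10 by
default); every start gets a short exploratory L-BFGS-B pass
(`explore_maxiter=30`) and the best point is polished to full accuracy
(ftol 1e-12). Seeding the dependent fit at the fitted independence
point means the dependent likelihood can essentially only improve on
the independent one, which enforces the nesting inequality
lnL_dep ≥ lnL_indep up to optimiser noise. Negative LR excursions
below 1e-3 are clamped to zero; larger ones trigger one refit with 5×
restarts and are flagged if they persist. A comparison against a 4×
heavier optimiser on null pairs showed mean lnL improvements below
0.01, i.e. the defaults are converged; on simulated pairs the fitted
LR and log-likelihoods also agree to 4 decimals with an independent
R implementation of the same test.

### All-pairs contract

`all_pairs_lrt` tests every unordered pair of distinct, informative
(non-constant) profiles once. Per-pair random seeds derive from the
global seed and the pair's position in sorted-id order, so results are
bit-identical regardless of evaluation order, chunking (`chunk=(k, n)`
static partitions) or checkpoint resumption. The diagonal of the LR
matrix is set to the maximum off-diagonal LR so that self-distance
becomes zero after the distance transform.

## Distances and clustering

d(i, j) = LR_max − LR(i, j) with a zero diagonal, where LR_max is the
largest observed LR; adding a constant to all LRs leaves d unchanged.
Clustering is between-group average linkage (UPGMA) via
`scipy.cluster.hierarchy`; merge heights are the plain between-group
mean distances (not halved), so cut heights h live on the LR scale.
Profile ids are sorted lexically before linkage, which fixes tie
resolution and makes the dendrogram independent of input order. `cut`
joins leaves connected through merges of height ≤ h; `cut_k` picks the
height yielding exactly k clusters. Singletons are reported as
clusters of size 1.

## Profiles

A gene is present in a genome when a homology hit reaches e-value ≤
threshold (default 1e-20; the comparison is configurable because
"threshold 1e-20" admits either convention) and always present in its
own source genome. Entries are strictly 0/1 — no copy-number
weighting. Identical columns collapse to one distinct profile whose
multiplicity counts its genes; the representative id is the lexically
smallest member. Ranks, when absent from a hit table, are assigned per
query by ascending e-value with ties broken by descending bitscore then
lexical subject id. `flag_unexpected_hits` uses a strict < e-value
comparison (default) and a rank ceiling, for flagging genes with
unexpectedly strong hits to a chosen genome set. Constant profiles
(all-present/all-absent over the analysed genomes) carry no signal for
the pairwise test and are excluded, with a record.

## Tree rooting

`midpoint_root` places the root halfway along the longest tip-to-tip
path (lexical tie-break). `mad_root` implements minimal ancestor
deviation rooting: for each branch position, every tip pair (i, j) with
induced ancestor m contributes the relative deviation
|2·d(i, m)/d(i, j) − 1|, and the root minimises the root-mean-square of
these deviations. Within a branch the spanning-pair sum of squares is
quadratic in the root position, so the per-branch optimum is closed
form; the branch winner is confirmed by evaluating the full objective,
and ties keep the first branch in post-order. Both operations work on
an unrooted adjacency view (a bifurcating root is suppressed first), so
they preserve tip-to-tip path lengths exactly.

## GO evaluation

Wang / G-SESAME term similarity with edge weights 0.8 (is_a) and 0.6
(part_of), configurable. Genes are compared by best-match averaging of
their directly assigned terms (no pre-propagation of annotations up the
DAG — ancestors enter only through the Wang S-values;
`propagate_annotations` expands annotation sets to their ancestor
closures for sensitivity analysis).
Cluster scores are means of within-cluster gene similarities; the
overall score weights clusters by their number of annotated genes, and
clusters with fewer than two annotated genes are excluded and reported.
The tip-relabel null permutes gene labels over the fixed cluster
structure.

Term enrichment uses Pearson's X² = Σ_c (O_c − E_c)²/E_c per GO term
with frequency ≥ 5 (default), with expected counts proportional to
annotated cluster sizes (annotated-gene totals, not all-gene totals).
The null distribution comes from randomly reassigning all annotated
genes to clusters of the observed sizes (default 100,000 resamples);
p-values use the add-one estimator (1 + exceedances)/(1 + resamples),
which never returns zero and differs from the naive fraction.
Benjamini–Hochberg adjustment spans all tested terms within one cut
height. Because X² is discrete, p-values are conservative
(super-uniform) when cluster sizes are highly regular; with
heterogeneous cluster sizes the null p-value distribution is close to
uniform (Kolmogorov distance < 0.05 in the calibration test).
`binomial_overrepresentation` is the exact one-sided tail
P(X ≥ k | n, p0) with p0 the global flagged fraction.

## Simulators (validation harness)

The simulators exist so that every statistic can be tested against
known truth; the latent-block construction is a harness device, not
part of the inference method. Trees come from a seeded birth–death
process (dendropy). Characters evolve by exact CTMC realisation
(exponential waiting times along each branch). Rates are interpreted
per unit of *mean root-to-tip depth* by default (`rate_unit="depth"`),
so "gain = loss = 1" means about one expected gain and one loss per
root-to-tip path regardless of the tree's absolute scale — the patchy,
informative regime for presence/absence data; `rate_unit="branch"`
exposes raw units. Correlated blocks share one latent
"pathway presence" character per block; each member copies its tip
states with independent per-tip flips at probability `noise` (default
0.05). Background profiles evolve independently. Draws can be
conditioned on being informative (non-constant), matching the
pipeline's exclusion of constant profiles.

What the simulations do *not* emulate: homology-search noise, copy
number, gene-family boundaries, correlated LGT of whole operons beyond
the block construction, or tree estimation error. Passing tests
demonstrate correctness of the statistics under the stated models, not
performance on real genomes.

## Problem sizes in the test suite

The statistical tests run at a deliberate desk scale: a 74-tip tree
(matching the subsampled analysis the method is designed for), 20
profiles / 190 pairs for rooting robustness, 500 simulated pairs for
null calibration, 20 replicate 10-profile datasets for block recovery,
and 2,000 null terms for enrichment calibration. The measured null
rejection rate at the χ²₄ 0.95 quantile is ≈ 0.048 under the default
simulation conditions; saturated regimes (rates well above ~1 event
per unit depth) make the test visibly conservative (≈ 0.02 at 4×).

## Known limitations

- The χ²₄ reference for the LR is asymptotic; at a few dozen tips the
  null tail is close to, but not exactly, χ²₄, and degrades away from
  the moderate-rate regime.
- The uniform root prior is a convention; LR values shift slightly
  under re-rooting (empirically r > 0.99 between rootings).
- UPGMA merge heights need not be monotone for arbitrary non-metric
  inputs; cuts are still well defined via cophenetic distances.
- All-pairs cost grows quadratically in the number of distinct
  profiles; use chunked runs with a shared checkpoint for large sets.
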