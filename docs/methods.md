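# Methods

## The model

`parsimotif` performs de novo discovery of a transcription-factor binding
motif in a set of DNA sequences under a ZOOPS ("zero or one occurrence per
sequence") mixture.  A sequence x of length L is generated either entirely
by a homogeneous *flanking* Markov model (probability 1 − γ), or
(probability γ) by drawing a start ℓ uniformly over the L − W + 1 valid
positions and a strand s (forward with probability p₊), emitting the
width-W window from the *motif* model — its reverse complement for the
minus strand — and the rest from the flanking model.  After the motif, the
flanking chain conditions on the actually observed preceding symbols, so
the mixture is a properly normalized distribution over sequences (the test
suite verifies that it sums to one by enumeration at small L and W).

The motif model is an **inhomogeneous parsimonious Markov model (PMM)**:
one parsimonious context tree (PCT) per motif position i, of depth
min(i − 1, d) with maximal order d = 4 by default, so position 1 always
has a single leaf.  A PCT partitions each layer of the context (the j-th
preceding position) by labelling the children of every inner node with
disjoint alphabet subsets that cover {A,C,G,T}; a leaf aggregates the
product set of subsets along its path and carries one conditional
distribution.  A PCT with one leaf ignores its context (PWM behaviour); a
complete tree with 4^depth leaves is a full inhomogeneous Markov model of
that order; everything in between shares parameters across contexts.

## Structure learning

Tree structures are learned by exact MAP search.  The score of a tree τ at
one position is

    S(τ) = Σ_leaves log DirMult(counts_leaf | α_leaf) + L(τ) · ln κ

where L(τ) is the number of leaves and the structure prior is proportional
to κ^L(τ); κ is exposed on a log2 scale (`log2_kappa`).  Leaf
hyperparameters are BDeu-style, α_leaf,a = ess · |context set| / 4^(d+1)
with ess = 4 by default, so the total prior mass at a position is the same
for every structure — a requirement for comparing structure scores.  Counts
may be fractional (expected counts from EM); the Dirichlet-multinomial
marginal is evaluated through log-Gamma functions.

The optimum is found by a bottom-up dynamic program over the lattice of
context product sets.  For the DNA alphabet each inner node chooses among
the 15 set partitions of {A,C,G,T}; aggregated counts for all 15^depth
product sets are computed by tensor contractions, leaf scores are
evaluated vectorized, and a max over partitions is propagated layer by
layer.  The search is exact; the test suite checks it against exhaustive
enumeration of every tree on random fractional count tables at depth ≤ 2.
Ties prefer fewer blocks, then lexicographically smaller subset labels, so
results are deterministic.

Limits: a very negative `log2_kappa` forces single-leaf trees (PWM); a
very positive one forces complete trees (full order-d model; order 1 gives
the weight array model, WAM).  Note that the limit is relative to the data
mass: with n sites and a dependency of I bits at one position, the prior
must satisfy 3·|ln κ| > n·I·ln 2 to force a single leaf there, so the
conventional "−1000" used in experiment configurations is the PWM limit
only for the sample sizes actually used; unit tests of the limit algebra
use ±10⁶.

## EM

Parameters are estimated by MAP-EM over the latent occurrence, position,
and strand variables.  The E-step computes exact posteriors in log space.
The M-step updates γ with a Beta(1,1)-equivalent pseudocount, refits every
position's context counts from responsibility-weighted windows
(reverse-strand windows contribute their reverse complements), re-learns
every PCT structure from those expected counts (structural EM), and sets
leaf distributions to posterior means.  The flanking model and p₊ (0.5 by
default; CTCF binding is strand-symmetric) stay fixed.

Inside the M-step the structure search uses the *profile* leaf score — the
expected complete-data log posterior with the posterior-mean parameters
plugged in — rather than the Dirichlet-multinomial marginal.  With the
marginal score, structure re-selection could in principle decrease the
traced objective; with the profile score, structure and parameters
maximize the same function, so the log joint posterior (likelihood +
Dirichlet pseudocount kernels + structure prior + γ kernel) is provably
non-decreasing across iterations, which the suite asserts on twenty seeded
fixtures with 10⁻⁸ slack.  Standalone structure learning (`learn_pct`,
`fit_pmm`) defaults to the marginal score.

Each restart initializes responsibilities by giving every sequence a
uniformly drawn (position, strand) with occurrence mass 0.5 and starts
with an M-step.  Convergence is declared when the posterior improvement is
below `tol · (|F| + 1)` *and* no longer growing — ZOOPS EM routinely
crawls for several iterations before taking off, and a naive relative-change
rule stops runs in that phase.  The best of `restarts` seeded runs is kept.

A fitted model is identifiable only up to a global window shift and strand
orientation: a motif shifted by one column, or reverse-complemented, with
the window moved accordingly, explains the data almost equally well
whenever the motif edges are uninformative.  Site-recovery metrics
therefore canonicalize by the run's modal alignment transform (offset
signed by the true strand, plus orientation) before comparing to ground
truth.

## Classification and evaluation

Following the classification protocol, a homogeneous order-2 background
model λ is trained on the union of positive and negative training
sequences and doubles as the flanking model of the foreground ZOOPS model,
so foreground and background differ only in the possibility of a motif
occurrence.  Test sequences are scored by the log-likelihood ratio.
Sensitivity at fixed specificity uses the ceiling/type-1 empirical
quantile: the threshold is the smallest score t such that at least
⌈specificity · n⌉ negative scores are ≤ t, and positives count when
strictly above t.  The same convention is used for the site-prediction
threshold (alpha-quantile of negative window scores, hits at ≥ threshold).
AUC-ROC uses the Mann–Whitney statistic with ties counted ½.

κ is selected by seeded, class-stratified k-fold cross-validation on the
training split (10-fold in the reference protocol): per fold, background
on the in-fold union, ZOOPS-EM on in-fold positives, sensitivity on the
held-out fold; the grid value with the highest mean sensitivity wins, ties
going to fewer leaves.  When two κ settings are compared on the same
folds, the fold-paired standard error is the appropriate scale for the
difference, and the benchmark test uses it.

## Site prediction and motif statistics

Sites are predicted by scanning every window on both strands with the
motif model alone and keeping windows scoring at or above the empirical
(1 − alpha)-quantile of the same scan on a control set.  alpha defaults to
10⁻⁴ per window-strand and is always logged; predictions are per-window,
so multiple sites per sequence are possible.

Mutual information of order k at position i is the plug-in estimate (in
bits, range [0, 2]) between the symbol at i and the preceding k-mer,
computed from the empirical joint table of the aligned sites.  G = 2·n·ln2·MI
is referred to a χ² distribution with (4 − 1)(4^k − 1) degrees of freedom
(the standard independence test for a 4 × 4^k table); a permutation null is
available as an option.  No bias correction is applied by default (the
plug-in estimator's positive bias, ≈ df / (2n ln 2) bits, is visible in
the tests' tolerances).  MI at fixed i is non-decreasing in k by
construction; the suite checks this on sampled sites.

Conditional sequence logos fix one position and display, per PCT leaf, the
raw conditional nucleotide frequencies of the sites whose context falls in
that leaf, scaled to the leaf's information content, with stack width
proportional to the number of matching sites; leaves are labelled with
Roman numerals in tree-traversal order.  Leaves matching no site render as
empty slots.  Rendering produces SVG via matplotlib glyph paths with a
fixed hash salt, so output bytes are reproducible for fixed inputs and
library versions.

## Synthetic data

The generator emulates exactly the statistical structure the model family
assumes.  Backgrounds come from an order-2 homogeneous chain with ~41% GC,
CpG dinucleotides depleted to a quarter of independence, and a mild run
persistence bonus; sequence lengths are uniform on 189–888 bp, the length
span of the reference ChIP-seq positives.  Motifs are planted zero-or-once
per sequence (occurrence probability 0.9 by default — ChIP-seq peak sets
contain a minority of sequences without a recoverable site) at a uniform
start on a random strand.

`default_dependent_motif()` is a width-20 fixture (its tables are invented
fixture values, not estimates from any data set) shaped like the CTCF core
motif's qualitative anatomy: a moderately conserved central block
(positions 4–15, consensus CCACCAGGTGGC) with mild first-order coupling at
alternating columns, and an unconserved 3′ block whose information is
carried almost entirely by dependencies — position 17 is a
near-deterministic permutation of the uniform position 16 (analytic MI
≈ 1.3 bits, invisible to a PWM), 18 a permutation coupling of 17, 19
conditioned on the run 15–18 through a table constant in position 16 (so
its dependencies genuinely reach the fourth predecessor), and 20 a
moderate coupling of 19.  Analytic MI of any (position, order) pair and
exact conditional laws of arbitrary context sets are computed from the
spec by closure enumeration, which is what the recovery tests compare
fitted models against.

The default benchmark is 1,500 positives / 3,000 negatives with a 2:1
train/test split per class.  What passing tests on this generator do *not*
show: robustness to real ChIP-seq artifacts — peak-shape positional bias,
repeats, copy-number effects, composite or multiple motifs, or motif-width
misspecification — none of which the generator emulates.

## Problem sizes and numerical choices

The test suite runs the heavy studies at desk scale as the package's own
choice of problem size: the complexity-sweep test uses the default
1,500/3,000 benchmark with 10-fold CV, two κ settings, 2 EM restarts and
capped iterations; conditional-law recovery uses 5,000 sampled sites; the
MI error-rate study uses 100 replicates of 20,000 sites each, a size at
which the weakest planted coupling (≈ 0.008 bit at fourth order, 765
degrees of freedom) is resolvable — at a few thousand sites those cells
fall below the χ² detection floor and a power claim would measure sample
size, not the test; EM monotonicity uses twenty 20-sequence fixtures.  The
acceptance script trains two full models on the benchmark's training split
and evaluates on the test split with 2 restarts.

Degenerate inputs: sequences shorter than the motif width are carried with
the occurrence forced absent; an M-step with zero motif mass leaves the
motif unchanged and logs a warning; unobserved contexts with ess = 0 fall
back to uniform; γ at the boundary {0, 1} is handled in log space.
Context words are indexed with the nearest predecessor as the most
significant digit throughout; PCT context labels are printed in sequence
order (nearest predecessor last), matching the usual figure convention.
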