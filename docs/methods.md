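# Methods

## Composition representation

A read is summarized by its 4ⁿ word counts over A,C,G,T, indexed
lexicographically (A<C<G<T); the order is fixed across the package and its
serialized centroids.  Counting is overlapping by default (step 1; L =
len − n + 1 valid windows) with non-overlapping (step n) and
reverse-complement stacking available as flags.  Windows containing a
non-ACGT character are skipped deterministically rather than randomized —
reproducibility outweighs the tiny bias for typical N rates.  Reads with
zero valid windows are dropped with a warning before clustering: the
likelihood is undefined at L = 0.

The package targets small word sizes (n ≤ 8 enforced, n = 1..3 sensible
for 30–400 bp reads) so that L ≫ 4ⁿ and counts are informative rather
than mostly 0/1.

## Likelihood and distances

The multinomial log-likelihood of counts c (total L, frequencies p)
against centroid composition q reduces, via Stirling, to −L·D_KL(p|q) with
natural logarithms and the 0·log 0 := 0 convention.  Near p = q it
degenerates to the Gaussian quadratic form Σ(c_i − Lq_i)²/(2Lq_i), which
the suite uses as a small-perturbation oracle (agreement to < 5% relative
at 1% perturbation).

The alternative kernels: L2 (Euclidean between simplex frequencies), d2
(1 − cos θ, scale-invariant, computed on unit-norm count vectors), d2\*
(½(1 − cos) between count vectors standardized as
(x − QS)/√(QS) against the cluster's zero-order Markov expectation Q —
the product of the cluster's pooled single-base frequencies), χ²
(Σ(c_i − Q_iL)²/(Q_iL) against the same Q), and the symmetrized KL
divergence Σ(p_i − q_i)log(p_i/q_i).  Standardized entries with Q_i = 0
and x_i = 0 are set to 0 for continuity; Q_i = 0 under positive counts is
an error.

## Clustering algorithms

All methods iterate assignment and centroid-update steps from a seeded
random initial assignment (every cluster seeded non-empty) followed by one
maximization step — this always produces valid simplex centroids, unlike
choosing raw reads as centroids.  Argmin ties break toward the lowest
cluster index.  Hard methods stop when assignments stop changing, or at
`max_iter` (default 300) with `converged=False`; soft EM stops when the
largest membership change drops below `tol` (default 1e-6).

Centroid updates: hard/soft EM pool (membership-weighted) member counts,
add the pseudocount, and normalize; d2 sums member unit vectors and
renormalizes; L2 and k-means take the arithmetic mean (k-means in the
whitened space, where whitening divides each coordinate by its population
standard deviation computed once on the input; zero-variance coordinates
pass through unscaled); d2\* and χ² recompute the cluster's pooled base
frequencies → Q and pooled count vector.  For the sym-KL method the
pooled-count centroid is used as well — no minimizer is derived for that
kernel in the literature this follows, and the pooled centroid is the
natural composition estimate.

Distortion is Σ_a L_a·D_KL for EM (the exact negative log-likelihood up
to a constant), the within-cluster sum of *squared* Euclidean distances
for L2/k-means (the intra-cluster variance — the quantity the mean update
actually minimizes, hence monotone), Σ d2 for d2 (monotone under the
renormalized-sum update), and the plain per-read distance sum for
d2\*/χ²/sym-KL, which carry no monotonicity guarantee.  Monotonicity
assertions use a tolerance of 1e-9 relative to the trace scale, since the
distortions are O(10³–10⁴) and float64 summation noise exceeds 1e-9
absolute.

The pseudocount (default 1 on pooled centroid counts, 0 on per-read
vectors) keeps centroid compositions strictly positive so D_KL stays
finite; per-read zeros are harmless under 0·log 0 = 0.  Two exceptions:
the sym-KL kernel needs mutual support, so there the pseudocount is also
applied to per-read frequencies (the method refuses to run with
pseudocount 0); and the zero-order kernels pseudocount the pooled *base*
counts so Q is strictly positive.  When a model is built from a bare
count matrix rather than sequences, per-read base counts for Q are
estimated from the positional marginals of the word counts (exact at
n = 1); building from sequences uses exact 1-mer counts.

Soft EM computes memberships in the log domain with max-subtraction —
exp(−L·D_KL) underflows already at moderate read lengths.  Equal cluster
priors are assumed throughout.  Three per-iteration traces are recorded:
the expected complete-data log-likelihood (the Q-function
−ΣZ_aα·L_a·D_KL), the observed-data mixture log-likelihood, and the
Dirichlet-penalized observed-data log-likelihood.  Only the last is
guaranteed non-decreasing: the E-step maximizes the free energy (Q-function
plus membership entropy), not the Q-function itself, so the Q-function can
dip by ~1e-5 relative mid-run; and the pseudocounted M-step maximizes the
penalized, not the raw, likelihood.  The monotonicity tests therefore
assert the penalized trace.

Empty clusters: by default the cluster is reseeded with the read farthest
from its current centroid (logged); the strict policy (`fail`) raises
instead, reproducing the behaviour of a plain EM implementation.

Restarts run seeds seed, seed+1, …, keeping the minimal-distortion
(maximal expected log-likelihood for soft EM) result.

## Consensus clustering

Each of `runs` rounds (default 20) draws floor(N·f) reads without
replacement (f default 0.8) and clusters them with the base method.  The
consensus distance is D_ij = 1 − #(together)/#(co-sampled); pairs never
co-sampled get D = 1 with a warning — conservative, and bounded in
runtime, unlike resampling until coverage.  The tree is scipy average
linkage on D, cut at K for the consensus partition, exported as Newick
via scikit-bio.

## Evaluation

Per-gene recall is R_G = max_k f_k over the gene's per-cluster fractions.
Soft runs are thresholded (read ∈ cluster α iff Z_aα ≥ ε); the ROC-like
sweep uses the exact grid of distinct membership values plus {0, 1}
rather than a fixed lattice, recomputes the "correct" cluster (the one
embracing the largest part of the gene's reads, ties to the lowest index)
at each ε, and closes the curve with the analytic (1,1) and (0,0)
endpoints before trapezoid integration for AUC.  A read assigned to both
the correct and another cluster counts toward TPR and FPR simultaneously;
this sweep is deliberately not the classical single-score ROC.

## Synthetic data

Sources are drawn i.i.d. from per-source zero-order base compositions,
lengths uniform in 500–10000 bp (the typical reference-transcript range);
the GC spread across sources (default 30–70%, with A=T and C=G within a
source) is the dial for inter-source divergence.  Reads are sampled with
source probability proportional to source length (uniform shotgun
coverage), uniform start, uniform strand (both strands by default, flag
to disable), and substitution-only errors: each base flips with the
configured probability to a uniformly chosen different base.  No indels,
no quality-score model, no paired ends.  Position/strand noise and error
noise come from independent substreams of the seed, so error-rate sweeps
are paired comparisons on identical fragments.

What passing on this generator shows — and does not.  Zero-order sources
make composition the *only* signal, so they exercise the estimators and
the optimization exactly, but they are kinder than real transcripts in
one way (no shared motifs between sources at matched composition) and
harsher in another (no higher-order structure to help).  In particular
the d2\* kernel standardizes away precisely the zero-order signal, so its
recall on these sources is near chance by construction — on real
sequences it draws on higher-order composition that this generator does
not emulate.  Trend results (recall vs read length and error rate) are
qualitative analogues at desk scale, not reproductions of reference-based
numbers.

## Problem sizes and defaults

The shipped experiments use 2–4 sources, 120–1000 reads of 30–400 bp,
word sizes 1–2, 10 seeds/replicates per condition, and 100 random
instances for the monotonicity sweeps; these sizes give stable means
(binomial standard errors well below the asserted margins) while keeping
any single check in seconds.  The trend experiments fix sources at GC
45%/55% — a moderate divergence comparable to the GC spread of mammalian
transcripts — so recall has headroom to move in both directions.  The
soft-threshold experiments use GC 45%/55% at 100 bp so memberships are
informative yet never saturate to exactly 1.0, keeping the ε → 1 limit
observable.  Defaults elsewhere: K = 2, max_iter = 300, tol = 1e-6,
pseudocount = 1, restarts = 1, subsample fraction 0.8, soft split cutoff
ε = 0.05.

## Known limitations

No automatic choice of K; no covariance corrections for overlapping-word
counts in d2\*; no amino-acid alphabets or gapped words; consensus
clustering is O(N² log N) and intended for thousands, not millions, of
reads; the d2\*/χ²/sym-KL engines can cycle and are reported honestly as
unconverged rather than forced to a fixed point.
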