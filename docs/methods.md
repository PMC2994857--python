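# Methods

This note records the statistical model as implemented, the numerical
choices behind it, and what the synthetic-data checks do and do not
establish.

## Data model and counting conventions

Input clones are assumed full length, pre-aligned, and indel-free; a clone
whose length differs from the wild type is rejected with an error rather
than aligned, because an indel breaks the codon frame that the whole
analysis depends on. The ambiguity code `N` masks a nucleotide position
from the 4×4 count matrix and masks its codon from the site counts for
that clone only (how the original experiments handled ambiguous calls is
not recorded anywhere we know of; masking is this package's convention).

Codon events are counted once per clone per site regardless of how many of
the three nucleotides changed, classified by translation: synonymous if
the translation is unchanged, nonsynonymous otherwise. Premature stops
count as nonsynonymous by default (`stop_policy="nonsynonymous"`); the
alternative `"drop-clone"` removes the clone from the stop site and all
downstream sites. The default follows the observation that stop-codon
production in these experiments is rare enough not to move results; a
rigorous treatment of truncation (every downstream codon is affected and
site-independence fails) is out of scope.

Coordinates are 1-based for both nucleotides and codons; the reading frame
is fixed at position 1.

## Multinomial estimation

Each column of the mutation matrix is an independent multinomial with the
Berger–Bernardo/Jeffreys reference prior Dirichlet(α), α = ½ per
component (one global α, also applied to the two-class codon counts).
Three point estimates appear in reports:

* relative counts `c_ij / c_+j`;
* the natural-parameter mean `E[log p_i] = ψ(n_i + α) − ψ(Σ(n_i + α))`
  (digamma), exponentiated and renormalized for tables — the *difference*
  of digammas is the standard Dirichlet result and is what reproduces the
  published estimates; and
* the polymerase-model MAP (below).

At the nucleotide count scale (~10⁴ events per column) all three agree to
well under 1% relative; at the codon scale (0–10 events per ~100 clones)
the prior matters, which is the reason for the Bayesian treatment.

## The polymerase PCR model

One thermal cycle acts on the sense/nonsense strand-frequency pair as
`Φ(s, n) = ((s + Tn)/2, (n + Ts)/2)` with T the 4×4 column-stochastic
polymerase operator; `P(T, k)` iterates Φ k times from each pure
nucleotide paired with its complement. k defaults to 30 — the experimental
number of mutagenic PCR cycles — and thermal cycles are treated as exactly
k applications of Φ (the distinction between thermal cycles and effective
doublings is not modelled). The iterative form is used directly; the
equivalent binomial-coefficient polynomial `2^k s_k = Σ_m C(k,m) T^m ·
(s₀ or n₀)` is kept only as a test oracle (k ≤ 7), since the expanded form
accumulates round-off.

Inference uses the log parameterization `T̃ = log vec T` with the four
column-sum constraints quotiented out: adding a constant to one column's
log-parameters leaves T unchanged, so the parameter space is the
12-dimensional quotient, represented by an orthonormal basis of the
orthogonal complement of the four column-indicator directions.

* **Likelihood**: product of four multinomials of the count columns under
  `P(T, k)`, with coefficients.
* **Fisher information**: expected information in the log-parameters with
  `E[c_ij] ≈ c_+j p_ij` (the observed column totals stand in for wild-type
  base composition, the usual approximation for coding sequences whose
  GC content is far from 0 or 1). Because every column of P sums to one
  identically, the Hessian-of-P term has exactly zero expectation, so the
  implementation's default path is the score outer-product form; the full
  expression is implemented and tested equal. All P-derivatives are
  propagated through the cycle recursion by forward-mode first/second-order
  differentiation arithmetic and are verified against central finite
  differences (step 1e-5, relative 1e-6).
* **Jeffreys prior**: half the log-determinant of the Fisher information
  projected onto the 12-dimensional quotient (the pseudo-determinant).
  It is invariant under the column gauge freedom, and scaling all column
  totals by c shifts the log-prior by exactly 6 log c (12 × ½), both of
  which are asserted in tests.
* **MAP**: BFGS in the quotient coordinates, analytic likelihood gradient
  plus a central-difference gradient of the (slowly varying) prior,
  gradient tolerance 1e-6, started from the linearized pull-back of the
  relative-frequency estimate through the complement operator
  (`T₀ = K + (2/k)(P_rel − I)K`, clipped and renormalized). The fit on the
  packaged counts converges in ~20 iterations / ~2 s.
* **Posterior sampling**: random-walk Metropolis in the quotient space.
  The proposal covariance is the inverse projected Fisher information at
  the MAP — which already contains the event totals c_+j, so no separate
  division by a sample size is needed (this resolves the ambiguity of
  "events vs clones": the effective sample size enters through c_+j, i.e.
  total event count) — with a scale factor adapted in short batches toward
  10–40% acceptance before the recorded chain. Rejection sampling makes
  the chain exact regardless of the proposal; acceptance rates of a few
  percent would only cost efficiency. Defaults: 50 000 steps, 5 000
  burn-in, thin 10, mandatory seed. Tests and the packaged analyses use
  shorter chains (2 500–12 000 steps), which for these count scales
  already reproduce posterior means to well within a posterior SD.

**Correctness anchor.** At k = 1 the map T → P is an affine bijection, so
by reparameterization-invariance of the Jeffreys prior the polymerase
posterior of P must coincide with the product-Dirichlet posterior; the
chain reproduces the Dirichlet mean and SD to within 0.1 posterior SD,
which validates likelihood, prior, and sampler jointly. At k = 30 the two
posteriors genuinely differ: multi-cycle strand mixing ties complementary
entries of P together (the posterior pools C←C with G←G), which is the
mechanistic structure the model exists to express. Consequently EoS scores
under the two nulls differ by a small but resolvable amount (~0.02–0.2
log₂ units at 87 clones) once the Monte-Carlo error is pushed below that
scale; the two nulls are interchangeable only at coarser MC precision.

## Codon operator and κ

The codon operator is the Kronecker cube `M = P ⊗ P ⊗ P` with codons
ordered lexicographically over (A, C, G, T) — exactly the index arithmetic
the Kronecker product induces; all named-codon access goes through an
explicit codon↔index map. `p_sn` sums the wild-type codon's column over
codons with identical translation *including the wild type itself*, so the
"synonymous" class means identical-or-synonymous and `p_sn + p_ns = 1`.
Genetic codes come from the NCBI translation tables (via Biopython), so
non-standard codes are available by table id. The partition machinery
operates on arbitrary codon classes; only the two-class analysis is
exposed, since amino-acid-level (20-class) analysis is underpowered at
realistic clone counts.

κ, the per-clone whole-protein nonsynonymous count, is simulated by
independent per-site Bernoulli(p_ns) draws (site independence is an
assumption of both hypotheses) and cross-checked against the exact
Poisson-binomial pmf computed by sequential convolution.

## Evidence of Selection and reliability

Site likelihoods fold the identity outcome into the synonymous class, so
each site is a binomial in `n_ns` out of `n` clones. The EoS integral is
evaluated with independent paired Monte-Carlo draws from the alternate
posterior (Beta on the site's own counts) and the null posterior
(mutation-matrix posterior pushed through the codon partition); whether
the draws should be paired or nested is not determined by the construction,
and the reported `mc_se` — the standard error of the paired-draw mean —
quantifies the integration error of this choice. Internally scores are in
nats; all reported values are log₂. Prior odds default to 1:1. The
reporting convention flags sites at 20:1 posterior odds (R ≥ log₂ 20 ≈
4.32); 4:1 or less is conventionally negligible. Negative R of small
magnitude is expected sampling variance (the alternate embeds the null)
and reads as zero.

Reliabilities D_HA and D_H0 are computed with the outcome sum done
*exactly* (n + 1 terms) and only the posterior integration by Monte Carlo;
each posterior draw contributes an exact binomial Kullback–Leibler
divergence, so both quantities are non-negative draw by draw.

The homogeneity check between populations at a site is a Bayes factor of
pooled versus independent two-class Dirichlet-multinomial marginal
likelihoods (α = ½). This is this package's own Bayes-factor realization
of the classical multinomial-homogeneity test — constants may differ from
other formulations. The per-site 1-d.o.f. χ² statistic is provided purely
for comparison plots against windowless χ² analyses.

## Synthetic data

The generator emulates the experiment's statistical structure: clones are
i.i.d. per-site draws from the columns of P (matching the inference
model's own assumptions), with optional hard purifying selection at
designated codons — a disallowed codon (nonsynonymous, or any change) is
redrawn until allowed, which under site independence equals rejecting
whole clones — and an optional pinned start codon emulating the cloning
artifact that makes the start site a built-in positive control. Defaults
mirror the experimental conditions: 87 clones per pool, 266 codons, the
packaged-count-derived mutation matrix, 30 cycles.

What it does *not* emulate: PCR lineage/jackpot effects (clones are
exchangeable), sequencing error, chromatogram quality, indels, stop-codon
truncation of downstream sites, epistasis/second-site suppression, or
fitness landscapes subtler than hard knockout. Passing tests therefore
show the estimators recover the model's own truth and control false
positives under the model's assumptions — not that real experiments are
free of the systematic artifacts (e.g. cloning hot-spots) that the
negative-control scoring of the unselected pool is designed to flag.

## Problem sizes and numerical choices

Validation runs use: MAP fits on count matrices of ~7×10⁴ events
(seconds); Metropolis chains of 2 500–12 000 steps; EoS at n_mc = 4 000–
20 000 draws per site (mc_se ≈ 0.01–0.03 log₂ units); a 203-codon,
87+87-clone simulation for threshold/false-positive checks; and 10⁵
replicates for κ (Kolmogorov distance to the exact pmf < 0.01 at 266
sites). Matrix validation tolerances are 1e-9 on column stochasticity;
the quotient projection uses an orthonormal SVD basis; softmax columns are
max-shifted before exponentiation.

## Known limitations

* The negative-control property is qualitative: at a null-generated site
  the score fluctuates at the scale set by the binomial sampling variance
  of the site's counts (typically within ±1 log₂ unit, far above the MC
  integration error), so "no selection" manifests as scores small relative
  to the 20:1 threshold, not as scores indistinguishable from zero.
* The black-box and polymerase nulls give interchangeable site calls at
  the 20:1 threshold, but their scores differ at the 0.02–0.2 log₂ level
  (see the correctness anchor above); analyses chasing sub-bit score
  differences should pick one null and keep it fixed.
* The MAP's effective cycle count k is taken at face value from the
  protocol; mis-specifying k redistributes error mass between T and the
  number of cycles with only second-order effects on P, but T itself
  should not be over-interpreted mechanistically.
* Hyper-mutability is not detectable by design: selection can only slow
  sequence drift, so unexpectedly many mutations at a site indicate
  sampling variance or experimental artifacts, and large R driven by
  *excess* mutations warrants scrutiny of the data rather than a
  selection call.
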