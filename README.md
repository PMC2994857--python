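# unigev — evidence of selection in unigenic evolution experiments

Unigenic evolution is a saturating-mutagenesis experiment: a single gene is
randomized by error-prone PCR, cloned, and passed through a functional
selection; sequencing the surviving ("selected") clones alongside a control
pool that skipped selection ("unselected") reveals which residues tolerate
mutation and which do not. `unigev` turns those two clone pools into
per-codon-site **Evidence-of-Selection (EoS)** scores — expected
log₂-odds-ratios between a site-specific selection hypothesis and a
selection-free null — together with Kullback–Leibler reliability (power)
estimates for every site.

It is aimed at molecular biologists and bioinformaticians analyzing
saturating-mutagenesis / functional-selection screens who want site-level
(not windowed) inference that is honest about small sample sizes
(50–100 clones) and rare events (per-nucleotide mutation rates of
10⁻³–10⁻²).

## The model

**Null models.** The unselected pool's substitutions are tabulated into a
4×4 count matrix *C* (entry *c₍ᵢⱼ₎* = wild-type nucleotide *j* read as
clone nucleotide *i*). Two nulls describe the per-nucleotide PCR mutation
matrix *P*:

* *Black box* (H₀): each column of *P* carries the objective Dirichlet(½)
  reference prior, giving the conjugate posterior
  `P[:, j] | C ~ Dirichlet(C[:, j] + ½)`.
* *Mechanistic polymerase* (H₀′): PCR is k (default 30) cycles of
  error-prone strand synthesis by a column-stochastic polymerase operator
  *T*; one cycle maps the sense/nonsense strand pair as
  `Φ(s, n) = ((s + Tn)/2, (n + Ts)/2)`, and *P(T, k)* is the k-fold iterate
  started from each pure nucleotide. *T* (12 free degrees of freedom) is
  inferred from *C* with a Jeffreys prior — the square root of the
  12-dimensional pseudo-determinant of the Fisher information on the
  quotient log-parameter space — by MAP optimization and Metropolis
  sampling. This null explains why complementary substitutions
  (e.g. C←A and G←T) occur at nearly equal rates.

**Codons.** Because sites mutate independently, the codon-level operator is
the Kronecker cube `M = P ⊗ P ⊗ P` (64×64). For each wild-type codon,
summing its column of *M* over codons with the same translation (under any
NCBI genetic code) gives `p_sn`, the probability of an
identical-or-synonymous outcome, and `p_ns = 1 − p_sn`.

**Scoring.** At site *j* with *n* clones and *n_ns* nonsynonymous codons,
the folded two-class multinomial likelihood is compared under the null
(parameters from the unselected pool's posterior pushed through *M*) and
the alternate (site-specific Dirichlet(½) posterior on the site's own
counts). The EoS score

  R_j = E[ log₂ Pr(data | H_A) / Pr(data | H₀) ]

integrates over both parameter posteriors (paired Monte-Carlo draws).
R ⪆ log₂ 20 ≈ 4.3 (20:1 posterior odds) is the conventional call for
selection; R is additive over disjoint sites. The reliability pair
(D_HA, D_H0) — exact sums over all possible outcomes, averaged over the
posteriors — gives the expected true-positive/false-negative and
true-negative/false-positive log-odds, i.e. the power of the test at that
site. The whole-protein nonsynonymous count κ per clone (a
Poisson-binomial variable) is provided as a mutagenesis-intensity
diagnostic.

## Worked example

The package ships the published misincorporation counts of the I-BmoI
homing-endonuclease experiment (87 + 87 clones, 266 codons, 30 PCR cycles):

```python
import numpy as np
import unigev as ug
from unigev.seqdata import SiteCounts

counts = ug.load_ibmoi_counts("unselected")
fit = ug.map_estimate(counts, k=30)
print(np.round(100 * fit.P.matrix, 2))

site = SiteCounts(site_index=17, wt_codon="TAT", n_sn=2, n_ns=0, n_total=87)
null = ug.dirichlet_null_hypothesis(counts, "TAT")
alt = ug.alternate_hypothesis(site)
res = ug.eos_score(site, null, alt, n_mc=10_000, seed=1)
d_ha, d_h0 = ug.reliability(null, alt, n_clones=87, n_mc=2_000, seed=1)
print(f"EoS R = {res.R:.2f} log2-odds, posterior odds ~ {2**res.R:.0f}:1")
print(f"reliability D_HA = {d_ha:.2f}, D_H0 = {d_h0:.2f} (log2)")
```

Output:

```
[[9.747e+01 1.300e-01 2.000e-01 1.130e+00]
 [2.400e-01 9.966e+01 2.000e-02 1.160e+00]
 [1.160e+00 2.000e-02 9.965e+01 2.300e-01]
 [1.130e+00 1.900e-01 1.300e-01 9.747e+01]]
EoS R = 7.40 log2-odds, posterior odds ~ 169:1
reliability D_HA = 6.10, D_H0 = 21.50 (log2)
```

The matrix is the MAP PCR mutation matrix in percent (columns = wild-type
nucleotide; note complementary entries nearly equal, e.g. G←G 99.65 vs
C←C 99.66). The example site is a tyrosine codon: tyrosine is
mutation-prone (≈5.5 nonsynonymous events expected among 87 clones), so
observing none yields decisive evidence of selection (169:1 odds), and the
reliability pair says such a site is, on average, clearly distinguishable
from an unselected one.

A command-line interface mirrors the library
(`unigev counts | fit-null | eos | power | kappa | simulate | subsample |
report`); try `unigev simulate --n-codons 50 --selected-sites 3,7` followed
by `unigev eos` on the generated FASTA files.

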