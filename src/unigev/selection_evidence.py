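"""Per-site Evidence-of-Selection scores and reliability estimates.

At each codon site the observed clone codons reduce to a two-class
multinomial: synonymous-or-identical versus nonsynonymous.  Two hypotheses
compete for those counts:

* the **null** — the site's (p_sn, p_ns) pair is whatever the selection-free
  mutagenic PCR process produces, with posterior uncertainty inherited from
  the unselected pool's misincorporation counts (either the black-box
  Dirichlet model or the mechanistic polymerase model) pushed through the
  codon operator; and
* the **alternate** — the pair is site-specific, with a Dirichlet(1/2)
  reference posterior built from the site's own counts, accommodating any
  selection mechanism.

The Evidence of Selection ``R`` is the expected log-odds-ratio of alternate
versus null given the observed counts, the expectation running over both
parameter posteriors; it is estimated by paired Monte-Carlo draws.  ``R``
is additive over disjoint sites.  Kullback-Leibler reliabilities ``D_HA``
and ``D_H0`` average the same log-ratio over all possible outcomes under
each hypothesis, giving the expected true-positive/false-negative and
true-negative/false-positive log-odds — the confusion matrix of the test.

Scores are accumulated in nats internally and reported in log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import betaln, gammaln

from .bayes_multinomial import DEFAULT_ALPHA, sample_mutation_matrices
from .codon_model import GeneticCode, STANDARD_CODE, synonymous_probability
from .seqdata import MisincorporationCounts, SiteCounts

LN2 = float(np.log(2.0))
#: Conventional posterior-odds cut for calling a site selected (20:1).
DEFAULT_ODDS_THRESHOLD = 20.0
#: Odds at or below this are conventionally negligible (4:1).
NEGLIGIBLE_ODDS = 4.0


@dataclass
class Hypothesis:
    """A hypothesis about a site's (p_sn, p_ns) pair.

    ``sample(m, rng)`` returns an ``(m, 2)`` array of simplex points drawn
    from the hypothesis' parameter posterior.  ``prior_odds`` multiplies the
    alternate-to-null prior ratio when this hypothesis is the alternate.
    """

    label: str
    sample: Callable[[int, np.random.Generator], np.ndarray]
    prior_odds: float = 1.0


@dataclass
class EoSResult:
    """Evidence of Selection at one site, reported in log base 2."""

    site_index: int
    population: str
    R: float
    mc_se: float
    D_HA: float | None = None
    D_H0: float | None = None
    n_ns_observed: int | None = None
    n_ns_expected: float | None = None

    @property
    def posterior_odds(self) -> float:
        return float(2.0**self.R)

    def flag(self, odds_threshold: float = DEFAULT_ODDS_THRESHOLD) -> bool:
        return self.R >= np.log2(odds_threshold)


def dirichlet_null_hypothesis(
    C: MisincorporationCounts,
    wt_codon: str,
    code: GeneticCode = STANDARD_CODE,
    alpha: float = DEFAULT_ALPHA,
    label: str = "H0_dirichlet",
) -> Hypothesis:
    """Null hypothesis from the black-box Dirichlet mutation-matrix posterior.

    Draws sample the four columns of P independently from their Dirichlet
    posteriors and push each draw through the codon partition for the
    wild-type codon.
    """

    def sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        P = sample_mutation_matrices(C, m, rng, alpha)
        p_sn = synonymous_probability(P, wt_codon, code)
        return np.column_stack([p_sn, 1.0 - p_sn])

    return Hypothesis(label=label, sample=sampler)


def polymerase_null_hypothesis(
    P_draws: np.ndarray,
    wt_codon: str,
    code: GeneticCode = STANDARD_CODE,
    label: str = "H0_polymerase",
) -> Hypothesis:
    """Null hypothesis from posterior draws of the PCR-model mutation matrix.

    ``P_draws`` is an ``(m, 4, 4)`` stack, e.g. a thinned Metropolis chain;
    the sampler bootstraps from it.
    """
    P_draws = np.asarray(P_draws, dtype=float)
    p_sn_all = synonymous_probability(P_draws, wt_codon, code)

    def sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, p_sn_all.size, size=m)
        p_sn = p_sn_all[idx]
        return np.column_stack([p_sn, 1.0 - p_sn])

    return Hypothesis(label=label, sample=sampler)


def point_mass_hypothesis(p_ns: float, label: str = "H0_point") -> Hypothesis:
    """Degenerate hypothesis concentrated at a single (p_sn, p_ns) pair."""

    def sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        return np.tile([1.0 - p_ns, p_ns], (m, 1))

    return Hypothesis(label=label, sample=sampler)


def alternate_hypothesis(
    site: SiteCounts, alpha: float = DEFAULT_ALPHA, prior_odds: float = 1.0
) -> Hypothesis:
    """Site-specific alternate: Dirichlet(n_sn + a, n_ns + a) posterior.

    The synonymous class folds in the identity outcome, so its count is
    ``n_total - n_ns``.
    """
    a_sn = site.n_total - site.n_ns + alpha
    a_ns = site.n_ns + alpha

    def sampler(m: int, rng: np.random.Generator) -> np.ndarray:
        p_ns = rng.beta(a_ns, a_sn, size=m)
        return np.column_stack([1.0 - p_ns, p_ns])

    return Hypothesis(label="HA", sample=sampler, prior_odds=prior_odds)


def site_log_likelihood(
    n_sn: int | np.ndarray,
    n_ns: int | np.ndarray,
    p_sn: float | np.ndarray,
    p_ns: float | np.ndarray,
) -> float | np.ndarray:
    """Log multinomial probability of the folded two-class site counts.

    ``n_sn`` counts identical-or-synonymous clones, ``n_ns`` nonsynonymous
    clones; together they exhaust the clones scored at the site.  Returns
    ``-inf`` where a zero-probability class has positive count.
    """
    n_sn = np.asarray(n_sn, dtype=float)
    n_ns = np.asarray(n_ns, dtype=float)
    n = n_sn + n_ns
    coeff = gammaln(n + 1) - gammaln(n_sn + 1) - gammaln(n_ns + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_sn = np.where(n_sn > 0, n_sn * np.log(p_sn), 0.0)
        term_ns = np.where(n_ns > 0, n_ns * np.log(p_ns), 0.0)
    out = coeff + term_sn + term_ns
    return out if out.ndim else float(out)


def eos_score(
    site: SiteCounts,
    null: Hypothesis,
    alt: Hypothesis,
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
    population: str = "mx",
) -> EoSResult:
    """Evidence of Selection: expected log-odds of alternate versus null.

    Monte-Carlo evaluation with independent paired draws from the two
    parameter posteriors; the reported ``mc_se`` is the standard error of
    the paired-draw mean.  ``R > 0`` favors selection; small negative values
    are sampling variance and read as zero.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sn = site.n_total - site.n_ns
    if site.n_total == 0:
        return EoSResult(site.site_index, population, 0.0, 0.0,
                         n_ns_observed=0, n_ns_expected=0.0)
    pA = alt.sample(n_mc, rng)
    p0 = null.sample(n_mc, rng)
    ll_A = site_log_likelihood(n_sn, site.n_ns, pA[:, 0], pA[:, 1])
    ll_0 = site_log_likelihood(n_sn, site.n_ns, p0[:, 0], p0[:, 1])
    terms = ll_A - ll_0 + np.log(alt.prior_odds)
    if not np.all(np.isfinite(terms)):
        raise FloatingPointError("degenerate posterior draws in EoS integrand")
    R_nats = float(terms.mean())
    se_nats = float(terms.std(ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else np.inf
    return EoSResult(
        site_index=site.site_index,
        population=population,
        R=R_nats / LN2,
        mc_se=se_nats / LN2,
        n_ns_observed=site.n_ns,
    )


def combined_eos(results: list[EoSResult]) -> float:
    """Combined log-odds over a set of disjoint sites: the sum of their R.

    Additivity of log-odds means the sum self-corrects for the number of
    sites considered, but it predicates on *all* sites being selected: mixing
    true and false positives systematically underestimates the posterior
    odds of the true ones.
    """
    sites = [r.site_index for r in results]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites in combined score")
    return float(sum(r.R for r in results))


def reliability(
    null: Hypothesis,
    alt: Hypothesis,
    n_clones: int,
    n_mc: int = 2_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Kullback-Leibler reliability pair (D_HA, D_H0), in log base 2.

    ``D_HA`` is the expectation, over paired posterior draws, of the exact
    sum over all ``n_clones + 1`` possible nonsynonymous counts of
    ``Pr(outcome | HA) * log[Pr(outcome | HA) / Pr(outcome | H0)]``;
    ``D_H0`` swaps the roles.  Both are non-negative in expectation by
    Gibbs' inequality.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.arange(n_clones + 1)
    pA = alt.sample(n_mc, rng)
    p0 = null.sample(n_mc, rng)
    ll_A = site_log_likelihood(
        (n_clones - x)[None, :], x[None, :], pA[:, :1], pA[:, 1:]
    )
    ll_0 = site_log_likelihood(
        (n_clones - x)[None, :], x[None, :], p0[:, :1], p0[:, 1:]
    )
    diff = ll_A - ll_0
    with np.errstate(over="ignore"):
        P_A = np.exp(ll_A)
        P_0 = np.exp(ll_0)
    d_ha = float(np.mean(np.sum(P_A * diff, axis=1)))
    d_h0 = float(np.mean(np.sum(P_0 * (-diff), axis=1)))
    return d_ha / LN2, d_h0 / LN2


def homogeneity_test(
    site_us: SiteCounts, site_mx: SiteCounts, alpha: float = DEFAULT_ALPHA
) -> float:
    """Log2 Bayes factor of multinomial homogeneity between the populations.

    Compares the marginal likelihood of the two sites' folded sn/ns counts
    under a single shared (p_sn, p_ns) pair against independent pairs, both
    with Dirichlet(alpha) reference priors (a Bayes-factor realization of
    the classical homogeneity test; the construction, not a transcription
    of any particular published formula).  Positive values favor
    homogeneity.  The multinomial coefficients cancel between the models.
    """
    s1, f1 = site_us.n_total - site_us.n_ns, site_us.n_ns
    s2, f2 = site_mx.n_total - site_mx.n_ns, site_mx.n_ns

    def log_ml(s: int, f: int) -> float:
        return float(betaln(s + alpha, f + alpha) - betaln(alpha, alpha))

    return (log_ml(s1 + s2, f1 + f2) - log_ml(s1, f1) - log_ml(s2, f2)) / LN2


def chi2_site_statistic(site: SiteCounts, null_p_ns: float) -> float:
    """One-degree-of-freedom chi-square of observed vs expected ns counts.

    Provided only for comparison with windowless chi-square analyses; the
    EoS score, not this statistic, is the inferential quantity.
    """
    n = site.n_total
    exp_ns = n * null_p_ns
    exp_sn = n * (1.0 - null_p_ns)
    if exp_ns <= 0 or exp_sn <= 0:
        raise ValueError("expected counts must be positive")
    obs_ns = site.n_ns
    obs_sn = n - site.n_ns
    return float((obs_ns - exp_ns) ** 2 / exp_ns + (obs_sn - exp_sn) ** 2 / exp_sn)
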