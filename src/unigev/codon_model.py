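"""Codon-level mutation probabilities from nucleotide mutation matrices.

Because mutagenic PCR acts independently on nucleotides, the codon-level
process is the triple Kronecker product ``M = P (x) P (x) P``, a 64x64
column-stochastic operator on codon frequencies.  Partitioning the rows of
a wild-type codon's column by translation under a genetic code yields the
per-site probabilities of synonymous (including identity) versus
nonsynonymous mutation; summing independent per-site nonsynonymous
indicator variables gives the whole-protein mutation count ``kappa``,
whose distribution is Poisson-binomial.

Codons are ordered lexicographically over the A, C, G, T alphabet, which is
exactly the index arithmetic the Kronecker construction induces.
Genetic codes are the NCBI translation tables (via Biopython), so
mitochondrial or chloroplast codes need no extra machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .bayes_multinomial import MutationMatrix
from .seqdata import NT_INDEX, NUCLEOTIDES

#: All 64 codons in lexicographic ACGT order; CODON_INDEX inverts it.
CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


@dataclass
class GeneticCode:
    """A codon -> amino-acid map (stop = ``'*'``), from the NCBI tables."""

    table_id: int
    name: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("a genetic code must map all 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: "*" for c in table.stop_codons}
        mapping.update(table.forward_table)
        mapping = {c: mapping[c] for c in CODONS}
        return cls(table_id=table_id, name=table.names[0], codon_to_aa=mapping)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "*"

    def synonymous_codons(self, codon: str) -> list[str]:
        """All codons translating identically to ``codon`` (itself included)."""
        aa = self.codon_to_aa[codon]
        return [c for c in CODONS if self.codon_to_aa[c] == aa]


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


@dataclass
class CodonOperator:
    """64x64 column-stochastic codon mutation operator."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (64, 64):
            raise ValueError("codon operator must be 64x64")

    def entry(self, to_codon: str, from_codon: str) -> float:
        return float(self.M[CODON_INDEX[to_codon], CODON_INDEX[from_codon]])


@dataclass
class SitePartitionProbs:
    """Synonymous/nonsynonymous outcome probabilities at one codon site.

    ``p_sn`` includes the identity (no-mutation) outcome, so
    ``p_sn + p_ns = 1``.
    """

    site_index: int
    wt_codon: str
    p_sn: float
    p_ns: float

    def __post_init__(self) -> None:
        if abs(self.p_sn + self.p_ns - 1.0) > 1e-9:
            raise ValueError("p_sn + p_ns must equal 1")


def codon_operator(P: MutationMatrix | np.ndarray) -> CodonOperator:
    """Triple Kronecker product of the nucleotide mutation matrix."""
    Pm = P.matrix if isinstance(P, MutationMatrix) else np.asarray(P, dtype=float)
    return CodonOperator(np.kron(Pm, np.kron(Pm, Pm)))


def _codon_nt_indices(codon: str) -> tuple[int, int, int]:
    return tuple(NT_INDEX[c] for c in codon)  # type: ignore[return-value]


def synonymous_probability(
    P: np.ndarray, wt_codon: str, code: GeneticCode = STANDARD_CODE
) -> float | np.ndarray:
    """``p_sn`` for one wild-type codon, without forming the 64x64 operator.

    ``P`` may be a single (4, 4) matrix or a stack ``(m, 4, 4)`` of posterior
    draws, in which case an ``(m,)`` vector is returned.  Equivalent to
    summing the synonymous rows of the codon operator's wild-type column,
    since each entry factorizes as ``p_i1j1 * p_i2j2 * p_i3j3``.
    """
    P = np.asarray(P, dtype=float)
    j1, j2, j3 = _codon_nt_indices(wt_codon)
    total = 0.0
    for syn in code.synonymous_codons(wt_codon):
        i1, i2, i3 = _codon_nt_indices(syn)
        total = total + P[..., i1, j1] * P[..., i2, j2] * P[..., i3, j3]
    return total


def synonymous_partition(
    M: CodonOperator, wt_codon: str, code: GeneticCode = STANDARD_CODE,
    site_index: int = 1,
) -> SitePartitionProbs:
    """Partition a wild-type codon's outcome column into sn/ns classes.

    ``p_sn`` sums the operator column over all codons translating like the
    wild type (the wild type itself included); stop codons fall in the
    nonsynonymous class.
    """
    if code.is_stop(wt_codon):
        raise ValueError(f"wild-type codon {wt_codon} is a stop codon")
    col = CODON_INDEX[wt_codon]
    rows = [CODON_INDEX[c] for c in code.synonymous_codons(wt_codon)]
    p_sn = float(M.M[rows, col].sum())
    return SitePartitionProbs(site_index, wt_codon, p_sn, 1.0 - p_sn)


def site_partitions_for_sequence(
    wild_type: str,
    P: MutationMatrix | np.ndarray,
    code: GeneticCode = STANDARD_CODE,
) -> list[SitePartitionProbs]:
    """Per-codon sn/ns probabilities for a frame-valid coding sequence."""
    if len(wild_type) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    Pm = P.matrix if isinstance(P, MutationMatrix) else np.asarray(P, dtype=float)
    out = []
    for j in range(len(wild_type) // 3):
        codon = wild_type[3 * j : 3 * j + 3]
        if code.is_stop(codon):
            raise ValueError(f"internal stop codon {codon} at site {j + 1}")
        p_sn = float(synonymous_probability(Pm, codon, code))
        out.append(SitePartitionProbs(j + 1, codon, p_sn, 1.0 - p_sn))
    return out


@dataclass
class KappaDistribution:
    """Distribution of the per-clone whole-protein nonsynonymous count.

    ``pmf`` is the Monte-Carlo estimate; ``exact_pmf`` the Poisson-binomial
    reference computed by sequential convolution.  Support runs from 0 to
    the number of codon sites.
    """

    pmf: np.ndarray
    exact_pmf: np.ndarray
    n_sim: int
    seed: int | None = None
    samples: np.ndarray | None = field(default=None, repr=False)

    def interval_mass(self, lo: int, hi: int, exact: bool = True) -> float:
        """Probability that kappa lies in [lo, hi], inclusive."""
        pmf = self.exact_pmf if exact else self.pmf
        return float(pmf[lo : hi + 1].sum())


def poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_j) variables."""
    pmf = np.array([1.0])
    for pj in np.asarray(p, dtype=float):
        pmf = np.convolve(pmf, [1.0 - pj, pj])
    return pmf


def mutation_count_distribution(
    partitions: list[SitePartitionProbs],
    n_sim: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> KappaDistribution:
    """Monte-Carlo in-silico mutagenesis of the whole protein.

    Each replicate draws one nonsynonymous indicator per site with
    probability ``p_ns_j``; ``kappa`` is their sum.  The exact
    Poisson-binomial pmf is returned alongside for validation.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_ns = np.array([s.p_ns for s in partitions])
    n_sites = p_ns.size
    kappa = np.zeros(n_sim, dtype=np.int64)
    block = max(1, int(5e7) // max(n_sites, 1))  # bound transient memory
    for start in range(0, n_sim, block):
        m = min(block, n_sim - start)
        draws = rng.random((m, n_sites)) < p_ns[None, :]
        kappa[start : start + m] = draws.sum(axis=1)
    pmf = np.bincount(kappa, minlength=n_sites + 1) / n_sim
    exact = poisson_binomial_pmf(p_ns)
    return KappaDistribution(
        pmf=pmf,
        exact_pmf=exact,
        n_sim=n_sim,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        samples=kappa,
    )


def partition_table(
    partitions: list[SitePartitionProbs],
    n_clones: int,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-site expected nonsynonymous counts with binomial percentiles.

    Columns: site, codon, amino acid, p_sn, p_ns, expected count
    ``n * p_ns`` and the 2%/50%/98% binomial percentiles of the observable
    count for ``n_clones`` sequenced clones.
    """
    rows = []
    for s in partitions:
        q02, q50, q98 = stats.binom.ppf([0.02, 0.5, 0.98], n_clones, s.p_ns)
        rows.append(
            {
                "site": s.site_index,
                "wt_codon": s.wt_codon,
                "aa": code.translate(s.wt_codon),
                "p_sn": s.p_sn,
                "p_ns": s.p_ns,
                "n_ns_expected": n_clones * s.p_ns,
                "Q02": int(q02),
                "Q50": int(q50),
                "Q98": int(q98),
            }
        )
    return pd.DataFrame(rows)
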