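"""Dirichlet-multinomial estimation of mutation frequencies.

Each column of the misincorporation count matrix is treated as a draw from
an independent multinomial whose parameters carry the objective
(Jeffreys / Berger-Bernardo) Dirichlet(1/2) reference prior, giving the
conjugate posterior ``p | n ~ Dirichlet(n + 1/2)``.  Three point estimates
are provided:

* **relative frequencies** — straight column normalization of the counts,
  valid only when every expected count is large;
* the **natural-parameter mean** ``E[log p_i] = psi(n_i + a_i) -
  psi(sum(n_i + a_i))`` (digamma), the posterior mean on the log scale of
  the multinomial's natural parameters, reported after exponentiation and
  renormalization; and
* the **mechanistic PCR-model MAP**, computed in :mod:`unigev.pcr_polymerase`
  and merely passed through here for table assembly.

Posterior sampling of whole mutation matrices draws the four columns
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .seqdata import NUCLEOTIDES, MisincorporationCounts

#: Jeffreys/reference prior weight per category.
DEFAULT_ALPHA = 0.5

_SOURCES = frozenset(
    {"relative", "natural", "posterior_draw", "pcr_model_map", "pcr_model_draw"}
)


@dataclass
class DirichletPosterior:
    """Dirichlet posterior over one multinomial parameter vector."""

    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(self.concentration <= 0):
            raise ValueError("all concentrations must be positive")

    @property
    def dim(self) -> int:
        return self.concentration.size

    @property
    def mean(self) -> np.ndarray:
        return self.concentration / self.concentration.sum()


@dataclass
class MutationMatrix:
    """Column-stochastic 4x4 per-PCR mutation operator.

    ``matrix[i, j]`` is Pr(clone nucleotide i | wild-type nucleotide j);
    every column sums to one.
    """

    matrix: np.ndarray
    source: str = "relative"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("mutation matrix must be 4x4")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES)
        )


def relative_frequencies(C: MisincorporationCounts) -> MutationMatrix:
    """Column-normalize the counts: ``p_ij = c_ij / c_+j``."""
    totals = C.column_totals
    if np.any(totals == 0):
        raise ValueError(
            "zero column total; use the Dirichlet posterior estimate instead"
        )
    return MutationMatrix(C.counts / totals, source="relative")


def dirichlet_posterior(counts, alpha: float = DEFAULT_ALPHA) -> DirichletPosterior:
    """Conjugate posterior for multinomial counts under a Dirichlet(alpha) prior."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return DirichletPosterior(counts + alpha)


def column_posteriors(
    C: MisincorporationCounts, alpha: float = DEFAULT_ALPHA
) -> list[DirichletPosterior]:
    """Independent Dirichlet posteriors for the four wild-type columns."""
    return [dirichlet_posterior(C.counts[:, j], alpha) for j in range(4)]


def natural_parameter_mean(post: DirichletPosterior) -> np.ndarray:
    """Posterior mean of log p under the Dirichlet posterior.

    ``E[log p_i] = psi(c_i) - psi(sum(c))`` with ``c`` the concentration
    vector; for large counts ``exp`` of this approaches ``n_i / sum(n)``.
    """
    c = post.concentration
    return digamma(c) - digamma(c.sum())


def natural_parameter_matrix(
    C: MisincorporationCounts, alpha: float = DEFAULT_ALPHA
) -> MutationMatrix:
    """Natural-parameter point estimate of the mutation matrix.

    Each column's ``E[log p]`` is exponentiated and renormalized to the
    simplex, which is how the estimate is reported in frequency tables.
    """
    cols = []
    for post in column_posteriors(C, alpha):
        v = np.exp(natural_parameter_mean(post))
        cols.append(v / v.sum())
    return MutationMatrix(np.column_stack(cols), source="natural")


def sample_frequencies(
    post: DirichletPosterior, n_draws: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n_draws`` frequency vectors from the Dirichlet posterior."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.dirichlet(post.concentration, size=n_draws)


def sample_mutation_matrices(
    C: MisincorporationCounts,
    n_draws: int,
    rng: np.random.Generator | int,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Draw mutation matrices column-wise from the four Dirichlet posteriors.

    Returns an ``(n_draws, 4, 4)`` array of column-stochastic matrices.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = np.empty((n_draws, 4, 4))
    for j, post in enumerate(column_posteriors(C, alpha)):
        draws[:, :, j] = rng.dirichlet(post.concentration, size=n_draws)
    return draws


def frequency_table(
    estimates: dict[str, MutationMatrix], decimals: int = 2
) -> pd.DataFrame:
    """Assemble named estimates into a percentage table.

    Produces the standard three-block layout (e.g. Relative Count,
    Natural Parameter, Maximum a posteriori) with entries in percent rounded
    to ``decimals`` places.
    """
    frames = {}
    for name, mm in estimates.items():
        frames[name] = (100.0 * mm.to_frame()).round(decimals)
    return pd.concat(frames, axis=1)


def write_frequency_table(
    estimates: dict[str, MutationMatrix], path, decimals: int = 2
) -> None:
    frequency_table(estimates, decimals).to_csv(path, sep="\t")
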