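"""Clone-sequence handling and mutation-count tabulation.

A unigenic evolution experiment yields a wild-type coding sequence plus two
pools of full-length, pre-aligned clone sequences: an *unselected* pool
(mutagenized, never subjected to functional selection) and a *selected* pool
(mutagenized, then required to retain function).  This module reads those
sequences, validates them, and reduces them to the two count summaries the
downstream statistics consume:

* a 4x4 nucleotide misincorporation matrix ``C`` where ``c[i, j]`` counts
  wild-type nucleotide ``j`` observed as clone nucleotide ``i``; and
* per-codon-site synonymous / nonsynonymous mutation counts.

Clones are assumed indel-free; any clone whose length differs from the
wild type is rejected rather than aligned.  The ambiguity code ``N`` masks a
position (and its codon) from the counts for that clone only.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .codon_model import GeneticCode

#: Fixed nucleotide alphabet ordering used for every 4-vector and 4x4 matrix.
NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: Index permutation realizing Watson-Crick complementation (A<->T, C<->G).
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])

VALID_CHARS = frozenset("ACGTN")


class AlignmentError(ValueError):
    """A clone's length does not match the wild type."""


class SequenceParseError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


def _normalize(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


@dataclass
class ClonePopulation:
    """A pool of aligned clone sequences with its wild-type reference.

    ``label`` is ``"us"`` for the unselected pool or ``"mx"`` for the
    functionally selected pool, following the superscripts used throughout
    the analysis.
    """

    label: str
    wild_type: str
    clones: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wild_type = _normalize(self.wild_type)
        self.clones = [_normalize(c) for c in self.clones]
        bad = set(self.wild_type) - VALID_CHARS
        if bad:
            raise SequenceParseError(f"wild type contains invalid characters {sorted(bad)}")
        L = len(self.wild_type)
        for idx, clone in enumerate(self.clones):
            if len(clone) != L:
                raise AlignmentError(
                    f"clone {idx} has length {len(clone)} != wild-type length {L}; "
                    "clones must be pre-aligned and indel-free"
                )
            bad = set(clone) - VALID_CHARS
            if bad:
                raise SequenceParseError(
                    f"clone {idx} contains invalid characters {sorted(bad)}"
                )

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def length(self) -> int:
        return len(self.wild_type)


@dataclass
class MisincorporationCounts:
    """4x4 integer matrix of wild-type -> clone nucleotide events.

    ``counts[i, j]`` is the number of positions where wild-type nucleotide
    ``j`` (column) was read as clone nucleotide ``i`` (row), in ACGT order.
    """

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def column_totals(self) -> np.ndarray:
        """c_+j: total events per wild-type nucleotide."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """c_++: total tabulated events."""
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(NUCLEOTIDES), columns=list(NUCLEOTIDES)
        )


@dataclass
class SiteCounts:
    """Observed mutation counts at one codon site (1-based ``site_index``).

    ``n_sn`` and ``n_ns`` count clones whose codon differs from the wild type
    synonymously / nonsynonymously; ``n_total`` counts clones scored at the
    site (codons containing N are excluded).  A clone identical to the wild
    type at the site contributes to ``n_total`` only.
    """

    site_index: int
    wt_codon: str
    n_sn: int
    n_ns: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_sn, self.n_ns, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_sn + self.n_ns > self.n_total:
            raise ValueError("n_sn + n_ns cannot exceed n_total")

    @property
    def n_unchanged(self) -> int:
        return self.n_total - self.n_sn - self.n_ns


def tabulate_nucleotide_counts(pop: ClonePopulation) -> MisincorporationCounts:
    """Tabulate all clone positions into the 4x4 misincorporation matrix.

    Each non-N clone position contributes exactly one count to the column of
    its wild-type nucleotide, so the grand total equals the number of scored
    positions.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    wt_idx = np.array([NT_INDEX.get(c, -1) for c in pop.wild_type])
    for clone in pop.clones:
        cl_idx = np.array([NT_INDEX.get(c, -1) for c in clone])
        mask = (wt_idx >= 0) & (cl_idx >= 0)
        np.add.at(counts, (cl_idx[mask], wt_idx[mask]), 1)
    return MisincorporationCounts(counts, label=pop.label)


def tabulate_codon_counts(
    pop: ClonePopulation,
    code: "GeneticCode",
    stop_policy: str = "nonsynonymous",
) -> list[SiteCounts]:
    """Count synonymous/nonsynonymous codon changes at each site.

    A clone codon differing from the wild-type codon counts once, as
    synonymous (same translation) or nonsynonymous (different translation),
    regardless of how many of its three nucleotides changed.  Premature stop
    codons count as nonsynonymous by default (``stop_policy='nonsynonymous'``);
    with ``stop_policy='drop-clone'`` the clone is excluded from the stop
    site and every downstream site.
    """
    if stop_policy not in ("nonsynonymous", "drop-clone"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    L = pop.length
    if L % 3 != 0:
        raise ValueError(f"wild-type length {L} is not divisible by 3")
    n_sites = L // 3
    wt_codons = [pop.wild_type[3 * j : 3 * j + 3] for j in range(n_sites)]
    n_sn = np.zeros(n_sites, dtype=np.int64)
    n_ns = np.zeros(n_sites, dtype=np.int64)
    n_tot = np.zeros(n_sites, dtype=np.int64)
    for clone in pop.clones:
        for j in range(n_sites):
            codon = clone[3 * j : 3 * j + 3]
            wt = wt_codons[j]
            if "N" in codon or "N" in wt:
                continue
            n_tot[j] += 1
            if codon == wt:
                continue
            aa_wt = code.translate(wt)
            aa_cl = code.translate(codon)
            if aa_cl == aa_wt:
                n_sn[j] += 1
            else:
                n_ns[j] += 1
                if aa_cl == "*" and stop_policy == "drop-clone":
                    n_tot[j] -= 1
                    n_ns[j] -= 1
                    break
    return [
        SiteCounts(j + 1, wt_codons[j], int(n_sn[j]), int(n_ns[j]), int(n_tot[j]))
        for j in range(n_sites)
    ]


def read_fasta_population(
    path: str | Path, wild_type_path: str | Path, label: str = "us"
) -> ClonePopulation:
    """Read a clone pool and its wild type from FASTA files.

    Sequences are upper-cased and U mapped to T; record order is preserved.
    """
    wt_records = list(SeqIO.parse(str(wild_type_path), "fasta"))
    if not wt_records:
        raise SequenceParseError(f"no FASTA records in {wild_type_path}")
    clones = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not clones:
        raise SequenceParseError(f"no FASTA records in {path}")
    return ClonePopulation(label=label, wild_type=str(wt_records[0].seq), clones=clones)


def write_nucleotide_counts_tsv(
    counts: Iterable[MisincorporationCounts], path: str | Path
) -> None:
    """Write one or more count matrices in the published table layout.

    Rows are clone nucleotides, columns wild-type nucleotides, with a final
    ``Total`` row of column sums; multiple populations are stacked with a
    ``population`` column.
    """
    frames = []
    for c in counts:
        df = c.to_frame()
        df.loc["Total"] = c.column_totals
        df.insert(0, "population", c.label)
        df.insert(1, "clone_nt", df.index)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_codon_counts_tsv(
    sites: Sequence[SiteCounts], code: "GeneticCode", path: str | Path
) -> None:
    rows = [
        {
            "site": s.site_index,
            "wt_codon": s.wt_codon,
            "aa": code.translate(s.wt_codon),
            "n_sn": s.n_sn,
            "n_ns": s.n_ns,
            "n_total": s.n_total,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def log_rejected_clone(idx: int, reason: str) -> None:
    print(f"clone {idx} rejected: {reason}", file=sys.stderr)
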