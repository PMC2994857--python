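"""Synthetic clone-population generator with known ground truth.

Emulates a unigenic evolution experiment end to end: a wild-type coding
sequence (given or generated), per-site i.i.d. nucleotide mutation from
the columns of a mutation matrix ``P`` (optionally derived from a
polymerase matrix ``T`` through ``k`` PCR cycles), and optional hard
purifying selection at designated codon sites.  Because the inference model
itself treats clones as independent draws from ``P``, clones are sampled
from the marginal per-site mutation matrix rather than by simulating strand
lineages through the PCR tree.

Selection is a functional knockout: at a selected site any disallowed codon
(nonsynonymous, or any change at all, depending on the mode) is redrawn
until allowed, which under site independence equals rejecting whole clones.
All randomness flows from a single seed, so identical configurations emit
byte-identical FASTA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bayes_multinomial import MutationMatrix
from .codon_model import CODONS, GeneticCode, STANDARD_CODE
from .pcr_polymerase import PolymeraseMatrix, pcr_mutation_matrix
from .seqdata import NT_INDEX, NUCLEOTIDES, ClonePopulation

SELECTION_MODES = ("reject-nonsynonymous", "reject-any-change")
_MAX_REDRAWS = 100_000


@dataclass
class SimulationConfig:
    """Recipe for one simulated experiment.

    ``selected_sites`` are 1-based codon indices under purifying selection
    in the selected (``mx``) population only.  ``preserve_start`` pins the
    first codon in *both* populations, emulating the cloning artifact that
    always restores the start codon — the standard positive control.
    """

    wild_type: str | None = None
    n_codons: int = 266
    gc_content: float = 0.5
    P: MutationMatrix | np.ndarray | None = None
    T: PolymeraseMatrix | np.ndarray | None = None
    k: int = 30
    n_clones: int = 87
    selected_sites: frozenset[int] = field(default_factory=frozenset)
    selection_mode: str = "reject-nonsynonymous"
    preserve_start: bool = False
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_mode not in SELECTION_MODES:
            raise ValueError(f"unknown selection mode {self.selection_mode!r}")
        if self.P is None and self.T is None:
            raise ValueError("either P or T must be given")

    def mutation_matrix(self) -> np.ndarray:
        if self.P is not None:
            return self.P.matrix if isinstance(self.P, MutationMatrix) else np.asarray(self.P)
        return pcr_mutation_matrix(self.T, self.k).matrix


def random_coding_sequence(
    n_codons: int,
    gc_content: float,
    rng: np.random.Generator,
    code: GeneticCode = STANDARD_CODE,
    start_with_atg: bool = True,
) -> str:
    """A random coding sequence with the given GC bias and no internal stop."""
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    codons = []
    if start_with_atg:
        codons.append("ATG")
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(NUCLEOTIDES), size=3, p=p))
        if not code.is_stop(codon):
            codons.append(codon)
    return "".join(codons)


def _draw_clone(wt_idx: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-site independent draw from the wild-type columns of P."""
    u = rng.random(wt_idx.size)
    cum = np.cumsum(P, axis=0)  # (4, 4): cumulative over clone nucleotide
    return (u[:, None] > cum.T[wt_idx]).sum(axis=1)


def _codon_ok(wt_codon: str, codon: str, mode: str, code: GeneticCode) -> bool:
    if mode == "reject-any-change":
        return codon == wt_codon
    return code.translate(codon) == code.translate(wt_codon)


def simulate_clones(
    cfg: SimulationConfig,
) -> tuple[ClonePopulation, ClonePopulation, dict]:
    """Simulate unselected and selected clone pools.

    Returns ``(us, mx, truth)`` where ``truth`` records the generating
    mutation matrix, selected sites, and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    code = cfg.code
    P = cfg.mutation_matrix()
    wt = cfg.wild_type or random_coding_sequence(cfg.n_codons, cfg.gc_content, rng, code)
    n_codons = len(wt) // 3
    bad = [j for j in cfg.selected_sites if not (1 <= j <= n_codons)]
    if bad:
        raise ValueError(f"selected sites out of codon range: {bad}")
    wt_idx = np.array([NT_INDEX[c] for c in wt])

    def emit(selected: bool) -> list[str]:
        clones = []
        for _ in range(cfg.n_clones):
            idx = _draw_clone(wt_idx, P, rng)
            clone = "".join(NUCLEOTIDES[i] for i in idx)
            constrained: list[int] = []
            if selected:
                constrained.extend(sorted(cfg.selected_sites))
            if cfg.preserve_start:
                clone = wt[:3] + clone[3:]
            for j in constrained:
                wt_codon = wt[3 * (j - 1) : 3 * j]
                codon = clone[3 * (j - 1) : 3 * j]
                tries = 0
                while not _codon_ok(wt_codon, codon, cfg.selection_mode, code):
                    codon_idx = _draw_clone(wt_idx[3 * (j - 1) : 3 * j], P, rng)
                    codon = "".join(NUCLEOTIDES[i] for i in codon_idx)
                    tries += 1
                    if tries > _MAX_REDRAWS:
                        raise RuntimeError(
                            f"selection rejection loop exceeded cap at site {j}"
                        )
                clone = clone[: 3 * (j - 1)] + codon + clone[3 * j :]
            clones.append(clone)
        return clones

    us = ClonePopulation(label="us", wild_type=wt, clones=emit(selected=False))
    mx = ClonePopulation(label="mx", wild_type=wt, clones=emit(selected=True))
    truth = {
        "P": P.tolist(),
        "selected_sites": sorted(cfg.selected_sites),
        "selection_mode": cfg.selection_mode,
        "preserve_start": cfg.preserve_start,
        "seed": cfg.seed,
        "n_clones": cfg.n_clones,
        "wild_type": wt,
    }
    return us, mx, truth


def write_fasta(pop: ClonePopulation, path: str | Path, prefix: str = "clone") -> None:
    """Write a clone pool as multi-record FASTA (one record per clone)."""
    with open(path, "w") as fh:
        for i, clone in enumerate(pop.clones, start=1):
            fh.write(f">{prefix}_{pop.label}_{i:04d}\n{clone}\n")


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
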