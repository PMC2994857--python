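"""Packaged example data.

The shipped fixture is the published pair of nucleotide misincorporation
count matrices from the I-BmoI homing-endonuclease unigenic evolution
experiment: 87 unselected and 87 functionally selected clones of the
266-codon coding sequence, tabulated against the wild type after 30 cycles
of mutagenic PCR.  Column totals are identical between the two pools
because every clone is full length.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .seqdata import NUCLEOTIDES, MisincorporationCounts

#: Experimental constants of the I-BmoI study.
IBMOI_N_CLONES = 87
IBMOI_N_CODONS = 266
IBMOI_PCR_CYCLES = 30

_LABELS = {"unselected": "us", "selected": "mx", "us": "us", "mx": "mx"}
_NAMES = {"us": "unselected", "mx": "selected"}


def load_ibmoi_counts(population: str = "unselected") -> MisincorporationCounts:
    """Load the packaged I-BmoI misincorporation count matrix.

    Parameters
    ----------
    population
        ``"unselected"``/``"us"`` or ``"selected"``/``"mx"``.
    """
    try:
        label = _LABELS[population]
    except KeyError:
        raise ValueError(f"unknown population {population!r}") from None
    with resources.files("unigev.data").joinpath("ibmoi_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df[df["population"] == _NAMES[label]].set_index("clone_nt")
    counts = df.loc[list(NUCLEOTIDES), list(NUCLEOTIDES)].to_numpy(dtype=np.int64)
    return MisincorporationCounts(counts, label=label)
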