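"""Worked example models.

The two-locus example below is a classic illustration of pure, strict
epistasis: with minor allele frequencies 0.4 (locus 1) and 0.5 (locus 2),
every single-locus marginal penetrance equals the population prevalence
K ≈ 0.614, so neither SNP is individually predictive of disease even though
the pair jointly is. Penetrances are given to three decimals, so marginal
flatness holds at tolerance 1e-3, not exactly.
"""

from __future__ import annotations

import numpy as np

from .genetics import PenetranceModel

__all__ = ["two_locus_example"]

_EXAMPLE_MAFS = (0.4, 0.5)
# Rows: locus-1 genotypes AA, Aa, aa; columns: locus-2 genotypes BB, Bb, bb.
_EXAMPLE_TABLE = [
    [0.266, 0.764, 0.664],
    [0.928, 0.398, 0.733],
    [0.456, 0.927, 0.147],
]


def two_locus_example() -> PenetranceModel:
    """The two-locus pure, strict epistatic example model (K ≈ 0.614)."""
    return PenetranceModel.from_table(_EXAMPLE_MAFS, np.array(_EXAMPLE_TABLE))
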