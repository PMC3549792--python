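"""Biallelic multi-locus penetrance models under Hardy-Weinberg equilibrium.

A penetrance model maps each of the 3^n multi-locus genotypes (MLGs) of n
biallelic loci to a disease probability f_G. Together with per-locus minor
allele frequencies it determines the population prevalence

    K = sum_G P(G) f_G

and the broad-sense heritability

    h^2 = (1 / (K (1 - K))) sum_G P(G) (f_G - K)^2,

where P(G) is the joint MLG probability under HWE and linkage equilibrium.

MLG indexing convention: each locus carries a genotype code g in {0, 1, 2}
counting copies of the minor allele (0 = homozygous major), and the flat MLG
index is sum_i g_i * 3^(n-1-i) -- row-major with locus 0 varying slowest. For
a two-locus table this puts locus 0 on the rows (AA, Aa, aa) and locus 1 on
the columns (BB, Bb, bb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property, reduce
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateModelError, InvalidParameterError

__all__ = [
    "hwe_genotype_frequencies",
    "joint_genotype_probs",
    "GenotypeDistribution",
    "PenetranceModel",
    "prevalence",
    "heritability",
    "marginal_penetrances",
    "is_pure_strict",
    "mlg_index_powers",
]


def hwe_genotype_frequencies(maf: float) -> np.ndarray:
    """Genotype frequency triple (p^2, 2pq, q^2) for minor allele frequency q.

    Parameters
    ----------
    maf
        Minor allele frequency q, with 0 < q <= 0.5 (p = 1 - q is the major
        allele frequency).

    Returns
    -------
    numpy.ndarray
        Length-3 array ordered (homozygous major, heterozygous, homozygous
        minor); sums to 1 up to floating rounding.
    """
    if not np.isfinite(maf) or not (0.0 < maf <= 0.5):
        raise InvalidParameterError(
            f"minor allele frequency must lie in (0, 0.5], got {maf!r}"
        )
    p = 1.0 - maf
    return np.array([p * p, 2.0 * p * maf, maf * maf])


def joint_genotype_probs(per_locus_freqs: Sequence[Sequence[float]]) -> np.ndarray:
    """Joint MLG probabilities as the outer product of per-locus triples.

    Loci are treated as independent (linkage equilibrium), so the probability
    of an MLG is the product of its per-locus genotype frequencies. The
    returned vector has length 3^n in canonical MLG order (locus 0 slowest).
    """
    freqs = [np.asarray(t, dtype=float) for t in per_locus_freqs]
    if not freqs:
        raise InvalidParameterError("at least one locus is required")
    for i, t in enumerate(freqs):
        if t.shape != (3,):
            raise InvalidParameterError(
                f"locus {i}: expected a genotype frequency triple, got shape {t.shape}"
            )
        if abs(float(t.sum()) - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"locus {i}: genotype frequencies sum to {t.sum()!r}, not 1"
            )
    return reduce(np.kron, freqs)


def mlg_index_powers(n_loci: int) -> np.ndarray:
    """Powers of 3 mapping per-locus genotype codes to the flat MLG index."""
    return 3 ** np.arange(n_loci - 1, -1, -1)


@dataclass(frozen=True, eq=False)
class GenotypeDistribution:
    """Per-locus HWE genotype frequencies and the joint MLG distribution."""

    per_locus_freqs: tuple[np.ndarray, ...]

    @classmethod
    def from_mafs(cls, mafs: Iterable[float]) -> "GenotypeDistribution":
        triples = tuple(hwe_genotype_frequencies(q) for q in mafs)
        if not triples:
            raise InvalidParameterError("at least one locus is required")
        return cls(per_locus_freqs=triples)

    @property
    def n_loci(self) -> int:
        return len(self.per_locus_freqs)

    @cached_property
    def joint_probs(self) -> np.ndarray:
        return joint_genotype_probs(self.per_locus_freqs)


@dataclass(frozen=True, eq=False)
class PenetranceModel:
    """An n-locus penetrance function with per-locus minor allele frequencies.

    Parameters
    ----------
    mafs
        Minor allele frequency per locus, each in (0, 0.5].
    penetrances
        Flat vector of 3^n disease probabilities f_G in canonical MLG order.
    """

    mafs: tuple[float, ...]
    penetrances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mafs", tuple(float(q) for q in self.mafs))
        f = np.array(self.penetrances, dtype=float).ravel()
        object.__setattr__(self, "penetrances", f)
        for q in self.mafs:
            if not (0.0 < q <= 0.5):
                raise InvalidParameterError(
                    f"minor allele frequency must lie in (0, 0.5], got {q!r}"
                )
        n = len(self.mafs)
        if n == 0:
            raise InvalidParameterError("a model needs at least one locus")
        if f.shape != (3**n,):
            raise InvalidParameterError(
                f"expected {3 ** n} penetrance values for {n} loci, got {f.size}"
            )
        if f.min() < 0.0 or f.max() > 1.0:
            raise InvalidParameterError(
                "penetrance values must lie in [0, 1]; "
                f"observed range [{f.min()!r}, {f.max()!r}]"
            )

    @classmethod
    def from_table(
        cls, mafs: Iterable[float], table: Sequence[Sequence[float]]
    ) -> "PenetranceModel":
        """Build a model from an n-dimensional penetrance table (locus 0 on
        the slowest axis)."""
        return cls(mafs=tuple(mafs), penetrances=np.asarray(table, dtype=float).ravel())

    @property
    def n_loci(self) -> int:
        return len(self.mafs)

    @cached_property
    def distribution(self) -> GenotypeDistribution:
        return GenotypeDistribution.from_mafs(self.mafs)

    @property
    def joint_probs(self) -> np.ndarray:
        return self.distribution.joint_probs

    def table(self) -> np.ndarray:
        """Penetrances reshaped to an n-dimensional (3, ..., 3) table."""
        return self.penetrances.reshape((3,) * self.n_loci)


def prevalence(model: PenetranceModel) -> float:
    """Population prevalence K = sum_G P(G) f_G (a probability in [0, 1])."""
    return float(model.joint_probs @ model.penetrances)


def heritability(model: PenetranceModel) -> float:
    """Broad-sense heritability of the model.

    h^2 = (1 / (K (1 - K))) * sum_G P(G) (f_G - K)^2, the fraction of
    phenotypic variance attributable to genotype for a binary trait.
    """
    k = prevalence(model)
    # floating rounding of the HWE triples can leave K a few ulp inside the
    # boundary for an all-0/all-1 table, so test with a small margin
    if k <= 1e-12 or k >= 1.0 - 1e-12:
        raise DegenerateModelError(
            f"heritability undefined for prevalence K = {k}: phenotypic variance is 0"
        )
    dev = model.penetrances - k
    return float(model.joint_probs @ (dev * dev) / (k * (1.0 - k)))


def _validate_subset(n_loci: int, subset: Iterable[int]) -> tuple[int, ...]:
    loci = tuple(sorted(set(int(i) for i in subset)))
    if not loci:
        raise InvalidParameterError("locus subset must be nonempty")
    if any(i < 0 or i >= n_loci for i in loci):
        raise InvalidParameterError(f"locus indices must lie in [0, {n_loci})")
    if len(loci) == n_loci:
        raise InvalidParameterError("locus subset must be proper (exclude some locus)")
    return loci


def marginal_penetrances(
    model: PenetranceModel, subset: Iterable[int]
) -> np.ndarray:
    """Marginal penetrance table over a proper nonempty subset of loci.

    Each excluded locus is averaged out with its HWE genotype frequencies
    (valid because loci are independent), giving the penetrance a subject
    shows conditional only on the subset MLG. Returns an array of shape
    (3,) * len(subset), axes ordered by ascending locus index.
    """
    loci = _validate_subset(model.n_loci, subset)
    arr = model.table()
    excluded = [i for i in range(model.n_loci) if i not in loci]
    for locus in sorted(excluded, reverse=True):
        w = model.distribution.per_locus_freqs[locus]
        arr = np.tensordot(arr, w, axes=([locus], [0]))
    return arr


def is_pure_strict(model: PenetranceModel, tol: float = 1e-9) -> bool:
    """Whether the model is purely and strictly epistatic.

    True iff every marginal penetrance over every (n-1)-locus subset equals
    the prevalence K within ``tol``. Flat (n-1)-marginals imply flat marginals
    over all smaller subsets (further averaging of a constant), so no proper
    subset of the loci carries any predictive signal. A single-locus model is
    vacuously pure and strict (it has no proper nonempty subsets).
    """
    if tol < 0:
        raise InvalidParameterError(f"tolerance must be nonnegative, got {tol!r}")
    n = model.n_loci
    if n == 1:
        return True
    k = prevalence(model)
    for dropped in range(n):
        loci = tuple(i for i in range(n) if i != dropped)
        marg = marginal_penetrances(model, loci)
        if float(np.max(np.abs(marg - k))) > tol:
            return False
    return True
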