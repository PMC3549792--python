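"""Random generation of pure, strict, n-locus epistatic penetrance models.

Strategy
--------
For fixed minor allele frequencies, the penetrance tables whose weighted
marginals over every proper locus subset are flat form an affine subspace of
dimension 2^n around the constant table. We construct an explicit orthonormal
basis for the pure-interaction deviation space: per locus, two contrast
vectors over its three genotypes that are orthogonal to the constant vector
under that locus's HWE genotype-frequency weights; the 2^n tensor products
taking one contrast from every locus are then orthonormal under the joint
MLG probabilities, and every proper-subset weighted marginal of every basis
table is identically zero.

A model draw is: sample a uniform random unit direction u in R^(2^n), form
the deviation table d = sum_j u_j b_j (which satisfies sum_G P(G) d_G^2 = 1
by orthonormality), and set

    f_G = K + c d_G,   c = sqrt(h^2 K (1 - K)),

which hits the target prevalence K exactly (flat marginals force
sum_G P(G) d_G = 0) and the target heritability h^2 exactly. The draw is
accepted iff every f_G lands in [0, 1]; otherwise it is rejected and the
algorithm starts over. Repeating until a population cap or an attempt cap is
reached yields a population of models sharing (n, MAFs, h^2, K) but varying
freely in architecture, which can then be ranked by a difficulty metric and
thinned to quantile representatives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import reduce
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .exceptions import (
    EmptySelectionError,
    InvalidParameterError,
    UndefinedCORError,
)
from .genetics import (
    GenotypeDistribution,
    PenetranceModel,
    heritability,
)
from .metrics import cor, edm, ptv

__all__ = [
    "ModelSpec",
    "InteractionBasis",
    "ModelPopulation",
    "pure_interaction_basis",
    "random_unit_direction",
    "build_model",
    "generate_population",
    "metric_values",
    "select_quantiles",
    "METRICS",
]

logger = logging.getLogger(__name__)

#: Difficulty metrics available for population ranking.
METRICS: dict[str, Callable[[PenetranceModel], float]] = {
    "edm": edm,
    "cor": cor,
    "ptv": ptv,
    "heritability": heritability,
}

_PROGRESS_EVERY = 100_000


@dataclass(frozen=True)
class ModelSpec:
    """Constraints a generated model must satisfy exactly.

    Attributes
    ----------
    n_loci
        Number of interacting loci n >= 1.
    mafs
        Minor allele frequency per locus, each in (0, 0.5].
    target_h2
        Broad-sense heritability in (0, 1).
    target_k
        Population prevalence K in (0, 1).
    rng_seed
        Nonnegative integer seeding the generation stream.
    """

    n_loci: int
    mafs: tuple[float, ...]
    target_h2: float
    target_k: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mafs", tuple(float(q) for q in self.mafs))
        if self.n_loci < 1:
            raise InvalidParameterError(f"n_loci must be >= 1, got {self.n_loci}")
        if len(self.mafs) != self.n_loci:
            raise InvalidParameterError(
                f"expected {self.n_loci} MAFs, got {len(self.mafs)}"
            )
        for q in self.mafs:
            if not (0.0 < q <= 0.5):
                raise InvalidParameterError(
                    f"minor allele frequency must lie in (0, 0.5], got {q!r}"
                )
        if not (0.0 < self.target_h2 < 1.0):
            raise InvalidParameterError(
                f"target heritability must lie in (0, 1), got {self.target_h2!r}"
            )
        if not (0.0 < self.target_k < 1.0):
            raise InvalidParameterError(
                f"target prevalence must lie in (0, 1), got {self.target_k!r}"
            )
        if self.rng_seed < 0:
            raise InvalidParameterError("rng_seed must be nonnegative")


@dataclass(frozen=True, eq=False)
class InteractionBasis:
    """Orthonormal basis of the pure-interaction deviation space.

    ``basis_tables`` has shape (2^n, 3^n); ``weights`` is the joint MLG
    probability vector under which the tables are orthonormal and all
    proper-subset marginals vanish.
    """

    basis_tables: np.ndarray
    weights: np.ndarray


def _locus_contrasts(freqs: np.ndarray) -> np.ndarray:
    """Two genotype contrasts orthonormal to the constant vector under the
    locus's genotype-frequency weights (weighted Gram-Schmidt)."""
    w = np.asarray(freqs, dtype=float)
    if w.shape != (3,) or np.any(w <= 0.0):
        raise InvalidParameterError(
            f"genotype frequency triple must be strictly positive, got {w!r}"
        )
    ortho = [np.ones(3) / np.sqrt(w.sum())]
    # Additive and recessive codings span the complement of the constant.
    for v in (np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 1.0])):
        u = v.copy()
        for b in ortho:
            u -= float((w * b) @ u) * b
        norm = np.sqrt(float((w * u) @ u))
        ortho.append(u / norm)
    return np.array(ortho[1:])


def pure_interaction_basis(distribution: GenotypeDistribution) -> InteractionBasis:
    """Build the 2^n orthonormal pure-interaction tables for a distribution.

    Every table's genotype-frequency-weighted marginal over every proper
    nonempty locus subset is identically zero, so any linear combination
    added to a constant table yields a purely, strictly epistatic model.
    """
    contrasts = [_locus_contrasts(t) for t in distribution.per_locus_freqs]
    n = distribution.n_loci
    tables = [
        reduce(np.kron, (contrasts[i][c] for i, c in enumerate(combo)))
        for combo in product(range(2), repeat=n)
    ]
    return InteractionBasis(
        basis_tables=np.array(tables), weights=distribution.joint_probs
    )


def random_unit_direction(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random direction on the unit sphere in R^dim."""
    if dim < 1:
        raise InvalidParameterError(f"dimension must be >= 1, got {dim}")
    while True:
        v = rng.standard_normal(dim)
        norm = float(np.linalg.norm(v))
        if norm > 1e-12:
            return v / norm


def build_model(
    spec: ModelSpec,
    direction: Sequence[float],
    basis: InteractionBasis,
) -> PenetranceModel | None:
    """Scale a unit direction into a penetrance model, or reject.

    The deviation table d = sum_j direction_j * basis_j is amplified by
    c = sqrt(h^2 K (1-K) / sum_G P(G) d_G^2), solved from the heritability
    definition, and added to the flat table at K. Returns the model when all
    entries land in [0, 1], else ``None`` (a rejection).
    """
    u = np.asarray(direction, dtype=float)
    if u.shape != (basis.basis_tables.shape[0],):
        raise InvalidParameterError(
            f"direction must have length {basis.basis_tables.shape[0]}, got {u.shape}"
        )
    if abs(float(np.linalg.norm(u)) - 1.0) > 1e-9:
        raise InvalidParameterError("direction must be a unit vector")
    d = u @ basis.basis_tables
    ssq = float(basis.weights @ (d * d))
    if ssq <= 1e-30:
        return None
    k, h2 = spec.target_k, spec.target_h2
    c = np.sqrt(h2 * k * (1.0 - k) / ssq)
    f = k + c * d
    if f.min() < 0.0 or f.max() > 1.0:
        return None
    return PenetranceModel(mafs=spec.mafs, penetrances=f)


@dataclass(eq=False)
class ModelPopulation:
    """Models generated under one constraint set, plus attempt bookkeeping."""

    spec: ModelSpec | None
    models: list[PenetranceModel]
    attempts_used: int = 0

    def __len__(self) -> int:
        return len(self.models)

    @classmethod
    def from_models(cls, models: Sequence[PenetranceModel]) -> "ModelPopulation":
        """Wrap an existing model list (e.g. read back from disk) for ranking."""
        return cls(spec=None, models=list(models), attempts_used=0)


def generate_population(
    spec: ModelSpec,
    pop_size: int = 100_000,
    max_attempts: int = 10_000_000,
    rng: np.random.Generator | None = None,
) -> ModelPopulation:
    """Generate models until ``pop_size`` are accepted or ``max_attempts``
    direction draws have been made.

    Attempt k draws its direction from a counter-derived substream
    ``default_rng((rng_seed, k))``, so runs are reproducible and attempt k is
    independent of how many earlier attempts were rejected. The population
    may come back smaller than ``pop_size`` (possibly empty) when the
    constraints are hard or infeasible; that is a reportable outcome, not an
    error.
    """
    if pop_size < 1:
        raise InvalidParameterError(f"pop_size must be >= 1, got {pop_size}")
    if max_attempts < pop_size:
        raise InvalidParameterError("max_attempts must be >= pop_size")
    dist = GenotypeDistribution.from_mafs(spec.mafs)
    basis = pure_interaction_basis(dist)
    dim = 2**spec.n_loci
    models: list[PenetranceModel] = []
    attempts = 0
    while len(models) < pop_size and attempts < max_attempts:
        attempt_rng = (
            np.random.default_rng((spec.rng_seed, attempts)) if rng is None else rng
        )
        u = random_unit_direction(dim, attempt_rng)
        attempts += 1
        model = build_model(spec, u, basis)
        if model is not None:
            models.append(model)
        if attempts % _PROGRESS_EVERY == 0:
            logger.info(
                "generation progress: %d attempts, %d models accepted",
                attempts,
                len(models),
            )
    return ModelPopulation(spec=spec, models=models, attempts_used=attempts)


def metric_values(
    population: ModelPopulation, metric: str
) -> tuple[list[int], np.ndarray]:
    """Evaluate a difficulty metric over a population.

    Returns the indices of models for which the metric is defined and their
    values; members with an undefined COR are dropped with a warning.
    """
    try:
        fn = METRICS[metric]
    except KeyError:
        raise InvalidParameterError(
            f"unknown metric {metric!r}; choose from {sorted(METRICS)}"
        ) from None
    kept: list[int] = []
    vals: list[float] = []
    dropped = 0
    for i, model in enumerate(population.models):
        try:
            vals.append(fn(model))
        except UndefinedCORError:
            dropped += 1
            continue
        kept.append(i)
    if dropped:
        warnings.warn(
            f"dropped {dropped} model(s) with undefined {metric} from ranking",
            stacklevel=2,
        )
    return kept, np.asarray(vals)


def select_quantiles(
    population: ModelPopulation, metric: str, n_select: int
) -> list[PenetranceModel]:
    """Pick ``n_select`` quantile-representative models by a metric.

    Models are sorted ascending by the metric (stable in generation order on
    ties); the selected ranks are round(i (M-1) / (n_select-1)) for
    i = 0..n_select-1, so ``n_select=2`` returns exactly the minimum- and
    maximum-metric models and ``n_select=1`` the median rank.
    """
    if n_select < 1:
        raise InvalidParameterError(f"n_select must be >= 1, got {n_select}")
    kept, vals = metric_values(population, metric)
    m = len(kept)
    if m == 0:
        raise EmptySelectionError(
            f"no models with a defined {metric!r} value to select from"
        )
    order = np.argsort(vals, kind="stable")
    if n_select == 1:
        ranks = [round((m - 1) / 2)]
    else:
        ranks = [round(i * (m - 1) / (n_select - 1)) for i in range(n_select)]
    return [population.models[kept[order[r]]] for r in ranks]
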