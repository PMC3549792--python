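"""Balanced case-control SNP dataset simulation from a penetrance model.

Each sample's predictive genotypes are drawn independently per locus from the
HWE genotype frequencies, and its affection status is a Bernoulli draw with
probability equal to the penetrance at the realized multi-locus genotype.
Balance is enforced by quota rejection sampling: individuals are simulated
until the case quota and the control quota are both filled, and surplus draws
for an already-full class are discarded. This preserves the within-class MLG
distributions P(G|case) and P(G|control) exactly, which is what the
difficulty metrics reason about.

Non-predictive "noise" SNPs each receive a minor allele frequency drawn
uniformly from a configured range and genotypes i.i.d. from HWE at that
frequency, independent of class. Genotypes are encoded as minor-allele
counts {0, 1, 2}; the class label is 1 for cases, 0 for controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, SamplingFailureError
from .genetics import PenetranceModel, mlg_index_powers, hwe_genotype_frequencies

__all__ = [
    "DatasetSpec",
    "GenotypeDataset",
    "simulate_individual",
    "simulate_balanced_dataset",
    "noise_snp",
    "simulate_replicate",
    "generate_replicates",
    "experiment_grid",
]

# Draw-attempt cap multiplier for quota filling; with 0 < K < 1 this is
# effectively unreachable but bounds pathological near-degenerate models.
_ATTEMPT_CAP_FACTOR = 10_000
_BATCH = 4096


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of one simulated case-control dataset family.

    Attributes
    ----------
    model
        Penetrance model driving the predictive loci.
    total_samples
        Cases plus controls; must be even (balance is exact).
    n_total_snps
        Total SNP columns including the model's predictive loci; the
        remainder are noise SNPs.
    noise_maf_range
        (low, high) bounds of the uniform distribution each noise SNP's
        minor allele frequency is drawn from.
    n_replicates
        Number of independently seeded replicate datasets.
    rng_seed
        Nonnegative master seed; replicate r uses substream (rng_seed, r).
    """

    model: PenetranceModel
    total_samples: int
    n_total_snps: int = 20
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    n_replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_samples < 2 or self.total_samples % 2:
            raise InvalidParameterError(
                f"total_samples must be even and >= 2, got {self.total_samples}"
            )
        if self.n_total_snps < self.model.n_loci:
            raise InvalidParameterError(
                f"n_total_snps must be >= n_loci = {self.model.n_loci}, "
                f"got {self.n_total_snps}"
            )
        low, high = self.noise_maf_range
        if not (0.0 < low <= high <= 0.5):
            raise InvalidParameterError(
                f"noise MAF range must satisfy 0 < low <= high <= 0.5, "
                f"got {self.noise_maf_range!r}"
            )
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.rng_seed < 0:
            raise InvalidParameterError("rng_seed must be nonnegative")


@dataclass(frozen=True, eq=False)
class GenotypeDataset:
    """Samples-by-SNPs genotype matrix with binary class labels."""

    genotypes: np.ndarray
    class_labels: np.ndarray
    snp_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view: one SNP column per name plus a ``Class`` column."""
        df = pd.DataFrame(self.genotypes, columns=list(self.snp_names))
        df["Class"] = self.class_labels
        return df


def simulate_individual(
    model: PenetranceModel, rng: np.random.Generator
) -> tuple[tuple[int, ...], int]:
    """Draw one individual's predictive MLG and affection status.

    Each locus genotype is drawn from its HWE triple; status is 1 (case)
    with probability equal to the penetrance at the drawn MLG.
    """
    freqs = model.distribution.per_locus_freqs
    mlg = tuple(int(rng.choice(3, p=t)) for t in freqs)
    idx = int(np.dot(mlg, mlg_index_powers(model.n_loci)))
    status = int(rng.random() < model.penetrances[idx])
    return mlg, status


def noise_snp(
    n_samples: int,
    noise_maf_range: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype column for one noise SNP, independent of class.

    One MAF is drawn uniformly from the range, then genotypes are sampled
    i.i.d. from HWE at that MAF.
    """
    low, high = noise_maf_range
    if not (0.0 < low <= high <= 0.5):
        raise InvalidParameterError(
            f"noise MAF range must satisfy 0 < low <= high <= 0.5, "
            f"got {noise_maf_range!r}"
        )
    maf = float(rng.uniform(low, high))
    return rng.choice(3, size=n_samples, p=hwe_genotype_frequencies(maf))


def simulate_balanced_dataset(
    spec: DatasetSpec, rng: np.random.Generator | None = None
) -> GenotypeDataset:
    """Simulate one balanced dataset by quota rejection sampling.

    Individuals are drawn in batches; each draw is assigned to its class
    quota in draw order, and surplus draws for a filled class are discarded.
    Rows are shuffled after both quotas fill so cases and controls are
    interleaved. Raises :class:`SamplingFailureError` if the attempt cap
    (10^4 x total_samples draws) is exceeded, naming the starved class.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    model = spec.model
    n = model.n_loci
    half = spec.total_samples // 2
    freqs = model.distribution.per_locus_freqs
    powers = mlg_index_powers(n)
    cap = _ATTEMPT_CAP_FACTOR * spec.total_samples

    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    n_cases = n_controls = 0
    draws = 0
    while n_cases < half or n_controls < half:
        if draws >= cap:
            starved = "case" if n_cases < half else "control"
            raise SamplingFailureError(
                f"exceeded {cap} draws with only "
                f"{n_cases if starved == 'case' else n_controls}/{half} "
                f"{starved}s sampled; model prevalence may be near-degenerate",
                starved_class=starved,
            )
        b = min(_BATCH, cap - draws)
        geno = np.column_stack([rng.choice(3, size=b, p=t) for t in freqs])
        f = model.penetrances[geno @ powers]
        is_case = rng.random(b) < f
        draws += b
        need = half - n_cases
        if need > 0:
            taken = geno[is_case][:need]
            case_rows.append(taken)
            n_cases += len(taken)
        need = half - n_controls
        if need > 0:
            taken = geno[~is_case][:need]
            control_rows.append(taken)
            n_controls += len(taken)

    predictive = np.vstack(case_rows + control_rows)
    labels = np.concatenate(
        [np.ones(half, dtype=np.int64), np.zeros(half, dtype=np.int64)]
    )
    n_noise = spec.n_total_snps - n
    columns = [predictive]
    if n_noise:
        columns.append(
            np.column_stack(
                [
                    noise_snp(spec.total_samples, spec.noise_maf_range, rng)
                    for _ in range(n_noise)
                ]
            )
        )
    genotypes = np.hstack(columns).astype(np.int8)
    perm = rng.permutation(spec.total_samples)
    names = tuple(f"P{i}" for i in range(n)) + tuple(f"N{i}" for i in range(n_noise))
    return GenotypeDataset(
        genotypes=genotypes[perm], class_labels=labels[perm], snp_names=names
    )


def simulate_replicate(spec: DatasetSpec, replicate: int) -> GenotypeDataset:
    """Simulate replicate ``replicate`` alone, reproducing exactly the
    dataset :func:`generate_replicates` would produce at that index."""
    if not (0 <= replicate < spec.n_replicates):
        raise InvalidParameterError(
            f"replicate index must lie in [0, {spec.n_replicates}), got {replicate}"
        )
    rng = np.random.default_rng((spec.rng_seed, replicate))
    return simulate_balanced_dataset(spec, rng)


def generate_replicates(spec: DatasetSpec) -> list[GenotypeDataset]:
    """Simulate all replicates, each from its own child seed (rng_seed, r)."""
    return [simulate_replicate(spec, r) for r in range(spec.n_replicates)]


def experiment_grid(factors: dict[str, Sequence]) -> list[dict]:
    """Full factorial expansion of named factor levels.

    Combinations are enumerated in deterministic lexicographic order: the
    first factor varies slowest, levels in the order given. The count is the
    product of the level counts.
    """
    if not factors:
        raise InvalidParameterError("at least one factor is required")
    names = list(factors)
    levels = []
    for name in names:
        lv = list(factors[name])
        if not lv:
            raise InvalidParameterError(f"factor {name!r} has no levels")
        levels.append(lv)
    return [dict(zip(names, combo)) for combo in _iterproduct(*levels)]
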