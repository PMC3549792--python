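"""Model generation: pure-interaction basis, direction sampling, scaling,
population generation, and quantile selection."""

import numpy as np
import pytest

from epistasim import (
    EmptySelectionError,
    InvalidParameterError,
    PenetranceModel,
    edm,
    generate_population,
    heritability,
    is_pure_strict,
    prevalence,
    select_quantiles,
)
from epistasim.generator import (
    ModelPopulation,
    ModelSpec,
    build_model,
    metric_values,
    pure_interaction_basis,
    random_unit_direction,
)
from epistasim.genetics import GenotypeDistribution


def brute_force_weighted_marginal(table, freqs, axis):
    """Independent marginalization oracle: weight-and-sum one locus out."""
    arr = np.asarray(table)
    w = np.asarray(freqs)
    return np.apply_along_axis(lambda v: float(v @ w), axis, arr)


class TestInteractionBasis:
    @pytest.mark.parametrize("mafs", [(0.5,), (0.4, 0.5), (0.2, 0.3, 0.45)])
    def test_count_and_orthonormality(self, mafs):
        dist = GenotypeDistribution.from_mafs(mafs)
        basis = pure_interaction_basis(dist)
        n = len(mafs)
        assert basis.basis_tables.shape == (2**n, 3**n)
        gram = (basis.basis_tables * basis.weights) @ basis.basis_tables.T
        np.testing.assert_allclose(gram, np.eye(2**n), atol=1e-12)

    def test_single_locus_contrasts_weighted_zero(self):
        dist = GenotypeDistribution.from_mafs((0.5,))
        basis = pure_interaction_basis(dist)
        for table in basis.basis_tables:
            assert float(basis.weights @ table) == pytest.approx(0.0, abs=1e-12)

    def test_two_locus_marginals_vanish(self):
        # brute-force row/column marginalization on every basis table
        dist = GenotypeDistribution.from_mafs((0.4, 0.5))
        basis = pure_interaction_basis(dist)
        f0, f1 = dist.per_locus_freqs
        for flat in basis.basis_tables:
            table = flat.reshape(3, 3)
            np.testing.assert_allclose(
                brute_force_weighted_marginal(table, f1, axis=1), 0.0, atol=1e-12
            )
            np.testing.assert_allclose(
                brute_force_weighted_marginal(table, f0, axis=0), 0.0, atol=1e-12
            )


class TestRandomUnitDirection:
    def test_unit_norm(self):
        rng = np.random.default_rng(41)
        for dim in (1, 2, 4, 8):
            v = random_unit_direction(dim, rng)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        v1 = random_unit_direction(4, np.random.default_rng(7))
        v2 = random_unit_direction(4, np.random.default_rng(7))
        np.testing.assert_array_equal(v1, v2)

    def test_directionally_unbiased(self):
        rng = np.random.default_rng(42)
        draws = np.array([random_unit_direction(4, rng) for _ in range(10_000)])
        # coordinates of a uniform direction have mean 0, variance 1/dim
        se = np.sqrt(1 / 4 / len(draws))
        assert np.all(np.abs(draws.mean(axis=0)) < 4 * se)

    def test_invalid_dim(self):
        with pytest.raises(InvalidParameterError):
            random_unit_direction(0, np.random.default_rng(0))


class TestBuildModel:
    @pytest.fixture
    def two_locus_setup(self):
        spec = ModelSpec(2, (0.25, 0.25), 0.02, 0.3, rng_seed=0)
        basis = pure_interaction_basis(GenotypeDistribution.from_mafs(spec.mafs))
        return spec, basis

    def test_accepted_model_hits_constraints_exactly(self, two_locus_setup):
        spec, basis = two_locus_setup
        rng = np.random.default_rng(43)
        accepted = 0
        while accepted < 20:
            model = build_model(spec, random_unit_direction(4, rng), basis)
            if model is None:
                continue
            accepted += 1
            assert prevalence(model) == pytest.approx(0.3, abs=1e-9)
            assert heritability(model) == pytest.approx(0.02, abs=1e-9)
            assert is_pure_strict(model, tol=1e-9)

    def test_excessive_heritability_is_rejected(self, two_locus_setup):
        spec, basis = two_locus_setup
        direction = random_unit_direction(4, np.random.default_rng(44))
        hard_spec = ModelSpec(2, spec.mafs, 0.9, 0.3)
        assert build_model(hard_spec, direction, basis) is None

    def test_raising_h2_never_rescues_a_rejection(self, two_locus_setup):
        # the amplitude grows monotonically with h^2, so a rejection at some
        # h^2 stays a rejection at every larger h^2 for the same direction
        spec, basis = two_locus_setup
        rng = np.random.default_rng(45)
        h2_grid = (0.01, 0.05, 0.1, 0.2, 0.4, 0.8)
        for _ in range(50):
            direction = random_unit_direction(4, rng)
            accepted = [
                build_model(ModelSpec(2, spec.mafs, h2, 0.3), direction, basis)
                is not None
                for h2 in h2_grid
            ]
            assert accepted == sorted(accepted, reverse=True)

    def test_non_unit_direction_rejected(self, two_locus_setup):
        spec, basis = two_locus_setup
        with pytest.raises(InvalidParameterError):
            build_model(spec, np.array([1.0, 1.0, 0.0, 0.0]), basis)

    def test_deviation_reconstructs_from_basis_projection(self, two_locus_setup):
        # the deviation f - K of any generated model lies in the span of the
        # 2^n basis tables (basis completeness)
        spec, basis = two_locus_setup
        pop = generate_population(spec, pop_size=5, max_attempts=10_000)
        for model in pop.models:
            dev = model.penetrances - spec.target_k
            coeffs = (basis.basis_tables * basis.weights) @ dev
            residual = dev - coeffs @ basis.basis_tables
            assert np.max(np.abs(residual)) < 1e-10


class TestGeneratePopulation:
    def test_population_satisfies_invariants(self):
        spec = ModelSpec(2, (0.2, 0.2), 0.005, 0.3, rng_seed=3)
        pop = generate_population(spec, pop_size=200, max_attempts=100_000)
        assert len(pop) == 200
        assert pop.attempts_used >= 200
        for m in pop.models:
            assert prevalence(m) == pytest.approx(0.3, abs=1e-9)
            assert heritability(m) == pytest.approx(0.005, abs=1e-9)
            assert is_pure_strict(m, tol=1e-9)

    def test_attempt_cap_bounds_population(self):
        spec = ModelSpec(2, (0.2, 0.2), 0.2, 0.3, rng_seed=3)
        pop = generate_population(spec, pop_size=50, max_attempts=50)
        assert len(pop) <= 50
        assert pop.attempts_used == 50

    def test_deterministic_under_seed(self):
        spec = ModelSpec(2, (0.3, 0.3), 0.01, 0.3, rng_seed=9)
        pop1 = generate_population(spec, pop_size=20, max_attempts=10_000)
        pop2 = generate_population(spec, pop_size=20, max_attempts=10_000)
        assert pop1.attempts_used == pop2.attempts_used
        for m1, m2 in zip(pop1.models, pop2.models):
            np.testing.assert_array_equal(m1.penetrances, m2.penetrances)

    def test_invalid_caps_rejected(self):
        spec = ModelSpec(2, (0.3, 0.3), 0.01, 0.3)
        with pytest.raises(InvalidParameterError):
            generate_population(spec, pop_size=0)
        with pytest.raises(InvalidParameterError):
            generate_population(spec, pop_size=10, max_attempts=5)


@pytest.fixture(scope="module")
def population():
    spec = ModelSpec(2, (0.3, 0.3), 0.02, 0.3, rng_seed=17)
    return generate_population(spec, pop_size=101, max_attempts=100_000)


class TestSelectQuantiles:

    def test_two_extremes(self, population):
        values = np.array([edm(m) for m in population.models])
        lo, hi = select_quantiles(population, "edm", 2)
        assert edm(lo) == pytest.approx(values.min(), rel=1e-12)
        assert edm(hi) == pytest.approx(values.max(), rel=1e-12)

    def test_full_population_is_sorted_order(self, population):
        selected = select_quantiles(population, "edm", len(population))
        values = [edm(m) for m in selected]
        assert values == sorted(values)
        assert len(selected) == len(population)

    def test_selection_nondecreasing_in_metric(self, population):
        for metric in ("edm", "cor", "ptv"):
            _, vals = metric_values(population, metric)
            selected = select_quantiles(population, metric, 10)
            from epistasim.generator import METRICS

            picked = [METRICS[metric](m) for m in selected]
            assert picked == sorted(picked)
            assert len(selected) == 10

    def test_single_selection_is_median_rank(self, population):
        (med,) = select_quantiles(population, "edm", 1)
        values = sorted(edm(m) for m in population.models)
        assert edm(med) == pytest.approx(values[len(values) // 2], rel=1e-12)

    def test_empty_population_raises(self):
        empty = ModelPopulation.from_models([])
        with pytest.raises(EmptySelectionError):
            select_quantiles(empty, "edm", 2)

    def test_undefined_cor_models_dropped_with_warning(self, population):
        flat = PenetranceModel(mafs=(0.3, 0.3), penetrances=np.full(9, 0.3))
        mixed = ModelPopulation.from_models(population.models[:5] + [flat])
        with pytest.warns(UserWarning, match="undefined"):
            selected = select_quantiles(mixed, "cor", 2)
        assert all(m is not flat for m in selected)

    def test_unknown_metric_rejected(self, population):
        with pytest.raises(InvalidParameterError):
            select_quantiles(population, "entropy", 2)


def test_spec_validation():
    with pytest.raises(InvalidParameterError):
        ModelSpec(2, (0.2,), 0.1, 0.3)  # MAF count mismatch
    with pytest.raises(InvalidParameterError):
        ModelSpec(2, (0.2, 0.2), 1.5, 0.3)  # h2 out of range
    with pytest.raises(InvalidParameterError):
        ModelSpec(2, (0.2, 0.2), 0.1, 0.0)  # K out of range
    with pytest.raises(InvalidParameterError):
        ModelSpec(2, (0.2, 0.6), 0.1, 0.3)  # MAF out of range
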