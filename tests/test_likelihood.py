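"""Poisson log-pmf, expected counts and the age-likelihood profile."""

import math

import numpy as np
import pytest

from txclock import (CountMatrix, ReferenceModel, expected_counts,
                     log_likelihood_profile, poisson_log_pmf, predict_age)

from _oracles import poisson_log_pmf_oracle, profile_oracle


def small_model(rng, n_genes=4, n_grid=3):
    grid = np.sort(rng.choice(np.arange(1.0, 28.0), size=n_grid,
                              replace=False))
    freq = rng.uniform(1e-3, 0.2, size=(n_genes, n_grid))
    rho = rng.uniform(0.2, 1.0, n_genes) * rng.choice([-1, 1], n_genes)
    return ReferenceModel(tau=0.7, age_grid=grid,
                          gene_ids=tuple(f"g{i}" for i in range(n_genes)),
                          rho=rho, fitted_freq=freq)


class TestPoissonLogPmf:
    def test_exact_small_cases(self):
        assert poisson_log_pmf(0, 1.0) == pytest.approx(-1.0, abs=1e-15)
        assert poisson_log_pmf(1, 1.0) == pytest.approx(-1.0, abs=1e-15)

    def test_matches_factorial_oracle(self):
        assert poisson_log_pmf(3, 2.5) == pytest.approx(
            math.log(math.exp(-2.5) * 2.5 ** 3 / 6), abs=1e-12)
        for k in range(21):
            for lam in (0.1, 0.5, 1.0, 2.5, 10.0):
                assert poisson_log_pmf(k, lam) == pytest.approx(
                    poisson_log_pmf_oracle(k, lam), abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            poisson_log_pmf(1, 0.0)
        with pytest.raises(ValueError):
            poisson_log_pmf(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_log_pmf(1.5, 1.0)


class TestExpectedCounts:
    def test_rates_scale_with_library_size(self):
        model = ReferenceModel(tau=0.7, age_grid=np.array([1.0, 3.0]),
                               gene_ids=("a", "b"), rho=np.array([1.0, -1.0]),
                               fitted_freq=np.array([[0.002, 0.1],
                                                     [0.003, 0.2]]))
        np.testing.assert_allclose(expected_counts(model, 0, 100.0),
                                   [0.2, 0.3])

    def test_floor_rate_stays_positive(self):
        model = ReferenceModel(tau=0.7, age_grid=np.array([1.0, 3.0]),
                               gene_ids=("a",), rho=np.array([1.0]),
                               fitted_freq=np.array([[1e-12, 0.1]]))
        assert expected_counts(model, 0, 1e6)[0] == pytest.approx(1e-6)

    def test_invalid_arguments_rejected(self):
        model = small_model(np.random.default_rng(0))
        with pytest.raises(ValueError):
            expected_counts(model, 0, 0.0)
        with pytest.raises(ValueError):
            expected_counts(model, 99, 1.0)


class TestLikelihoodProfile:
    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            model = small_model(rng, n_genes=int(rng.integers(1, 6)),
                                n_grid=int(rng.integers(2, 5)))
            counts = rng.integers(0, 51, size=model.n_genes)
            counts[0] = max(counts[0], 1)
            prof = log_likelihood_profile(model.gene_ids, counts, model)
            np.testing.assert_allclose(
                prof.log_lik, profile_oracle(model.gene_ids, counts, model),
                atol=1e-10)

    def test_recovers_generating_age_at_large_library(self):
        rng = np.random.default_rng(7)
        model = small_model(rng, n_genes=5, n_grid=4)
        lib = 1e6
        for gi, age in enumerate(model.age_grid):
            k = np.rint(model.fitted_freq[:, gi] * lib).astype(int)
            prof = log_likelihood_profile(model.gene_ids, k, model,
                                          lambda_scale="intersection")
            assert prof.point_estimate == age

    def test_flat_model_gives_uniform_posterior_and_youngest_age(self):
        model = ReferenceModel(tau=0.7, age_grid=np.array([1.0, 3.0, 6.0]),
                               gene_ids=("a",), rho=np.array([0.5]),
                               fitted_freq=np.full((1, 3), 0.25))
        prof = log_likelihood_profile(("a",), np.array([10]), model)
        np.testing.assert_allclose(prof.posterior, 1 / 3, atol=1e-12)
        assert prof.point_estimate == 1.0  # tie resolves to youngest

    def test_missing_model_genes_are_dropped(self, fixture_data,
                                             fixture_model):
        cm, _, _ = fixture_data
        keep = [i for i, g in enumerate(cm.gene_ids)
                if g not in fixture_model.gene_ids[:3]]
        prof = log_likelihood_profile([cm.gene_ids[i] for i in keep],
                                      cm.counts[keep, 0], fixture_model)
        assert prof.n_genes_used == 9
        assert prof.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_intersection_and_zero_library_rejected(self):
        model = small_model(np.random.default_rng(1))
        with pytest.raises(ValueError, match="no genes"):
            log_likelihood_profile(("other",), np.array([1]), model)
        with pytest.raises(ValueError, match="zero library"):
            log_likelihood_profile(model.gene_ids,
                                   np.zeros(model.n_genes, dtype=int), model)

    def test_posterior_normalized_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            model = small_model(rng, n_genes=int(rng.integers(1, 8)),
                                n_grid=int(rng.integers(2, 8)))
            counts = rng.integers(0, 500, size=model.n_genes)
            counts[0] = max(counts[0], 1)
            prof = log_likelihood_profile(model.gene_ids, counts, model)
            assert prof.posterior.sum() == pytest.approx(1.0, abs=1e-9)
            assert (prof.posterior >= 0).all()

    def test_log_factorial_term_never_moves_argmax(self):
        # the -ln(k!) term is constant in age, so argmax is unaffected
        rng = np.random.default_rng(9)
        for _ in range(50):
            model = small_model(rng, n_genes=int(rng.integers(1, 6)),
                                n_grid=int(rng.integers(2, 6)))
            counts = rng.integers(0, 60, size=model.n_genes)
            counts[0] = max(counts[0], 1)
            prof = log_likelihood_profile(model.gene_ids, counts, model)
            lam = model.fitted_freq * counts.sum()
            partial = (-lam + counts[:, None] * np.log(lam)).sum(axis=0)
            assert np.argmax(partial) == np.argmax(prof.log_lik)


class TestPredictAge:
    def test_per_sample_error_isolation(self, fixture_model):
        genes = list(fixture_model.gene_ids)
        counts = np.column_stack([
            np.full(12, 20), np.full(12, 40), np.zeros(12, dtype=int)])
        cm = CountMatrix(genes, ["ok1", "ok2", "empty"], counts)
        result = predict_age(cm, fixture_model)
        assert len(result.results) == 2
        assert set(result.failures) == {"empty"}

    def test_duplicated_sample_predicts_identically(self, fixture_data,
                                                    fixture_model):
        cm, _, _ = fixture_data
        col = cm.counts[:, 5]
        dup = CountMatrix(cm.gene_ids, ["a", "b"],
                          np.column_stack([col, col]))
        result = predict_age(dup, fixture_model)
        r1, r2 = result.results
        np.testing.assert_array_equal(r1.log_lik, r2.log_lik)
        assert r1.point_estimate == r2.point_estimate

    def test_doubled_counts_keep_argmax_on_fixture(self, fixture_data,
                                                   fixture_model):
        cm, _, _ = fixture_data
        col = cm.counts[:, 12]
        base = log_likelihood_profile(cm.gene_ids, col, fixture_model)
        doubled = log_likelihood_profile(cm.gene_ids, 2 * col, fixture_model)
        assert base.point_estimate == doubled.point_estimate
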