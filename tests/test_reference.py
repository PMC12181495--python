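"""Frequency normalization, Spearman ranking and reference training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from txclock import (AgeAnnotation, CountMatrix, build_reference,
                     normalize_counts, rank_and_select, spearman_rho)


class TestNormalizeCounts:
    def test_hand_computed_frequencies(self):
        cm = CountMatrix(["a", "b", "c"], ["s"], np.array([[2], [3], [5]]))
        np.testing.assert_allclose(normalize_counts(cm).freqs[:, 0],
                                   [0.2, 0.3, 0.5])

    def test_single_gene_normalizes_to_one(self):
        cm = CountMatrix(["a"], ["s"], np.array([[7]]))
        assert normalize_counts(cm).freqs[0, 0] == 1.0

    def test_zero_column_rejected_by_name(self):
        cm = CountMatrix(["a", "b"], ["ok", "empty"],
                         np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError, match="empty"):
            normalize_counts(cm)

    @settings(max_examples=30, deadline=None)
    @given(arrays(np.int64, (6, 4), elements=st.integers(0, 1000)))
    def test_columns_conserve_mass(self, counts):
        counts[0] += 1  # keep every column total positive
        cm = CountMatrix([f"g{i}" for i in range(6)],
                         [f"s{j}" for j in range(4)], counts)
        np.testing.assert_allclose(normalize_counts(cm).freqs.sum(axis=0),
                                   1.0, atol=1e-9)


class TestSpearmanRho:
    @pytest.mark.parametrize("values, ages, expected", [
        ((1, 2, 3, 4), (1, 3, 6, 9), 1.0),
        ((4, 3, 2, 1), (1, 3, 6, 9), -1.0),
        # hand-computed: ranks (1,3,2,4) vs (1,2,3,4) -> rho = 0.8
        ((1, 3, 2, 4), (1, 2, 3, 4), 0.8),
    ])
    def test_known_values(self, values, ages, expected):
        assert spearman_rho(values, ages) == pytest.approx(expected)

    def test_constant_input_is_undefined(self):
        assert np.isnan(spearman_rho((5, 5, 5, 5), (1, 3, 6, 9)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho((1, 2, 3), (1, 2))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=15,
                    unique=True),
           st.floats(0.1, 4.0))
    def test_invariant_under_monotone_transform(self, values, scale):
        ages = np.arange(len(values), dtype=float) + 1
        v = np.asarray(values, dtype=float)
        direct = spearman_rho(v, ages)
        transformed = spearman_rho(np.exp(scale * v / 50.0), ages ** 3)
        assert direct == pytest.approx(transformed, abs=1e-12)


class TestRankAndSelect:
    def _freq(self, mat, ids=None):
        cm = CountMatrix(ids or [f"g{i}" for i in range(mat.shape[0])],
                         [f"s{j}" for j in range(mat.shape[1])], mat)
        ann = AgeAnnotation({f"s{j}": float(a)
                             for j, a in enumerate([1, 3, 6, 9])})
        return normalize_counts(cm), ann

    def test_monotone_genes_beat_constant_ones(self):
        # 2 genes monotone in age, 3 with constant frequency
        mat = np.array([[10, 20, 30, 40],
                        [40, 30, 20, 10],
                        [25, 25, 25, 25],
                        [25, 25, 25, 25],
                        [25, 25, 25, 25]]) * 4
        fm, ann = self._freq(mat)
        ranking = rank_and_select(fm, ann, 2)
        assert set(ranking.gene_ids) == {"g0", "g1"}
        assert np.all(np.abs(ranking.rho) == 1.0)

    def test_tie_breaks_to_lexicographic_gene_id(self):
        mat = np.array([[10, 20, 30, 40],
                        [10, 20, 30, 40],
                        [40, 30, 20, 10]])
        fm, ann = self._freq(mat, ids=["zeta", "alpha", "mid"])
        ranking = rank_and_select(fm, ann, 1)
        assert ranking.gene_ids == ("alpha",)

    def test_n_top_exceeding_defined_genes_reports_both_numbers(self):
        mat = np.array([[10, 20, 30, 40],
                        [40, 30, 20, 10],
                        [25, 25, 25, 25]])
        fm, ann = self._freq(mat)
        with pytest.raises(ValueError, match="5.*2|2.*5"):
            rank_and_select(fm, ann, 5)

    def test_ranked_rho_magnitudes_non_increasing(self, fixture_data):
        cm, ann, _ = fixture_data
        ranking = rank_and_select(normalize_counts(cm), ann, 30)
        mags = np.abs(ranking.rho)
        assert np.all(np.diff(mags) <= 1e-15)


class TestBuildReference:
    def test_default_panel_shape(self, fixture_model):
        assert fixture_model.n_genes == 12
        assert fixture_model.fitted_freq.shape == (12, 10)
        np.testing.assert_array_equal(fixture_model.age_grid,
                                      [1, 3, 6, 9, 12, 15, 18, 21, 24, 27])

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(10, 1000, size=(5, 8))
        counts[2] = 77  # identical in every sample
        totals = counts.sum(axis=0)
        counts = np.vstack([counts, totals.max() * 3 - totals])  # equal totals
        cm = CountMatrix([f"g{i}" for i in range(6)],
                         [f"s{j}" for j in range(8)], counts)
        ann = AgeAnnotation({f"s{j}": float(a) for j, a in
                             enumerate([1, 1, 3, 3, 6, 6, 9, 9])})
        model = build_reference(cm, ann, n_top=3)
        assert "g2" not in model.gene_ids
        assert model.diagnostics["n_undefined_rho"] >= 1

    def test_fits_clamped_at_freq_floor(self, fixture_data):
        cm, ann, _ = fixture_data
        floor = 5e-4  # above some genes' fitted frequencies, forcing clamps
        model = build_reference(cm, ann, freq_floor=floor)
        assert model.fitted_freq.min() >= floor

    def test_training_is_deterministic(self, fixture_data, fixture_model):
        cm, ann, _ = fixture_data
        again = build_reference(cm, ann)
        assert again == fixture_model

    def test_explicit_grid_is_respected(self, fixture_data):
        cm, ann, _ = fixture_data
        model = build_reference(cm, ann, age_grid=np.array([3.0, 9.0, 21.0]))
        assert model.fitted_freq.shape == (12, 3)
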