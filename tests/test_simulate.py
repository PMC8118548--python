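import numpy as np
import pytest

import dpccn
from dpccn import (
    BackboneSpec,
    apply_collinearity,
    apply_disruption,
    generate_backbone,
    relu_term,
    scaled_layout,
    simulate_model_A,
    simulate_model_B,
)


class TestBackbone:
    def test_default_mirrors_real_dataset_dimensions(self):
        X = generate_backbone(BackboneSpec(seed=1))
        assert (X.n, X.p) == (191, 231)
        assert X.standardized

    def test_independent_columns_uncorrelated(self):
        X = generate_backbone(BackboneSpec(n=5000, p=6, seed=2))
        corr = np.corrcoef(X.values, rowvar=False)
        off = corr[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.05

    def test_block_structure_hits_target_rho(self):
        X = generate_backbone(
            BackboneSpec(n=5000, p=10, structure="block", block_size=5, rho=0.6, seed=3)
        )
        corr = np.corrcoef(X.values, rowvar=False)
        within = [corr[i, j] for i in range(5) for j in range(i + 1, 5)]
        across = [corr[i, j] for i in range(5) for j in range(5, 10)]
        assert abs(np.mean(within) - 0.6) < 0.05
        assert np.abs(across).max() < 0.06

    def test_seed_reproducibility(self):
        a = generate_backbone(BackboneSpec(n=50, p=5, seed=9))
        b = generate_backbone(BackboneSpec(n=50, p=5, seed=9))
        np.testing.assert_array_equal(a.values, b.values)


class TestReluTerm:
    def test_median_rectification(self):
        out = relu_term(np.array([1.0, 1, 1, 1]), np.array([1.0, 2, 3, 4]))
        np.testing.assert_array_equal(out, [0, 0, 3, 4])  # median 2.5

    def test_constant_products_pass_through(self):
        out = relu_term(np.full(5, 2.0), np.full(5, 3.0))
        np.testing.assert_array_equal(out, np.full(5, 6.0))

    def test_exactly_half_nonzero_for_continuous_even_n(self, rng):
        xj = rng.standard_normal(10000)
        xk = rng.standard_normal(10000)
        out = relu_term(xj, xk)
        assert (out != 0).sum() == 5000


class TestCollinearity:
    def test_zero_noise_perfect_correlation(self):
        X = generate_backbone(BackboneSpec(n=100, p=4, seed=4))
        Xc = apply_collinearity(X, ((0, 1),), noise_sd=0.0, seed=5)
        assert np.corrcoef(Xc.values[:, 0], Xc.values[:, 1])[0, 1] == pytest.approx(1.0)

    def test_closed_form_correlation(self):
        # unit-variance source + N(0, 0.25^2) noise: rho = (1.0625)^(-1/2)
        X = generate_backbone(BackboneSpec(n=20000, p=3, seed=6))
        Xc = apply_collinearity(X, ((0, 1),), noise_sd=0.25, seed=7)
        r = np.corrcoef(Xc.values[:, 0], Xc.values[:, 1])[0, 1]
        assert abs(r - (1 + 0.0625) ** -0.5) < 0.01

    def test_only_targets_change(self):
        X = generate_backbone(BackboneSpec(n=50, p=5, seed=8))
        Xc = apply_collinearity(X, ((0, 1),), seed=9)
        np.testing.assert_array_equal(Xc.values[:, 1:], X.values[:, 1:])
        assert not np.allclose(Xc.values[:, 0], X.values[:, 0])

    def test_overlapping_targets_rejected(self):
        X = generate_backbone(BackboneSpec(n=50, p=5, seed=8))
        with pytest.raises(ValueError, match="overlap"):
            apply_collinearity(X, ((0, 1), (0, 2)), seed=1)


class TestDisruption:
    def test_degenerate_cut_leaves_matrix_unchanged(self):
        X = generate_backbone(BackboneSpec(n=50, p=4, seed=10))
        y = np.arange(50.0)
        Xd = apply_disruption(X, y, ((0, 1, 1),), cut_quantile=1.0, seed=11)
        np.testing.assert_array_equal(Xd.values, X.values)

    def test_modified_rows_strongly_correlated(self):
        X = generate_backbone(BackboneSpec(n=20000, p=4, seed=12))
        y = np.random.default_rng(13).standard_normal(20000)
        Xd = apply_disruption(X, y, ((0, 1, -1),), cut_quantile=0.8, seed=14)
        rows = y >= np.quantile(y, 0.8)
        r = np.corrcoef(Xd.values[rows, 0], Xd.values[rows, 1])[0, 1]
        assert r <= -0.9

    def test_untouched_rows_keep_backbone_correlation(self):
        X = generate_backbone(BackboneSpec(n=20000, p=4, seed=12))
        y = np.random.default_rng(13).standard_normal(20000)
        Xd = apply_disruption(X, y, ((0, 1, 1),), cut_quantile=0.8, seed=14)
        rows = y >= np.quantile(y, 0.8)
        np.testing.assert_array_equal(Xd.values[~rows], X.values[~rows])
        np.testing.assert_array_equal(Xd.values[:, [0, 2, 3]], X.values[:, [0, 2, 3]])


class TestModelA:
    def test_truth_has_14_positive_pairs_default(self):
        X = generate_backbone(BackboneSpec(n=191, p=231, seed=15))
        y, truth, X_out = simulate_model_A(X, seed=16)
        assert len(truth.type1_pairs) == 6
        assert len(truth.relu_pairs) == 2
        assert len(truth.disrupted_pairs) == 6
        assert len(truth.positive_pairs()) == 14
        assert len(y) == 191

    def test_zeroed_columns_and_noise_give_zero_phenotype(self):
        layout = scaled_layout(40)
        vals = np.random.default_rng(17).standard_normal((100, 40))
        idx = sorted(
            {i for pr in layout.type1_pairs for i in pr}
            | {i for pr in layout.relu_pairs for i in pr}
        )
        vals[:, idx] = 0.0
        X = dpccn.ExpressionMatrix(
            values=vals,
            gene_names=[f"g{i}" for i in range(40)],
            sample_ids=[f"s{i}" for i in range(100)],
        )
        # drop the collinearity overwrite so zeroed sources stay zero
        from dataclasses import replace

        layout0 = replace(layout, collinear_pairs=())
        y, truth, _ = simulate_model_A(X, seed=18, noise_sd=0.0, layout=layout0)
        np.testing.assert_allclose(y.values, 0.0, atol=1e-12)

    def test_noise_only_variance(self):
        # all interaction columns zeroed: y is pure N(0, 1.75^2) noise
        layout = scaled_layout(40)
        vals = np.random.default_rng(19).standard_normal((20000, 40))
        idx = sorted(
            {i for pr in layout.type1_pairs for i in pr}
            | {i for pr in layout.relu_pairs for i in pr}
        )
        vals[:, idx] = 0.0
        X = dpccn.ExpressionMatrix(
            values=vals,
            gene_names=[f"g{i}" for i in range(40)],
            sample_ids=[f"s{i}" for i in range(20000)],
        )
        from dataclasses import replace

        layout0 = replace(layout, collinear_pairs=())
        y, _, _ = simulate_model_A(X, seed=20, noise_sd=1.75, layout=layout0)
        assert abs(np.var(y.values) - 1.75**2) < 0.15

    def test_seed_reproducibility(self):
        X = generate_backbone(BackboneSpec(n=100, p=40, seed=21))
        out1 = simulate_model_A(X, seed=22)
        out2 = simulate_model_A(X, seed=22)
        np.testing.assert_array_equal(out1[0].values, out2[0].values)
        np.testing.assert_array_equal(out1[2].values, out2[2].values)

    def test_index_out_of_range_rejected(self):
        X = generate_backbone(BackboneSpec(n=100, p=40, seed=23))
        with pytest.raises(ValueError, match="out of range"):
            simulate_model_A(X, seed=1, layout=scaled_layout(60))


class TestModelB:
    def test_main_effects_recovered_by_ols(self):
        X = generate_backbone(BackboneSpec(n=20000, p=40, seed=24))
        y, truth, X_out = simulate_model_B(X, seed=25)
        assert len(truth.main_effects) == 6
        assert all(v == 2.0 for v in truth.main_effects.values())
        cols = sorted(truth.main_effects)
        A = np.column_stack([X_out.values[:, cols], np.ones(X.n)])
        coef, *_ = np.linalg.lstsq(A, y.values, rcond=None)
        np.testing.assert_allclose(coef[:6], 2.0, atol=0.1)

    def test_reduces_to_model_A_when_mains_zeroed(self):
        # zero the main-effect columns: model B is model A plus extra noise
        layout = scaled_layout(40)
        vals = np.random.default_rng(26).standard_normal((5000, 40))
        vals[:, list(layout.main_effect_indices)] = 0.0
        X = dpccn.ExpressionMatrix(
            values=vals,
            gene_names=[f"g{i}" for i in range(40)],
            sample_ids=[f"s{i}" for i in range(5000)],
        )
        yB, truthB, _ = simulate_model_B(X, seed=27, layout=layout)
        yA, truthA, _ = simulate_model_A(X, seed=27, layout=layout)
        assert truthB.positive_pairs() == truthA.positive_pairs()
        # extra independent noise term: variance difference ~ noise_sd^2
        assert abs((np.var(yB.values) - np.var(yA.values)) - 1.75**2) < 0.35


class TestWriteReplicate:
    def test_sidecar_round_trip(self, tmp_path):
        import json

        X = generate_backbone(BackboneSpec(n=60, p=40, seed=28))
        y, truth, X_out = simulate_model_A(X, seed=29)
        dpccn.simulate.write_replicate(X_out, y, truth, tmp_path)
        X_back = dpccn.read_expression(tmp_path / "expression.tsv")
        assert (X_back.n, X_back.p) == (60, 40)
        meta = json.loads((tmp_path / "truth.json").read_text())
        assert [tuple(t) for t in meta["type1_pairs"]] == list(truth.type1_pairs)
        assert meta["noise_sd"] == 1.75
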