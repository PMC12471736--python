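"""Attribution layer: exact additivity, Shapley oracle, importances, reports."""

import numpy as np
import pytest

from hemonam import (BootstrapConfig, FeatureTable, NAMConfig,
                     additive_attributions, classwise_summary,
                     global_importance, init_nam, nam_intrinsic_importance,
                     per_sample_report, predict_batch,
                     shapley_enumeration_oracle)
from hemonam.explain import AttributionSet
from hemonam.nam import SubnetworkParams, predict_matrix


def _identity_subnet():
    return SubnetworkParams(np.array([1.0, -1.0]), np.zeros(2), np.eye(2),
                            np.zeros(2), np.array([1.0, -1.0]), 0.0)


def _zeroed(p, hidden=(2, 2), seed=0):
    params = init_nam(NAMConfig(hidden_sizes=hidden, dropout_rate=0.0), p,
                      seed=seed)
    for arr in (params.W1, params.B1, params.W2, params.B2, params.W3,
                params.B3):
        arr[...] = 0.0
    return params


def _table(X):
    return FeatureTable(X, [f"x{i}" for i in range(X.shape[1])],
                        np.zeros(X.shape[0], dtype=int))


class TestAdditiveAttributions:
    def test_zero_network_gives_zero_phi(self):
        params = _zeroed(3)
        params.bias = 0.8
        X = np.random.default_rng(0).normal(size=(6, 3))
        attrs = additive_attributions(params, _table(X), _table(X))
        np.testing.assert_array_equal(attrs.phi, np.zeros((6, 3)))
        assert attrs.base_value == 0.8

    def test_identity_subnet_with_centered_reference(self):
        params = _zeroed(1)
        params.set_subnetwork(0, _identity_subnet())
        ref = _table(np.array([[-1.0], [1.0]]))  # mean contribution 0
        X = np.array([[0.7], [-2.0]])
        attrs = additive_attributions(params, _table(X), ref)
        np.testing.assert_allclose(attrs.phi[:, 0], [0.7, -2.0], atol=1e-12)

    def test_matches_direct_centering_recomputation(self):
        params = init_nam(NAMConfig(hidden_sizes=(8, 4)), 3, seed=3)
        params.bias = -0.2
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        ref = rng.normal(size=(5, 3))
        attrs = additive_attributions(params, _table(X), _table(ref))
        f_x = predict_batch(params, _table(X)).contributions
        f_ref = predict_batch(params, _table(ref)).contributions
        np.testing.assert_allclose(attrs.phi, f_x - f_ref.mean(axis=0),
                                   atol=1e-12)

    def test_efficiency_reconstructs_logit(self):
        params = init_nam(NAMConfig(hidden_sizes=(8, 4)), 4, seed=4)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        attrs = additive_attributions(params, _table(X), _table(X))
        np.testing.assert_allclose(attrs.base_value + attrs.phi.sum(axis=1),
                                   attrs.logits, atol=1e-10)

    def test_empty_reference_rejected(self):
        params = _zeroed(2)
        with pytest.raises(ValueError, match="reference"):
            additive_attributions(params, _table(np.zeros((1, 2))),
                                  _table(np.empty((0, 2))))


class TestShapleyOracle:
    def test_additive_model_equals_centered_contributions(self):
        params = init_nam(NAMConfig(hidden_sizes=(8, 4)), 3, seed=5)
        params.bias = 0.3
        rng = np.random.default_rng(3)
        row = rng.normal(size=3)
        bg = rng.normal(size=(20, 3))

        def predict_fn(X):
            return predict_matrix(params, X).logits

        phi = shapley_enumeration_oracle(predict_fn, row, bg)
        attrs = additive_attributions(params, _table(row[None]), _table(bg))
        np.testing.assert_allclose(phi, attrs.phi[0], atol=1e-9)

    def test_efficiency_property(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=4)
        bg = rng.normal(size=(12, 4))

        def predict_fn(X):  # deliberately non-additive
            return X[:, 0] * X[:, 1] + np.sin(X[:, 2]) - X[:, 3] ** 2

        phi = shapley_enumeration_oracle(predict_fn, row, bg)
        assert phi.sum() == pytest.approx(
            float(predict_fn(row[None])[0] - predict_fn(bg).mean()),
            abs=1e-9)

    def test_single_feature_model(self):
        def predict_fn(X):
            return 2.0 * X[:, 0] + 1.0

        row = np.array([1.5])
        bg = np.array([[0.0], [1.0]])
        phi = shapley_enumeration_oracle(predict_fn, row, bg)
        assert phi[0] == pytest.approx(2 * 1.5 - 2 * 0.5, abs=1e-12)

    def test_constant_model_all_zero(self):
        phi = shapley_enumeration_oracle(
            lambda X: np.full(X.shape[0], 3.0), np.zeros(3),
            np.random.default_rng(0).normal(size=(4, 3)))
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_symmetry_identical_subnetworks(self):
        params = _zeroed(2)
        params.set_subnetwork(0, _identity_subnet())
        params.set_subnetwork(1, _identity_subnet())
        row = np.array([0.9, 0.9])
        bg = np.array([[0.1, 0.1], [-0.4, -0.4]])

        def predict_fn(X):
            return predict_matrix(params, X).logits

        phi = shapley_enumeration_oracle(predict_fn, row, bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_dimension_guard(self):
        with pytest.raises(ValueError, match="p_max"):
            shapley_enumeration_oracle(lambda X: X.sum(1), np.zeros(12),
                                       np.zeros((3, 12)), p_max=10)


class TestGlobalImportance:
    def _attrs(self, phi):
        n, p = phi.shape
        return AttributionSet(phi, 0.0, phi.sum(1), np.full(n, 0.5),
                              [f"x{i}" for i in range(p)])

    def test_all_zero_attributions(self):
        rep = global_importance(self._attrs(np.zeros((5, 3))))
        np.testing.assert_array_equal(rep.mean_abs_phi, np.zeros(3))

    def test_duplication_invariance(self):
        rng = np.random.default_rng(5)
        phi = rng.normal(size=(8, 3))
        a = global_importance(self._attrs(phi))
        b = global_importance(self._attrs(np.vstack([phi, phi])))
        np.testing.assert_allclose(a.mean_abs_phi, b.mean_abs_phi,
                                   atol=1e-12)

    def test_ranks_are_permutation_and_cis_contain_point(self):
        rng = np.random.default_rng(6)
        phi = rng.normal(size=(50, 4)) * np.array([3.0, 1.0, 0.3, 0.1])
        rep = global_importance(self._attrs(phi),
                                BootstrapConfig(200, seed=1))
        assert sorted(rep.rank) == [1, 2, 3, 4]
        assert rep.rank[0] == 1  # strongest column ranked first
        assert (rep.ci_lower <= rep.mean_abs_phi + 1e-12).all()
        assert (rep.mean_abs_phi <= rep.ci_upper + 1e-12).all()


class TestIntrinsicImportance:
    def test_sums_to_one_and_zero_subnet_zero_share(self):
        params = init_nam(NAMConfig(hidden_sizes=(8, 4)), 3, seed=7)
        # silence feature 2
        params.W3[2] = 0.0
        params.B3[2] = 0.0
        X = np.random.default_rng(7).normal(size=(40, 3))
        imp = nam_intrinsic_importance(params, _table(X))
        assert imp.sum() == pytest.approx(1.0, abs=1e-12)
        assert imp[2] == 0.0

    def test_two_linear_features_share_by_slope(self):
        params = _zeroed(2)
        sub = _identity_subnet()
        params.set_subnetwork(0, SubnetworkParams(
            sub.w1, sub.b1, sub.w2, sub.b2, 2.0 * sub.w3, 0.0))  # slope 2
        params.set_subnetwork(1, sub)                            # slope 1
        X = np.random.default_rng(8).normal(size=(4000, 2))
        imp = nam_intrinsic_importance(params, _table(X))
        assert imp[0] == pytest.approx(2 / 3, abs=0.02)
        assert imp[1] == pytest.approx(1 / 3, abs=0.02)

    def test_degenerate_constant_model_warns_uniform(self):
        params = _zeroed(4)
        with pytest.warns(UserWarning, match="constant"):
            imp = nam_intrinsic_importance(
                params, _table(np.random.default_rng(9).normal(size=(5, 4))))
        np.testing.assert_allclose(imp, 0.25)

    def test_rank_order_matches_mean_abs_phi(self):
        params = init_nam(NAMConfig(hidden_sizes=(8, 4)), 5, seed=10)
        X = np.random.default_rng(10).normal(size=(60, 5))
        t = _table(X)
        intrinsic = nam_intrinsic_importance(params, t)
        attrs = additive_attributions(params, t, t)
        mean_abs = np.abs(attrs.phi).mean(axis=0)
        np.testing.assert_array_equal(np.argsort(-intrinsic),
                                      np.argsort(-mean_abs))


class TestClasswise:
    def _setup(self):
        rng = np.random.default_rng(11)
        phi = rng.normal(size=(30, 2))
        attrs = AttributionSet(phi, 0.0, phi.sum(1), np.full(30, 0.5),
                               ["a", "b"])
        labels = np.array([0, 1] * 15)
        return attrs, labels

    def test_single_class_rejected(self):
        attrs, _ = self._setup()
        with pytest.raises(ValueError, match="absent"):
            classwise_summary(attrs, np.zeros(30, dtype=int))

    def test_null_attributions_near_zero_means(self):
        rng = np.random.default_rng(12)
        phi = rng.normal(scale=0.1, size=(2000, 3))
        attrs = AttributionSet(phi, 0.0, phi.sum(1), np.full(2000, 0.5),
                               ["a", "b", "c"])
        labels = rng.integers(0, 2, size=2000)
        rep = classwise_summary(attrs, labels)
        for c in (0, 1):
            assert np.abs(rep.mean_phi[c]).max() < 0.02

    def test_rank_concordance_with_intrinsic(self):
        attrs, labels = self._setup()
        mean_abs = np.abs(attrs.phi).mean(axis=0)
        rep = classwise_summary(attrs, labels,
                                intrinsic_importance=mean_abs)
        assert rep.rank_concordance == pytest.approx(1.0)


class TestPerSampleReport:
    def _attrs(self):
        phi = np.array([[0.5, -2.0, 0.1]])
        return AttributionSet(phi, 1.0, phi.sum(1) + 1.0, np.array([0.4]),
                              ["a", "b", "c"],
                              feature_values=np.array([[10.0, 20.0, 30.0]]))

    def test_ordering_by_absolute_value(self):
        rep = per_sample_report(self._attrs(), 0)
        assert [e["phi"] for e in rep["contributions"]] == [-2.0, 0.5, 0.1]
        assert rep["contributions"][0]["feature"] == "b"
        assert rep["contributions"][0]["direction"] == "toward control"
        assert rep["contributions"][0]["value"] == 20.0

    def test_top_k_at_least_p_returns_all(self):
        rep = per_sample_report(self._attrs(), 0, top_k=10)
        assert len(rep["contributions"]) == 3

    def test_sum_check_with_base(self):
        rep = per_sample_report(self._attrs(), 0)
        total = rep["base_value"] + sum(e["phi"]
                                        for e in rep["contributions"])
        assert total == pytest.approx(rep["logit"], abs=1e-12)

    def test_truncated_listing_tracks_omitted_sum(self):
        rep = per_sample_report(self._attrs(), 0, top_k=1)
        total = (rep["base_value"] + rep["omitted_phi_sum"]
                 + sum(e["phi"] for e in rep["contributions"]))
        assert total == pytest.approx(rep["logit"], abs=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            per_sample_report(self._attrs(), 5)
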