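"""SVM decision-function and log-odds decomposition, model spec I/O, and the
scikit-learn adapter."""

import math
import warnings
from itertools import combinations

import numpy as np
import pytest

from sverad import (
    ConfigurationError,
    InvalidInputError,
    KernelParams,
    SparseBinaryVector,
    SVMModelSpec,
    UniverseMismatchError,
    UnsupportedModelError,
    exact_shapley_enumeration,
    explain_svm_distance,
    explain_svm_logodds,
    extract_model_spec,
    generate_random_vectors,
    generate_toy_svm,
    svm_distance,
)


def dense_distance(model: SVMModelSpec, x: SparseBinaryVector) -> float:
    """Independent dense-algebra evaluation of the decision function."""
    xd = x.to_dense().astype(float)
    total = model.bias
    for sv, w in zip(model.support_vectors, model.dual_weights):
        d2 = float(((xd - sv.to_dense().astype(float)) ** 2).sum())
        total += w * math.exp(-model.params.gamma * d2)
    return total


class TestModelSpec:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            SVMModelSpec(
                support_vectors=[SparseBinaryVector([0], 5)],
                dual_weights=[1.0, 2.0],
                bias=0.0,
                params=KernelParams(1.0),
            )

    def test_platt_fields_are_paired(self):
        with pytest.raises(InvalidInputError):
            SVMModelSpec(
                support_vectors=[SparseBinaryVector([0], 5)],
                dual_weights=[1.0],
                bias=0.0,
                params=KernelParams(1.0),
                platt_A=-1.0,
            )

    def test_json_round_trip_is_bit_exact(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        toy_model.to_json(path)
        back = SVMModelSpec.from_json(path)
        assert back.params.gamma == toy_model.params.gamma
        assert back.bias == toy_model.bias
        assert back.dual_weights == toy_model.dual_weights
        assert back.platt_A == toy_model.platt_A and back.platt_B == toy_model.platt_B
        assert [v.active_indices for v in back.support_vectors] == [
            v.active_indices for v in toy_model.support_vectors
        ]

    def test_toy_generator_is_seed_deterministic(self):
        a = generate_toy_svm(5, 15, seed=7)
        b = generate_toy_svm(5, 15, seed=7)
        assert a.to_dict() == b.to_dict()
        assert a.n_support == 5 and a.universe_size == 15

    def test_single_support_vector_model_is_valid(self):
        m = generate_toy_svm(1, 10, seed=0)
        assert m.n_support == 1


class TestDistance:
    def test_support_vector_equal_to_instance(self):
        sv = SparseBinaryVector([1, 3], 6)
        m = SVMModelSpec([sv], [0.7], bias=0.2, params=KernelParams(1.0))
        assert svm_distance(m, sv) == pytest.approx(0.9, abs=1e-15)

    def test_zero_weights_leave_only_bias(self):
        m = SVMModelSpec(
            [SparseBinaryVector([0], 4)], [0.0], bias=-1.3, params=KernelParams(1.0)
        )
        assert svm_distance(m, SparseBinaryVector([2], 4)) == -1.3

    def test_matches_independent_dense_evaluation(self, toy_model):
        for x in generate_random_vectors(10, toy_model.universe_size, 0.3, seed=8):
            assert svm_distance(toy_model, x) == pytest.approx(
                dense_distance(toy_model, x), abs=1e-10
            )

    def test_universe_mismatch_rejected(self, toy_model):
        with pytest.raises(UniverseMismatchError):
            svm_distance(toy_model, SparseBinaryVector([0], toy_model.universe_size + 1))


class TestExplainDistance:
    def test_single_support_vector_reduces_to_pair_explanation(self, sigma1):
        from sverad import explain_kernel_pair

        sv = SparseBinaryVector([0, 2, 3, 4], 5)
        x = SparseBinaryVector([0, 3], 5)
        m = SVMModelSpec([sv], [1.0], bias=0.0, params=sigma1)
        expl = explain_svm_distance(m, x)
        pair = explain_kernel_pair(x, sv, sigma1)
        assert expl.per_feature_distance == pytest.approx(pair.per_feature)

    def test_efficiency_identity(self, toy_model):
        for x in generate_random_vectors(20, toy_model.universe_size, 0.3, seed=13):
            e = explain_svm_distance(toy_model, x)
            assert e.attribution_sum() == pytest.approx(
                e.distance, rel=1e-8, abs=1e-8
            )

    def test_matches_oracle_composition(self):
        """phi_f equals the dual-weighted sum of enumerated pair values."""
        m = generate_toy_svm(4, 12, seed=21)
        for x in generate_random_vectors(5, 12, 0.3, seed=22):
            e = explain_svm_distance(m, x)
            composed: dict[int, float] = {}
            for sv, w in zip(m.support_vectors, m.dual_weights):
                pair = exact_shapley_enumeration(x, sv, m.params)
                for f, v in pair.per_feature.items():
                    composed[f] = composed.get(f, 0.0) + w * v
            assert set(composed) == set(e.per_feature_distance)
            for f in composed:
                assert e.per_feature_distance[f] == pytest.approx(
                    composed[f], abs=1e-9
                )

    def test_linearity_in_dual_weights(self, toy_model):
        c = 3.5
        scaled = SVMModelSpec(
            support_vectors=toy_model.support_vectors,
            dual_weights=[c * w for w in toy_model.dual_weights],
            bias=toy_model.bias,
            params=toy_model.params,
            platt_A=toy_model.platt_A,
            platt_B=toy_model.platt_B,
        )
        x = generate_random_vectors(1, toy_model.universe_size, 0.3, seed=31)[0]
        base = explain_svm_distance(toy_model, x)
        big = explain_svm_distance(scaled, x)
        assert big.bias_contribution == base.bias_contribution
        for f, v in base.per_feature_distance.items():
            assert big.per_feature_distance[f] == pytest.approx(c * v, rel=1e-12)

    def test_absent_feature_receives_nonzero_attribution(self):
        # a feature set to 0 in the instance but 1 in a support vector enters
        # the symmetric difference and generally carries a nonzero value
        sv = SparseBinaryVector([0, 1, 2], 5)
        x = SparseBinaryVector([0], 5)
        m = SVMModelSpec([sv], [1.0], bias=0.0, params=KernelParams(0.5))
        e = explain_svm_distance(m, x)
        assert 1 not in x
        assert e.per_feature_distance[1] != 0.0

    def test_degenerate_pair_flagged_and_excluded(self):
        m = SVMModelSpec(
            [SparseBinaryVector([], 5), SparseBinaryVector([0], 5)],
            [0.5, 1.0],
            bias=0.0,
            params=KernelParams(1.0),
        )
        z = SparseBinaryVector([], 5)
        e = explain_svm_distance(m, z)
        assert e.degenerate_pairs == (0,)
        # the flagged pair contributes w*1 to the distance but nothing to phi
        assert e.attribution_sum() + 0.5 == pytest.approx(e.distance, abs=1e-12)

    def test_classification_sign_preserved_through_decomposition(self, toy_model):
        for x in generate_random_vectors(20, toy_model.universe_size, 0.3, seed=17):
            e = explain_svm_distance(toy_model, x)
            direct = svm_distance(toy_model, x)
            assert (e.attribution_sum() >= 0) == (direct >= 0)


class TestLogOdds:
    def test_requires_platt_parameters(self):
        m = SVMModelSpec(
            [SparseBinaryVector([0], 4)], [1.0], bias=0.0, params=KernelParams(1.0)
        )
        with pytest.raises(ConfigurationError):
            explain_svm_logodds(m, SparseBinaryVector([1], 4))

    def test_negative_unit_slope_reduces_to_distance(self):
        m = SVMModelSpec(
            [SparseBinaryVector([0, 1], 4)],
            [1.2],
            bias=0.3,
            params=KernelParams(1.0),
            platt_A=-1.0,
            platt_B=0.0,
        )
        x = SparseBinaryVector([0, 2], 4)
        e = explain_svm_logodds(m, x)
        assert e.expected_value == pytest.approx(0.3, abs=1e-15)
        for f, v in e.per_feature_distance.items():
            assert e.per_feature_logodds[f] == pytest.approx(v, abs=1e-15)

    def test_logit_reconstruction_identities(self, toy_model):
        """expected value + per-feature logit terms = logit(p) = log(p/(1-p))."""
        worst = 0.0
        for x in generate_random_vectors(100, toy_model.universe_size, 0.3, seed=41):
            e = explain_svm_logodds(toy_model, x)
            recon = e.expected_value + sum(e.per_feature_logodds.values())
            worst = max(worst, abs(recon - e.logodds))
            from_p = math.log(e.probability / (1 - e.probability))
            assert from_p == pytest.approx(e.logodds, abs=1e-8)
        assert worst <= 1e-8


@pytest.fixture(scope="module")
def fitted():
    from sklearn.svm import SVC

    vectors = generate_random_vectors(80, 25, density=0.3, seed=5)
    X = np.array([v.to_dense() for v in vectors])
    y = (X[:, :5].sum(axis=1) >= 2).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(kernel="rbf", gamma=0.3, probability=True, random_state=0)
        clf.fit(X, y)
    return clf


class TestSklearnAdapter:
    def test_decision_function_reproduced_on_held_out_vectors(self, fitted):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            spec = extract_model_spec(fitted)
        held = generate_random_vectors(50, 25, density=0.3, seed=99)
        H = np.array([v.to_dense() for v in held])
        reference = fitted.decision_function(H)
        ours = np.array([svm_distance(spec, v) for v in held])
        assert np.abs(reference - ours).max() <= 1e-8

    def test_probability_calibrated_model_has_platt_fields(self, fitted):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            spec = extract_model_spec(fitted)
        assert spec.platt_A is not None and spec.platt_B is not None

    def test_spec_round_trips_through_json(self, fitted, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            spec = extract_model_spec(fitted)
        path = tmp_path / "extracted.json"
        spec.to_json(path)
        back = SVMModelSpec.from_json(path)
        assert back.to_dict() == spec.to_dict()

    def test_linear_kernel_rejected(self):
        from sklearn.svm import SVC

        X = np.array([[0, 1], [1, 0], [1, 1], [0, 0]])
        clf = SVC(kernel="linear").fit(X, [0, 1, 1, 0])
        with pytest.raises(UnsupportedModelError):
            extract_model_spec(clf)
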