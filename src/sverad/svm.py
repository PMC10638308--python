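"""Shapley-value decomposition of RBF-SVM predictions.

The decision function of a trained SVM,

    dist(x) = b + sum_n y_n w_n K(x, V_n),

is linear in the kernel evaluations against the support vectors V_n.  By
additivity of Shapley values, the attribution of feature f to dist(x) is the
weighted sum of f's per-pair kernel Shapley values:

    phi_f = sum_n y_n w_n phi_{f,n},

and the bias b is booked as one extra "feature" whose Shapley value is b
itself, so that  b + sum_f phi_f = dist(x)  exactly (efficiency).

When the model carries Platt calibration  p = 1 / (1 + exp(A*dist + B)),
the logit is linear in the distance, logit(p) = -A*dist - B, so log-odds
attributions are just the distance attributions scaled by -A, with the
instance-independent baseline -(A*b + B) acting as the expected value.

A feature absent from the test instance but present in support vectors
generally receives a nonzero attribution — absence is informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import exp

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidInputError,
    UniverseMismatchError,
    UnsupportedModelError,
)
from .kernel_shapley import (
    KernelParams,
    explain_kernel_pair,
    rbf_kernel_from_counts,
)
from .vectors import SparseBinaryVector, decompose_pair

__all__ = [
    "SVMModelSpec",
    "ModelExplanation",
    "svm_distance",
    "explain_svm_distance",
    "explain_svm_logodds",
    "extract_model_spec",
]


@dataclass(frozen=True)
class SVMModelSpec:
    """Everything needed to evaluate and decompose an RBF-SVM decision function.

    ``dual_weights`` store the signed products y_n * w_n (class label times
    dual coefficient) — that product is all the decision function uses, and
    fitted models expose it pre-multiplied.  Platt parameters follow the
    convention p = 1 / (1 + exp(A*dist + B)); both must be present or absent.
    """

    support_vectors: list[SparseBinaryVector]
    dual_weights: list[float]
    bias: float
    params: KernelParams
    platt_A: float | None = None
    platt_B: float | None = None

    def __post_init__(self):
        if len(self.support_vectors) < 1:
            raise InvalidInputError("a model needs at least one support vector")
        if len(self.support_vectors) != len(self.dual_weights):
            raise InvalidInputError(
                f"{len(self.support_vectors)} support vectors but "
                f"{len(self.dual_weights)} dual weights"
            )
        universes = {v.universe_size for v in self.support_vectors}
        if len(universes) != 1:
            raise InvalidInputError("support vectors must share one universe size")
        if (self.platt_A is None) != (self.platt_B is None):
            raise InvalidInputError("platt_A and platt_B must both be present or both absent")

    @property
    def universe_size(self) -> int:
        return self.support_vectors[0].universe_size

    @property
    def n_support(self) -> int:
        return len(self.support_vectors)

    @property
    def has_platt(self) -> bool:
        return self.platt_A is not None

    # -- JSON round trip ----------------------------------------------------
    # Floats serialize via repr (shortest round-trip form), so the cycle is
    # bit-exact.

    def to_dict(self) -> dict:
        d = {
            "universe_size": self.universe_size,
            "gamma": self.params.gamma,
            "bias": self.bias,
            "support_vectors": [sorted(v.active_indices) for v in self.support_vectors],
            "dual_weights": list(self.dual_weights),
        }
        if self.has_platt:
            d["platt_A"] = self.platt_A
            d["platt_B"] = self.platt_B
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModelSpec":
        try:
            universe = int(d["universe_size"])
            svs = [SparseBinaryVector(idx, universe) for idx in d["support_vectors"]]
            return cls(
                support_vectors=svs,
                dual_weights=[float(w) for w in d["dual_weights"]],
                bias=float(d["bias"]),
                params=KernelParams(gamma=float(d["gamma"])),
                platt_A=d.get("platt_A"),
                platt_B=d.get("platt_B"),
            )
        except KeyError as e:
            raise InvalidInputError(f"model spec missing field {e}") from e

    @classmethod
    def from_json(cls, source) -> "SVMModelSpec":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ModelExplanation:
    """Per-feature Shapley attribution of one SVM prediction.

    ``per_feature_distance`` covers every feature active in the instance or
    in any support vector; everything else is zero by construction and
    omitted.  ``bias_contribution`` is the bias b, booked as a feature.  With
    Platt parameters, log-odds attributions (-A * phi_f), the expected value
    -(A*b + B), the logit and the calibrated probability are populated.

    ``degenerate_pairs`` lists support-vector indices whose union with the
    instance is empty (both all-zero); those kernel evaluations contribute
    w_n * 1 to the distance but admit no per-feature attribution, so the
    efficiency identity excludes them.
    """

    per_feature_distance: dict[int, float]
    bias_contribution: float
    distance: float
    per_feature_logodds: dict[int, float] | None = None
    expected_value: float | None = None
    logodds: float | None = None
    probability: float | None = None
    degenerate_pairs: tuple[int, ...] = ()

    @property
    def predicted_class(self) -> int:
        """Sign of the decision function: 1 if dist(x) >= 0 else -1."""
        return 1 if self.distance >= 0 else -1

    def attribution_sum(self) -> float:
        return self.bias_contribution + sum(self.per_feature_distance.values())


def _check_universe(model: SVMModelSpec, x: SparseBinaryVector) -> None:
    if x.universe_size != model.universe_size:
        raise UniverseMismatchError(
            f"instance universe {x.universe_size} != model universe {model.universe_size}"
        )


def svm_distance(model: SVMModelSpec, x: SparseBinaryVector) -> float:
    """Decision-function value b + sum_n y_n w_n exp(-gamma * D_n), where D_n
    is the symmetric-difference count between x and support vector V_n."""
    _check_universe(model, x)
    total = model.bias
    for sv, w in zip(model.support_vectors, model.dual_weights):
        dec = decompose_pair(x, sv)
        total += w * rbf_kernel_from_counts(dec.D, model.params)
    return total


def explain_svm_distance(model: SVMModelSpec, x: SparseBinaryVector) -> ModelExplanation:
    """Shapley attribution of the decision-function distance.

    Per-pair values share the memoized (I, D, gamma) closed forms, so support
    vectors with the same overlap signature against x cost one evaluation.
    """
    _check_universe(model, x)
    phi: dict[int, float] = {}
    distance = model.bias
    degenerate: list[int] = []
    for n, (sv, w) in enumerate(zip(model.support_vectors, model.dual_weights)):
        pair = explain_kernel_pair(x, sv, model.params)
        distance += w * pair.kernel_value
        if pair.degenerate:
            degenerate.append(n)
            continue
        for f, value in pair.per_feature.items():
            phi[f] = phi.get(f, 0.0) + w * value
    return ModelExplanation(
        per_feature_distance=phi,
        bias_contribution=model.bias,
        distance=distance,
        degenerate_pairs=tuple(degenerate),
    )


def explain_svm_logodds(model: SVMModelSpec, x: SparseBinaryVector) -> ModelExplanation:
    """Shapley attribution of the Platt-calibrated log-odds.

    logit(p) = -A*dist - B decomposes as the expected value -(A*b + B) plus
    per-feature terms -A * phi_f.
    """
    if not model.has_platt:
        raise ConfigurationError("model has no Platt parameters; cannot express log-odds")
    base = explain_svm_distance(model, x)
    A, B = model.platt_A, model.platt_B
    logodds_map = {f: -A * v for f, v in base.per_feature_distance.items()}
    dist = base.distance
    probability = 1.0 / (1.0 + exp(A * dist + B))
    return ModelExplanation(
        per_feature_distance=base.per_feature_distance,
        bias_contribution=base.bias_contribution,
        distance=dist,
        per_feature_logodds=logodds_map,
        expected_value=-(A * base.bias_contribution + B),
        logodds=-A * dist - B,
        probability=probability,
        degenerate_pairs=base.degenerate_pairs,
    )


def extract_model_spec(trained_model) -> SVMModelSpec:
    """Adapter: pull an :class:`SVMModelSpec` out of a fitted scikit-learn
    ``SVC`` with RBF kernel on binary inputs.

    The extracted spec reproduces ``decision_function`` exactly:
    support vectors, signed dual coefficients (class label already folded
    in), intercept and the resolved gamma.  If the classifier was fitted with
    ``probability=True`` the internal sigmoid parameters are mapped onto the
    p = 1/(1 + exp(A*dist + B)) convention.  Note that the library fits its
    calibration on cross-validated decision values, and its internal sign
    handling depends on the class order seen at fit time; the extracted (A, B)
    define a self-consistent probability for the positive decision side,
    which is what the log-odds decomposition needs.
    """
    kernel = getattr(trained_model, "kernel", None)
    if kernel != "rbf":
        raise UnsupportedModelError(f"only RBF-kernel SVMs are supported, got kernel={kernel!r}")
    try:
        sv_matrix = trained_model.support_vectors_
        dual = np.asarray(trained_model.dual_coef_)
        intercept = float(np.asarray(trained_model.intercept_).ravel()[0])
        gamma = float(trained_model._gamma)
    except AttributeError as e:
        raise UnsupportedModelError(f"model is not a fitted SVC-like object: {e}") from e
    if dual.shape[0] != 1:
        raise UnsupportedModelError("only binary classification models are supported")

    if hasattr(sv_matrix, "toarray"):
        sv_matrix = sv_matrix.toarray()
    sv_matrix = np.asarray(sv_matrix)
    if not np.isin(sv_matrix, (0, 1)).all():
        raise InvalidInputError("support vectors are not binary 0/1 vectors")

    svs = [SparseBinaryVector.from_dense(row) for row in sv_matrix]
    platt_a = platt_b = None
    if getattr(trained_model, "probability", False):
        prob_a = np.asarray(trained_model.probA_).ravel()
        prob_b = np.asarray(trained_model.probB_).ravel()
        if prob_a.size:
            platt_a = float(prob_a[0])
            platt_b = float(prob_b[0])
    return SVMModelSpec(
        support_vectors=svs,
        dual_weights=dual.ravel().tolist(),
        bias=intercept,
        params=KernelParams(gamma=gamma),
        platt_A=platt_a,
        platt_B=platt_b,
    )
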