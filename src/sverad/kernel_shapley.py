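"""Exact closed-form Shapley values for a single RBF kernel evaluation.

On binary vectors the Gaussian RBF kernel K(x, x') = exp(-gamma * ||x - x'||^2)
reduces to exp(-gamma * D), where D counts the features active in exactly one
of the two vectors (the symmetric difference).  Viewing one kernel evaluation
as a cooperative game whose players are the U = I + D features active in
either vector (I of them intersecting), with coalition value
v(S) = exp(-gamma * N_d(S)) for nonempty S and v(empty) = 0, the Shapley
values collapse to two scalars:

* every intersecting feature receives  1 / (I + D)  — the only nonzero
  marginal contribution of an intersecting feature is its addition to the
  empty coalition, which lifts the kernel value from 0 to 1;
* every symmetric-difference feature receives a three-term sum over
  coalition count classes (empty coalition / intersecting-only coalitions /
  mixed coalitions), evaluated here in log space.

Efficiency holds by construction: I * phi_plus + D * phi_minus = exp(-gamma*D).

Features active in neither vector are dummy players and are never
materialized; their Shapley value is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, exp, expm1, lgamma, log

from .errors import InvalidInputError
from .vectors import SparseBinaryVector, decompose_pair

__all__ = [
    "KernelParams",
    "PairExplanation",
    "rbf_kernel_from_counts",
    "phi_intersecting",
    "phi_symmetric_difference",
    "log_coalition_weight",
    "explain_kernel_pair",
    "coalition_table",
]


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel width parameter.

    gamma = 1 / (2 * sigma^2); either parameterization may be supplied but
    only gamma is stored.
    """

    gamma: float

    def __post_init__(self):
        if not self.gamma > 0:
            raise InvalidInputError(f"gamma must be positive, got {self.gamma}")

    @classmethod
    def from_sigma(cls, sigma: float) -> "KernelParams":
        if not sigma > 0:
            raise InvalidInputError(f"sigma must be positive, got {sigma}")
        return cls(gamma=1.0 / (2.0 * sigma * sigma))


@dataclass(frozen=True)
class PairExplanation:
    """Per-feature Shapley values for one kernel evaluation K(x, y).

    All intersecting features share ``phi_intersecting`` and all
    symmetric-difference features share ``phi_sym_difference`` (feature
    exchangeability within each class is structural).  ``per_feature`` maps
    every union feature index to its value; features active in neither vector
    are absent (implicitly zero).  If the union is nonempty the values sum to
    ``kernel_value``.

    ``degenerate`` flags the I + D = 0 pair of two all-zero vectors: the
    kernel value is 1 but the game has no players, so no attribution exists
    and ``per_feature`` is empty.
    """

    phi_intersecting: float | None
    phi_sym_difference: float | None
    per_feature: dict[int, float]
    kernel_value: float
    I: int
    D: int
    degenerate: bool = False


def rbf_kernel_from_counts(D: int, params: KernelParams) -> float:
    """RBF kernel value between two binary vectors with symmetric-difference
    count ``D``: exp(-gamma * D).  Intersecting and jointly-absent features do
    not enter the Euclidean distance."""
    if D < 0:
        raise InvalidInputError(f"D must be >= 0, got {D}")
    return exp(-params.gamma * D)


def phi_intersecting(I: int, D: int) -> float:
    """Shapley value of one intersecting feature: (I+D-1)!/(I+D)! = 1/(I+D).

    Independent of gamma: adding an intersecting feature never changes the
    distance, so its only nonzero marginal contribution is the jump from
    v(empty) = 0 to v({f}) = 1.
    """
    if I < 1:
        raise InvalidInputError("no intersecting feature exists when I = 0")
    if D < 0:
        raise InvalidInputError(f"D must be >= 0, got {D}")
    return 1.0 / (I + D)


@lru_cache(maxsize=1 << 18)
def _phi_symdiff_cached(I: int, D: int, gamma: float) -> float:
    n = I + D
    # log-factorial table; keeps every summand in log space so nothing
    # overflows even at fingerprint-scale I, D
    lgf = [lgamma(k + 1.0) for k in range(n + 1)]

    # (a) addition to the empty coalition: v jumps 0 -> exp(-gamma)
    total = exp(-gamma) / n

    # (b) additions to intersecting-only coalitions: v jumps 1 -> exp(-gamma)
    #     sum over N_i of C(I, N_i) * N_i! (I+D-N_i-1)!/(I+D)!  =  I!/(I-N_i)! * .../...
    s = 0.0
    for n_i in range(1, I + 1):
        s += exp(lgf[I] - lgf[I - n_i] + lgf[n - n_i - 1] - lgf[n])
    total += expm1(-gamma) * s  # expm1(-gamma) = exp(-gamma) - 1 < 0

    # (c) mixed coalitions (N_d >= 1): v jumps exp(-g*N_d) -> exp(-g*(N_d+1))
    if D >= 2:
        log_neg_dv0 = log(-expm1(-gamma))  # log(1 - exp(-gamma))
        for n_d in range(1, D):
            log_neg_dv = log_neg_dv0 - gamma * n_d
            row = 0.0
            for n_i in range(0, I + 1):
                logw = (
                    lgf[I] - lgf[I - n_i] - lgf[n_i]
                    + lgf[D - 1] - lgf[D - 1 - n_d] - lgf[n_d]
                    + lgf[n_i + n_d] + lgf[n - n_i - n_d - 1] - lgf[n]
                )
                row += exp(logw)
            total -= exp(log_neg_dv) * row
    return total


def phi_symmetric_difference(I: int, D: int, params: KernelParams) -> float:
    """Shapley value of one symmetric-difference feature for K between binary
    vectors with intersection count ``I`` and symmetric-difference count ``D``.

    Evaluates the exact three-term grouping of the coalition sum — the empty
    coalition, intersecting-only coalitions, and mixed coalitions — at
    O(D * (I + 1)) cost.  Results are memoized on (I, D, gamma).
    """
    if D < 1:
        raise InvalidInputError("no symmetric-difference feature exists when D = 0")
    if I < 0:
        raise InvalidInputError(f"I must be >= 0, got {I}")
    return _phi_symdiff_cached(I, D, params.gamma)


def log_coalition_weight(
    N_i: int, N_d: int, I: int, D: int, assessed_from_intersection: bool
) -> float:
    """Natural log of (#coalitions) x (inverse multinomial coefficient) for a
    coalition count class (N_i, N_d) when assessing one feature.

    The count of coalitions is C(I-1, N_i)*C(D, N_d) when the assessed feature
    is intersecting and C(I, N_i)*C(D-1, N_d) when it is in the symmetric
    difference; the Shapley permutation weight is
    (N_i+N_d)! (I+D-N_i-N_d-1)! / (I+D)!.  Everything is evaluated through
    log-gamma, so the result is finite for union sizes well beyond 1e5.
    """
    if assessed_from_intersection:
        i_max, d_max = I - 1, D
    else:
        i_max, d_max = I, D - 1
    if not (0 <= N_i <= i_max and 0 <= N_d <= d_max):
        raise InvalidInputError(
            f"coalition counts (N_i={N_i}, N_d={N_d}) out of range for "
            f"I={I}, D={D}, from_intersection={assessed_from_intersection}"
        )

    def lbinom(m: int, k: int) -> float:
        return lgamma(m + 1.0) - lgamma(k + 1.0) - lgamma(m - k + 1.0)

    n = I + D
    log_count = lbinom(i_max, N_i) + lbinom(d_max, N_d)
    log_weight = (
        lgamma(N_i + N_d + 1.0) + lgamma(n - N_i - N_d + 0.0) - lgamma(n + 1.0)
    )
    return log_count + log_weight


def explain_kernel_pair(
    x: SparseBinaryVector, y: SparseBinaryVector, params: KernelParams
) -> PairExplanation:
    """Exact Shapley values of every union feature for K(x, y).

    Intersecting features each get ``phi_intersecting(I, D)``; symmetric-
    difference features each get ``phi_symmetric_difference(I, D, gamma)``.
    The values sum to the kernel value exp(-gamma * D) whenever I + D > 0.
    """
    dec = decompose_pair(x, y)
    I, D = dec.I, dec.D
    kernel = rbf_kernel_from_counts(D, params)
    if I + D == 0:
        return PairExplanation(None, None, {}, kernel, 0, 0, degenerate=True)
    phi_i = phi_intersecting(I, D) if I else None
    phi_d = phi_symmetric_difference(I, D, params) if D else None
    per_feature: dict[int, float] = {}
    for f in dec.intersection:
        per_feature[f] = phi_i
    for f in dec.sym_difference:
        per_feature[f] = phi_d
    return PairExplanation(phi_i, phi_d, per_feature, kernel, I, D)


def coalition_table(
    I: int, D: int, params: KernelParams, assessed_from_intersection: bool
) -> list[dict]:
    """Worked-example breakdown of one feature's Shapley value by coalition
    count class.

    Returns one row per admissible (N_i, N_d) with the coalition value before
    and after adding the assessed feature, the marginal contribution delta_v,
    the number of coalitions in the class, the inverse multinomial weight and
    the row product.  The products sum to the feature's Shapley value; this is
    the table the CLI prints under ``--show-work``.
    """
    g = params.gamma
    if assessed_from_intersection:
        if I < 1:
            raise InvalidInputError("no intersecting feature to assess")
        i_max, d_max = I - 1, D
    else:
        if D < 1:
            raise InvalidInputError("no symmetric-difference feature to assess")
        i_max, d_max = I, D - 1
    n = I + D
    rows = []
    for n_i in range(i_max + 1):
        for n_d in range(d_max + 1):
            v_s = 0.0 if (n_i + n_d) == 0 else exp(-g * n_d)
            nd_after = n_d if assessed_from_intersection else n_d + 1
            v_sf = exp(-g * nd_after)
            delta_v = v_sf - v_s
            count = (
                comb(i_max, n_i) * comb(d_max, n_d)
            )
            size = n_i + n_d
            weight = exp(lgamma(size + 1.0) + lgamma(n - size + 0.0) - lgamma(n + 1.0))
            rows.append(
                {
                    "N_i": n_i,
                    "N_d": n_d,
                    "v_S": v_s,
                    "v_S_plus_f": v_sf,
                    "delta_v": delta_v,
                    "n_coalitions": count,
                    "weight": weight,
                    "product": delta_v * count * weight,
                }
            )
    return rows
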