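"""Self-contained agreement check: closed forms vs exhaustive enumeration.

Regenerates the desk-scale validation experiment — random binary vectors
over a small universe, per-feature Shapley values for every pair computed
both by the closed forms and by explicit coalition enumeration — and reports
the maximum absolute deviation and the Pearson correlation between the two
routes.  The closed forms pass when the deviation stays below 1e-10 and the
correlation is (numerically) exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .exhaustive import exact_shapley_enumeration
from .generate import DEFAULT_DENSITY, generate_random_vectors
from .kernel_shapley import KernelParams, explain_kernel_pair

__all__ = ["ValidationResult", "run_validation", "DEVIATION_LIMIT"]

DEVIATION_LIMIT = 1e-10


@dataclass(frozen=True)
class ValidationResult:
    n_vectors: int
    universe_size: int
    gamma: float
    seed: int
    n_pairs: int
    n_values: int
    max_abs_deviation: float
    pearson_r: float

    @property
    def passed(self) -> bool:
        return self.max_abs_deviation < DEVIATION_LIMIT

    def summary(self) -> str:
        return (
            f"pairs={self.n_pairs} paired_values={self.n_values} "
            f"max_abs_deviation={self.max_abs_deviation:.3e} "
            f"pearson_r={self.pearson_r:.12g} "
            f"{'PASS' if self.passed else 'FAIL'}"
        )


def run_validation(
    n_vectors: int = 20,
    universe_size: int = 15,
    gamma: float = 1.0,
    seed: int = 0,
    density: float = DEFAULT_DENSITY,
    method: str = "counts",
) -> ValidationResult:
    """Compare closed-form and enumerated Shapley values over all vector pairs.

    Degenerate pairs (both vectors all-zero) contribute no values; identical
    nonzero vectors contribute their uniform 1/I values through both routes.
    """
    params = KernelParams(gamma=gamma)
    vectors = generate_random_vectors(n_vectors, universe_size, density, seed)
    closed: list[float] = []
    enumerated: list[float] = []
    n_pairs = 0
    for x, y in combinations(vectors, 2):
        n_pairs += 1
        a = explain_kernel_pair(x, y, params)
        b = exact_shapley_enumeration(x, y, params, max_union=universe_size, method=method)
        assert a.per_feature.keys() == b.per_feature.keys()
        for f in sorted(a.per_feature):
            closed.append(a.per_feature[f])
            enumerated.append(b.per_feature[f])
    closed_arr = np.array(closed)
    enum_arr = np.array(enumerated)
    max_dev = float(np.max(np.abs(closed_arr - enum_arr))) if closed else 0.0
    r = float(stats.pearsonr(closed_arr, enum_arr).statistic) if len(closed) > 1 else float("nan")
    return ValidationResult(
        n_vectors=n_vectors,
        universe_size=universe_size,
        gamma=gamma,
        seed=seed,
        n_pairs=n_pairs,
        n_values=len(closed),
        max_abs_deviation=max_dev,
        pearson_r=r,
    )
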