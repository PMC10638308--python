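"""Deterministic synthetic generators for vectors and toy SVM models.

The generators exist so the whole validation pipeline — closed forms against
exhaustive enumeration, SVM decomposition against direct evaluation — runs
from scratch with no external data.  Bits are independent Bernoulli draws
(no feature correlation); a fixed seed reproduces identical output across
processes.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .kernel_shapley import KernelParams
from .vectors import SparseBinaryVector

__all__ = ["generate_random_vectors", "generate_toy_svm", "DEFAULT_DENSITY"]

# Bit density of the random validation vectors.  The exhaustive-validation
# experiment only needs "random binary vectors with a small number of
# features"; 0.3 gives unions spanning the full range 0..15 at |F| = 15 while
# keeping vectors sparse, as fingerprints are.
DEFAULT_DENSITY = 0.3


def generate_random_vectors(
    n: int, universe_size: int, density: float = DEFAULT_DENSITY, seed: int = 0
) -> list[SparseBinaryVector]:
    """Draw ``n`` random binary vectors; each bit active independently with
    probability ``density``."""
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if universe_size < 1:
        raise InvalidInputError(f"universe_size must be >= 1, got {universe_size}")
    if not 0.0 < density <= 1.0:
        raise InvalidInputError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    bits = rng.random((n, universe_size)) < density
    return [
        SparseBinaryVector(np.flatnonzero(row).tolist(), universe_size) for row in bits
    ]


def generate_toy_svm(
    n_support: int,
    universe_size: int,
    seed: int = 0,
    density: float = DEFAULT_DENSITY,
    gamma: float | None = None,
):
    """Random but structurally valid RBF-SVM model specification.

    Support vectors are random sparse binary vectors (redrawn if all-zero, so
    toy models avoid the degenerate empty-pair case), dual weights are signed
    uniforms in [-2, -0.1] u [0.1, 2], the bias is uniform in [-1, 1] and
    Platt parameters (A < 0, as fitted calibrations on a working classifier
    come out) are always populated.  Reproducible per seed.
    """
    from .svm import SVMModelSpec  # deferred: svm imports KernelParams from here

    if n_support < 1:
        raise InvalidInputError(f"n_support must be >= 1, got {n_support}")
    rng = np.random.default_rng(seed)
    svs = []
    while len(svs) < n_support:
        row = np.flatnonzero(rng.random(universe_size) < density)
        if row.size:
            svs.append(SparseBinaryVector(row.tolist(), universe_size))
    magnitudes = rng.uniform(0.1, 2.0, n_support)
    signs = rng.choice([-1.0, 1.0], n_support)
    weights = (magnitudes * signs).tolist()
    bias = float(rng.uniform(-1.0, 1.0))
    if gamma is None:
        gamma = float(rng.uniform(0.05, 1.0))
    platt_a = float(-rng.uniform(0.5, 2.0))
    platt_b = float(rng.uniform(-0.5, 0.5))
    return SVMModelSpec(
        support_vectors=svs,
        dual_weights=weights,
        bias=bias,
        params=KernelParams(gamma=gamma),
        platt_A=platt_a,
        platt_B=platt_b,
    )
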