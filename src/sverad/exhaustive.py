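"""Brute-force Shapley values by explicit coalition enumeration.

This module exists to validate the closed forms in
:mod:`sverad.kernel_shapley`: at small union sizes the Shapley value of each
feature is recomputed directly from its definition,

    phi_f = sum over S subset of U \\ {f} of |S|!(n-|S|-1)!/n! * (v(S u f) - v(S)),

with v(S) = exp(-gamma * N_d(S)) for nonempty S and v(empty) = 0.  Two
enumeration routes are provided: a count-class mode that exploits the fact
that v depends only on the number of symmetric-difference players in S
(coalitions are grouped by (N_i, N_d) with multiplicity), and a literal
subset-by-subset bitmask mode for paranoid cross-checking at n <= 15.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, lgamma
from typing import Callable

from .errors import CapacityError, InvalidInputError
from .kernel_shapley import KernelParams, PairExplanation, rbf_kernel_from_counts
from .vectors import SparseBinaryVector, decompose_pair

__all__ = ["CoalitionGame", "shapley_weight", "exact_shapley_enumeration"]

DEFAULT_MAX_UNION = 20
BITMASK_MAX_UNION = 15


@dataclass(frozen=True)
class CoalitionGame:
    """The cooperative game of one kernel evaluation.

    Players are the union features of a vector pair, each labelled
    intersecting or symmetric-difference; the value of a coalition depends
    only on how many symmetric-difference players it contains.
    """

    intersecting_players: tuple[int, ...]
    sym_difference_players: tuple[int, ...]
    params: KernelParams

    @property
    def n_players(self) -> int:
        return len(self.intersecting_players) + len(self.sym_difference_players)

    def value(self, n_d_in_coalition: int, coalition_size: int) -> float:
        """v(S): zero for the empty coalition, else exp(-gamma * N_d)."""
        if coalition_size == 0:
            return 0.0
        return exp(-self.params.gamma * n_d_in_coalition)

    def grand_value(self) -> float:
        return rbf_kernel_from_counts(len(self.sym_difference_players), self.params)


def shapley_weight(set_size: int, n_players: int) -> float:
    """Shapley permutation weight |S|!(n-|S|-1)!/n! evaluated via log-gamma."""
    if not 0 <= set_size <= n_players - 1:
        raise InvalidInputError(
            f"set_size must be in [0, n_players-1], got {set_size} with n={n_players}"
        )
    return exp(
        lgamma(set_size + 1.0)
        + lgamma(n_players - set_size + 0.0)
        - lgamma(n_players + 1.0)
    )


def _enumerate_by_counts(game: CoalitionGame) -> tuple[float, float]:
    """Enumerated (phi_intersecting, phi_sym_difference) by (N_i, N_d) class.

    Grouping subsets by their composition is exact because v(S) depends only
    on N_d(S); each class carries multiplicity C(I', N_i) * C(D', N_d).
    """
    I = len(game.intersecting_players)
    D = len(game.sym_difference_players)
    n = game.n_players
    g = game.params.gamma

    def enumerate_for(from_intersection: bool) -> float:
        i_max, d_max = (I - 1, D) if from_intersection else (I, D - 1)
        total = 0.0
        for n_i in range(i_max + 1):
            for n_d in range(d_max + 1):
                size = n_i + n_d
                v_s = game.value(n_d, size)
                nd_after = n_d if from_intersection else n_d + 1
                v_sf = exp(-g * nd_after)
                mult = comb(i_max, n_i) * comb(d_max, n_d)
                total += mult * shapley_weight(size, n) * (v_sf - v_s)
        return total

    phi_i = enumerate_for(True) if I else None
    phi_d = enumerate_for(False) if D else None
    return phi_i, phi_d


def _enumerate_by_bitmask(game: CoalitionGame) -> tuple[float, float]:
    """Literal subset enumeration over bitmasks; exponential, n <= 15 only."""
    I = len(game.intersecting_players)
    D = len(game.sym_difference_players)
    n = game.n_players
    g = game.params.gamma
    # players 0..I-1 intersecting, I..n-1 symmetric difference
    symdiff_mask = ((1 << D) - 1) << I

    def value(mask: int) -> float:
        if mask == 0:
            return 0.0
        return exp(-g * (mask & symdiff_mask).bit_count())

    def phi_for(player: int) -> float:
        others = [p for p in range(n) if p != player]
        total = 0.0
        for sub in range(1 << (n - 1)):
            mask = 0
            for bit, p in enumerate(others):
                if sub >> bit & 1:
                    mask |= 1 << p
            size = mask.bit_count()
            total += shapley_weight(size, n) * (value(mask | (1 << player)) - value(mask))
        return total

    phi_i = phi_for(0) if I else None
    phi_d = phi_for(I) if D else None
    return phi_i, phi_d


def exact_shapley_enumeration(
    x: SparseBinaryVector,
    y: SparseBinaryVector,
    params: KernelParams,
    max_union: int | None = None,
    method: str = "counts",
) -> PairExplanation:
    """Shapley values of K(x, y) by brute-force coalition enumeration.

    ``method`` is ``"counts"`` (group coalitions by composition, default
    union-size guard 20) or ``"bitmask"`` (every subset individually, guard
    15).  Refuses larger unions with :class:`CapacityError` — the bitmask
    route is exponential and the count-class route is only meant for
    validation at small sizes.
    """
    if method not in ("counts", "bitmask"):
        raise InvalidInputError(f"unknown enumeration method {method!r}")
    if max_union is None:
        max_union = DEFAULT_MAX_UNION if method == "counts" else BITMASK_MAX_UNION
    dec = decompose_pair(x, y)
    n = dec.union_size
    if n > max_union:
        raise CapacityError(
            f"union size {n} exceeds the enumeration guard {max_union}"
        )
    kernel = rbf_kernel_from_counts(dec.D, params)
    if n == 0:
        return PairExplanation(None, None, {}, kernel, 0, 0, degenerate=True)

    game = CoalitionGame(
        intersecting_players=tuple(sorted(dec.intersection)),
        sym_difference_players=tuple(sorted(dec.sym_difference)),
        params=params,
    )
    enumerate_fn: Callable = (
        _enumerate_by_counts if method == "counts" else _enumerate_by_bitmask
    )
    phi_i, phi_d = enumerate_fn(game)
    per_feature: dict[int, float] = {}
    for f in dec.intersection:
        per_feature[f] = phi_i
    for f in dec.sym_difference:
        per_feature[f] = phi_d
    return PairExplanation(phi_i, phi_d, per_feature, kernel, dec.I, dec.D)
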