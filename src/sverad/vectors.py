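"""Sparse binary feature vectors and pairwise set decomposition.

A molecular fingerprint (or any binary feature row) is stored as the set of
active (bit = 1) positions inside a fixed universe of ``universe_size``
features.  All downstream Shapley computations depend on a pair of vectors
only through the sizes of the intersection (``I``) and the symmetric
difference (``D``) of their active sets, so the sparse representation is the
natural one: the union ``U = I + D`` is typically far smaller than the
universe.

Feature indices are 0-based everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, UniverseMismatchError

__all__ = [
    "SparseBinaryVector",
    "PairDecomposition",
    "decompose_pair",
    "read_vectors",
    "write_vectors",
]


@dataclass(frozen=True)
class SparseBinaryVector:
    """A binary vector represented by its set of active feature indices.

    Parameters
    ----------
    active_indices
        Feature positions set to 1.  Stored as a ``frozenset``; duplicates
        in the input collapse silently (set semantics).
    universe_size
        Total number of binary features (the fingerprint length |F|).
    """

    active_indices: frozenset[int]
    universe_size: int

    def __init__(self, active_indices: Iterable[int], universe_size: int):
        object.__setattr__(self, "active_indices", frozenset(int(i) for i in active_indices))
        object.__setattr__(self, "universe_size", int(universe_size))
        if self.universe_size < 1:
            raise InvalidInputError(f"universe_size must be >= 1, got {universe_size}")
        for i in self.active_indices:
            if i < 0 or i >= self.universe_size:
                raise InvalidInputError(
                    f"feature index {i} outside universe [0, {self.universe_size})"
                )

    @classmethod
    def from_dense(cls, row: Sequence[int] | np.ndarray) -> "SparseBinaryVector":
        """Build from a dense 0/1 row; any nonzero entry must be exactly 1."""
        arr = np.asarray(row)
        if arr.ndim != 1:
            raise InvalidInputError("dense row must be one-dimensional")
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            raise InvalidInputError(f"dense row contains non-binary value {arr[bad][0]!r}")
        return cls(np.flatnonzero(arr).tolist(), arr.size)

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.universe_size, dtype=np.int8)
        if self.active_indices:
            out[sorted(self.active_indices)] = 1
        return out

    @property
    def n_active(self) -> int:
        return len(self.active_indices)

    def __contains__(self, index: int) -> bool:
        return index in self.active_indices


@dataclass(frozen=True)
class PairDecomposition:
    """Partition of the union of two binary vectors' active features.

    ``intersection`` holds indices active in both vectors, ``sym_difference``
    indices active in exactly one.  Indices active in neither vector appear in
    neither set — they never enter the Shapley game of a kernel evaluation.
    """

    intersection: frozenset[int]
    sym_difference: frozenset[int]
    I: int = field(init=False)
    D: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "I", len(self.intersection))
        object.__setattr__(self, "D", len(self.sym_difference))

    @property
    def union_size(self) -> int:
        """U = I + D, the number of players in the pair's coalition game."""
        return self.I + self.D


def decompose_pair(x: SparseBinaryVector, y: SparseBinaryVector) -> PairDecomposition:
    """Split the union of active features of ``x`` and ``y`` into the
    intersecting set (count ``I``) and the symmetric-difference set (count ``D``).

    Raises
    ------
    UniverseMismatchError
        If the two vectors declare different universe sizes.
    """
    if x.universe_size != y.universe_size:
        raise UniverseMismatchError(
            f"universe sizes differ: {x.universe_size} vs {y.universe_size}"
        )
    a, b = x.active_indices, y.active_indices
    return PairDecomposition(intersection=a & b, sym_difference=a ^ b)


# ---------------------------------------------------------------------------
# Text I/O
#
# Sparse format: optional comment lines, a header `#universe_size=<int>`,
# then one vector per line as whitespace- or comma-separated active indices
# (an empty line = the all-zero vector).
# Dense format: delimited 0/1 rows, no header; every row the same length.
# ---------------------------------------------------------------------------

_HEADER = "#universe_size="


def _tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_vectors(path, fmt: str = "auto") -> list[SparseBinaryVector]:
    """Read binary vectors from a text file.

    ``fmt`` is ``"sparse"``, ``"dense"`` or ``"auto"`` (sparse iff a
    ``#universe_size=`` header is present).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()

    universe = None
    body: list[str] = []
    for line in raw:
        stripped = line.strip()
        if stripped.startswith(_HEADER):
            universe = int(stripped[len(_HEADER):])
        elif stripped.startswith("#"):
            continue
        else:
            body.append(line)

    if fmt == "auto":
        fmt = "sparse" if universe is not None else "dense"

    if fmt == "sparse":
        if universe is None:
            raise InvalidInputError(f"sparse vector file {path} lacks a {_HEADER}<int> header")
        return [SparseBinaryVector(_tokens(line), universe) for line in body]
    if fmt == "dense":
        rows = [np.array([int(t) for t in _tokens(line)]) for line in body if line.strip() != ""]
        if not rows:
            raise InvalidInputError(f"no vectors found in {path}")
        widths = {r.size for r in rows}
        if len(widths) != 1:
            raise InvalidInputError(f"dense rows in {path} have unequal lengths {sorted(widths)}")
        return [SparseBinaryVector.from_dense(r) for r in rows]
    raise InvalidInputError(f"unknown vector format {fmt!r}")


def write_vectors(path, vectors: Sequence[SparseBinaryVector]) -> None:
    """Write vectors in the sparse text format (shared universe required)."""
    universes = {v.universe_size for v in vectors}
    if len(universes) != 1:
        raise InvalidInputError("vectors to write must share one universe size")
    with open(path, "w") as fh:
        fh.write(f"{_HEADER}{universes.pop()}\n")
        for v in vectors:
            fh.write(" ".join(str(i) for i in sorted(v.active_indices)) + "\n")
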