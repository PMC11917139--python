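"""Amino-acid distance matrices and their conversion to similarity scores.

Residue-level comparison is done in physicochemical space: a 20x20
distance matrix D' (Grantham by default, any symmetric non-negative
matrix accepted) is rescaled to a similarity matrix D in [0, 1] with
identity mapped to 1 and the most dissimilar pair mapped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._grantham import GRANTHAM_ORDER, GRANTHAM_PAIRS

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
NONCANONICAL_RESIDUES = set("BZXUOJ")


class MatrixValidationError(ValueError):
    """Raised when a distance matrix violates a structural invariant."""


@dataclass(frozen=True)
class DistanceMatrix:
    """A labeled, symmetric, non-negative 20x20 amino-acid distance table."""

    labels: tuple[str, ...]
    values: np.ndarray
    name: str = "grantham"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _validate_distance(self.labels, values, self.name)
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.labels)}
        )

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


@dataclass(frozen=True)
class SimilarityMatrix:
    """Per-residue similarity D in [0, 1]; diagonal exactly 1."""

    labels: tuple[str, ...]
    values: np.ndarray
    name: str = "grantham"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.labels),) * 2:
            raise MatrixValidationError("similarity matrix shape mismatch")
        if not np.allclose(values, values.T):
            raise MatrixValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0):
            raise MatrixValidationError("similarity diagonal must be 1")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise MatrixValidationError("similarity entries must lie in [0, 1]")
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(self.labels)}
        )

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def index_of(self, a: str) -> int:
        return self._index[a]


def _validate_distance(
    labels: Sequence[str], values: np.ndarray, name: str
) -> None:
    if sorted(labels) != sorted(CANONICAL_RESIDUES):
        extra = set(labels) - set(CANONICAL_RESIDUES)
        missing = set(CANONICAL_RESIDUES) - set(labels)
        raise MatrixValidationError(
            f"matrix '{name}' must cover exactly the 20 canonical residues; "
            f"extra={sorted(extra)} missing={sorted(missing)}"
        )
    if values.shape != (20, 20):
        raise MatrixValidationError(
            f"matrix '{name}' must be 20x20, got {values.shape}"
        )
    for i, a in enumerate(labels):
        if values[i, i] != 0:
            raise MatrixValidationError(
                f"matrix '{name}': diagonal entry ({a},{a}) is "
                f"{values[i, i]}, expected 0"
            )
        for j, b in enumerate(labels):
            if values[i, j] < 0:
                raise MatrixValidationError(
                    f"matrix '{name}': negative entry at ({a},{b})"
                )
            if values[i, j] != values[j, i]:
                raise MatrixValidationError(
                    f"matrix '{name}': asymmetric at ({a},{b}): "
                    f"{values[i, j]} != {values[j, i]}"
                )


def grantham_matrix() -> DistanceMatrix:
    """The bundled Grantham (1974) distance matrix."""
    labels = tuple(GRANTHAM_ORDER)
    index = {aa: i for i, aa in enumerate(labels)}
    values = np.zeros((20, 20))
    for (a, b), d in GRANTHAM_PAIRS.items():
        values[index[a], index[b]] = d
        values[index[b], index[a]] = d
    return DistanceMatrix(labels=labels, values=values, name="grantham")


def load_distance_matrix(source: str | Path) -> DistanceMatrix:
    """Load a distance matrix by built-in name or from a labeled table.

    Files are whitespace- or tab-delimited square tables whose first row
    and first column carry the residue one-letter codes.
    """
    if isinstance(source, str) and source.lower() == "grantham":
        return grantham_matrix()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"no bundled matrix or file named '{source}'"
        )
    table = pd.read_csv(path, sep=r"\s+", index_col=0)
    labels = tuple(str(c) for c in table.index)
    if tuple(str(c) for c in table.columns) != labels:
        raise MatrixValidationError(
            f"matrix '{path.name}': row labels differ from column labels"
        )
    return DistanceMatrix(
        labels=labels, values=table.to_numpy(dtype=float), name=path.stem
    )


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Default distance-to-similarity map: D = 1 - D'/max(D')."""
    vmax = values.max()
    if vmax == 0:
        raise MatrixValidationError("degenerate distance matrix (all zero)")
    return 1.0 - values / vmax


def distance_to_similarity(
    dm: DistanceMatrix,
    normalize: Callable[[np.ndarray], np.ndarray] = minmax_normalize,
) -> SimilarityMatrix:
    """Convert distances to similarities in [0, 1].

    The normalization is pluggable; the default min-max form maps zero
    distance (identity) to 1 and the table maximum to 0 and preserves
    the reverse ranking of all residue pairs.
    """
    return SimilarityMatrix(
        labels=dm.labels, values=normalize(dm.values), name=dm.name
    )


def check_canonical(sequence: str) -> str | None:
    """Return the first non-canonical residue in ``sequence``, if any."""
    for ch in sequence:
        if ch not in CANONICAL_RESIDUES:
            return ch
    return None
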