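"""Labelled symmetric distance matrices.

The diagonal can carry either zeros (specimen-level matrices) or the
within-unit divergence printed by unit-level summary tables, where a
missing diagonal cell marks a singleton unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError

#: allowed diagonal semantics
DIAG_ZERO = "zero"
DIAG_WITHIN = "within"

_SYM_TOL = 1e-9


@dataclass
class LabelledMatrix:
    labels: list[str]
    values: np.ndarray  # square float array, NaN = missing
    diagonal_semantics: str = DIAG_ZERO

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in matrix")
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} labels")
        if self.diagonal_semantics not in (DIAG_ZERO, DIAG_WITHIN):
            raise FormatError(
                f"unknown diagonal semantics {self.diagonal_semantics!r}")
        off = ~np.eye(n, dtype=bool)
        if np.isnan(self.values[off]).any():
            raise FormatError("missing values allowed only on the diagonal")
        with np.errstate(invalid="ignore"):
            if (self.values < 0).any():
                raise FormatError("negative distance values")
        if not np.allclose(self.values, self.values.T,
                           atol=_SYM_TOL, equal_nan=True):
            raise FormatError("matrix is asymmetric beyond tolerance 1e-9")

    # -- access ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def value(self, a: str, b: str) -> float:
        """Cell value; NaN for a missing diagonal entry."""
        return float(self.values[self.index(a), self.index(b)])

    def diagonal(self, label: str) -> float:
        i = self.index(label)
        return float(self.values[i, i])

    def is_missing(self, a: str, b: str) -> bool:
        return bool(np.isnan(self.values[self.index(a), self.index(b)]))

    # -- manipulation ---------------------------------------------------
    def rename(self, mapping: dict[str, str]) -> "LabelledMatrix":
        return LabelledMatrix([mapping.get(l, l) for l in self.labels],
                              self.values.copy(), self.diagonal_semantics)

    def submatrix(self, labels: list[str]) -> "LabelledMatrix":
        idx = [self.index(l) for l in labels]
        return LabelledMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.diagonal_semantics)

    def offdiagonal_values(self) -> np.ndarray:
        """Upper-triangle off-diagonal values (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]
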