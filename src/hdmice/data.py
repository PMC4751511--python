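"""Core containers for incomplete data and chained-equation state.

An :class:`IncompleteMatrix` holds an ``n x p`` numeric table ``Z`` together
with an observedness mask.  Columns with any missing cell are the targets of
the chained-equations cycle; their observed counts ``r_j`` drive the
degrees-of-freedom bookkeeping in the imputers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ColumnEntirelyMissingError(ValueError):
    """A column has no observed value, so it cannot be initialized."""


@dataclass
class IncompleteMatrix:
    """An ``n x p`` real matrix with missing cells flagged by a mask.

    Parameters
    ----------
    values
        The data, with ``np.nan`` in missing cells.
    mask
        Boolean array, same shape as ``values``; ``True`` marks an observed
        cell.  If omitted it is derived from ``~isnan(values)``.
    column_names
        Optional identifiers, one per column.
    """

    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    column_names: Sequence[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values must have identical shape")
        if self.column_names is None:
            self.column_names = [f"z{k + 1}" for k in range(self.values.shape[1])]
        else:
            self.column_names = list(self.column_names)
            if len(self.column_names) != self.values.shape[1]:
                raise ValueError("one column name per column required")
        # observed cells must be finite; missing cells are normalized to nan
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def r(self) -> np.ndarray:
        """Per-column observed counts ``r_j``."""
        return self.mask.sum(axis=0)

    @property
    def incomplete_columns(self) -> list[int]:
        """Indices of columns with at least one missing cell, ascending."""
        r = self.r
        return [j for j in range(self.p) if r[j] < self.n]

    def check_initializable(self) -> None:
        r = self.r
        for j in self.incomplete_columns:
            if r[j] == 0:
                raise ColumnEntirelyMissingError(
                    f"column {self.column_names[j]!r} (index {j}) is entirely missing"
                )


@dataclass
class ChainState:
    """The completed data ``W(t)`` after iteration ``t`` of one chain."""

    completed: np.ndarray
    iteration: int = 0

    def copy(self) -> "ChainState":
        return ChainState(self.completed.copy(), self.iteration)


@dataclass
class ImputationEnsemble:
    """``M`` completed datasets produced by one multiple-imputation run."""

    datasets: list[np.ndarray]
    provenance: list[dict] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.datasets)
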