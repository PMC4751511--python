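"""Chained-equations driver: initialize, cycle, emit M completed datasets.

The engine is agnostic to the per-column imputation strategy: an imputer is
any callable ``imputer(state, data, j, rng) -> values`` returning one value
per originally missing cell of column ``j`` (in row order), computed from
the current completed data.  Observed cells are never modified.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .data import ChainState, ImputationEnsemble, IncompleteMatrix

ColumnImputer = Callable[[ChainState, IncompleteMatrix, int, np.random.Generator], np.ndarray]

__all__ = ["initialize_fill", "run_chain", "multiple_impute", "ImputerError"]


class ImputerError(RuntimeError):
    """Wraps an imputer failure with the column and iteration attached."""

    def __init__(self, column: int, iteration: int, cause: Exception):
        self.column = column
        self.iteration = iteration
        self.cause = cause
        super().__init__(f"imputer failed on column {column} at iteration {iteration}: {cause}")


def initialize_fill(data: IncompleteMatrix) -> ChainState:
    """Mean-impute every missing cell from its column's observed values."""
    data.check_initializable()
    completed = data.values.copy()
    for j in data.incomplete_columns:
        obs = data.mask[:, j]
        completed[~obs, j] = completed[obs, j].mean()
    return ChainState(completed, iteration=0)


def run_chain(
    data: IncompleteMatrix,
    imputer: ColumnImputer,
    T: int,
    rng: np.random.Generator,
    visit_order: Optional[Sequence[int]] = None,
    trace: Optional[list] = None,
) -> ChainState:
    """Run one chain for ``T`` full cycles and return the final state.

    Within a cycle the incomplete columns are visited in ascending index
    order (or ``visit_order`` if given); imputing column ``j`` conditions on
    the current values of all other columns — observed data plus the most
    recent imputations.  When ``trace`` is a list, per-(iteration, column)
    mean/SD of the imputed values are appended for convergence inspection.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    state = initialize_fill(data)
    columns = list(visit_order) if visit_order is not None else data.incomplete_columns
    for t in range(1, T + 1):
        state = _cycle(state, data, imputer, columns, rng, t, trace)
    return state


def _cycle(state, data, imputer, columns, rng, t, trace):
    for j in columns:
        missing = ~data.mask[:, j]
        if not missing.any():
            continue
        try:
            values = imputer(state, data, j, rng)
        except Exception as exc:  # attach location, keep the cause
            raise ImputerError(j, t, exc) from exc
        values = np.asarray(values, dtype=float)
        if values.shape != (int(missing.sum()),):
            raise ImputerError(
                j, t, ValueError(f"imputer returned shape {values.shape}")
            )
        state.completed[missing, j] = values
        if trace is not None:
            trace.append(
                {
                    "iteration": t,
                    "column": data.column_names[j],
                    "mean_imputed": float(values.mean()),
                    "sd_imputed": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                }
            )
    state.iteration = t
    return state


def multiple_impute(
    data: IncompleteMatrix,
    imputer: ColumnImputer,
    M: int = 10,
    T: int = 20,
    mode: str = "parallel_chains",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    trace: Optional[list] = None,
) -> ImputationEnsemble:
    """Produce ``M`` completed datasets.

    ``parallel_chains`` (default) runs M independent chains for T cycles
    each from sub-seeds spawned off the master stream, which avoids
    between-imputation autocorrelation.  ``thinned_chain`` runs a single
    chain for ``T * M`` cycles and keeps every T-th state.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if mode not in ("parallel_chains", "thinned_chain"):
        raise ValueError("mode must be 'parallel_chains' or 'thinned_chain'")
    if rng is None:
        rng = np.random.default_rng(seed)
    datasets: list[np.ndarray] = []
    provenance: list[dict] = []

    if mode == "parallel_chains":
        child_seeds = rng.integers(2**31, size=M)
        for m, s in enumerate(child_seeds):
            chain_rng = np.random.default_rng(int(s))
            state = run_chain(data, imputer, T, chain_rng, trace=trace)
            datasets.append(state.completed.copy())
            provenance.append({"chain": m, "seed": int(s), "iterations": T})
    else:
        state = initialize_fill(data)
        columns = data.incomplete_columns
        for cycle in range(1, T * M + 1):
            state = _cycle(state, data, imputer, columns, rng, cycle, trace)
            if cycle % T == 0:
                datasets.append(state.completed.copy())
                provenance.append({"chain": 0, "kept_at_cycle": cycle, "iterations": cycle})
    return ImputationEnsemble(datasets, provenance)
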