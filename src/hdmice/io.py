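"""CSV input/output for incomplete tables, plus data-cleaning rules.

Covers the preprocessing conventions used with registry-style survey data:
dropping variables whose missing rate exceeds a threshold, and the
skip-pattern strategy of imputing structurally skipped items together with
real missing values and then restoring them to a skip sentinel afterwards.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ImputationEnsemble, IncompleteMatrix

DEFAULT_NA_TOKENS = ("", "NA", "NaN")
SKIP_SENTINEL = "SKIP"

__all__ = [
    "read_table",
    "write_imputations",
    "filter_missing_rate",
    "skip_restore",
    "DEFAULT_NA_TOKENS",
    "SKIP_SENTINEL",
]


def read_table(path, na_tokens: Sequence[str] = DEFAULT_NA_TOKENS) -> IncompleteMatrix:
    """Read a numeric CSV (header row required) into an IncompleteMatrix.

    Cells matching one of ``na_tokens`` become missing; any other
    non-numeric cell is rejected.
    """
    df = pd.read_csv(
        path, na_values=list(na_tokens), keep_default_na=False, skipinitialspace=True
    )
    if df.shape[0] == 0:
        raise ValueError(f"{path}: zero rows")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(
            f"{path}: non-numeric cells in column(s) {bad}; only numeric "
            f"columns are supported (NA tokens: {list(na_tokens)})"
        )
    return IncompleteMatrix(df.to_numpy(dtype=float), column_names=list(df.columns))


def write_imputations(
    ensemble: ImputationEnsemble,
    data: IncompleteMatrix,
    out_dir,
    stem: str,
) -> list[Path]:
    """Write each completed dataset as ``<stem>.imp<k>.csv``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, dataset in enumerate(ensemble.datasets, start=1):
        path = out_dir / f"{stem}.imp{k}.csv"
        pd.DataFrame(dataset, columns=data.column_names).to_csv(path, index=False)
        paths.append(path)
    return paths


def filter_missing_rate(data: IncompleteMatrix, threshold: float = 0.40):
    """Drop columns whose missing fraction is strictly greater than threshold.

    Returns ``(filtered, dropped_names)``; a column whose rate equals the
    threshold exactly is retained.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    rate = 1.0 - data.r / data.n
    keep = np.flatnonzero(rate <= threshold)
    dropped = [data.column_names[j] for j in np.flatnonzero(rate > threshold)]
    if keep.size == 0:
        raise ValueError("all columns exceed the missing-rate threshold")
    filtered = IncompleteMatrix(
        data.values[:, keep],
        data.mask[:, keep],
        [data.column_names[j] for j in keep],
    )
    return filtered, dropped


def skip_restore(
    ensemble: ImputationEnsemble,
    data: IncompleteMatrix,
    skip_mask: np.ndarray,
    sentinel: float = np.nan,
) -> ImputationEnsemble:
    """Reset structurally skipped cells to the skip sentinel in every dataset.

    ``skip_mask`` must be a subset of the originally missing cells: skips
    are imputed along with real missing values (so they can inform other
    columns during chaining) and restored afterwards.
    """
    skip_mask = np.asarray(skip_mask, dtype=bool)
    if skip_mask.shape != data.values.shape:
        raise ValueError("skip_mask shape must match the data")
    if (skip_mask & data.mask).any():
        raise ValueError("skip conflicts with observed data")
    restored = []
    for dataset in ensemble.datasets:
        out = dataset.copy()
        out[skip_mask] = sentinel
        restored.append(out)
    return ImputationEnsemble(restored, list(ensemble.provenance))
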