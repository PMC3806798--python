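"""Normalization of raw macroarray spot signals.

Every spotted cDNA probe on a nylon macroarray carries two hybridization
signals: the sample signal ``Si`` from the labelled cDNA target and a
vector-oligo signal ``Vi`` from an oligonucleotide recognizing the cloning
vector, which reports the amount of cDNA actually deposited in the spot.

Normalization proceeds in a fixed order:

1. vector correction: ``(Si / Vi) * medVi`` where ``medVi`` is the median
   vector signal of the spot across all arrays — this removes spot-amount
   variation without distorting between-spot expression ratios;
2. log2 transform (small values floored before the log);
3. quantile normalization across arrays (rank-mean dialect), so every
   array ends up with an identical empirical distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawArraySet",
    "ExpressionMatrix",
    "vector_correct",
    "log2_transform",
    "quantile_normalize",
    "normalize",
]


@dataclass
class RawArraySet:
    """Spot-level raw signals for a set of arrays.

    Attributes
    ----------
    sample_signal:
        Clones x arrays matrix of raw sample intensities (Si).
    vector_signal:
        Clones x arrays matrix of raw vector-oligo intensities (Vi).
    background:
        Per-array background level (Series indexed by array) or a full
        clones x arrays matrix of local background estimates.
    sample_sheet:
        Per-array metadata indexed by array id with at least a ``group``
        column; ``batch`` and ``replicate`` are carried if present.
    """

    sample_signal: pd.DataFrame
    vector_signal: pd.DataFrame
    background: pd.Series | pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        si, vi = self.sample_signal, self.vector_signal
        if not si.index.equals(vi.index) or not si.columns.equals(vi.columns):
            raise ValueError("sample_signal and vector_signal must share clone and array indexing")
        if not si.index.is_unique:
            raise ValueError("clone ids must be unique")
        if isinstance(self.background, pd.DataFrame):
            if not self.background.index.equals(si.index) or not self.background.columns.equals(si.columns):
                raise ValueError("background matrix must share clone and array indexing")
        else:
            if not self.background.index.equals(si.columns):
                raise ValueError("per-array background must be indexed by array id")
        if not self.sample_sheet.index.equals(si.columns):
            raise ValueError("sample_sheet must be indexed by array id in matrix column order")
        if "group" not in self.sample_sheet.columns:
            raise ValueError("sample_sheet requires a 'group' column")
        if (si.to_numpy() < 0).any() or (vi.to_numpy() < 0).any():
            raise ValueError("raw signals must be non-negative")

    @property
    def groups(self) -> pd.Series:
        return self.sample_sheet["group"]

    @property
    def background_per_array(self) -> pd.Series:
        """Per-array scalar background (median over spots for local estimates)."""
        if isinstance(self.background, pd.DataFrame):
            return self.background.median(axis=0)
        return self.background

    def subset_clones(self, clones: pd.Index) -> "RawArraySet":
        bg = self.background
        if isinstance(bg, pd.DataFrame):
            bg = bg.loc[clones]
        return RawArraySet(
            self.sample_signal.loc[clones],
            self.vector_signal.loc[clones],
            bg,
            self.sample_sheet,
        )


@dataclass
class ExpressionMatrix:
    """Clones x arrays log2 expression values with array metadata."""

    values: pd.DataFrame
    sample_sheet: pd.DataFrame
    vector_corrected: bool = True
    quantile_normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("clone ids must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if not self.sample_sheet.index.equals(self.values.columns):
            raise ValueError("sample_sheet must be indexed by array id in matrix column order")

    @property
    def groups(self) -> pd.Series:
        return self.sample_sheet["group"]


def vector_correct(sample_signal, vector_signal: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correct sample signals for spotted-cDNA amount: ``(Si/Vi) * medVi``.

    ``medVi`` is the per-spot median of the vector signal across arrays, so
    a spot with identical Vi on every array is returned unchanged and the
    result is invariant to rescaling a spot's Vi by a constant factor.

    Accepts either a :class:`RawArraySet` or the two matrices directly.
    Raises ``ValueError`` naming the first offending spot if any retained
    spot has a non-positive vector signal.
    """
    if vector_signal is None:
        raw = sample_signal
        sample_signal, vector_signal = raw.sample_signal, raw.vector_signal
    vi = vector_signal.to_numpy(dtype=float)
    if (vi <= 0).any():
        g, a = np.argwhere(vi <= 0)[0]
        raise ValueError(
            "non-positive vector signal for clone "
            f"{vector_signal.index[g]!r} on array {vector_signal.columns[a]!r}; "
            "flag non-informative spots before vector correction"
        )
    medvi = np.median(vi, axis=1)
    corrected = sample_signal.to_numpy(dtype=float) / vi * medvi[:, None]
    return pd.DataFrame(corrected, index=sample_signal.index, columns=sample_signal.columns)


def log2_transform(values: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Log2-transform non-negative intensities, flooring small values.

    ``floor`` defaults to the smallest strictly positive value in the
    matrix; every value at or below the floor is replaced by it before
    taking the log, so zeros never produce ``-inf``.
    """
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    if floor is None:
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValueError("all-zero matrix: supply an explicit positive floor")
        floor = float(positive.min())
    if floor <= 0:
        raise ValueError("floor must be strictly positive")
    out = np.log2(np.maximum(arr, floor))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(values: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Force every array column onto a common empirical distribution.

    Each value is replaced by the across-array summary (``mean`` by
    default, ``median`` optionally) of the values at its rank; ties within
    an array receive the mean of the reference values they span.  The
    operation is idempotent and a single-column matrix is returned
    unchanged up to the reference summary of itself (i.e. unchanged).
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("quantile_normalize does not support missing values")
    n, m = arr.shape
    if n == 0 or m == 0:
        return values.copy()
    srt = np.sort(arr, axis=0)
    ref = srt.mean(axis=1) if stat == "mean" else np.median(srt, axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        new_run = np.empty(n, dtype=bool)
        new_run[0] = True
        new_run[1:] = sorted_col[1:] != sorted_col[:-1]
        run_id = np.cumsum(new_run) - 1
        run_mean = np.bincount(run_id, weights=ref) / np.bincount(run_id)
        out[order, j] = run_mean[run_id]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(
    raw: RawArraySet,
    floor: float | None = None,
    stat: str = "mean",
    quantile: bool = True,
) -> ExpressionMatrix:
    """Full normalization stack: vector correction, log2, quantile step."""
    corrected = vector_correct(raw.sample_signal, raw.vector_signal)
    logged = log2_transform(corrected, floor=floor)
    values = quantile_normalize(logged, stat=stat) if quantile else logged
    return ExpressionMatrix(
        values=values,
        sample_sheet=raw.sample_sheet,
        vector_corrected=True,
        quantile_normalized=quantile,
        provenance={"floor": floor, "quantile_stat": stat},
    )
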