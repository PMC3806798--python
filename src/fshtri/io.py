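"""Tab-delimited readers and writers for the pipeline's artifacts.

The raw array set is stored as a directory of TSV files:
``sample_signal.tsv``, ``vector_signal.tsv`` (clones x arrays),
``background.tsv`` (per-array scalar or clones x arrays),
``samples.tsv`` (sample sheet) and optionally ``truth.tsv`` for
synthetic data.  Matrices are plain TSV with clones as rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import ExpressionMatrix, RawArraySet

__all__ = [
    "write_raw_array_set",
    "read_raw_array_set",
    "write_matrix",
    "read_matrix",
    "write_expression",
    "read_expression",
]


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="clone")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_raw_array_set(
    raw: RawArraySet, outdir: str | Path, truth: pd.DataFrame | None = None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(raw.sample_signal, outdir / "sample_signal.tsv")
    write_matrix(raw.vector_signal, outdir / "vector_signal.tsv")
    if isinstance(raw.background, pd.DataFrame):
        write_matrix(raw.background, outdir / "background.tsv")
    else:
        raw.background.rename("background").to_csv(
            outdir / "background.tsv", sep="\t", index_label="array"
        )
    raw.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index_label="array")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="clone")


def read_raw_array_set(indir: str | Path) -> RawArraySet:
    indir = Path(indir)
    sample_signal = read_matrix(indir / "sample_signal.tsv")
    vector_signal = read_matrix(indir / "vector_signal.tsv")
    bg = pd.read_csv(indir / "background.tsv", sep="\t", index_col=0)
    background = bg["background"] if list(bg.columns) == ["background"] else bg
    sample_sheet = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    sample_sheet = sample_sheet.reindex(sample_signal.columns)
    return RawArraySet(sample_signal, vector_signal, background, sample_sheet)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    write_matrix(expr.values, path)


def read_expression(path: str | Path, sample_sheet: pd.DataFrame) -> ExpressionMatrix:
    values = read_matrix(path)
    return ExpressionMatrix(
        values=values,
        sample_sheet=sample_sheet.reindex(values.columns),
        quantile_normalized=True,
    )
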