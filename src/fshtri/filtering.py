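"""Three-stage clone-selection cascade applied before statistics.

1. informativeness — drop clones whose vector-oligo signal is below
   3x the background level in more than 20% of arrays (too little cDNA
   was spotted for the signal to be trusted);
2. expression level — keep clones whose mean log2 expression reaches the
   global median of the experiment in at least one treatment group;
3. fold change — keep clones with at least a 1.5-fold Fsh response in
   the absence or presence of the inhibitor.

The comparison directions are strict exactly where printed in the rule
(" < 3x " and " > 20% "), inclusive for the fold-change bound (">= 1.5").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FSH_VS_CTRL, FSHTRI_VS_TRI
from .preprocess import ExpressionMatrix, RawArraySet

__all__ = [
    "FilterReport",
    "flag_noninformative",
    "filter_expression_level",
    "filter_fold_change",
    "apply_filters",
]


@dataclass
class FilterReport:
    """Per-clone filter flags and cascade counts.

    ``flags`` holds boolean columns ``informative``, ``expression``,
    ``fold_change`` and ``retained`` (the conjunction of the three).
    ``counts`` records the cascade: clones surviving after each stage.
    """

    flags: pd.DataFrame
    counts: dict[str, int]

    @property
    def retained(self) -> pd.Index:
        return self.flags.index[self.flags["retained"]]


def flag_noninformative(
    vector_signal: pd.DataFrame,
    background: pd.Series | pd.DataFrame | float,
    k: float = 3.0,
    frac: float = 0.20,
) -> pd.Series:
    """Informative-clone flags from raw vector signals and background.

    A clone is *non*-informative iff its vector signal falls strictly
    below ``k x background`` in strictly more than ``frac`` of the arrays.
    Returns a boolean Series that is True for informative (kept) clones.
    """
    if isinstance(background, pd.DataFrame):
        if not background.index.equals(vector_signal.index):
            raise ValueError("background matrix must be indexed like vector_signal")
        thresh = k * background
        low = vector_signal.lt(thresh)
        bg_values = background.to_numpy(dtype=float)
    elif isinstance(background, pd.Series):
        thresh = k * background.reindex(vector_signal.columns)
        low = vector_signal.lt(thresh, axis="columns")
        bg_values = thresh.to_numpy(dtype=float)
    else:
        low = vector_signal.lt(k * float(background))
        bg_values = np.asarray([background], dtype=float)
    if (bg_values <= 0).any():
        raise ValueError("background level must be strictly positive")
    frac_low = low.sum(axis=1) / vector_signal.shape[1]
    informative = ~(frac_low > frac)
    informative.name = "informative"
    return informative


def _group_means(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("every array column needs a group label")
    means = values.T.groupby(groups, sort=False).mean().T
    return means


def filter_expression_level(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Expression-level flags: max group mean >= median of all values.

    The reference is a single scalar, the median over every value of the
    matrix handed in (so apply this after the informativeness stage to
    reproduce the cascade).  Equality keeps the clone, hence a constant
    matrix passes everywhere.
    """
    global_median = float(np.median(values.to_numpy(dtype=float)))
    keep = _group_means(values, groups).max(axis=1) >= global_median
    keep.name = "expression"
    return keep


def filter_fold_change(
    values: pd.DataFrame,
    groups: pd.Series,
    pairs: tuple[tuple[str, str], ...] = (FSH_VS_CTRL, FSHTRI_VS_TRI),
    fc: float = 1.5,
) -> pd.Series:
    """Fold-change flags: |mean log2 difference| >= log2(fc) on >=1 pair.

    Differences are computed on group means of log2 values and the rule is
    direction-agnostic; the bound is inclusive.
    """
    means = _group_means(values, groups)
    available = set(means.columns)
    for pair in pairs:
        missing = [g for g in pair if g not in available]
        if missing:
            raise ValueError(f"unknown group label(s) {missing} in fold-change pair {pair}")
    bound = np.log2(fc)
    keep = pd.Series(False, index=values.index, name="fold_change")
    for ref, treated in pairs:
        keep |= (means[treated] - means[ref]).abs() >= bound
    return keep


def apply_filters(
    raw: RawArraySet,
    expr: ExpressionMatrix,
    k: float = 3.0,
    frac: float = 0.20,
    fc: float = 1.5,
    pairs: tuple[tuple[str, str], ...] = (FSH_VS_CTRL, FSHTRI_VS_TRI),
) -> FilterReport:
    """Run the cascade and report per-clone flags plus stage counts.

    The informativeness stage uses the raw vector signals; the expression
    and fold-change stages are computed on the normalized matrix restricted
    to informative clones.  Those two downstream flags are independent of
    each other, so their order does not change the retained set.
    """
    all_clones = raw.sample_signal.index
    informative = flag_noninformative(raw.vector_signal, raw.background, k=k, frac=frac)
    keep = expr.values.index.intersection(informative[informative].index)
    sub = expr.values.loc[keep]
    informative = informative.reindex(all_clones, fill_value=False)
    expression = filter_expression_level(sub, expr.groups).reindex(all_clones, fill_value=False)
    fold = filter_fold_change(sub, expr.groups, pairs=pairs, fc=fc).reindex(all_clones, fill_value=False)
    retained = informative & expression & fold
    flags = pd.DataFrame(
        {
            "informative": informative,
            "expression": expression,
            "fold_change": fold,
            "retained": retained,
        }
    )
    counts = {
        "total": int(len(flags)),
        "informative": int(informative.sum()),
        "informative_and_expression": int((informative & expression).sum()),
        "retained": int(retained.sum()),
    }
    return FilterReport(flags=flags, counts=counts)
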