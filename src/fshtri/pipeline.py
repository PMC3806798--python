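"""End-to-end orchestration of the array analysis.

``run_array_pipeline`` chains the stages exactly as a full analysis would:
informativeness flagging on raw vector signals, normalization
(vector correction, log2, quantile), the expression-level and fold-change
filters, the moderated group-means statistics with BH FDR on the omnibus
F, and response-class calling of the significant clones.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import ResponseCall, classify_response
from .diffexpr import LinearModelFit, ModeratedStats, contrast_table, ebayes_moderate, fit_group_means
from .filtering import FilterReport, apply_filters, flag_noninformative
from .preprocess import ExpressionMatrix, RawArraySet, normalize

__all__ = ["PipelineResult", "run_array_pipeline"]


@dataclass
class PipelineResult:
    expression: ExpressionMatrix  # normalized matrix (informative clones)
    report: FilterReport
    fit: LinearModelFit
    moderated: ModeratedStats
    contrasts: pd.DataFrame  # contrast table for retained clones
    significant: pd.Index  # clones with omnibus F_q <= fdr
    calls: ResponseCall  # response classes of the significant clones


def run_array_pipeline(
    raw: RawArraySet,
    fdr: float = 0.01,
    alpha: float = 0.05,
    fc: float = 1.5,
    quantile_stat: str = "mean",
) -> PipelineResult:
    """Run the full analysis on a raw array set.

    The informativeness filter runs on raw vector signals before
    normalization (it is the only self-consistent placement: it consumes
    raw Vi and background, and vector correction cannot divide by the
    deficient signals it flags).  Statistics are computed on the clones
    surviving the whole filter cascade; the headline significant list is
    the omnibus moderated F at BH ``q <= fdr``; response classes are
    called on that list with raw pairwise p-value gates at ``alpha``.
    """
    informative = flag_noninformative(raw.vector_signal, raw.background)
    raw_inf = raw.subset_clones(raw.sample_signal.index[informative])
    expression = normalize(raw_inf, stat=quantile_stat)
    report = apply_filters(raw, expression, fc=fc)
    retained = report.retained
    values = expression.values.loc[retained]
    fit = fit_group_means(values, expression.groups)
    moderated = ebayes_moderate(fit)
    contrasts = contrast_table(fit, moderated)
    significant = contrasts.index[contrasts["F_q"] <= fdr]
    calls = classify_response(contrasts.loc[significant], alpha=alpha)
    return PipelineResult(
        expression=expression,
        report=report,
        fit=fit,
        moderated=moderated,
        contrasts=contrasts,
        significant=significant,
        calls=calls,
    )
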