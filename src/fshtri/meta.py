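"""Cross-experiment combination of two macroarray studies.

Two experiments hybridized on different membrane batches cannot be
compared directly: each gene carries an additive batch offset on the log2
scale.  The per-gene median scheme removes it — for every shared gene the
first experiment's arrays are median-centered and shifted onto the second
experiment's row median, after which the two batches agree in location
gene by gene.  Concordance between inhibitor sensitivity (this design)
and responsiveness to the other gonadotropin (Lh, from the reference
experiment) is then tested on a contingency table with Fisher's exact
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterResult, hierarchical_cluster

__all__ = [
    "CombinedMatrix",
    "cross_experiment_normalize",
    "concordance_table",
    "combined_cluster",
]


@dataclass
class CombinedMatrix:
    """Shared clones x pooled arrays with batch labels."""

    values: pd.DataFrame
    batch: pd.Series  # array -> experiment label

    def __post_init__(self) -> None:
        if not self.batch.index.equals(self.values.columns):
            raise ValueError("batch labels must be indexed by array id in column order")


def cross_experiment_normalize(
    expr1: pd.DataFrame,
    expr2: pd.DataFrame,
    batch_labels: tuple[str, str] = ("exp1", "exp2"),
) -> CombinedMatrix:
    """Align experiment 1 onto experiment 2's per-gene medians.

    For every shared gene the experiment-1 arrays have their own row
    median subtracted and the experiment-2 row median added; experiment-2
    arrays are returned unchanged.  After the operation the two batches
    have exactly equal row medians, and re-applying it is a no-op.
    """
    shared = expr1.index.intersection(expr2.index)
    if len(shared) == 0:
        raise ValueError("no shared clones between the two experiments")
    e1 = expr1.loc[shared]
    e2 = expr2.loc[shared]
    overlap = e1.columns.intersection(e2.columns)
    if len(overlap) > 0:
        raise ValueError(f"array ids shared between experiments: {list(overlap)[:3]}")
    shifted = e1.sub(e1.median(axis=1), axis=0).add(e2.median(axis=1), axis=0)
    values = pd.concat([shifted, e2], axis=1)
    batch = pd.Series(
        [batch_labels[0]] * e1.shape[1] + [batch_labels[1]] * e2.shape[1],
        index=values.columns,
        name="batch",
    )
    return CombinedMatrix(values=values, batch=batch)


@dataclass
class ConcordanceResult:
    """2x3 contingency of inhibitor sensitivity vs Lh response + exact test."""

    table: pd.DataFrame  # rows sensitive/insensitive, columns up/down/none
    collapsed: pd.DataFrame  # 2x2: sensitive x Lh-regulated
    odds_ratio: float
    p_value: float


def concordance_table(sensitive: pd.Series, lh_response: pd.Series) -> ConcordanceResult:
    """Cross-tabulate trilostane sensitivity against Lh responsiveness.

    ``sensitive`` is boolean per clone (steroid-mediated response);
    ``lh_response`` takes values in {"up", "down", "none"}.  The exact
    association p-value comes from Fisher's test on the collapsed 2x2
    table (sensitive x Lh-regulated-at-all).
    """
    common = sensitive.index.intersection(lh_response.index)
    if len(common) == 0:
        raise ValueError("no clones shared between calls and Lh annotation")
    s = sensitive.loc[common].astype(bool)
    lh = lh_response.loc[common].astype(str)
    bad = set(lh.unique()) - {"up", "down", "none"}
    if bad:
        raise ValueError(f"unexpected Lh response labels: {sorted(bad)}")
    rows = s.map({True: "trilostane_sensitive", False: "trilostane_insensitive"})
    table = pd.crosstab(rows, lh).reindex(
        index=["trilostane_sensitive", "trilostane_insensitive"],
        columns=["up", "down", "none"],
        fill_value=0,
    )
    regulated = lh != "none"
    collapsed = pd.crosstab(rows, regulated.map({True: "lh_regulated", False: "lh_none"})).reindex(
        index=["trilostane_sensitive", "trilostane_insensitive"],
        columns=["lh_regulated", "lh_none"],
        fill_value=0,
    )
    odds, p = stats.fisher_exact(collapsed.to_numpy(), alternative="two-sided")
    return ConcordanceResult(table=table, collapsed=collapsed, odds_ratio=float(odds), p_value=float(p))


def combined_cluster(combined: CombinedMatrix, method: str = "average", k: int | None = None) -> ClusterResult:
    """Hierarchical clustering of the combined matrix rows (same engine)."""
    return hierarchical_cluster(combined.values, method=method, k=k)
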