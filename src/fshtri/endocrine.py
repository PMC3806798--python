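"""Endocrine endpoint summaries and nonparametric qPCR statistics.

Covers the non-array endpoints of the study design: 11-ketotestosterone
(11KT) concentrations measured by radioimmunoassay in culture media, and
qPCR relative expression normalized to a reference gene.  Group
comparisons use exact nonparametric tests (Kruskal-Wallis omnibus, then
pairwise Mann-Whitney U only when the omnibus is significant), and group
differences are summarized with a compact letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_steroid",
    "percent_inhibition",
    "mann_whitney_exact",
    "kruskal_wallis",
    "kruskal_gated_pairwise",
    "relative_expression",
    "qpcr_relative_expression",
    "letter_grouping",
]


def percent_inhibition(reference_mean: float, treated_mean: float) -> float:
    """``100 * (1 - treated/reference)``; NaN when the reference is zero.

    Invariant to rescaling both concentrations by the same factor.
    """
    if reference_mean == 0:
        return float("nan")
    return 100.0 * (1.0 - treated_mean / reference_mean)


@dataclass
class SteroidSummary:
    group_stats: pd.DataFrame  # mean, sd, n per treatment
    fold_change: float  # treated mean / reference mean
    percent_inhibition: float
    reference_treatment: str
    treated_treatment: str
    undefined: bool  # True when the reference mean is zero


def summarize_steroid(
    series: pd.DataFrame,
    reference_treatment: str,
    treated_treatment: str,
    period: str | None = None,
) -> SteroidSummary:
    """Group means +/- SD, fold change and percent inhibition.

    ``series`` is a long table with columns ``treatment``, ``period``,
    ``replicate``, ``concentration`` and optionally ``duplicate``;
    duplicate assay measurements are averaged per replicate before any
    replicate-level statistic.  ``period`` restricts to one culture
    period (default: the last one present).
    """
    df = series.copy()
    if period is None:
        period = sorted(df["period"].unique())[-1]
    df = df[df["period"] == period]
    if df.empty:
        raise ValueError(f"no records for period {period!r}")
    per_rep = (
        df.groupby(["treatment", "replicate"], sort=False)["concentration"].mean().reset_index()
    )
    counts = per_rep.groupby("treatment")["concentration"].count()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"treatments with fewer than 2 replicates: {small}")
    group_stats = per_rep.groupby("treatment")["concentration"].agg(["mean", "std", "count"])
    group_stats.columns = ["mean", "sd", "n"]
    for t in (reference_treatment, treated_treatment):
        if t not in group_stats.index:
            raise ValueError(f"treatment {t!r} absent from the series")
    ref = float(group_stats.loc[reference_treatment, "mean"])
    trt = float(group_stats.loc[treated_treatment, "mean"])
    undefined = ref == 0
    return SteroidSummary(
        group_stats=group_stats,
        fold_change=(trt / ref) if not undefined else float("nan"),
        percent_inhibition=percent_inhibition(ref, trt),
        reference_treatment=reference_treatment,
        treated_treatment=treated_treatment,
        undefined=undefined,
    )


@dataclass
class MannWhitneyResult:
    U: float  # U statistic of the first sample
    p: float
    exact: bool  # True when the permutation distribution was enumerated


def mann_whitney_exact(
    group_a,
    group_b,
    two_sided: bool = True,
    max_exact: int = 20,
) -> MannWhitneyResult:
    """Mann-Whitney U with an exact permutation p-value for small samples.

    Mid-ranks handle ties.  When ``n_a + n_b <= max_exact`` the p-value is
    computed by enumerating every assignment of the pooled observations to
    the two groups and counting arrangements at least as extreme (in
    ``|U - n_a*n_b/2|`` for the two-sided test) as observed, ties
    included.  Larger samples fall back to the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    if n <= max_exact:
        obs_dev = abs(u_obs - mu)
        rank_min = na * (na + 1) / 2.0
        extreme = 0
        total = math.comb(n, na)
        for idx in itertools.combinations(range(n), na):
            u = ranks[list(idx)].sum() - rank_min
            if two_sided:
                if abs(u - mu) >= obs_dev - 1e-9:
                    extreme += 1
            else:
                if u >= u_obs - 1e-9:
                    extreme += 1
        return MannWhitneyResult(U=u_obs, p=extreme / total, exact=True)

    # Normal approximation with tie correction.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(U=u_obs, p=1.0, exact=False)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z) if two_sided else stats.norm.sf((u_obs - mu - 0.5) / math.sqrt(sigma2))
    return MannWhitneyResult(U=u_obs, p=min(float(p), 1.0), exact=False)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction against a chi-square reference.

    All-identical data (every rank tied) gives ``H = 0, p = 1`` rather
    than the 0/0 of the tie-correction formula.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def kruskal_gated_pairwise(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> tuple[tuple[float, float], pd.DataFrame | None]:
    """Omnibus Kruskal-Wallis, then pairwise Mann-Whitney if significant.

    Follows the testing hierarchy used for the endocrine and qPCR
    endpoints: the pairwise exact U tests run only when the omnibus
    p-value is below ``alpha``.  Returns ``((H, p), pairwise)`` where
    ``pairwise`` is a symmetric p-value matrix or ``None`` if gated out.
    """
    names = list(groups)
    h, p = kruskal_wallis([groups[g] for g in names])
    if p >= alpha:
        return (h, p), None
    pmat = pd.DataFrame(1.0, index=names, columns=names)
    for g1, g2 in itertools.combinations(names, 2):
        res = mann_whitney_exact(groups[g1], groups[g2])
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = res.p
    return (h, p), pmat


def relative_expression(ct_target, ct_ref, efficiency: float = 2.0):
    """Efficiency-corrected delta-Ct quantification.

    ``level = efficiency ** (ct_ref - ct_target)``, so one cycle of
    advantage doubles the level at perfect efficiency.  Invariant to
    adding a constant to both Ct values (e.g. a plate offset).
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must lie in (1, 2]")
    ct_target = np.asarray(ct_target, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if np.isnan(ct_ref).any():
        raise ValueError("missing reference Ct")
    out = efficiency ** (ct_ref - ct_target)
    return float(out) if out.ndim == 0 else out


def qpcr_relative_expression(
    records: pd.DataFrame,
    reference_gene: str = "rps15",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample relative levels for every gene against the reference.

    ``records`` is a long Ct table with columns ``sample``, ``group``,
    ``gene``, ``ct`` (one row per technical duplicate).  Duplicates are
    averaged per sample x gene first, then each gene is normalized to the
    reference gene of the same sample.  Returns a table indexed by sample
    with a ``group`` column and one column per non-reference gene.
    """
    mean_ct = records.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from the dataset")
    if mean_ct[reference_gene].isna().any():
        raise ValueError("missing reference Ct for some samples")
    targets = [g for g in mean_ct.columns if g != reference_gene]
    levels = pd.DataFrame(index=mean_ct.index)
    for gene in targets:
        levels[gene] = relative_expression(
            mean_ct[gene].to_numpy(), mean_ct[reference_gene].to_numpy(), efficiency
        )
    sample_groups = records.drop_duplicates("sample").set_index("sample")["group"]
    levels.insert(0, "group", sample_groups.reindex(levels.index))
    return levels


def letter_grouping(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    Groups share no letter iff their pairwise p-value is below ``alpha``.
    Uses the deterministic insert-and-absorb construction: start with one
    letter covering everything; for each significant pair (taken in index
    order) split every letter set containing both members; drop sets that
    became subsets of others.  Letters are assigned a, b, c ... by the
    smallest member index of each set.
    """
    names = list(pairwise_p.index)
    pos = {g: i for i, g in enumerate(names)}
    sets: list[set] = [set(names)]
    for g1, g2 in itertools.combinations(names, 2):
        if pairwise_p.loc[g1, g2] >= alpha:
            continue
        new_sets: list[set] = []
        for s in sets:
            if g1 in s and g2 in s:
                new_sets.append(s - {g1})
                new_sets.append(s - {g2})
            else:
                new_sets.append(s)
        # absorb strict subsets and duplicates, keeping first occurrences
        sets = []
        for s in new_sets:
            if any(s < t for t in new_sets if t is not s):
                continue
            if s not in sets:
                sets.append(s)
    sets.sort(key=lambda s: min(pos[g] for g in s))
    letters = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}
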