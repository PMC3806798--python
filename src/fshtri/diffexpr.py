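"""Per-clone linear models with empirical-Bayes moderated statistics.

Each clone is fitted with a one-way group-means model; the residual
variances are then shrunk towards a common prior by the moderated-t
construction: sample variances are assumed to follow

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi2_d / d,
    1 / sigma_g^2      ~  chi2_d0 / (d0 * s0^2),

so that the posterior variance is the precision-weighted blend

    s~_g^2 = (d0*s0^2 + d*s_g^2) / (d0 + d)

and moderated t / F statistics gain d0 extra degrees of freedom.  The
hyperparameters (d0, s0^2) are estimated by matching the mean and the
variance of log s_g^2 to their theoretical digamma/trigamma expressions.
Multiplicity is handled with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import FSH_VS_CTRL, FSHTRI_VS_TRI, TRI_VS_CTRL

__all__ = [
    "LinearModelFit",
    "ModeratedStats",
    "fit_group_means",
    "ebayes_moderate",
    "moderated_contrast",
    "moderated_linear_contrast",
    "moderated_F",
    "bh_fdr",
    "contrast_table",
]

#: Floor applied to zero sample variances before taking logs.
_VAR_FLOOR = 1e-12


@dataclass
class LinearModelFit:
    """Group means and pooled residual variance per clone."""

    group_means: pd.DataFrame  # clones x groups (design order)
    s2: pd.Series  # pooled residual variance per clone
    df_residual: float  # n_arrays - n_groups (complete data)
    n_per_group: pd.Series  # arrays per group
    groups: pd.Series  # array -> group


@dataclass
class ModeratedStats:
    """Empirical-Bayes hyperparameters and posterior variances."""

    d0: float  # prior degrees of freedom, may be inf
    s02: float  # prior variance
    s2_post: pd.Series  # posterior (moderated) variance per clone
    df_total: float  # d0 + residual df, may be inf


def fit_group_means(values: pd.DataFrame, groups: pd.Series) -> LinearModelFit:
    """One-way fit per clone: group means and pooled residual variance.

    Residual df is ``n_arrays - n_groups``; every group must contribute at
    least two arrays so the pooled variance is estimable.
    """
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("every array column needs a group label")
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 arrays: {small}")
    means = values.T.groupby(groups, sort=False).mean().T
    fitted = means[groups.to_numpy()].to_numpy()
    resid = values.to_numpy(dtype=float) - fitted
    df = values.shape[1] - means.shape[1]
    s2 = pd.Series((resid**2).sum(axis=1) / df, index=values.index, name="s2")
    return LinearModelFit(
        group_means=means,
        s2=s2,
        df_residual=float(df),
        n_per_group=counts.reindex(means.columns),
        groups=groups,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x + 1/(2x^2): start from the large-x asymptote
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-12 * (1.0 + abs(x)):
            return float(x_new)
        x = x_new
    return float(x)


def ebayes_moderate(fit: LinearModelFit, d0: float | None = None) -> ModeratedStats:
    """Estimate (d0, s0^2) by moment matching and form posterior variances.

    With ``e_g = log s_g^2 - digamma(d/2) + log(d/2)`` the model implies
    ``E[e] = log s0^2 - digamma(d0/2) + log(d0/2)`` and
    ``Var[e] = trigamma(d/2) + trigamma(d0/2)``; the excess spread of
    ``e`` over ``trigamma(d/2)`` therefore identifies ``d0``.  When the
    sample variances carry no excess spread the prior is degenerate
    (``d0 = inf``) and every posterior variance equals ``s0^2``.

    ``d0`` may be forced (``d0=0`` recovers the classical unmoderated
    statistics; ``d0=inf`` pools everything).
    """
    s2 = fit.s2.to_numpy(dtype=float)
    df = fit.df_residual
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    if d0 is None and s2.size < 10:
        raise ValueError("hyperparameter estimation needs at least 10 clones")
    e = np.log(np.maximum(s2, _VAR_FLOOR)) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())

    if d0 is not None:
        d0 = float(d0)
        if d0 < 0:
            raise ValueError("d0 must be non-negative")
        if not np.isfinite(d0):
            s02 = float(s2.mean())  # degenerate prior: plain average variance
        elif d0 > 0:
            s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            s02 = float("nan")
    else:
        excess = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0)) if s2.size > 1 else 0.0
        if excess <= 0:
            d0 = np.inf
            s02 = float(s2.mean())
        else:
            d0 = 2.0 * _trigamma_inverse(excess)
            s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if not np.isfinite(d0):
        post = np.full_like(s2, s02)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return ModeratedStats(
        d0=float(d0),
        s02=s02,
        s2_post=pd.Series(post, index=fit.s2.index, name="s2_post"),
        df_total=float(d0 + df) if np.isfinite(d0) else np.inf,
    )


def _t_pvalue(t: np.ndarray, df: float) -> np.ndarray:
    if np.isfinite(df):
        return 2.0 * stats.t.sf(np.abs(t), df)
    return 2.0 * stats.norm.sf(np.abs(t))


def moderated_linear_contrast(
    fit: LinearModelFit,
    mod: ModeratedStats,
    weights: Mapping[str, float],
) -> pd.DataFrame:
    """Moderated t-test of an arbitrary linear contrast of group means.

    ``weights`` maps group labels to contrast coefficients; the standard
    error is ``sqrt(s~^2 * sum(w_k^2 / n_k))`` and the reference is a t
    distribution with ``d0 + d`` degrees of freedom (normal when d0 is
    infinite).  A clone with zero effect and zero posterior variance gets
    ``t = 0, p = 1``.
    """
    missing = [g for g in weights if g not in fit.group_means.columns]
    if missing:
        raise ValueError(f"unknown group(s) in contrast: {missing}")
    effect = np.zeros(len(fit.group_means))
    varfac = 0.0
    for g, w in weights.items():
        effect = effect + w * fit.group_means[g].to_numpy()
        varfac += w * w / float(fit.n_per_group[g])
    se = np.sqrt(mod.s2_post.to_numpy() * varfac)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    p = _t_pvalue(t, mod.df_total)
    p = np.where(np.isinf(t), 0.0, p)
    return pd.DataFrame({"effect": effect, "t": t, "p": p}, index=fit.group_means.index)


def moderated_contrast(
    fit: LinearModelFit,
    mod: ModeratedStats,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Moderated t for a pairwise contrast ``treated - reference``."""
    ref, treated = pair
    if ref == treated:
        # Degenerate contrast of a group against itself: no evidence.
        idx = fit.group_means.index
        return pd.DataFrame({"effect": 0.0, "t": 0.0, "p": 1.0}, index=idx)
    return moderated_linear_contrast(fit, mod, {treated: 1.0, ref: -1.0})


def moderated_F(fit: LinearModelFit, mod: ModeratedStats) -> pd.DataFrame:
    """Omnibus moderated F across all groups.

    ``F = MS_between / s~^2`` on ``(k - 1, d0 + d)`` degrees of freedom;
    with an infinite prior the reference becomes ``chi2_{k-1} / (k-1)``.
    """
    means = fit.group_means.to_numpy(dtype=float)
    n_k = fit.n_per_group.to_numpy(dtype=float)
    k = means.shape[1]
    if k < 2:
        raise ValueError("omnibus F needs at least 2 groups")
    n_total = n_k.sum()
    grand = (means * n_k).sum(axis=1) / n_total
    ss_between = ((means - grand[:, None]) ** 2 * n_k).sum(axis=1)
    ms_between = ss_between / (k - 1)
    s2p = mod.s2_post.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(s2p > 0, ms_between / np.where(s2p > 0, s2p, 1.0), np.where(ms_between == 0, 0.0, np.inf))
    if np.isfinite(mod.df_total):
        p = stats.f.sf(F, k - 1, mod.df_total)
    else:
        p = stats.chi2.sf((k - 1) * F, k - 1)
    p = np.where(np.isinf(F), 0.0, p)
    return pd.DataFrame({"F": F, "p": p}, index=fit.group_means.index)


def bh_fdr(pvalues) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` clipped to [0, 1]; selecting at
    ``q <= alpha`` reproduces the step-up rejection set at level alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d array of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def contrast_table(
    fit: LinearModelFit,
    mod: ModeratedStats,
    pairs: Mapping[str, tuple[str, str]] | None = None,
    interaction: bool = True,
) -> pd.DataFrame:
    """Assemble the per-clone contrast table used by response classification.

    Columns: for every named pair ``<name>_effect``, ``<name>_t``,
    ``<name>_p``; optionally the hormone x inhibitor interaction contrast
    ``(Fsh - Ctrl) - (FshTri - Tri)``; plus omnibus ``F``, ``F_p`` and the
    BH-adjusted ``F_q``.
    """
    if pairs is None:
        pairs = {
            "fsh_vs_ctrl": FSH_VS_CTRL,
            "fshtri_vs_tri": FSHTRI_VS_TRI,
            "tri_vs_ctrl": TRI_VS_CTRL,
        }
    out = {}
    for name, pair in pairs.items():
        res = moderated_contrast(fit, mod, pair)
        out[f"{name}_effect"] = res["effect"]
        out[f"{name}_t"] = res["t"]
        out[f"{name}_p"] = res["p"]
    if interaction:
        res = moderated_linear_contrast(
            fit, mod, {"Fsh": 1.0, "Ctrl": -1.0, "FshTri": -1.0, "Tri": 1.0}
        )
        out["interaction_effect"] = res["effect"]
        out["interaction_p"] = res["p"]
    omni = moderated_F(fit, mod)
    out["F"] = omni["F"]
    out["F_p"] = omni["p"]
    out["F_q"] = bh_fdr(omni["p"])
    return pd.DataFrame(out, index=fit.group_means.index)
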