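"""Hierarchical clustering and response-class calling.

Clustering uses the uncentered Pearson (cosine-like) distance on clone
expression profiles and is purely descriptive: it orders the heatmap.
Class membership is decided by explicit contrast rules on the three
pairwise effects of the factorial design, never by cluster cut labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "uncentered_pearson_distance",
    "uncentered_pearson_distances",
    "hierarchical_cluster",
    "median_center_rows",
    "classify_response",
    "ResponseCall",
    "plot_heatmap",
]


def uncentered_pearson_distance(x, y) -> float:
    """1 - uncentered Pearson correlation; lies in [0, 2].

    The similarity is ``sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` without
    mean-centering, so the distance is zero iff the vectors are positively
    proportional and 2 for anti-proportional vectors.  Zero vectors have
    undefined similarity and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("uncentered Pearson distance is undefined for a zero vector")
    r = float((x * y).sum() / (nx * ny))
    return float(np.clip(1.0 - r, 0.0, 2.0))


def uncentered_pearson_distances(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Condensed pairwise uncentered-Pearson distance matrix over rows."""
    X = np.asarray(values, dtype=float)
    norms = np.sqrt((X * X).sum(axis=1))
    if (norms == 0).any():
        bad = int(np.argwhere(norms == 0)[0, 0])
        label = values.index[bad] if isinstance(values, pd.DataFrame) else bad
        raise ValueError(f"zero row {label!r}: uncentered Pearson distance undefined")
    sim = (X @ X.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


@dataclass
class ClusterResult:
    """Agglomerative tree with optional k-cut labels and leaf order."""

    linkage: np.ndarray
    labels: pd.Series | None
    order: np.ndarray  # dendrogram leaf order (row positions)


def hierarchical_cluster(
    values: pd.DataFrame,
    method: str = "average",
    k: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of rows under uncentered Pearson distance.

    ``method`` is the linkage rule (average by default).  Cutting the tree
    at ``k`` clusters yields integer labels (1..k).  The merge order is
    deterministic for a fixed input order: on exact distance ties the
    lowest-index pair merges first (scipy's tie-break).
    """
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    if k is not None and k > values.shape[0]:
        raise ValueError(f"cannot cut {values.shape[0]} rows into {k} clusters")
    condensed = uncentered_pearson_distances(values)
    Z = hierarchy.linkage(condensed, method=method)
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=values.index, name="cluster")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(linkage=Z, labels=labels, order=order)


def median_center_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's median (display convention for heatmaps)."""
    return values.sub(values.median(axis=1), axis=0)


def group_mean_profiles(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-clone treatment-mean profiles (clones x groups).

    Averaging replicate arrays before descriptive clustering suppresses
    the per-array technical noise that otherwise blurs response classes
    with similar profiles (e.g. cooperative vs steroid-independent up).
    """
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("every array column needs a group label")
    return values.T.groupby(groups, sort=False).mean().T


@dataclass
class ResponseCall:
    """Per-clone response-class assignments with supporting evidence."""

    calls: pd.DataFrame  # response_class, rho and the supporting contrasts

    @property
    def classes(self) -> pd.Series:
        return self.calls["response_class"]


def classify_response(
    contrasts: pd.DataFrame,
    alpha: float = 0.05,
    rho_abolished: float = 0.25,
    rho_reduced: float = 0.75,
) -> ResponseCall:
    """Assign each clone to a response class from its factorial contrasts.

    Inputs are the per-clone effects and raw p-values of the three
    pairwise contrasts (``fsh_vs_ctrl``, ``fshtri_vs_tri``,
    ``tri_vs_ctrl``) plus the hormone x inhibitor interaction contrast.
    The reduction ratio is ``rho = (FshTri - Tri effect)/(Fsh - Ctrl
    effect)``, i.e. the fraction of the Fsh response that survives the
    inhibitor.

    Rules, in order:

    * Fsh response significant (up or down):

      - inhibitor response absent (not significant) or nearly so
        (``rho < rho_abolished``): steroid-mediated, abolished (1a);
      - ``rho < rho_reduced`` *and* the interaction contrast shows a
        significant reduction of the response: steroid-mediated,
        reduced (1b) — "significantly reduced" is a pairwise-test claim,
        so the ratio alone is not enough;
      - up-regulated with a significant *negative* inhibitor-alone effect
        (basal lowered when steroids are blocked): cooperative (3);
      - otherwise the response is maintained: steroid-independent
        (2 when up, 5 when down; a significant opposite-sign response
        under the inhibitor is left unclassified).

    * Fsh response not significant but both the inhibitor-alone and the
      under-inhibitor Fsh responses are significantly up: antagonistic
      (4) — steroids mask an Fsh effect that the inhibitor unveils.

    * anything else: unclassified.
    """
    required = [
        "fsh_vs_ctrl_effect", "fsh_vs_ctrl_p",
        "fshtri_vs_tri_effect", "fshtri_vs_tri_p",
        "tri_vs_ctrl_effect", "tri_vs_ctrl_p",
        "interaction_effect", "interaction_p",
    ]
    missing = [c for c in required if c not in contrasts.columns]
    if missing:
        raise ValueError(f"contrast table is missing columns: {missing}")

    f = contrasts["fsh_vs_ctrl_effect"].to_numpy(dtype=float)
    pf = contrasts["fsh_vs_ctrl_p"].to_numpy(dtype=float)
    ft = contrasts["fshtri_vs_tri_effect"].to_numpy(dtype=float)
    pft = contrasts["fshtri_vs_tri_p"].to_numpy(dtype=float)
    tc = contrasts["tri_vs_ctrl_effect"].to_numpy(dtype=float)
    ptc = contrasts["tri_vs_ctrl_p"].to_numpy(dtype=float)
    dint = contrasts["interaction_effect"].to_numpy(dtype=float)
    pint = contrasts["interaction_p"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(f != 0, ft / np.where(f != 0, f, 1.0), np.nan)

    sig_f = pf < alpha
    up = sig_f & (f > 0)
    down = sig_f & (f < 0)
    sig_ft = pft < alpha
    # Reduction of the Fsh response magnitude is significant: for an
    # up-regulated clone the interaction (Fsh-Ctrl)-(FshTri-Tri) is
    # significantly positive, for a down-regulated clone significantly
    # negative.
    reduced_sig = (pint < alpha) & (np.sign(dint) == np.sign(f))
    same_sign_ft = sig_ft & (np.sign(ft) == np.sign(f))
    rho_low = np.where(np.isnan(rho), True, rho < rho_abolished)
    rho_mid = np.where(np.isnan(rho), False, rho < rho_reduced)

    labels = np.full(len(contrasts), "unclassified", dtype=object)
    antagonistic = (~sig_f) & (ptc < alpha) & (tc > 0) & sig_ft & (ft > 0)
    labels[antagonistic] = "antagonistic"

    responsive = up | down
    abolished = responsive & (~sig_ft | rho_low)
    labels[abolished] = "mediated_abolished"
    reduced = responsive & ~abolished & rho_mid & reduced_sig
    labels[reduced] = "mediated_reduced"
    rest = responsive & ~abolished & ~reduced
    # Maintained responses must keep the Fsh sign under the inhibitor.
    labels[rest & up & (ptc < alpha) & (tc < 0)] = "cooperative"
    labels[rest & up & ~((ptc < alpha) & (tc < 0)) & ~(sig_ft & (ft < 0))] = "independent_up"
    labels[rest & down & ~(sig_ft & (ft > 0))] = "independent_down"

    calls = pd.DataFrame(
        {
            "response_class": labels,
            "rho": rho,
            "fsh_vs_ctrl_effect": f,
            "fsh_vs_ctrl_p": pf,
            "fshtri_vs_tri_effect": ft,
            "fshtri_vs_tri_p": pft,
            "tri_vs_ctrl_effect": tc,
            "tri_vs_ctrl_p": ptc,
            "interaction_effect": dint,
            "interaction_p": pint,
        },
        index=contrasts.index,
    )
    return ResponseCall(calls=calls)


def plot_heatmap(
    values: pd.DataFrame,
    order: np.ndarray | None = None,
    path: str | None = None,
    center: bool = True,
):
    """Cluster-ordered heatmap of clones x arrays (display helper).

    Rows are median-centered by default, matching the usual expression
    heatmap convention; the analysis itself never uses centered values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = median_center_rows(values) if center else values
    if order is not None:
        mat = mat.iloc[order]
    fig, ax = plt.subplots(figsize=(6, 8))
    vmax = float(np.abs(mat.to_numpy()).max()) or 1.0
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.5, label="log2 expression (row-centered)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
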