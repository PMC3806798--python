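"""Synthetic factorial macroarray experiments with planted ground truth.

The generator emulates the statistical structure of an organotypic-culture
macroarray study: four treatment groups (Ctrl, Fsh, Tri, FshTri) with six
replicate arrays each, spot-level sample and vector-oligo signals, an
additive raw-scale background, log-normal spot-amount variation, planted
log2 treatment effects organized into response classes, and a fraction of
non-informative spots with deficient vector signal.  Companion generators
produce the endocrine endpoint data: an androgen (11KT) concentration
series censored at the assay sensitivity, and duplicate-well qPCR Ct
tables with a reference gene.

Every generator is deterministic under a fixed seed, and each returns the
planted truth needed by recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GROUPS, RESPONSE_CLASSES, class_pattern
from .preprocess import RawArraySet

__all__ = [
    "SyntheticDesign",
    "SteroidSeriesParams",
    "generate_array_experiment",
    "generate_steroid_series",
    "generate_qpcr_dataset",
    "QpcrDataset",
]

#: Default planted class mix: mostly unresponsive clones, the responsive
#: minority spread over the six response classes.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "null": 0.85,
    "mediated_abolished": 0.03,
    "mediated_reduced": 0.03,
    "independent_up": 0.03,
    "independent_down": 0.02,
    "cooperative": 0.02,
    "antagonistic": 0.02,
}


@dataclass
class SyntheticDesign:
    """Parameters of a synthetic factorial array experiment.

    Attributes
    ----------
    n_clones:
        Number of spotted clones.
    groups:
        Ordered treatment labels (the 2x2 hormone x inhibitor design).
    n_replicates_per_group:
        Replicate arrays per group (six culture wells per treatment).
    class_proportions:
        Fraction of clones planted in each response class; must sum to 1.
    effect_size_log2:
        Magnitude of planted treatment effects on the log2 scale.
    residual_sd_log2:
        Within-group biological + technical noise SD (log2 scale).
    baseline_log2_mean / baseline_log2_sd:
        Distribution of per-clone basal expression (log2 scale).
    vector_signal_median / vector_signal_log_sd:
        Log-normal law of the per-spot spotted-cDNA amount.
    vector_jitter_sd:
        Small across-array log-scale jitter of the vector signal.
    background_level:
        Mean of the additive raw-scale background (0 disables background).
    frac_noninformative:
        Fraction of spots with deficient vector signal (< 3x background
        in more than 20% of arrays); requires a positive background.
    seed:
        RNG seed; fixed seed gives byte-identical outputs.
    """

    n_clones: int = 1000
    groups: tuple[str, ...] = GROUPS
    n_replicates_per_group: int = 6
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size_log2: float = 1.0
    residual_sd_log2: float = 0.3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    vector_signal_median: float = 1000.0
    vector_signal_log_sd: float = 0.5
    vector_jitter_sd: float = 0.05
    background_level: float = 20.0
    frac_noninformative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicate arrays per group")
        unknown = set(self.class_proportions) - set(RESPONSE_CLASSES)
        if unknown:
            raise ValueError(f"unknown response classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total!r}, not 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        for name in ("residual_sd_log2", "vector_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vector_signal_median <= 0 or self.vector_signal_log_sd <= 0:
            raise ValueError("vector signal law needs positive location and scale")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not 0.0 <= self.frac_noninformative <= 1.0:
            raise ValueError("frac_noninformative must lie in [0, 1]")
        if self.frac_noninformative > 0 and self.background_level <= 0:
            raise ValueError("non-informative spots need a positive background level")


def generate_array_experiment(design: SyntheticDesign) -> tuple[RawArraySet, pd.DataFrame]:
    """Simulate a factorial array experiment and its ground truth.

    Raw signals follow ``Si = background noise + Vi * 2**mu`` where ``mu``
    is the planted log2 expression (baseline + class pattern + residual
    noise) and ``Vi`` is the per-spot vector signal, shared across arrays
    up to a small log-scale jitter.  Non-informative spots have their
    vector signal deflated below 3x background in a random subset of more
    than 20% of the arrays.

    Returns the :class:`~fshtri.preprocess.RawArraySet` and a ground-truth
    table (one row per clone: ``response_class``, ``informative`` and the
    true log2 group means).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_clones
    groups = list(design.groups)
    reps = design.n_replicates_per_group
    arrays = [f"{g}_{r + 1}" for g in groups for r in range(reps)]
    n_arrays = len(arrays)
    array_group = np.repeat(np.arange(len(groups)), reps)

    class_names = [c for c in RESPONSE_CLASSES if c in design.class_proportions]
    probs = np.array([design.class_proportions[c] for c in class_names], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(np.array(class_names, dtype=object), size=n, p=probs)

    patterns = {c: class_pattern(c, design.effect_size_log2) for c in class_names}
    offsets = np.stack([patterns[c] for c in classes])  # n x 4
    baseline = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, size=n)
    mu = baseline[:, None] + offsets  # n x n_groups (true log2 means)

    vi_base = rng.lognormal(math.log(design.vector_signal_median), design.vector_signal_log_sd, size=n)
    jitter = rng.normal(0.0, design.vector_jitter_sd, size=(n, n_arrays)) if design.vector_jitter_sd > 0 else np.zeros((n, n_arrays))
    vi = vi_base[:, None] * np.exp(jitter)

    if design.background_level > 0:
        bg_levels = design.background_level * rng.uniform(0.8, 1.2, size=n_arrays)
        bg_noise = rng.gamma(2.0, bg_levels / 2.0, size=(n, n_arrays))
    else:
        bg_levels = np.zeros(n_arrays)
        bg_noise = np.zeros((n, n_arrays))

    informative = np.ones(n, dtype=bool)
    if design.frac_noninformative > 0:
        bad = rng.random(n) < design.frac_noninformative
        informative = ~bad
        low = math.floor(0.2 * n_arrays) + 1  # strictly more than 20% of arrays
        high = max(low, math.ceil(0.5 * n_arrays))
        for g in np.flatnonzero(bad):
            n_bad = int(rng.integers(low, high + 1))
            cols = rng.choice(n_arrays, size=n_bad, replace=False)
            vi[g, cols] = rng.uniform(0.2, 0.9, size=n_bad) * 3.0 * bg_levels[cols]

    expr_log2 = mu[:, array_group]
    if design.residual_sd_log2 > 0:
        expr_log2 = expr_log2 + rng.normal(0.0, design.residual_sd_log2, size=(n, n_arrays))
    si = bg_noise + vi * np.exp2(expr_log2)

    clones = [f"clone_{i + 1:05d}" for i in range(n)]
    sample_signal = pd.DataFrame(si, index=clones, columns=arrays)
    vector_signal = pd.DataFrame(vi, index=clones, columns=arrays)
    background = pd.Series(bg_levels, index=arrays, name="background")
    sample_sheet = pd.DataFrame(
        {
            "group": [groups[i] for i in array_group],
            "batch": "exp1",
            "replicate": [r + 1 for _ in groups for r in range(reps)],
        },
        index=pd.Index(arrays, name="array"),
    )
    raw = RawArraySet(sample_signal, vector_signal, background, sample_sheet)
    truth = pd.DataFrame(
        {
            "response_class": classes,
            "informative": informative,
            **{f"mu_{g}": mu[:, i] for i, g in enumerate(groups)},
        },
        index=pd.Index(clones, name="clone"),
    )
    return raw, truth


@dataclass
class SteroidSeriesParams:
    """Parameters of the simulated androgen (11KT) concentration series.

    Defaults reproduce the endpoint structure of the culture experiment:
    two 48-hour periods, a ~5-fold Fsh stimulation, strong per-period
    trilostane suppression of both basal and stimulated production, and
    replicate scatter comparable to the assay's variability.  Values below
    the assay sensitivity (0.08 ng/mL) are censored at the bound.
    """

    basal_level: tuple[float, ...] = (10.0, 26.8)  # ng/mL per period
    fsh_fold: float = 5.0
    tri_inhibition_frac: tuple[float, ...] = (0.86, 0.93)  # per period
    assay_sensitivity: float = 0.08  # ng/mL
    replicate_cv: float = 0.11
    duplicate_cv: float = 0.06
    n_replicates: int = 6
    periods: tuple[str, ...] = ("0-48h", "48-96h")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.basal_level) != len(self.periods) or len(self.tri_inhibition_frac) != len(self.periods):
            raise ValueError("basal_level and tri_inhibition_frac need one value per period")
        if any(b < 0 for b in self.basal_level):
            raise ValueError("concentrations must be >= 0")
        if any(not 0.0 <= f <= 1.0 for f in self.tri_inhibition_frac):
            raise ValueError("inhibition fractions must lie in [0, 1]")
        if self.fsh_fold <= 0 or self.assay_sensitivity < 0:
            raise ValueError("fsh_fold must be positive and sensitivity non-negative")
        if self.replicate_cv < 0 or self.duplicate_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV (exact at cv=0)."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size=size)


def generate_steroid_series(params: SteroidSeriesParams) -> pd.DataFrame:
    """Simulate the per-well 11KT concentration series.

    Returns a long table with one row per duplicate assay measurement:
    ``treatment``, ``period``, ``replicate``, ``duplicate``,
    ``concentration`` (ng/mL) and a ``censored`` flag set when the
    generated value fell below the assay sensitivity and was reported at
    the bound.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for p_idx, period in enumerate(params.periods):
        basal = params.basal_level[p_idx]
        keep = 1.0 - params.tri_inhibition_frac[p_idx]
        means = {
            "Ctrl": basal,
            "Fsh": basal * params.fsh_fold,
            "Tri": basal * keep,
            "FshTri": basal * params.fsh_fold * keep,
        }
        for treatment, mean in means.items():
            rep_values = mean * _lognormal_noise(rng, params.replicate_cv, params.n_replicates)
            for r, rep_value in enumerate(rep_values, start=1):
                dups = rep_value * _lognormal_noise(rng, params.duplicate_cv, 2)
                for d, value in enumerate(dups, start=1):
                    censored = value < params.assay_sensitivity
                    rows.append(
                        {
                            "treatment": treatment,
                            "period": period,
                            "replicate": r,
                            "duplicate": d,
                            "concentration": params.assay_sensitivity if censored else float(value),
                            "censored": bool(censored),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class QpcrDataset:
    """Long Ct table (one row per technical duplicate) plus planted truth."""

    records: pd.DataFrame  # sample, group, gene, duplicate, ct
    reference_gene: str
    planted_log2fc: pd.DataFrame  # genes x groups true log2 fold changes


def generate_qpcr_dataset(
    n_genes: int = 4,
    groups: tuple[str, ...] = GROUPS,
    planted_log2fc: float | dict[str, dict[str, float]] = 0.0,
    reference_stable: bool = True,
    n_replicates: int = 6,
    ct_sd: float = 0.15,
    duplicate_sd: float = 0.1,
    reference_gene: str = "rps15",
    seed: int = 0,
) -> QpcrDataset:
    """Simulate duplicate-well qPCR Ct tables with a reference gene.

    A planted log2 fold change ``f`` for (gene, group) lowers the target
    gene's Ct by ``f`` relative to the reference in that group, so the
    delta-Ct chain recovers ``2**f`` downstream.  ``planted_log2fc`` is
    either a scalar (applied to the Fsh group of every target gene) or a
    nested mapping ``gene -> group -> log2fc``; the first group is the
    reference condition (fold change 0 by construction).  When
    ``reference_stable`` the reference gene's expected Ct is constant
    across groups; otherwise it drifts per group (a deliberately broken
    reference for sensitivity checks).
    """
    if n_genes < 1:
        raise ValueError("need at least one target gene")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1:02d}" for i in range(n_genes)]
    fc = pd.DataFrame(0.0, index=genes, columns=list(groups))
    if isinstance(planted_log2fc, dict):
        for gene, per_group in planted_log2fc.items():
            if gene not in fc.index:
                raise ValueError(f"unknown gene {gene!r} in planted_log2fc")
            for grp, val in per_group.items():
                if grp not in fc.columns:
                    raise ValueError(f"unknown group {grp!r} in planted_log2fc")
                fc.loc[gene, grp] = float(val)
    else:
        if "Fsh" in fc.columns:
            fc.loc[:, "Fsh"] = float(planted_log2fc)

    ref_base = 20.0
    gene_base = rng.uniform(22.0, 28.0, size=n_genes)
    ref_drift = (
        np.zeros(len(groups)) if reference_stable else rng.normal(0.0, 0.5, size=len(groups))
    )
    rows = []
    for g_idx, group in enumerate(groups):
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_{rep}"
            sample_shift = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
            expected = {reference_gene: ref_base + ref_drift[g_idx] + sample_shift}
            for i, gene in enumerate(genes):
                expected[gene] = gene_base[i] - fc.loc[gene, group] + sample_shift
            for gene, e_ct in expected.items():
                noise = rng.normal(0.0, duplicate_sd, size=2) if duplicate_sd > 0 else np.zeros(2)
                for d in (1, 2):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "duplicate": d,
                            "ct": float(e_ct + noise[d - 1]),
                        }
                    )
    records = pd.DataFrame(rows)
    return QpcrDataset(records=records, reference_gene=reference_gene, planted_log2fc=fc)
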