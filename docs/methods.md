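# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data experiments do and do not
establish.

## The design and its logic

Testis explants are incubated under four conditions: control, Fsh,
trilostane, and Fsh + trilostane. Trilostane blocks 3β-HSD and hence the
synthesis of Δ4-steroids (testosterone, 11-ketotestosterone, DHP,
estradiol). For each clone the three informative contrasts are

* `Fsh − Ctrl` — the hormone response with steroidogenesis intact,
* `FshTri − Tri` — the hormone response with steroidogenesis blocked,
* `Tri − Ctrl` — the effect of removing basal steroid tone.

A steroid-mediated response is present in the first contrast and absent
(or reduced) in the second; a steroid-independent response survives both.
The additional patterns — basal expression lowered by the inhibitor alone
(cooperative) or an Fsh effect visible *only* under the inhibitor
(antagonistic) — complete the class taxonomy
(1a abolished, 1b reduced, 2 independent-up, 3 cooperative,
4 antagonistic, 5 independent-down).

## Normalization

Raw spot signals from nylon macroarrays confound expression with the
amount of cDNA deposited per spot. The vector-oligo signal `Vi` measures
that amount, so the corrected intensity is `(Si/Vi)·medVi`, where
`medVi` is the per-spot median vector signal across arrays. The rescaling
by `medVi` keeps between-spot intensity ratios meaningful; the operation
is exactly invariant to rescaling one spot's `Vi` on all arrays, and
fixes expression only up to a per-spot constant (group *differences* are
recovered exactly on noise-free data; absolute levels carry the spot's
amount constant — this is why recovery tests compare contrasts).

Values are floored at the smallest positive entry before the log2
transform (zeros never produce −∞). Quantile normalization then replaces
each value by the across-array mean of the values at its rank, with ties
receiving the mean of the reference values they span; the rank statistic
(mean by default, median optional) is configurable because the dialect of
the original software is not documented. The step is idempotent and makes
every column's empirical distribution identical. Quantile normalization
is only distribution-preserving when the differentially expressed
fraction is small; the tests deliberately keep the responsive minority at
realistic levels (~5 %) because at tens of percent the step visibly
removes planted shifts — a property of the method, not an implementation
artifact.

Order of operations is fixed: vector correction → log2 → quantile.

## Clone filtering

Three independent flags, applied as a cascade:

1. **Informativeness** (raw scale, before normalization — the only
   self-consistent placement, since it consumes raw `Vi` and the
   background, and vector correction cannot divide by the deficient
   signals it flags): a clone is removed iff `Vi < 3×background` on
   strictly more than 20 % of arrays. Both inequalities are strict, as
   printed in the rule; boundary cases are pinned by tests. Background is
   a per-array scalar by default (a per-spot matrix is accepted; the
   per-array global estimate is the default because the original
   estimation procedure is not documented).
2. **Expression level**: maximum group mean ≥ the median of every value
   of the (informative-clone) matrix; equality keeps the clone.
3. **Fold change**: |mean log2 difference| ≥ log2(1.5) on `Fsh − Ctrl`
   or `FshTri − Tri`, direction-agnostic, inclusive bound. Fold change is
   a difference of group means of log2 values, matching the linear-model
   effect sizes downstream.

Stages 2 and 3 are computed on the same informative-clone matrix and are
mutually independent, so their order never changes the retained set.

## Moderated statistics

Per clone, a one-way group-means fit gives means, pooled residual
variance `s²_g` and residual df `d = n_arrays − n_groups`. The
empirical-Bayes model places a scaled inverse-χ² prior on the true
variances: `s²_g|σ²_g ~ σ²_g χ²_d/d` and `1/σ²_g ~ χ²_{d₀}/(d₀s₀²)`.
With `e_g = log s²_g − ψ(d/2) + log(d/2)`, the model implies
`E[e] = log s₀² − ψ(d₀/2) + log(d₀/2)` and
`Var[e] = ψ′(d/2) + ψ′(d₀/2)`, so the excess of the sample variance of
`e` over `ψ′(d/2)` identifies `d₀` through a trigamma inverse (Newton
iteration from the asymptotic start `x = 1/2 + 1/y`, 1e-12 relative
tolerance). Numerical choices:

* zero sample variances are floored at 1e-12 before the log;
* non-positive excess spread means a degenerate prior: `d₀ = ∞` and
  `s₀²` estimated by the plain average of the `s²_g` (the moment
  estimator for that branch); every posterior variance then equals `s₀²`
  and test references become normal / scaled-χ²;
* `d₀` can be forced: 0 recovers the classical unmoderated statistics
  (verified to 1e-10 against the pooled two-sample t), ∞ pools fully.

Posterior variances are `s̃² = (d₀s₀² + d·s²)/(d₀+d)`; moderated t uses
`d₀+d` df; the omnibus moderated F is `MS_between/s̃²` on
`(k−1, d₀+d)` df. Multiplicity uses Benjamini–Hochberg
(`q_(i) = min_{j≥i} p_(j)·m/j`). The headline list is the omnibus F at
`q ≤ 0.01` on clones surviving the cascade; pairwise gates use raw
two-sided p-values at 0.05, mirroring the distinction between the
FDR-controlled discovery list and the per-contrast claims.

On 200 variances simulated from the prior (`d₀ = 4, s₀² = 1, d = 20`)
the moment estimator recovers the hyperparameters to within (±1.5, ±0.3)
averaged over 20 seeds, and under a global null (1000 clones, 4×6
design) the realized false-discovery proportion at `q ≤ 0.01` stays
within the BH bound over 50 simulations.

## Response-class calling

Classification is rule-based on the contrasts — clustering is
descriptive only, and never feeds the class labels. The reduction ratio
is `ρ = (FshTri−Tri)/(Fsh−Ctrl)`, the surviving fraction of the
response; the gates `ρ < 0.25` (abolished) and `ρ < 0.75` (reduced) are
a quantitative rendering of what was originally visual cluster
membership, and are exposed as parameters.

For a significant Fsh response: no significant response under the
inhibitor (or `ρ < 0.25`) → abolished (1a); `ρ < 0.75` *and* a
significant hormone×inhibitor interaction in the reducing direction →
reduced (1b); up-regulated with a significantly negative `Tri − Ctrl` →
cooperative (3); otherwise maintained → independent (2 up / 5 down).
Without a significant Fsh response, significant positive `Tri − Ctrl`
and `FshTri − Tri` → antagonistic (4); anything else is unclassified.

The interaction-significance gate on 1b deserves a note: the "reduced"
category is a *significance* claim (a pairwise-test distinction between
abolished/reduced/maintained), and the raw ratio alone is far too noisy
at n = 6 — the ratio of two contrast estimates with SE ≈ 0.17 has
SE ≈ 0.24, so a pure `ρ < 0.75` gate mislabels ~12 % of genuinely
maintained responses as "reduced". With the gate, recovery of the
abolished / independent-up / independent-down / antagonistic classes
exceeds 95 % under the reference conditions (effect 1.0 log2, residual
SD 0.3, 6 replicates), while the intrinsically boundary-shaped
mediated-reduced class confuses only with its ρ-neighbours (1a and 2).

## Clustering

Distance is uncentered Pearson, `d = 1 − Σxy/√(Σx²·Σy²)` ∈ [0, 2]:
zero iff positively proportional, 2 for anti-proportional vectors, and
undefined (hard error) on zero vectors. Linkage is average by default
(single/complete available); scipy's deterministic tie-break (lowest
index pair merges first) applies. Rows are median-centered for display
only — the distance itself is computed on whatever matrix is handed in,
and uncentered Pearson is scale- but not shift-invariant, so centering
is a substantive choice the caller makes.

For class-recovery purposes the package clusters per-clone
*treatment-mean* profiles (`group_mean_profiles`) rather than per-array
values: replicate averaging suppresses the per-array noise that
otherwise blurs structurally similar classes. The cooperative and
independent-up patterns have uncentered correlation 0.87 by construction
— and the similarity is scale-invariant, so larger effects do not
separate them; at per-array noise SD 0.3 average linkage merges the two
classes (agreement plateaus near ARI 0.78), whereas on treatment means a
5-way cut recovers the five main planted classes at ARI ≥ 0.9.

## Meta-analysis

Two experiments hybridized on different membrane batches carry per-gene
additive offsets. For every shared gene, experiment 1's arrays are
median-centered and shifted onto experiment 2's row median; experiment 2
is the reference frame and is returned unchanged. After the operation the
per-gene batch medians are exactly equal and re-application is a no-op.
A symmetric variant (both batches to the pooled median) would also be
defensible; anchoring on the reference experiment was chosen so the
combined display stays in that study's scale. Lh responsiveness is
consumed as an external per-clone annotation (it was established by the
reference experiment, not recomputed here); concordance between
trilostane sensitivity and Lh regulation is tested by Fisher's exact
test on the collapsed 2×2 table.

## Endocrine and qPCR endpoints

Duplicate assay measurements (RIA duplicates, qPCR technical duplicates)
are always averaged before replicate-level statistics. Percent
inhibition is `100·(1 − treated/reference)` on group means (flagged
undefined when the reference mean is zero; scale-invariant). The
steroid generator uses per-period basal levels (10.0 and 26.8 ng/mL), a
5-fold Fsh stimulation and per-period inhibitor suppression fractions
(0.86, 0.93) so the noise-free end-of-culture means are 134 and
9.38 ng/mL; replicate CV 0.11 and duplicate CV 0.06 match the assay's
reported inter/intra variability, and values below the 0.08 ng/mL assay
sensitivity are reported at the bound with a censored flag, not dropped.

The Mann–Whitney U test enumerates the full permutation distribution
(all `C(n, n_a)` assignments, mid-ranks for ties) whenever
`n_a + n_b ≤ 20`, counting arrangements with `|U − n_a n_b/2|` at least
the observed (two-sided); larger samples use the normal approximation
with tie and continuity corrections. Kruskal–Wallis (scipy, tie-corrected,
χ² reference; the all-ties case returns H = 0, p = 1 explicitly) gates
the pairwise U tests at p < 0.05 — pairwise tests never run when the
omnibus is non-significant. Group differences are summarized as a
compact letter display built by deterministic insert-and-absorb on the
significance graph.

qPCR quantification is the efficiency-corrected ΔCt model
`level = E^(Ct_ref − Ct_target)` with E = 2 by default (configurable in
(1, 2]; amplification efficiency was verified but not reported, so
perfect doubling is the interpretation). The reference gene (`rps15`)
must be measured in every sample; levels are invariant to adding a
constant to both Ct values.

## Synthetic generators — what they emulate and what they do not

The array generator produces `Si = background + Vi·2^μ` with per-spot
log-normal `Vi` (median 1000, log-SD 0.5, 5 % across-array jitter),
per-array background levels (uniform ±20 % around the nominal mean,
gamma-distributed additive noise), Gaussian log2 residuals, baseline
expression N(8, 1), and class-patterned group means. Non-informative
spots are made by deflating `Vi` below 3×background on a random 20–50 %
subset of arrays. Defaults mirror the study conditions: 4 groups × 6
replicate arrays, planted effect 1.0 log2, residual SD 0.3, and a
responsive minority (the default class mix is 85 % null; recovery
experiments use 94 % null, 1 % per class, matching the ~1–3 % responsive
fraction a real screen of this kind yields).

Not emulated: hybridization physics, phosphor-imaging point-spread,
radioactive decay, spatial artifacts, probe cross-hybridization, or
clone redundancy (several spots per gene). Passing recovery tests
therefore shows the *statistical* chain is correct under the declared
noise model, not that the pipeline is robust to spatially structured or
probe-specific artifacts in real membranes.

## Problem sizes

The test-suite simulations use 400–6000 clones, 24 arrays, 25–50 null
replicates and 3 seeds for recovery aggregates; the acceptance script
uses 30 null experiments of 1000 clones, three 6000-clone recovery
experiments and one 4000-clone end-to-end run. These sizes give
Monte-Carlo errors well inside the asserted margins while keeping a full
run in seconds.

## Known limitations

* Missing values are unsupported; upstream filters must drop incomplete
  spots (zero `Vi` on a retained spot is a hard error by design).
* The moderated model assumes a common residual df across clones
  (complete data); unbalanced designs fit but the moment matching uses
  the shared df.
* The 1a/1b/2 boundaries are an interpretation of a visual taxonomy;
  the ρ thresholds (0.25/0.75) and the interaction gate are exposed
  parameters, and borderline clones legitimately move between 1a/1b/2
  under resampling.
* The exact U enumeration is O(C(n, n_a)) and capped at n ≤ 20 by
  default.
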