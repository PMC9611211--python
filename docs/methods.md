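# Methods

This note documents the statistical procedures, the synthetic-data
generators that stand in for laboratory measurements, and the design
choices made where the methodology was genuinely open.

## Composite treatment-efficiency scoring

**Data model.** The input is a long table of removal fractions
A ∈ [0, 1] keyed by (system, pollutant, day, replicate). Observations for
the correlation matrix are formed either as replicate means per
(system, day) — the default, since replicate noise is measurement noise
rather than treatment signal — or with every replicate as its own row
(`aggregate="none"`).

**Correlation and adequacy.** Pearson correlations are used, the
convention for factor analysis of continuous indicators. KMO is computed
from the anti-image partial correlations q_ij = −(R⁻¹)_ij /
√((R⁻¹)_ii (R⁻¹)_jj) as Σ r² / (Σ r² + Σ q²) over off-diagonal entries;
Bartlett's sphericity statistic is −(n − 1 − (2p + 5)/6)·ln det R on
p(p−1)/2 degrees of freedom. Both are reported as diagnostics and warn
(KMO ≤ 0.6, Bartlett p > 0.05) rather than abort: they are applicability
checks, not estimation steps.

**Extraction and rotation.** Principal-component factoring: column j of
the unrotated loading matrix is eigvec_j·√λ_j, with each column's sign
fixed so its largest-magnitude entry is positive (ties broken by first
index). Retention is Kaiser's λ > 1 by default, or a fixed k. Rotation
maximises the unnormalised varimax criterion
Σ_j [Σ_i ℓ⁴_ij − (Σ_i ℓ²_ij)²/p] using Kaiser's pairwise algorithm: for
every column pair the closed-form optimal angle
φ = ¼·atan2(D − 2AB/p, C − (A² − B²)/p) (with u = x² − y², v = 2xy,
A = Σu, B = Σv, C = Σ(u² − v²), D = 2Σuv) is applied, and sweeps repeat
until the largest angle falls below 10⁻¹². An SVD fixed-point iteration
was tried first and found to stall far from the optimum on two-factor
problems; the pairwise algorithm matches a 0.01°-grid-search oracle to
≤ 5·10⁻⁸ in criterion value in the test suite. Kaiser row normalisation
is off by default (`row_normalize=True` enables it); rotated columns are
reordered by descending sum of squared loadings and sign-fixed again.

**Weights.** The factor weight T_j is the share of post-rotation explained
variance: T_j = SS_j / Σ SS with SS_j the column sum of squared rotated
loadings. Interpreting the "variance contribution" post-rotation (rather
than as initial eigenvalue shares) is deliberate: it is the quantity that
the rotated loading matrix actually distributes over factors, and it is
the only reading under which the published factor weights (0.569/0.431)
and all six published indicator weights are reproduced from the published
loading matrix to ±0.001. The indicator weight combines each factor's
weight with the within-factor L1-normalised loadings,
B_i = Σ_j T_j · ℓ_ij / Σ_i ℓ_ij, which guarantees Σ B_i = 1. A "literal"
combination (B ∝ Σ_j T_j ℓ_ij, then normalised) is also implemented for
comparison but does not reproduce the published weight table; the
normalised form is the default. Loadings that remain negative after
sign-fixing are used in absolute value with a warning.

**Score.** E = Σ A_i B_i per (system, day); with fractional removals and
normalised non-negative weights, E ∈ [0, 1] and is monotone in every
indicator.

## Alpha diversity

Observed taxa, Chao1, Shannon, Gini–Simpson and Good's coverage, on raw
counts without rarefaction. Choices: Chao1 uses the classic
S + F1²/(2F2) with the bias-corrected S + F1(F1−1)/(2(F2+1)) fallback
when no doubletons exist; Shannon uses the natural log (ecology default;
`base` overridable); "Simpson" is reported as Gini–Simpson 1 − Σp², the
variant consistent with values near 0.99 for diverse communities. Group
comparisons attach compact letters from one-way ANOVA + Tukey HSD at
α = 0.05 when every group has ≥ 2 replicate samples; with zero
within-group variance the letter display degenerates to grouping by
distinct means.

## Beta diversity and differential abundance

**Bray–Curtis** on column-normalised relative abundances,
d = 1 − 2Σ min(u, v)/(Σu + Σv). It is the standard abundance-weighted
ecological dissimilarity and needs no phylogeny (no tree is available at
the genus/phylum aggregation level this pipeline works at).

**UPGMA** merges the closest cluster pair; the new cluster's distance to
the rest is the size-weighted mean of member distances, merge height is
d/2 (so cophenetic distance = 2·height), and distance ties are broken by
the lexicographically smallest pair of sorted leaf tuples, making the
dendrogram deterministic. Output trees are ultrametric by construction
and are written as Newick with branch lengths.

**Kruskal–Wallis** uses midranks with tie correction. For pooled n ≤ 8
the p-value is exact by complete enumeration of group assignments;
beyond that the χ² approximation with df = groups − 1 is used. At n = 9
the approximation tracks enumeration closely in the small-p tail (the
regime that decides significance) but can deviate by more than 0.05 in
the body of the null distribution — a known property of the χ²
approximation at this sample size, stated here so screen p-values near
0.5 are not over-interpreted.

**LEfSe-style effect size.** The published LEfSe algorithm is
under-specified at the effect-size step, so this implementation fixes a
documented variant rather than attempting a bit-exact clone: relative
abundances are scaled to 10⁶; features pass an unadjusted Kruskal–Wallis
screen at α (unadjusted, matching the original tool's convention); for
each survivor a two-class comparison (its top-mean group vs the rest) is
bootstrapped 30 times, fitting a ridge-regularised Fisher discriminant
on the surviving features; the per-resample effect is
|w_f·s + Δ_f|/2 with w the unit discriminant axis, s the projected
class-mean separation and Δ_f the raw class-mean difference; the score
is log₁₀(max(mean effect, 1)) and features at score ≥ 2 (default) are
reported. The subclass-consistency step of the original tool is omitted
(no subclass structure in this design). All resampling is seeded. Note a
small-sample interaction worth knowing: with 3 replicates per group and
two groups, the exact Kruskal–Wallis p cannot fall below 0.1, so the
screen at α = 0.05 reports nothing — null behaviour is therefore
characterised in tests at 10 replicates per class, where the per-feature
false-report rate stays at the screen's nominal level (≤ 0.1).

**Phylum shifts** are percentage-point differences of mean relative
abundance between two groups with two-sided rank-sum tests and BH-FDR
across taxa; the deltas sum to zero by compositionality.

## Correlations and networks

Spearman by default (robust to monotone distortions of compositional
abundances; Pearson by flag). For n ≤ 7 pairs the two-sided p is exact by
enumeration of rank permutations, otherwise the t-approximation. The
taxon × variable grid gets BH adjustment; the significance flag follows
raw p < 0.05 (both columns are emitted). Network edges require
|rho| ≥ 0.6 and p < 0.05 by default (a common microbiome-network
convention, configurable); node sizes carry mean relative abundance or
mean concentration; output is GraphML plus an edge-list TSV. Layout is
left to the viewer.

## Biomass conversion

biomass (mg/L) = 4021.9·OD₆₈₀ − 8.6817, overridable for other strains or
instruments. The intercept is a fit artifact of the calibration line, so
predictions below zero (OD ≲ 0.0022) are clipped to 0 with a warning
rather than extrapolated. Final-day system comparisons reuse the
ANOVA + Tukey letter display.

## Synthetic data

The generators emulate the *structure* of the study conditions — 6
systems × 6 pollutants × 7 days × 3 replicates, multi-group communities
with planted fold-changes, logistic algal growth — not any particular
measured dataset.

**Removal kinetics** follow r(d) = r_max(1 − e^{−kd}) + ε,
ε ~ N(0, 0.02²) truncated to [0, 1]: the simplest two-parameter form
that rises quickly and then levels off, matching removal dynamics that
slow after day 5. The default calibration pins the noise-free day-7
value of each (system, pollutant) to the study's final removal rates
(entries without a reference value default to 0.85) with k = 0.5/day.
Two endpoints — the near-complete antibiotic removals of the pure-algae
systems (0.9876, 0.9884) — exceed what r_max ≤ 1 can reach at k = 0.5 by
day 7; for those the asymptote is pinned at 1 and k = −ln(1 − target)/7,
which reproduces the endpoint exactly while saturating faster
(physically: removal approaching completion).

**Communities**: per group the expected composition is
softmax(base log-abundances + ln2·planted log2 effects) with base
log-abundances N(0, 1); replicate counts are multinomial at depth 10⁵
(Dirichlet-multinomial overdispersion optional). The default fixture has
20 taxa across 7 phyla, 5 groups (baseline + 4 treatments, 3 replicates
each — the study's replicate count), phylum-level directional effects
(Firmicutes up in T1/T2, Proteobacteria/Bacteroidetes up in T5/T6,
oligotroph phyla down everywhere) and one +3 log2 marker genus per
treated group. Tests verify the planted directions and marker-group
assignments are recovered downstream.

**Growth**: logistic OD₆₈₀ with carrying capacity and an early-phase
suppression — before `lag` days effective time accumulates at
(1 − lag_inhibition) of real time, modelling antibiotic stress before
adaptation. Defaults order the four algal systems ASG > AS > AG > A in
both carrying capacity and (inversely) suppression.

**Planted factors**: for factor-recovery tests, six indicators are
generated from a known 6 × 2 loading matrix ({COD, NO₃-N, CED} on factor
1 and {TP, TN, NH₄-N} on factor 2; primary loading 0.85, cross-loading
0.2) plus independent uniqueness, then mapped affinely into [0, 1]
(0.55 + 0.1x, clipped at 0.001/0.999) so correlations are preserved. At
n = 500 observations the pipeline retains exactly two factors and the
varimax-rotated loadings reach Tucker congruence ≥ 0.95 with the planted
matrix across seeds.

**What passing tests do and do not show.** The synthetic communities are
compositionally simple (few taxa, log-normal-free baseline, no
phylogenetic correlation, no copy-number bias) and the removal noise is
homoscedastic Gaussian; passing tests demonstrate correctness of the
estimators and recovery of planted structure under the assumed model,
not robustness to the messiness of real amplicon or chemistry data.
Published alpha-diversity values and dendrogram/cladogram topologies
depend on the raw sequencing reads and are not reproduction targets.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed; there is no
global random state. Simulation-based tests use 200 null seeds for the
differential-abundance false-report rate, 300 seeds for the
correlation-grid type-I check, depth 10⁶ for the Simpson limit check and
n = 500 × 5 seeds for factor recovery — sizes at which Monte-Carlo error
is well below the asserted tolerances while the whole suite runs in
about a minute.

## Known limitations

- Eigendecomposition factoring only (no ML or principal-axis factoring),
  orthogonal rotation only, no factor scores — the scoring chain needs
  none of them.
- The LEfSe-style score is a documented variant, not a clone; absolute
  scores are comparable within this tool, not across tools.
- No rarefaction or copy-number correction; indices are computed on the
  counts as given.
- The Kruskal–Wallis χ² branch is approximate just above the n = 8
  enumeration cutoff (see above).
- Weighted UniFrac-style phylogenetic beta diversity is out of scope (no
  tree at the aggregated ranks).
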