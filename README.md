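# cwevalkit

Analysis toolkit for **algae–bacteria constructed-wetland (CW) microcosms
treating antibiotic wastewater**: a factor-analysis-weighted composite
treatment score over six pollutant removal indicators, microbial community
response metrics (alpha diversity, Bray–Curtis/UPGMA beta diversity, a
LEfSe-style differential-genus procedure), genus–pollutant correlation
networks, and OD₆₈₀ → *Chlorella* biomass conversion. A seeded synthetic-data
module generates removal-kinetics, community-count and growth fixtures with
the statistical structure the analysis assumes, so every stage is testable
without raw measurements.

It is aimed at environmental engineers and microbial ecologists comparing CW
microcosm designs (sediment S, sediment+gravel SG, algae A, algae+gravel AG,
algae+sediment AS, algae+sediment+gravel ASG) on wastewater containing a
β-lactam antibiotic (cephradine, CED) alongside COD, TP, TN, NO₃⁻-N and
NH₄⁺-N.

## The model

Removal indicators are correlated, so a composite built from a plain mean
double-counts shared variance. The score is instead built from a factor
analysis of the indicator correlation matrix *R*:

1. **Adequacy diagnostics** — KMO sampling adequacy and Bartlett's
   sphericity test (χ² = −(n − 1 − (2p+5)/6)·ln det R).
2. **Extraction** — eigendecomposition of *R*; loadings λ_j^{1/2}·v_j;
   Kaiser retention (eigenvalue > 1).
3. **Varimax rotation** of the retained loadings (Kaiser's pairwise
   closed-form-angle algorithm).
4. **Factor weights** T_j = SS_j / Σ SS (shares of post-rotation explained
   variance, SS_j = column sum of squared rotated loadings).
5. **Indicator weights** B_i = Σ_j T_j · ℓ_ij / Σ_i ℓ_ij (factor weights
   distributed over indicators by within-factor L1-normalised loadings);
   Σ B_i = 1.
6. **Composite score** E = Σ_i A_i B_i per (system, day), with A_i the
   removal fractions in [0, 1].

Biomass uses the linear calibration *biomass* = 4021.9·OD₆₈₀ − 8.6817 mg/L.

## Worked example

```python
from cwevalkit import simulate as sim
from cwevalkit.scoring import score_pipeline

table = sim.simulate_removal(sim.default_calibration(seed=1))
res = score_pipeline(table)
print(res.summary())
```

prints (abridged)

```
Composite treatment-efficiency model
====================================================
observations: 42   indicators: 6   factors retained: 1
KMO sampling adequacy: 0.748
Bartlett sphericity:   chi2 = 520.82, df = 15, p = 2.22e-101
...
Indicator weights
COD     0.1806
TP      0.1611
TN      0.1734
NO3-N   0.1806
NH4-N   0.1370
CED     0.1673

Final-day composite scores
system
S     0.7837
SG    0.8129
A     0.7800
AG    0.8649
AS    0.8367
ASG   0.8433
```

KMO 0.748 (> 0.6) says the six indicators share enough correlation for
factor analysis; the day-7 composite scores summarise each microcosm's
overall treatment efficiency on the [0, 1] scale, here ranking the
gravel-bearing algal systems highest. (On this synthetic table all
indicators share one saturating time course, so a single factor is
retained; with the planted two-factor generator
`sim.simulate_planted_factors` the pipeline retains two.)

The same stages are scriptable from a shell:

```sh
cwevalkit --seed 7 --outdir out simulate --kind removal
cwevalkit --outdir out score --removal out/removal.tsv
cwevalkit --seed 7 --outdir out simulate --kind community
cwevalkit --outdir out diversity --counts out/counts.tsv
cwevalkit --outdir out compare --counts out/counts.tsv --rank genus
```

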