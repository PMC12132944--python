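# lwrbiomass

Literature-based estimation of fish individual biomass from
length–weight relationships (LWRs), with the concordance diagnostics
needed to decide *where the shortcut is trustworthy*.

## The problem

Ecosystem models need a typical individual biomass for every fish species
in a community, but field weighing is expensive and many survey datasets
only report densities. A common shortcut estimates each species' weight
from literature alone: take a representative body length — the General
Total Length (GTL), the midpoint of published min–max lengths or an
explicitly stated average — and push it through the allometric
length–weight relationship

```
W = a · TL^b        (TL in cm, W in g)
```

pooling published coefficient pairs per species as

```
a_rep = geometric mean of a_k        b_rep = arithmetic mean of b_k
```

The field-side reference is the surveyed individual biomass,
`biomass density (g/m²) / number density (ind/m²)`, one point per
species × month. Whether the shortcut works is scored by the coefficient
of determination **against the identity line y = x**
(`R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` with ŷ the estimate), which measures absolute
agreement and goes negative when estimates predict worse than the mean —
alongside the ordinary OLS R², which only measures trend consistency.
Two screens clean the comparison: points whose absolute residual exceeds
6× the median absolute residual (Q > 6, typically juvenile-dominated
records whose field mass is far below the species-typical estimate) are
excluded, and Cook's-distance influential points (default cutoff 4/n) are
removed from the regression.

The package implements the full pipeline — ingestion of the three input
tables, habitat stratification (freshwater-only / seawater-and-mudflat /
their union; mixed-habitat and unrecorded species are excluded), the six
dataset variants (3 scopes × raw/Q-filtered), and all diagnostics — plus a
synthetic fish-community generator so every stage is testable without the
original survey compilation.

## Worked example

```python
from lwrbiomass import (
    SpeciesProfile, LWRCoefficientRecord, FieldSurveyRecord,
    build_paired_points, build_variants, evaluate_variant,
)

profiles = [SpeciesProfile("Carp", frozenset({"freshwater"}), gtl_cm=20.0)]
coeffs = [LWRCoefficientRecord("Carp", a=0.01, b=3.0)]
survey = [FieldSurveyRecord("Carp", "06", biomass_density=160.0, number_density=2.0)]

points, drops = build_paired_points(survey, coeffs, profiles)
print(points[0].measured_g, points[0].estimated_g)
# 80.0 80.0   (160/2 g measured; 0.01 · 20³ = 80 g estimated)
```

End to end on a synthetic community (the `contaminated` scenario plants
juvenile recruitment pulses in a quarter of the survey records):

```
$ python analysis/02_run_concordance_study.py --seed 0
== contaminated (results/runs/contaminated) ==
  only_freshwater|raw              n= 192  R2(y=x)= +0.1536  R2(reg)=0.4373  slope= 0.5850  Q-removed=  0  influential=15
  only_freshwater|q_filtered       n= 140  R2(y=x)= +0.9922  R2(reg)=0.9922  slope= 0.9999  Q-removed= 52  influential=16
  ...
```

Reading the numbers: with juvenile-contaminated records present the
estimates disagree with the field weights in absolute terms (identity-line
R² = 0.15) even though some trend exists (OLS R² = 0.44); dropping the
Q > 6 points restores near-perfect absolute agreement (identity-line
R² = 0.99, slope ≈ 1.00). The paired-seed contrast
(`analysis/03_scenario_contrast.py`) shows the seawater-like regime —
wide length dispersion with an overstated GTL — scoring below the
freshwater-like regime on every seed, which is exactly the habitat
asymmetry the method's users need to respect.

A thin CLI wraps the same entry points:

```
lwrbiomass simulate --scenario contaminated --seed 0 --out results/simulated
lwrbiomass run --scenario contaminated --seed 0 --out results/run
lwrbiomass run --config run.yaml --q-threshold 6 --cooks-rule 4/n
```

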