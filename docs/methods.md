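# Methods

## Model and procedure

The estimation target is a single representative individual biomass per
fish species, obtained without weighing anything: a representative body
length (GTL) is pushed through the allometric length–weight relationship
`W = a · TL^b` (TL in cm, W in g — the convention of the coefficient
source databases; coefficients published for other length types or units
must be pre-converted). When a species has several published coefficient
pairs, they are pooled as

- `a_rep = exp(mean(ln a_k))` — the geometric mean, computed in log space
  because typical `a` values sit around 10⁻³–10⁻², and products of many
  such values underflow;
- `b_rep = mean(b_k)` — the arithmetic mean.

The geometric mean is scale-equivariant and never exceeds the arithmetic
mean; for a single-source species the pooled prediction equals that
source's own prediction exactly.

The GTL comes from literature with a fixed precedence: an explicitly
stated average length (typically a field guide) wins over the midpoint of
a reported min–max range, and a range whose backing sample size is known
and below 20 is considered unreliable and ineligible — species with no
eligible source are dropped with a logged reason rather than guessed at.

The field-side reference is `biomass density / number density`, computed
separately for each species × month record; each monthly value is a
distinct data point, never pooled across months before pairing.

## Validation design

Each (estimated, measured) pair enters one of three habitat scopes —
freshwater-only species, seawater/mudflat-only species, and their union
("whole"). Mixed-habitat species (any set touching both fresh and salt
water, or containing an estuary, including estuary-only species) and
species with no habitat record are excluded from all scopes: the method's
question is precisely whether habitat conditions the shortcut's validity,
so ambiguous species would blur the contrast. Each scope is analysed raw
and after outlier filtering, giving six dataset variants.

Agreement statistics per variant:

- **Identity-line R²** — `1 − Σ(y−ŷ)²/Σ(y−ȳ)²` with y the measured and ŷ
  the estimated weight. This is the decision statistic: it scores absolute
  agreement with y = x and is negative when the estimates predict worse
  than the measured mean. Undefined (error) when all measured values are
  identical.
- **Regression R², slope, intercept** — OLS of measured on estimated (the
  estimate on the x axis). Measures trend consistency only; because OLS
  minimizes SSE over all lines, identity-line R² ≤ regression R² always.
- **RMSE/MAE** — reported for both the identity model and the fitted line.
- **Q filter** — residuals are absolute differences in raw grams;
  MedAD is their median; `Q_i = |y_i − ŷ_i| / MedAD`; points with Q
  strictly greater than 6 are removed in a single pass (Q is not
  recomputed after removal). Raw-gram residuals are deliberate: a log
  residual would change which points exceed the threshold, and the screen
  is aimed at records whose absolute mass is far off (juvenile pulses).
  Degenerate cases: MedAD = 0 with some non-zero residual gives those
  points Q = +∞ (always removed); MedAD = 0 with all residuals zero gives
  all Q = 0. When the data agree to machine precision the Q scores are
  ratios of float noise and the filter may discard arbitrary points — this
  changes no statistic (R² stays 1) and is left as-is. Q scores are
  invariant under a common positive rescaling of the residuals.
- **Cook's distance** — computed per variant (influence depends on the
  point set) with the leverage closed form
  `D_i = e_i² h_ii / (p · MSE · (1−h_ii)²)`, p = 2, MSE from the full fit,
  which is algebraically identical to the deletion definition
  `Σ_j(ŷ_j − ŷ_{j(i)})² / (p · MSE)`; the test suite verifies the
  equivalence against brute-force leave-one-out refits to 1e-10 relative
  tolerance. The threshold is the conventional 4/n, single pass, exposed
  as a config knob (`cooks_cutoff`: "4/n", a number, or ("top_k", k)),
  since published analyses rarely state the cutoff they used. A fit
  perfect to machine precision (SSE ≤ 1e-20 · SST) yields all-zero
  distances rather than float-noise ratios.
- **Ordering** — Q filtering precedes influential-point removal; Cook's
  distances for a Q-filtered variant are computed on the Q-filtered set.
  The whole-species scope derives its own Q scores from the union's MedAD
  rather than inheriting per-scope decisions.
- **ln-scale IQR screen** — descriptive only: flags ln(weight) outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linear-interpolation quantiles
  (numpy's default); never removes data.

Variants with fewer than 4 points after filtering, or with degenerate
geometry (constant estimates, zero measured variance), produce reports
flagged `degenerate` with NaN statistics instead of raising, so parameter
sweeps never abort.

Species matching across the three input tables is exact on trimmed,
case-folded names; fuzzy joins are refused because silent mismatches are
untraceable. Every dropped record is logged and tallied by cause, and
accepted + rejected row counts always sum to the input count.

## Synthetic community generator

The generator emulates what the estimation method assumes and what breaks
it, with one integer seed driving named `SeedSequence` children (pool /
coefficients / survey), so identical configs give identical tables.

Defaults (one community): 40 species — 40% freshwater-only, 40%
seawater/mudflat-only, 16% mixed, 4% unrecorded, matching the rough
composition of a multi-source literature compilation — observed monthly
for a year (~480 records, with 30 individuals behind each record over
1000 m²). True `a` is lognormal with median 0.01 g·cm⁻ᵇ (log-sd 0.4),
true `b` ~ N(3.0, 0.15) (near-isometric growth), species GTL log-uniform
on 5–40 cm. Each species gets 3 published coefficient reports with
multiplicative lognormal noise on `a` (log-sd 0.15) and additive noise on
`b` (sd 0.05); under this noise the pooled `a_rep` is lognormal with
log-sd s/√k, so E[a_rep/a] = exp(s²/2k), which the tests verify by Monte
Carlo.

Individual lengths are lognormal about the species GTL with a per-habitat
log-sd: 0.1 for freshwater-type populations, 0.5 for seawater-type, whose
reported GTL additionally overstates the sampled population's typical
length by a factor 1.3 by default — the seawater failure is modeled as
GTL unrepresentativeness (dispersion + offset), not as habitat-dependent
allometry, since single-species evidence suggests `a` and `b` differ
little between habitats while size ranges differ a lot. Masses follow the
true allometry and aggregate so that biomass density equals number
density times the realized mean mass exactly; the pipeline's
individual-biomass division therefore recovers the realized mean with no
aggregation error.

Juvenile contamination operates at the record level: with probability
`juvenile_fraction` a species-month is a recruitment pulse whose lengths
are `juvenile_length_ratio` (default 0.3) times the adult draws. A pulse
month's mean mass drops by roughly `ratio^b` ≈ 0.027, producing exactly
the heavy "estimated ≫ measured" outliers the Q filter targets.
Per-individual mixing at the same rate would instead bias *every* monthly
mean by the near-constant factor `1 − π + π·ratio^b` and produce no
outliers at all — the record-level design is what makes the contamination
scenario informative. The default pulse rate is 0.1; the `contaminated`
scenario raises it to 0.25.

Benchmark scenarios (`generate_benchmark_scenarios`): `noiseless` (all
noise off — the pipeline must return identity-line R² = 1 everywhere),
`freshwater_like` (tight dispersion, faithful GTL, 2% pulses),
`seawater_like` (log-sd 0.5 everywhere, GTL offset 1.5), `contaminated`
(freshwater-like plus 25% pulses). Scenario dispersion/offset values are
calibration knobs chosen to make the qualitative contrast robust across
seeds, not quantitative claims about any real community.

What the generator does **not** emulate: gear selectivity, spatial
structure, seasonal migration, age-structured growth, heavy-tailed size
distributions, reporting error in the field densities themselves, or
correlated coefficient errors across literature sources. Passing tests
therefore show that the pipeline's logic and statistics behave correctly
under the stated generative assumptions — not that the estimation
shortcut is valid for any particular real fauna.

## Determinism and problem sizes

A full run is a pure function of (input tables, config): reports, audit
tables and the manifest (config SHA-256, thresholds, drop counts) contain
no timestamps, and reruns are byte-identical. The test suite and the
acceptance script use communities of 20–40 species (~200–500 paired
points), 10 paired seeds for the scenario contrasts, 100 random
regressions (n ≤ 200) for the Cook's-distance oracle check, and 1000
random paired sets for the R² ordering property — sizes at which every
check is stable yet the whole suite runs in seconds.

## Known limitations

- The Q threshold (6) and Cook's cutoff (4/n) are conventions, exposed as
  knobs; results near the thresholds are sensitive to them, which is why
  the audit tables export every per-point score.
- Identity-line R² is undefined for a single species observed at constant
  weight (SST = 0); such variants are reported degenerate.
- The raw-gram Q residual makes the filter stricter for large-bodied
  species under multiplicative error; a log-scale alternative would
  change the removed set and is intentionally not offered.
- Habitat classification trusts the input labels; taxonomic synonymy and
  estuary-use ambiguity are not resolved (estuary-only species are
  conservatively treated as mixed and excluded).
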