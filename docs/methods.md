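# Methods

`snowcat` implements the computational chain of a mesopelagic particle-fraction
study: Marine Snow Catcher (MSC) fraction accounting, leucine-based secondary
production and carbon-loss calculus, OTU-table diversity analysis, and the
richness–production regression. A seeded synthetic-data generator stands in for
the sequencing and isotope raw data so every stage is testable offline. This
note records the models, the defaults and why, and what the synthetic design
does and does not establish.

## MSC fraction accounting

The MSC samples `v_total` = 100 L of seawater; after 2 h of on-deck settling,
fast-sinking particles concentrate in a `v_plate` = 0.243 L tray beneath a 7 L
base compartment. A quantity measured on the plate slurry contains the
fast-sinking signal *plus* the ambient non-sinking signal carried in the tray
seawater. The deconvolution to a per-litre-of-water-column value is

```
Q_fast = max(0, plate − ambient) × v_plate / v_total
```

i.e. excess-over-ambient rescaled from tray to catcher volume. The exact form
of the published correction lives in supplementary material we treat as
adapted from the slow-sinking correction of the original instrument paper;
`deconvolve_fast_sinking` is a single swappable function so an alternative
(e.g. one with an explicit base-compartment term) can be substituted. A
negative excess has no physical meaning for a sinking quantity and is clamped
to zero with a warning. Handling dilutions are undone first (`undilute`
multiplies by the dilution factor); mixing diluted and undiluted inputs is an
error rather than a silent bias.

**Deck warming.** The thermal artefact of the 2 h settle is bounded with a
lumped-capacitance Newton model: conduction-limited wall `U = k_wall / d`
over the full cylinder area `A = 2πrh + 2πr²` (r = 0.3 m, h = 1.5 m,
d = 0.01 m), water mass 100 kg at c = 4186 J kg⁻¹ K⁻¹. With
`k_wall` = 0.10 W m⁻¹ K⁻¹ (typical polypropylene; configurable because no
measured value is available) water at 12 °C under an 18 °C deck reaches
14.65 °C after 2 h. Film resistances and radiation are neglected; the model
is a bound, not a heat-budget simulation.

## Production and carbon loss

Leucine incorporation converts to carbon production at 1.55 kg C per **mol**
Leu, i.e. 1.55 ng C per pmol, with isotopic dilution 1. (Source material
sometimes prints the factor as "kg C pmol⁻¹"; taken literally that misstates
all production magnitudes by 10¹², so the package uses the standard molar
value; the factor is configurable.) Replicate SDs propagate exactly through
linear conversions; the cell-specific quotient PHP/cells uses a first-order
delta-method SD, reported but not used for inference.

Growth rate follows the dimensional equation
`μ (h⁻¹) = cell-specific PHP (ng C cell⁻¹ h⁻¹) × 10⁶ / cell carbon (fg C cell⁻¹)`
with a conservative 12 fg C cell⁻¹ default. Note that published growth rates
for comparable inputs (0.13–0.4 h⁻¹) are ≈12× larger than this dimensional
computation yields (e.g. 4.00 × 10⁻⁷ ng C cell⁻¹ h⁻¹ → 0.033 h⁻¹, not 0.4);
the package asserts the dimensionally consistent value and leaves the
discrepancy documented here. Similarly, a printed deep cell-specific rate of
4.4 × 10⁻⁹ differs from the quotient of the printed deep PHP and cell
concentration (5.9 × 10⁻⁹); the package always computes the quotient.

Carbon loss supports two modes: prokaryotic growth efficiency
(`demand = PHP/PGE`, `respiration = demand − PHP`; default PGE = 8%, used for
the non-sinking fraction) and respiratory coefficient
(`respiration = PHP × RQ`, default RQ = 1, used for the fast-sinking
fraction). In PGE mode respiration + production = demand holds exactly.

Fast-sinking cell concentrations can be estimated by ratio transfer from a
reference study: a power law `c(z) = a·z^b` fitted to the reference sinking
pool (OLS in log–log space — multiplicative error model, exact on clean
data), divided by the reference non-sinking concentration at the same depth,
applied to the local non-sinking concentration. Extrapolation beyond the
reference depth range warns but computes.

## Diversity

All estimators operate on an `OtuTable` (samples × OTUs integer counts with
fraction/depth/replicate metadata) and are implemented from first principles,
with scikit-bio / SciPy / scikit-learn used only as independent oracles in
the test-suite:

- **Rarefaction**: multivariate hypergeometric subsampling to a common depth
  (default: the smallest library), preserving expected proportions. Alpha
  diversity and presence-based statistics are computed on the rarefied table;
  raw-table computation is available by passing the unrarefied table.
- **Chao1**: bias-corrected form `S_obs + f₁(f₁−1)/(2(f₂+1))`, finite when no
  doubletons are observed and equal to `S_obs` whenever f₁ ≤ 1.
- **Shannon** in natural log (no base is canonical here; a `base` argument is
  provided). **Simpson** as Gini-Simpson 1 − Σp², with the inverse form as an
  option, since "Simpson index" is ambiguous in the literature.
- **Bray-Curtis** on counts; a pair of all-zero samples is defined as 0 with
  a warning. Scale invariance holds only between equal-sum (e.g. rarefied)
  samples.
- **NMDS**: Kruskal's algorithm — isotonic (pool-adjacent-violators)
  regression of configuration distances on dissimilarity ranks with primary
  (weak) tie treatment, alternated with a Guttman-transform update; objective
  is stress-1 with the configuration-distance denominator, so it is invariant
  to rotation, translation and uniform scaling. A worsening update is rolled
  back and the run stops, making accepted stress non-increasing. The first
  start is classical (Torgerson) scaling, the remaining restarts random; the
  lowest-stress solution over 20 restarts is returned. Two dimensions fixed.
- **Shared/core OTUs**: presence pooled within a sample group (count > 0 in
  any member after rarefaction; no separate detection threshold), shared
  percentage as 100 × |A∩B|/|A∪B|, core microbiome as the intersection over
  all groups.
- **Family summary**: relative abundance per family, top-k (default 20)
  families by mean relative abundance across samples, remainder merged into
  "other"; unassigned OTUs form an "Unassigned" family.

## Richness–production regression

OLS of `y = log₁₀(cell-specific PHP)` on `x = observed richness` via the
closed-form normal equations; r² = 1 − SSE/SST; two-sided slope p-value from
the t distribution with n − 2 df (SciPy's regularised-incomplete-beta-based
t distribution); a seeded permutation p is available. The log₁₀ response is
a deliberate reading: intercepts of order −6 to −7 are only meaningful for
per-cell rates of order 10⁻⁷–10⁻⁹ on a log₁₀ scale. Excluding a fraction
label removes exactly those samples (36 → 24 when dropping the fast-sinking
fraction in the default design).

For calibration, `residual_sd_for_r2` returns the noise SD for which the
population R² of `y = a + bx + N(0, σ²)` equals a target:
`σ = |b|·sd(x)·√((1−r²)/r²)`.

## Synthetic-data generator

The generator's defaults *are* the study conditions: 36 samples = 3 fraction
types (Niskin, MSC non-sinking top, MSC fast-sinking plate) × 4 depths (28,
70, 128, 500 m) × 3 replicates, 20,000 reads per sample (the order of
retained reads per sample in the emulated design). Anchored targets:

- fast-sinking observed richness 314 → 128 between 28 and 500 m; non-sinking
  262 → 531. Interior depths (70, 128 m) are interpolated — fast: 262, 200;
  non-sinking: geometric interpolation 331, 419 — and are synthetic values,
  not measurements.
- fast-sinking dominance by *Acinetobacter* (Moraxellaceae) and *Pseudomonas*
  (Pseudomonadaceae), two reserved OTUs per genus (0.6/0.4 split of the genus
  mass): 57% summed at 128 m and 92% at 500 m, with a small 11%
  *Acinetobacter* presence at 70 m.
- shared-OTU (pooled-presence Jaccard) percentage between the fast- and
  non-sinking fractions decaying 53% → 16% (log-interpolated 36%, 24%
  inside).

**Community model.** Non-dominant OTUs follow a geometric rank-abundance
series (one shape parameter θ; simple enough that expected detected richness
has a closed form). Counts are multinomial at the library size (marginal per
OTU: Binomial(L, pᵢ)), optionally Dirichlet-overdispersed (off by default).
Because rare OTUs escape detection, calibration targets *observed* rather
than latent quantities:

- the series truncation S is solved (bisection on the exact expectation
  Σ 1−(1−pᵢ)^L) so the expected detected richness per sample equals the
  target; θ defaults to `ln(L_eff/R)/R`, which places the detection
  saturation comfortably above the target;
- the number of OTU identities shared between the fast and non-sinking pools
  at a depth is solved from the expected pooled (3-replicate) detection
  probabilities so the expected *observed* Jaccard matches the target.

OTU identities are drawn per depth from a regional pool of 1100 ids and
partitioned disjointly into shared and private sets (incidental collisions
would otherwise inflate the overlap); the whole study lands near the ~1000
distinct OTUs of the emulated design. Niskin samples draw from the
non-sinking composition — bottle and MSC-top water are statistically
indistinguishable in this design. Taxonomy is assigned deterministically from
the OTU id (≈30% "Unassigned", mirroring the low assignment rate typical of
short V4 amplicons), so taxonomy does not depend on the seed.

**Rates.** Per (fraction, depth): triplicate leucine uptakes are lognormal
around the cell mean with CV 0.15 (typical triplicate leucine precision;
CV = 0 reproduces the mean exactly), cells truncated-normal with relative SD
0.45 (matching the quoted ±SD of the measured concentrations). Volumetric
PHP anchors: non-sinking 111.755 → 1.161 ng C L⁻¹ h⁻¹ and fast-sinking
0.211 → 0.003 ng C L⁻¹ h⁻¹ between 28 and 500 m (geometric interpolation
inside); non-sinking cells 2.10 × 10⁶ → 1.97 × 10⁵ mL⁻¹. Fast-sinking cell
concentrations are expressed per mL of MSC-sampled seawater and set so that
fast cell-specific rates sit at 1.29–1.53 × 10⁻⁷ ng C cell⁻¹ h⁻¹ with a
4.0 × 10⁻⁷ maximum at 128 m — per-particle-volume concentrations cannot be
combined with per-catcher-volume production without a particle-volume
bookkeeping the source data do not support. The simulated measurement table
re-expresses fast rows on the concentrated plate scale (×v_total/v_plate,
plus the paired ambient replicate, then a 2× handling dilution) so that the
deconvolution stage inverts them exactly.

**Regression design.** Coefficient-recovery experiments use the design's 36
richness targets (spanning 128–531) as fixed x, simulate
log₁₀ rates at chosen slope/intercept with σ from `residual_sd_for_r2`, and
refit. With the all-fraction generating model (slope −0.00359, intercept
−6.19, r² 0.59) 200 seeded datasets recover the mean slope within ±0.0003
and the mean intercept within ±0.1; the 24-point design without the fast
fraction recovers slope −0.00289 analogously.

**What passing does not show.** The generator reproduces marginal richness,
dominance, overlap and rate magnitudes — not phylogenetic structure, spatial
or temporal autocorrelation, compositional correlations between OTUs, read
error/chimera processes, or the real family-level abundance patterns. Tests
passing on synthetic data validate the estimators and the calibration logic,
not ecological conclusions about real communities; quantities tied to the
deposited reads (measured PHP profiles, the published NMDS stress of 0.045,
real family percentages) are covered instead by exact hand-oracle and
property checks on small tables.

## Numerical choices and problem sizes

- Expected-detection solves are cached per (target, θ, library, dominance)
  tuple; generation of a full 36-sample study takes ~50 ms.
- Monte-Carlo sizes: 200 datasets for regression recovery, 50 for community
  calibration — enough that Monte-Carlo error is several times smaller than
  the corresponding tolerance (slope SE of the mean ≈ 3.5 × 10⁻⁵ against a
  ±3 × 10⁻⁴ band).
- NMDS: 20 restarts × ≤300 iterations, relative tolerance 10⁻⁶; ties in the
  dissimilarities are ordered by current configuration distance (primary
  treatment).
- Sub-seeds are spawned from the root seed (`SeedSequence`), all below 2³¹.
- Degenerate inputs: empty samples are rejected by entropy indices; all-zero
  Bray-Curtis pairs are 0 with a warning; rarefaction refuses depths above
  the smallest library; a constant response yields slope 0 and r² defined
  as 0.

## Known limitations

- The deconvolution ignores a possible slow-sinking contribution inside the
  plate; no slow-sinking measurements exist in this design to constrain it.
- The two-parameter geometric/dominance community model cannot reproduce
  arbitrary rank-abundance shapes; `overdispersion` adds Dirichlet noise but
  defaults off, so replicate count tables are exchangeable multinomials.
- The regression assumes a single pooled OLS with homoscedastic log-scale
  noise; no depth stratification or mixed effects.
- The warming model is conduction-limited; adding film resistances would
  lower the predicted warming.
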