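# Methods

## Data model and preprocessing

A measurement record is one tracheid with its positional context: tree,
calendar year (ring), radial row, and rank from the ring's inner border
(rank 1 = first-formed cell). Two traits are carried per cell, the radial
diameter `D` and the cell wall thickness `CWT`, both in μm. Validity
requires `D > 0`, `CWT > 0` and `CWT/D < 1/2` — the last because the
radial lumen `L = D − 2·CWT` must be positive.

**Tracheidogram normalization.** Rows of one ring differ in cell count for
random reasons. Each row is resampled to the ring's mean row length
(rounded half-up) by an overlap-averaging rule: an input row of `n` cells
is treated as a piecewise-constant profile on [0, 1] with cells of width
`1/n`; each output cell of width `1/m` takes the overlap-weighted average
of the input values covering its interval. This rule conserves constant
rows exactly, never extrapolates outside the input value range, and is the
identity when `m = n`. It is the single supported resampling method;
alternates could be added behind `resample_profile`. Rows are then
averaged position-wise.

**Standardization (indexing).** Traits are divided by their means over the
standardization scope — the whole dataset by default, per tree as an
option (useful when inter-tree variability dominates, as it does for
stone pine). By construction `mean(D_i) = mean(CWT_i) = 1`, so a cell with
both traits at the species mean has slope angle
`φ_i = arctan(1) = 45°`. Indexing is what turns the heavily skewed raw
`CWT/D` distribution into a bimodal angle distribution that a mixture can
resolve.

Angles are stored and reported in degrees; trigonometry is done in
radians internally.

## The mixture model

The density of `φ_i` over a ring population is

    f(φ) = A_EW·f_B(φ; α_E, β_E, a_E, b_E)
         + A_TW·f_GN(φ; μ, α_T, β_T)
         + A_LW·f_B(φ; α_L, β_L, a_L, b_L),      A_TW = 1 − A_EW − A_LW,

13 free parameters in total.

**Four-parameter beta** (EW and LW), support `(a, b)`, shapes `α, β > 1`
so the component is unimodal but possibly skewed — skewness captures
intra-seasonal drift of cell traits inside a zone:

    f_B(x) = (x−a)^(α−1) (b−x)^(β−1) / [B(α, β) (b−a)^(α+β−1)]

with closed-form statistics

    mean   = a + (b−a)·α/(α+β)
    mode   = a + (b−a)·(α−1)/(α+β−2)
    median ≈ a + (b−a)·(α−1/3)/(α+β−2/3)
    σ      = (b−a)·sqrt(αβ / ((α+β)²(α+β+1)))

The median line above is the standard closed-form approximation (good to
about 0.5 % of the range for shapes ≥ 1); an exact numeric median (root of
cdf = ½) is also computed, but printed reports use the approximation. Note
a widely circulated variant of the mean formula, `(αa + βb)/(α+β)`, is
inconsistent with the density above (it swaps the roles of the endpoints);
the package uses the standard form, which is the one consistent with the
mode, median and σ expressions.

**Generalized normal** (TW), center `μ`, scale `α > 0`, shape `β ≥ 2`:

    f_GN(x) = β / (2αΓ(1/β)) · exp(−(|x−μ|/α)^β)

At `β = 2` this is the normal law with sd `α/√2`; as `β → ∞` it tends to
the uniform distribution on `(μ−α, μ+α)`. Mean = median = mode = `μ`;
`σ = α·sqrt(Γ(3/β)/Γ(1/β))`. The family expresses the physical picture of
the transition: a uniform drift of cell proportions from EW-like to
LW-like, blurred by normally distributed noise. Shape exactly 2 is
allowed as the normal limit; during fitting the shape is additionally
capped at 50, beyond which the density is numerically indistinguishable
from uniform and an unbounded plateau can swallow neighboring components.

Densities and distribution functions are evaluated from these explicit
formulas (via `scipy.special`); `scipy.stats` provides the sampling
backend and serves as an independent cross-check in the tests.

## Estimation

The pipeline mirrors a spreadsheet-solver workflow, reconciling binned
least squares and maximum likelihood by using them in sequence:

1. **Histogram** of `φ_i` on 1.5° bins (left-closed, labels are lower bin
   edges).
2. **Initialization** (deterministic): earlywood sits at the left end of
   the angle axis and latewood at the right, so the leftmost and rightmost
   prominent histogram peaks (≥ 30 % of the global maximum, ≥ 5° apart)
   seed the EW and LW modes. Each peak's half-width sets the component
   spread (robust against mass from the neighboring transition zone);
   supports start at mode ± 6 sd; TW starts midway with shape 4;
   amplitudes from the mass split at the inter-peak density minimum. A
   unimodal histogram falls back to a quantile split.
3. **Binned least squares**: minimize Σ_bins (observed bin fraction −
   model bin probability)², where model bin probabilities are cdf
   differences. The stage is multi-started from the base initialization
   plus two support-tightened variants (mode ± 4 sd and ± 2.5 sd, TW scale
   halved); the best objective wins. Tight variants matter when components
   are well separated, wide ones when they overlap.
4. **MLE refinement** on the raw angles: maximize Σ log f(φ_i).
5. **Adequacy**: Pearson χ² on 50 equal-width bins over the observed
   range, bins with fewer than 5 *observed* counts merged inward from the
   two outskirts only, `dof = m − 13 − 1` for `m` final bins; the model is
   adequate iff p > 0.05.

All stages search an unconstrained 13-vector through smooth transforms:
softmax for the amplitude simplex, `log(shape − 1)` for beta shapes,
logistic maps keeping `0 ≤ a < b ≤ 90`, and a scaled logistic keeping the
TW shape in (2, 50). The optimizer is Nelder-Mead (adaptive), restarted
from the incumbent until it stops improving (up to 8 restarts within a
10,000-evaluation budget per start, objective tolerance 1e−8 for MLE,
1e−10 for LS); restarts rebuild the simplex at full size, which escapes
the collapsed-simplex stalls a single 13-dimensional run is prone to. The
MLE result is never allowed to be worse than its starting point.

Four-parameter betas have hard supports, so an observation outside both
beta supports with negligible TW density would give a −∞ log-likelihood;
supports are auto-widened to the data range in that case before
optimization, and a remaining zero-density observation is an error.

`fit_min_chi2` additionally offers minimum-χ² estimation (the fitting
objective *is* the test statistic). When the same statistic is minimized
and then tested, the fitted statistic follows its asymptotic
χ²(m − 13 − 1) law, which makes this the estimator used in the
calibration study below; likelihood-based fits tested with the same dof
are slightly anti-conservative (the Chernoff–Lehmann effect).

## Zonation criteria

- **Mork thresholds** (for comparison): `CWT/D = 1/6` (form `4·CWT > L`)
  and `1/4` (form `2·CWT > L`), exact rationals.
- **Back-transformation**: an indexed angle statistic maps to raw trait
  units via `CWT/D = (mean CWT / mean D)·tan(φ_i)` using the same means
  that defined the standardization.
- **Two-zone split**: threshold at the TW center `μ` (mean = median =
  mode of the symmetric TW law), so the more-EW-like half of the
  transition cells joins EW and the other half LW. Hence
  `EW% = 100·(A_EW + A_TW/2)`, `LW% = 100 − EW%`. Cells exactly at the
  boundary go to the late side (an arbitrary, documented convention).
- **Three-zone split**: either the angles where neighboring weighted
  densities intersect (bisection between the component centers, 1e−10°
  tolerance), or the mixture percentiles at `A_EW` and `A_EW + A_TW`
  (the percentile method makes classified zone fractions match the
  amplitudes by construction).
- **Irreversibility**: optionally, the first cell of a ring is earlywood
  by definition and labels are made monotone EW → TW → LW along the ring
  (cumulative-maximum post-processing). Off by default in the library
  (exploratory use), on by default in the CLI `classify` command. Rings
  with intra-annual density fluctuations are the known exception; the
  switch is manual, not auto-detected.

Zone reports print, per zone, the amplitude (%), the angle-space mean,
median (approximation), mode and σ, and each of those angle statistics
back-transformed to CWT/D. Back-transforming a mean angle is not the same
as averaging raw ratios (tan is nonlinear); `zone_ratio_means` exposes the
raw per-zone mean of CWT/D over classified cells for comparison.

## Synthetic data

The generator produces datasets with the statistical structure the model
assumes, at the scale of the emulated field study: 5 trees × 50 rings ×
5 radial rows, ~20–25 cells per row (~25,000 cells per species). Per ring:
the cell count is drawn from a normal law; each cell's zone comes from the
amplitudes and its angle from the zone's distribution (ancestral
sampling); cells are ordered EW → TW → LW along the ring and by angle
within a zone — the simplest ordering consistent with transition cells
sitting between typical early- and latewood; no xylogenesis dynamics are
claimed. Relative diameters `D_i` are drawn from zone-dependent truncated
normals (EW 1.25, TW 0.90, LW 0.55, sd 0.12 — synthetic conventions that
reproduce the large-thin/small-thick cluster geometry, not measured
values), and `CWT_i = D_i·tan(φ_i)` ties the traits together. Cells are
de-standardized by species-level trait means and replicated into rows
with multiplicative lognormal jitter (sd 0.05) representing row-to-row
noise; the geometric constraint `CWT/D < 1/2` is enforced by rejection.

Species presets reconstruct the per-zone beta parameters numerically from
published mean/median/mode/σ tables (`beta4_from_stats`, a least-squares
inversion of the closed forms — the four statistics pin down the four
parameters essentially exactly). The TW shape parameter is not published;
presets use shape 4 with the scale set from the published σ. This is a
convention of the generator, stated as such.

What the generator does **not** emulate: seasonal weather signals, age
trends, intra-annual density fluctuations, missing rings, measurement
error correlated along a row. Tests passing on synthetic data therefore
demonstrate the correctness and calibration of the machinery under the
model's own assumptions, not robustness to real-world anomalies.

## Identifiability — what a fit can and cannot pin down

A numerical Fisher-information analysis at the spruce-like preset (the
hardest case: a broad TW between two nearby humps) gives, at n = 5,000
cells, asymptotic standard errors of roughly **0.037 for A_EW, 0.039 for
A_TW, and 2.2° for the TW center** — while the EW and LW component means
are tight (≈ 0.6°). Empirically the log-likelihood surface shows basins
with indistinguishable likelihood (differences of ~1 unit in 20,000)
whose three-way amplitude decompositions differ by more than 0.1: the
EW–TW split is intrinsically soft at realistic sample sizes. The
**two-zone quantities are nevertheless identified**: `EW% = A_EW +
A_TW/2` and the transition center agree across those basins to about one
percentage point and ~1°, which is exactly why the two-zone criterion is
the recommended deliverable of a fit. Tests assert parameter recovery at
tolerances scaled to these information bounds; the full-pipeline
round-trip (simulate → restandardize → fit) additionally carries a small
systematic angle shift (~1°) because the empirical index means of a
finite zone-structured sample are not exactly 1.

## Numerical choices and limitations

- Histogram bins are left-closed/right-open, labeled by lower edge;
  defaults 0.01 for raw CWT/D, 0.5° for raw φ, 1.5° for φ_i.
- χ² merging operates on observed counts and only from the outskirts
  inward; interior sparse bins are left alone.
- Quadrature/root-finding tolerances: mixture cdf inversion by Brent to
  1e−10; density-intersection boundaries to 1e−10°.
- The mean-row-length target is rounded half-up.
- Fitting is deterministic given the data (no random multi-start);
  simulation takes an explicit seed and uses independent per-tree
  substreams.
- Pooled fitting is the default; per-tree fitting is available and the
  CLI reports per-tree ranges. For species with weak inter-tree common
  signal the pooled fit may fail the χ² test while per-tree fits pass.
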