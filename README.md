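# tracheidzones

Model-based division of conifer tree rings into **earlywood (EW)**,
**transition wood (TW)**, and **latewood (LW)** from per-cell tracheid
measurements.

## The problem

Conifer wood is built from tracheids: earlywood cells are wide and
thin-walled (water conduction), latewood cells are narrow and thick-walled
(mechanical strength). The classical **Mork criterion** calls a cell
latewood when its wall is thick relative to the lumen
(`4·CWT > L` or, in the second historical form, `2·CWT > L`, with
`L = D − 2·CWT`); as CWT/D thresholds these are the fixed constants 1/6 ≈
0.167 and 1/4 = 0.25. Fixed constants ignore species and habitat, and in
practice often land inside the latewood cluster rather than between the
zones.

`tracheidzones` instead derives a **species-specific, functionally grounded
criterion** from the statistical distribution of the cells themselves:

1. Per-ring radial files (tracheidograms) of radial diameter `D` and wall
   thickness `CWT` are **normalized** to the ring's mean cell count and
   **averaged** across rows.
2. Traits are **standardized** (indexed) by their dataset means:
   `D_i = D / mean(D)`, `CWT_i = CWT / mean(CWT)`.
3. The working coordinate is the slope angle
   `φ_i = arctan(CWT_i / D_i)` (degrees). After indexing, its
   distribution is distinctly bimodal.
4. The density of `φ_i` is fitted with a 13-parameter mixture

   `f(φ) = A_EW·Beta(φ; α, β, a, b) + A_TW·GN(φ; μ, α, β) + A_LW·Beta(φ; α′, β′, a′, b′)`

   — a four-parameter beta on a finite support for each of EW and LW
   (unimodal, possibly skewed) and a **generalized normal**
   (exponential-power, shape ≥ 2) for the gradual EW→LW transition, with
   `A_TW = 1 − A_EW − A_LW`.
5. Adequacy is tested with Pearson's χ² on 50 bins (outskirt bins with
   fewer than 5 observations merged inward), `dof = m − 13 − 1`.
6. Zonation criteria follow from the fit: the TW center `μ` back-transforms
   to a two-zone CWT/D threshold
   `k = (mean CWT / mean D)·tan(μ)`; three-zone boundaries come from the
   intersections of neighboring weighted densities or from mixture
   percentiles; ring classification can enforce the irreversible
   EW → TW → LW order along the ring.

## Worked example

Generate a synthetic spruce-like dataset (5 trees × 50 rings × 5 radial
rows, ~24,000 cells, bundled `picea_obovata` preset), fit the mixture, and
classify:

```sh
$ tracheidzones simulate --preset picea_obovata --seed 42 -o sim
wrote 24205 cells to sim/measurements.csv (+ truth.csv, generating_model.json)

$ tracheidzones fit sim/measurements.csv -o fit
    A_percent  mu_deg  median_deg  mode_deg  sigma_deg  cwt_d_mean  cwt_d_median  cwt_d_mode
EW     50.385  29.544      29.014    27.883      4.804       0.054         0.053       0.050
TW     21.046  47.542      47.542    47.542      7.025       0.104         0.104       0.104
LW     28.569  67.682      67.944    68.905      4.599       0.232         0.235       0.246

two-zone split at CWT/D = 0.104 (tw-center): EW 60.9% / LW 39.1%
chi2 = 46.55, dof = 36, p = 0.112
wrote model.json, fit_report.json, zone_report.csv to fit

$ tracheidzones classify sim/measurements.csv --model fit/model.json -o labeled.csv --zones 3
wrote labeled.csv: EW 48.8%, TW 21.9%, LW 29.4%
```

Reading the output: the generator used zone amplitudes 49.2 / 22.1 / 28.7 %
and a transition center of 49.0°; the fit recovers 50.4 / 21.0 / 28.6 % and
47.5°, the χ² test accepts the model (p = 0.112 > 0.05), and the derived
two-zone threshold CWT/D ≈ 0.104 — a species-specific value well below both
Mork constants, as expected for spruce. The classified zone fractions match
the generating amplitudes to about one percentage point.

The same machinery is available as a library:

```python
import tracheidzones as tz

cells = tz.read_measurements("sim/measurements.csv")
df, summary = tz.standardize(cells)
result = tz.fit_pipeline(df["phi_i"].to_numpy())        # LS then MLE + chi2
report = tz.zone_report(result.model, summary.d_mean, summary.cwt_mean)
```

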