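# lvattention

Nonautonomous Lotka–Volterra analysis of attention-share time series.

Given weekly relative-interest series for N topics in one area (the Google
Trends multi-topic CSV dialect, 0–100 scale), the pipeline:

1. converts the panel to market shares with an outside good
   (`S_i = α·v_i/Σv_j`, constant outside share `1−α`),
2. recovers per-topic utilities via the exact logit inverse
   (`f_i = ln S_i − ln S_0`),
3. fits a smooth Fourier (or polynomial) utility per topic and
   differentiates it analytically to get the time-varying interaction
   coefficients `g_i(t) = df_i/dt`,
4. classifies every topic pair per week into one of six ecological roles
   (competition, predator–prey, mutualism, commensalism, amensalism,
   neutralism) from the coefficient signs, with the positive-coefficient
   topic as predator,
5. reports the interaction-intensity profile `Σ|g_i(t)|`, a ratio-based
   intensification changepoint, per-topic share-scale MSE diagnostics and
   (optionally) plots.

The share trajectories are the closed-form solution of an integrable
nonautonomous Lotka–Volterra system; `lv_dynamics` carries the closed form,
the LV right-hand side, a residual check and an adaptive Runge–Kutta
integrator used as an independent test oracle. `synthetic_data` generates
Trends-like observations (joint 0–100 normalization, additive noise,
integer rounding) from known ground-truth utilities with regime changes, so
everything is testable fully offline.

## CLI

```sh
# generate synthetic data (built-in pandemic-like preset, or a YAML scenario)
lv-attention synth --preset pandemic --out data/
lv-attention synth --scenario examples/scenario.yaml --out data/

# run the full analysis on a Trends-style CSV
lv-attention analyze data/trends.csv --out results/ --plots

# summarize a role-timeline report
lv-attention report results/report.csv
```

`analyze` writes `report.csv` (one row per week × topic pair: role,
predator, coefficients, intensity), `coefficients.csv`, `shares.csv`,
`fitted_shares.csv`, `mse.csv` and a reproducibility `manifest.json`.
Options of note: `--coverage` (the outside-share gauge constant α — the
coefficients and role labels are provably invariant to it), `--order`
(Fourier order; default: leave-one-out cross-validation), `--eps` (zero
threshold for role signs; default: 15% of the maximum |g|),
`--smooth-weeks` (majority-vote label smoothing, off by default). A YAML
config can be passed with `--config`; explicit flags win.

## A note on identifiability

Relative-interest data carry only within-panel ratios, so utilities are
identified up to one common time-varying gauge term. The constant-coverage
share conversion fixes that gauge. Consequently pairwise coefficient
*differences* (and hence all role labels) are estimated exactly from
noise-free data, while the common level of the coefficients inherits a
small gauge component; analyses starting from true shares are exact.
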