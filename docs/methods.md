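# Methods

This note documents the statistical and numerical choices in rccpipe:
what each stage computes, the defaults and why they were chosen, and the
known limitations.

## 1. Input format and codeset

Lane files follow the nCounter RCC layout: `<Header>`,
`<Sample_Attributes>`, `<Lane_Attributes>`, and `<Code_Summary>`
sections with CSV rows; counts are non-negative integers. The parser
reports the missing section or the offending line number on malformed
input, and `write_rcc`/`read_rcc` round-trip exactly (binding density is
written with full float precision).

The bundled panel (`rccpipe/data/codeset_panel.tsv`) contains 12
endogenous probes (cytokine and neuroactive-ligand genes), 3 reference
probes (GAPDH, GUSB, YWHAZ), the 6-point positive-control titration
(POS_A..POS_F at 128, 32, 8, 2, 0.5, 0.125 fM), and 6 negative probes.
All endogenous/reference targets are 100-nt intervals on their
accessions.

## 2. Lane QC

Four checks per lane, all thresholds configurable via `QCThresholds`:

- **Imaging**: fields-of-view counted / requested >= 75 %. Fails
  strictly below the threshold, so exactly 75.0 % passes.
- **Binding density**: within [0.1, 2.25] spots/um^2, both bounds
  inclusive.
- **Positive-control linearity**: r^2 of log2(count + 1) versus
  log2(concentration) over the titration >= 0.95. The +1 offset keeps
  zero counts finite; a zero-variance ladder scores r^2 = 0.
- **Limit of detection**: the POS_E count must strictly exceed
  mean(negatives) + 2 x SD(negatives), with the sample (ddof = 1)
  standard deviation.

A lane passes overall iff all four checks pass. Downstream stages can
drop failing lanes (`NormalizeOptions(drop_qc_failures=True)`).

## 3. Normalization

Three sequential steps, each recorded in `NormalizationFactors`:

1. **Background subtraction**: cutoff = max(negatives) + 2 x SD
   (per lane); counts are clamped at zero after subtraction. `mean`
   instead of `max` is available via `background_summary`.
2. **Positive-control scaling**: per-lane factor = (arithmetic mean over
   lanes of the per-lane geometric mean of positive counts) / (this
   lane's geometric mean). Computed on raw positive counts.
3. **Reference-gene scaling**: same geometric-mean construction on the
   three reference genes, applied after positive scaling.

Because every factor is normalized by the across-lane mean of geometric
means, multiplying one lane's counts by a constant changes *all* lanes'
output by a common global factor while leaving every relative comparison
(and hence every downstream contrast on a log scale, up to an additive
constant absorbed by the intercept) unchanged. The invariance the
pipeline guarantees — and tests — is therefore "identical up to a common
rescaling", not elementwise identity.

A zero geometric mean (a lane with a zero positive or reference count)
is a hard error rather than a silent NaN.

## 4. Per-gene repeated-measures model

For each gene, the post-baseline responses (default times 4 h and 24 h;
transform `identity` or `log2p1`) are modelled by generalized least
squares with fixed effects

    intercept + group + time + group:time + beta * baseline

and an AR1 correlation structure across a given animal's measurements
(in measurement order), shared variance sigma^2. The baseline (0 h)
value enters as a covariate, so each animal acts as its own control.

**Estimation.** REML with sigma^2 profiled out; the single remaining
parameter rho is maximized by bounded Brent search on (-0.99, 0.99) with
`xatol = 1e-10`. Per-block inverse-correlation matrices are cached by
block size. Rank-deficient designs, groups with fewer than two animals,
and missing baselines raise `EstimationError`/`InsufficientDataError`
up front rather than producing unstable fits.

**Degrees of freedom.** A between/within partition: columns of the
design that are constant within animal (intercept, group, baseline)
count as between-animal parameters; contrasts involving only
between-animal columns use the between-animal error df
(n_animals - q_between), all others use the within-animal remainder.
With 16 animals and 2 post-baseline times this gives df = 13 for the
between-group contrast at the first time and df = 14 for within-animal
contrasts — an intentional, documented asymmetry of the partition.

**Least-squares means.** Group x time cell predictions evaluated at the
grand mean of the baseline covariate.

**Contrasts.** Between groups at each modelled time, and within each
group versus baseline. The versus-baseline contrasts come from a
companion fit that models all three timepoints without the covariate
(the covariate model cannot predict its own baseline). Optional
Benjamini-Hochberg adjustment across the gene panel.

**Exact reductions** (enforced by tests to 1e-8): independence
correlation reproduces OLS; one group at two timepoints reproduces the
paired t-test, because the 2x2 REML covariance solution equals the
sample covariance.

**Residual diagnostics.** Shapiro-Wilk and Anderson-Darling on the
whitened residuals, requiring at least 8 non-constant values.

## 5. Power analysis

Exact noncentral-t computations (`scipy.stats.nct`):

- two-sample: delta = d * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2;
- paired: dz = mean_diff / sd_diff with
  sd_diff^2 = sd1^2 + sd2^2 - 2 r sd1 sd2, delta = dz sqrt(n), df = n - 1.

`solve_effect_size` inverts power in d by Brent's method
(xtol = 1e-10); `solve_n` searches integer n upward (capped at 10^6).
Far-tail NaNs in `scipy.stats.nct.sf` (a known boost issue) are handled
by the symmetry `P(T' > x) = P(T'' < -x)` with negated noncentrality,
falling back to 0/1 when the tail mass is numerically negligible.

Headline calibration: d = 1.3447 gives power 0.706 at 8/group; the same
effect gives 0.8114 at 10/group and 0.9572 at 16/group.

## 6. Simulator

`simulate_runset` generates a full study from `SimConfig`. Defaults: 8
animals per group, times (0, 4, 24) h, negative-binomial endogenous and
reference counts with dispersion 20 (Poisson in the limit
dispersion -> inf), Poisson positive controls scaled to concentration
(`pos_scale = 150` counts/fM) and Poisson background on negatives
(mean 5). Each animal carries a latent AR1 log2 trajectory
(`animal_sd = 0.5`, `rho_within_animal = 0.5`); lanes carry lognormal
scale factors (`lane_scale_sd = 0.15`). Binding density is derived as
total counts / (FOV x 100), which lands in the passing range at the
default depth. Multiplicative effects are planted as `log2_effects`
keyed by (gene, group, time) and recorded in `GroundTruth`.

Every random stream is keyed by (seed, CRC32 of a token path), so
regeneration is byte-identical and independent of iteration order.
`inject_qc_failure` minimally perturbs one lane to fail exactly one
named check. A small `scenario_library()` provides null, effect-bearing
(`paper_like`), high-correlation, and single-QC-failure configurations.

`simulate_gaussian_linear` generates data *exactly* from the Section-4
model (independent Gaussian baseline, linear baseline slope, AR1 errors
over the post-baseline times only) for calibration studies: the
acceptance suite uses it to verify type-I error in [0.03, 0.07] at
alpha = 0.05 for rho in {0, 0.3, 0.6} (pooled over both between-group
contrasts, 500 replicates each) and unbiased effect recovery at 1-2
residual SDs.

## 7. Known limitations

- At high within-animal correlation (rho = 0.6), the between-group test
  at the later timepoint alone is mildly conservative (empirical size
  ~0.026 at nominal 0.05); pooled over both times the size is 0.034.
  This comes from the between/within df partition interacting with the
  estimated rho, and is the usual conservative direction.
- The AR1 structure treats the 4 h -> 24 h gap as one lag step; unequal
  spacing is not converted to continuous-time decay.
- Normalization factors assume at least one positive and reference
  count per lane is nonzero; lanes violating this must be dropped.
- `solve_n` assumes balanced groups.

## 8. Numerical conventions

- REML rho search: bounded Brent, `xatol = 1e-10`.
- Power inversions: Brent, `xtol = 1e-10`, `rtol = 1e-12`.
- Boundary conventions: QC thresholds as in Section 2 (imaging fails
  strictly below, binding density inclusive, LOD strict).
- Pipeline output files are written with `%.9g` float formatting, so
  reruns are byte-identical.
- Significance: `p <= alpha` (alpha default 0.05).
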