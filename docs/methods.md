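# Methods

`peersusc` implements an individual-differences moderation analysis from
developmental cognitive neuroscience: does intrinsic (resting-state)
within-network connectivity moderate the association between perceived
peer-group norms and adolescent behavior, and if so, does the moderation
follow a differential-susceptibility (for-better-AND-for-worse) pattern
rather than a one-sided diathesis-stress pattern? Because raw cohorts of
this kind are not publicly shareable, the package pairs the analysis
chain with a synthetic-data generator whose ground truth makes every
stage falsifiable.

## The model

For each candidate network, subjects' standardized peer-norms score `X`,
standardized within-network connectivity `Z`, and covariates `C` (sex,
age, usable resting-state volumes) enter a three-step hierarchical OLS
on the behavior composite `y`:

1. `y ~ C`
2. `y ~ C + X + Z`
3. `y ~ C + X + Z + X·Z`

The product is formed after standardizing `X` and `Z` and is not
re-standardized, because every probing quantity below is algebra on the
raw product term. Reported per step: coefficients with conventional OLS
SEs and t-based p-values, R², the step-3 − step-2 change ΔR² (equal to
the squared semipartial correlation of the product term), adjusted R²,
and AIC in the `n·ln(RSS/n) + 2k` convention (`k` counts the intercept,
slopes and error variance; absolute AIC values are
convention-dependent and only differences are meaningful). Interaction
tests across the four candidate networks form one family, gated at the
Bonferroni threshold `0.05/4 = 0.0125` (strict inequality).

Confidence intervals are bias-corrected (BC, not BCa) case-resampling
bootstrap percentiles: subjects are resampled with replacement
(default B = 5000), the step-3 model refit per resample (vectorized
normal equations; rank-deficient resamples are redrawn and counted), and
the percentile endpoints shifted by twice the median-bias `z0`. A
coefficient is called significant when its interval excludes zero.

Cross-model "is the moderation stronger in network A than B" questions
use a Wald z on the coefficient difference. The default is the
independence approximation `z = (bA − bB)/√(seA² + seB²)`; because the
two models share subjects this understates the evidence when the
coefficient estimates are positively correlated, so a shared-resample
bootstrap variant is provided. Neither claims to reproduce any
particular published z value — the cross-model covariance of a given
dataset is not recoverable from printed tables.

## The probing battery

Writing the step-3 coefficients `bX, bZ, bXZ` with covariance `V` and
residual df `ν`:

- **Simple slopes / small multiples.** The slope of `X` at moderator
  level `z0` is `bX + bXZ·z0` with SE
  `√(V_XX + z0²·V_XZXZ + 2·z0·V_XXZ)`, t-tested on `ν` df; the default
  grid is −1 SD to +1 SD in 0.5 SD steps, two-sided α = 0.05 (the
  Bonferroni gate applies only to the four-network interaction family,
  not to probing).
- **Crossover.** `x_c = −bZ/bXZ`, the predictor value at which all
  moderator levels predict the same outcome; undefined (NaN) when
  `bXZ = 0`.
- **Regions of significance (Johnson–Neyman).** By default on the
  *predictor* axis: the values of `X` at which the conditional effect of
  `Z`, `θ(x) = bZ + bXZ·x`, is significant — obtained by solving
  `a·x² + b·x + c = 0` with `a = bXZ² − t²·V_XZXZ`,
  `b = 2(bZ·bXZ − t²·V_ZXZ)`, `c = bZ² − t²·V_ZZ`. Differential
  susceptibility requires significance at both ends of the ±2 SD
  normative range, i.e. both real roots inside ±2 SD with the
  significant region outside them. A negative discriminant is tagged
  `entire_range_significant` or `no_real_roots` by the sign of `a`. The
  conventional moderator-axis probe is exposed via `axis="moderator"`.
- **Proportion of Interaction (PoI).** With moderator lines drawn at
  ±1 SD over a ±2 SD predictor window, the area between the lines grows
  as `(x − x_c)²` on each side of the crossover, so
  `PoI = (hi − x_c)² / ((hi − x_c)² + (x_c − lo)²)`; a crossover outside
  the window saturates the index at 0 or 1 (an ordinal interaction, not
  an error). Bands: 0.40–0.60 strict, 0.20–0.80 lenient.
- **Proportion Affected (PA).** The fraction of observed predictor
  values above `x_c`; above 16% is the customary minimum, ~50% ideal.

### Verdict logic

The published criteria lists in this literature are narrative, so the
package fixes an explicit mapping. `no_moderation` unless criterion 1
holds (interaction under the corrected threshold, and the BC interval
excluding zero whenever a bootstrap table is available). Given
criterion 1, `differential_susceptibility` requires the index battery:
both RoS bounds inside ±2 SD with significance at both ends, PoI in the
*lenient* band, and PA > 0.16; anything else is `diathesis_stress_like`.
Two deliberate choices: (a) criterion 2 (simple slope significant at
high but not low moderator) is reported as evidence but does not gate
the verdict — when the low-moderator slope sits near the significance
boundary, gating on it would flip the verdict on a coin, while the index
battery asks the same question continuously; (b) the lenient PoI band is
the operative one because a crossover at ~±0.3 SD — a clearly disordinal
interaction — already puts PoI near 0.65, outside the strict band.

## Timeseries preparation and connectivity

Framewise displacement is the summed absolute backward difference of the
six rigid-body parameters, rotations converted to arc length on a 50 mm
sphere (exposed as a parameter); the first volume's FD is 0 by
convention. Subjects are excluded when strictly more than 10% of volumes
exceed 0.30 mm before scrubbing or the run is shorter than 4 minutes.
Scrubbing censors exactly the volumes with FD > 0.30 mm (strict, no
neighbor augmentation). DVARS (ROI-level RMS of the temporal difference)
is computed as a QC descriptive only and never drives censoring.

The fixed pipeline order is FD → QC → confound regression → scrubbing,
with a `censor_aware_regression` flag to estimate the projection on kept
volumes only; the two orderings are not equivalent and the package logs
which one ran. The regression design always contains an intercept, the
six motion parameters, CSF and white-matter signals, and the
discrete-cosine drift basis (components with period strictly longer
than the 128 s cutoff; 7 columns for 240 volumes at TR 2 s). The global
signal is extracted into the confounds table but regressed only on
request, since global-signal regression changes the sign structure of
correlations and is a study-level choice. Pre-computed CompCor
components can be passed as extra confound columns but are never
computed here.

Within-network connectivity is the arithmetic mean of Pearson
correlations over all ROI pairs of a network's roster (21 edges for the
7-ROI affective-salience roster). Raw-r averaging is the default, with a
Fisher-z option; for the moderate correlations typical here the two
agree to well under 0.01. The four default rosters (mentalizing 8,
cognitive control 4, motivational relevance 6, affective salience 7
ROIs) are label contracts against the timeseries TSV header — mask
construction is out of scope. VTA and OFC are carried as single
combined labels.

## Questionnaire scoring

Peer norms: 16 items on 1–6, the positive-behavior items reverse coded
(`x → min + max − x`), scored as the item mean, then z-scored; higher
means relatively more negative norms. The 8 negative / 8 positive split
is a package convention (configurable) — instruments of this type mix
both valences but the exact keying varies. Prosocial tendencies: 21
items on 1–5. Risk taking: 14 items on 0–3. The behavior composite
reverses the prosocial mean on its range (`6 − mean`), z-scores both
ingredients across the cohort (sample SD, n−1 everywhere) and averages
them; higher = more risky than prosocial. Rows with under 80% of a
scale's items answered are scored NaN and drop out by listwise deletion
rather than imputation. Cronbach's alpha uses the variance-of-sums
formula after reverse coding. Sex is coded girl = 1, boy = 0; only the
sign of the sex coefficient depends on this.

## The synthetic cohort

The generator's defaults are the package's canonical study conditions
and are not tuned per analysis:

| parameter | default | meaning |
|---|---|---|
| `n_volumes`, `tr_seconds` | 240, 2.0 | 8-minute resting scan |
| `network_r` (AS/MR/MENT/CC) | .49/.30/.51/.53 | network-level mean within-network r |
| `network_r_sd` | .18/.15/.13/.15 | between-subject spread of targets |
| `between_network_r` | 0.10 | weak positive cross-network background |
| `motion_spike_rate`, scale | 0.03, 0.6 mm | sparse high-FD frames |
| `p_high_motion`, spike rate | 0.05, 0.12 | QC-failing subpopulation |
| `p_partial_scan`, min volumes | 0.14, 129 | truncated (≥4 min) runs |
| `beta_x, beta_z, beta_xz` | 0.4, 0.1, 0.3 | standardized generative effects |
| `cov_betas` (age/sex/volumes) | .17/−.15/.20 | covariate effects |
| `noise_sd` | 0.5 | residual SD of the composite |
| `item_alpha` | .83/.75/.78 | target reliabilities |
| age, sex | U(11.94, 14.49), Bernoulli(0.5) | early-adolescent covariates |

Timeseries are multivariate normal with block covariance (within-network
off-diagonal at the subject's target, background between networks) plus
a motion-locked artifact (FD times per-ROI loadings) that the prep stage
exists to remove. Items follow a parallel-items model whose item-noise
variance is set from the target alpha by the Spearman–Brown relation,
linearly mapped to the response range and rounded/clamped —
discretization costs a little reliability, which is why alpha targets
are calibrated on the continuous items. The outcome is generated from
the *latent* standardized peer norms and the *true* standardized
moderator connectivity; item responses and estimated connectivity are
noisy measurements layered on top. Consequently the fully observed
analysis route (scored items, pipeline-estimated connectivity)
attenuates coefficients relative to the generative values — visible in
the acceptance output as `as_interaction_b_observed_route` — which is a
faithful property of measurement error, not a defect. Peer norms and
connectivity are generated independently (their empirical association
in such cohorts is near zero).

What the generator does not emulate: hemodynamics, spatial structure or
voxel-level noise, autocorrelated BOLD spectra (volumes are white within
the block covariance), item-level response styles, missing
questionnaires, or any true coupling between behavior and motion.
Passing tests therefore demonstrate correctness of the estimators and
the probing algebra under the stated generative model, not robustness to
every property of real resting-state data.

## Numerical choices and problem sizes

z-scoring uses the sample SD; boundary comparisons (scrub threshold, QC
fractions, Bonferroni, PoI bands, PA minimum) are strict, matching how
such rules are printed. The JN quadratic handles `a ≈ 0` linearly and
tags sign-definite cases instead of erroring. Bootstrap BC proportions
are clipped to `(1/(B+1), 1−1/(B+1))` before the normal quantile.

Simulation-based tests run at the canonical n = 200 / 100–200 replicates
for recovery and coverage, 50 replicates for verdict rates, and
records-only cohorts (no timeseries draw) where the regression is the
object under test; the acceptance script analyzes one 92-subject cohort
end to end (≈87 after QC). These sizes are the package's choices for a
desk-scale demonstration; all are parameters, not constants.

## Known limitations

- The Wald comparison's independence approximation is conservative for
  same-sample fits; the bootstrap variant is better calibrated but
  slower.
- BC (not BCa) intervals ignore acceleration; for OLS coefficients at
  these sample sizes the difference is small.
- The simultaneous all-networks model shares the separate models'
  covariates and reports a condition number, but no formal collinearity
  remedy is applied.
- PoI/PA depend on the plotting window and the observed predictor
  distribution respectively; both are reported with their settings.
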