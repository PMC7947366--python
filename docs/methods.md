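# Methods

This note documents the models, conventions and design choices behind
`t2nomo`, in the order the pipeline applies them.

## Signal model and relaxometry

Multi-echo magnitude images are assumed to follow the mono-exponential
decay `S(TE) = S0 · exp(−TE/T2)` per voxel. The default echo train is the
clinical protocol the package emulates: 8 echoes, TE = 9.9–79.2 ms,
ΔTE = 9.9 ms.

Two estimators are provided.

* `loglinear_wls` (default): least squares of `log S` on TE with weights
  `S²`. The weights undo the first-order variance distortion of the log
  transform, so for additive noise the estimator closely tracks the
  nonlinear fit while being deterministic and fully vectorised.
* `nls`: Levenberg-style nonlinear least squares of the exponential model
  itself (`scipy.optimize.least_squares`), initialised from the
  log-linear solution. Preferable deep in the Rician regime.

Voxels are accepted only if the fitted T2 lies in **[1, 500] ms** — the
extraocular-muscle range with a wide margin. The window exists to keep
divergent fits (non-decaying noise, air) out of the histograms; it is a
config knob. Non-positive signals, which can occur on magnitude images at
the noise floor: a single non-positive echo is dropped when at least three
points remain, two or more invalidate the voxel. Goodness of fit is the
signal-domain R², clipped to [0, 1]. No spatial regularisation is applied.

Accuracy is bounded by the echo train, not the estimator: with
TE ≤ 79.2 ms a 60 ms component is recovered with ≈ 2.8 ms median absolute
error at SNR 30, but a 110 ms component — sampled over less than one time
constant — carries ≈ 6.6 ms regardless of estimator. The test suite
asserts these measured bounds.

## Histogram features

All features are computed volumetrically on the pooled valid-voxel T2
values of a VOI. Conventions, pinned for determinism:

* **Percentiles**: linear interpolation between order statistics,
  inclusive endpoints (index `(n−1)·q/100`); this makes interpolated
  percentiles only asymptotically invariant to duplicating a VOI, which
  the tests acknowledge.
* **Moments**: population (1/N) central moments; skewness `μ₃/σ³`,
  kurtosis `μ₄/σ⁴` (normal → 3). Because the cutoff scale of kurtosis in
  the clinical literature suggests the excess convention, an excess
  (−3) column is emitted alongside.
* **Entropy / inhomogeneity**: computed on a fixed-width histogram,
  width 1 ms anchored at 0 (T2 is already in physical units), zero-count
  bins discarded; `ε = 2.2×10⁻¹⁶` guards the logarithm. Bin width is a
  config knob recorded in the output metadata.
* **Aggregation**: default `pooled_all_eoms` (the five muscles of an
  orbit as one VOI). `per_muscle` and `max_mean_muscle` (the muscle with
  the highest mean T2, an automated stand-in for visually picking the
  most inflamed muscle) are provided because published descriptions of
  per-orbit feature sets are ambiguous between these readings; none of
  the three is claimed to replicate any specific study.

## Statistics

Orbits are the unit of analysis and are treated as independent (n = 2 ×
patients), replicating common practice despite bilateral correlation.
AUC is the rank (Mann–Whitney) estimator with half credit for ties; its
CI is DeLong's (validated against R `pROC` to 6 decimals). Youden cutoffs
come from an exhaustive scan of midpoints between adjacent distinct
values, both orientations, ties toward the smallest cutoff; flag semantics
are strict (`>` / `≤`). The χ² test is uncorrected Pearson with 1 df
(Yates correction by flag); its asymptotic p is validated against a
hypergeometric permutation mid-p. ICC is ICC(2,1) — two-way random
effects, absolute agreement, single measure — delegated to `pingouin` and
cross-checked against explicit mean-squares formulas. No multiple-testing
correction is applied anywhere, matching the analysis style the package
reproduces.

## Model and nomogram

Features significant in univariate analysis (α = 0.05) enter a
maximum-likelihood logistic regression (statsmodels, Newton/IRLS; Wald
95 % CIs). Flags that are linearly dependent on the intercept and earlier
flags are aliased out before fitting. Perfect separation — entirely
possible at 90 orbits with strongly discriminating flags — is detected
(`converged=False`, non-finite information) and the offending predictor
is removed and reported in `model_notes.json`, because no finite ML
estimate exists for it; nothing is silently shrunk or penalised.

The nomogram assigns predictor *i* the points
`100 · βᵢ·rangeᵢ / maxⱼ(βⱼ·rangeⱼ)` (binary predictors: range 1), so
exactly one predictor spans 100 points, and maps total points back to
probability through the model's own linear predictor — scoring is
algebraically identical to evaluating the logistic model, which the tests
check to 1e−9. Predictors with non-positive β keep their (non-positive)
points and trigger a recorded sign warning rather than silent removal.
The reported model table is the full fit with a `retained` flag (Wald
p < 0.05); the nomogram is refit on the retained subset. The C-index is
apparent (in-sample), with no validation split.

## Synthetic cohort

The phantom generates what the analysis needs and nothing more: a
45-patient bilateral cohort (responder fraction 24/45) on a 64×64×10 grid
(0.7×0.7×3.6 mm voxels — a scaled-down field of view at the clinical
in-plane resolution), ten box-shaped muscle VOIs on a fixed template
(≥ 20 voxels each; no anatomical realism, since first-order features
depend only on value distributions), Rician noise at SNR 100 relative to
the muscle S0, and a response label produced by drawing per-eye therapy
deltas whose improvement probabilities depend on the latent group and
passing them through the 3-major/6-minor criteria — labels and criteria
are therefore consistent by construction. All randomness derives from one
integer seed through counter-based per-patient substreams (Philox), so
per-patient output is independent of cohort size and processing order.

Voxel T2 values are drawn from a per-group three-component Gaussian
mixture (truncated at > 0), with patient-level heterogeneity:

| component | responders | non-responders |
|---|---|---|
| base peak | N(μ, 1.5 ms), weight rest | N(μ, 7 ms), weight rest |
| high tail (edema) | w = 0.28·LN(0, 0.45), N(μ+25, 16 ms) | w = 0.02·LN(0, 1.3), N(μ+25, 2 ms) |
| low bump (focal fibrosis) | w = 0.17·LN(0, 0.45), N(μ−15, 6 ms) | — |

with μ = 70 ms plus a per-patient offset N(0, 3 ms); tail weights are
capped (0.45 / 0.30) and shared by both orbits of a patient.

This structure is the simplest one we found that reproduces, robustly at
200-orbit scale, the clinically reported contrast pattern: responders
show *lower* 5th/10th percentiles, *higher* 75th/90th/95th percentiles,
skewness, entropy **and** histogram energy. A plain base-plus-elevated-tail
mixture provably cannot do this (extra upper-tail mass raises the low
percentiles and lowers Σp²); the sharp responder base peak carries the
energy contrast, the low bump the low-percentile contrast, and the
log-normal weight jitter the between-patient overlap. The heavy-tailed
non-responder jitter gives a minority of non-responders substantial
compact high-T2 foci — mirroring the clinical observation that over half
of non-responder orbits can lie above a 95th-percentile cutoff — and its
compactness (SD 2 ms) keeps their entropy low while letting upper
percentiles overlap. Mixture parameters are free knobs of the phantom,
fixed once at design time; they are not estimates of real tissue.

What the phantom does **not** emulate: orbital anatomy, partial-volume
contamination at muscle boundaries, fat suppression or motion artifacts,
B1/stimulated-echo effects, slice gaps, or reader variability in VOI
drawing. Consequently, passing tests demonstrate the correctness and
internal consistency of the computational chain under the assumed voxel
model — not clinical performance. The synthetic group contrast is crisper
than real cohorts (apparent C-index ≈ 0.9–0.98 versus ≈ 0.79 reported
clinically), which is deliberate: the acceptance checks need direction
signs that are stable at desk scale.

## Numerical and degenerate-input choices

* Constant-T2 VOIs: entropy 0, inhomogeneity 1, percentiles equal;
  skewness/kurtosis are NaN (a degenerate-distribution error when the
  moments are requested directly).
* Youden ties break toward the smallest cutoff, then the `>` direction.
* The logistic score residual `max |Xᵀ(y − p̂)|` must be < 1e−8 for a fit
  to count as converged.
* Problem sizes in the test suite (16–100 patients, 32×32×8 grids, 100
  replicates for sign-direction checks) are the package's chosen
  desk-scale study conditions; the full default pipeline runs in seconds.

## Known limitations

Bilateral orbits are treated as independent observations, inflating
effective n (a patient-level cluster bootstrap would be the sensitivity
analysis of choice). The apparent C-index is optimistic by construction.
ICC enters only as a statistical primitive — the phantom does not simulate
two readers. Profile-likelihood CIs and penalised fits are out of scope.
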