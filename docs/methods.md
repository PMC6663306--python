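# Methods

This note documents the models, estimators, and design choices behind
`stimnet`, and what its synthetic-data experiments do and do not show.

## The analysis pipeline

A stimulation-mapping session consists of a 30-s baseline epoch followed by
a series of stimulation trials. Each trial delivers a biphasic pulse train
whose pulse frequency (10, 25, 50, 100, 200 Hz), amplitude (default grid
1, 2, 3 mA) and duration (0.25, 0.5, 1.0 s) are drawn independently and
uniformly — 45 parameter combinations — with inter-stimulation intervals
uniform on 2.75–3.25 s. Around each trial the pipeline analyzes three
half-second windows: a **pre** window ending at stimulation onset and two
consecutive **post** windows beginning 100 ms after stimulation offset (the
buffer discards amplifier recovery). The baseline is tiled into
nonoverlapping half-second windows.

Preprocessing screens channels for stimulation-locked artifact on the raw
signal — a paired t test of mean absolute voltage, pre vs. post, across
trials; a channel is discarded at uncorrected p < 0.05 only when its post
amplitude is *elevated* (suppression is not artifact). "Mean signal
amplitude" is implemented as mean absolute voltage per window, and paired
differences with zero variance are assigned p = 1. The stimulated contact
pair is exempt from screening and retained as network nodes. A common
average reference (CAR) is then applied.

**Functional networks.** Edge weights are magnitude-squared multitaper
coherence (DPSS tapers, time–bandwidth 5, 8 tapers) averaged over the
frequency bins inside four bands: alpha/theta 5–15 Hz, beta 15–25 Hz, low
gamma 30–40 Hz, high gamma 95–105 Hz. Within-band aggregation is the
arithmetic mean over bins whose centers fall in the closed interval; at
500 Hz and 0.5-s windows the bins are 2 Hz apart, ~6 per band. Windows are
demeaned before tapering. Note that with a 0.5-s window the taper
half-bandwidth is 10 Hz, comparable to the band widths: estimates are
smoothed across band edges, and the independent-noise bias floor of the
estimator is ≈ 1/k = 0.125 for white noise but higher (~0.17) for
narrowband processes, whose neighboring bins carry fewer effective degrees
of freedom. Tests calibrate the floor against a Monte-Carlo oracle on
white noise.

**Reconfiguration metrics.** With node strength
k_i = (1/(N−1)) Σ_j A_ij, the pipeline reports, per trial and band, the
signed change in the mean and in the (population) variance of node
strengths between the pre and first post window; the per-node magnitude
|k_i(post) − k_i(pre)|; and the configuration similarity — the Pearson
correlation of the two windows' upper-triangle edge vectors. Surrogate
baseline "trials" replicate each true trial's geometry (two half-second
windows separated by stimulation duration + 100 ms) at start times drawn
uniformly with replacement from the baseline span, and are processed by
exactly the same code path.

**Statistics.** Stimulation vs. surrogate contrasts use the Wilcoxon
rank-sum (Mann–Whitney) test with rank-biserial correlation
1 − 2U/(n₁n₂) as effect size (exact permutation null for small tie-free
samples, tie-corrected normal approximation otherwise). Dose
(amplitude × pulse frequency × duration) and location analyses use
within-session Spearman correlations summarized across sessions with a
one-sample t test and Cohen's d = mean/sd. Structure–function coupling is
an edge-wise Pearson r between structural weights and baseline coherence,
split into intra- and inter-hemispheric edge sets, Fisher-transformed with
z capped at atanh(1 − 1e−15). Band families are Bonferroni-corrected with
family size 4.

**Network control.** The structural connectome S (symmetric, nonnegative,
zero diagonal) defines linear dynamics x(t+1) = A x(t) + B u(t) with
A = S/(1 + ξ₀(S)), ξ₀ the largest singular value of the unnormalized S, so
the spectral radius is < 1. Modal controllability is
φ_i = Σ_j (1 − λ_j²) v_ij², computed from the symmetric eigendecomposition
of the *normalized* A (this choice makes the two-node unit-edge closed
form φ = (0.75, 0.75) exact and keeps |λ| < 1). Orthonormality of the
eigenvector rows is asserted before use, which guarantees
1 − λ_max² ≤ φ_i ≤ 1. Electrodes inherit ROI-level φ and strength by
nearest-centroid assignment (ties to the lowest ROI index, logged); the
centroid rule is the volume-free analogue of nearest-voxel assignment on a
labeled image.

**Memory state.** A logistic classifier on per-channel log multitaper
power in eight log-spaced bands (default 3–180 Hz; the edges are
configurable) scores the probability of a "good encoding" state. Features
are z-scored with training-set statistics stored on the classifier; the
fit is L2-regularized lbfgs with fixed tolerances, so retraining on the
same data reproduces identical weights. The session-level readout is the
mean change in state probability from pre to post window across trials,
correlated across sessions with the stimulated region's φ.

## The synthetic-data generator

The generator is the package's test bed: it emulates the statistical
structure the analysis assumes, with known ground truth.

*Signals.* Per band, each channel receives a band-limited Gaussian
component; channels are mixed so the band components' correlation matrix
equals the requested coupling matrix C (projected to the PSD cone by
eigenvalue clipping when infeasible). Between two unit-variance components
with correlation c the magnitude-squared coherence is c², giving an
analytic, monotone coupling→coherence map: ≈ c² at high SNR, exactly 1 at
c = 1, the estimator floor at c = 0. Defaults: 500 Hz sampling (the lowest
clinical rate, so all bands resolve), 20 µV band components over a 5 µV
broadband noise floor (the in-band noise contribution is then negligible),
baseline couplings drawn uniformly per edge (0.15–0.45; 0.35–0.65 in high
gamma so suppressive effects have headroom).

*Stimulation effects.* The post-stimulation response windows (1 s starting
100 ms after offset) are re-synthesized under a perturbed coupling
C′ = clip(C + g·W, 0, 1); all other samples are untouched, and with all
gains zero the recording is returned bit-for-bit. The per-trial gain is
g = effect_gain + intensity_slope · log(I/I_min)/log(I_max/I_min): the
grid spans a 240-fold intensity range, so a log scale spreads the planted
dose–response across trials (rank-equivalent for the Spearman analysis).
Routing is either *global* (W = 1) or *stim-routed*:
W_ij = s_i s_j with s the stimulation node's baseline coupling profile
normalized to mean one. The product form matters: with a small montage,
CAR absorbs any equicorrelated or additive per-node correlation change
(they lie in the null space of the reference's double-centering), and only
genuine pairwise interaction structure remains observable. The
stimulation epoch itself is overwritten with a saturated square wave on
the stimulated pair, exercising the buffer/discard rules.

*Small-montage caveat — the downstream predictor.* The downstream
analysis correlates each node's baseline coherence with the stimulation
node against its across-trial mean |Δk|. At clinical montages
(~100 channels) the stimulation node contributes ~1% of the common
average; at the generator's 8–10 channels it contributes ~1/N, and
referencing partials out exactly the shared variance that defines its
coherence partners — empirically inverting the coherence-to-stim profile
(rank correlation with true coupling ≈ −0.6 after CAR vs. ≈ +0.8 raw).
The pipeline therefore measures this one predictor on the raw,
pre-reference signal; every other quantity uses the referenced data. At
large montages the two versions coincide.

*Structural networks.* `heavy_tailed` grows a preferential-attachment
graph with lognormal edge weights — strength is heavy-tailed and strong
modal controllers are weak hubs, matching the expected φ/strength
anticorrelation; `lattice` and `ring` give degenerate, equal-strength
controls. Hemisphere labels split the ROIs half/half with centroids
separated along x in a ±70 mm box.

*Recall features.* Standard-normal features with labels drawn from a
logistic model on planted weights plus logit noise; draws are repeated
until both classes are present with balance in [0.2, 0.8].

## Study sizes and what the experiments show

Simulated experiments are sized for a desk-scale machine while keeping
the statistics honest:

- **Type-I calibration**: 200 null sessions (6 channels, 15 trials); the
  rejection rate of the within-session stim-vs-surrogate rank-sum tests
  is pooled over the 4 bands × 3 metrics of each session and must stay
  ≤ 7% at α = 0.05. Surrogate draws reuse baseline data (sampling with
  replacement), so their values are weakly dependent; the pooled rate
  absorbs the slight inflation.
- **Parameter recovery**: 20 cohorts of 30 sessions (8 channels, 30
  trials each) with the planted structure: alpha/theta gain +0.35 and
  high-gamma intensity slope −0.7, both stim-routed. Recovered per
  cohort: the alpha/theta stim > surrogate rank-sum (significant at the
  Bonferroni level 0.0125), the negative mean dose correlation, and the
  positive mean downstream correlation. The planted dose and downstream
  effects deliberately produce *small per-session* effect sizes —
  comparable to clinical sessions, which need hundreds of sessions for
  power — so cohort size, not per-session strength, carries the test.
  The dose-sign recovery operates near 90% power at these conditions:
  single cohort draws occasionally miss.
- **Memory-state link**: 20 cohorts of 12 sessions whose stimulation
  sites are chosen by φ quantile on a 60-ROI heavy-tailed connectome
  (random sites cluster at high φ and leave no spread to correlate
  against); post-window mid-gamma power is boosted in proportion to
  normalized φ plus session noise, and the classifier-based Δp recovers
  a positive Pearson correlation with φ.

What passing does **not** show: the generator has no volume conduction,
no 1/f spectral background, no line noise, no nonstationarity or epileptic
activity, and its stimulation effect is an idealized coupling change, not
a biophysical response. Recovery of planted signs validates the pipeline's
statistical machinery, not any physiological claim.

## Numerical choices

- Windows are `round(0.5·fs)` samples with half-open sample spans, so odd
  rates (512, 1024 Hz) stay aligned.
- Coherence at zero-power bins is NaN (flagged, not raised); adjacency
  matrices are symmetrized after estimation to remove float round-off.
- Population (ddof = 0) variance for node-strength variance; sample
  (ddof = 1) sd inside Cohen's d.
- Eigenvalues are reported descending; φ itself is order-invariant.
- Degenerate statistics (zero-variance configuration vectors, constant
  correlation inputs, single-class training labels) raise typed errors;
  session aggregation catches the configuration-similarity case, logs it,
  and records NaN, which session averages skip.
- All generators accept integer seeds; session-level seeds are derived
  with `numpy.random.SeedSequence` so schedules, signals, injections and
  surrogates are independently reproducible.

## Known limitations

- The 0.5-s window with time–bandwidth 5 smooths coherence across ±10 Hz,
  blurring band edges; band values are therefore correlated between
  adjacent bands.
- The surrogate scheme inherits the limited 30-s baseline: surrogate
  trials overlap, and session-level surrogate averages are slightly
  dependent.
- At desk-scale montages CAR materially reshapes coherence networks (see
  above); conclusions about reference-sensitive quantities should be
  checked at realistic channel counts.
- `screen_artifact_electrodes` assumes artifact manifests as sustained
  amplitude elevation in the post window; transient ringing confined to
  the 100-ms buffer is invisible to it (by design — the buffer discards
  it).
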