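# Methods

`mskit` implements a complete analysis chain for quantifying motion-sickness
level (MSL) from multimodal physiological and behavioral recordings: raw
multi-rate streams are reconstructed onto exact sample grids, filtered with
per-sensor chains, summarized into 30-s windowed features, and related to
subjective MSL reports through repeated-measures correlation and an
interpretable additive model.  Because the cohort the design emulates is not
publicly deposited, the package ships a synthetic-data generator that
reproduces the statistical structure the analysis assumes, with ground truth,
so that every stage is testable end to end.

## Timeline reconstruction

Recording interruptions leave chronologically overlapping fragments (a
restart rewinds about 10 s).  Fragments are merged pairwise left-to-right
with the seam at the midpoint of each overlap — symmetric and reproducible,
given that only "at least 5 s per side" of trimming is constrained by the
acquisition protocol.  The first and last 30 s of the nominal 1200-s session
are trimmed, leaving the 1140-s effective segment.

Each sensor then receives an *expected sample grid*: nominal rate × 1140 s
indices (e.g. 128 Hz → 145,920).  Observed samples map to their nearest grid
index; when several samples compete for one index the temporally closest
wins, ties resolved toward the earlier sample (a determinism choice).  Empty
indices are filled by shape-preserving piecewise cubic Hermite (PCHIP)
interpolation over the observed anchors, which preserves monotonicity and
cannot overshoot.  Boundary gaps take the nearest observed value rather than
Hermite extrapolation: extrapolated cubics overshoot, and the edges fall
inside the trimmed margin anyway.  Grids are anchored at t = 0 of the merged
stream; with a synthetic common clock this is equivalent to anchoring on the
500-Hz reference stream.

Two properties of this scheme are worth stating precisely, because the test
suite freezes them:

- PCHIP influence is local but spans *two* intervals on each side of an
  anchor (the derivative estimates at the neighboring anchors move too).
- The chunk-jitter round trip (below) reconstructs a band-limited tone with
  RMSE < 1 % of amplitude for frequencies up to one eighth of Nyquist; at a
  quarter of Nyquist the shape-preserving limiter flattens the extrema of a
  period-of-eight-samples tone and the error grows to ≈ 2 %.

## Chunk-timing jitter model

The acquisition transport delivers samples in chunks at 15–20 Hz and logs
them in 1-s blocks, so the per-second sample count can deviate by about one
chunk.  Sample *timing* is synchronized against the reference clock, so the
deviation is modeled as grid-synced count jitter: a short second drops one
chunk's worth of samples, spread evenly so the gaps stay isolated (PCHIP
then fills them accurately), and a long second gains interstitial samples
read midway between grid points (which lose the nearest-sample contest
harmlessly).  A model that instead re-times samples within the second is
irreconcilable with nearest-index assignment: the timing quantization alone
costs on the order of 2π·f·Δt in amplitude, far above any useful tolerance.

## Preprocessing chains

Deterministic, length-preserving, zero-phase chains per sensor:

| sensor | chain |
|---|---|
| PPG 128 Hz | notch {30, 60} Hz → band-pass 0.1–10 Hz |
| EDA 128 Hz | R (kΩ) → G = 1000/R (µS) → notch 60 Hz → band-pass 0.03–5 Hz |
| EEG 500 Hz | notch {60, 120, 180, 240} Hz (±5 Hz) → band-pass 1–50 Hz → common average reference → artifact hook |
| SKT 1 Hz | three-point moving average (edges: two-point) |

The notch is realized as frequency-domain suppression with a raised-cosine
taper placed entirely *inside* the notch band: ≥ 20 dB attenuation inside
(the core is zeroed), exactly 0 dB ripple outside, zero phase.  Band-passes
are Blackman-windowed linear-phase FIR designs applied as centered
convolution over a reflection-padded signal (a symmetric odd-length FIR
applied centered is exactly zero-phase); the number of taps is chosen so the
transition band reaches the stopband one octave outside each edge, which for
the 0.03-Hz EDA lower edge means ~47k taps — applied via FFT convolution,
this is still milliseconds per session.  Attenuation depths and orders are
an engineering contract of this package; the acquisition study specifies
only the band edges.

The EEG artifact stage is a pluggable hook (any shape-preserving callable,
e.g. an external ICA-based component remover); the default is the identity
because the synthetic signals carry no ocular or muscular components.

## Windowing and features

A 1140-s session yields 38 aligned, non-overlapping 30-s windows.  The FMS
report trajectory (1–5 scale, re-reported at least every 30 s) is treated as
piecewise constant and integrated over each window (time-weighted mean).
Windows that preprocessing has split into discontinuous segments compute
each feature per segment and average.

Every signal-wise feature (SwF) source signal receives the same 8-feature
template — mean, variance (n−1 denominator), excess (Fisher) kurtosis,
standardized skewness, sample entropy (m = 2, r = 0.2 × SD), peak-to-peak in
the time domain; band power and PSD entropy in the frequency domain.
Conventions fixed here:

- **Sample entropy** counts Chebyshev template matches (pairs i < j,
  distance ≤ r) via a k-d tree; the naive O(N²) count in the test suite is
  the oracle and the two agree exactly.  A zero-variance segment is defined
  to have entropy 0 (the no-irregularity limit); a vanishing match count
  yields a missing value.  EEG sample entropy is computed after zero-phase
  decimation to 125 Hz.
- **Welch PSD**: Hann window, 50 % overlap, DC bin excluded, numerical
  negatives clipped.  PPG/EDA use FFT 8192 with 2560-sample (20-s) segments
  (narrow LF/SCL bands need the resolution); EEG uses FFT 2048 = segment
  length (≈ 0.24 Hz/bin); all other signals use rate × 20 s.  PSD entropy is
  the base-2 Shannon entropy of the PSD normalized to unit sum over the
  band; the heatmap entropy is also base 2 — bits throughout.
- **Band membership**: lower edge inclusive, upper edge exclusive, except at
  the scheme's top edge — so the EEG standard bands partition the whole-band
  bins exactly.
- Time-domain sub-band SwFs come from zero-phase band-pass copies;
  frequency-domain sub-band SwFs decompose the Welch PSD of the full-band
  signal.

Band schemes: PPG LF 0.1–0.15 / HF 0.15–0.4 Hz; EDA SCL 0–0.05, SCR 0.05–2,
sympathetic LF 0.045–0.25 Hz; EEG δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz.

**PPG window features** (12): beats are local maxima above an adaptive
mean + 0.5 SD threshold with a 0.3-s refractory period, on the 0.66–3.33 Hz
pre-filtered window; < 5 beats flags the window missing.  SD1 and SD2 always
use the Poincaré identities SD1 = RMSSD/√2 and SD2² = 2·SDNN² − SDSD²/2,
and CSI = L/T, CVI = log₁₀(L·T) with T = 4·SD1, L = 4·SD2.  LF/HF and the
breath rate come from the 4-Hz-resampled, linearly detrended inter-beat
series: LF/HF as the band-power ratio over the PPG LF/HF bands, breath rate
as the dominant spectral peak in 0.067–1 Hz, clipped to 4–60 breaths/min.

**EEG**: 5 scalp regions × 6 bands = 30 region-band signals (channel means);
7 spectral ratios (six from the global region plus frontal-θ/parietal-α);
336 functional-network metrics (28 channel pairs × 6 bands × {magnitude-
squared coherence over in-band Welch bins, phase-locking value from analytic
-signal phases}).

**Eye**: closure per eye (null position or within 1 mm L∞ of the gaze
origin), denoised by iterated suppression of isolated single-frame
inversions to a fixed point; AND/OR combinations as SwF sources; blink rate
by rising-edge counts averaged over the eyes; convergence distance as the
skew-lines distance with NaN for near-parallel gazes (cross-product norm
< 10⁻³) and the NaN fraction as the vergence-loss feature; gaze angles
(yaw = atan2(x, z), pitch = asin(clip(y))); gaze velocity from consecutive
direction dot products, saccades strictly above 100 °/s; 64 × 64 heatmap
entropy over [−90°, 90°]²; path length as summed per-frame angle.

**Head**: positions/rotations and IMU channels are direct SwF sources (the
IMU accelerations are sway/heave/surge); direction signals express each
frame relative to the window-average rotation — the normalized sign-aligned
component-wise quaternion mean, adequate for small intra-window rotations —
applied to (0, 0, 1).  The VOR proxy is the mean gaze-to-head velocity
ratio, excluding frames with head velocity below 10⁻³ °/s.

The registry enumerates 828 features: PPG 36, EDA 32, EEG 583
(240 + 7 + 336), SKT 8, Eye 55, HeadPose 64, HeadIMU 48, plus gender and the
merged susceptibility group.  The "HRV" token in the source instrument table
is a group label, not a 13th PPG feature; SDSD is computed internally for
the SD2 identity but not registered.

## Questionnaire scoring

SSQ: 16 items (0–3), subscale raw sums weighted N × 9.54, O × 7.58,
D × 13.92, total = 3.74 × (raw_N + raw_O + raw_D); exposure effect is the
post-minus-pre difference.  The item→subscale map is the standard 16-item
instrument's.  The Film IEQ (24 items) is scored by simple subscale
summation; the shipped item allocation is a synthetic stand-in following the
published four-subscale structure (the analyses only need the partition).

Susceptibility: per era, 9 transport/ride types score
9 × Σ(sickness frequency)/(9 − N_miss), with frequencies of 4 ("always")
remapped to 3 and vomiting sub-scores excluded; a fully missed era
contributes 0.  The percentile quartic is evaluated **exactly as printed**
in its source — `A·x − B·x² − C·x³ + D·x⁴` with A = 5.1160923,
B = −0.055169904, C = 0.00067784495, D = 0.000010714752 — which, B being
negative, adds the quadratic term; a documented
`convention="all-positive"` switch evaluates the conventional
all-positive-magnitude form instead.  Percentiles are clamped to [0, 100]
(the printed form exceeds 100 for scores above ≈ 17, so under that
convention most scored participants saturate into the high-susceptibility
tertile; the discrepancy is surfaced rather than silently resolved).
Tertile boundaries 33 and 66 go to the lower group; low and moderate merge
into "normal".

## Statistics

Repeated-measures correlation uses the common-slope ANCOVA formulation:
within-participant centering of both variables, r from the centered
correlation with the common slope's sign, df = N − k − 1, two-sided p from
the t transform.  Missing values are deleted pairwise and participants need
at least two complete observations.  The implementation is checked to 1e-9
against an explicit design-matrix least-squares oracle and cross-checked
against an independent statistics package.

The feature–MSL scan is exploratory and deliberately unadjusted; instead a
smallest-effect-size-of-interest gate is applied jointly with p < 0.05,
with strict thresholds |r| > 0.20 (medium), 0.25 (conservative), 0.30
(large).  Benjamini–Hochberg step-up adjustment (delegated to statsmodels,
oracle-checked) is available with named families for the confirmatory
analyses (per-dependent-variable ANOVA effects, the 16 IEQ × SSQ tests, the
6 MSL intercorrelations).  Mixed repeated-measures ANOVA is a thin
delegation to an established routine and is not re-implemented; its
real-cohort tables are outside what synthetic data can reproduce.

## Additive contribution model

The interpretable model is a generalized additive model fitted by cyclic
gradient boosting, written in-package: features are quantile-binned (32
bins); each boosting round sweeps the features in order, nudging each
piecewise-constant shape function toward the residual bin means with
learning rate 0.05; a 20 % internal validation split (the `validation
ratio`) drives early stopping, after which terms roll back to the best
validation state.  Pairwise interactions are then selected among the top
main effects by residual heterogeneity on a coarse 8 × 8 grid — the
`interaction` parameter (default 0.9) sets the pair budget as a fraction of
the feature count — and boosted the same way as 2-D terms.  Predictions are
intercept + Σ term contributions; a term's global importance is its mean
absolute contribution over the training rows, interactions attributed to
the pair.  Missing features are median-imputed from the training rows.
Everything is deterministic given the seed (default 42).

Fit metrics (R², Pearson and Spearman correlation of predicted vs observed)
are computed in-sample on the full fitted data, matching a full-dataset
attribution fit; a constant target is flagged degenerate.  Domain ablation
refits with one domain's columns removed (HeadPose and HeadIMU merge into a
single Head domain); single-domain and combination evaluations
(Head+PPG, +EDA, +Eye, +EDA+Eye) keep only the named columns.  All refits
assert the identical row set, and the degradation rate is
Δm(%) = (m_full − m_ablated)/m_full × 100 (positive = worse).
Participant-wise k-fold cross-validation partitions participants, never
rows, and reports per-feature importance mean and SD across folds.

## Synthetic cohort

The generator's defaults are the emulated study's conditions: sessions of
1200 s, sensors at their nominal rates (PPG/EDA 128 Hz, EEG 8 × 500 Hz, SKT
1 Hz, head pose and eye 30 Hz, head IMU 4 Hz), three MS conditions per
participant (classical, visually induced, composite), cyclic assignment to
the 16 counterbalancing cells (2 visual-induction types × 4 scenario
versions × 2 movie orders), fragmentation at ~0.3 interruptions/session
with 10-s restart overlap, ±1-chunk count jitter at a 16-Hz chunk rate.

The latent MSL trajectory is a logistic ramp (onset 25–60 % into the
session, rise time 7–13 % of it) scaled by a per-participant lognormal
susceptibility and the condition (composite 1.2 ×, visual-only 0.85 ×), plus
AR(1) noise, clipped non-negative — the simplest shape consistent with
monotone symptom accumulation.  FMS reports every 30 s apply a clipped
affine map (1 + 2 × MSL) with observation noise and integer rounding.

Each stream is a baseline oscillatory/noise process whose amplitude or
spectral balance is modulated by the latent MSL through signed loadings
(default magnitudes 0.3, signs matching the reported univariate effect
directions): electrodermal tonic/phasic amplitude ↓, head pitch-rotation
and surge energy ↑, eye-direction spectral flatness ↑ (a slow/fast process
mixture whose fast weight rises with MSL), EEG 10-Hz rhythm amplitude ↑
(hence sample entropy ↓).  Noise correlation times are kept well under the
30-s window so that, with all loadings zero, window features are near-
independent across windows and the rmcorr null is calibrated.
Questionnaire items derive from the same susceptibility scalar with
independent truncated-Gaussian item noise — only subscale-level behavior
matters downstream.

What the generator does **not** emulate: real pulse/EDA waveform morphology
and artifacts, ocular/muscular EEG contamination (the artifact hook is
exercised with synthetic removers only), vehicle dynamics or visual
content, distributional parameters of any real signal (none are published),
or between-feature correlation structure beyond what the shared latent
trajectory induces.  Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it assumes — not that it would reproduce
any particular cohort's numeric tables, which require the unreleased data.

## Validation experiments and problem sizes

- **Planted-sign recovery**: 30 participants × 3 sessions, loadings ±0.3 on
  the electrodermal and head families, 20 seeds; the headline features
  (whole-band EDA peak-to-peak, pitch-rotation variance) recover the
  planted signs with p < 0.05 in ≥ 90 % of seeds (in practice: all).
- **Null calibration**: 12 participants × 3 sessions, all loadings zero,
  8 seeds × 48 near-independent moment features (mean/variance/kurtosis of
  distinct channels); the fraction of rmcorr tests with p < 0.05 falls
  inside the binomial 95 % interval around 0.05.
- **Model attribution**: 12 participants × 3 sessions with a dominant
  electrodermal loading (−0.8), 10 seeds, ~40-column multi-domain matrix;
  the top-importance feature is electrodermal and the electrodermal
  ablation shows the largest R² degradation in ≥ 90 % of seeds.

These cohort sizes are the package's validation design; the full-scale
machinery (90 participants, all sensors) runs through the same code paths.

## Known limitations

- EEG sessions are written as CSV alongside the other streams; an EDF
  export hook would need an EDF writer dependency.
- The breath-rate estimator is a spectral-peak contract, not a validated
  respiratory algorithm.
- The printed-convention susceptibility percentile saturates quickly (see
  above), compressing the synthetic tertile structure.
- Coherence needs at least two Welch segments; short windows flag it
  missing rather than returning the degenerate value 1.
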