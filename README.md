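# mskit

A tested, reusable pipeline for quantifying **motion-sickness level (MSL)**
from multimodal physiological and behavioral recordings — the kind of data
collected while participants ride a motion simulator, watch sickness-
inducing video, or both: photoplethysmography (PPG, 128 Hz), electrodermal
activity (EDA, 128 Hz, recorded as skin resistance), 8-channel EEG (500 Hz),
skin temperature (1 Hz), head pose (30 Hz), head IMU (4 Hz), and eye
tracking (30 Hz), alongside questionnaire instruments (SSQ, FMS, MSSQ,
Film IEQ).

It is written for researchers who need the full chain from raw multi-rate
streams to interpretable statistics:

1. **Timeline reconstruction** — merge fragmented recordings (seam at the
   overlap midpoint), trim session edges (1200 s → 1140 s), map samples to
   an expected grid (rate × 1140 s; 128 Hz → 145,920 indices) with nearest-
   index assignment and shape-preserving cubic (PCHIP) gap filling.
2. **Preprocessing** — per-sensor zero-phase chains (notch, Blackman-FIR
   band-pass, conductance conversion G = 1/R, common average reference,
   pluggable artifact-removal hook, moving average).
3. **Feature extraction** — 38 aligned 30-s windows per session; a uniform
   8-feature signal-wise template (mean, variance, kurtosis, skewness,
   sample entropy with m = 2, r = 0.2·SD, peak-to-peak, band power, PSD
   entropy) over every source signal and band, plus window-derived features:
   HRV/Poincaré indices (SD1 = RMSSD/√2, SD2² = 2·SDNN² − SDSD²/2,
   CSI = L/T, CVI = log₁₀(L·T)), EEG power ratios and 336 functional-network
   metrics (coherence, PLV), blink/vergence/saccade/VOR eye features, and
   window-relative head-direction signals — 828 registered features.
4. **Questionnaire scoring** — SSQ subscales (N × 9.54, O × 7.58, D × 13.92,
   T = 3.74 × raw sum) and ΔSSQ; MSSQ score
   9·ΣS/(9 − N_miss) per era with the printed percentile quartic; Film IEQ
   subscale sums; tertile susceptibility groups.
5. **Statistics** — repeated-measures correlation (common-slope ANCOVA:
   r from within-participant-centered data, df = N − k − 1), SESOI effect-
   size tiers (|r| > 0.20 / 0.25 / 0.30 jointly with p < 0.05),
   Benjamini–Hochberg families.
6. **Contribution analysis** — an interpretable additive boosted model
   (quantile-binned shape functions, pairwise interactions, deterministic),
   global importances, domain ablation with degradation rate
   Δm(%) = (m_full − m_abl)/m_full × 100, single-domain and lightweight
   combination evaluation, participant-wise cross-validation.

Because the cohort this design emulates is available only on request, the
package includes a first-class **synthetic-data generator**
(`mskit.synthgen`): latent per-session MSL trajectories, quantized FMS
reports, all sensor streams with planted signal–MSL associations matching
the reported effect directions, fragmented recordings with overlap,
per-second chunk jitter, and the 16-cell counterbalancing design — with
ground truth, so recovery is checkable.

## Worked example

The numbered scripts under `analysis/` drive the pipeline over a
demonstration cohort (4 participants × 3 conditions, electrodermal +
temperature + head-pose sensors):

```bash
python analysis/01_simulate.py  --out scratch/demo/raw --seed 5
python analysis/02_reconstruct.py --in scratch/demo/raw  --out scratch/demo/recon
python analysis/03_preprocess.py  --in scratch/demo/recon --out scratch/demo/prep
python analysis/04_extract_features.py --in scratch/demo/prep \
       --raw scratch/demo/raw --out scratch/demo/features.csv
python analysis/05_score_questionnaires.py --in scratch/demo/raw --out scratch/demo/scores.csv
python analysis/06_correlate.py --features scratch/demo/features.csv --out scratch/demo/rmcorr.csv
python analysis/07_contribution.py --features scratch/demo/features.csv --out scratch/demo/contribution.json
```

The correlation scan prints the strongest feature–FMS repeated-measures
correlations; with the default planted loadings (head pitch/surge energy
rising with MSL, electrodermal amplitude falling) the head energy features
dominate:

```
104 features screened; 1 at the conservative tier
                      descriptor_id        r            p  tier
       HeadPose:rot_pitch:whole:var 0.789581 5.350952e-96 large
       HeadPose:dir_pitch:whole:var 0.789569 5.407158e-96 large
       HeadPose:pos_surge:whole:var 0.769438 2.783982e-88 large
HeadPose:dir_pitch:whole:band_power 0.729793 3.555361e-75 large
HeadPose:rot_pitch:whole:band_power 0.729749 3.665487e-75 large
```

— i.e. pitch-rotation variance correlates at r ≈ 0.79 with the per-window
FMS across sessions, with the planted positive sign.  The contribution
analysis then reports the additive-model fit and which sensor domain the
explanation rests on:

```
full model: R2=0.912 PLCC=0.956 SRCC=0.920
largest ablation degradation: Head (dR2 = 3.95%)
```

Removing the head domain degrades the fit most — consistent with where the
signal was planted (the small magnitude reflects redundancy with the
remaining correlated features, which is exactly what the single-domain and
combination evaluations are for).

## Layout

```
src/mskit/        library: synthgen, timeline, prefilter, features,
                  scales, stats, contrib, experiments
analysis/         numbered narrative drivers (simulate → contribution)
tests/            pytest suite incl. independent oracles (tests/_oracles.py)
scripts/          acceptance recomputation
docs/methods.md   model, conventions, design choices, limitations
```
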