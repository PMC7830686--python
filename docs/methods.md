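# Methods

`ppgsleep` stages sleep from a single photoplethysmography (PPG) channel.
Each 30-s epoch of the denoised pulse wave is reduced to 21 features —
11 time-domain statistics, 4 heart-rate-variability (HRV) spectral band
powers, and 6 nonlinear regularity measures — and a gradient-boosted
classifier assigns one of 3, 4 or 5 sleep stages under cross-validation.
This note records the model assumptions, the parameter choices that
matter, and what the synthetic-data experiments do and do not demonstrate.

## Pipeline

### Denoising

Raw PPG carries baseline drift (respiration, movement of the probe) below
~0.3 Hz and power-line plus broadband interference above the pulse band.
Both are removed in the wavelet domain with the biorthogonal-3.5 wavelet:

* The decomposition depth is chosen per sampling rate so the deepest
  approximation band covers less than 0.35 Hz (8 levels at 128 Hz, 6 at
  32 Hz); that approximation is zeroed, removing drift.
* Detail bands whose span exceeds 20 Hz are soft-thresholded with the
  universal threshold `σ·sqrt(2 ln N)`, with the noise scale σ estimated
  from the median absolute deviation of the finest detail level.
* Boundary handling uses periodization. With periodized filters the
  transform is a bijection between signal and coefficients, which makes
  the denoiser exactly idempotent — denoising an already-denoised signal
  is a no-op to machine precision. (With padded modes the transform is
  redundant and a modified coefficient set is not a fixed point; we
  measured a ~1% self-distortion under symmetric padding, which is why
  periodization is used.)

Measured on 30-s test signals at 128 Hz: a 0.1-Hz baseline tone is
attenuated by ~30 dB; a clean pulse train passes with Pearson r ≈ 0.99.

### Epoching and labels

The recording is cut into non-overlapping 30-s epochs, each carrying one
six-stage R&K label (W, S1–S4, REM). Labels outside the recognized
vocabulary (e.g. movement time) mark the epoch unscored, and unscored
epochs are dropped. Coarser schemes merge stages: 5-class (AASM-style)
S3+S4→N3; 4-class S1+S2→LS (light sleep), S3+S4→SWS (slow-wave sleep);
3-class S1–S4→NREM. Class balancing, when requested, randomly
undersamples every class to the minority count with a seeded generator.

### Time-domain features (11)

Median, maximum, minimum, range, mean, population (1/n) variance,
standardized skewness `E[(z−m)³]/σ³` and non-excess kurtosis
`E[(z−m)⁴]/σ⁴`, plus the Shannon entropy (nats) of a 100-bin histogram of
the first- and second-order difference sequences and their ratio. The
moment features are standardized (rather than raw moment sums) so they are
scale-free; the histogram bin count is fixed so the difference entropies
are deterministic and comparable across epochs. Degenerate inputs are
flagged rather than raised: a constant epoch returns skewness/kurtosis 0,
and a zero second-difference entropy returns ratio 0.

### HRV band powers (4)

Systolic peaks are detected on the denoised epoch: local maxima at least
0.3 s apart (a 200-bpm ceiling) exceeding a rolling mean + 1.0·SD
threshold (2-s window), then refined to sub-sample precision by parabolic
interpolation through the three samples around each peak. The refinement
matters: beat-interval spectra are sensitive to timing jitter at the
sample-period scale, and with it the detected per-stage heart rate tracks
the simulator's configured means to well under 1 bpm at low noise.

The RR series (successive peak-time differences, in ms) keeps intervals in
[0.3, 2.0] s, is cubically interpolated onto a 4-Hz grid, mean-removed,
and a single-segment Hann-windowed Welch periodogram is integrated over

| band | range (Hz) |
|------|-----------|
| TLF  | 0.04–0.10 |
| MF   | 0.10–0.15 |
| LF   | 0.04–0.15 |
| HF   | 0.15–0.40 |

Band powers are in ms². LF is accumulated as TLF + MF over identical
half-open frequency bins, so band additivity holds exactly on every epoch.
Caveat: a 30-s window gives a frequency resolution of ~0.033 Hz, so the
TLF band edge at 0.04 Hz is barely resolved; the bands are kept as defined
and per-epoch TLF/MF values should be read as coarse summaries. Epochs
with fewer than 4 usable beats are flagged and report zero powers.

### Nonlinear features (6)

All computed on the denoised PPG epoch itself (u₁…u_N), with Chebyshev
(maximum-coordinate) distances throughout and embedding dimension m = 2,
tolerance r = 0.15·SD of the epoch:

* **ApEn** — Φ^m − Φ^{m+1} with Φ^m the mean of ln of each template's
  match fraction, self-matches included.
* **SampEn** — −ln(A/B) with B (resp. A) the mean fraction of other
  templates within r at length m (resp. m+1), self-matches excluded, the
  average running over all templates of each length. A constant series
  scores exactly 0; if no pairs match at either length the value is the
  flagged sentinel +inf (substituted with 0, flagged, in the feature
  table).
* **FuzzyEn** — ln Φ^m − ln Φ^{m+1} where template similarity is the
  Gaussian membership exp(−ln2·(d/r)²) of mean-centered templates;
  exactly offset-invariant by construction.
* **PerEn** — Shannon entropy (nats) of ordinal patterns of order 3,
  delay 1; ties ranked by subscript (stable sort). Unnormalized.
* **Recurrence rate / DET** — binary recurrence plot of the m = 2,
  delay 1 embedding at threshold ε = 0.15·SD; the main diagonal is
  excluded from both statistics. RR is the density of recurrent points;
  DET the fraction of recurrent points on diagonal runs of length ≥ 2.
  Because the two single-cell corner diagonals can never reach the
  minimum run length, a constant series has DET = 1 − 2/(n²−n) rather
  than exactly 1 — a deliberate consequence of excluding the line of
  identity, so that constant-offset signals do not saturate DET.

The optimized kernels compute template matches as conjunctions of shifted
diagonals of the scalar match matrix |uᵢ−uⱼ| ≤ r (an O(N²)-bit
computation); the test suite checks all six measures against independent
direct-count brute-force implementations to 1e-10 on hundreds of random
series.

### Classifier and protocol

The classifier is off-the-shelf gradient boosting (LightGBM; scikit-learn
HistGradientBoostingClassifier as a fallback when LightGBM is absent) with
depth limit 8, 200 trees, learning rate 0.1, and a pinned seed. The
evaluation protocol is stratified 10-fold cross-validation over epochs
(leave-one-subject-out is available for multi-subject tables); features
are z-scored with training-fold statistics only, so no test information
leaks into scaling; every epoch is predicted exactly once and pooled into
a single confusion matrix. Feature columns are reordered canonically
before fitting, making predictions invariant to the column order of the
input table.

### Metrics

Accuracy = trace/total; per-class precision (column), recall (row), F1
(harmonic mean); Cohen's kappa = (p_o − p_e)/(1 − p_e) with p_e from
row×column marginal products. A never-predicted class takes precision 0
(flagged); a degenerate p_e = 1 reports kappa 0. The engine is
cross-checked against scikit-learn and against a published 3/4/5-class
evaluation of PPG staging on the CAP sleep database, whose printed
matrices it reproduces cell by cell (one 4-class REM precision cell in
the source is a typesetting error — the printed counts give 0.78, not
0.86 — and is excluded).

## The synthetic night generator

Real overnight PPG with expert-scored hypnograms cannot ship with the
package, so the generator produces recordings with the statistical
structure the pipeline exploits:

* a first-order Markov chain over the six R&K stages (row-stochastic
  transition matrix, strong self-persistence; default stationary
  occupancy ≈ 17% W, 58% NREM, 25% REM);
* per-beat heart rates drawn from stage-dependent normal distributions —
  defaults W 74, S1 70, S2 66, S3 62, S4 60, REM 72 bpm, with the
  beat-to-beat spread roughly doubled in REM (4 bpm vs 1–2 bpm), encoding
  the elevated autonomic variability of REM sleep;
* each beat rendered as two Gaussian bumps (systolic peak at 30% of the
  beat interval, dicrotic bump at 65%, amplitudes 1 : 0.35, widths
  proportional to the interval);
* additive baseline sinusoid (default 0.1 Hz, amplitude 0.2), power-line
  sinusoid (50 Hz, amplitude 0.02), and white noise (SD 0.05).

One seeded generator drives everything; a fixed seed reproduces the night
bit for bit. The recording carries its true systolic-peak times, so tests
can validate the peak detector and the HRV features against the
simulator's own draws.

What the generator does **not** emulate: respiratory amplitude modulation
of the pulse wave, SpO₂ coupling, arrhythmia, motion artifacts,
subject-to-subject morphology differences, and any stage-dependent change
in pulse *shape* (only the beat timing varies by stage). Passing the
synthetic end-to-end test therefore shows that the pipeline recovers
stage structure when it is carried by cardiac dynamics — it does not
certify clinical accuracy on real recordings.

## Problem sizes and numerical choices

* Simulated test recordings use 32 Hz sampling. The pulse band is fully
  resolved there, and the O(N²) nonlinear measures on a 960-sample epoch
  are ~100 ms; the generator default stays 128 Hz, which is the realistic
  bedside rate. At 32 Hz a 50-Hz tone would alias, so low-rate
  simulations set the power-line amplitude to 0.
* The end-to-end experiment generates 5000 epochs (~41 h) at low noise
  (SD 0.02, no power line), balances the three-class labels by
  undersampling (≥ 2000 epochs survive under the default occupancy), and
  runs stratified 10-fold staging. With the default feature set it
  reaches a kappa well above chance, and the shuffled-label control falls
  to 1/3 accuracy — the recovery is real, not pipeline leakage.
* Detector adequacy (band powers from detected vs true beats within 10%)
  is asserted at 128 Hz and near-zero noise: the comparison isolates the
  detector, whose residual error is sub-sample timing bias from the
  dicrotic overlap, a few ms per beat.
* Entropy sentinels: SampEn with zero matches returns +inf and the
  feature assembler substitutes 0 with a logged flag, so classifiers
  always see finite values. At 30-s epochs and r = 0.15·SD this occurs
  only for pathological inputs.
* All RNG flows through `numpy.random.default_rng` with explicit seeds;
  no global state is used or mutated.

## Known limitations

* Per-epoch HRV from 30-s windows cannot resolve the TLF lower edge; the
  band powers are coarse at the low end by design.
* The 4-class REM precision cell of the published benchmark is
  irreproducible from its own printed counts (documented print error).
* Real-data performance claims require a clinical dataset with PPG and
  expert scoring; the package reads EDF + hypnogram CSV for that purpose
  but ships no clinical data.
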