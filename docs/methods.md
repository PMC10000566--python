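# Methods

`ppgrr` estimates respiratory rate (RR, breaths/min) from a
photoplethysmography (PPG) waveform alone.  It combines a data-driven
spectral pre-estimate with four signal-quality features in a sparse
Bayesian regressor whose kernel is tuned by a population metaheuristic.
This note records the model, its assumptions, the tunable parameters,
the numerical choices, and what the synthetic-data experiments do and do
not show.

## Signal model and pre-estimation

Respiration imprints on PPG through three routes: amplitude modulation
(AM) of the pulse envelope, frequency modulation (FM) of the
beat-to-beat rate, and additive baseline wander (BW) at the respiratory
frequency.  Rather than filtering with fixed cut-offs — which discards
respiratory information at unusual rates — each 32-s PPG window
(advanced by an 8-s stride, i.e. 24 s overlap, matching an 8-s RR
update interval) is decomposed by ensemble empirical mode decomposition
(EEMD):

* **EMD sifting.** Cubic-spline envelopes through the local maxima and
  minima (mirrored-extrema boundary extension), iterated until a
  Cauchy-type criterion `sum((h_prev-h)^2)/sum(h_prev^2) < 0.2` or a
  hard cap of 50 sift iterations; at most 10 IMFs.  These are the
  standard sifting settings; the decomposition is complete by
  construction (input = sum of IMFs + residual to machine precision).
* **EEMD.** IMF k is the ensemble mean of trial IMF k over
  white-noise-perturbed copies (noise sd = 0.2 x signal sd, ensemble
  size 100 by default; a single integer seed drives the whole
  ensemble).  Trials with fewer IMFs are padded with zero IMFs before
  averaging.  Ensemble averaging suppresses the mode mixing that makes
  plain EMD unreliable on noisy PPG, at the cost of exact additivity.
* **IMF selection.** IMFs whose full-band dominant FFT frequency falls
  in the respiratory band (default 0.05–0.5 Hz, i.e. 3–30 bpm) are
  "respiration-dominated".  Windows with no such IMF are discarded and
  counted, never imputed.
* **PCA denoising.** The selected IMFs (columns of a samples x k
  matrix, centred) are reduced to the leading principal-component score
  series; its sign is fixed against the plain IMF sum.  Keeping exactly
  one component is the minimal reading of PCA-as-denoiser; the output
  variance is bounded by the stacked IMF variance.
* **Spectral peak.** The pre-estimate is `RR_P = 60 * f_peak`, where
  f_peak maximizes the magnitude spectrum of the mean-removed wave
  restricted to the band, after zero-padding by a factor of 16
  (bin width 60/(16*32) ≈ 0.117 bpm; the raw 1/32 Hz resolution of a
  32-s window, 1.875 bpm, is far too coarse).  Ties break toward the
  lower frequency.

## Quality indices

Four per-window features quantify how much the pre-estimate should be
trusted:

* **Mean skewness SQI.**  Skewness `(1/N) sum(((x-mean)/sd)^3)` (population
  sd; zero-variance convention 0) of each nonoverlapping 2-s PPG
  subwindow, averaged over the 16 subwindows of a 32-s window.  Clean
  pulsatile PPG is strongly skewed; symmetric noise dilutes it.
* **Respiratory quality indices** on the pre-extracted wave,
  down-sampled to 4 Hz (zero-phase Butterworth low-pass at 1.6 Hz, then
  index-rounded decimation to `round(n*4/fs)` samples — the rate ratio
  125→4 is not an integer, so polyphase decimation offers no shortcut):
  * `QR1`: peak of the unbiased normalized autocorrelation over lags
    of 2–20 s (30 down to 3 bpm).  The unbiased estimate keeps a
    perfectly periodic wave near 1 at long lags.
  * `QR2`: fraction of in-band spectral power within ±0.05 Hz of the
    dominant in-band peak.
  * `QR3`: largest magnitude among AR(9) poles (Burg method) whose
    angular frequency maps into the band; 0 when no pole is in band.

  All three are clipped to [0, 1].  A known limitation: `QR3` stays
  high on narrowband noise, because the mode-decomposed wave of even
  white-noise input is band-limited and its AR pole sits near the unit
  circle; the discriminative burden on noise falls mainly on QR1/QR2.
  This matches the modest per-subject correlations reported for the
  AR-based index on real data.

## The regression model

The five features (RR_P, mean SQI, QR1, QR2, QR3; z-scored with
training-set statistics, stored in the model) predict the reference RR
by a relevance vector machine (RVM) over the hybrid kernel

    K(x,z) = d1 exp(-gG||x-z||^2) + d2 tanh(a<x,z>+c)
           + d3 (s<x,z>+1)^2      + d4 exp(-gL||x-z||_1),

with d_m >= 0 and sum d_m = 1 (the simplex constraint removes the scale
redundancy between mixture weights and kernel amplitudes).  Local
(Gaussian, Laplacian) components interpolate; nonlocal (sigmoid,
polynomial) components carry global trends — the degree-2 polynomial in
particular can represent the identity map on RR_P exactly, which is the
model's fallback when quality features carry no signal.

Evidence maximization uses the MacKay fixed-point updates
(`alpha_i <- gamma_i/mu_i^2`, `beta <- (n - sum gamma_i)/RSS`), pruning
bases whose precision exceeds 1e9.  Numerical choices: alpha init
1/n^2, beta init 1/(0.1 var y), tolerance 1e-3 on max |d log alpha|,
max 1000 iterations, and a constant 1e-8 jitter on the Gram diagonal
(the sigmoid component can make it indefinite).  The bias column is
never pruned; its precision is capped at the prune threshold instead,
so a constant target is always representable and the linear algebra
stays finite.  The log marginal likelihood is tracked per iteration and
is non-decreasing in practice (asserted in tests to 1e-8 relative).
Predictions are clipped to a plausible 3–40 bpm.

## Kernel tuning

The whale optimization algorithm (WOA) searches a 9-dimensional box:
log10 Gaussian and Laplacian widths in [-3,3], log10 polynomial scale
in [-3,1], sigmoid scale/offset in [-2,2], and four raw weight
coordinates in [0,1] normalized by their sum (uniform fallback when all
are ~0).  WOA mechanics follow the standard formulation: control
parameter `a` decays linearly 2→0; per whale per iteration, coin flips
choose encircling the best solution, exploring toward a random whale,
or a logarithmic spiral (b = 1); positions are clipped to the box and
the best-so-far solution is elitist.  Defaults: 20 whales, 100
iterations, one integer seed for everything.

The tuning objective is k-fold cross-validated MAE of the fitted RVM
(k = 5 by default; folds split by subject whenever subject ids are
available, so no subject's windows leak across folds).  MAE is the most
direct reading of "closest to the reference rate", and it measurably
stabilizes the headline MAE improvement without hurting the (large)
RMSE improvement; squared loss remains available via
`tune_kernel(..., objective="rmse")`.  For training sets beyond 400
rows the CV objective is evaluated on a deterministic 400-row
subsample — evidence maximization is O(n^3) per candidate, and the
metaheuristic evaluates hundreds of candidates — while the final model
is refitted on the full training set at the tuned parameters.

## Synthetic data: what it emulates and what it does not

The generator produces a pulsatile PPG carrier (two-Gaussian beat
template — a systolic peak and a smaller dicrotic wave — evaluated on
an accumulated cardiac phase) with all three respiratory modulation
routes: AM swings the envelope by ±30% x depth, FM swings the
instantaneous heart rate by ±5% x depth, BW adds a respiratory-band
baseline at 50% x depth of the pulse amplitude.  Default depths are 0.5.
Each subject's RR is drawn from a normal centred at 18 bpm (sd 3.5),
truncated to 6–28 bpm, and follows a piecewise-constant schedule
(steps every 30–60 s, sd 1.5 bpm) emulating within-record RR
variability; the respiration channel's dominant frequency recovers the
schedule exactly by construction.

Corruption has three components, and their structure matters:

* broadband white noise (barely affects spectral RR estimation);
* **band-limited (0.05–0.5 Hz) motion noise**, the component that
  actually competes with respiration in the spectrum.  Degraded
  profiles apply a moderate floor to every window — so the
  pre-estimator's error distribution is continuous, with the "poor"
  profile calibrated to an RR_P test MAE near 1.9 bpm, the error scale
  reported for EEMD-PCA pre-estimation on critical-care data — plus a
  subject-level severity term and a slow latent temporal envelope, so
  corruption (and hence RR_P error) is genuinely correlated with the
  quality indices;
* occasional 1-s high-amplitude transients (motion artifacts).

Not emulated: realistic pulse morphology variation, arrhythmia,
sensor-specific baseline drift, or annotation noise in the reference
RR.  Consequently, passing the synthetic battery shows the pipeline's
mechanics and the quality-fusion principle work; it does not certify
clinical accuracy on monitor data, which requires evaluation on real
recordings (the WFDB import path exists for that purpose).

## Evaluation protocol and problem sizes

Metrics: MAE, RMSE, Bland–Altman mean difference with 95% limits of
agreement (mean ± 1.96 x sample sd of the differences), a per-range
breakdown over reference-RR bins (<12, 12–16, 17–20, 21–24, >24 bpm;
the reference is rounded to the nearest integer before binning, as the
gapped integer bin labels require), and per-subject Pearson
correlations between each quality index and the pre-estimate's
relative error |RR_P − RR_I|/RR_I.

The packaged experiments (test suite and `scripts/acceptance.py`) run
the full pipeline on 10-subject, 180-s "poor"-profile cohorts with an
EEMD ensemble of 25, a 6-whale x 8-iteration WOA budget and 3-fold CV,
averaged over 5 seeded cohort replicates — sizes chosen so the whole
battery runs in minutes on one CPU while every stage operates at its
real sampling rate (125 Hz) and window length (32 s).  At these
conditions the fused prediction's RMSE improvement over the raw
pre-estimate is large and consistent (≈1 bpm, nearly every seed); the
MAE improvement holds on the 5-seed average (≈0.1–0.2 bpm) and on
most but not all individual cohort draws.  This asymmetry is expected:
the RVM is tuned under a homoscedastic noise model, so its largest
gains come from suppressing the catastrophic errors that dominate
RMSE.

## Degenerate inputs and tie-breaks

Constant or monotone signals decompose to zero IMFs with the input as
residual.  Zero-variance inputs return 0 for skewness and all RQIs.
Spectral peak ties break toward the lower frequency.  Windows with no
reference RR sample are skipped; windows with no respiratory IMF are
discarded and reported as a discard percentage.  A singular system in
the RVM update is retried once with an added 1e-8 ridge.
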