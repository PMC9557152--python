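# Methods

`bspmaf` implements a spatiotemporal analysis chain for dense body-surface
potential mapping (BSPM) of persistent atrial fibrillation (AF): from a raw
252-lead torso recording to segment-level indices of AF organization and
their cross-validated association with catheter-ablation outcome. This note
documents the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not show.

## The signal model

A recording is an `m x n` matrix `X` (samples x leads, 1 kHz, canonically
n = 252). It superimposes:

* **atrial activity (AA)** — quasi-periodic fibrillatory f-waves, dominant
  frequency (DF) ≈ 4–9 Hz, spatially structured and approximately low-rank
  across leads;
* **ventricular activity (VA)** — QRST complexes at irregular RR intervals,
  roughly an order of magnitude larger than the AA;
* baseline wander and broadband noise.

All analyses operate on 1-min *AA segments*: the recording after VA
cancellation, z-normalized per lead, divided into contiguous non-overlapping
5-s windows (12 windows per canonical segment; the duration is configurable,
any segment of ≥ 2 windows is accepted).

## Preprocessing

1. **Lead repair.** Leads flagged bad are replaced by the inverse-distance-
   weighted mean of their `K = 4` nearest good neighbours on the vest plane.
   Quality flags are an *input*: bad-lead identification on clinical data is
   typically visual, so the package does not attempt automatic detection.
2. **Band-pass 1–30 Hz**, 4th-order Butterworth, forward–backward
   (zero-phase). Zero-phase filtering everywhere is a deliberate choice:
   phase distortion would bias DF-peak shapes and template alignment.
3. **R-peak detection** — Pan–Tompkins-style: 5–15 Hz band-pass, derivative,
   squaring, 150-ms moving-window integration (MWI), adaptive threshold,
   200-ms refractory. Peak positions are refined to the dominant local
   extremum of the reference lead (highest-RMS lead by default). Two
   robustness details matter in practice: refinement iterates to a fixed
   point (so a hit on the S wave migrates to the R deflection), and a
   recording whose MWI peaks do not stand out from the background (ratio
   < 5) is declared beat-free — without this gate the *relative* threshold
   would hallucinate beats on ventricular-free signals.
4. **Delineation and clustering.** Fixed windows (−80 ms … +400 ms around
   each R peak) are clustered by correlation distance of their concatenated
   multi-lead shapes (complete-linkage hierarchical clustering, cut at 2
   clusters by default, clusters under 3 beats merged into their nearest
   neighbour). The cut is accepted only when it shows real structure (mean
   silhouette ≥ 0.3). This last rule is load-bearing: f-waves are narrowband
   and temporally coherent over seconds, so forcing a cut of a homogeneous
   beat population groups beats *by their atrial background*; each ensemble
   then retains coherent AA and re-injects it on subtraction. A genuinely
   multi-morphology population (e.g. ectopic beats of opposite polarity)
   scores silhouette ≈ 0.85 and is still split.
5. **Spatiotemporal QRST cancellation.** Per beat, the cluster's ensemble-
   average template is aligned by an integer shift search (±20 ms, scored on
   the 20 highest-energy template leads) and fitted by least squares with a
   per-lead scalar scale (optionally, per lead, a 3-lead mixing of the
   template on the lead and its two nearest neighbours). Two refinements:
   * per-lead scales are ridge-shrunk toward the beat's global scale
     (weight 0.3 × mean per-lead template energy). On leads where the
     template is weak an unconstrained scalar fit mostly absorbs atrial
     signal; shrinkage lets those leads inherit the globally estimated beat
     amplitude.
   * the subtracted waveform extends 300 ms beyond the core window, using a
     neighbour-masked extended ensemble. A zero-phase 1-Hz high-pass smears
     the large-area T wave into a slow rebound that outlives the delineation
     window; subtracting only the core window leaves that rebound behind
     (measured at ≈ 0.5× the AA power on synthetic data).
   Beats are processed in temporal order on a running residual.
6. **Finalization.** Per-lead z-normalization, then a zero-phase 10th-order
   30-Hz Butterworth low-pass (smoothing subtraction discontinuities),
   then re-standardization of mean and variance. The final step is a ~0.1%
   correction on band-limited input; it makes the unit-variance contract of
   a normalized segment exact rather than approximate.

## Spectral analysis

Welch periodogram per lead: 2-s Hamming window, 50% overlap, 4096-point FFT
(bin width fs/4096 ≈ 0.244 Hz at 1 kHz), no detrending (segments are already
band-passed and normalized). The DF is the frequency of the highest PSD peak
within the fibrillatory search band, 3–12 Hz by default (configurable; ties
break toward the lower frequency for determinism). A flat in-band spectrum
leaves the DF undefined (NaN), and undefined leads are excluded—and
counted—wherever DFs are aggregated.

## Reconstruction and electrode selection

For a window `X` and a subset `S = X[:, idx]` of k lead signals, the
least-squares reconstruction of all leads is `X_hat = S A` with `A = S⁺ X`
(Moore–Penrose pseudoinverse; singular values below 1e-10 × σ_max are
treated as zero, and rank-deficient subsets yield the minimum-norm solution
with a warning). The optimal rank-k reconstruction is the truncated SVD
`X_k = U_k Σ_k V_kᵀ`; by the Eckart–Young theorem its Frobenius error
√(Σ_{j>k} σ_j²) lower-bounds every k-lead subset reconstruction. Errors are
summarized as

* `NRMSE = ‖X − X_hat‖_F / ‖X‖_F`, and
* `ABSE` = mean absolute per-lead DF difference between `X` and `X_hat` (Hz).

**Greedy sequential selection (SEQ_k).** Electrodes are chosen one at a
time, each step adding the column that minimizes the residual Frobenius
error given those already chosen (exact column-subset selection is NP-hard).
The implementation works on the n×n Gram matrix with incremental
orthogonalization — O(k·n²) after one `XᵀX` — and is algebraically identical
to naive pseudoinverse refitting (asserted in the tests). Ties break toward
the lowest lead index; columns adding no span (duplicates) are never chosen
while informative candidates remain. k is free in [1, n); the clinical
survey range is 8–30, with k = 8 matching the number of independent leads in
a standard ECG.

**Fixed ECG-analogue subsets.** `ECG8` is the 8 vest leads closest to the
six precordial plus two limb-equivalent positions; `ECG11` adds three
posterior leads (V8/V9/V10 analogues) on V6's horizontal plane. The exact
vest coordinates are proprietary, so the shipped geometry is synthetic but
consistent: two 9×14 panels with the analogue subsets defined positionally
and overridable via a JSON geometry file. Lead indices are 0-based
internally and 1-based in every file and report.

## The indices

For each segment the subset (SEQ selected on the *first* window; ECG fixed)
and its mixing `A¹` are anchored on window 1. Each later window `i` is
reconstructed from its own subset samples through the anchored `A¹` and
compared with its own rank-k truncation:

    ER_NRMSE(i) = ‖Xⁱ − S_kⁱ A¹‖_F / ‖Xⁱ − X_kⁱ‖_F
    ER_ABSE(i)  = Σ_l |DF(Xⁱ_l) − DF(X_hatⁱ_l)| / Σ_l |DF(Xⁱ_l) − DF(X_kⁱ_l)|

averaged over windows 2..W. Since the anchored reconstruction has rank ≤ k,
ER_NRMSE ≥ 1 always; values near 1 mean the first-window representation
stays near-optimal over time — spatiotemporally stable, organized
fibrillation. Temporally drifting activity inflates the numerator but not
the (per-window-optimal) denominator, which is the signal the index carries.

Edge policies, chosen because the ratio definitions leave them open: a
window with a vanishing PCA denominator (exactly low-rank) is excluded and
the segment value is the mean of the remaining windows; for ER_ABSE a window
with zero denominator *and* zero numerator scores 1 (both reconstructions
DF-perfect), zero denominator with nonzero numerator is excluded, and leads
with undefined DF are dropped from both sums. A segment where every window
is excluded reports the index as absent.

**NDI** (non-dipolar component index): per window, the fraction of variance
not captured by the first three principal components of the column-centered
window (centering implements the variance semantics), averaged over all
windows. NDI is subset-independent and lies in [0, 1].

## Outcome evaluation

Segments carry patient identity and a per-patient outcome: SR (sinus rhythm
maintained after ablation) vs AR (arrhythmia recurrence). Because segments
from one patient are correlated, all resampling is *group-wise* at the
patient level:

* **Folds.** Three independent outcome-stratified random 80/20 splits of the
  patients (the 3-fold/80-20 protocol is not a partition; a partitioning
  mode is a one-line change via `test_frac`). A patient never appears on
  both sides of a fold.
* **Significance.** Per fold, on the 80% side: Lilliefors normality check on
  each group at α = 0.05, then one-way ANOVA (both normal) or Wilcoxon
  rank-sum; the mean p over folds is reported with the dominating test.
* **ROC.** A univariate logistic model (unpenalized, standardized predictor)
  is fitted per fold; AUC and ROC are computed on held-out segments with
  *fixed orientation* — higher index value scores toward AR, the positive
  class — so the AUC is a property of the index and can legitimately fall
  below 0.5 for an index lower in AR than SR. (A per-fold re-orientation by
  the fitted slope would clamp every AUC to ≥ ~0.5 and hide the direction
  of the association.) Sensitivity (AR detection rate) and specificity (SR
  detection rate) are reported at the Youden-J threshold of the ROC pooled
  over test folds; per-fold p-values accompany the report.

## The synthetic generator

No public clinical BSPM recordings exist for this setting, so the package
ships a generator whose defaults are the study conditions: 252 leads, 1 kHz,
60-s segments, DF field a smooth 5→7 Hz spatial gradient, 4 atrial sources,
QRST at log-normal RR (mean 0.7 s, CV 0.25) scaled 8× the AA, broadband
noise 0.1, baseline wander 0.2 at 0.3 Hz.

* **f-waves**: each source is a harmonic series (f, 2f, 3f at amplitudes
  1, ½, ¼) on a phase track with slow sinusoidal modulation *plus Brownian
  phase diffusion* (0.6 rad²/s, coherence time ≈ 1.5 s). The diffusion is
  essential realism: AF f-waves are quasi-periodic, not phase-stable tones,
  and without it atrial activity stays coherent across beats, making
  ensemble-average cancellation unrealistically adversarial. Source
  fundamentals are the distinct values of the DF field (quantized to
  `n_sources` levels for smooth fields) and each lead predominantly mixes
  its nearest-frequency source, so per-lead DF tracks the field up to that
  quantization; a weak per-lead oscillator (relative amplitude 0.08, < 1%
  energy) pins each lead's exact target.
* **Regimes.** *Organized*: constant mixing and fundamentals. 
  *Disorganized*: the mixing takes an independent random step (relative
  magnitude 0.3) at every 5-s window boundary — aligned with the analysis
  windows so the instability the indices detect is explicit — and
  fundamentals jitter ±0.5 Hz per window.
* **QRST**: analytic sum of Gaussians (Q/R/S plus a wide T at +220 ms,
  total ≈ 480 ms, decaying to negligible amplitude within the span), a
  spatially smooth per-lead amplitude pattern with flipped, attenuated
  posterior polarity, and 5% per-beat amplitude variability.

**What passing on this generator shows — and does not.** The generator
reproduces the structural features the pipeline exploits (low-rank spatially
smooth AA, narrowband DF, large quasi-irregular VA, the two organization
regimes); it does not model real torso volume conduction, electrode-contact
artifacts, respiration, or true fibrillatory dynamics. Synthetic results
therefore validate the *machinery* (cancellation accuracy, index direction,
protocol integrity), not clinical effect sizes: the clinical index values
and AUCs reported for patient cohorts cannot be reproduced without the
original recordings.

## Problem sizes and runtime

The validation suite runs the expensive studies at the canonical conditions
but with deliberately chosen replication counts: cancellation efficacy on 3
full recordings; index direction on 20 organized + 20 disorganized 60-s
segments (one-sided Wilcoxon); the evaluation protocol on a synthetic
cohort of 11 patients × 7 segments with regime-linked labels (a scaled
replica of a realistic study design), with a 20-permutation patient-level
label null. Index-level studies consume AA segments directly from the
generator; the cancellation chain is validated separately against ground
truth rather than re-run inside every index study. Whole-suite runtime is
roughly 15 minutes on one CPU.

## Known limitations

* The ECG-analogue lead mapping is positional on a synthetic geometry; on
  real vest data the mapping must be supplied by the user.
* Per-window PCA errors inside the index computation come from eigenvalues
  of the lead-space Gram matrix (identical quantity to the SVD route,
  cross-checked to 1e-9, but accuracy degrades for singular values below
  ~1e-8 × σ_max — irrelevant at the noise floors considered).
* The cancellation's spatial model is a per-lead scale (with shrinkage) or a
  3-lead mixing; a full spatial transform as in richer spatiotemporal
  formulations is out of scope.
* WFDB input requires the optional `wfdb` package; the native formats are
  delimited text or flat binary with a JSON sidecar.
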