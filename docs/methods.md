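# Methods

## Pipeline

The analysis path is: continuous multichannel EEG → zero-phase 0.3 Hz
elliptic high-pass → zero-phase 60 Hz elliptic band-stop → common average
reference → per-trial extraction of the middle second of the fixation window
(condition `rest`, pooled across trials) and the middle second of the cue
window (condition = the trial's finger) → Hanning periodogram on 1..70 Hz →
log normalization against the across-segment mean spectrum → spectral PCA →
projection-weight features, alongside mu (8–12 Hz) and beta (13–30 Hz) mean
band powers → r²-based channel selection → RBF-SVM decoding under repeated
stratified cross-validation.

Conventions that the code fixes deliberately:

- **Windows and indexing.** Sample indexing is 0-based with half-open
  intervals.  With 0-based trial onset `o` at rate `r`, the rest segment is
  `[o + 2.5r, o + 3.5r)` and the movement segment `[o + 4.5r, o + 5.5r)`.
  The periodogram window is taken literally as `H(t) = (1+cos(2πt/T))/2` on
  `t = 0..T−1`, a circularly shifted Hann whose leakage magnitude equals the
  conventional mid-peaked Hann for bin-centered tones; bin `k` of the 1-s
  DFT is `k` Hz.  No window-power compensation is applied — every downstream
  quantity (log differences, PCA, r², min-max-scaled features) is invariant
  to that constant.
- **Covariance pooling.** One spectral basis per session: the covariance
  sums uncentered outer products over every (segment, channel) observation,
  so the same eigenvectors apply at all channels.  No mean removal is
  performed; log normalization already references the mean spectrum.  A
  consequence of the uncentered form is that the leading eigenvector is
  close to the flat (broadband) direction, because single-periodogram log
  noise has a negative, frequency-independent mean (E ln X < ln E X).
- **Eigenvector signs.** Each eigenvector is flipped so that its mean over
  the 8–12 Hz bins is ≥ 0; on an exact tie the largest-magnitude component
  is made positive.
- **r² statistic.** The pooled standard deviation uses the population
  convention (divide by n₁+n₂), which makes the statistic exactly the
  Pearson correlation between pooled feature values and a 0/1 condition
  indicator (point-biserial).  Channel-ranking ties break by channel index.
- **Channel selection leakage.** By default, r² channel selection is refit
  inside each training fold (selection on all data before CV is optimistic);
  `RunConfig.selection_mode = "all"` reproduces the optimistic variant.
  Classic mu/beta features always use C3 plus its 8 montage neighbors for
  right-hand movements (C4 for left).
- **Classifier.** Soft-margin SVM with Gaussian RBF kernel.  The penalty and
  kernel width come from base-2 exponent grids −10..20 and −15..10 at unit
  step (31 × 26 = 806 candidates), scored by inner cross-validated accuracy
  on the training fold only; ties prefer the first candidate in (C, γ)
  order.  Multiclass uses one-vs-one majority voting; vote ties break by the
  summed signed decision values over the tied labels, then by the smallest
  class index.  Outer protocol: stratified 5-fold CV, 30 repeats, all
  partitions seeded.
- **Significance.** Accuracy comparisons use two-sided t-tests on
  per-repeat mean accuracies (one-sample against chance, paired between
  feature sets run with identical partitions).  With a single synthetic
  session these units are CV repeats, not independent subjects; treat the
  p-values as descriptive.

## Numerical choices

- High-pass: order-4 elliptic, 0.01 dB passband ripple, 40 dB stopband.  The
  small ripple keeps the doubled (forward+backward) passband response within
  1% of unity; a conventional 0.5 dB ripple would sit ~11% low across the
  passband after two passes because even-order elliptic high-passes approach
  their ripple floor far above the cutoff.
- Notch: elliptic band-stop with stopband 60 ± 0.15 Hz and 0.3 Hz transition
  bands (minimal order via `ellipord`, 40 dB stopband, 0.01 dB ripple).
  Zero-phase filtering uses reflect padding of min(10 s, signal length);
  these narrow-band filters ring for seconds, far beyond scipy's default pad
  length.
- PSDs are floored at a configurable ε (default 1e-20) before logarithms;
  without a floor, non-positive values raise.
- Eigenvalues in [−1e-10·scale, 0) are clipped to zero; more negative values
  raise.  Asymmetry beyond 1e-8·scale raises.
- SVM fits carry a deterministic libsvm iteration cap (10 000).  It binds
  only in the pathological large-C corners of the grid on inseparable data,
  where the exact solution is worthless anyway, and bounds grid-search cost.

## The synthetic generator

Real recordings for this task are not available, so validation runs on a
generative model whose planted quantities are exactly the ones the pipeline
measures.  Per channel `n` and condition `c` the target one-sided PSD in
µV²/Hz is

    S_nc(f) = exp(s_nc) · A·f^(−χ)  +  (g_nc · a_α,n)² G_α(f)  +  (g_nc · a_β,n)² G_β(f)

with `A·f^(−χ)` the 1/f background (default scale 20 µV²/Hz at 1 Hz,
χ = 1), `G` unit-peak Gaussian bumps at the rhythm centers (defaults:
alpha 10 ± 2 Hz, beta 20 ± 2.5 Hz), and rhythm amplitudes placing the peaks
`log_amp · rhythm_map[n]` natural-log units above the background at the
center (defaults 2.2 alpha / 1.2 beta on the most rhythmic channels).
Movement sets the ERD attenuation `g_nc < 1` (default 0.55 over C3 and its
neighbors, 0.75 over the right homolog; power falls as g²) and the broadband
log offset `s_nc` (default 0.4 over left premotor/parietal channels).
Per-finger signatures add broadband offsets (default +0.35) on channel duos
sliding along the premotor and parietal rows — a synthetic somatotopic
gradient.  The rhythm component additionally waxes and wanes: every 2-s
block draws a per-channel log-amplitude jitter (sd 0.3) applied jointly to
the alpha and beta bumps.  This coupled fluctuation is the cross-frequency
structure the PCA is designed to expose; without it the rhythm structure is
visible only through ERD and its eigenvalue sits at the edge of the
periodogram-noise bulk.

Signals are realized per 2-s block as colored noise (target amplitude
spectrum, seeded random phases, inverse FFT), joined with 10-ms equal-power
raised-cosine cross-fades, plus a continuous 60 Hz sinusoid (default 2 µV,
per-channel phase) and white noise (default 1 µV).  The trial timeline is
blank 2 s / fixation 2 s / cue 2 s at 250 Hz, 80 trials per finger by
default, in seeded-random order.  The montage is a schematic 64-channel
10-10-style grid in which C3 has exactly 8 annotated neighbors.

**Ground truth.**  The generator reports two unit-norm planted profiles on
the 1..70 Hz grid: the broadband profile (flat) and the coupled rhythm
profile, defined as the log-power direction along which a joint alpha+beta
amplitude change moves the spectrum, `2R(f)/(B(f)+R(f))` on the most
rhythmic channel, with its flat component removed.  The removal reflects an
identifiability fact, not a convenience: a frequency-independent log-power
component of a rhythm modulation cannot be distinguished from broadband
modulation by any orthogonal decomposition, so only the non-flat part of the
rhythm structure is recoverable even in principle.  Expected per-condition
log-power curves (background + rhythm + white-noise floor) are also
reported for spectrum-level checks.

**What the generator does not emulate:** ocular/muscle/cardiac artifacts,
electrode drift or bridging, inter-subject variability, volume conduction
from modeled cortical sources, non-stationarity beyond block-wise rhythm
jitter, and harmonics of the line frequency.  Passing recovery and
calibration tests therefore says the *pipeline* is correct and calibrated,
not that real EEG will yield comparable accuracies; on real data the
artifact-rejection steps this package deliberately omits (ICA-based
cleaning, trial video review) matter.

## Study problem sizes

The reference experiments (`motorspec.experiments`) use 64 channels and 20
trials per finger (200 segments), the size at which the planted effects are
comfortably above the periodogram-noise floor of a single session:

- *Recovery*: planted-effect session; best |cosine| between each planted
  profile and the top-3 eigenvectors.
- *Null calibration*: all condition effects switched off (rhythm jitter
  kept); detection and 5-finger decoding at 5 folds × 30 repeats = 150 test
  folds; the 95% band is the empirical 2.5–97.5 percentile interval of the
  per-fold accuracies; plus the maximum channel r² at 100 segments per
  group.
- *Feature-set comparison*: 5 folds × 6 repeats with identical partitions
  across feature sets (paired comparisons).
- *ERD check*: one channel with a strong alpha peak and amplitude
  attenuation 0.5, all other effects off; the movement/rest alpha band-power
  ratio is ≈ 0.25 because power scales as amplitude squared.

These runs coarsen the hyperparameter grid to exponent step 4 (56
candidates; the printed ranges are kept) and use 2-fold inner CV for the
~26-sample pairwise problems of the finger task.  Null calibration and
accuracy orderings are insensitive to grid resolution; the full 806-point
grid remains the default everywhere else.

## Limitations

- Single-session scope: no cross-subject aggregation or statistics over
  subjects; `compare_accuracies` operates on CV repeats.
- The EDF import path for real recordings is out of scope; sessions enter as
  float32 binary + JSON sidecar containers.
- Scalp maps are exported as per-channel CSV (channel, x, y, value); no
  interpolated scalp rendering.
- The literal uncentered covariance ties PC1 to the broadband direction;
  with a centered covariance the decomposition would differ.  This is
  faithful to the printed formula and matches the reported broadband PC1.
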