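# motorspec

Spectral-PCA features for detecting and decoding individual finger movements
in EEG, with a seeded synthetic-session generator for validation.

Classic motor-rhythm analysis summarizes sensorimotor EEG by band power in
the mu (8–12 Hz) and beta (13–30 Hz) bands, whose movement-related
attenuation (event-related desynchronization, ERD) separates movement from
rest but carries little information about *which* finger moved.  `motorspec`
implements the alternative: decompose the full 1–70 Hz log power spectrum
into data-driven **cross-frequency spectral structures** and use the
per-trial expression of those structures as decoding features.  It is aimed
at BCI/neurophysiology researchers who want a tested, reproducible reference
implementation of this analysis together with a generative model for sanity
checks that real recordings cannot provide.

## The analysis

For each 1-s segment `m` and channel `n` the pipeline computes a
Hanning-windowed periodogram on the integer frequency grid `f = 1..70` Hz,

    P_nm(f) = (1/T) | Σ_t X_nm(t) H(t) e^{-i2πft/T} |²,   H(t) = (1+cos(2πt/T))/2,

log-normalizes each spectrum against the across-segment mean (movement and
rest pooled),

    P̃_nm(f) = ln P_nm(f) − ln( (1/M) Σ_m P_nm(f) ),

and forms the uncentered spectral covariance pooling every
(segment, channel) pair as one observation,

    C(f, f′) = Σ_{m,n} P̃_nm(f) · P̃_nm(f′).

The eigenvectors `e_k` of `C` (spectral principal components, ordered by
descending eigenvalue, deterministic sign) are the spectral structures; the
projection weights `W_nm,k = Σ_f e_k(f) P̃_nm(f)` are the features.  PC1 is
characteristically a flat broadband profile; PC2 carries coupled alpha+beta
peaks.

Channel selection ranks channels by the point-biserial discriminability

    r = √(n₁n₂)/(n₁+n₂) · (mean(w₁) − mean(w₂)) / std(w₁ ∪ w₂),   r² = r·r,

keeping the top 10 per condition pair (union across pairs); classic mu/beta
features instead use C3 and its 8 montage neighbors (right-hand movements).
Decoding is an RBF-kernel SVM with `C` and `γ` grid-searched over base-2
exponents −10..20 and −15..10 (806 candidates) by inner CV on the training
fold, features scaled to [−1, 1] with training-fold extrema, one-vs-one
majority voting for the 5-finger task, under stratified 5-fold CV repeated
30 times.  Two tasks are built from each session: movement-vs-rest detection
(fingers pooled) and 5-finger classification (rest excluded).

The synthetic generator plants a 1/f background, alpha/beta rhythm bumps
with spontaneous coupled amplitude fluctuation, movement-related ERD, a
broadband log-power offset, per-finger somatotopic signatures, 60 Hz line
noise and sensor noise — all seeded — and reports the planted profiles as
ground truth so recovery is testable.

## Worked example

```python
from motorspec.experiments import recovery_study, ordering_study

print(recovery_study(seed=0))
# {'cosine_broadband': 0.9983, 'cosine_rhythm': 0.975, 'n_segments': 200}

result = ordering_study(seed=0)
print(result["detection_accuracy"])
# {'pc1': 0.999, 'pc2': 0.939, 'pc3': 0.483, 'pc123': 1.0,
#  'alpha': 0.956, 'alpha_beta': 0.97}
print(result["finger_accuracy"])
# {'pc123': 0.522, 'alpha_beta': 0.19}
```

The first call generates a 64-channel session (20 trials per finger), runs
the full pipeline and reports how well the top-3 spectral PCs recover the
two planted spectral structures (cosine similarity; both ≳ 0.97 here).  The
second compares feature sets: projection weights on PC1 detect movement
essentially perfectly and the three PCs together decode the five fingers at
52% (chance 20%), while mu/beta band powers detect movement (95–97%) but
are uninformative about finger identity (19%) — the qualitative signature
of cross-frequency structure carrying fine body-part information.

The same pipeline is scriptable from the shell:

```bash
motorspec run --config examples/run.yaml --seed 7 --out results/run7
```

which writes the session container, PC-profile CSV, per-channel r²
topography CSVs, accuracy tables and predicted-by-actual confusion matrices.

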