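# Methods

## The pipeline

The package estimates a single latent quantity — how deeply hypnotized a
subject currently is — as the posterior probability of the "deep" extreme
of a two-state classification. The model is deliberately minimal and
subject-specific:

1. **Calibration.** A first-session recording with manually labelled
   wakefulness and deepest-state intervals supplies training epochs. Only
   the two extremes are labelled; intermediate depth is never trained on,
   it is *read off* the posterior between the extremes.
2. **Band-pass.** 4th-order Butterworth, zero-phase (forward–backward)
   for training and offline analysis, single-pass causal for streaming.
   The causal group delay near the low band edge (~2/(π·f_low) s) is the
   price of real-time operation. Four candidate bands are first-class:
   1.5–45, 1.5–8, 1.5–14 and 4–15 Hz; which band discriminates best is an
   empirical, per-subject question, answered by the band sweep.
3. **Epoching.** 4 s windows emitted every 0.5 s. The "overlap of 0.5 s"
   phrasing used for such settings is ambiguous; we read it as *stride*
   0.5 s (a new epoch twice a second, so a 50-epoch smoothing window spans
   ~24.5 s). The literal reading (3.5 s stride) is available by setting
   `epoch_stride`. Epochs are labelled only when wholly inside one
   labelled interval; windows straddling a boundary are discarded from
   training rather than diluting a class.
4. **CSP.** Per-epoch sample covariances are trace-normalized (a gain
   control: each epoch contributes its covariance *shape*, not its
   power), class-averaged, and symmetrically ridged by `COV_RIDGE = 1e-6`
   × the composite's mean diagonal for conditioning. Filters solve
   `C_deep w = λ (C_deep + C_wake) w`; the returned filters exactly
   simultaneously diagonalize the two regularized class covariance
   estimates (machine precision; this is what the test-suite oracle
   checks against an independent `scipy.linalg.eig` route). Signs are
   fixed by making each filter's largest coefficient positive. Default
   `n_pairs = 3` (6 features) — a conventional choice that keeps the LDA
   well-posed on short calibration recordings with up to 19 channels.
5. **Features.** Log-variance of each filtered epoch. Doubling the
   signal amplitude shifts every feature by exactly log 4, which is why a
   *scalar* drift offset subtracted from the feature vector (default 0;
   values like 1.5 or 2.5 rescue sessions with electrode-gain drift) is
   the natural one-parameter non-stationarity correction. It is applied
   at prediction time only.
6. **LDA.** Closed-form pooled-covariance discriminant with a tiny ridge
   (1e-8 × mean diagonal). Priors are forced equal: labelled WAKE and
   DEEP durations are an artifact of the labelling procedure, not of
   state prevalence, and must not bias the curve. The Probability Value
   is the logistic of the discriminant; identical class means are
   rejected as an error rather than returning uninformative posteriors.
7. **Curves.** The Predictive curve streams a later session through the
   calibration model causally (each value uses only samples up to its
   epoch's end; chunked replay with carried filter state is bit-equivalent
   to the one-shot causal filter). The Native curve trains an auxiliary
   model on the session's own labels and rescoring the same session gives
   the best-case trace. Smoothing is a trailing average over
   `smoothing_epochs = 50` epochs, "immediate" variant: the first k−1
   outputs average whatever exists, so the curve starts with the session.
   `summarize_curve` reports maximal stretches with smoothed values at or
   above 0.7 — a heuristic reading threshold that shifts with the
   smoothing settings and is exposed in the configuration.

## Evaluation

**Blocked versus shuffled folds.** Overlapping epochs 0.5 s apart share
87.5 % of their samples. 10-fold CV that shuffles epochs before
partitioning therefore trains on near-copies of its test windows; on a
weakly separable synthetic session this inflates accuracy from ~58 % to
~97 % with nothing but leakage. Blocked mode keeps each class's epochs in
contiguous runs **and purges from the training set any epoch whose window
shares samples with a test window** (`ceil(epoch_length/stride) − 1 = 7`
index positions on each side of a test chunk). Blocked is the default;
shuffled exists precisely to demonstrate the optimism. Fold SD is the
sample SD (ddof = 1) over the ten fold accuracies. Ties at posterior 0.5
classify as WAKE, never over-claiming depth.

**Chance-level calibration.** The type-I control asks whether the
pipeline reports ~50 % when there is nothing to find. With overlapping
epochs this must not be tested against binomial bounds: each fold has only
~6 statistically independent 4 s windows per class while the fitted CSP
has 19 × 6 adaptive parameters, so the null distribution of the CV mean is
far wider than binomial (measured sd ≈ 10 points). The identical-signature
null therefore uses non-overlapping epochs (stride = epoch length, 240 s
per state), under which every epoch's correctness is an independent
Bernoulli(0.5) given the purged blocked folds and the binomial 99 % bound
is exact (measured over 8 seeds: mean 50.5 %, sd 4.45 vs theoretical
4.56). The permuted-label null keeps the study epoching and uses a
3-standard-deviation binomial band.

**Cross-session agreement** is plain per-epoch percent agreement at
threshold 0.5 with per-state recall, using the model's own band and
epoching.

## The synthetic generator

The generator emulates exactly what the method consumes: per-channel,
per-band power differences between two states over a 1/f background.
Each gain band contributes unit-variance Butterworth-filtered Gaussian
noise per channel, *shared* between the states and scaled by the
respective per-state gains; a coefficient c(t) ∈ [0, 1] crossfades WAKE
(0) into DEEP (1), linearly over scripted "MIX" ramps. Consequences, by
construction rather than by tuning: the DEEP/WAKE band-power ratio on an
isolated band equals the squared gain ratio up to Welch estimation error;
the MIX continuum is exactly amplitude-linear; c = 0/1 segments are
sample-distributed as the pure states. A 1/f^α background (α = 1,
amplitude 0.25 relative to the unit-variance rhythms) adds broadband
floor; overall scale is 10 µV before EDF quantization.

Default signatures (19-channel 10–20 montage, delta/theta/alpha): WAKE
has posterior-dominant alpha (occipital gain 2.0, parietal 1.6, else 0.8)
over weak slow waves (0.6); DEEP raises delta to 1.6 (frontal 2.0) and
theta to 1.8 while cutting alpha to 0.45. No study reports quantitative
effect sizes for these shifts, so the defaults are synthetic conventions
chosen once for clear separability — the benchmark shows the pipeline
*can* recover a strong, stable signature; it does not certify performance
on real EEG.

What the generator deliberately does **not** model: volume conduction
(channels are independent by default; an optional mixing matrix exists —
CSP only needs covariance differences, which the band gains supply),
eye-blink/EMG artefacts (only a crude optional burst injector for
robustness experiments), non-Gaussian microstructure, and within-state
non-stationarity. Passing tests therefore demonstrate correctness of the
machinery and sensible behaviour under the stated model, not clinical
validity.

## Numerical and design notes

- **EDF layer.** Plain 16-bit EDF, written and read natively; per-channel
  physical ranges cover the signal with 0.1 % headroom (range values are
  formatted to fit the 8-byte header fields exactly, so the stored and
  applied scalings agree), giving a round-trip error of at most one
  quantization step. Recordings whose length is not a whole number of
  1 s records are zero-padded, with the true sample count kept in the
  header's reserved field. Non-finite samples and out-of-range values
  are errors, never silent clipping. An independent reader (MNE) is used
  as the oracle in tests. Labels live in a trivially diffable TSV
  sidecar (`t_start<TAB>t_end<TAB>STATE`, seconds, half-open intervals).
- **Spectral maps.** Welch, 4 s Hann segments, 50 % overlap (matching
  the epoch scale), intervals combined weighted by usable segment count;
  seven conventional bands 1.5–4 … 25–45 Hz; the numeric channel × band
  difference table is the product, scalp rendering is an optional thin
  matplotlib layer.
- **CSP invariance.** With trace normalization, filter/feature invariance
  under a common channel mixing is exact for scaled orthogonal mixings
  (per-epoch traces preserved; a uniform gain k shifts all features by
  log k²) and only approximate (~1e-2 on eigenvalues) for general
  invertible mixings, which reweight the per-epoch normalization. Both
  regimes are tested.
- **Feature choice.** Whether the original tooling used log-variance,
  raw variance or normalized band power is unknowable from the outside;
  log-variance is standard for CSP + LDA and makes gain drift an additive
  scalar, which is the only reading under which "subtracting a constant
  from the feature vector" is a meaningful drift correction. Likewise the
  offset is applied to features, not the discriminant, following that
  wording.
- **Degenerate inputs.** Zero-variance projected epochs, empty
  recordings, montage/rate mismatches, missing classes, singular
  covariances after ridging, and out-of-band configurations all raise
  `ValueError` with the offending item named; the CLI maps validation
  errors to exit code 2 and numerical failures to 3.
- **Problem sizes.** The bundled tests and the acceptance script use
  250 Hz, 19-channel sessions of 4–10 minutes — enough for ~230 labelled
  epochs per class at the 0.5 s stride, which keeps every statistical
  check comfortably powered while a full run of suite plus acceptance
  completes in about a minute.

## Known limitations

- Two-state training cannot distinguish "medium depth" from "uncertain";
  the posterior conflates them by design.
- The probability scale is calibrated only at the extremes; 0.7 is a
  reading convention, not a validated depth unit.
- Blocked 10-fold CV on one session still shares slow session-level
  non-stationarity between folds; cross-session agreement is the honest
  generalization estimate.
- The EDF writer emits the plain dialect only (no EDF+ annotations);
  labels travel in the TSV sidecar.
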