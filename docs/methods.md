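# Methods

`oscipain` re-implements, as a tested pipeline, an analysis that asks
whether acute postoperative pain can be predicted from resting-state EEG
recorded shortly before surgery: patients whose day-3 numerical rating
scale (NRS) pain score exceeds 3 form a moderate/high-pain group, and both
the group label and the continuous rating are predicted from presurgery
spectral power. The clinical dataset behind the original analysis is not
publicly downloadable, so the package pairs the analysis chain with a
synthetic-cohort generator that reproduces the statistical structure the
analysis assumes. Everything below is the package's own account of what is
computed and why.

## Pipeline

1. **Re-reference** — every scalp channel minus the average of the two
   mastoids (M1, M2); mastoids are dropped, leaving 30 channels. The exact
   electrode labels of the original cap are not published; a canonical
   10-20 extended list is pinned in `oscipain.montage` so the feature
   index is deterministic.
2. **Filter** — zero-phase (forward-backward) IIR: 4th-order Butterworth
   high-pass at 0.5 Hz, 12th-order Butterworth low-pass with cutoff
   1.0375 × 80 Hz, 2nd-order band-stop at 48–52 Hz. The low-pass order and
   the slightly raised cutoff are needed jointly: a conventional 4th-order
   band-pass cannot keep 55–75 Hz within 1 dB while attenuating 95 Hz by
   20 dB. Measured responses (test suite): ≤1 dB ripple for 2–75 Hz tones,
   −32 dB at 50 Hz, < −20 dB at 0.1 and 95 Hz, no group delay on a
   symmetric pulse.
3. **Epoch** — consecutive non-overlapping 5-s windows; the trailing
   remainder is discarded.
4. **ICA** — extended infomax (via `mne.preprocessing.infomax`) on
   PCA-whitened concatenated epochs, components = channels, seeded and
   deterministic. Requires at least as many kept epochs as channels.
5. **Artifact components** — a deliberately small three-criterion
   classifier stands in for semi-automatic IC-triage toolboxes:
   (a) *focal frontal topography*: top-2 frontal squared loadings > 80% of
   the squared topography norm; (b) *broadband noise*: maximum absolute
   source autocorrelation over lags up to 20 ms below 0.5 — the absolute
   maximum over short lags, rather than the value at one fixed lag, is
   used because a narrowband oscillation's autocorrelation swings through
   ±1 within a cycle and would otherwise be misflagged at coarse sampling
   rates; (c) *eye blink*: >50% of source power below 4 Hz together with
   >50% of the squared topography on frontal channels. All thresholds are
   config keys. Flagged components are zeroed on back-projection.
6. **Amplitude rejection** — an epoch is rejected iff its absolute
   amplitude strictly exceeds 75 µV on any channel (|x| = 75 µV is kept).
   Rejection is idempotent and runs after IC removal.
7. **Spectra** — Welch PSD per channel: 2-s Hamming windows, 50% overlap,
   windows taken inside epochs (epochs are non-contiguous after
   rejection), averaged over all windows of all kept epochs, restricted to
   0.5–80 Hz in 0.5 Hz steps (160 bins). Features are linear-power µV²/Hz;
   a log10 transform is available behind a config flag but off by default.
   The cohort matrix is subject × (electrode-major, frequency-minor),
   30 × 160 = 4800 columns.
8. **Group statistics** — pooled-variance two-sample t-tests at every
   (electrode, frequency) cell; Benjamini–Hochberg FDR at q = 0.05 across
   the 160 bins within each electrode (a config flag widens the family to
   all 4800 cells; per-electrode is the minimal family consistent with
   per-electrode interval reporting); only maximal runs of significant
   bins spanning strictly more than 5 Hz (≥11 bins) are reported as
   intervals. Zero-variance cells yield t = 0, p = 1 with a warning rather
   than NaN. Band tests use FCz by default (beta 14–30 Hz, gamma
   31–50 Hz, inclusive edges). Partial correlations of band power with
   the day-3 NRS control for age; subjects whose band power lies more than
   3 sample standard deviations from the mean are removed first (the rule
   applies to the EEG-power variable only), and p uses a t reference with
   n − 3 degrees of freedom.
9. **Prediction** — features are shrunk to 20–70 Hz (3030 columns), then
   sequential floating forward selection (SFFS) wraps either a two-class
   LDA (group label) or multiple linear regression (day-3 NRS). The
   selection criterion is the leave-one-out cross-validated accuracy (LDA)
   or Pearson r between predicted and true ratings (MLR). Forward steps
   insert the best candidate; after each forward step, backward steps
   delete any in-set feature whose removal strictly improves the
   criterion (the just-added feature is protected against cycling; ties
   break toward the lowest feature index; improvement means an increase
   beyond 1e-12). The search stops when nothing improves or at 50
   features.

## Models and numerical choices

**LDA.** w = (Σ_pooled + λ·(tr(Σ)/p)·I)⁻¹(μ₁ − μ₀), with the bias placing
the boundary at the midpoint of the projected class means shifted by the
log prior ratio. The ridge λ defaults to 1e-3 (scaled by the mean
eigenvalue, so dimensionless); with up to 50 features against 66 training
subjects the pooled covariance approaches singularity and an
unregularized solve is unstable. A tiny absolute floor (1e-12) keeps
perfectly separable zero-within-class-variance features solvable; the
boundary midpoint is invariant to the ridge magnitude.

**MLR.** Ordinary least squares with intercept through a rank-revealing
solver; rank-deficient designs get the minimum-norm solution (logged).

**Fast LOOCV.** The wrapper evaluates thousands of candidate sets, so both
criteria use exact closed-form leave-one-out paths: a rank-one downdate of
the pooled scatter for LDA and the hat-matrix identity
e_loo = e/(1 − h_ii) for OLS. Both are asserted equal to explicit
per-fold refits in the test suite; they are algebraic identities, not
approximations.

**Non-nested vs. nested evaluation.** In the default ("paper") mode the
reported LOOCV performance is the same quantity the selection maximized —
the convention this style of analysis historically used — and a leakage
warning is emitted because the estimate is optimistically biased. The
nested mode reruns the entire selection inside each outer training fold
and is leakage-free; its trace is the full-data selection (the model one
would deploy) while its metrics come from the outer folds. On pure-noise
cohorts the non-nested estimate exceeds chance by a large margin (the
documented optimism) while the nested estimate does not. Nested LOOCV on
null data is in fact slightly *pessimistic* at small n (each fold's model
is weakly anti-correlated with the held-out label — the anti-learning
effect of cross-validation); the honesty test therefore bounds the
optimistic side strictly and the pessimistic side generously.

## Synthetic cohort

Each subject carries a latent pain-sensitivity trait z ~ N(0,1) that
couples two observables:

* frontocentral beta/gamma band variance, multiplicatively:
  power × exp(a·z) with a = effect_size / 1.596, so that a median split of
  z separates groups by about `effect_size` standard deviations of log
  band power (1.596 = E[z|z>0] − E[z|z<0]);
* the day-3 NRS: clip(round(3.5 + 2.5·z + N(0,1)), 0, 10). With the
  baseline at the 3-vs-4 group threshold the groups come out roughly
  balanced, matching the ~49% moderate/high incidence the analysis
  design assumes.

The signal model per channel is: 1/f^χ background (χ = 1, sd 9 µV,
spectrally shaped white noise); an occipital-weighted 8–12 Hz band-limited
alpha source (variance 25 µV² at unit gain); frontocentral-weighted
band-limited beta (14–30 Hz, 5 µV²) and gamma (31–50 Hz, 2.5 µV²) sources
peaking at FCz; 50 Hz line noise (2 µV); 300–500 ms frontal-dominant
blink bumps (60–90 µV at Fp, 6/min); and, in a controlled fraction of 5-s
windows, 150 µV 10-Hz bursts on one random channel that guarantee a ±75 µV
exceedance (exactly round(rate × windows) distinct windows are hit, so
rejection bookkeeping is testable). Mastoids carry attenuated background
only. All randomness flows from one root seed through per-subject
`SeedSequence` children, so cohorts are bit-reproducible and any subject
can be regenerated alone.

What the generator does *not* emulate: volume conduction from dipolar
sources, EMG/ECG artifacts, non-stationarity, electrode drift, or any
true physiological coupling between oscillations and pain. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes
— planted effects are detected, null cohorts stay null, bookkeeping is
exact — not that the clinical effect itself replicates.

A second, feature-level generator (`simulate_weak_feature_cohort`)
produces cohorts with hundreds of weakly informative, mutually
independent predictors of a continuous rating. This is the regime in
which a greedy LOOCV-driven selection keeps finding improvements instead
of plateauing, and it is used to study the wrapper running to its
50-feature cap. With the classification criterion this cap is essentially
out of reach at n = 60 — accuracy moves in steps of 1/60, so at most ~30
strict improvements exist — which is why the cap study uses the
continuous regression criterion.

## Problem sizes

The generator's defaults are the study conditions (67 subjects, 300 s at
1000 Hz, 32 channels). The test suite and the bundled analysis scripts
run reduced sizes chosen so each property is still decisively testable:
20–155 s recordings at 200 Hz (the 0.5 Hz spectral grid needs only a 2-s
Welch window and a Nyquist above 80 Hz; ICA needs 30 kept epochs),
cohorts of 40–60 subjects, 50 replicate cohorts for Monte-Carlo rates,
and pure-noise cohorts of n = 40 with 40 features for the nested/non-
nested comparison.

## Known limitations

* SASICA-style IC triage is replaced by the three documented criteria; no
  parity with the original toolbox is claimed, and muscle/ECG components
  are outside the generator, so criterion (b) is exercised mainly as a
  specificity guard.
* Whether the original analysis assessed the ±75 µV rule before or after
  IC removal is ambiguous; this pipeline rejects after removal.
* The headline clinical numbers (92.54% accuracy, R = 0.84, the 21–55 Hz
  interval, beta/gamma t and partial R values) belong to the unavailable
  patient data; nothing here claims to reproduce them, and the planted
  effect size of the synthetic cohort is a free parameter, not a
  reconstruction.
* EDF output quantizes to 16 bits over ±1000 µV (≈0.03 µV steps) and
  requires integer sampling rates and whole-second durations.
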