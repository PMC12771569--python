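# Methods

`mindstate` re-implements, as a tested pipeline, the EEG/behavioral analyses
that distinguish three mind states sampled by experience probes during a
sustained attention to response task (SART): task-focused (ON), mind
wandering (MW) and mind blanking (MB).  Because the original recordings are
not required (or assumed available), every stage is exercised end-to-end on
a synthetic session generator with planted, parameterized state signatures.
This note documents the generative model, the estimators, the statistical
conventions, the problem sizes the built-in studies run at, and what
passing those studies does and does not establish.

## The synthetic session model (`synthgen`)

The generator is a design of this package: it emulates the *structure* of a
SART experience-sampling session and plants qualitative state signatures
with tunable effect sizes.  One session is

```
EEG(t) = 1/f background + band oscillations x state/row gains
       + ERP templates at stimulus onsets + coupled shared sources
```

* **Background.** Gaussian noise with 1/f power restricted to 1–45 Hz
  (`noise_sd`, default 3 µV per channel), synthesized in the frequency
  domain.
* **Channels.** 32 named channels in 4 scalp rows (frontal, central,
  parietal, occipital; 8 each) with a 2-D layout.  Rows are the spatial
  resolution at which state effects are planted.
* **Oscillations.** Independent band-limited Gaussian noise per channel and
  band (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz;
  baseline amplitudes 3.0/2.5/3.0/2.0/1.4 µV), multiplied by a per-state,
  per-row gain (`band_power_map`).  Defaults plant the front–back
  dissociation: relative fast (beta+gamma) power in MB is raised frontally
  (gain 1.6) and suppressed posteriorly (0.5), with the opposite profile in
  MW (0.55 frontal, 1.45 occipital) plus fronto-central theta; MB
  additionally carries posterior delta (slow-wave-like) excess.  ON is flat.
* **Evoked responses.** Hann ("half-cosine") bumps added at stimulus onset:
  a posterior P1 (4 µV, 125 ± 40 ms) in every state; a central P3b present
  in ON (5 µV, 400–650 ms), reduced and delayed in MW (2.5 µV, 450–600 ms)
  and absent in MB.  A stimulus-category code (faces +, digits −) supports
  temporal decoding: an early occipital component (3 µV at ~200 ms, ON and
  MW only) and a late central component that is sustained in ON (2.5 µV,
  ~250–590 ms), brief and weak in MW (1.0 µV, ~360–580 ms) and absent in
  MB.  Amplitudes were chosen so a single desk-scale session decodes with
  peak AUC comparable to the group-level curves the method is meant to
  reproduce.
* **Coupling.** Each configured channel pair (defaults: two
  frontal–parietal pairs) shares alpha-band sources in two ways.  The
  *linear* path adds an identical zero-lag copy to both channels: it
  saturates phase locking but produces identical rank patterns, which the
  wSMI weighting discards.  The *nonlinear* path adds a copy lagged by 7
  samples and passed through a rank-preserving cubic distortion: symbolic
  dependence survives, phase coherence is diluted.  Per-state strengths
  (shared-variance-style fractions) are ON 0.1/0.7, MW 0.3/0.4, MB 0.8/0.1
  (linear/nonlinear), planting the PLV-up / wSMI-down dissociation in MB.
* **Task and behavior.** Stimuli tile each block with SOA ~ U(750, 1250) ms,
  1-in-9 No-Go, category drawn per trial (see "deviations" below).
  Responses follow per-state Bernoulli/log-normal behavior: miss
  probabilities 0.05/0.09/0.19, false-alarm probabilities 0.20/0.55/0.40,
  median RTs 500/440/620 ms for ON/MW/MB.  These were set once so that (i)
  the orderings are the reported ones (misses MB>MW>ON; RT MB slowest, MW
  fastest; FA MW,MB > ON), (ii) MB misses stay below 20%, and (iii) the
  prevalence-weighted means reproduce the printed overall rates (~10%
  misses, ~37% FA).
* **States and probes.** A semi-Markov schedule: exponential dwell per
  state, uniform switching, truncated at block boundaries.  Default mean
  dwells (47/32/15 s) make stationary occupancy ≈ the reported probe shares
  (52/35/16%).  Probes occur every U(40, 70) s within each block; the
  answer is the latent state at probe onset (optional report noise adds
  "don't remember" answers, merged into MB downstream).  Dwell is assumed
  long relative to the 5-s labeling window; with the default dwells ~90% of
  labeled trials match the latent state at stimulus onset, and the
  remainder act as label noise.

What the generator does **not** emulate: volume conduction and realistic
sensor mixing, eye/muscle artifacts, drowsiness drift, reporting biases,
inter-subject topography differences, or the separate-block design for
stimulus category.  Passing the recovery studies therefore shows the
*analysis machinery* recovers planted effects of plausible size at desk
scale — not that the effects exist in any real recording.

## Estimators

* **Normalized band power.** Welch PSD (Hann, 50% overlap; 1-s segments on
  5-s epochs, half-epoch segments on stimulus epochs), band integrals
  normalized by the 1–45 Hz union so the five fractions sum to 1.  A
  batched stride-tricks Welch (`welch_batch`) matches `scipy.signal.welch`
  to 1e-12 and is used for marker extraction at scale.
* **Sample entropy.** SampEn(m=2, r=0.2·SD), Chebyshev distance,
  self-matches excluded, same template count at both lengths; −ln(A/B) in
  nats.  Implemented as a numba-compiled O(n²) count; degenerate inputs
  (A=0 or B=0) yield a NaN sentinel that is excluded, never imputed.
* **Compression complexity (KC).** Median binarization (≥ median → 1, with
  a strict-inequality fallback when the median equals the lower of two
  values), bit-packing, deflate at level 9; KC = compressed/packed bytes.
* **Symbolic transform and wSMI.** k=3 rank patterns at lag τ, ties broken
  earlier-index-smaller; τ per band = max(1, round(fs/(3·f_hi))) (21/10/7
  samples for delta/theta/alpha at 250 Hz) so the kernel spans ~one cycle
  of the band's upper edge.  wSMI = (1/ln 6)·Σ w·p·ln[p/(p·p)] with w = 0
  on identical and time-reversed (sign-flip) pattern pairs; probabilities
  are maximum-likelihood histograms, degenerate distributions return 0.
  Signals are band-passed (zero-phase Hamming FIR, ~3 cycles of the band's
  low edge, length-capped on short epochs) and edge-trimmed 10% per side
  before symbolization.
* **PLV.** Analytic-signal phase difference after the same band-pass;
  resultant length over the central 80% of samples.
* **ROI aggregation.** Source-pair values averaged into 10 ROIs (5 regions
  × 2 hemispheres → 45 pairs).  The bundled 68-source scheme is a synthetic
  stand-in for an atlas-based lobe grouping; real source labels can be
  supplied instead.
* **ERP contrasts.** Two-stage hierarchical contrast: per-subject
  state-mean differences, paired t across subjects (Welch t over trials in
  single-subject mode), BH-FDR jointly over channels × timepoints.
* **Temporal decoding.** Per-timepoint regularized linear discriminative
  model on within-fold standardized channel amplitudes — a
  diagonal-covariance LDA with a fixed variance ridge (0.1) — under
  stratified 5-fold CV, scored by the Mann–Whitney (rank) AUC of pooled
  per-fold decision values.  The diagonal form makes the whole curve, and
  the label-permutation null, computable with batched matrix products, so
  the null re-runs the *identical* CV for every permutation.  Significance:
  add-one permutation p per timepoint, BH-FDR across timepoints, q < 0.05.
* **Behavior.** Misses = unanswered Go; FA = answered No-Go; RT over
  responded Go trials only; responses own their stimulus within a grace of
  the maximum SOA.  Contrasts: subject-level summaries, paired Wilcoxon
  signed-rank across subjects, BH-FDR over the measure × pair family; a
  within-subject bootstrap serves the single-subject case.  The two-stage
  scheme replaces the original mixed models; an external mixed-model
  backend can be hooked in where needed.
* **Group node statistics.** Same two-stage scheme per electrode or
  connection; paired t for ≥15 subjects, Wilcoxon signed-rank below; BH-FDR
  within one contrast's node family.
* **State classifier.** Features per stimulus epoch: 5 PSD fractions +
  SampEn + KC per channel, wSMI (delta/theta/alpha) between scalp-row
  averages (6 pairs × 3 bands), and mean ERP amplitude per channel in
  0.08–0.15, 0.15–0.35 and 0.35–0.70 s.  Pipeline per fold: median
  imputation → standardization → RBF kernel PCA (γ from the median
  pairwise-distance heuristic; components to 95% of the kernel spectrum) →
  random forest (300 trees).  The forest trains on a class-balanced
  downsample of the (embedded) training rows: labeled trials arrive in
  probe clusters whose members are strongly correlated, so per-class counts
  are effectively much smaller than they look and class weights alone let
  the majority state absorb the decision space.  Evaluation is
  leave-one-block-out CV scored by pooled balanced accuracy; the
  permutation null shuffles labels within subject and re-runs the CV,
  reusing the label-blind fold embeddings.  Unlabeled trials (> 5 s from
  any probe) are predicted by the pipeline refitted on all labeled rows and
  validated behaviorally.

## Numerical and convention choices

* Windows are half-open `[lo, hi)` seconds; sample index = round(t·fs).
* The 5-s labeling boundary is inclusive; "don't remember" merges into MB;
  the nearest following probe wins when probes overlap.
* EDF fixtures are 16-bit with per-file physical scaling (quantization
  < 0.1 µV at ±200 µV); lengths are padded to whole seconds.
* One top-level seed fans out to per-stage seeds via blake2 hashing, so any
  stage can be re-run in isolation bit-identically.
* Ties in predicted-state probabilities resolve toward ON, then MW.

## Study sizes in the built-in validation experiments

The seeded recovery studies (`mindstate.experiments`, also driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) run at desk scale:

* Marker/connectivity recovery: 20 sessions of 3 × 80 s blocks with equal
  15-s dwell; six 5-s ground-truth epochs per state.
* Decoding recovery: 20 sessions of 4 × 150 s blocks, equal 15-s dwell;
  trials balanced across states, decoded on a 125 Hz timepoint grid with a
  500-permutation null (the permutation count keeps the add-one p floor
  well below the BH threshold at 125 tests).
* Classifier study: 20 subjects, 6 × 250 s blocks with equal 25-s dwell
  (~27 probes and ~120 labeled trials per subject), features decimated to
  125 Hz, a 50-tree forest inside the cross-validation/permutation loops
  (balanced accuracy at these sample sizes is insensitive to ensemble size
  beyond ~50 trees; the final prediction pipeline uses the full 300), and a
  20-permutation within-subject null whose medians feed the group rank-sum
  test.  Equal dwell is used here deliberately: at the reported prevalences
  a 25-minute session yields too few labeled MB trials to train on, which
  is a sample-size limitation, not a property of the method.
* Behavioral descriptives: 6 subjects at the default (prevalence-weighted)
  conditions.

## Deliberate deviations from the original design

* Stimulus category is randomized per trial instead of alternating
  face/digit blocks: with block-grouped CV and per-state decoding at desk
  scale, block-pure categories would confound category with block.
* Mixed models are replaced by the two-stage surrogates described above.
* EEG inverse modeling is out of scope; the ROI connectivity stage consumes
  source-space-style signals directly (synthetic or user-supplied).
* Probes do not pause the stimulus train; probe interruption dynamics and
  vigilance covariates are not modeled.

## Known limitations

* wSMI carries a small positive estimator bias on short narrowband epochs
  (few effective samples after filtering); contrasts between states are
  unaffected but absolute values on 5-s epochs should not be compared
  across bandwidths.
* KC on 1-s epochs compresses only ~32 packed bytes and is correspondingly
  coarse; it is retained for completeness, the classifier weighs it
  accordingly.
* The permutation p floor is 1/(n_perm+1); with few permutations per
  subject the per-subject p is coarse, which is why group-level claims rest
  on the rank-sum test across subjects.
* Single-subject ERP contrasts use trial-level Welch tests and are
  anticonservative relative to the hierarchical analysis when trials are
  autocorrelated; the synthetic generator draws trials independently, real
  data should use the multi-subject path.
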