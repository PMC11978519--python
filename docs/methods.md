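# Methods

This note documents the models and numerical choices behind
`unitmatch`: what is computed, which parameters matter, what the
simulator does and does not emulate, and where the design was genuinely
open.

## Inputs and assumptions

The unit of input is a split-half average spike waveform: a
`(T, S, 2)` array of microvolts — time samples by recording sites by
the two halves of one session — together with the probe's site
positions in micrometers. The method assumes (i) spike sorting was done
independently per session and produced well-isolated units, (ii) the
averaged waveform of a neuron is stable within a session, so the two
halves act as an internal replication, and (iii) across sessions the
dominant geometric change is a rigid translation of the tissue relative
to the probe. All sessions compared together must share one sampling
rate, or the analysis windows would not be commensurable.

## Waveform features

All features are computed inside a peak window from 0.23 ms before to
0.50 ms after the global absolute peak (bounds rounded to samples; at
30 kHz the window is 23 samples). The window bounds are configurable
(`pre_peak_ms`, `post_peak_ms`).

* **Spatial decay.** The per-site footprint (max |amplitude| in the
  window) is fit as `A·exp(-λ·d)` by ordinary least squares in
  log-amplitude over sites within 150 µm of the max site. The fit is
  deterministic — no iterative optimiser. Sites whose amplitude is at
  or below the 0.1 µV floor are excluded from the fit: clamping them
  would flatten the log-space slope and bias λ downward (with fewer
  than three informative sites the clamped fit is used as a fallback).
  A non-decaying fit (λ ≤ 1e-9 per µm) triggers a flagged fallback to
  the full 150 µm radius. The site neighborhood for all later features
  is `d < min(d10, 150 µm)` with `d10 = ln(10)/λ`, always including the
  max site.
* **Centroids.** The centroid trajectory weights each selected site's
  position by the *absolute* waveform value at that sample. Signed
  weights, as a literal reading of the defining formula would have,
  can place centroids outside the site hull and divide by values near
  zero when the waveform changes sign across sites; absolute weights
  are stable and consistent with the footprint-weighted average
  centroid. Frames where every selected site is zero fall back to the
  average centroid and are flagged.
* **Travel direction** folds into one quadrant,
  `θ = atan(|Δx|/|Δy|)`, as defined. Steps below 1e-9 µm are treated
  as zero-length with direction 0; without this rule, numerically
  constant trajectories produce directions that are pure floating-point
  noise.
* **Baseline noise** (RMS on the max-site trace in a same-length window
  ending 1.33 ms before the peak window) is stored per half for
  diagnostics but is not used by the matcher.

## Similarity scores and scaling

Six scores are computed for every ordered pair (first half of one unit
versus second half of the other) and the two orientations are averaged,
making every matrix symmetric with the diagonal holding each unit's own
split-half comparison. Raw distances become similarities through 0–99
scaling: pooled minimum → 1, pooled 99th percentile → 0, clipped into
[0, 1], so raw values beyond the percentile (the most dissimilar ~1% of
pairs) score exactly 0. One pool spans *all* pairs, within- and
across-session, which keeps scores mutually comparable; constant raw
input (zero spread) maps to 1 everywhere and is flagged.

Notable choices:

* The waveform-correlation term is Fisher-transformed; the transform
  diverges at |ρ| = 1, so correlations are clipped to `1 − 1e-6`. The
  clip magnitude makes truly identical waveforms dominate the pooled
  minimum (score 1) rather than produce infinities.
* Centroid similarity is not percentile-scaled: it maps mean centroid
  distance linearly to 0 at `d_max = 100 µm`. Pairs beyond `d_max`
  score 0 on C but are still scored on the other five components —
  candidate pruning is left to the classifier, not to a hidden
  distance cutoff.
* Volatility similarity subtracts each unit's average centroid before
  comparing trajectories, so a trajectory rigidly displaced by
  uncorrected drift still scores as identical on its relative-shape
  term; trajectories identical up to a constant offset score maximally
  on both of its terms.

## Threshold, drift, classifier

**Putative-match threshold.** Histograms (100 bins on [0, 1], smoothed
with a 3-bin moving average) of the same-unit split-half total scores
and the within-session neighbor (< 50 µm) total scores are scanned from
1 downward; the crossing is the upper edge of the first bin where the
neighbor density exceeds the same-unit density. When the two
distributions are separated by a zero-density gap every point in the
gap is a crossing; the gap midpoint is used. This matters in
near-noiseless regimes: taking the gap bottom would admit across-session
pairs whose scores fall inside the gap into the putative-match class,
where they would then certify themselves through the classifier. The
threshold is finally lowered by `max(0, mean_within − mean_across)`
(Gaussian fits to the within- and across-session candidate score
distributions), compensating the systematic across-day score deficit
that drift and day-to-day variability produce. With no neighbor pairs
the threshold falls back, flagged, to the 5% quantile of the self-pair
scores.

**Drift.** For each ordered session pair, drift is the componentwise
median of the average-centroid displacement over putative
across-session matches — a translation-only (rigid) model, one
refinement pass: scores and threshold are recomputed once with the
correction applied to all position-dependent quantities, including the
centroid distances used to select across-session candidate pairs (this
makes the pipeline exactly equivariant to a rigid translation of one
session's coordinates). Session pairs without putative matches get zero
displacement and a flag. Per-shank or nonrigid drift is out of scope.

**Classifier.** Class-conditional densities per score: 100 shared bins
on [0, 1], 3-bin moving-average smoothing, floored at 1e-6 and
renormalised; the floor prevents zero likelihoods, and bin count,
smoothing and floor are config-exposed. Training pairs are all scored
pairs (upper triangle including the diagonal) labelled by the final
threshold; the classifier is fully refit after drift correction using
the post-correction labels. The prior is the empirical putative-match
fraction by default (`prior_mode="flat"` gives 0.5; the posterior is
otherwise prior-dominated at large session counts, which is the
intended behaviour — most pairs are not matches). A pair is called a
match when its posterior exceeds 0.5.

## Tracking

All cross-session pairs with posterior > 0.5 are visited in descending
probability (ties broken lexicographically by session and unit ids) and
merged under disjoint-set bookkeeping when the mode's rule holds:
liberal — always; default — each unit of the pair must exceed 0.5 with
every member of the other group in the same or an immediately adjacent
recording (adjacency by session order index, not calendar days);
conservative — every cross-group pair must exceed 0.5. A merge that
would put two units of one session into one group is skipped in every
mode, so session-uniqueness is an invariant, and blocked merges are not
revisited. Within-session pairs above 0.5 are reported as potential
oversplits but never merged. The three rules produce nested partitions
on graphs whose probabilities reflect a consistent underlying identity
structure (conservative ⊆ default ⊆ liberal); adversarial probability
patterns could in principle break the nesting, but graphs derived from
actual posteriors behave like the consistent case.

`P(track)` curves divide, for each ordered session pair, the number of
the reference session's units recovered in the other session by the
reference session's unit count, binned by signed day difference;
recordings sharing a calendar day land in the Δ = 0 bin.

## Functional validation

Fingerprints are computed per unit and per half; similarity between two
unit-days is always a cross-half correlation (half 1 × half 2, both
orientations averaged), so a unit against itself on one day yields
split-half reliability. ISI histograms use 50 log-spaced bins from 1 ms
to 5 s (bin count configurable; intervals beyond 5 s discarded; fewer
than two spikes gives a flagged zero vector). Population coupling uses
10 ms count bins against a tracked reference population, with self-
entries set to missing. Image fingerprints concatenate an onset-locked
(−0.3..0.5 s) and offset-locked (0..0.5 s) trial-averaged PSTH at 5 ms
with a per-image tuning curve — 160 + 100 + 112 = 372 entries for the
112-image protocol; the windows are protocol-independent, stimulus
timing comes from the stimulus table. AUC is the Mann–Whitney U
statistic normalised by the two group sizes (ties counted one half).
AUC reports keep only session pairs with at least 20 matched units,
optionally require day-1 split-half reliability > 0.2 (image
fingerprints), exclude units with a within-recording match, and fit an
ordinary least-squares slope of AUC against day gap.

The learning analysis normalises trial-averaged rates by the
pre-stimulus baseline (−0.2..0 s), and the cross-day discrepancy is, by
default, the plain sum over time bins of squared differences of the
normalised responses — exactly as the defining expression is written,
although it is named an RMS; `true_rms=True` switches to the literal
root-mean-square. Zero-baseline units are marked missing.

## Simulator

The generator is the study-conditions oracle for every test, so its
defaults are chosen once as a realistic desk-scale chronic recording:

* **Probe.** Two columns × 72 rows, 20 µm row pitch, 32 µm column
  spacing (144 sites, Neuropixels-like axial density). The 20 µm axial
  pitch is load-bearing: the amplitude-weighted centroid of a site grid
  tracks a rigid 15 µm displacement to within ~1.7 µm at this pitch,
  while at 32 µm pitch the truncated site neighborhood recovers only
  ~10–13 µm of it, making median-displacement drift estimation
  systematically biased.
* **Waveforms.** Per neuron: a three-lobe temporal template (trough,
  repolarisation bump, optional pre-peak deflection; the trough is kept
  the global extreme), an amplitude drawn from 80–300 µV, a decay scale
  λ in 0.02–0.08 per µm (d10 of roughly 29–115 µm), and a signed
  conduction delay along the probe axis (0.02–0.08 samples per µm)
  that shifts the template at distant sites. The propagation term is
  what makes centroid trajectories actually travel; without it the
  waveform is a rank-one spatiotemporal product, trajectories are
  static, and the route/volatility scores degenerate to noise.
* **Sessions.** Survival 0.8 per transition (dead neurons optionally
  replaced by fresh ones so the yield stays constant), rigid drift per
  session with magnitude up to 15 µm oriented predominantly along the
  probe axis, 10% multiplicative amplitude jitter per session.
* **Noise.** The stored waveform is a per-half average over that half's
  spikes, so its residual noise is the per-spike noise divided by the
  square root of the number of spikes averaged. `snr` (default 20) is
  the per-spike max-site SNR; the spike count per half follows the
  unit's firing rate over the session duration (min 25). Setting
  `snr=None` gives bit-identical noiseless halves.
* **Activity.** Spike trains are gamma-renewal processes (shape
  0.5–4, rate log-uniform 0.5–20 Hz) time-rescaled through a shared
  smoothed log-rate modulation with per-unit coupling, so ISI
  statistics are unit-specific and population co-fluctuations are
  controllable. Image responses add Poisson spike packets with
  per-image log-uniform gains and gamma-distributed latencies.

What the simulator does **not** emulate — and what passing tests
therefore do not certify about real recordings: spike-sorting errors
(oversplits, merges, contamination), nonrigid or within-session drift,
bursting and refractory structure beyond the gamma shape, electrode
degradation, waveform changes intrinsic to the neuron, and site-level
correlated noise. Results on real data depend on sorting quality in
ways the synthetic ground truth cannot capture.

## Problem sizes and determinism

Default test and acceptance runs use 60 neurons × 3 sessions (≈180
units, ~16,000 scored pairs) and 600 s halves for spike-based
fingerprints; the full pipeline runs in a few seconds on one CPU, and
everything is reproducible from a single integer seed (one
`numpy.random.Generator` drives the simulator; the pipeline itself is
deterministic).

## Known limitations

Translation-only drift; a single refinement iteration; the naive Bayes
independence assumption across the six scores (two score pairs are
internally averaged precisely because their components are too
correlated to treat as independent); percentile pooling ties every
score to the composition of the full pair set, so adding units changes
individual scores slightly; and the crossing-point threshold is a
histogram estimate whose bin width (0.01) bounds its resolution.
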