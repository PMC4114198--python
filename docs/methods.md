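# Methods

This note documents the models, algorithms, synthetic-data design and
numerical choices behind `bcgomp`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model and assumptions

Contaminated recordings are modelled as the elementwise sum
`Y = X_bcg + X_eeg + ε` of the cardiac artifact, the brain signal and
sensor noise (C channels × T samples, microvolts; default 250 Hz). No
statistical relationship between artifact and signal is assumed — in
particular no orthogonality or independence, which is what
distinguishes the spatial-inference approach from spatial PCA/ICA.

Two structural assumptions carry the method:

1. **Spatial low rank.** Full-scalp artifact-only data are approximately
   rank-r in space (r ≈ 4), so signals from a small channel subset
   linearly determine the rest.
2. **Temporal consistency of the spatial relationship.** The linear map
   W from insulated to non-insulated channels is stable over minutes
   within a session, even though the artifact waveform itself is highly
   non-stationary. Between sessions (cap re-seating), W can change
   substantially while the *selected channels* remain representative;
   the recalculation procedure (below) repairs W without re-insulating
   the scalp.

## Stage I: greedy subset selection

The inner problem — given a subset, find the best linear predictor of
all channels from the subset — is ordinary least squares on the expanded
form `min_W̃ ‖X − W̃ X[Λ_ins,:]‖_F²`; we use LAPACK `gelsd`, which
returns the minimum-norm solution when the selected rows are rank
deficient (a warning is emitted). The residual is then orthogonal to the
span of the selected rows, and the restriction of W̃ to the selected
rows is the identity block whenever those rows are linearly independent.

The outer subset problem is NP-hard; it is solved greedily. At step k
the score of candidate channel i is

    score(i) = Σ_j ⟨ R_j^(k−1) , X_i / ‖X_i‖_F ⟩²

summed over **all** channels j, with X_i the *original* (not residual)
row of channel i. The argmax joins the subset, W̃ is refit, the residual
recomputed. Choices the formulation leaves open:

* **Tie-breaking:** smallest channel index wins (deterministic, and what
  a literal argmax over increasing indices produces — the brute-force
  oracle in the test suite does exactly this).
* **Already-selected channels** are excluded from the argmax. Their
  score is zero anyway when the selected rows are independent; exclusion
  guards the rank-deficient case.
* **No demeaning or whitening** is applied by default (a `demean` flag
  exists).
* **Early termination** with a warning when the residual falls below
  1e-10 of the training norm before the budget is reached (degenerate
  low-rank inputs); the default budget is 20.

`cross_validate_budget` splits a recording into contiguous equal folds
(default 13), trains the greedy selection on each fold alone, and scores
held-out artifact estimation on the remaining folds, per budget. Because
the greedy selection is nested, one pass at the largest budget yields
the selection order, and smaller budgets refit W on the order's prefix.

Ad hoc comparison patterns: the **lines** pattern walks
nearest-neighbour chains radially outward from the four angular-quadrant
centroids of the montage; **patches** takes each quadrant-centroid
channel plus its nearest neighbours; **random** draws a uniform subset.
Group geometry is reconstructed qualitatively (quadrant placement); an
explicit channel list can always be supplied instead.

## Stage II: artifact estimation and reconstruction

`X̂_bcg = W X_bcg[Λ_ins,:]` is a plain matrix product — estimation is
linear, scale-covariant and suitable for streaming. Reconstruction is
either direct subtraction or subtraction followed by per-channel
group-sparse denoising: cut the channel into non-overlapping L-sample
segments (default L = 250, i.e. 1 s; the trailing remainder passes
through unmodified), stack them as columns of Y, and solve

    min_C ‖C‖_{2,1} + 1/(2µ) ‖Y − B C‖_F².

* **Basis B** (L × m, unit-norm columns): PCA over pooled non-overlapping
  segments of out-of-scanner clean EEG (default m = 40), or the first m
  DCT-II atoms as a data-free fallback. Both are pragmatic stand-ins for
  a learned dictionary; the group structure (one atom across all
  segments per group) is taken literally.
* **Solver:** monotone FISTA. Gradient of the fidelity term is
  `(1/µ)Bᵀ(BC − Y)`, step size `µ/σ_max(B)²`, proximal map the row-wise
  shrinkage `row ← max(0, 1 − τ/‖row‖₂)·row`. A candidate that increases
  the objective is rejected and the momentum restarted, so the recorded
  objective trace is non-increasing by construction. Convergence is
  declared when both the accepted and the candidate objective change
  fall below `tol` (default 1e-6) relative to the initial objective;
  the solution satisfies the ℓ2,1 subgradient condition to ~1e-4 on
  small instances when run to tight tolerance.
* **µ:** chosen by grid search `{10⁻³…10³} × (mean segment energy /
  (2m))` on a validation split (the first third of the acquisition in
  the pipeline), scored against ground truth in synthetic mode. Note
  that exact scale covariance of the whole pipeline requires µ to scale
  *linearly* with the data (the penalty is 1-homogeneous, the fidelity
  2-homogeneous).

## Inference-matrix recalculation

When a session's spatial mixing has drifted, a new W is estimated
without re-insulating: both the contaminated non-insulated recordings
and the artifact-only insulated recordings are 1-Hz high-passed
(zero-phase 4th-order Butterworth, forward–backward; the design is a
choice — only the cutoff is prescribed by the procedure), divided into
segments of a fixed number of heartbeats (default 10), truncated to the
shortest segment length, and averaged per channel. Heartbeat-locked
artifact survives the average; high-passed EEG, being incoherent with
the cardiac phase, attenuates like 1/√N. W is refit on the averaged
templates (min-norm least squares), insulated side averaged the same
way. Ten beats per segment leaves ≥ 10 segments in a 2-minute recording
at 60 bpm while making the per-segment EEG mean small.

## The OBS baseline

Per channel: epoch the signal in windows of one median RR interval
(default 25% before to 75% after each R-peak; edge-incomplete beats
skipped), compute the epoch-mean template and the top n_pcs (default 3)
principal components of the demeaned epoch matrix, and subtract each
epoch's least-squares fit onto {mean, PCs}. Samples outside any epoch
pass through. This follows the published algorithm, not any specific
plug-in release; artifact-template pre-smoothing and epoch
interpolation details of particular software versions are deliberately
omitted.

## Evaluation

* `nRMSE_i = 100·‖X_i − X̂_i‖₂/‖X_i‖₂` per channel; `ave nRMSE` is its
  mean over a channel set. Undefined (error) for zero-norm truth.
* Consistency matrices: entry (i, j) is the ave nRMSE on segment j under
  the model of segment i, in three modes — `full`/`fixed_model` (subset
  and W from i), and `fixed_subset` (subset from i, W refit on j, the
  channel-representativeness test).
* Alpha EC/EO test: within each 30-s block, non-overlapping 3-s epochs
  excluding 3-s guards after/before onsets; band power is the
  periodogram integral over the closed 8–10 Hz band; EC vs EO epoch
  samples are compared with a two-sided Wilcoxon rank-sum (epochs are
  unpaired between states), significance at 0.05.
* Spectrogram report: Hamming window 256, overlap 200, power units.
* Error maps are label → value tables with optional 2-D positions;
  figure rendering is out of scope.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of config + seed.

**Artifact (BCG) sessions.** r beat-locked sources mixed through smooth
spatial profiles, plus white sensor noise (default σ = 1 µV; the
noiseless part has exact rank r). Beats follow a 60 bpm rhythm with 5%
RR jitter. Each source waveform is a sum of 2–3 Gaussian-derivative
bumps (30–80 ms) **plus two Gaussian-windowed 7–12 Hz oscillations** —
the damped "ringing" that dominates real pulse-artifact spectra and
places a large share of artifact energy in the alpha band, as the
band-power magnitudes reported for real contaminated recordings demand.
Non-stationarity: 20% per-beat amplitude jitter, 20 ms per-beat latency
jitter, and a slow lognormal per-source gain drift (std 0.5, 20 s
correlation time — the Mayer-wave/vasomotor timescale). None of this
affects spatial inference accuracy by construction: the drift and
jitters act in source space, and any static W with `W·M_ins = M_nins`
remains exact whatever the sources do. Mixing columns are a smooth
Gaussian kernel over the montage plus a broad baseline, so adjacent
channels mix similarly and *every* channel is appreciably contaminated
(as at 3 T). The noiseless artifact is scaled to a 50 µV mean channel
RMS — 5:1 over the EEG.

**Clean EEG.** Per-channel 1/f² (power) background at 10 µV RMS, flat
below 1 Hz, plus a 9 Hz alpha tone on the posterior third of the cap:
10 µV amplitude eyes-closed, 7.5 µV eyes-open (the ~1.3 amplitude
contrast that cleaned in-scanner recordings actually show), random phase
per 30-s block. An optional lognormal waxing/waning envelope exists but
defaults off: burst correlation between contiguous 3-s epochs inflates
the rank-sum false-positive rate beyond its nominal level, and the
calibrated null is the more important default property.

**Session perturbation.** A follow-up session regenerates the cardiac
realisation and adds a smooth random perturbation to the mixing with
exactly the requested relative Frobenius magnitude; zero perturbation
reproduces the original spatial relationships.

**What passing tests do and do not show.** The generator reproduces the
features the method's correctness depends on — low spatial rank,
beat-locking, adjacent-channel similarity, temporal non-stationarity,
alpha-band-dominant artifact spectra, EC/EO alpha modulation — but not
real electrode physics (impedance changes, Hall-effect topography
distortion, gradient artifacts, heartbeat-detection errors: R-peaks are
an input throughout). Quantitative error levels on synthetic scenes are
therefore indicative, not predictions for any particular scanner or
subject; the qualitative orderings (baseline vs inference methods,
masked-then-recovered significance, consistency patterns) are the
claims under test.

## Problem sizes

Synthetic scenes run at desk scale by choice: 64 channels × 2 minutes
for the method-comparison scene (a stand-in for a 256-channel cap, with
a 256-point spherical-cap montage available for pattern geometry),
16 channels × 14 minutes for the EC/EO analysis (112 3-s epochs per
state), 24–32 channels for consistency studies. The full default
pipeline completes in a few seconds; the entire test suite and the
acceptance script each run in well under a minute on one CPU.

## Known limitations

* Heartbeat detection is out of scope; annotation quality directly
  bounds the beat-averaged procedures.
* The prior-basis construction (PCA/DCT) is a stand-in for the richer
  dictionary a dedicated out-of-scanner protocol could learn.
* The group-sparse route treats channels independently; no joint
  multi-channel sparse coding.
* EDF support is read-only, uniform-rate, via mne; the native format is
  the plain-text matrix + JSON sidecar pair.
* Offline batch only; the subtraction path is real-time-capable in
  principle but no streaming interface is provided.
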