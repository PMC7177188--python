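# Methods

`dfcstates` re-implements, as a tested pipeline, a computational chain for
identifying large-scale functional brain networks and dynamic
functional-connectivity (dFC) states from two simultaneously acquired
modalities — hemodynamic (fMRI-like) parcel time series sampled once per
TR, and electrophysiological source-strength (EEG-source-like) parcel
series sampled at 1 Hz — and for statistically matching networks and
states across the modalities. Because the recordings such a study rests on
cannot be shipped, a synthetic-data module with planted ground truth is a
first-class component: every empirical claim the test suite makes is a
recovery or calibration statement about known planted structure.

## The processing chain

1. **Source strength and parcel series.** For the electrophysiological
   modality, the three dipole moment components collapse to an overall
   strength `p(t) = sqrt(jx² + jy² + jz²)`, which is block-mean
   downsampled to 1 Hz. Voxel data are averaged within parcels (labels
   `1..R`; the full-scale convention is R = 90 anatomical parcels). The
   hemodynamic parcel series is low-pass filtered at 0.1 Hz
   (synchronized hemodynamic fluctuations of neuronal origin live below
   this) with a zero-phase forward–backward Butterworth filter (order 5 by
   default); the 1-Hz electrophysiological series is used unfiltered.

2. **Sliding-window dFC.** Pearson correlation matrices are computed in
   left-aligned, half-open windows: 42 s / step 6 s (21 / 3 samples at
   TR = 2 s) for the hemodynamic modality and 40 s / step 5 s (40 / 5
   samples at 1 Hz) for the electrophysiological one; 30 / 50 / 60-s
   presets support robustness re-analyses. The geometry must cover the
   final samples exactly; a `trim` option drops leading samples otherwise.
   Each window's upper triangle is vectorized (M = (R² − R)/2 values), the
   participant's static FC (the window average) is subtracted, and
   participants are concatenated in time into the group matrix
   `C ∈ R^(M×T)`.

3. **Connectivity states by dictionary learning.** `C ≈ D A` with
   unit-l2-norm dictionary columns (the state connectivity patterns) and an
   l1 penalty λ on the weights A, minimized by alternating exact sparse
   coding (cyclic coordinate descent to a KKT tolerance of 1e-6) with
   block coordinate descent on the dictionary columns (each column is the
   exact unit-sphere minimizer given the rest, so the fit term never
   increases). The state count k (grid 5..10) and λ (ten log-spaced values
   from 1 down to 10^-0.9 ≈ 0.1259) are selected by a 5-5-fold nested
   cross-validation minimizing a Gaussian-residual BIC,
   `n ln(RSS/n) + p_eff ln n` with `p_eff = kM + nnz(A_val)`; folds are
   contiguous column blocks within participants because windows are
   strongly autocorrelated, and the most recurrent per-fold optimum wins
   (ties toward smaller k, then larger λ).

4. **Validation by phase randomization.** Surrogate dFC matrices add
   independent uniform phases to each connectivity pair's Fourier
   transform (amplitude spectra, variances and autocorrelations preserved;
   coordinated structure destroyed; a shared-phase variant additionally
   preserves cross-correlations as a stricter null). A state is
   *meaningful* when its rank-1 reconstruction error
   `E(i) = ||C − d_i a_i||²_F` lies below the 5th percentile of the errors
   of states re-estimated from surrogates (10,000 surrogates at full
   scale; the desk-scale default of 200 runs the identical code path). The
   cross-modal match is validated by re-estimating states from
   phase-randomized hemodynamic data and correlating them with the true
   electrophysiological states.

5. **Network and state matching.** Component maps are thresholded at
   pseudo-Z = 3.0 and compared to network templates by Dice overlap; the
   permutation null is the 95th percentile of the full components ×
   templates Dice matrix (40 × 10 = 400 values at full scale). States are
   compared by the Pearson correlation of their pattern vectors with
   two-sided t-based p-values, Bonferroni-corrected over all k_a × k_b
   pairs. Non-exclusive best matches are resolved by the randomized greedy
   procedure: permute the order of the smaller set (exhaustively when the
   factorial fits the `n_orderings` budget, else seeded draws), assign
   each item in order to its best unassigned partner, and keep the
   ordering with the highest average similarity. This greedy procedure is
   itself the object of study; an exhaustive brute-force optimum is
   included as a testing oracle only, and the tests confirm the greedy
   result never exceeds and almost always equals it.

6. **Task mapping.** A GLM with one unit-boxcar regressor per condition —
   convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
   1:6 ratio, 32-s kernel) for the hemodynamic modality, raw for the
   electrophysiological one — is fitted by OLS; contrast t-values map to Z
   through the t CDF; clusters form at voxel Z > 2.7 with a configurable
   extent threshold (26-connectivity), and subject maps combine by the
   fixed-effects Stouffer rule. Prewhitened or mixed-effects inference is
   intentionally out of scope: it belongs to external tooling, not to this
   chain's substance. Each state's weight course is correlated with the
   window-averaged task contrast, Bonferroni-corrected over states.

## The synthetic ground truth

`synth` plants k_true community-structured correlation matrices (elevated
within-community correlation 0.8, shrunk toward the identity by 0.9 S +
0.1 I so every mixture is a samplable covariance; candidate states with
vectorized-pattern correlation above 0.3 are redrawn). A nonnegative
weight course mixes them over time — by default one-hot dwells of 60 s, so
a ~40-s window sees mostly-pure states — and the latent series draws
independently at each native-rate sample from the mixture covariance, with
leftover mass on the identity. Both modalities observe the *same* latent
path: the hemodynamic one after HRF convolution at native rate, block-mean
decimation to the TR and additive Gaussian noise (SD 0.05 by default); the
electrophysiological one after block-mean decimation to 1 Hz and the same
noise model. Spatial fixtures are sums of 3-D Gaussian blobs (mirrored
across the midline when bilateral, peak pseudo-Z 8); each template spawns
a noisy "independent component" re-scaled to unit robust background SD,
optionally with one hemisphere suppressed to emulate lateralized
electrophysiological networks. Task designs cycle five 8-s facial
expression conditions with pseudo-randomized order per cycle (a strictly
periodic order would make the 40-s cycle alias exactly against the 40-s
analysis window), or alternate 24-s up/down regulation blocks.

What the generator does *not* emulate: scanner and physiological
artifacts, spatial leakage between parcels, the electromagnetic forward
problem, inter-subject anatomical variability, or temporally
autocorrelated latent innovations. Passing tests therefore demonstrate
that the chain recovers what it is designed to recover under its own
generative assumptions, not that it would perform identically on real
recordings.

## Numerical choices that turned out to matter

**Window-estimator noise.** After HRF convolution (bandwidth ~0.06 Hz) and
the 0.1-Hz filter, a 42-s hemodynamic window retains roughly six effective
samples, so each window's correlation estimate carries per-pair noise of
SD ≈ 0.4 — an order of magnitude more than the 1-Hz modality. Because
consecutive windows overlap 7-fold, this estimator noise is temporally
persistent and mimics brief state visits. Measured consequence: the
population optimum of the dictionary objective can sit away from the
planted solution (polishing an oracle-initialized solution lowers the
objective while degrading recovery), and more data alone does not fix it.
Four safeguards address the resulting local-minimum landscape:

- *Farthest-point initialization*: the first atom is a seeded random data
  column; each further atom is the candidate column least correlated with
  those chosen, which essentially never seeds two atoms inside one
  recurring pattern.
- *Near-duplicate repair*: when two converged atoms correlate above 0.75,
  the one with the weaker weights is re-seeded from the worst-reconstructed
  data column and the alternation continues (at most three repairs).
- *Deterministic restarts*: `n_restarts` independently initialized fits,
  keeping the lowest penalized objective.
- *Sign canonicalization*: `d a = (−d)(−a)`, so each returned state is
  flipped to make its weight sum nonnegative, keeping patterns comparable
  across fits and modalities. Centered dFC deviations sum to zero across
  states, which makes the *negative* of a state exactly representable;
  constraining the weights nonnegative (`nonneg=True`, used by the
  pipeline and the cross-modal experiments; the plain library default
  stays unconstrained) removes the incentive to code such anti-states.

**Positive-only matching.** A cross-modal match asserts that two states
describe the same connectivity pattern, so by default only significantly
*positive* correlations are admissible pairs (`positive_only=False`
restores any-sign matching).

**Task association sign.** Total state expression is conserved, so when a
task-locked state rises every other state's weight is diluted: negative
weight–contrast correlations are an expected side effect, not task
involvement. The state–task table reports two-sided significance and a
separate `task_associated` flag requiring a positive correlation.

**Degenerate inputs.** Zero-variance parcels within a window and empty
parcels are hard errors (silent NaNs would corrupt the factorization);
constant weight courses yield r = NaN with a warning and count as
non-significant; a zero validation residual returns a −∞ BIC sentinel with
a warning; an empty cross-modal assignment is a reported outcome, not an
error.

## Experiment scales

The bundled experiments run at desk scale, chosen once as conditions under
which each estimator in the chain is demonstrably capable: planted-factor
recovery at M = 190 (R = 20), T = 300, k* = 5, noise SD 0.05 with the full
nested-CV grids; cross-modal matching on groups of 4 participants × 1200-s
sessions (R = 20, five states, λ = 0.25, nonnegative weights, three
restarts), with 200-member surrogate ensembles; null calibration on the
same conditions with independent ground truths per modality; task-state
detection on 12 participants × 640-s localizer sessions with one task
state and three 60-s-dwell background states. Matching accuracy is scored
over the pairs the Bonferroni gate returns, with coverage (returned pairs
per planted state) reported alongside: abstaining on a state the noisy
hemodynamic estimator failed to resolve is correct behavior of the gate.

## Known limitations

- The calibration of the cross-modal null test is mildly conservative
  (empirical positive rate ≈ 3% at a nominal 5%): Bonferroni plus the
  dependence among the k × k correlations guarantees control, not
  equality.
- The per-state significance test pools all k states' errors into one
  null; with few states that each explain a large energy share, margins
  are thin at small T (the alternative per-index null is a configuration
  switch away in spirit but not implemented).
- Dictionary learning guarantees monotone descent only between repairs; a
  repair step can transiently raise the objective before the next
  alternations lower it again.
- The greedy assignment is faithful to the procedure it models and can
  (rarely) return a sub-optimal assignment; the brute-force oracle exists
  for tests, not as a replacement.
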