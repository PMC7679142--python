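# Methods

This note documents the models, estimators and design choices behind
`pavnet`, in the order data flows through the pipeline.

## Synthetic sessions

The generator (`pavnet.synth`) emulates one recording session of a
two-valence Pavlovian task.  Its defaults describe the emulated design
rather than tuning knobs:

- **Timeline.**  Two conditioned stimuli (R-CS rewarded, F-CS
  shock-paired), each 10 s long, presented in alternating blocks of two
  (R R F F …), `n_trials_per_cs = 6` per type in a 600 s session.  In the
  conditioning stages each CS is followed at offset by its matching US;
  habituation and recall sessions have no USs.  Trials are laid out in
  equal slots with ≥ 20 s between CS windows; an infeasible schedule raises
  rather than overlapping trials.
- **Events.**  Spiking/calcium-event activity is generated per 1 s bin —
  the resolution at which all event analyses operate — as a Bernoulli draw
  with per-bin probability `baseline_rate` (default 0.2 events/s, a typical
  sparse single-unit/calcium event rate), multiplied inside CS windows and
  for `us_response_bins` after a US by configurable (region, stimulus,
  stage) factors.  Sub-bin event times get uniform jitter so 500 ms binning
  is also meaningful.  The CS/US response amplitudes are free parameters of
  the emulation: the recordings they imitate report only z-scored
  responses, so no attempt is made to calibrate them; analysis scripts use
  3×, which produces clearly decodable but imperfect single-region
  decoding, as in real data.
- **Coupling.**  A directed entry (source, target, excess_prob, lag) gives
  each target neuron (paired round-robin with one source neuron) an event
  probability of `p_base + excess_prob` in bin t+lag when its source
  partner fired at t, and `p_base` otherwise.  The conditional excess
  probability is therefore exactly `excess_prob`, which is what the
  recovery tests estimate.  Coupling acts on probabilities, keeping states
  binary for the information-theoretic analyses; cyclic region coupling is
  rejected.
- **LFP.**  1/f ("pink") noise plus configured sinusoids; spikes of a
  region with a locking entry are placed, within their bin, at phases drawn
  from a von Mises density with concentration κ (κ = 0 reduces to uniform
  jitter).  The oscillation's initial phase is random per session; locking
  is therefore in phase *consistency*, which is what spike-field coherence
  measures.
- **Behavior.**  One episode per trial of the kind matching the CS (port
  visit for R, freezing onset for F): inside the CS window with probability
  `behavior_correct_prob`, otherwise placed uniformly in inter-trial
  intervals ≥ 5 s from any CS window.  The motion-index trace is high
  (≈ 5, SD 1) except during planted freezing bouts (3 s of ≈ 0.02), so the
  freezing scorer sees unambiguous episodes at any threshold in between.

What the generator does **not** emulate: bursting and refractory structure,
firing-rate heterogeneity within a region, slow drift and electrode
instability, correlated noise beyond the planted coupling, video — only a
scalar motion index — and imaging artifacts.  Tests passing on this
surface demonstrate correctness of the estimators and their calibration
under the stated model, not robustness to every property of real
recordings.

## Binning, PETHs, labels

Bins are half-open `[t0 + b·w, t0 + (b+1)·w)` with 0-based indices; events
on a boundary belong to the later bin, so refining 1 s → 0.5 s and summing
adjacent bins is exact.  PETHs use 500 ms bins, a fixed −8…18 s window
around CS onset, z-scoring per neuron over the whole stage (zero-variance
neurons map to zeros, not NaN), and Gaussian smoothing along time with
kernel SD equal to the "degree" parameter in bins (5 for cortical, 8 for
amygdala data), truncated at 4 SD.  Smoothing is NaN-aware: shock-artifact
bins (the 1 s bin(s) containing an F-US) are masked to NaN and stay NaN, so
they can never silently enter a downstream mean; channel-blackout entries
are replaced by the population mean of the same bin before smoothing.

Decoding labels come from 1 s bins: CS task (class 0 = the 10 bins before
onset, class 1 = the 10 CS bins), US task (class 1 = 8 bins after US
offset; the window mirrors the PETH's +18 s bound), and a three-class task
(pre-CS / R-CS / F-CS).  The pre-window length (10 bins, mirroring the CS
length) and post-US window (8 bins) are package choices; both are
parameters.  Pre-windows that would reach into the previous trial are
truncated, so no bin ever carries two labels.

## Behavior scoring

Freezing: a sliding 1 s window mean of the motion index; an episode is any
maximal run of sub-threshold windows covering ≥ 1 s of frames, reported at
the run's first frame.  The scorer is verified frame-for-frame against a
brute-force oracle.  The motion threshold is exposed as a parameter: the
source hardware conventions (a vendor "motion threshold" or a %-area-change
criterion) do not translate to an abstract motion index.

Correctness is onset-based: an episode is correct iff its onset lies inside
the 10 s window of a CS of matching kind (port visit ↔ R-CS, freezing ↔
F-CS); everything else — including episodes just before onset — is
incorrect.  A trial is correct iff at least one correct matching episode
starts inside it.

## Calcium events

ΔF/F traces are low-pass filtered (4th-order Butterworth, zero phase,
0.5 Hz default) and thresholded at median + 3 × 1.4826·MAD of the whole
filtered trace.  Events are trace peaks above threshold, thinned to a
minimum separation of τ_off = 0.2 s with priority to larger peaks, and
reported at the upward threshold crossing of their excursion.  This
separation rule — rather than a literal decay-below-threshold criterion —
was chosen because it makes the detected count provably non-increasing in
the threshold multiplier, a property the detector is tested for; a decay
rule can split one low-threshold excursion into several high-threshold
events.  The vendor algorithm being imitated is unpublished, so this is an
approximation by construction.

## Decoding suite

All four modes share one iteration scheme: draw a neuron subset, balance
classes by random under-sampling, then stratified 5-fold cross-validation
in which z-scoring (and everything else fit to data) is computed on the
training folds only.  Under-sampling precedes the split, matching the
stated order of the emulated analysis; the leakage test verifies that
shuffled-label accuracy stays at chance regardless.  Decoder accuracy *Da*
is the mean held-out accuracy over folds × repeats (default 40 repeats).

- Classifier defaults: MLP with one hidden layer of 100 rectified units,
  adaptive-moment optimization, ≤ 200 epochs, per-iteration seeds (the
  emulated analysis names the classifier but not its architecture);
  random forest with 100 trees and impurity-based feature importances
  (summing to 1 per fit).
- Cross-stimulus transfer fits scaler + classifier on the training
  stimulus and applies them unchanged to a balanced test set of the other
  stimulus (10 repeats), with a shuffled-test-label control.
- Three-class discrimination reports, besides overall accuracy, the
  conditional CS accuracy: among held-out bins that are truly CS and also
  *predicted* as some CS class, the fraction assigned to the correct CS.
  It is flagged undefined when no bin is predicted as CS.
- Multi-region decoding draws `n_total = 100` neurons with per-region
  counts proportional to the pool (largest-remainder rounding, ties broken
  by region name), and accumulates per-iteration per-region mean
  importances.  Contrasts between two conditions use the difference of
  per-region means with a two-sided permutation test over the pooled
  per-iteration values (10⁴ permutations); the choice of a permutation
  test is ours — the emulated analysis marks significance without naming a
  test.

## Transfer entropy

`discrete_te` is a plug-in (maximum-likelihood histogram) estimator of
TE(X→Y) in bits over all valid transitions, for arbitrary finite alphabets
and history length k.  Bin counts are clipped to binary by default (any
event → 1), matching discrete-state estimation on sparse event trains; a
count alphabet (clip at 3) is available.  The implementation accumulates
joint histograms for *all* source/target pairs at once via one-hot tensor
contractions, which is what makes 10³-surrogate testing affordable; it is
verified to 10⁻¹⁰ against an independent dictionary-based enumeration
oracle.  Estimates are clipped at 0 (the plug-in TE is nonnegative; tiny
negative values are float residue).

Aggregation: per pair, the peak TE over the history scan (default scan
{k=1}: a 1 s history at 1 s bins); per ordered region pair, the mean of the
upper 50% of pair peaks (stable sort, keep ⌈n/2⌉, ties broken by pair
order).  Surrogate significance permutes each **source** neuron's time bins
independently, recomputes the full pipeline (pairwise peak → top-50% →
mean), and reports p = proportion of surrogate region TEs ≥ the real one
(α = 0.05).  Permuting the source destroys source→target dependence while
preserving marginal rates and the target's own dynamics, which the TE
conditions on; permute-everything and circular-shift surrogates are
available as options.  The literal proportion can be exactly 0; a
conservative (count+1)/(n+1) companion value is always returned alongside.

Two calibration properties are verified: under truly independent regions
the rejection rate at α = 0.05 is nominal (≈ 0.05 over hundreds of runs),
and planted one-way coupling (excess probability 0.3, 600 bins, 20 neurons
per region) is detected in ≥ 90% of runs with the reverse edge rarely
significant.  Known limitation: when forward coupling exists, the
*reverse* test is mildly anticonservative (empirically ≈ 0.10 at α = 0.05)
— the real reverse statistic inherits variance from the forward dependence
that shuffled surrogates cannot reproduce.  The same mechanism produces
occasional spurious edges adjacent to strongly coupled populations in full
5-region networks, on top of ordinary α-level multiplicity over 20 ordered
region pairs; interpret single borderline edges accordingly.

Network assembly draws `n_draw = 500` neurons proportionally across
regions (largest remainder), extracts and concatenates the bins of a named
window — CS bins, post-US bins, or ±2 bins around behavioral episode
onsets — computes every ordered region-pair TE with surrogate p, and
attaches mean feature importances as node attributes.  Both the full and
the significant-edge (p < α) views are exportable (GraphML, edge-list CSV,
node JSON).

## Spike-triggered averages and spike-field coherence

The STA is the mean of 200 ms LFP snippets centered on spikes whose full
window lies inside the record and inside the condition (pre-CS = the 10 s
before onset, CS = the 10 s stimulus; boundary-crossing spikes are
excluded).  SFC(f) divides the power spectrum of the STA by the mean power
spectrum of the individual snippets, both Hann-tapered; by convexity this
ratio is ≤ 1 (float excess is shaved), equals 1 for perfect locking and
≈ 1/n for unlocked spikes.  The "normalize the STA spectrum to the LFP
amplitude" phrasing being imitated is ambiguous; the snippet-power
normalization was chosen because it yields the bounded coherence
convention, and the raw STA spectrum is kept as a secondary output.
Spectra are zero-padded (default ≥ 4× the snippet, next power of two) so
the frequency grid (≈ 1 Hz at 1 kHz sampling) resolves peaks finer than
the 5 Hz native resolution of a 200 ms window; the planted-locking test
requires ±2 Hz recovery at 33 Hz.

## Pipeline and determinism

`run_pipeline` chains simulate → bin → behavior → decode → TE → SFC →
report from one flat key=value config; any failure aborts with a
stage-tagged error.  A single master seed generates per-stage seeds as
`master·1000 + stage_index`, so stages can be re-run in isolation, and the
manifest records config, seeds and a SHA-256 per artifact; two runs of the
same config produce byte-identical artifacts (HDF5 is written without
modification timestamps for this reason).  Every stochastic routine in the
package takes an explicit seed and is reproducible to the last bit.

## Problem sizes

The shipped demo config and the acceptance script use reduced sizes chosen
to exercise every code path at desk scale: sessions of 420–600 s with
12–24 trials and 40–82 neurons, 60–200 surrogates instead of 1000, 10–40
decoding repeats, 10–20 recovery runs per rate estimate.  The estimators
themselves are size-agnostic; all counts are parameters.
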