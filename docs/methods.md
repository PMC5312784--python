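# Methods

## Task model

The simulator generates instructed probabilistic reversal-learning
schedules for three designs:

| design | blocks | lengths | reversal rule | reliability ρ |
|--------|--------|---------|---------------|----------------|
| exp1a  | 36 (18 volatility / 18 stability) | 25/33/41 | 2/3 vs 1/3 of blocks, at the midpoint (trial 13/17/21) | 0.75 |
| exp1b  | 27, response-feedback interval 1200 ms | 25/33/41 | as exp1a | 0.75 |
| exp2   | 32 (8 per reliability cell) | 33 | 3/4 of blocks, equally often at trial 9/17/25 | 0.875 / 0.75 / 0.625 |

Counterbalancing is exact, not sampled: block counts per
condition × length × reversal cell are computed as integers and only the
ordering (plus exp2 reversal-position assignment and stimulus identities)
is shuffled by the seed. When the implied cell counts are not integers the
builder raises an error naming the offending cell; the 27-block design
cannot be split exactly (27 blocks over 2 instructions × 3 lengths), so its
shipped configuration opts into a deterministic largest-remainder rounding.

Feedback is drawn per trial: valence matches rule-correctness with
probability ρ, independently. Responses are always produced (no response
deadline is modelled; no analysis in scope uses missed trials). Each block
uses two fresh stimuli, each appearing ⌈L/2⌉ or ⌊L/2⌋ times in a
seed-shuffled order; the sequence rule beyond that balance is this
package's assumption. Blocks without a reversal carry a notional midpoint
as the phase boundary so that "first half" comparisons use matched trial
counts across instruction conditions.

## The observer model

A two-state hidden-Markov filter over "which mapping is correct", with

* hazard h (default 0.03 ≈ one reversal per 33 trials) — a single shared
  parameter, not instruction-dependent: instructions act through the
  decision threshold only;
* assumed reliability ρ (default 0.75, the experienced contingency of the
  target blocks); both are fixed by design, not fitted;
* entropy-aversion threshold α ∈ [0, 1] bits — the only fitted learning
  parameter. The agent switches mapping iff p < 0.5 and H(p) ≤ α. This
  direction (switch once uncertainty has *resolved* against the current
  mapping) makes larger α produce earlier switching, which is required for
  internal consistency: the more entropy-averse volatility setting must
  adapt faster. The belief, surprise I, and entropy H are logged per trial;
  I is descriptive only and never enters the decision;
* lapse rate ε: with probability ε the executed mapping is flipped. The
  agent conditions its belief on what it actually did.

Belief and (for the RL learner) values reset at block boundaries — new
stimuli appear each block, so no carry-over is warranted. The belief
update and the recursive filter are verified in the tests against a
brute-force enumeration of hidden-state paths (≤ 10 trials, agreement to
1e−12).

## Fitting and model comparison

The filter is replayed on the observed choice/feedback sequence. Because
the replay conditions on observed choices, the belief trajectory is
independent of α; each trial contributes a switch threshold
τ_t = H(p_t) (if p_t < 0.5, else ∞), and the model predicts a switch at
t+1 iff α ≥ τ_t. The first trial of each block has no prediction history
and is excluded from scoring; n is the number of scored trials.

The likelihood is lapse-Bernoulli: an observed choice matches the
deterministic prediction with probability 1 − ε. ε is profiled as the
observed mismatch rate, clipped to [0.01, 0.49] to keep the likelihood
finite; since the likelihood is strictly decreasing in the mismatch count,
the grid search (α on 0:0.01:1, ties to the smallest α) reduces to
mismatch minimisation, and the instruction-sensitive fit separates exactly
into one independent search per instruction (equivalent to the full
101×101 grid). The lapse is counted as a shared nuisance parameter in both
variants (k = 2 blind, k = 3 sensitive), so the BIC difference reflects
only the α structure; the group comparison sums BIC over subjects
(fixed-effects), with the conventional >2 / >6 evidence bands.

## Behavioural measures

Accuracy is percent rule-correct (not percent positive feedback);
trials-to-repetition is the 1-based index of the second trial of the first
consecutive rule-correct pair, from block start or from the first
post-reversal trial; blocks where repetition never occurs are excluded and
counted rather than imputed. "Surprising negative feedback" is negative
feedback on a rule-correct trial; the switch probability conditions on such
events that have a successor in the same block. Cohen's d for paired data
uses the SD of the differences, consistent with the paired t statistics.
Repeated-measures ANOVAs use statsmodels' AnovaRM; empty cells are flagged
(NaN), never silently zeroed.

## ERP quantification

Contracts on the `EpochSet` container (channels × samples × trials, µV,
canonical rate 250 Hz):

* rejection of trials whose within-epoch peak-to-peak range exceeds 100 µV
  on any scalp channel;
* zero-phase Hamming-window FIR band-pass, 0.1–24 Hz (0.05–24 Hz on the
  slow-wave path). On 2 s epochs a textbook 0.1 Hz transition band would
  require a filter far longer than the epoch, so the tap count is capped
  near a third of the epoch length (zero-phase filtering needs padding
  headroom): the 24 Hz edge keeps a sharp transition (50 Hz is attenuated
  to < 0.1% in steady state) while the high-pass edge is soft — the
  standard compromise for short epochs;
* baseline correction −200 to −100 ms before feedback (200–300 ms after
  response onset for the SPN path).

Component measures, over named electrode clusters of the 32-channel
montage:

* **FRN** (fronto-central F3/FZ/F4/FC3/FCZ/FC4/C3/CZ/C4):
  average-base-to-peak — mean of the highest voltages in 160–220 ms and
  300–420 ms minus the lowest voltage in 240–280 ms. If a peak lies on a
  window edge, that edge is moved outward one sample (4 ms) at a time,
  never into the trough window and never past 0/800 ms, until the extremum
  is interior or the edge is capped; the windows actually used are
  reported. This minimal deterministic reading of "gradual widening" is one
  of two possible conventions (the alternative would widen toward the
  trough); it is configurable via `widen=False` and the simple
  trough-minus-preceding-peak variant is available as `mode="preceding_peak"`.
* **SPN** (left FC3/C3/CP3, central FCZ/CZ/CPZ, right FC4/C4/CP4): mean
  amplitude in three pre-feedback windows (−600..−400, −400..−200,
  −200..0 ms), feeding a 2×3×3 instruction × time × laterality analysis.
* **P3**: window maximum 300–420 ms over CP3/CPZ/CP4/P3/PZ/P4/POZ, also
  split by next-trial behaviour (repeat/reverse from the next trial's
  applied mapping; block-final trials have no label and are excluded).
* **P1 / N1**: window maximum 60–100 ms / minimum 140–200 ms over
  P7/P3/PZ/P4/P8/POZ/O1/OZ/O2.

## Synthetic EEG generator

Templates are raised-cosine bumps (compact support, analytic extrema):
P1 +3 µV @ 80 ms, N1 −4 µV @ 170 ms, FRN −5 µV @ 260 ms,
P3 +8 µV @ 360 ms, each with unit weight on its measurement cluster and a
0.3 halo elsewhere; the SPN is a linear negative ramp over the last 600 ms
before feedback with right-lateralised weights (0.5/0.75/1.0), giving
closed-form window means (amplitude × 1/6, 1/2, 5/6). Condition effects
are additive amplitude offsets keyed on trial-log labels; noise is
zero-mean Gaussian, white or 1/f-shaped, default SD 10 µV per sample
(a plausible single-trial scalp-EEG scale). The generator emits per-trial
ground-truth amplitudes so every measure has an oracle.

What this does and does not show: the generator reproduces the statistical
structure the analyses assume (component timing/topography, condition
offsets, additive noise), not biophysics — no ocular artifacts, channel
drift, bad channels, or trial-to-trial latency jitter. Passing
injection-recovery therefore validates the measurement code, not its
robustness to real-data pathologies (the artifact-rejection and filtering
contracts are tested separately on constructed signals).

## Simulation scales and numerical choices

* Parameter recovery and prediction-rate summaries use 28 synthetic
  subjects on the 36-block design (the scale at which group means are
  stable to ~0.01–0.02 in α).
* The directional instruction-effect checks (post-reversal accuracy and
  trials-to-repetition lower/higher under volatility, switch propensity
  higher) use 300 subjects (~10,800 blocks): at the fitted means
  α_v = 0.7 / α_s = 0.52 the switch-propensity effect is genuinely small
  (≈ +0.7 percentage points), so the check is run at a scale where
  Monte-Carlo noise cannot mask its sign.
* Grid comparisons use a 1e−12 tolerance guard (α ≥ τ) so that fitted and
  generating thresholds compare identically under floating-point rounding.
* Degenerate inputs: empty logs raise; one-mapping logs warn and still
  fit (tie-break returns the smallest α); empty condition cells are
  flagged NaN; all-rejected epoch sets raise.

## Known limitations

* The observer's h and ρ are fixed, not fitted; misspecification of either
  biases α̂ (the recovery tests quantify this only at the matched values).
* The fitted α̂ is identified only up to the lattice of entropies the
  belief actually visits; the smallest-α tie-break gives a small downward
  bias (visible as recovered means ≈ 0.69 for a generating 0.70).
* The high-pass filtering contract is epoch-limited (soft transition), so
  very slow drifts are attenuated, not removed, on 2 s epochs.
* exp1b's 27 blocks cannot be exactly counterbalanced; largest-remainder
  rounding preserves totals and approximates the 2/3–1/3 reversal
  proportions (e.g. 9/15 volatility reversal blocks).
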