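# Methods

This note documents the models, defaults and numerical choices behind
`ensemblestates`, and what the synthetic sessions do and do not establish
about real recordings.

## Task structure and data model

A session consists of three contiguous epochs: a 15 min event-free
baseline (exploration), a 15 min pellet-drop period in which 90 food
pellets fall at 10 s intervals (exploitation), and a 5 min post period.
Each pellet drop is followed by a consumption event at a latency of
4.39 ± 0.65 s, truncated to (0.5 s, drop interval) so every pellet is
consumed before the next falls. Raw data are per-unit spike timestamps
plus this event schedule and epoch partition, all as delimited text.

## Instantaneous firing rates

Each spike contributes a unit-area Gaussian kernel (SD = 125 ms); the iFR
in a 500 ms bin is the average of the summed kernel function over the
bin, evaluated exactly as a difference of normal CDFs at the bin edges —
there is no sampling grid, so the values carry no resolution ambiguity.
Numerical choices:

* Kernels are truncated at the session boundaries without
  renormalisation; only the first/last ~0.5 s of a session are affected.
* The bin grid is anchored at session start; events need not coincide
  with bin edges (an event's bin is the bin containing it).
* Units with whole-session mean rate strictly below 0.1 spikes/s are
  excluded (a unit at exactly the threshold is retained); removing every
  unit raises an explicit empty-ensemble error.
* Multi-session merging aligns each session's time axis to a reference
  event (the first pellet drop), truncates to the common support and
  stacks units.

## Hidden Markov model

Gaussian-emission HMM with diagonal covariances on the N-dimensional iFR
vectors. Estimation details, all of which matter for reproducibility:

* **Recursions.** Forward–backward uses Rabiner per-step rescaling after
  factoring the per-bin maximum out of the emission densities, so
  sessions of tens of thousands of bins are stable; posteriors are exact
  (they match brute-force path enumeration to 1e-10 in the tests).
  Viterbi runs in log space with ties broken toward the lower state
  index.
* **Initialisation.** Random stochastic initial/transition distributions
  (Dirichlet), emission means copied from randomly chosen data columns,
  variances from the per-unit data variance. Means from data columns
  rather than pure noise avoid early emission collapse.
* **Restarts.** 5 random restarts by default; the best final
  log-likelihood is kept and the count is recorded in the fit.
* **Convergence.** Relative log-likelihood improvement below 1e-6, cap
  500 iterations. The per-iteration log-likelihood trace is stored and
  must be non-decreasing (1e-8 slack in tests).
* **Variance floor.** 1e-3 (spikes/s)² applied every M-step; silent
  units otherwise collapse emission variances to 0.
* **State identity.** Labels are arbitrary; cross-run comparisons
  relabel by greedy nearest-mean matching (`relabel_by_means`).

**State-count selection.** BIC(Q) = −2L + ln(T)(2QN + Q(Q−1)), natural
log, parameter count = means + diagonal variances + free transition
entries. The selected Q is the grid argmin when the minimum is interior;
when the BIC decreases monotonically to the grid edge, the "asymptote"
rule picks the smallest Q after which every further decrease is below 1%
of the BIC range over the grid. Normalised BIC is (BIC−min)/(max−min).
Failed fits for individual Q are recorded and dropped.

## Complexity measures

* **Entropy.** Posteriors are smoothed with a centred 3-bin moving
  average (edges use shrunken windows) and renormalised; 61 bins is the
  whole-session visualisation variant. H(t) = −Σ Pᵢ ln Pᵢ with
  0·ln 0 = 0. The effective state count is the perplexity exp(H); a
  hard-threshold count (Pᵢ > 0.01) is provided as an alternative because
  "number of states with non-zero posterior" is a verbal definition with
  more than one defensible operationalisation.
* **Change point.** CUSUM of the mean-centred entropy values;
  the |S| extremum gives k = number of bins before the change (earliest
  k on ties); a constant trace returns k = 1 with a degeneracy flag. No
  other change-point statistic is implied.
* **Compression complexity.** Each 150 s window (default step 5 s; the
  step is a package choice, exposed) is serialised as fixed 4-decimal
  text, row-major units × bins, single-space separated, one line per
  unit, and compressed with bzip2 at maximum level; the value is the
  compressed byte count at the window centre. Compressed sizes are only
  comparable within this serialisation dialect.
* **PCA dimensionality.** Principal axes are fit once on the whole
  mean-centred session (not per epoch — the analysis asks how a fixed
  session-wide basis is used through time). Per bin, absolute scores on
  all N axes are sorted descending and counted until the partial sum
  strictly exceeds 90% of the total; the count series is smoothed with a
  61-bin centred moving average for display (tests use the raw integer
  counts). A zero-variance matrix yields count 1 with a degeneracy flag.

## State categorisation and peri-event analyses

* **Dominance.** Per state, the time-mean posterior over the baseline is
  compared with the mean over an equal-duration interval at the *start*
  of the drop period (the spec's "equivalent interval" is otherwise
  undefined); strictly greater ⇒ baseline-dominant, ties ⇒
  drop-dominant. Pooled comparisons use paired t-tests across states
  (df = n−1), two-sided, no multiple-testing correction; identical
  samples return t = 0, p = 1.
* **Peri-event averaging.** 10 s windows ([−5, +5) s, 20 bins) centred
  on each drop; posterior profiles are averaged across events. Entropy
  AUC (rectangle rule: plain sum of per-bin entropies) is computed per
  window symmetrically on both sides — per-event windows and an equal
  number of 10 s baseline windows tiled from the baseline start — and
  the side means are compared. Computing the event side from averaged
  posteriors but the baseline side per window would inject a Jensen-gap
  bias between the sides, so the symmetric per-window form is the
  comparison statistic; the averaged-posterior entropy profile is still
  stored for display.
* **Top peri-event states.** The k = 3 states with the largest mean
  averaged posterior over the window, with their 20-bin profiles.
* **Factor regression.** Drop-period bins are partitioned into
  pellet-drop [−0.5, +1.5) s, consumption [+3, +6) s (bracketing the
  ~4.4 s mean consume latency) and intertrial (remainder) relative to
  each drop; windows are package choices exposed in the config. Each
  unit's drop-period iFR is regressed on the three indicators without
  intercept, so each coefficient is that factor's mean rate and an
  exact-indicator unit recovers its coefficient exactly. Because rates
  are non-negative, per-factor p-values test "mean rate = 0" and are not
  null-calibrated for selectivity; `factor_contrasts` therefore reports
  factor-minus-intertrial contrasts whose t statistics are exactly
  centred under no selectivity — that is the quantity to use for
  null-calibrated screening.
* **Epoch distribution tests.** Two-sample Kolmogorov–Smirnov between a
  complexity trace's values in epoch pairs (baseline vs drop, baseline
  vs post).

## Synthetic sessions: what they emulate

The generator produces the statistical structure the analysis assumes,
with defaults at the study's task conditions (20 units, ~1.8 spikes/s
grand mean, 15/15/5 min epochs, 90 drops at 10 s):

* A hidden Markov chain simulated directly at the 500 ms analysis bin
  width (finer dynamics would be unidentifiable to the HMM), mean state
  dwell time 5 s, with disjoint epoch repertoires: 6 baseline states and
  2 drop-period states by default. The post epoch reuses the baseline
  repertoire, matching the observation that baseline states reappear
  after the task. At epoch boundaries the chain jumps to a uniformly
  random member of the new repertoire — the data constrain the
  abruptness of the transition, not its mechanism.
* Per-unit log-normal base rates modulated by per-state log-normal
  gains whose spread depends on the repertoire: weak (σ = 0.4) for
  baseline states, so exploration states overlap and many states share
  posterior mass; strong (σ = 1.2) plus near-silencing of a quarter of
  (state, unit) pairs for drop states, producing sharply contrasted
  reward states and abrupt on/off units at pellet onset. Rates are
  rescaled so the grand mean over (state, unit) hits the target.
* One designated consumption state occupies the chain persistently in a
  [−1, +2) s window around each consumption event (with per-event
  probability 0.85), clipped to the drop period so epoch purity holds.
* Spikes are inhomogeneous Poisson within bins given the state's rates.

Everything is deterministic under the config seed. What passing tests on
these sessions do **not** show about real data: the simulator has
genuinely discrete states (real ensembles may drift continuously),
conditionally independent Poisson units (no noise correlations within a
state), no rate nonstationarity or electrode drift, no behavioural
covariates (movement, position), and epoch repertoires that are disjoint
by construction rather than by discovery. Recovery results here bound
what the method can do when its assumptions hold, not how it behaves
under misspecification.

## Problem sizes and defaults in the shipped analyses

The acceptance script and the heavier tests use full-length
study-condition sessions (4200 bins, 20 units). EM options are reduced
where many fits are needed (2–3 restarts, 100–300 iteration cap,
tolerance 1e-5), which on well-separated synthetic data converges in a
few dozen iterations; single fits use the defaults. Epoch-level
directional comparisons aggregate entropy/PCA bins into 30 s block means
(blocks ≫ the 5 s dwell time, so blocks are nearly independent) and use
non-overlapping 150 s compression windows, avoiding
autocorrelation-inflated significance.

## Known limitations

* EM finds local optima; restarts mitigate but do not guarantee the
  global maximiser, and the BIC curve inherits that variance.
* Diagonal emissions ignore within-state noise correlations; states that
  differ only in correlation structure are invisible.
* Compressed-size complexity depends on the serialisation dialect and
  compressor; only within-dialect comparisons are meaningful.
* The CUSUM statistic localises a single dominant level shift; multiple
  change points are out of scope.
* With strongly overlapping baseline states the fitted state count need
  not match the generative count; dominance scoring therefore matches
  fitted states to ground-truth states by posterior-mass overlap rather
  than assuming a bijection.
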