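# Methods

## Entropy features

Sample entropy of a series y with embedding dimension m and tolerance r is
−log(A/B), where B counts unordered template pairs of length m within
Chebyshev distance r and A the pairs still within r at length m+1. Both
counts run over the compatible template range i = 1…N−m (the standard
Richman–Moorman convention), so a constant series scores exactly 0 and
A ≤ B always. Matching is inclusive (≤ r) and self-pairs are excluded.

Multiscale variants coarse-grain the series first. MSE takes the sample
entropy of the single offset-1 coarse series per scale; RCMSE computes
match counts on *every* offset series k = 1…τ and pools them before the
logarithm. Pooling multiplies the effective pair count by ≈ τ, which is
why RCMSE is undefined less often and has lower across-realization
variance on short series — the property the test suite verifies by
simulation (50 white-noise series, N = 300, τ = 10).

Parameter defaults and rationale:

* **m = 2** — the conventional choice for short physiological epochs;
  larger m needs quadratically more data per defined estimate.
* **r = 0.2·σ** of the *original* (raw) epoch series, computed once and
  reused unchanged at every scale. Rescaling r per coarse series would
  conflate the scale-dependent variance shrinkage with irregularity.
* **scales τ = 1, 2, 3, 5** — entropy profiles of physiological signals
  change fastest below scale 5; four scales × three channels give the
  twelve-feature reconstructed space f1…f12 (feature index
  (c−1)·Ms + s for channel rank c and scale rank s).
* **log base 2** (entropies in bits) by default; the base is a parameter
  and natural log is available, since both conventions circulate.

Undefined entropies (zero pooled matches) are carried as explicit missing
values, never ±inf. When building the decision table they are imputed with
the column median of the defined values (logged); a fully undefined column
is retained, filled with 0, and flagged — dropping it silently would break
the (channel, scale) ↔ f-index bijection.

Degenerate inputs: a scale with N < (m+1)τ is flagged undefined rather
than raised; a series shorter than m+1 raises. A constant series has σ = 0,
so the tolerance falls back to the bare coefficient (any positive value
matches everything and the entropy is 0, as it should be).

## Discrete information estimators and selection criteria

Features are discretized once per selection run into equal-frequency bins,
B = min(⌈√n⌉, 10) by default: plug-in (maximum-likelihood) probabilities
are biased for many near-empty bins, and √n bins is a serviceable
compromise at the table sizes this package targets. Ties share a bin (a
constant feature occupies one bin); bin assignments are rank-based, so
occupancies differ by at most one for tie-free data. No smoothing is
applied — the estimators implement the bare Shannon formulas, with a 1e-12
clip absorbing floating-point cancellation in MI and CMI.

The greedy criteria are listed in the package docstring
(`physiostate.mi_selection`). Design points:

* Step 1 always maximises the marginal I(f;C) under every criterion.
* The CR-MIFS conditional-relevance term is *averaged* over the selected
  set, mirroring its 1/|S| redundancy normalisation; a sum would make the
  relevance and redundancy terms grow at different rates with |S|.
* β = 0.5 for MIFS/MIFS-U (mid of the conventional (0, 1] range),
  configurable; mRMR/NMIFS/CR-MIFS need no trade-off parameter.
* Ties break to the lowest feature index, making traces deterministic.

The constructed 40-case XOR table (`synthetic.make_xor_table`) is the
package's sharpest behavioural probe: its second feature carries exactly
zero marginal information but one conditional bit, so CR-MIFS selects it
at step 2 while every static criterion prefers a weak marginal feature.
All per-step scores are cross-checked against explicit probability-table
summation in the tests.

## SAPSO-SVM

The SVM is scikit-learn's `SVC` (libsvm): the quadratic program is
deliberately bought, not built — the package's contribution is the search
and the pipeline around it. Positions are (log₂C, log₂g) so the
2⁻¹⁰…2¹⁰ range is a symmetric box and steps are scale-free.

PSO uses the canonical Kennedy–Eberhart update with linearly decaying
inertia 0.9 → 0.4, c₁ = c₂ = 2.0, velocity clamped to 20 % of the box
width, positions clipped to the box. The SA gate is per particle: after a
move is evaluated, Δf = (personal-best fitness) − (new fitness);
non-worsening moves always survive, worsening ones survive with
probability exp(−Δf/T); a rejected move reverts both position and
velocity. T₀ = 0.1 (the scale of accuracy differences) cooled by
α = 0.9 per iteration. Personal/global bests are updated outside the gate,
so the recorded global-best trace is non-decreasing by construction.

Fitness is stratified 5-fold CV accuracy with a fixed shuffle seed; a
class smaller than the fold count lowers the fold count (logged) rather
than failing. Non-finite fitness re-initialises the particle (logged).
The full run is a pure function of (data, config, seed).

Pipeline defaults use a 12-particle, 15-iteration swarm — on the smooth
CV-accuracy surfaces of the bundled benchmarks this reliably matches or
beats a 5×5 grid over the same box (verified over seeds in the tests);
raise both for rougher surfaces. The split is a literal stratified 70 %
train / 20 % test of the whole table with the remaining 10 % untouched,
and CV folds are drawn from the train partition only.

## Evaluation

Metrics come straight from the confusion matrix with C1 (awake) as the
positive class: ACC = (TP+TN)/n; F1 = 2·pre·rec/(pre+rec) with
pre = TP/(TP+FP), rec = TP/(TP+FN); kappa = (ACC−p_c)/(1−p_c) with the
chance agreement p_c estimated from the marginal products
[(TP+FN)(TP+FP) + (FP+TN)(FN+TN)]/n². Zero-denominator precision/recall/F1
report 0 with a logged warning; p_c = 1 (single-cell tables) makes kappa
undefined (NaN). scikit-learn's metric functions serve as independent
cross-checks in the tests, never as the implementation.

## Synthetic test bed

`gen_record` emulates an epoch-annotated two-class multichannel recording:
200 epochs per class of 30 s (0.5 min) by default. The class signal is
carried by the EEG-like channel's *autocorrelation* — C1 epochs are white
Gaussian noise, C2 epochs AR(1) with φ = 0.9 — while the SaO2- and
PR-like channels are class-neutral (white noise; sinusoid + noise). An
effect expressed through complexity rather than mean level is the point:
it is invisible to the raw-level statistics and recovered only through
the entropy features. Sampling rates (4 Hz SaO2/PR, 16 Hz EEG) are
desk-scale stand-ins for clinical hardware chosen so a full 400-epoch
pipeline runs in seconds; entropy estimates at these epoch lengths
(120–480 samples) are well inside the defined regime for m = 2.

What the generator does *not* emulate: physiological waveform morphology,
stage transitions and temporal continuity across epochs (epochs are
independent realizations), artifacts/arousals, inter-subject variability,
and class imbalance. Passing the end-to-end benchmark therefore shows the
pipeline recovers a planted complexity difference — not that it reaches
any particular accuracy on clinical recordings.

`gen_feature_table` plants ground truth directly in feature space: a
class-shifted feature (Cohen's d = 1.5 by default), a jittered duplicate,
a ±1-cluster XOR pair and standard-normal distractors, for selection
benchmarks with known correct answers.

## Numerical and scope choices

* Entropy values are compared bit-for-bit against a naive O(N²)
  enumeration oracle in the tests; the vectorized path must be exactly
  equivalent, not approximately.
* Record/table I/O is delimited text (CSV/TSV by extension), 12
  significant digits; EDF ingestion is a stub that raises with a pointer,
  keeping the package free of binary-format dependencies.
* Multiclass labels are outside scope (estimators would cope; the
  pipeline, confusion matrix and generators are binary C1/C2).
* Known limitation: plug-in MI on continuous features inherits
  discretization bias; rankings are stable for the bundled benchmarks but
  bin count matters for very small tables (it is exposed as `n_bins`).
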