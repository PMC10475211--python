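# Methods

This note records the models, estimators, numerical choices and known limits
of `scnsync`, in the order the pipeline runs.

## Scope and assumptions

The pipeline starts at per-cell hourly bioluminescence traces (one matrix per
SCN slice); image acquisition and ROI segmentation are upstream of it. All
phase models are rotating-frame noisy Kuramoto models with identical natural
frequencies: the recordings they describe are in steady state, with the
population period, the mean intrinsic period and (in vivo) the light-dark
period all ≈ 24 h, so intrinsic-frequency dispersion is absorbed into the
noise strength D and any periodic drive into the coupling K. Simulations run
in the lab frame with a common frequency 2π/τ, which is equivalent.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
for everything downstream.

- **SDEs.** One community: dθ_i = (K/N)Σ_j sin(θ_j−θ_i)dt + D dW_i. Two
  communities of N cells each: both the within- (K_c) and between- (L_c)
  community mean fields carry a 2N divisor, so the drift on community 1 is
  (K₁/2)r₁sin(ψ₁−θ) + (L₁/2)r₂sin(ψ₂−θ). With D = 1 the stationary order
  parameters then satisfy V(K₁r₁+L₁r₂) = r₁ and V(K₂r₂+L₂r₁) = r₂, the same
  self-consistency pair the inference inverts.
- **Integrator.** Euler–Maruyama, default dt = τ/200. The scheme's O(dt)
  bias broadens the stationary phase distribution by roughly a factor
  1 + λ·dt/2 (λ the linearized restoring rate ≈ K·r), lowering r by ~0.015
  at K = 2, D = 1. Validation runs that compare against the mean-field fixed
  point therefore use dt = τ/500; at the default step the bias is well inside
  every tolerance the pipeline itself uses.
- **Randomness.** One master seed; each cell draws its initial phase and its
  entire noise path from its own spawned substream, so enlarging the
  population never perturbs existing cells. Initial phases are
  wrapped-normal around 0 (default SD 1 rad; fixtures mostly use 0.5), with
  an optional mean offset for community 2 to seed phase-split states.
- **Rendering.** I_i(t) = b_i + a_i(1+cos θ_i)/2 + ε, hourly samples;
  baselines and amplitudes are per-cell Gaussian draws (amplitudes clipped at
  a small positive floor), ε is i.i.d. Gaussian. Noiseless-waveform peaks sit
  exactly at θ_i = 0 (mod 2π). Defaults (baseline 100±20, amplitude 200±40,
  noise SD 5 a.u.) give the high signal-to-noise typical of smoothed
  PER2::LUC ROI traces.
- **Condition presets.** `calibrate_condition` inverts the two-community
  lines to place (K₁, K₂) so that a chosen (r₁, r₂) — e.g. the per-condition
  values 0.77/0.81 (young LP) through 0.94/0.94 (young SP) — is the
  stationary coherence at a chosen L.

What the generator does *not* emulate: photon-counting statistics, slow
amplitude damping, detrending artifacts, cell death, spatial optics, or
inter-slice variability in waveform shape. Passing tests show the estimators
invert the model class they assume; they cannot certify robustness to those
unmodeled features of real recordings.

## Trace processing

- **Smoothing/resampling.** Centered moving average on the native grid, then
  cubic-spline resampling to one point per minute. The default window is
  1 h — enough to suppress sampling-scale measurement noise. This is a
  deliberate choice: the moment bounds downstream estimate the variance of
  genuine fast phase jitter, and a wide window (e.g. 3 h) filters that very
  signal, inflating r (0.93 vs a true 0.81 in the recovery fixtures) and
  deflating h₂/h₄ until the inferred K interval no longer contains the truth.
  Widen the window only for noisy recordings, knowingly.
- **Peak detection.** Local maxima with ≥16 h separation and prominence
  ≥20% of the cell's amplitude range — safe for periods in [20, 28] h.
- **Cycle alignment.** Peaks are indexed by *population* cycle: the pooled
  peak times define a reference phase (circular mean at the consensus
  period) and each peak is assigned the nearest cycle number. Without this,
  a cell whose first peak is clipped at the record edge shifts all its
  cycle-indexed statistics by a full period (observed: slice dispersion
  inflated from ~1.3 h to ~5.8 h).
- **Inclusion rules.** A cell is retained with ≥3 complete cycles
  (= 4 peaks; one cycle = one inter-peak interval) and mean inter-peak
  period in [20, 28] h, boundaries inclusive. The slice consensus period is
  the median of retained cells' periods. Filtering is idempotent.
- **Dispersion.** Sample SD (ddof = 1) of one population cycle's peak times
  across cells. The default analysis cycle is the second in-vitro cycle
  (index 1 — the first full cycle after the culture transient); configurable,
  since which cycle a given dataset used is a free choice.

## Phase coherence

Relative phases use the linear peak-time-to-phase map (small-angle regime —
offsets are small against the period; no wrapping correction). The order
parameter is the magnitude of the mean unit phasor. Per-community order
parameters use each community's own mean peak time, so two internally tight
communities half a cycle apart both score r ≈ 1 while the whole slice does
not — matching the observation that subpopulation coherence exceeds
whole-slice coherence. Groups with fewer than two cells report no value.

## Community detection

A stand-in for heavier clustering machinery, built from its stated
properties: Pearson correlations of the raw traces; eigendecomposition;
removal of the global mode and of all components with eigenvalues inside
the Marchenko–Pastur bulk [(1−√(N/T))², (1+√(N/T))²]; sign split of the
leading residual eigenvector. Two refinements proved necessary:

- Only components *above* the bulk are kept. The near-zero eigenvalues below
  the bulk's lower edge are degenerate directions of a strongly correlated
  matrix, and keeping them hands the split meaningless structure.
- The global mode is identified as the largest eigenvalue *with a
  single-signed eigenvector* (≥90% one sign among non-negligible loadings).
  When two communities sit in antiphase their common rhythm cancels, the
  largest eigenvalue is the community contrast itself, and removing it
  blindly destroys the signal.

If nothing survives the filter the assignment is flagged degenerate (no
two-community structure). The quality score is the mean within-group minus
mean between-group entry of the filtered matrix; it is positive whenever a
split is reported. Labels are defined up to the 1↔2 swap. External label
files can bypass this module entirely.

## One-community inference

- **Increments.** For consecutive detected peaks of a cell at population
  cycles c₀ < c₁ (gap g = c₁−c₀ ≤ 2), the unwrapped relative-phase change is
  Δ = 2π(1−g) + ω[(t̄(c₁)−t₁) − (t̄(c₀)−t₀)]. The gap term records full-cycle
  phase slips as single ±2π samples. This matters: at K = 2, D = 1 about 2%
  of cell-cycles slip, and those tail samples dominate the fourth moment —
  censoring them (as a naive per-cycle wrapped difference does) collapses the
  estimated h₄ and pushes the lower coupling bound far above the truth.
  Increments are pooled across cells and transitions by default (a per-cell
  first-pair-only mode exists, since pooling granularity is a free choice).
- **h-statistics.** h₂ = n·m₂/(n−1);
  h₄ = [3(3−2n)n²m₂² + n²(n²−2n+3)m₄] / [(n−1)(n−2)(n−3)n]. Both exactly
  unbiased (verified by simulation: means → 1 and 3 on standard-normal
  samples).
- **Bounds.** C solves V(Cr) = r by bracketing + Brent to 1e−12 (series
  limit C → 2 as r → 0⁺). K⁺ and K⁻ are the positive roots of
  4K² − 2C²h₂rK − C²h₂/T = 0 and 12K² − C²r(6h₂−h₄)K − 3C²h₂/T = 0,
  obtained by substituting K = CD/2 into the Itô moment inequalities;
  D± = 2K±/C. For h₄ ≥ 0, K⁻ ≤ K⁺ structurally; a strongly negative sample
  h₄ (possible at small n) is reported as-is. V(x) is computed with
  exponentially scaled Bessel functions, stable for arbitrarily large x.
- **Convention.** C = 2K/D is used throughout (the standard stationary
  analysis gives 2K/D²; the two coincide at D = 1, and all fixtures and the
  two-community stage operate at D = 1).

The bounds rest on a Taylor truncation that assumes |Δ_T| ≪ 1; phase slips
violate it, which is precisely why the resulting intervals are wide. On the
recovery conditions (50 rendered slices, N = 300, K = 2, D = 1, 10 cycles)
the median interval brackets both K and D and the per-slice K interval
contains the truth in well over ⅔ of slices. Perfection is not expected and
not claimed.

## Two-community inference

C_c solves V(C_c) = r_c; the lines K_c = −(r_other/r_c)L_c + C_c·D/r_c follow
analytically. D is fixed at 1, the value the one-community stage recovers
across conditions (only the qualitative K–L relationship depends on it).
Anterior and posterior slices of a condition are pooled by arithmetic mean of
slice-level (r₁, r₂) — the averaging weights are a free choice and the
operator is configurable. No unique (K₁,K₂,L₁,L₂) point is estimable from
coherence data by construction; the lines are the deliverable.

## Search-space analysis

- **Solution space.** Per condition and community, K runs over [0,10] in
  steps of 0.1, L follows from the line and must lie in [−5,10]. A solution
  configuration picks one point per line (8 points), independently and
  uniformly.
- **Statistics.** Total adaptive capacity of an age group:
  Σ_c |K_SP−K_LP| + |L_SP−L_LP|. Young–old difference within a photoperiod:
  Σ_c |K_Y−K_O| + |L_Y−L_O|. The L-difference convention is configurable:
  `plain` (default) compares signed couplings; `magnitude` compares
  ||L_a|−|L_b||. Plain is the default because, inside the constrained set,
  the magnitude convention makes "old capacity exceeds young" and
  "difference larger in LP" the *same* event (an algebraic identity), which
  contradicts the distinct behaviour of the two constrained fractions; the
  plain reading reproduces the unconstrained fractions and the
  near-impossibility of old out-adapting young under constraints.
- **Constraints** (all strict; L compared by magnitude, the only feasible
  reading on negatively sloped lines): (1) K and |L| higher in young than
  old, both photoperiods; (2) higher in SP than LP, both ages; (3) the sign
  of K₁−K₂ and of L₁−L₂ identical across all four conditions.
- **Estimation.** Unconstrained fractions: Monte Carlo (default 10⁷
  configurations) or exact enumeration via per-community component
  distributions and cross products (tractable on reduced grids; used as the
  sampler's oracle). Constrained fractions: constraints 1–2 couple
  conditions only within a community, so each community's admissible
  4-tuples are enumerated exhaustively (~1.4·10⁵ and ~4.1·10⁵ of ~7.7·10⁷);
  uniform pairing plus rejection on constraint 3 (~35% acceptance) then
  samples the conditional distribution exactly, ~10⁵× faster than naive
  rejection from the product measure (overall pass rate ~3·10⁻⁶), which is
  retained for cross-validation. Ties count as "not greater". Default
  survivor target 10⁶.

## Pipeline

`run_all` executes simulate/ingest → process → coherence → (external labels
or community detection) → one-community bounds → per-condition lines →
search space, writing per-stage outputs and one summary JSON. Every stage
output carries the config hash (which excludes the output directory) and
the master seed; with a fixed seed the summary is byte-reproducible. An
order-parameter table (or the built-in condition values) can bypass the
trace stages and drive the search-space analysis alone.

## Problem sizes used in validation

Recovery and acceptance checks use: 50 slices of 300 cells × 10 cycles for
one-community recovery; 500 cells per community × 30 cycles at dt = τ/500
for two-community line recovery; 10⁷ Monte-Carlo configurations and ≥10⁶
constrained survivors for the search-space fractions. These sizes hold every
Monte-Carlo error well below the corresponding tolerance.

## Known limitations

- The moment bounds assume stationarity and small one-cycle increments;
  strong desynchronization (r ≲ 0.3) or very noisy recordings yield
  uninformatively wide or biased intervals.
- Peak-based phase observation low-passes the phase process; the smoothing
  window trades measurement-noise suppression against jitter attenuation,
  and no window removes the trade-off entirely.
- The spectral community split is a two-group method; more communities, or
  gradual phase gradients without block structure, are outside its design.
- Between-community divisor 2N is a modelling convention; comparing K and L
  values against conventions that use N requires rescaling L by 2.
- The search-space fractions are proportions of a uniform measure over
  discretized lines — not posterior probabilities of biological states.
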