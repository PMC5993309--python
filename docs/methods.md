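# Methods

## The model of a foraging observation

An observation is a binary time series sampled at a fixed resolution
(default 1 s): at each time unit the animal is either moving (1) or
stopped (0). A *bout* is a maximal run of one state. The package's
reference model of such data is a stationary alternating renewal process:
move-bout durations are i.i.d. with mean M, stop-bout durations i.i.d.
with mean S (seconds), and successive bouts are independent. Under this
model the long-run proportion of time moving is

    PTM = M / (M + S)

and the true movement frequency — complete move bouts initiated per
minute — is

    MPM_true = 60 / (M + S).

All indices of one window of OD minutes:

| index | definition | properties |
|---|---|---|
| PTM | moving units / total units | unbiased for M/(M+S) |
| naive MPM | move runs intersecting the window / OD | biased high: fragments at the window edges count as whole moves |
| MPM′ | naive MPM − PTM/OD | bias-corrected |
| CPM | state changes / (OD − 1 time unit) | CPM/2 unbiased for MPM_true |
| AM, AS | mean durations of interior move / stop bouts (min) | edge bouts dropped (their full duration is unobserved) |

The expected excess of naive MPM is PTM/OD moves per minute (absolute),
equivalently AM/OD in relative terms, since AM = PTM/MPM. Both the
correction MPM′ and the bias-model predictions assume independence of
successive bout durations; with strong serial correlation in real data
the correction is approximate and CPM/2 (which needs no bout-splitting at
the edges at all) is preferable whenever raw sequences are available.

### Study-level correction

Published summaries rarely contain per-observation values. Applying
MPM′ = MPM − PTM/OD to study-level *arithmetic means* of MPM, PTM and OD
removes part of the bias and never adds any: the exact averaged
correction subtracts a term proportional to the reciprocal of the
harmonic-mean OD, the feasible one a term proportional to the reciprocal
of the arithmetic mean, and the harmonic mean never exceeds the
arithmetic mean. `published.correct_table` implements this for whole
tables, deriving mean OD from total time / n when that is all a study
reports, and flagging (never dropping) rows where OD cannot be derived.

## Feasibility constraints on the MPM–PTM plane

With minimal recognizable bout durations M_min and S_min (minutes), the
attainable naive MPM at a given PTM is capped by

    MPM_max = min( PTM / M_min,  ((1 − PTM)·OD/S_min + 1) / OD ).

The low branch caps how many distinct moves fit into the moving time; the
high branch caps how many stops of at least S_min fit into the non-moving
time (+1 because moves flank the stops; at PTM = 1 exactly one continuous
move remains, MPM = 1/OD). The high branch is implemented in the
dimensionally consistent form above, which reduces to (1 − PTM)/S_min
when OD is large. Both branches are smooth approximations to the exact
staircase boundary and assume M_min, S_min ≪ OD; `FeasibilityBounds`
warns when either exceeds OD/10. Feasibility checks allow a tolerance of
one edge fragment, 1/OD, above the bound, because the naive estimator
counts edge-truncated fragments.

`am_as_from_summary` converts reported (MPM, PTM) averages to the
AM–AS plane via AM = PTM/MPM, AS = (1 − PTM)/MPM. These derived
species-level values inherit the bias and pooling error of their inputs;
they are rough. Either naive or corrected MPM may be supplied — with OD
available the corrected value is the less biased input.

## The simulator

`simulate_sequence` draws alternating bouts from a chosen family:

- **geometric** (default): discrete, memoryless, support ≥ 1 unit, mean
  M (or S) units. The natural discrete analogue of the independence
  assumptions above; the property tests rely only on features common to
  any i.i.d. bout family, plus geometric closed forms where stated.
- **fixed**: every bout exactly its mean — deterministic periodic
  sequences, useful as exact oracles.

Initialization is stationary by construction rather than by burn-in: the
initial state is moving with probability M/(M+S) and the first (edge)
bout's remaining length is drawn from the discrete forward-recurrence
distribution P(R = r) = P(L ≥ r)/E[L]. For geometric bouts this residual
is again geometric (memorylessness); for fixed bouts it is uniform on
1..L. Every window of the output is then statistically identical to a
window of an infinitely long realization, which is what makes small
windowed experiments exact rather than approximate. A `burnin` option
(10·(M+S) discarded units from a fresh bout) exists as a cross-check.
All randomness flows through one `numpy` generator seeded per sequence;
experiment outputs record their seeds.

What the simulator does *not* emulate: serial correlation between bouts,
heavy-tailed or multimodal bout durations, diel or thermal nonstationarity,
and observer error. Tests passing under the generator therefore establish
the estimator algebra and the bias/variance laws under the stated
independence assumptions — not that real foraging data satisfy those
assumptions.

## Window-resampling experiments

`window_bias_experiment` slides a window (default 2 min) along a sequence
at a fixed step (default 1 s), computes naive MPM, MPM′ and CPM/2 in
every window via O(n) sliding sums, and reports the mean difference from
the *naive MPM of the entire sequence* — the reference used for all three
estimators, since all three estimate movement frequency. Window
variances are population variances (windows overlap heavily, so they
support point estimates, not confidence intervals). The reference itself
is known to sit (PTM − 1/(M+S))/OD_total above the true rate; result
objects carry it so summaries can note that measured biases slightly
underestimate the truth.

### Exact discrete-time expectations

With w samples per window at resolution r seconds, the expected window
move count is PTM + (w − 1)/(M+S)·r, because a window of w samples
exposes only w − 1 transition slots. Hence, exactly,

    E[naive window MPM] − MPM_true = (PTM − r/(M+S)_units…) / OD
                                   = PTM/OD − r/((M+S)·OD·1s) ,

i.e. the continuous-time law PTM/OD minus a discretization term of order
r/(M+S), and MPM′ retains exactly −r-per-unit/( (M+S)·OD ) of residual
bias while CPM/2 (whose denominator already discounts the unobservable
last slot) is exactly unbiased at any resolution. Two consequences shape
the experiment defaults:

- Experiments that validate the continuous-time laws (the bias-vs-PTM
  slope; zero bias of MPM′) simulate at **0.1-s resolution** and use
  **4×10⁴-s sequences**, so that both known deviations — the
  discretization term and the reference's own 1/OD_total edge bias — are
  small relative to Monte-Carlo error, while keeping the observation
  protocol itself unchanged (2-min windows at 1-s offsets).
- At 1-s resolution with short bouts these terms are resolvable: users
  comparing window means to long-sequence values at high precision should
  expect them.

### Bias-vs-PTM slope

`simulate_bias_vs_ptm` spans PTM 0.05–0.9 (24 targets) with stop means
S ∈ {20, 40, 80} s and M = S·PTM/(1 − PTM), three replicate sequences per
combination (216 sequences). Regressing per-sequence mean window bias on
the sequence's measured PTM recovers the theoretical slope 1/OD = 0.5 for
2-min windows; `bias_vs_ptm_slope` fits OLS and reports a 95% normal
approximation CI half-width. The S grid keeps move bouts at least one
second at the lowest PTM and keeps the discretization slope contribution
(≈ r/(2S) within each S) below the fitted CI.

### Relative-bias grid

`bias_grid` estimates E(naive MPM − MPM_true)/MPM_true per (M, S) cell
from independent stationary replicates of length OD, compared against the
analytic rate 60/(M+S). Because initialization is exactly stationary,
this estimates the same quantity as carving 10⁴ windows out of one
2×10⁶-s master sequence — the classical protocol, which
`window_bias_experiment` also provides — at much lower cost. Cells match
AM/OD and are constant along the S axis (the relative bias does not
depend on stop durations).

### Variance comparison

`variance_ratio` returns var(CPM/2)/var(naive MPM) over the windows of
one sequence. Across the stated default grid — M ∈ {2, 5, 10, 20, 40} s
crossed with S ∈ {10, 20, 40, 80, 160} s, 3-min windows — the ratio is
below 1 in 24 of 25 cells: the change-based estimator is the more precise
one except for animals that almost never pause (mean stops ≲ 10 s
combined with long moves, e.g. M = 40, S = 10), where naive MPM is
slightly more precise (ratio ≈ 1.02). That corner corresponds to the
small region above the unit contour of the variance-ratio surface.

## Numerical and policy choices

- **Minimum-duration enforcement.** The default `absorb` rule makes a
  left-to-right pass absorbing each sub-threshold bout into its preceding
  bout (the first bout into the following one), merging same-state
  neighbours, repeating until stable. It is deterministic, idempotent and
  conserves total duration. Field protocols differ on whether
  window-truncated edge bouts should be exempt from thresholds, so an
  `absorb_interior` rule (edges exempt) is provided; the policy used
  (m_min, s_min, rule) is always carried into index output, since indices
  are not comparable across unreported thresholds.
- **PTM is a fraction internally**, converted from percent only at I/O
  (the correction formula requires a fraction; `correct_table`
  auto-detects percent columns with a warning).
- **Negative MPM′** (possible when a reported MPM is already at or below
  the correction term) is returned with a warning, not clamped — clamping
  would re-introduce positive bias in averages.
- **Degenerate inputs**: CPM requires ≥ 2 samples; AM/AS are NaN (never
  zero) when no interior bout of the state exists; `variance_ratio` is
  NaN with a warning when window MPM is constant; an all-stop window has
  MPM = CPM = 0.
- **Problem sizes.** Default experiment sizes (≈ 200–220 sequences of
  4×10⁴ s for the slope; 600 replicates per bias-grid cell; 25-cell
  variance grid with 4 replicates) put Monte-Carlo error comfortably
  below the effects being measured while the full suite runs in well
  under a minute of simulation time.

## Known limitations

- The exact staircase feasibility boundary is not implemented; the smooth
  two-branch approximation requires M_min, S_min ≪ OD.
- The bias correction and all closed forms assume independent bout
  durations; serially correlated or heavy-tailed bout processes are out
  of scope.
- Velocity-based indices, attack-rate indices and behavioural-mode
  classification are deliberately excluded; in particular no MPM = 1
  cut-off between foraging modes is provided, because similar low MPM
  values arise both from rarely moving and from rarely stopping.
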