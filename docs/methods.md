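# Methods

## Pipeline

The analysis chain, per subject and condition block, is fixed:

1. zero-phase Butterworth band-pass 0.5–45 Hz (order 12 per pass);
2. common-average re-reference;
3. amplitude artifact mask: any sample where any channel exceeds 50 μV,
   dilated by ±200 ms to cover filter ringing;
4. band split into mu [8, 13) Hz and beta [13, 30] Hz (order 4 per pass,
   zero-phase; the shared 13 Hz boundary is attributed to beta);
5. five non-overlapping 10-s windows drawn at random from the artifact-free
   spans (deterministic given the seed); both bands use identical window
   positions so cross-band comparisons share data support;
6. pairwise GCI for every ordered channel pair per window, averaged
   entry-wise over the five windows — the network is built from the
   *average* causality matrix, not from per-window networks;
7. thresholding into a binary directed network (strict `>`);
8. graph metrics; cross-state paired t-tests and change rates.

Zero-phase (forward–backward) filtering is used because group delay would
corrupt the lagged autoregressive fits. Its cost is that the filter is
non-causal: it smears temporal precedence, so within a narrow band the
estimated GCI becomes nearly symmetric between the two directions of a
truly unidirectional coupling. The *magnitude* of the index still tracks
coupling strength, which is what the network stage consumes; directional
asymmetry is fully recovered on unfiltered data (see the estimator
validation below).

## GCI estimation

All autoregressions are ordinary least squares over lags 1..p with no
intercept. Residual variance is the mean squared residual; the GCI is
clamped at 0 from below, since finite-sample noise can make the restricted
model fit marginally better and the index quantifies a *reduction* in
prediction error. The estimator is deliberately bivariate: conditional
(multi-channel) GC is out of scope.

Band-passed signals are numerically rank-deficient in lag space (the
filter's stop-band creates near-zero singular values), so least squares is
solved with pseudo-inverse semantics (pivoted-QR LAPACK driver). Only a
channel paired with a near-exact copy of itself (|correlation| within
1e−12 of 1) is rejected as degenerate.

**Model order.** `select_order` implements BIC/AIC selection for the
bivariate model over a common sample span and recovers the true order of
simulated VAR(3) data reliably. The *pipeline default*, however, is a fixed
order p = 5 at 1000 Hz. On heavily oversampled narrowband data BIC drives
the order to 10–20 (narrowband signals have long predictable memory), and
at those orders the spurious GCI floor between uncoupled channels grows to
the size of the true-edge values, erasing the edge/non-edge contrast.
Orders 3–5 preserve the contrast in both bands; 5 is the default, and BIC
selection remains available via `gc_matrix(..., p="auto")`.

## Threshold rule

An edge requires GCI strictly above a per-band threshold. The integrity
rule returns the largest candidate threshold (100-point grid between the
off-diagonal extremes) for which at most a configurable fraction of nodes
(default 0) is left with total degree zero. In the multi-state pipeline the
rule is applied to each state's across-subject mean matrix and the minimum
over states is used, so the single per-band threshold preserves the
integrity of *every* network it is used to build; a threshold chosen on an
all-states pooled matrix sits at rest-state level and empties the
task-state networks. Fixed per-band thresholds are available via
`threshold_policy="fixed"`.

## Graph metrics

Distances are unweighted directed hop counts. Characteristic path length L
averages over reachable ordered pairs only and reports the unreachable-pair
count alongside (L is undefined on a fully disconnected digraph and is then
NaN); global efficiency gives unreachable pairs their natural limit 0, so
both statistics stay finite and comparable across thresholds. Clustering
uses the undirected formula Cᵢ = 2Eᵢ/(kᵢ(kᵢ−1)) on the symmetrized graph
(an undirected edge wherever either direction is present), with Cᵢ = 0 for
kᵢ < 2, and the network mean taken over all N nodes. Degrees are reported
as in, out, and total (in + out). Shortest paths and clustering are
delegated to networkx; the test suite checks them against independently
coded Floyd–Warshall and exhaustive neighbor-pair oracles.

## Synthetic data generator

The generator emulates a motor-imagery session as a stable MVAR process
observed with broadband background noise:

- **Per-node dynamics.** Each channel is an order-4 autoregression: the
  product of two order-2 resonances, one in mu and one in beta, with pole
  radius 0.95. Pole angles are solved so the *spectral peak* (not the pole)
  lands on the requested frequency — at EEG frequencies relative to a
  1000 Hz rate the AR(2) peak sits visibly below the pole angle. Peak
  frequencies vary across channels (9.5–11.5 Hz and 18–22 Hz), as
  individual rhythms do.
- **Coupling graph.** Directed and acyclic: an anterior→posterior backbone
  (Fp1→F3→C3→P3, F4→C4→P4) plus weaker interhemispheric links and a weaker
  right-prefrontal branch (Fp1→Fp2→F4) — subjects imagine *right-hand*
  movement, making the left-hemisphere drive dominant. Acyclicity is a
  stability guarantee: with resonant node dynamics, any feedback cycle's
  loop gain is amplified by each node's resonance peak and destabilises the
  process at realistic weights, whereas a feed-forward graph leaves the
  companion spectrum equal to the self-dynamics poles regardless of
  coupling strength.
- **Gain-normalised weights.** Near 10–20 Hz every node's AR dynamics have
  a large steady-state gain, so a raw lag-1 coupling coefficient would be
  re-amplified by the receiver and compound down chains. Each edge weight
  is divided by the receiver's gain at the sender's peak frequencies;
  `coupling_weight` (default 0.8 for backbone edges, half for secondary
  edges) is therefore approximately the amplitude ratio of transmitted to
  intrinsic oscillation, wherever the edge sits.
- **Amplitude calibration.** Innovation SDs are fixed-point iterated
  against the exact stationary covariance (companion-form discrete Lyapunov
  equation) so every channel's RMS is 10 μV — resting-EEG-like and safely
  inside the 50 μV artifact bound.
- **Background noise.** Additive 1/f noise at 20 % of signal RMS. This is
  both realism (real EEG has a continuous background spectrum) and a
  numerical necessity: a finite-order MVAR is band-limited-deterministic
  after band-pass filtering, leaving residual variances at machine noise
  and the GCI undefined.
- **Condition blocks.** Three 60-s states. During "task", every edge
  incident to a frontal or central channel is scaled by 0.4; the
  "rest-after" block recovers to 0.7, emulating suppression of effective
  connectivity over frontal/sensorimotor cortex that outlasts the task.
  Task-state channels also show slightly reduced power, the analogue of
  task-related desynchronisation. Per-state noise streams derive
  deterministically from the master seed (numpy `SeedSequence` spawn keys),
  so one integer reproduces the whole session.
- **Stationarity guard.** Every emitted process must have companion
  spectral radius < 1. The radius is computed by Gelfand's formula
  (repeated squaring with renormalisation, k = 2¹⁶) rather than eigenvalue
  routines: with many channels sharing near-identical poles the companion
  matrix is defective and its numerical eigenvalues overshoot by ~0.1,
  falsely rejecting stationary specifications.

**What the generator does not emulate:** volume conduction and reference-
electrode field spread (channels mix only through the common-average
re-reference and the coupling itself), ocular/muscle artifact morphology
(amplitude outliers can be injected, but no blink templates), non-
stationarity within a block, and inter-subject variability beyond
independent noise realisations (all subjects share one coupling graph).
Consequently, passing tests demonstrate that the *pipeline* recovers known
causal structure and its condition-dependent changes — not that real EEG
satisfies the MVAR assumptions.

## Study-scale defaults

The default study uses 16 subjects, 8 channels (Fp1, Fp2, F3, F4, C3, C4,
P3, P4), 1000 Hz, 60 s per state, five 10-s segments per state. The
channel count keeps the full study and its tests at around a minute of
CPU; 62-channel generation over the extended 10–20 montage is supported.

## Numerical and statistical conventions

- Paired t-tests are two-sided, computed on A − B differences (t < 0 means
  the metric rose from A to B), with α = 0.05 and no multiple-testing
  correction in the default report. All-zero difference vectors return
  (t, p) = (0, 1); zero-variance *nonzero* differences are degenerate and
  raise (at cohort sizes ≥ 4 this does not occur in practice; the pipeline
  records such a comparison as NaN with a warning rather than aborting).
- Change rate = (mean_B − mean_A)/mean_A × 100.
- Summary SDs use ddof = 1; a single subject reports SD 0.
- All numeric text output is written at %.17g, making reruns
  byte-comparable; every output directory includes the resolved config, its
  hash, and a log of seeds, orders, and thresholds.
- Missing subjects in a state are dropped pairwise with a warning.

## Known limitations

- Pairwise GC cannot distinguish direct from indirect influence: a two-hop
  ancestor acquires a genuine positive GCI to its descendant. The network
  therefore encodes "directed influence", not anatomical-style direct
  coupling; metric *changes* between states remain interpretable because
  indirect influence scales with the coupling it rides on.
- Zero-phase narrowband filtering symmetrises directional asymmetry within
  a band (see above); in-band GCI should be read as coupling strength.
- The GCI is unbounded above; values well above 1 occur at strong coupling.
- Stationarity of 10-s segments is assumed. An explicit check is not
  enforced; the generator guarantees it by construction.
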