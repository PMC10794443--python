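# Methods

## The network model

Each of the *N* neurons is a discrete-time (1 ms) stochastic leaky
integrate-and-fire unit on a complete graph.  Excitatory neurons
(indices 0..N_E−1, N_E = pN) project weight *J/N*; inhibitory neurons
project *W/N = gJ/N*.  The membrane update is

    V_i[t+1] = (mu V_i[t] + I_ext + J p rho_E[t] − W q rho_I[t]) (1 − X_i[t]),

where rho_E/I are the firing fractions and the (1 − X) factor resets a
neuron that just fired.  Spikes are Bernoulli draws from the
piecewise-linear gain Φ(V) = Γ(V − θ) on θ ≤ V ≤ θ + 1/Γ (0 below, 1
above).  Because the couplings are homogeneous, the recurrent input is
identical for every neuron and one step costs O(N); with μ = 0 every
non-refractory neuron additionally sits at the same potential, which the
simulator exploits (a single scalar firing probability per step).

### Parameter conventions (θ and I_ext)

Defaults: N=1000, p=0.8, q=0.2, J=10, Γ=0.2, μ=0, θ=1, **I_ext=1**.
The tonic current equals the threshold, holding quiescent neurons exactly
*at* threshold.  This is not a redundant choice — it is what makes the
model critical at finite coupling:

* Φ(θ) = 0, so total silence is still an absorbing state and the offline
  drive (below) is required to keep dynamics alive;
* one presynaptic spike changes each neuron's firing probability by
  ±ΓJ/N (E) or ΓgJ/N (I), so the branching ratio is σ = ΓW̄ with
  W̄ = pJ − qW, and σ = 1 at W̄_c = 1/Γ, i.e. g_c = p/q − 1/(qΓJ) = 1.5;
* with I_ext = 0 and θ = 1 the recurrent input (≤ J/N per spike) could
  never reach threshold and no value of g would sustain activity.

At μ = 0 the spike process is invariant under shifting (θ, I_ext) by a
common constant, so these defaults are equivalent to the θ = 0, I = 0
convention in which the critical-point formula is usually derived.

### Mean-field map

`mean_field_trajectory` iterates the exact N → ∞ limit of the homogeneous
network: V[t+1] = μV[t] + I_ext + pJρ_E − qWρ_I (the quiescent-neuron
potential, *not* the population average) and ρ[t+1] = (1 − ρ[t]) Φ(V[t+1]),
the (1 − ρ) factor accounting for just-reset neurons (at V = 0, unable to
fire since Φ(0) = 0).  Averaging V over the population first — including
the reset factor inside the potential — would shift the apparent critical
point to W̄ = θ + 1/Γ and contradict both the microscopic simulation and
the closed-form g_c; the per-population form reproduces both (tested:
Monte-Carlo one-step rates at N = 10⁴ match within 3 standard errors, and
the active fixed point obeys ρ* = 1 − W̄_c/W̄).

### Offline drive and avalanches

After the Bernoulli draws of a step, if no neuron fired, exactly one
neuron chosen uniformly over all N is forced to spike at that same step;
the step index is recorded.  Every recorded step therefore has activity
≥ 1, and consecutive forced spikes delimit avalanches exactly (no
zero-activity gaps exist, so a gap-based definition would coincide).
The trailing interval cut off by the end of the recording is discarded.
Time is not binned before avalanche extraction (Δt = 1 step).

Initialization: V = 0, each neuron independently active with probability
0.1; the transient (default 10,000 steps at full scale, 5,000 at desk
scale) makes the choice immaterial.  All randomness in a simulation —
initialization, spiking, drive-neuron choice — comes from one generator;
uniforms are consumed in a fixed order (N + 1 per step), so rasters are
bit-for-bit reproducible from the seed.

## Dissimilarity measures

Neurons with fewer than 2 spikes in the analysis window, or whose binned
counts are exactly constant, are removed before all three measures; an
optional seeded uniform subsample caps the vertex count in desk-scale
runs (H1 cost grows steeply with vertex count).

* **Pearson**: 1 − r of spike counts in half-open 4 ms bins (the one
  concrete bin width the source protocol states; configurable).  r < 0
  would give values in (1, 2], so the result is clipped to [0, 1] to keep
  the filtration on the unit interval.
* **SPIKE-synchronization**: each spike is matched if the nearest spike
  of the other train lies strictly within the adaptive coincidence
  window τ = ½ · min of the up-to-four surrounding inter-spike intervals
  (missing neighbors at train edges are simply omitted from the min).
  S = matched fraction over both trains; dissimilarity = 1 − S.
* **SPIKE-distance**: the time-resolved profile S(t) built from the
  distances of the previous/following spikes to their nearest partner in
  the other train, linearly interpolated within each local inter-spike
  interval and weighted by the two local interval lengths.  Auxiliary
  spikes at the window edges provide the standard edge correction.  S(t)
  is linear between consecutive pooled spike times, so the time average
  is computed as an exact trapezoid over those breakpoints — no
  quadrature grid.

The reference implementation of the SPIKE measures (PySpike) is not
available in this environment, so both are implemented here from their
published definitions and validated against brute-force O(n²) matching,
dense-grid numerical integration of the profile (agreement ~10⁻⁵,
limited by the oracle's grid), and closed-form toy cases.  A consequence
worth stating: agreement with PySpike to machine precision is *asserted
nowhere*; the tests establish agreement with the definitions, not with a
particular implementation's edge-case choices.

## Persistent homology

Weights are already in [0, 1]; the filtration threshold sweeps that range
(eps_max = 1).  A simplex enters when its maximum pairwise weight is ≤ ε
(closed convention); Betti curves use half-open [birth, death) bars, so
boundary conventions do not affect any integral.  Maximum simplex
dimension is 2 — only β₀ and β₁ are used.

* **H0**: Kruskal sweep over weight-sorted edges; the n − 1 component
  merges are the finite deaths (elder rule), plus one essential bar.
* **H1**: GF(2) reduction of the triangle boundary matrix over the edge
  basis.  Columns are Python integer bitmasks (one bit per edge in
  filtration order; pivot = highest set bit), which keeps the reduction
  fast at the vertex counts used here (~1 s at n = 100).  Cycle-creating
  edges are identified by union-find; an unkilled cycle at eps_max gets
  death = +∞.  Ties in filtration value are broken deterministically
  (by vertex tuple); the resulting diagram is independent of the
  tie-break, which the exhaustive-oracle tests confirm.

Features are computed from the diagrams, never from sampled curves, so
grid resolution is not a hidden parameter: f1 = smallest finite H0 death
(eps_max for a single vertex), f2 and f4 = Σ over bars of
min(death, eps_max) − birth (the exact Betti-curve integrals; the
essential H0 bar contributes eps_max), f3 = maximum bar overlap by an
endpoint sweep.  Curves on an explicit grid are produced only for
inspection and plotting.

The whole pipeline (H0 + H1, both fixture families and random matrices
with n ≤ 8) is tested for *exact* equality against an independent
textbook oracle: enumerate all simplices of dimension ≤ 2, sort
simplexwise, reduce the full boundary matrix.  Betti numbers at fixed
thresholds are additionally cross-checked against a rank computation
(β₁ = E − V + β₀ − rank of the triangle boundary).

## Classification

One sample per simulation: 4 features × available measures, plus the
baseline descriptors mean_activity = Σ_t A[t]/(NT) and
activity_variance = Var_t(A[t]/N).  Labels: super-critical (g < 1.5),
critical (g = 1.5), sub-critical (g > 1.5).  Tasks: (1) super vs sub,
critical samples discarded; (2) all three; (3) critical vs merged
non-critical.

The classifier is sklearn's `SVC` (RBF kernel, squared-norm
regularization).  Per repeat: stratified 80/20 split; standardization
fitted on the training portion only; kernel width from the median
heuristic (γ = 1/median squared pairwise distance of standardized
training points); C selected from {10⁻², …, 10³} by stratified 10-fold
cross-validation on the training portion (folds clamped to the rarest
training-class count in very small runs, with a no-search C = 1 fallback
below 2 usable folds).  "Mean accuracy" is the plain test accuracy
averaged over 20 such repeats — the source protocol does not say what
its mean is over; repeated splits with fresh hyperparameter selection is
this package's choice and is documented as such, not inferred.
Stratification protects the critical minority class in task 3.

## Desk scale vs full scale

The full protocol (N = 1000, 10⁶ steps, 61 g values × 10 replicates
+ 190 critical replicates, no vertex cap) is emitted by
`paper_scale_config()` but costs hours.  The shipped defaults
(`reduced_config()`: N = 200, 6×10⁴ steps, 5 replicates + 100 critical,
vertex cap 100) run in minutes, and the test suite scales further
(coarser 0.05 grid, 4 replicates, cap 60 for the topological dataset).
What a green desk-scale test establishes: the qualitative physics
(activity ordering, finite-size avalanche cutoffs, feature trends in g)
and classification accuracy ≥ 95 %.  What it does not establish: the
full-scale accuracy table to its printed precision (e.g. 100.00 % for
task 1 on SPIKE-distance features), which is only approached as
simulation length and replicate counts grow.  The synthetic generator
emulates exactly this one homogeneous model; it does not emulate
heterogeneous or sparse connectivity, refractory periods beyond the
one-step reset, or any experimental recording artifacts, so green tests
say nothing about real recordings.

## Known limitations

* Supercritical runs at small N collapse to silence often, so desk-scale
  mean activity underestimates the N → ∞ fixed point ρ* = 1 − W̄_c/W̄;
  the regime ordering is preserved.
* The SPIKE-synchronization fallback window for two single-spike trains
  (half the observation window) is a convention; it is unreachable after
  vertex selection, which requires ≥ 2 spikes.
* Pearson dissimilarity saturates near 1 for weakly correlated short
  recordings, compressing the upper filtration range.
* β₁ reduction cost grows roughly with the number of triangles (n³/6);
  vertex caps beyond ~150 become the pipeline bottleneck.
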