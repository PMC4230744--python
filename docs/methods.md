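# Methods

## The model

`dopasim` simulates a network of N brain regions, each a neural mass with
three state variables: the mean membrane potential of excitatory neurons
V_i (mV), the mean potential of inhibitory interneurons Z_i (mV), and the
fraction W_i of open potassium channels.  Currents through voltage-gated
Ca/Na/K channels and a passive leak drive V; channel open fractions and
population firing rates are tanh sigmoids arising from normally distributed
thresholds,

    m_j(V) = (1 + tanh((V - T_j)/delta_j)) / 2,
    Q_V(V) = Q_V_max (1 + tanh((V - V_T)/delta_V)) / 2,

and analogously Q_Z(Z).  Regions interact only through excitatory firing:
the input to region i is the weighted average u_i = sum_j c_ij Q_V(V_j)
with a nonnegative structural coupling matrix C whose diagonal carries
local excitatory input (set to 1 before normalization) and which is
normalized by its largest row-sum, so max_i sum_j c_ij = 1.  u_i enters
both the NMDA-scaled calcium term and the sodium term of dV_i/dt.
Inhibition (a_ie Z Q_Z) and excitatory-to-inhibitory feedback (a_ei V Q_V)
stay within a region; there are no conduction delays and no inhibitory
projections between regions.  Non-specific input is a single scalar Wiener
process entering additively: excitatory components with amplitude
delta*a_ne_i, inhibitory with delta*kappa*a_ni, W and dopamine components
noise-free.  The shared noise source is a deliberate model feature — it
makes regional co-fluctuation the default and lets coupling and
neuromodulation shape its pattern.

Two additional components c = (c_l, c_r) hold the dopamine concentration
in the left/right laryngeal motor cortex (LMC).  Dopamine is released in
proportion to ipsilateral substantia nigra (SNc) firing with a
production rate beta(t) that steps between beta_min (rest, acquisition
gaps) and beta_max (speech windows), and is cleared by Michaelis-Menten
re-uptake:

    dc/dt = beta(t) Q_snc - V_max c / (K_m + c).

Concentration feeds back through a saturating gain
G(c) = 1 + (G_max - 1) k c / (1 + k c) (k the antagonism parameter), which
(i) multiplies the LMC's excitatory-to-excitatory coupling,
a_ee -> G a_ee, and (ii) multiplies the *opening odds* of LMC potassium
channels, m -> G m / (1 + (G - 1) m), keeping the open fraction a
probability.  G(0) = 1 exactly, so an LMC without dopamine is
indistinguishable from any other region.  The exact algebraic gain and
modulation forms were design choices constrained to the documented
properties (unity at zero, monotone, bounded by G_max; modulated fraction
bounded by 1); the odds form was chosen because it is the minimal way to
"make channels more likely to open" without leaving probability space.

The full state [V(N), Z(N), W(N), c(2)] gives a (3N+2)-dimensional SDE
with constant additive scalar noise.  Dopamine components are clamped at
zero after each discrete step: the continuous-time model preserves c >= 0,
but a discrete step can undershoot.

Default parameters (model units, not physiological ones — mV/mM values are
normalized): thresholds/dispersions/conductances per the standard table in
`ModelParameters`; a_ee = 0.4, a_ei = 2.0, r_NMDA = 0.25, phi = 0.7,
tau_K = 1 ms; noise amplitude delta = 0.3, inhibitory noise scaling
kappa = 0.1; dopamine V_max = 0.004 mM/ms, K_m = 0.125 mM, c_0 = 0.05 mM,
beta in [0.0005, 0.01] mM per unit firing, antagonism 0.2 /mM,
G_max = 50.  Per-region heterogeneity a_ie ~ N(2.0, 0.1) and
a_ne ~ N(0.4, 0.05), truncated positive, drawn once per experiment with a
fixed seed, is what allows regions to desynchronize despite identical
equations.  The distribution parameters are package defaults (flagged as
such in config).  beta has units mM per unit firing so that beta*Q (Q in
kHz = events/ms) is a concentration flux in mM/ms.

## Numerical integration

The drift is globally Lipschitz and of linear growth on the physically
relevant domain (W in [0, 1]; firing rates and open fractions bounded), so
solutions exist and are unique; the suite checks a fitted linear-growth
constant over three state radii as a property test.

Because the noise is additive and scalar, an explicit strong order-1.5
Runge-Kutta scheme needs no diffusion derivatives and exactly three drift
evaluations per step: with a0 = a(t, Y), supporting points
Y± = Y + a0 h ± b sqrt(h), and a± = a(t+h, Y±),

    Y' = Y + b dW + (h/2) a0 + (h/4)(a+ + a-) + dZ (a+ - a-) / (2 sqrt(h)).

The increment pair (dW, dZ) — Wiener increment and its time integral — is
jointly Gaussian with Var dW = h, Var dZ = h^3/3, Cov = h^2/2, generated
from two iid standard normals as dW = u1 sqrt(h),
dZ = (h^{3/2}/2)(u1 + u2/sqrt(3)).  The RNG is numpy's PCG64 with an
explicit seed; one stream per simulation run, two normals per step, so
paths are bit-reproducible.  A Milstein reference scheme (= Euler-Maruyama
under additive noise) is kept for cross-checks; at the default h = 0.1 ms
both schemes agree on the full model, while Milstein at h = 1 ms diverges
(non-finite state within a second of model time) — the instability that
motivates the higher-order scheme.  No adaptive stepping, no order-2.0
scheme.

A note on measured convergence orders: on the Ornstein-Uhlenbeck benchmark
the order-1.5 scheme shows an empirical strong slope of ~2, not 1.5.  This
is genuine superconvergence, not a bug: the leading strong-error term of
the scheme is proportional to b^2 a'' (the drift's second derivative),
which vanishes identically for a linear drift.  Milstein measures ~1.0 as
expected.  The benchmark couples every step size to the same Wiener path
by pairwise coarsening of (dW, dZ) and compares against the exact OU
propagator X' = e^{-ah} X + sigma (dW - a dZ), whose truncation error is
O(h^2) with a much smaller constant than either scheme's error.

The integration loop is JIT-compiled (numba); the public `drift()` calls
the same kernel, and an independent scalar-loop transcription in the test
suite pins the two to 1e-12.  An output stride decouples the integration
step (0.1 ms) from stored resolution (default 1 ms).

## From neural activity to BOLD

The neural drive is the regional excitatory firing rate Q_V (configurable),
averaged into 10 ms bins and fed through a Balloon-Windkessel model
(vasodilatory signal, inflow, venous volume, deoxyhemoglobin; RK4 at the
drive resolution) with canonical constants kappa = 0.65/s, gamma = 0.41/s,
tau0 = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02, efficacy 0.5.  Output
is percent signal change; zero drive yields an exact 0% baseline.  The
dense BOLD is then boxcar-averaged to the acquisition TR — and the TR
differs by condition, mirroring the empirical protocol: rest is sampled
continuously at TR 2 s, the speech task sparsely at TR 10.6 s (one volume
per 10.6 s cycle: 8.6 s production + 2 s acquisition).  The first two
cycles' worth of volumes are discarded from both conditions: the
hemodynamic states start at rest and their equilibration under sustained
drive otherwise imprints a shared onset transient on every region, which
at sparse sampling saturates all pairwise dependence estimates.

## Functional networks and statistics

Connectivity is normalized mutual information,
NMI = I(X;Y)/sqrt(H(X)H(Y)), estimated with equal-width histograms of
ceil(sqrt(T)) bins by default (configurable); constant series get NMI 0
with a warning.  NMI matrices are symmetric with unit diagonal and entries
in [0, 1] and are analyzed unthresholded.  Per node: strength (sum of edge
weights), degree (count of nonzero edges), Onnela clustering (mean
geometric mean of triangle weights, scaled by the network maximum), and
Latora local efficiency (mean inverse shortest-path length within the
neighborhood subgraph, distances = 1/weight, Dijkstra via scipy).
Clustering and efficiency are also normalized by their means over 100 null
networks that redistribute the off-diagonal weight multiset uniformly at
random (preserving size, density, and the weight distribution exactly);
nodes with zero null-mean metric report NaN.

Rest/task contrasts use a paired sign-flip permutation test with
max-statistic family-wise error control at alpha = 0.05.  Each permutation
flips the sign of every node's paired difference and *studentizes the
flipped vector by its own mean and sd* before taking the maximum across
nodes; the adjusted p of node i is the fraction of permutations (identity
included, so p >= 1/n_perm) whose max reaches node i's observed
studentized difference.  The within-permutation studentization matters:
the raw signed maximum is dominated by the largest |d_i| in half of all
flips and can never reject, whereas the studentized max is exactly
exchangeable under the null — the suite verifies a 5% +/- 2% rejection
rate over 1000 simulated null replicates and exact agreement with full
enumeration on tiny inputs.  A consequence worth knowing: a shift common
to *all* nodes is removed by the centering, so the test detects
node-differential effects, not uniform ones.

## Synthetic study design

Every input the empirical study measured is generated: a symmetric sparse
connectome with log-normal weights (density 0.3 — sparse, heavy-tailed,
like tract-count matrices), the 70-region manifest (64 cortical + 6
subcortical labels, LMC/SNc roles resolvable by name; generic labels for
other sizes with the roles at indices 0-3), heterogeneity draws, and the
rest/task schedules.  The paired experiment runs both conditions from one
global seed expanded into named substreams (connectome, heterogeneity,
initial state, simulation, null models, permutations): rest and task share
the connectome, the heterogeneity, the initial state (V, Z uniform in
[-0.1, 0.1] mV, W at its K-channel fixed point, c = c_0) and the
bit-identical Wiener path, and differ only in beta(t).  Setting
beta_max = beta_min makes the two pipelines bit-identical end to end,
which the suite asserts.

The default scaled-down experiment uses N = 10 regions and 20 cycles
(212 s of model time per condition; about 15-20 s wall-clock per pair),
chosen so the full five-seed design finishes in minutes on one CPU; the
full-scale N = 70, 50-cycle configuration is expressible through the same
config and runs in a few minutes per condition.

## What the scaled-down experiment does and does not show

With dopamine modulation on, mean nodal strength and local efficiency
increase from rest to task consistently across seeds, and clustering
increases in most seeds — the direction reported for the full-scale
system.  Two honest caveats.  First, at the neural level the net effect of
dopamine on the LMC is a *slight* firing increase (the excitatory a_ee
gain and the hyperpolarizing K-channel gain nearly cancel), and the
task-locked component that propagates to other regions is weak at N = 10;
in fact, under matched sampling of both conditions the LMC's cyclic regime
shift *de*-correlates it from the common-noise-driven network and all
three metrics decrease.  The rest-to-task increase emerges under the
faithful acquisition asymmetry — few sparse task samples versus many rest
samples — which inflates the plug-in NMI estimate of the task condition.
The same asymmetry is built into the empirical design this package
emulates, so the reproduction is faithful, but the contrast should be read
as a property of the full acquisition-plus-estimation pipeline, not of
neural dynamics alone.  Second, Onnela clustering is scaled by the network
maximum, so a roughly uniform NMI elevation cancels out of it; at N = 10
(45 node pairs) the scaling makes clustering the noisiest of the three
metrics across seeds, while at N = 70 the maximum saturates in both
conditions and clustering tracks raw weights.

The synthetic connectome also does not emulate real tractography:
distance-dependent connection probability, hemispheric symmetry and hub
structure are absent, so passing tests show pipeline correctness and
direction of effect under the stated generator, not quantitative agreement
with DTI-derived systems.

## Degenerate inputs and numerical edges

Nonpositive dispersions, conductances, or rates are rejected at
construction.  Non-finite states abort integration with the step and
component identified and the partial path attached.  Venous volume and
inflow are floored at 1e-9 inside the balloon model.  NMI is clipped to
[0, 1] against floating-point spill.  Isolated nodes score 0 clustering
and efficiency; unreachable neighbor pairs contribute zero efficiency.
All-zero paired differences give p = 1 at every node.  Region manifests
require at least 4 regions with distinct LMC/SNc roles.
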