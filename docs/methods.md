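# Methods

## The model

`burstnet` simulates a mesoscopic cortical motif: a population of
N_E = 100 excitatory pyramidal cells that drives a population of
N_I = 50 inhibitory fast-spiking interneurons. Each neuron follows the
two-variable Izhikevich quadratic integrate-and-reset model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_ext + I_syn
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

with (a, b, c, d) = (0.02, 0.2, -65, 8) for pyramidal (regular-spiking)
cells and (0.1, 0.2, -65, 2) for fast-spiking interneurons. Integration
is forward Euler at dt = 0.1 ms for 10 s by default.

Connectivity is probabilistic and directed: each ordered E→I pair is a
synapse with probability p_EI (default 0.7), each I→I pair with
probability p_II (default 0.4, no self-connections). E→E and I→E are
absent by default but config-expressible. Synapses are instantaneous
pulses: a presynaptic spike at step k increments each target's membrane
potential by the signed weight (w = +0.3 excitatory, -0.3 inhibitory) at
step k+1. The increment is applied after the step's Euler derivative
update, which makes the voltage-kick form numerically identical (to
float rounding) to injecting a one-step current of w/dt — the unit-area
reading of an instantaneous pulse. Both `coupling_mode`s are provided and
equivalence-tested.

Pyramidal cells receive a common constant drive I_ext and no feedback,
so the population fires as a frozen set of phase-locked oscillators; the
interneurons receive no external drive and are driven exclusively by the
pyramidal volleys. All results are indexed by the realized pyramidal
population frequency f (inverse of the pooled mean interspike interval,
first 500 ms discarded), never by the current, and the drive grid is
chosen adaptively by inverting the isolated-neuron f–I curve.

### Initial conditions

The literature convention leaves initial states unspecified; we draw
v0 = c + U(0, jitter) per neuron (default jitter 2 mV, configurable down
to 0) and u0 = b·v0, from a recorded seed. The jitter breaks the exact
permutation symmetry of the network while keeping the pyramidal
population tightly synchronized (volley width ≈ 0.4 × jitter in ms at
the default drive range); wider jitter disperses the volleys, weakens
the effective per-cycle drive, and eventually silences the interneurons
— this dependence was mapped explicitly and 2 mV retained.

## Burst-phase extraction

Interneuron membrane traces are recorded with spike peaks preserved:
each stored sample is the maximum of min(v, 30 mV) over its decimation
window, so spike deflections survive decimation and no sample exceeds
the 30 mV threshold. The phase pipeline is

1. 5th-order low-pass Butterworth, zero-phase (forward–backward) by
   default so filtering cannot shift phase relations *between* neurons;
2. per-channel standardization to zero mean, unit population SD;
3. instantaneous phase as the angle of the analytic (Hilbert) signal,
   wrapped to (−π, π].

The first 500 ms (burn-in) and 100 ms at each end (Hilbert edge
artifacts) are excluded from all downstream metrics.

**Cutoff rule.** Interneurons lock at subharmonics of the drive: a
neuron participating in an n-cluster state fires on every n-th volley,
so its distinguishing fundamental sits at f/n, while *all* neurons share
a driven spectral line at exactly f. A cutoff above f keeps that common
line and the Hilbert phases collapse onto it (G1 ≈ 1 at every operating
point, clusters invisible). The default cutoff is therefore 0.75 × f —
above the subharmonic fundamentals, below the drive — clipped to
[5 Hz, 0.45 × sampling rate]. A fixed cutoff can be passed explicitly
for sensitivity analyses.

## Cluster metrics

Phase differences φ_j are collected from 10 random sets of 100 distinct
interneuron pairs at every retained time sample (a decimation factor,
default every 10th sample of the 5 kHz recording, is a speed knob that
leaves the distributions unchanged). For each set,

    Z_n = (1/N) Σ_j exp(i n φ_j),
    G_n = |Z_n| · Π_{k<n} (1 − |Z_k|),   n = 1..7,

with mean ± SD across the 10 sets. G_n is close to 1 only for a
near-ideal n-cluster arrangement; the dominant cluster count is
argmax_n mean G_n (ties to the smaller n — prefer the simpler
partition). A "no clustering" flag is raised when the best G_n falls
below a stability floor of 0.2; the uniform-phase null at these sample
sizes stays far below this (all G_n ≤ 0.1 at N = 10^4), so the floor is
conservative. The flag never alters the reported n*.

Gn-vs-f curves are smoothed with a 3-point moving average before peak
finding; a "well-defined" peak is an interior local maximum above the
floor.

## Perturbation protocol and collective response

A network is simulated twice from identical seeds; in the perturbed run,
k randomly chosen interneurons (k in 1..20) each receive one exogenous
spike of weight 0.1–1.0 at a random time t_p > 0.5 s. At each evaluation
time (every 10 ms), the instantaneous phases of each run are partitioned
into n clusters by a one-dimensional Gaussian mixture (n frozen to the
baseline's dominant cluster count; 100 EM iterations; best of 5
random-from-data initializations; the phases are first rotated so the
widest empty arc maps to the wrap boundary, and the paired fits share
the baseline's rotation and seed so identical snapshots yield identical
labels). Partitions are compared with the adjusted Rand index; the
closed-form hypergeometric expectation is the default, with a
Monte-Carlo permutation estimate of E[RI] as an option (both equal 1
for identical partitions and average 0 for independent ones). Baselines
whose best G_n is below the stability floor are rejected and counted.

The collective response over M trials (fresh topology, targets and t_p
per trial) is CR = 1 − mean_i ARI_i, with ARI_i the time-average of
trial i's ARI over [t_p, t_p + 2 s]. Whether ARI_i is a time average or
a point value is a genuinely open choice; the time average is the
default and the single-time variant is reachable through
`TrialResult.time_average`.

Because the zero-phase filter and the Hilbert transform are acausal, a
perturbation leaks a small distance backwards through the *measurement*
(the raw simulations are bit-identical before t_p, which is asserted):
phases just before t_p can shift by up to ~0.1 rad, occasionally
flipping one boundary neuron's GMM label. Pre-perturbation ARI is
therefore exactly 1 at the large majority of evaluation times rather
than at all of them. CR windows start at t_p, so CR is unaffected.

## Problem sizes

The default experiment scale is chosen for desk-scale runs with a
documented path to larger fidelity, all through the same code paths:

- representative frequency sweep: realized f covering 10–200 Hz in
  ≈5 Hz steps, 10 s runs, 3 topology seeds;
- connectivity grid: 5 × 5 values of (p_EI, p_II) in [0.2, 1.0], 10 Hz
  frequency steps, 5 s runs, one seed per cell (the 50 × 50 grid is a
  pure config change);
- collective response: M = 10 trials per condition, 3.5 s runs (long
  enough for the 0.5 s burn-in, a random t_p and the full 2 s averaging
  window), perturbed counts {1, 2, 5, 10, 20} at weight 0.3.

## What the model reproduces, and what it does not

The package reproduces, under its default conditions: induced rhythmic
interneuron firing locked to the pyramidal volleys; an in-phase (G1)
regime at low drive; a two-cluster anti-phase band (G2 well above the
floor, phase-difference histograms bimodal at 0/180°) with itinerant
neuron hopping at higher drive; washout to near-uniform phase
differences at the highest frequencies; connectivity-grid argmax
frequencies confined to the mid-band, sensitive to p_EI and relatively
insensitive to p_II; and collective responses that vanish for k = 1,
grow with k, saturate near k ≈ 5, and are strongest in the
lower-frequency cluster states.

Two quantitative features of the reference phenomenology do not emerge
under the instantaneous pulse coupling implemented here. With an E→I
in-degree of ~70 at w = 0.3, a synchronized pyramidal volley delivers
≈ 21 mV — well above the ≈ 15 mV separatrix gap of a resting
fast-spiking cell — so interneurons either follow the drive 1:1 or, at
short drive periods where the recovery variable is still elevated, 1:2.
The two-cluster band therefore sits near ~100 Hz rather than in the
low-gamma range, and a three-cluster (1:3) state is dynamically
unreachable at the representative connectivity: membrane memory decays
within ~2 ms, so multi-cycle suppression would require sub-threshold
volleys, and sub-threshold volleys of any size leave the population
silent (verified by scaling w down). Three-cluster states do appear in
this model at full E→I connectivity (p_EI = 1.0 cells of the grid show
G3 above the floor near 70 Hz). These boundaries are properties of the
pulse-coupling reading, not of the measurement stack; a synaptic current
with a nonzero time course (deliberately out of scope) would lower the
locking thresholds and shift the bands down.

## Synthetic fixtures

The fixture generators plant known structure — cluster memberships with
wrapped-Gaussian scatter and common drift, square burst envelopes with
smooth intra-burst spike waveforms (sampling-rate invariant by
construction), independent random partitions, and a single
cluster-hopping neuron — so every metric is validated against planted
truth without a simulator run. The fixtures emulate the *geometry* of
the network's phase data, not its dynamics: passing fixture tests shows
the metrics are correct, not that the network produces any particular
state; that link is made by the simulator-based experiments above.

## Numerical choices

- Spike detection at v ≥ 30 mV after the Euler update; reset before any
  recording, delivery at the next step (one-step delay removes
  update-order ambiguity; negligible at dt = 0.1 ms).
- Eq-6 products use magnitudes |Z_k|; G_n is real by construction.
- Standardization uses the population (1/N) SD.
- Wrapping convention (−π, π]; degrees only in histograms.
- GMM `reg_covar` = 1e-6 guards near-degenerate clusters.
- Binomial wiring is realized per synapse group from `seed_topology`;
  identical seeds give bit-identical networks, rasters and traces
  (asserted in tests).

## Known limitations

- Conductance-based synapses, synaptic/conduction delays, plasticity and
  heterogeneous within-population parameters are out of scope.
- Forward Euler is the only integrator (accuracy studies out of scope);
  chaotic trajectories make cross-`coupling_mode` agreement exact only
  over short horizons, though the per-step updates agree to rounding.
- The frequency positions of the cluster-state bands depend on the
  pulse-coupling reading as discussed above.
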