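# burstnet

Metastable phase clustering in pulse-coupled excitatory–inhibitory
spiking networks.

Cortical interneurons burst and transiently synchronize in shifting
phase relationships — neurons lock, unlock and hop between phase-locked
groups (metastability / itinerancy). `burstnet` is a compact laboratory
for this phenomenon: a mesoscopic network of 100 excitatory Izhikevich
pyramidal cells driving 50 inhibitory fast-spiking interneurons through
instantaneous pulse coupling, plus the full measurement stack needed to
quantify the interneurons' burst-phase cluster states and how they
respond to perturbations. It is written for computational
neuroscientists studying network-level synchronization mechanisms.

## The model and the metrics

Each neuron follows the Izhikevich model

    dv/dt = 0.04 v² + 5 v + 140 − u + I_ext + I_syn
    du/dt = a (b v − u),    if v ≥ 30 mV: v ← c, u ← u + d

(regular-spiking parameters for pyramidal cells, fast-spiking for
interneurons), integrated with forward Euler at dt = 0.1 ms. E→I and
I→I synapses exist independently per pair with probabilities p_EI, p_II
and act as instantaneous pulses of weight ±0.3. Only the pyramidal cells
receive external drive; its strength sets the pyramidal population
frequency f, which indexes all results.

Interneuron voltages are low-pass filtered (5th-order Butterworth,
zero-phase), standardized, and converted to instantaneous burst phases
with the Hilbert transform. Pairwise phase differences φ_j feed the
Kuramoto–Daido order parameters and the cluster-stability metric

    Z_n = (1/N) Σ_j e^{i n φ_j},      G_n = |Z_n| · Π_{k<n} (1 − |Z_k|),

where G_n ≈ 1 only for a near-ideal arrangement of n equally spaced
phase clusters, so argmax_n G_n estimates the cluster count.

Perturbation response: a network is simulated twice from identical
seeds; in the second run k interneurons each receive one exogenous spike
at t_p. Phases are partitioned by a 1-D Gaussian mixture and compared
over time with the adjusted Rand index (ARI); the collective response
over M trials is

    CR = 1 − (1/M) Σ_i ARI_i,

0 when perturbations never rearrange the clusters, 1 when they scramble
them completely.

## Worked example

```python
import numpy as np
from burstnet import default_network_config, simulate, population_frequency
from burstnet.phase import extract_phases
from burstnet.order import (pairwise_phase_differences,
                            order_parameter_profile, dominant_cluster_count)
from burstnet.experiments import drive_for_frequencies

i_ext = float(drive_for_frequencies(np.array([104.0]))[0])   # ~104 Hz drive
cfg = default_network_config(i_ext=i_ext, duration=10_000.0,
                             seed_topology=1, seed_init=2, record_decimation=2)
raster, traces = simulate(cfg)
f = population_frequency(raster, "pyramidal")
phases = extract_phases(traces, driving_frequency_hz=f)
samples = pairwise_phase_differences(phases, n_pairs=100, n_sets=10,
                                     rng=5, time_decimation=10)
profile = order_parameter_profile(samples)
n_star, g_star, clustered = dominant_cluster_count(profile)
print(f"f = {f:.1f} Hz  G1..G4 = {np.round(profile.g_mean[:4], 2)}  "
      f"n* = {n_star} (G = {g_star:.2f}, clustered = {clustered})")
```

prints

```
f = 103.9 Hz  G1..G4 = [0.06 0.38 0.03 0.07]  n* = 2 (G = 0.38, clustered = True)
```

i.e. at a ~104 Hz pyramidal rhythm the interneurons split into **two
anti-phase burst clusters** (G2 dominant and above the 0.2 stability
floor; the pairwise phase-difference histogram is bimodal at 0° and
180°). At low drive the population locks in-phase instead (G1 ≈ 1), and
above ~125 Hz clustering washes out — the frequency-indexed sequence of
states explored by `burstnet.experiments.sweep_frequency`.

## Command line

```bash
burstnet simulate --seed 7 --i-ext 47 --out runs/demo     # raster + traces CSV
burstnet sweep-frequency --out runs/sweep                 # Gn-vs-f curves + landmarks
burstnet sweep-connectivity --out runs/grid               # max G2/G3 over (p_EI, p_II)
burstnet cr-curves --trials 10 --out runs/cr              # CR vs k and weight
burstnet --print-config                                   # all defaults as JSON
```

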