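"""Synthetic data with planted structure for metric validation.

Every generator is deterministic given its seed, and the planted truth
(cluster centers, memberships, envelope frequency, switching times) is
returned alongside the data so tests can score recovery exactly.
"""

from __future__ import annotations

import numpy as np

from .network import VoltageTraces
from .phase import FilterSpec, PhaseSeries, wrap_phase

__all__ = [
    "planted_cluster_phases",
    "burst_envelope_traces",
    "random_partitions",
    "itinerant_switching_phases",
    "make_fixture",
]


def _phase_series(time_ms: np.ndarray, phases: np.ndarray, fs_hz: float) -> PhaseSeries:
    spec = FilterSpec(cutoff_hz=0.4 * fs_hz, sampling_rate_hz=fs_hz)
    return PhaseSeries(
        time_ms=time_ms,
        phases=phases,
        neuron_ids=np.arange(phases.shape[1]),
        filter_spec=spec,
        valid=np.ones(time_ms.size, dtype=bool),
    )


def planted_cluster_phases(
    n_clusters: int = 2,
    n_neurons: int = 50,
    sd: float = 0.1,
    duration_ms: float = 2000.0,
    dt_ms: float = 1.0,
    drift_hz: float = 25.0,
    seed: int = 0,
) -> tuple[PhaseSeries, np.ndarray]:
    """Phases forming ``n_clusters`` equally spaced, equally populated
    clusters with von-Mises-like (wrapped Gaussian) scatter ``sd`` and a
    common drift. Returns (series, planted membership)."""
    rng = np.random.default_rng(seed)
    t = np.arange(dt_ms, duration_ms + dt_ms / 2, dt_ms)
    membership = np.arange(n_neurons) % n_clusters
    rng.shuffle(membership)
    centers = 2 * np.pi * membership / n_clusters
    drift = 2 * np.pi * drift_hz / 1000.0 * t
    noise = rng.normal(0.0, sd, size=(t.size, n_neurons))
    phases = wrap_phase(drift[:, None] + centers[None, :] + noise)
    return _phase_series(t, phases, 1000.0 / dt_ms), membership


def burst_envelope_traces(
    n_channels: int = 2,
    envelope_hz: float = 50.0,
    spike_hz: float = 400.0,
    duration_ms: float = 2000.0,
    dt_ms: float = 0.1,
    offsets: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[VoltageTraces, float]:
    """Voltage-like traces with square burst envelopes: fast spikes at
    ``spike_hz`` ride the active half of each envelope cycle.

    ``offsets`` are per-channel envelope phase offsets in radians
    (default 0). Returns (traces, planted envelope frequency).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(dt_ms, duration_ms + dt_ms / 2, dt_ms)
    if offsets is None:
        offsets = np.zeros(n_channels)
    offsets = np.asarray(offsets, dtype=float)
    env_phase = 2 * np.pi * envelope_hz / 1000.0 * t[:, None] + offsets[None, :]
    active = np.cos(env_phase) > 0.0
    # smooth intra-burst spike waveform so the fixture is sampling-rate
    # invariant (a hard indicator aliases between dt values)
    s = np.sin(2 * np.pi * spike_hz / 1000.0 * t)
    spike_wave = np.clip((s - 0.8) / 0.2, 0.0, 1.0)[:, None]
    v = np.full((t.size, n_channels), -65.0)
    v += 10.0 * active  # depolarized plateau during the burst
    v += 95.0 * spike_wave * active
    v += rng.normal(0.0, 0.3, size=v.shape)
    traces = VoltageTraces(
        time_ms=t, v=v, neuron_ids=np.arange(n_channels), dt_ms=dt_ms
    )
    return traces, envelope_hz


def random_partitions(
    n_items: int = 50, n_clusters: int = 3, n_partitions: int = 2, seed: int = 0
) -> list[np.ndarray]:
    """Independent uniformly random label vectors (for ARI null checks)."""
    rng = np.random.default_rng(seed)
    return [rng.integers(0, n_clusters, size=n_items) for _ in range(n_partitions)]


def itinerant_switching_phases(
    n_neurons: int = 50,
    switch_time_ms: float = 1000.0,
    hopping_neuron: int = 0,
    sd: float = 0.05,
    duration_ms: float = 2000.0,
    dt_ms: float = 1.0,
    seed: int = 0,
) -> tuple[PhaseSeries, np.ndarray, np.ndarray]:
    """Two-cluster phases in which one neuron hops to the other cluster at
    ``switch_time_ms``. Returns (series, membership_before, membership_after)."""
    series, before = planted_cluster_phases(
        n_clusters=2, n_neurons=n_neurons, sd=sd,
        duration_ms=duration_ms, dt_ms=dt_ms, seed=seed,
    )
    after = before.copy()
    after[hopping_neuron] = 1 - after[hopping_neuron]
    late = series.time_ms >= switch_time_ms
    series.phases[np.ix_(late, [hopping_neuron])] = wrap_phase(
        series.phases[np.ix_(late, [hopping_neuron])] + np.pi
    )
    return series, before, after


_KINDS = {
    "planted_cluster_phases": planted_cluster_phases,
    "burst_envelope_traces": burst_envelope_traces,
    "random_partitions": random_partitions,
    "itinerant_switching_phases": itinerant_switching_phases,
}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch to a fixture generator by name; unknown kinds raise."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](**{**(params or {}), "seed": seed})
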