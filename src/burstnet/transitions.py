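"""Perturbation-induced cluster transitions and the collective response.

A network is simulated twice with identical wiring and initial state; in
the second run a small set of interneurons each receives one exogenous
spike at time t_p. At each evaluation time the instantaneous burst phases
of both runs are partitioned into n clusters with a 1-D Gaussian mixture
(n fixed from the baseline's dominant cluster count), and the two
partitions are compared with the adjusted Rand index. The collective
response over M trials is

    CR = 1 - (1/M) sum_i ARI_i,

where ARI_i is trial i's ARI time-averaged over a post-perturbation
window: CR = 0 when perturbations never rearrange the clusters, and
CR = 1 when they scramble them completely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb
from sklearn.mixture import GaussianMixture

from .config import NetworkConfig
from .network import Adjacency, build_network, population_frequency, simulate
from .order import (
    STABILITY_FLOOR,
    dominant_cluster_count,
    order_parameter_profile,
    pairwise_phase_differences,
)
from .phase import extract_phases, wrap_phase

__all__ = [
    "PerturbationSpec",
    "ClusterAssignment",
    "TrialResult",
    "CRSummary",
    "gmm_assign",
    "rand_index",
    "adjusted_rand_index",
    "paired_perturbation_trial",
    "collective_response",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One exogenous single-spike volley: ``k`` interneurons, chosen by
    ``seed_targets``, each get a voltage increment ``weight`` at ``t_p_ms``."""

    k: int
    weight: float
    t_p_ms: float
    seed_targets: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weight < 0:
            raise ValueError("perturbation weight must be >= 0")
        if self.t_p_ms <= 500.0:
            raise ValueError("perturbation time must exceed the 500 ms burn-in")


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # one label in 0..n-1 per interneuron
    n: int
    converged: bool
    n_iter: int


@dataclass
class TrialResult:
    t_ms: np.ndarray  # evaluation grid
    ari: np.ndarray
    spec: PerturbationSpec
    n_clusters: int
    baseline_g: float
    accepted: bool
    status: str  # "ok" | "no_clustering"
    seeds: dict = field(default_factory=dict)

    def time_average(self, t_start: float, t_stop: float) -> float:
        m = (self.t_ms >= t_start) & (self.t_ms <= t_stop)
        if not m.any():
            raise ValueError("empty averaging window")
        return float(self.ari[m].mean())


@dataclass
class CRSummary:
    cr: float
    m: int
    per_trial_ari: np.ndarray
    window_ms: float
    operating_point: dict = field(default_factory=dict)
    n_rejected: int = 0


# --------------------------------------------------------------------------
# partition comparison (pair counting)
# --------------------------------------------------------------------------


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table

def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of item pairs on which two partitions agree.

    Agreement: the pair is co-clustered in both, or separated in both.
    """
    t = _contingency(a, b)
    n = int(t.sum())
    if n < 2:
        raise ValueError("need at least two items")
    pairs = comb(n, 2)
    same_both = comb(t, 2).sum()  # g
    same_a = comb(t.sum(axis=1), 2).sum()
    same_b = comb(t.sum(axis=0), 2).sum()
    diff_both = pairs - same_a - same_b + same_both  # h
    return float((same_both + diff_both) / pairs)


def adjusted_rand_index(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "closed_form",
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Chance-corrected Rand index: (RI - E[RI]) / (max RI - E[RI]).

    ``closed_form`` uses the hypergeometric (permutation-model)
    expectation; ``permutation`` estimates E[RI] by Monte-Carlo label
    permutation. Both are 1 for identical partitions and ~0 in
    expectation for independent ones. The degenerate all-one-cluster /
    all-singleton comparison (zero denominator) is defined as 1.
    """
    t = _contingency(a, b)
    n = int(t.sum())
    if method == "closed_form":
        sum_nij = comb(t, 2).sum()
        sum_a = comb(t.sum(axis=1), 2).sum()
        sum_b = comb(t.sum(axis=0), 2).sum()
        pairs = comb(n, 2)
        expected = sum_a * sum_b / pairs
        max_index = 0.5 * (sum_a + sum_b)
        if max_index == expected:
            return 1.0
        return float((sum_nij - expected) / (max_index - expected))
    if method == "permutation":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        ri = rand_index(a, b)
        b = np.asarray(b)
        eri = float(
            np.mean([rand_index(a, rng.permutation(b)) for _ in range(n_permutations)])
        )
        if eri >= 1.0:
            return 1.0
        return float((ri - eri) / (1.0 - eri))
    raise ValueError(f"unknown ARI method {method!r}")


# --------------------------------------------------------------------------
# GMM phase clustering
# --------------------------------------------------------------------------


def largest_gap_center(phi: np.ndarray) -> float:
    """Midpoint angle of the widest empty arc in a set of phases.

    A 1-D Gaussian mixture is wrap-blind; placing the domain boundary
    inside the widest empty arc guarantees no cluster straddles it.
    """
    order = np.sort(np.asarray(phi, dtype=float).ravel())
    gaps = np.diff(order)
    wrap_gap = order[0] + 2 * np.pi - order[-1]
    if gaps.size and gaps.max() > wrap_gap:
        i = int(np.argmax(gaps))
        return float(order[i] + gaps[i] / 2.0)
    return float(order[-1] + wrap_gap / 2.0)


def gmm_assign(
    phases: np.ndarray, n: int, seed: int = 0, gap_center: float | None = None
) -> ClusterAssignment:
    """Hard n-cluster assignment of instantaneous phases via a 1-D GMM.

    Phases are re-centered so the largest angular gap falls on the wrap
    boundary, then fit with an n-component Gaussian mixture (100 EM
    iterations max, best of 5 random-from-data initializations).
    ``gap_center`` overrides the data-derived rotation — paired
    comparisons pass the baseline's so both fits share one frame.
    """
    phi = np.asarray(phases, dtype=float).ravel()
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.unique(phi).size < n:
        raise ValueError(f"need at least {n} distinct phases for {n} components")
    if n == 1:
        return ClusterAssignment(np.zeros(phi.size, dtype=int), 1, True, 0)
    if gap_center is None:
        gap_center = largest_gap_center(phi)
    x = wrap_phase(phi - gap_center - np.pi).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n,
        max_iter=100,
        n_init=5,
        init_params="random_from_data",
        random_state=int(seed) & 0x7FFFFFFF,
        reg_covar=1e-6,
    ).fit(x)
    return ClusterAssignment(
        labels=gm.predict(x).astype(int),
        n=n,
        converged=bool(gm.converged_),
        n_iter=int(gm.n_iter_),
    )


# --------------------------------------------------------------------------
# paired-simulation protocol
# --------------------------------------------------------------------------


def paired_perturbation_trial(
    config: NetworkConfig,
    spec: PerturbationSpec,
    eval_pre_ms: float = 500.0,
    eval_post_ms: float = 2000.0,
    eval_step_ms: float = 10.0,
    n_max: int = 7,
    stability_floor: float = STABILITY_FLOOR,
    adjacency: Adjacency | None = None,
    sample_seed: int = 0,
) -> TrialResult:
    """One baseline/perturbed simulation pair and its ARI-versus-time curve.

    Both runs share every seed; only the perturbed run receives the
    single-spike volley. The cluster count n is frozen to the baseline's
    dominant cluster count; each evaluation time uses one GMM seed shared
    by the two fits so identical phase snapshots yield identical labels.
    Baselines without detectable clustering (G_{n*} below the floor) are
    rejected with status ``no_clustering``.
    """
    if adjacency is None:
        adjacency = build_network(config)
    if spec.t_p_ms >= config.duration:
        raise ValueError("perturbation time outside the simulation")

    raster_b, traces_b = simulate(config, adjacency=adjacency)
    fs = adjacency.global_indices("fast_spiking")
    rng_t = np.random.default_rng(spec.seed_targets)
    targets = rng_t.choice(fs, size=spec.k, replace=False)
    raster_p, traces_p = simulate(
        config, adjacency=adjacency, perturbation=(spec.t_p_ms, targets, spec.weight)
    )

    f_drive = population_frequency(raster_b, "pyramidal")
    ph_b = extract_phases(traces_b, driving_frequency_hz=f_drive)
    ph_p = extract_phases(traces_p, driving_frequency_hz=f_drive)

    profile = order_parameter_profile(
        pairwise_phase_differences(ph_b, rng=sample_seed, time_decimation=10),
        n_max=n_max,
    )
    n_star, g_star, clustered = dominant_cluster_count(profile, floor=stability_floor)

    t_lo = max(spec.t_p_ms - eval_pre_ms, float(ph_b.time_ms[ph_b.valid][0]))
    t_hi = min(spec.t_p_ms + eval_post_ms, float(ph_b.time_ms[ph_b.valid][-1]))
    grid = np.arange(t_lo, t_hi + 1e-9, eval_step_ms)
    seeds = {
        "seed_topology": config.seed_topology,
        "seed_init": config.seed_init,
        "seed_targets": spec.seed_targets,
        "sample_seed": sample_seed,
        "targets": np.asarray(targets, dtype=int).tolist(),
    }
    if not clustered:
        return TrialResult(
            t_ms=grid,
            ari=np.full(grid.size, np.nan),
            spec=spec,
            n_clusters=n_star,
            baseline_g=g_star,
            accepted=False,
            status="no_clustering",
            seeds=seeds,
        )

    idx = np.searchsorted(ph_b.time_ms, grid)
    idx = np.clip(idx, 0, ph_b.time_ms.size - 1)
    ari = np.empty(grid.size)
    ss = np.random.SeedSequence([sample_seed, config.seed_topology, spec.seed_targets])
    gmm_seeds = ss.generate_state(grid.size) & 0x7FFFFFFF
    for i, (ti, s) in enumerate(zip(idx, gmm_seeds)):
        center = largest_gap_center(ph_b.phases[ti])
        lab_b = gmm_assign(ph_b.phases[ti], n_star, seed=int(s), gap_center=center).labels
        lab_p = gmm_assign(ph_p.phases[ti], n_star, seed=int(s), gap_center=center).labels
        ari[i] = adjusted_rand_index(lab_b, lab_p)
    return TrialResult(
        t_ms=grid,
        ari=ari,
        spec=spec,
        n_clusters=n_star,
        baseline_g=g_star,
        accepted=True,
        status="ok",
        seeds=seeds,
    )


def collective_response(
    trials: list[TrialResult], window_ms: float = 2000.0, operating_point: dict | None = None
) -> CRSummary:
    """CR = 1 - mean over accepted trials of the windowed time-average ARI."""
    accepted = [t for t in trials if t.accepted]
    if not accepted:
        raise ValueError("no accepted trials")
    ari_i = np.array(
        [t.time_average(t.spec.t_p_ms, t.spec.t_p_ms + window_ms) for t in accepted]
    )
    return CRSummary(
        cr=float(1.0 - ari_i.mean()),
        m=len(accepted),
        per_trial_ari=ari_i,
        window_ms=window_ms,
        operating_point=operating_point or {},
        n_rejected=len(trials) - len(accepted),
    )
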