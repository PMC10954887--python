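"""Experiment drivers: frequency sweeps, connectivity grids, CR curves.

All results are tidy pandas DataFrames so they serialize to CSV directly;
every row is traceable to a config hash and seeds. The drive currents are
chosen adaptively from the isolated pyramidal f-I curve so that realized
population frequencies tile the requested range — all results are indexed
by realized frequency, not by current.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PYRAMIDAL_PARAMS, NetworkConfig, default_network_config
from .network import (
    UndefinedFrequencyError,
    build_network,
    fi_curve,
    population_frequency,
    simulate,
)
from .order import (
    STABILITY_FLOOR,
    order_parameter_profile,
    pairwise_phase_differences,
)
from .phase import extract_phases
from .transitions import (
    PerturbationSpec,
    collective_response,
    paired_perturbation_trial,
)

__all__ = [
    "SweepConfig",
    "SilentInterneuronsError",
    "drive_for_frequencies",
    "run_operating_point",
    "sweep_frequency",
    "gn_curves",
    "find_curve_peaks",
    "frequency_landmarks",
    "sweep_connectivity",
    "cr_curves",
]

logger = logging.getLogger("burstnet")


class SilentInterneuronsError(RuntimeError):
    """Raised when a sweep produces no interneuron activity at all."""


@dataclass
class SweepConfig:
    """Parameters of a frequency / connectivity sweep at configurable scale.

    The reduced defaults (5x5 grid, 5 s runs for grid cells, three
    topology seeds for the representative sweep) are pure subsets of the
    full-scale protocol (50x50, 10 s, more seeds), reachable by changing
    these fields.
    """

    f_min_hz: float = 10.0
    f_max_hz: float = 200.0
    f_step_hz: float = 5.0
    p_ei: float = 0.7
    p_ii: float = 0.4
    seeds: tuple[int, ...] = (0, 1, 2)
    duration_ms: float = 10_000.0
    grid_p_values: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    grid_duration_ms: float = 5_000.0
    grid_f_step_hz: float = 10.0
    record_decimation: int = 2
    time_decimation: int = 10
    n_pairs: int = 100
    n_sets: int = 10
    n_max: int = 7
    floor: float = STABILITY_FLOOR
    network_kwargs: dict = field(default_factory=dict)


def drive_for_frequencies(
    f_targets: np.ndarray, i_max: float = 150.0, n_grid: int = 300
) -> np.ndarray:
    """Pick i_ext values whose isolated pyramidal frequency is closest to
    each target; the pyramidal population receives no feedback, so the
    realized population frequency equals the isolated one."""
    i_grid = np.linspace(0.5, i_max, n_grid)
    f_grid = fi_curve(PYRAMIDAL_PARAMS, i_grid)
    return np.array([i_grid[np.argmin(np.abs(f_grid - f))] for f in np.atleast_1d(f_targets)])


def run_operating_point(
    i_ext: float,
    seed_topology: int = 0,
    seed_init: int = 0,
    duration_ms: float = 10_000.0,
    p_ei: float = 0.7,
    p_ii: float = 0.4,
    record_decimation: int = 2,
    time_decimation: int = 10,
    n_pairs: int = 100,
    n_sets: int = 10,
    n_max: int = 7,
    sample_seed: int | None = None,
    **network_kwargs,
) -> tuple[float, "pd.DataFrame"]:
    """Simulate one operating point and measure its order-parameter profile.

    Returns (realized pyramidal frequency, tidy per-n table). Operating
    points whose interneurons never fire are reported with NaN metrics.
    """
    cfg = default_network_config(
        i_ext=float(i_ext),
        p_ei=p_ei,
        p_ii=p_ii,
        duration=duration_ms,
        seed_topology=seed_topology,
        seed_init=seed_init,
        record_decimation=record_decimation,
        **network_kwargs,
    )
    raster, traces = simulate(cfg)
    f = population_frequency(raster, "pyramidal")
    n_fs_spikes = len(raster.for_population("fast_spiking"))
    rows = []
    if n_fs_spikes == 0:
        for n in range(1, n_max + 1):
            rows.append(dict(n=n, g_mean=np.nan, g_sd=np.nan, z_mean=np.nan, z_sd=np.nan))
    else:
        phases = extract_phases(traces, driving_frequency_hz=f)
        samples = pairwise_phase_differences(
            phases,
            n_pairs=n_pairs,
            n_sets=n_sets,
            rng=seed_topology if sample_seed is None else sample_seed,
            time_decimation=time_decimation,
        )
        prof = order_parameter_profile(samples, n_max=n_max)
        for j, n in enumerate(prof.n_values):
            rows.append(
                dict(
                    n=int(n),
                    g_mean=prof.g_mean[j],
                    g_sd=prof.g_sd[j],
                    z_mean=prof.z_mean[j],
                    z_sd=prof.z_sd[j],
                )
            )
    df = pd.DataFrame(rows)
    df.insert(0, "f_hz", f)
    df.insert(1, "i_ext", i_ext)
    df.insert(2, "seed_topology", seed_topology)
    df["fs_active"] = n_fs_spikes > 0
    df["p_ei"] = p_ei
    df["p_ii"] = p_ii
    return f, df


def sweep_frequency(sweep: SweepConfig | None = None) -> pd.DataFrame:
    """Gn-vs-frequency curves for the representative network.

    One row per (seed, i_ext, n). Aborts with a diagnostic if the whole
    sweep leaves the interneurons silent (e.g. zero coupling weights).
    """
    sweep = sweep or SweepConfig()
    f_targets = np.arange(sweep.f_min_hz, sweep.f_max_hz + sweep.f_step_hz / 2, sweep.f_step_hz)
    i_values = drive_for_frequencies(f_targets)
    frames = []
    for seed in sweep.seeds:
        for i_ext in i_values:
            _, df = run_operating_point(
                i_ext,
                seed_topology=seed,
                seed_init=seed + 1000,
                duration_ms=sweep.duration_ms,
                p_ei=sweep.p_ei,
                p_ii=sweep.p_ii,
                record_decimation=sweep.record_decimation,
                time_decimation=sweep.time_decimation,
                n_pairs=sweep.n_pairs,
                n_sets=sweep.n_sets,
                n_max=sweep.n_max,
                **sweep.network_kwargs,
            )
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if not out["fs_active"].any():
        raise SilentInterneuronsError(
            "no interneuron spikes anywhere in the sweep; check coupling weights/probabilities"
        )
    return out


def gn_curves(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Average the tidy sweep across seeds: one row per (i_ext, n), with
    the realized frequency averaged as well (it is seed-independent up to
    measurement)."""
    g = (
        sweep_df.groupby(["i_ext", "n"], as_index=False)
        .agg(f_hz=("f_hz", "mean"), g_mean=("g_mean", "mean"), g_sd=("g_mean", "std"))
        .sort_values(["n", "f_hz"])
    )
    return g.reset_index(drop=True)


def find_curve_peaks(
    f: np.ndarray, g: np.ndarray, floor: float = STABILITY_FLOOR
) -> list[tuple[float, float]]:
    """Well-defined local maxima of a Gn-vs-f curve.

    The curve is smoothed with a 3-point moving average; a peak is an
    interior sample strictly greater than both neighbours (plateaus take
    the first sample) whose smoothed height exceeds the stability floor.
    Returns [(f_peak, g_peak), ...] in increasing frequency order.
    """
    order = np.argsort(f)
    f, g = np.asarray(f)[order], np.asarray(g)[order]
    if f.size < 3:
        return []
    gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    gs[0], gs[-1] = g[0], g[-1]  # unsmoothed endpoints (half windows)
    peaks = []
    for i in range(1, f.size - 1):
        if gs[i] > floor and gs[i] >= gs[i - 1] and gs[i] > gs[i + 1]:
            peaks.append((float(f[i]), float(gs[i])))
    return peaks


def frequency_landmarks(sweep_df: pd.DataFrame, floor: float = STABILITY_FLOOR) -> dict:
    """Landmark frequencies of the cluster-state sequence.

    - ``first_g2_peak_hz`` / ``second_g2_peak_hz``: first well-defined G2
      local maximum, and the first one above the G3 argmax frequency.
    - ``g3_peak_hz``: argmax of mean G3 (with its height).
    - ``multicluster_onset_hz``: lowest f where max(G2..Gn) exceeds G1.
    - ``washout_hz``: highest f at which any mean Gn exceeds the floor.
    """
    curves = gn_curves(sweep_df)
    by_n = {n: grp.sort_values("f_hz") for n, grp in curves.groupby("n")}
    f2 = by_n[2]["f_hz"].to_numpy()
    g2 = by_n[2]["g_mean"].to_numpy()
    g2_peaks = find_curve_peaks(f2, g2, floor=floor)

    f3 = by_n[3]["f_hz"].to_numpy()
    g3 = by_n[3]["g_mean"].to_numpy()
    i3 = int(np.nanargmax(g3))
    g3_peak_hz, g3_peak = float(f3[i3]), float(g3[i3])

    first_g2 = g2_peaks[0][0] if g2_peaks else np.nan
    # the two-cluster maximum at or above the three-cluster peak frequency;
    # coincides with the first when the curve has a single G2 peak
    above = [p for p in g2_peaks if p[0] >= g3_peak_hz]
    second_g2 = above[0][0] if above else (g2_peaks[-1][0] if g2_peaks else np.nan)

    # onset: lowest f where the best multi-cluster Gn beats G1
    f_axis = by_n[1].sort_values("f_hz")["f_hz"].to_numpy()
    g1 = by_n[1].sort_values("f_hz")["g_mean"].to_numpy()
    gmulti = np.nanmax(
        np.stack([by_n[n].sort_values("f_hz")["g_mean"].to_numpy() for n in by_n if n >= 2]),
        axis=0,
    )
    onset_idx = np.flatnonzero(gmulti > g1)
    onset = float(f_axis[onset_idx[0]]) if onset_idx.size else np.nan

    gany = np.nanmax(
        np.stack([by_n[n].sort_values("f_hz")["g_mean"].to_numpy() for n in by_n]), axis=0
    )
    wash_idx = np.flatnonzero(gany > floor)
    washout = float(f_axis[wash_idx[-1]]) if wash_idx.size else np.nan

    return {
        "first_g2_peak_hz": first_g2,
        "g3_peak_hz": g3_peak_hz,
        "g3_peak_height": g3_peak,
        "second_g2_peak_hz": second_g2,
        "multicluster_onset_hz": onset,
        "washout_hz": washout,
        "g2_peaks": g2_peaks,
    }


def sweep_connectivity(sweep: SweepConfig | None = None) -> pd.DataFrame:
    """Max-over-frequency G2/G3 per (p_EI, p_II) grid cell.

    One row per cell with the maxima, their argmax frequencies, and
    whether the cell showed any interneuron activity / clustering.
    """
    sweep = sweep or SweepConfig()
    f_targets = np.arange(
        max(sweep.f_min_hz, 20.0), sweep.f_max_hz + 1e-9, sweep.grid_f_step_hz
    )
    i_values = drive_for_frequencies(f_targets)
    rows = []
    for p_ei in sweep.grid_p_values:
        for p_ii in sweep.grid_p_values:
            recs = []
            for i_ext in i_values:
                _, df = run_operating_point(
                    i_ext,
                    seed_topology=sweep.seeds[0],
                    seed_init=sweep.seeds[0] + 1000,
                    duration_ms=sweep.grid_duration_ms,
                    p_ei=p_ei,
                    p_ii=p_ii,
                    record_decimation=sweep.record_decimation,
                    time_decimation=sweep.time_decimation,
                    n_pairs=sweep.n_pairs,
                    n_sets=sweep.n_sets,
                    n_max=sweep.n_max,
                    **sweep.network_kwargs,
                )
                recs.append(df)
            cell = pd.concat(recs, ignore_index=True)
            active = bool(cell["fs_active"].any())
            row = dict(p_ei=p_ei, p_ii=p_ii, fs_active=active)
            for n in (2, 3):
                sub = cell[(cell["n"] == n) & cell["fs_active"]]
                if active and not sub.empty and sub["g_mean"].notna().any():
                    j = sub["g_mean"].idxmax()
                    row[f"max_g{n}"] = float(sub.loc[j, "g_mean"])
                    row[f"f_at_max_g{n}"] = float(sub.loc[j, "f_hz"])
                else:
                    row[f"max_g{n}"] = np.nan
                    row[f"f_at_max_g{n}"] = np.nan
            rows.append(row)
            logger.info("grid cell p_ei=%.2f p_ii=%.2f -> %s", p_ei, p_ii, row)
    return pd.DataFrame(rows)


def cr_curves(
    operating_points: dict[str, float],
    k_values: tuple[int, ...] = (1, 2, 5, 10, 20),
    weights: tuple[float, ...] = (0.3,),
    m_trials: int = 10,
    duration_ms: float = 3_500.0,
    window_ms: float = 2_000.0,
    base_seed: int = 0,
    p_ei: float = 0.7,
    p_ii: float = 0.4,
    record_decimation: int = 2,
    **network_kwargs,
) -> pd.DataFrame:
    """Collective response versus perturbed-neuron count and weight.

    ``operating_points`` maps a label (e.g. "48") to the i_ext realizing
    that pyramidal frequency. Each trial uses a fresh topology seed, a
    fresh random target set, and a random perturbation time > 0.5 s.
    Rejected trials (baseline below the stability floor) are counted.
    """
    rows = []
    for label, i_ext in operating_points.items():
        # the pyramidal population gets no feedback, so its realized rate
        # equals the isolated-neuron rate for this drive
        f_real = float(fi_curve(PYRAMIDAL_PARAMS, np.array([i_ext]), duration=1500.0)[0])
        for weight in weights:
            for k in k_values:
                trials = []
                for m in range(m_trials):
                    ss = np.random.SeedSequence(
                        [base_seed, int(1000 * float(weight)), k, m,
                         zlib.crc32(label.encode()) & 0xFFFF]
                    )
                    s_top, s_init, s_tgt, s_tp, s_sample = (
                        int(x) for x in ss.generate_state(5) & 0x7FFFFFFF
                    )
                    rng = np.random.default_rng(s_tp)
                    t_p = float(
                        rng.uniform(600.0, duration_ms - window_ms - 200.0)
                    )
                    cfg = default_network_config(
                        i_ext=float(i_ext),
                        p_ei=p_ei,
                        p_ii=p_ii,
                        duration=duration_ms,
                        seed_topology=s_top,
                        seed_init=s_init,
                        record_decimation=record_decimation,
                        **network_kwargs,
                    )
                    spec = PerturbationSpec(
                        k=k, weight=float(weight), t_p_ms=t_p, seed_targets=s_tgt
                    )
                    trial = paired_perturbation_trial(
                        cfg, spec, eval_pre_ms=0.0, eval_post_ms=window_ms,
                        sample_seed=s_sample,
                    )
                    trials.append(trial)
                accepted = [t for t in trials if t.accepted]
                if accepted:
                    summary = collective_response(
                        accepted, window_ms=window_ms, operating_point={"label": label}
                    )
                    cr, m_acc = summary.cr, summary.m
                else:
                    cr, m_acc = np.nan, 0
                rows.append(
                    dict(
                        operating_point=label,
                        i_ext=i_ext,
                        f_hz=f_real,
                        k=k,
                        weight=weight,
                        cr=cr,
                        m_accepted=m_acc,
                        m_rejected=len(trials) - m_acc,
                    )
                )
                logger.info("CR %s k=%d w=%.2f -> %.3f (%d accepted)", label, k, weight, cr, m_acc)
    return pd.DataFrame(rows)
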