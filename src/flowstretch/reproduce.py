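"""End-to-end recomputation of the headline single-molecule statistics.

Every quantity is recomputed from scratch: traces are simulated at the
per-condition preset parameters, noise is characterized from simulated
baselines, traces are segmented with the two-pass threshold procedure, and
the ensemble statistics are fitted exactly as in the analysis modules.
Stochastic quantities are reported as the median over five sub-seeds derived
from the master seed.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .calibration import GEOMETRIES
from .errors import FlowstretchError
from .kinetics import fit_exponential, fit_rate_gaussian
from .mst import fit_kd
from .segmentation import (
    characterize_noise,
    compute_threshold_rate,
    trace_statistics,
    two_pass_segment,
)
from .simulate import PRESETS, simulate_baseline, simulate_mst, simulate_trace

N_SUB_SEEDS = 5
BASELINE_S = 300.0
N_BASELINES = 8


def _sub_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), *key])
    return int(ss.generate_state(1)[0] % (2**31))


def _noise_profile(preset, seed: int):
    baselines = [
        simulate_baseline(preset.noise_sd_bp, BASELINE_S, _sub_seed(seed, 77, i))
        for i in range(N_BASELINES)
    ]
    return characterize_noise(baselines)


def run_condition(
    preset_name: str,
    seed: int,
    min_events: int = 0,
    min_active_traces: int = 0,
    min_traces: int = 0,
    batch: int = 40,
    max_traces: int = 400,
):
    """Simulate, two-pass segment and pool one condition until the requested
    number of detected events (or traces with events) is reached."""
    from .segmentation import segment_trace

    preset = PRESETS[preset_name]
    geometry = GEOMETRIES[preset.geometry_name]
    profile = _noise_profile(preset, seed)

    def new_trace(i: int):
        return simulate_trace(
            preset,
            np.random.SeedSequence([seed, i]),
            trace_id=f"{preset_name}_{i:04d}",
        ).trace

    # pass 1 on an initial batch sets the category threshold
    traces = [new_trace(i) for i in range(batch)]
    result = two_pass_segment(traces, profile, geometry)
    threshold = result.threshold_bp_s
    stats = [trace_statistics(segs) for segs in result.segments_by_trace]
    n = batch
    while n < max_traces:
        n_events = sum(s.n_events for s in stats)
        n_active = sum(1 for s in stats if s.n_events > 0)
        if n < min_traces:
            pass
        elif min_events and n_events < min_events:
            pass
        elif min_active_traces and n_active < min_active_traces:
            pass
        else:
            break
        for i in range(n, n + batch):
            tr = new_trace(i)
            stats.append(
                trace_statistics(segment_trace(tr, profile, threshold, geometry))
            )
        n += batch
    return stats, threshold, profile


def _pooled_rates(stats, limit: int | None = None) -> list[float]:
    rates = [st.rate_bp_s for s in stats for st in s.single_steps]
    return rates[:limit] if limit else rates


def _multi_values(stats, limit: int | None = None) -> list[float]:
    vals = [s.multi_step_processivity_bp for s in stats if s.n_events > 0]
    return vals[:limit] if limit else vals


def _median_over_seeds(fn: Callable[[int], float], master_seed: int, key: int) -> float:
    vals = []
    for k in range(N_SUB_SEEDS):
        try:
            vals.append(fn(_sub_seed(master_seed, key, k)))
        except FlowstretchError:
            continue
    if not vals:
        raise FlowstretchError("all sub-seed replicates failed")
    return float(np.median(vals))


# -- individual quantities --------------------------------------------------


def _rate_target(preset: str, n_events: int, seed: int) -> float:
    stats, _, _ = run_condition(preset, seed, min_events=n_events)
    rates = _pooled_rates(stats, n_events)
    return fit_rate_gaussian(rates).mean


def _multi_target(preset: str, n_traces: int, seed: int, resolution: float = 200.0) -> float:
    stats, _, _ = run_condition(preset, seed, min_active_traces=n_traces)
    vals = _multi_values(stats, n_traces)
    return fit_exponential(vals, resolution, resolution).mean


def pol_delta_rate(seed: int) -> float:
    return _rate_target("pol_delta_pe", 151, seed)


def pol_delta_processivity_knt(seed: int) -> float:
    stats, _, prof = run_condition("pol_delta_pe", seed, min_events=151)
    procs = [st.processivity_bp for s in stats for st in s.single_steps][:151]
    return fit_exponential(procs, prof.resolution_bp, prof.resolution_bp).mean / 1000.0


def ltag_alone_rate(seed: int) -> float:
    return _rate_target("ltag_alone", 51, seed)


def ltag_rpa_rate(seed: int) -> float:
    return _rate_target("ltag_rpa", 81, seed)


def ltag_rpa_multi_kb(seed: int) -> float:
    return _multi_target("ltag_rpa", 40, seed) / 1000.0


def sv40_ssb_rate(seed: int) -> float:
    return _rate_target("sv40_ssb", 111, seed)


def sv40_rpa_rate(seed: int) -> float:
    return _rate_target("sv40_rpa", 84, seed)


def sv40_rpa_multi_kb(seed: int) -> float:
    return _multi_target("sv40_rpa", 39, seed) / 1000.0


def restart_pause_s(seed: int) -> float:
    stats, _, _ = run_condition("sv40_ssb", seed, min_traces=120, max_traces=160)
    pauses = [p for s in stats for p in s.restart_pauses_s]
    return fit_exponential(pauses, 3.0, 20.0).mean


def mst_kd_nM(seed: int) -> float:
    kds = []
    for rep in range(50):
        curve = simulate_mst(
            kd_nM=6.7, target_nM=20.0, top_titrant_nM=250.0, n_points=16,
            dilution_factor=2.0, noise_sd=0.02, seed=_sub_seed(seed, 5, rep),
        )
        kds.append(fit_kd(curve).kd_nM)
    return float(np.median(kds))


def fpc_mcm10_multi_kb(seed: int) -> float:
    stats, _, _ = run_condition(
        "sv40_fpc_mcm10", seed, min_active_traces=100, max_traces=200
    )
    vals = _multi_values(stats)
    return fit_exponential(vals, 200.0, 200.0).mean / 1000.0


def leading_strand_threshold() -> float:
    return compute_threshold_rate(5.3)


# -- target registry --------------------------------------------------------

TARGETS: dict[str, dict] = {
    "t1": {"fn": pol_delta_rate, "n": 151, "units": "nt/s"},
    "t2": {"fn": pol_delta_processivity_knt, "n": 151, "units": "knt"},
    "t3": {"fn": ltag_alone_rate, "n": 51, "units": "bp/s"},
    "t4": {"fn": ltag_rpa_rate, "n": 81, "units": "bp/s"},
    "t5": {"fn": ltag_rpa_multi_kb, "n": 40, "units": "kb"},
    "t6": {"fn": sv40_ssb_rate, "n": 111, "units": "bp/s"},
    "t7": {"fn": sv40_rpa_rate, "n": 84, "units": "bp/s"},
    "t8": {"fn": sv40_rpa_multi_kb, "n": 39, "units": "kb"},
    "t9": {"fn": restart_pause_s, "n": 120, "units": "s"},
    "t10": {"fn": mst_kd_nM, "n": 50, "units": "nM"},
    "t11": {"fn": fpc_mcm10_multi_kb, "n": 100, "units": "kb"},
    "t12": {"fn": leading_strand_threshold, "n": 1, "units": "bp/s"},
}


def run_target(target_id: str, master_seed: int) -> float:
    spec = TARGETS[target_id]
    fn = spec["fn"]
    if target_id == "t12":
        return float(fn())
    key = int(target_id[1:])
    return _median_over_seeds(fn, master_seed, key)


def run_targets(master_seed: int, ids=None) -> dict:
    out = {}
    for tid in ids or TARGETS:
        out[tid] = {
            "value": run_target(tid, master_seed),
            "n": TARGETS[tid]["n"],
        }
    return out
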