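"""Stochastic generator of flow-stretching replication traces with ground truth.

The generative model mirrors the structure the downstream analysis assumes: a
flat leading baseline, then alternating activity bursts and pauses.  Each
burst has an exponentially distributed length (mean ``proc_mean_bp``, clamped
to the remaining template) and a per-burst rate drawn from a positive
truncated normal (or a heavy-tailed mixture).  After each burst the complex
restarts with probability ``p_restart`` following a pause of ``3 s + Exp``
duration, otherwise it terminates; on shortening substrates an optional
re-annealing ramp returns the tether to its initial length.  The activity is
mapped to bead displacement through the substrate geometry, i.i.d. Gaussian
baseline noise (bp-equivalent) is added, and the result is sampled at 2 Hz.

Ground-truth intervals are recorded alongside the trace so segmentation and
parameter-recovery can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import GEOMETRIES, SubstrateGeometry
from .errors import ValidationError
from .io import DEFAULT_ACQUISITION_HZ, Trace

__all__ = [
    "RateModel",
    "KineticPreset",
    "TruthInterval",
    "SimulatedTrace",
    "PRESETS",
    "draw_plan",
    "render_plan",
    "simulate_trace",
    "simulate_ensemble",
    "simulate_baseline",
    "simulate_force_extension",
    "simulate_mst",
]


@dataclass(frozen=True)
class RateModel:
    """Per-burst rate distribution: positive truncated normal, or a mixture of
    a narrow normal peak with an exponential upper tail (heavy-tailed rate
    populations such as the FPC-stimulated replisome)."""

    family: str  # "normal" | "mixture"
    mean_bp_s: float
    sd_bp_s: float
    tail_weight: float = 0.0
    tail_excess_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "mixture"):
            raise ValidationError(f"rate_model.family {self.family!r} unknown")
        if self.mean_bp_s <= 0:
            raise ValidationError("rate_model.mean_bp_s must be positive")
        if self.sd_bp_s < 0:
            raise ValidationError("rate_model.sd_bp_s must be non-negative")
        if not 0 <= self.tail_weight < 1:
            raise ValidationError("rate_model.tail_weight must be in [0, 1)")
        if self.family == "mixture" and self.tail_excess_mean <= 0:
            raise ValidationError("rate_model.tail_excess_mean must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "mixture" and rng.uniform() < self.tail_weight:
            return self.mean_bp_s + rng.exponential(self.tail_excess_mean)
        if self.sd_bp_s == 0:
            return self.mean_bp_s
        for _ in range(1000):
            r = rng.normal(self.mean_bp_s, self.sd_bp_s)
            if r > 0:
                return r
        raise ValidationError("rate_model: could not draw a positive rate")

    @property
    def arithmetic_mean(self) -> float:
        """Population mean including any tail component (truncation ignored)."""
        return self.mean_bp_s + self.tail_weight * self.tail_excess_mean


@dataclass(frozen=True)
class KineticPreset:
    """Ground-truth generative parameters for one experimental condition."""

    name: str
    rate_model: RateModel
    proc_mean_bp: float
    p_restart: float = 0.0
    pause_mean_s: float = 182.0
    template_len_bp: float | None = None
    noise_sd_bp: float = 150.0
    reanneal_rate_bp_s: float = 0.0
    geometry_name: str = "primer_extension"

    def __post_init__(self) -> None:
        if self.proc_mean_bp <= 0:
            raise ValidationError("proc_mean_bp must be positive")
        if not 0 <= self.p_restart < 1:
            raise ValidationError("p_restart must be in [0, 1)")
        if self.p_restart > 0 and self.pause_mean_s < 3:
            raise ValidationError("pause_mean_s must be >= 3 s when p_restart > 0")
        if not 0 <= self.noise_sd_bp < 200:
            raise ValidationError("noise_sd_bp must be in [0, 200) bp")
        if self.reanneal_rate_bp_s < 0:
            raise ValidationError("reanneal_rate_bp_s must be non-negative")
        if self.geometry_name not in GEOMETRIES:
            raise ValidationError(f"geometry_name {self.geometry_name!r} unknown")
        if self.template_len_bp is not None and self.template_len_bp <= 0:
            raise ValidationError("template_len_bp must be positive")

    @property
    def geometry(self) -> SubstrateGeometry:
        return GEOMETRIES[self.geometry_name]

    @property
    def template(self) -> float:
        if self.template_len_bp is not None:
            return self.template_len_bp
        return self.geometry.template_len

    @property
    def multi_step_mean_bp(self) -> float:
        """Analytic mean of total per-trace activity: proc_mean / (1 - p_restart)."""
        return self.proc_mean_bp / (1.0 - self.p_restart)


#: Per-condition presets.  Rate/processivity/pause/restart values follow the
#: printed per-condition statistics; distribution widths and noise levels are
#: the package's documented choices (see docs/methods.md).
PRESETS: dict[str, KineticPreset] = {
    # Pol delta-PCNA primer extension: 240 nt/s, 0.4 knt, single burst.
    "pol_delta_pe": KineticPreset(
        name="pol_delta_pe",
        rate_model=RateModel("normal", 240.0, 72.0),
        proc_mean_bp=400.0,
        p_restart=0.0,
        template_len_bp=7200.0,
        noise_sd_bp=100.0,
        geometry_name="primer_extension",
    ),
    # L-Tag alone on the shortening substrate: 1.1 bp/s, sub-resolution
    # processivity, post-termination re-annealing.
    "ltag_alone": KineticPreset(
        name="ltag_alone",
        rate_model=RateModel("normal", 1.1, 0.33),
        proc_mean_bp=150.0,
        p_restart=0.0,
        template_len_bp=13500.0,
        noise_sd_bp=150.0,
        reanneal_rate_bp_s=5.0,
        geometry_name="unwinding_shortening",
    ),
    # L-Tag + RPA on the lengthening substrate: 1.4 bp/s; restarts give a
    # 0.8 kb multi-step mean (0.64 / (1 - 0.2)).
    "ltag_rpa": KineticPreset(
        name="ltag_rpa",
        rate_model=RateModel("normal", 1.4, 0.42),
        proc_mean_bp=640.0,
        p_restart=0.2,
        pause_mean_s=182.0,
        template_len_bp=7000.0,
        noise_sd_bp=150.0,
        geometry_name="unwinding_lengthening",
    ),
    # SV40 leading-strand synthesis with E. coli SSB: 5.3 bp/s, 0.3 kb single
    # steps, 0.5 kb multi-step (0.3 / 0.6), 182 s restart pauses.
    "sv40_ssb": KineticPreset(
        name="sv40_ssb",
        rate_model=RateModel("normal", 5.3, 1.59),
        proc_mean_bp=300.0,
        p_restart=0.4,
        pause_mean_s=182.0,
        template_len_bp=7000.0,
        noise_sd_bp=150.0,
        geometry_name="leading_ssb",
    ),
    # Same with human RPA on the lengthening substrate: 4.5 bp/s.
    "sv40_rpa": KineticPreset(
        name="sv40_rpa",
        rate_model=RateModel("normal", 4.5, 1.35),
        proc_mean_bp=300.0,
        p_restart=0.4,
        pause_mean_s=182.0,
        template_len_bp=7000.0,
        noise_sd_bp=150.0,
        geometry_name="leading_rpa",
    ),
    # SV40 + FPC + Mcm10: more frequent restarts double the multi-step
    # processivity (0.55 / (1 - 0.5) = 1.1 kb).
    "sv40_fpc_mcm10": KineticPreset(
        name="sv40_fpc_mcm10",
        rate_model=RateModel("normal", 3.8, 1.14),
        proc_mean_bp=550.0,
        p_restart=0.5,
        pause_mean_s=182.0,
        template_len_bp=7000.0,
        noise_sd_bp=150.0,
        geometry_name="leading_ssb",
    ),
    # SV40 + FPC: narrow 3.8 bp/s peak plus a heavy exponential tail sized so
    # the arithmetic mean rate is 23 bp/s.
    "sv40_fpc": KineticPreset(
        name="sv40_fpc",
        rate_model=RateModel("mixture", 3.8, 1.0, tail_weight=0.3, tail_excess_mean=64.0),
        proc_mean_bp=400.0,
        p_restart=0.3,
        pause_mean_s=100.0,
        template_len_bp=7000.0,
        noise_sd_bp=150.0,
        geometry_name="leading_ssb",
    ),
}


@dataclass(frozen=True)
class TruthInterval:
    """One ground-truth interval, in the enzymatic-activity domain
    (delta > 0 = forward activity, regardless of substrate geometry)."""

    kind: str  # baseline | event | pause | reanneal
    t_start_s: float
    t_end_s: float
    rate_bp_s: float
    delta_bp: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class SimulatedTrace:
    trace: Trace
    truth: list[TruthInterval]
    preset_name: str = ""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_plan(
    preset: KineticPreset,
    rng: np.random.Generator,
    baseline_s: float = 60.0,
    trailing_s: float = 60.0,
    max_duration_s: float = 3000.0,
) -> list[TruthInterval]:
    """Draw the ground-truth event plan (continuous time, activity domain)."""
    if baseline_s < 0:
        raise ValidationError("baseline_s must be non-negative")
    plan: list[TruthInterval] = []
    t = 0.0
    if baseline_s > 0:
        plan.append(TruthInterval("baseline", 0.0, baseline_s, 0.0, 0.0))
        t = baseline_s
    total = 0.0
    while True:
        remaining = preset.template - total
        if remaining <= 0:
            break
        length = min(rng.exponential(preset.proc_mean_bp), remaining)
        rate = preset.rate_model.draw(rng)
        dur = length / rate
        plan.append(TruthInterval("event", t, t + dur, rate, length))
        t += dur
        total += length
        if t >= max_duration_s or total >= preset.template:
            break
        if rng.uniform() >= preset.p_restart:
            break
        pause = 3.0 + rng.exponential(max(preset.pause_mean_s - 3.0, 0.0))
        plan.append(TruthInterval("pause", t, t + pause, 0.0, 0.0))
        t += pause
        if t >= max_duration_s:
            break
    if preset.reanneal_rate_bp_s > 0 and total > 0 and t < max_duration_s:
        dur = total / preset.reanneal_rate_bp_s
        plan.append(
            TruthInterval("reanneal", t, t + dur, -preset.reanneal_rate_bp_s, -total)
        )
        t += dur
    if trailing_s > 0:
        plan.append(TruthInterval("baseline", t, t + trailing_s, 0.0, 0.0))
        t += trailing_s
    # clip to the duration cap, scaling the partial interval's delta
    if t > max_duration_s:
        clipped: list[TruthInterval] = []
        for iv in plan:
            if iv.t_start_s >= max_duration_s:
                break
            if iv.t_end_s <= max_duration_s:
                clipped.append(iv)
            else:
                frac = (max_duration_s - iv.t_start_s) / iv.duration_s
                clipped.append(
                    TruthInterval(
                        iv.kind, iv.t_start_s, max_duration_s,
                        iv.rate_bp_s, iv.delta_bp * frac,
                    )
                )
        plan = clipped
    return plan


def _truth_nodes(plan: list[TruthInterval]) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoint times and cumulative activity values of a plan."""
    times = [plan[0].t_start_s]
    values = [0.0]
    for iv in plan:
        times.append(iv.t_end_s)
        values.append(values[-1] + iv.delta_bp)
    return np.asarray(times), np.asarray(values)


def render_plan(
    plan: list[TruthInterval],
    geometry: SubstrateGeometry,
    noise_sd_bp: float,
    rng,
    trace_id: str = "sim",
    acquisition_hz: float = DEFAULT_ACQUISITION_HZ,
) -> SimulatedTrace:
    """Sample a plan onto the uniform acquisition grid and add baseline noise.

    The returned trace's bp series is the *displacement* (activity times the
    geometry's direction sign) so that shortening substrates run negative, as
    in the raw experiment.
    """
    rng = _as_rng(rng)
    dt = 1.0 / acquisition_hz
    total = plan[-1].t_end_s - plan[0].t_start_s
    n = int(np.floor(total / dt + 1e-9)) + 1
    duration = (n - 1) * dt
    t = plan[0].t_start_s + np.arange(n) * dt
    node_t, node_v = _truth_nodes(plan)
    activity = np.interp(t, node_t, node_v)
    noise = rng.normal(0.0, noise_sd_bp, size=n) if noise_sd_bp > 0 else 0.0
    pos_bp = geometry.direction_sign * activity + noise
    trace = Trace(
        trace_id=trace_id,
        time_s=t - t[0],
        position_bp=pos_bp,
        position_nm=pos_bp / geometry.nt_per_nm,
        geometry_name=geometry.name,
        force_pN=geometry.force_pN,
        acquisition_hz=acquisition_hz,
    )
    # re-clip truth so it tiles [0, duration] exactly on the sampled grid
    truth: list[TruthInterval] = []
    t0 = plan[0].t_start_s
    for iv in plan:
        a, b = iv.t_start_s - t0, iv.t_end_s - t0
        if a >= duration:
            break
        if b > duration:
            frac = (duration - a) / (b - a)
            iv = TruthInterval(iv.kind, a, duration, iv.rate_bp_s, iv.delta_bp * frac)
        else:
            iv = TruthInterval(iv.kind, a, b, iv.rate_bp_s, iv.delta_bp)
        truth.append(iv)
    return SimulatedTrace(trace=trace, truth=truth)


def simulate_trace(
    preset: KineticPreset,
    seed,
    baseline_s: float = 60.0,
    trailing_s: float = 60.0,
    max_duration_s: float = 3000.0,
    trace_id: str | None = None,
) -> SimulatedTrace:
    """Simulate one trace: draw the burst/pause plan, then render it at 2 Hz."""
    rng = _as_rng(seed)
    plan = draw_plan(preset, rng, baseline_s, trailing_s, max_duration_s)
    sim = render_plan(
        plan,
        preset.geometry,
        preset.noise_sd_bp,
        rng,
        trace_id=trace_id or preset.name,
    )
    sim.preset_name = preset.name
    return sim


def per_trace_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Fixed, documented master-seed -> per-trace-seed derivation."""
    return np.random.SeedSequence([int(master_seed), int(index)])


def simulate_ensemble(
    preset: KineticPreset,
    n_traces: int,
    seed: int,
    **kwargs,
) -> list[SimulatedTrace]:
    """Simulate ``n_traces`` reproducible traces; trace *i* uses the seed
    sequence ``(master_seed, i)`` so ensembles are reproducible element-wise."""
    if n_traces < 1:
        raise ValidationError("n_traces must be >= 1")
    out = []
    for i in range(n_traces):
        sim = simulate_trace(
            preset,
            per_trace_seed(seed, i),
            trace_id=f"{preset.name}_{i:04d}",
            **kwargs,
        )
        out.append(sim)
    return out


def simulate_baseline(
    noise_sd_bp: float,
    duration_s: float,
    seed,
    acquisition_hz: float = DEFAULT_ACQUISITION_HZ,
    trace_id: str = "baseline",
) -> Trace:
    """Pure-noise baseline trace (unreplicated molecule) at 2 Hz."""
    if duration_s < 3:
        raise ValidationError("duration_s must be at least 3 s")
    if noise_sd_bp < 0:
        raise ValidationError("noise_sd_bp must be non-negative")
    rng = _as_rng(seed)
    dt = 1.0 / acquisition_hz
    n = int(np.floor(duration_s / dt + 1e-9)) + 1
    pos = rng.normal(0.0, noise_sd_bp, size=n) if noise_sd_bp > 0 else np.zeros(n)
    return Trace(
        trace_id=trace_id,
        time_s=np.arange(n) * dt,
        position_bp=pos,
        acquisition_hz=acquisition_hz,
    )


def simulate_force_extension(
    persistence_nm: float,
    contour_nm: float,
    forces_pN,
    noise_sd_pN: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Synthetic WLC force-extension point set: (extension_nm, force_pN) rows."""
    from .calibration import wlc_extension

    if persistence_nm <= 0 or contour_nm <= 0:
        raise ValidationError("persistence_nm and contour_nm must be positive")
    forces = np.asarray(forces_pN, dtype=float)
    if np.any(forces < 0):
        raise ValidationError("forces_pN must be non-negative")
    ext = np.array([wlc_extension(f, persistence_nm, contour_nm) for f in forces])
    obs = forces.copy()
    if noise_sd_pN > 0:
        obs = obs + _as_rng(seed).normal(0.0, noise_sd_pN, size=forces.size)
    return np.column_stack([ext, obs])


def simulate_mst(
    kd_nM: float,
    target_nM: float = 20.0,
    top_titrant_nM: float = 250.0,
    n_points: int = 16,
    dilution_factor: float = 2.0,
    noise_sd: float = 0.0,
    seed=None,
    unbound_level: float = 0.0,
    bound_level: float = 1.0,
):
    """Simulated MST titration: serial dilution, ligand-depletion isotherm,
    Gaussian signal noise.  Defaults match a 16-point two-fold series from
    250 nM titrant against a 20 nM labeled target."""
    from .mst import MSTCurve, isotherm

    if kd_nM < 0:
        raise ValidationError("kd_nM must be non-negative")
    if target_nM <= 0 or top_titrant_nM <= 0:
        raise ValidationError("target_nM and top_titrant_nM must be positive")
    if n_points < 4:
        raise ValidationError("n_points must be at least 4")
    if dilution_factor <= 1:
        raise ValidationError("dilution_factor must exceed 1")
    titrant = top_titrant_nM / dilution_factor ** np.arange(n_points)
    fb = isotherm(titrant, target_nM, kd_nM)
    signal = unbound_level + (bound_level - unbound_level) * fb
    if noise_sd > 0:
        signal = signal + _as_rng(seed).normal(0.0, noise_sd, size=n_points)
    return MSTCurve(titrant_nM=titrant, signal=signal, target_nM=target_nM)
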