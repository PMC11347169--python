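"""Trace segmentation into baseline, pauses, and activity events.

The classifier applies the operational rules of the flow-stretching analysis:

* a *pause* is at least six consecutive 2 Hz samples (>= 3 s) whose spread
  about the run mean is within the baseline noise SD and whose slope is below
  the per-category threshold rate (one tenth of the mean rate);
* an *event* is an interval whose length change matches the direction of
  enzymatic activity, is at least the spatial resolution (200 bp), and whose
  rate is at least the threshold rate;
* residual negative-progress intervals after the final event on a shortening
  substrate are *re-annealing*; everything else is baseline.

Candidate boundaries come from a continuous piecewise-linear (free-knot
linear-spline) least-squares fit rather than from growing flat runs: the bead
position is continuous, so forcing the fitted segments to connect at the
kinks concentrates statistical power exactly where flat-run growth is
scale-confused (at 150 bp noise a 1 bp/s event is indistinguishable from a
pause on any sub-minute window).  Knots are inserted greedily while the RSS
gain exceeds a noise-scaled threshold, then swept with per-knot reposition /
elimination passes.  The flat-run detector of the operational definition is
still available as :func:`detect_pauses`.

The literal comparison "run SD < noise SD" would reject half of all true
pauses by chance (the sample SD of pure noise straddles the true SD), so
flatness is tested one-sidedly at the 5% level:
``SD < noise_sd * sqrt(chi2_{n-1, 0.95} / (n - 1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2

from .calibration import SubstrateGeometry
from .errors import DegenerateDataError, ValidationError
from .io import Trace

MIN_PAUSE_SAMPLES = 6
MIN_PAUSE_S = 3.0
RESOLUTION_FLOOR_BP = 200.0
THRESHOLD_DIVISOR = 10.0
FLATNESS_ALPHA = 0.05

#: Knot-insertion threshold for the spline fit, in units of the noise
#: variance.  Deliberately below the max-selection null level (~2 ln n): a
#: missed kink smears an event into its flanking flats and biases every
#: downstream statistic, whereas a spurious kink only splits a segment that
#: classification re-merges.
Q_INSERT = 7.0
#: Knot-elimination threshold: once localized, a kink is kept if it still
#: carries an (unselected) chi2(1) improvement at the 1% level.
Q_REMOVE = 6.6


@dataclass(frozen=True)
class NoiseProfile:
    """Baseline noise level and the derived spatial resolution."""

    noise_sd_bp: float
    resolution_bp: float = RESOLUTION_FLOOR_BP
    n_baselines: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_bp < 0:
            raise ValidationError("noise_sd_bp must be non-negative")
        if self.resolution_bp < self.noise_sd_bp:
            raise ValidationError("resolution_bp must be >= noise_sd_bp")


@dataclass
class Segment:
    """One classified interval of a trace, in the activity-positive domain
    (delta_bp > 0 = net enzymatic progress irrespective of geometry)."""

    kind: str  # baseline | event | pause | reanneal
    t_start_s: float
    t_end_s: float
    delta_bp: float
    rate_bp_s: float
    r2: float = float("nan")
    n_samples: int = 0
    sd_bp: float = float("nan")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


class SingleStep(NamedTuple):
    processivity_bp: float
    lifetime_s: float
    rate_bp_s: float


@dataclass
class TraceStats:
    """Per-trace single-step / multi-step kinetic bookkeeping."""

    single_steps: list[SingleStep] = field(default_factory=list)
    multi_step_processivity_bp: float = float("nan")
    multi_step_lifetime_s: float = float("nan")
    restart_pauses_s: list[float] = field(default_factory=list)
    n_events: int = 0
    restarted: bool = False


# --------------------------------------------------------------------------
# display-only smoothing and noise characterization


def smooth_fft(trace: Trace, cutoff_hz: float) -> Trace:
    """Brick-wall low-pass FFT filter (display/QC only, never used for rates)."""
    nyquist = trace.acquisition_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValidationError(
            f"cutoff_hz {cutoff_hz} must be below the Nyquist frequency {nyquist}"
        )
    if cutoff_hz <= 0:
        raise ValidationError("cutoff_hz must be positive")

    def lowpass(y: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(y)
        freqs = np.fft.rfftfreq(y.size, d=1.0 / trace.acquisition_hz)
        spec[freqs > cutoff_hz] = 0.0
        return np.fft.irfft(spec, n=y.size)

    return Trace(
        trace_id=trace.trace_id,
        time_s=trace.time_s.copy(),
        position_bp=lowpass(trace.position_bp) if trace.position_bp is not None else None,
        position_nm=lowpass(trace.position_nm) if trace.position_nm is not None else None,
        geometry_name=trace.geometry_name,
        force_pN=trace.force_pN,
        acquisition_hz=trace.acquisition_hz,
    )


def _gaussian_hist_sd(values: np.ndarray) -> float:
    """SD of a Gaussian fitted to the value histogram (fallback: sample SD)."""
    from scipy.optimize import curve_fit

    sd0 = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if sd0 == 0.0:
        return 0.0
    counts, edges = np.histogram(values, bins="auto")
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 4:
        return sd0
    model = lambda x, a, mu, sd: a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    try:
        popt, _ = curve_fit(
            model, centers, counts,
            p0=(counts.max(), float(np.mean(values)), sd0),
            bounds=([0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        return float(popt[2])
    except RuntimeError:
        return sd0


def characterize_noise(
    baselines: Sequence[Trace],
    resolution_floor_bp: float = RESOLUTION_FLOOR_BP,
) -> NoiseProfile:
    """Fit a Gaussian to each baseline's position histogram; the worst-case SD
    sets the noise level.  The spatial resolution is the 200 bp floor when all
    SDs are below it, otherwise the largest SD rounded up to the next 100 bp."""
    if not baselines:
        raise ValidationError("baselines must not be empty")
    sds = []
    for tr in baselines:
        if tr.duration_s < 60.0:
            raise ValidationError(
                f"baseline {tr.trace_id}: shorter than 60 s ({tr.duration_s:g} s)"
            )
        y = tr.position_bp
        if y is None:
            raise ValidationError(f"baseline {tr.trace_id}: needs position_bp")
        sds.append(_gaussian_hist_sd(np.asarray(y, float)))
    worst = float(max(sds))
    if worst < resolution_floor_bp:
        resolution = resolution_floor_bp
    else:
        resolution = math.ceil(worst / 100.0) * 100.0
    return NoiseProfile(noise_sd_bp=worst, resolution_bp=resolution,
                        n_baselines=len(baselines))


# --------------------------------------------------------------------------
# threshold-rate rule


def compute_threshold_rate(mean_rate_bp_s: float) -> float:
    """One tenth of the mean rate, rounded to one significant figure
    (1.1 -> 0.1, 5.3 -> 0.5, 240 -> 20)."""
    if mean_rate_bp_s <= 0:
        raise ValidationError("mean_rate_bp_s must be positive")
    x = mean_rate_bp_s / THRESHOLD_DIVISOR
    exp = math.floor(math.log10(x))
    return round(x / 10**exp) * 10.0**exp


# --------------------------------------------------------------------------
# flat-run pause detector (the operational rule, standalone)


def _flat_limit(n: int, noise_sd: float, scale: float = 1.0) -> float:
    """One-sided 95% bound on the sample SD of n noise samples."""
    if noise_sd == 0:
        return 1e-9 * max(1.0, scale)
    return noise_sd * math.sqrt(chi2.ppf(1.0 - FLATNESS_ALPHA, n - 1) / (n - 1))


def detect_pauses(
    trace_bp,
    noise_sd_bp: float,
    threshold_rate_bp_s: float = 0.0,
    acquisition_hz: float = 2.0,
) -> list[tuple[float, float]]:
    """Maximal flat runs: >= 6 consecutive samples within the noise about the
    run mean, |OLS slope| below the threshold rate (skipped when the threshold
    is 0, i.e. before it has been determined), at least 3 s long; runs closer
    than 2 samples are merged.  Returns (t_start_s, t_end_s) candidates."""
    if isinstance(trace_bp, Trace):
        y = np.asarray(trace_bp.position_bp, float)
        acquisition_hz = trace_bp.acquisition_hz
    else:
        y = np.asarray(trace_bp, dtype=float)
    dt = 1.0 / acquisition_hz
    n = y.size
    scale = float(np.ptp(y)) if n else 1.0
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        j = i + 2
        best = None
        while j <= n:
            if np.std(y[i:j], ddof=1) < _flat_limit(j - i, noise_sd_bp, scale):
                best = j
                j += 1
            else:
                # small lookahead: a single outlier should not end the run
                extended = False
                for k in (j + 1, j + 2):
                    if k <= n and np.std(y[i:k], ddof=1) < _flat_limit(
                        k - i, noise_sd_bp, scale
                    ):
                        best, j, extended = k, k + 1, True
                        break
                if not extended:
                    break
        if best is not None and best - i >= MIN_PAUSE_SAMPLES:
            runs.append((i, best))
            i = best
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < 2:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        if (b - a) * dt < MIN_PAUSE_S:
            continue
        if threshold_rate_bp_s > 0:
            tt = np.arange(a, b) * dt
            slope = np.polyfit(tt, y[a:b], 1)[0]
            if abs(slope) >= threshold_rate_bp_s:
                continue
        out.append((a * dt, b * dt))
    return out


# --------------------------------------------------------------------------
# continuous piecewise-linear (free-knot linear spline) fit


def _suffix(v: np.ndarray) -> np.ndarray:
    return np.cumsum(v[::-1])[::-1]


def _knot_gains(t: np.ndarray, resid: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """RSS reduction from adding a hinge max(t - t[c], 0) at every candidate
    sample c, given the orthonormal basis Q of the current design and the
    current residual.  O(n * K) via suffix sums."""
    s1 = _suffix(resid)
    st = _suffix(resid * t)
    num = st - t * s1
    sn = _suffix(np.ones_like(t))
    sst = _suffix(t)
    stt = _suffix(t * t)
    h2 = stt - 2.0 * t * sst + t * t * sn
    proj = np.zeros_like(t)
    for k in range(Q.shape[1]):
        q = Q[:, k]
        qh = _suffix(q * t) - t * _suffix(q)
        proj += qh * qh
    den = h2 - proj
    good = den > 1e-9 * np.maximum(h2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(good, num * num / np.where(good, den, 1.0), 0.0)
    return gains


def _spline_design(t: np.ndarray, knots: Sequence[int]) -> np.ndarray:
    cols = [np.ones_like(t), t]
    cols += [np.maximum(t - t[k], 0.0) for k in knots]
    return np.column_stack(cols)


def _mask_near(gains: np.ndarray, knots: Sequence[int]) -> None:
    # only the exact positions of existing knots (and the trace ends) are
    # excluded: adjacent-sample knots are needed to represent step-like
    # events, and masking neighbours can permanently hide a true kink
    n = gains.size
    gains[:2] = 0.0
    gains[n - 1 :] = 0.0
    for k in knots:
        gains[k] = 0.0


def fit_piecewise_linear(
    t: np.ndarray, y: np.ndarray, noise_sd: float, max_knots: int = 40
) -> tuple[list[int], np.ndarray]:
    """Fit a continuous piecewise-linear function with data-chosen kinks.

    Returns the sorted knot sample indices and the fitted values.  Knots are
    inserted greedily while the RSS improvement exceeds ``Q_INSERT`` times the
    noise variance, then repositioned/eliminated in sweeps at ``Q_REMOVE``.
    """
    n = t.size
    scale = float(np.ptp(y)) or 1.0
    var = max(noise_sd, 1e-7 * scale) ** 2
    knots: list[int] = []

    def qr_resid(kn: Sequence[int]):
        X = _spline_design(t, kn)
        Q, _ = np.linalg.qr(X)
        resid = y - Q @ (Q.T @ y)
        return Q, resid

    while len(knots) < max_knots:
        Q, resid = qr_resid(knots)
        gains = _knot_gains(t, resid, Q)
        _mask_near(gains, knots)
        c = int(np.argmax(gains))
        if gains[c] <= Q_INSERT * var:
            break
        knots = sorted(knots + [c])

    for _ in range(3):
        changed = False
        j = 0
        while j < len(knots):
            others = knots[:j] + knots[j + 1 :]
            Q, resid = qr_resid(others)
            gains = _knot_gains(t, resid, Q)
            _mask_near(gains, others)
            c = int(np.argmax(gains))
            if gains[c] <= Q_REMOVE * var:
                knots.pop(j)
                changed = True
                continue
            if c != knots[j]:
                knots[j] = c
                knots.sort()
                changed = True
            j += 1
        if not changed:
            break

    X = _spline_design(t, knots)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return knots, X @ beta


class _Sums:
    """Prefix sums for O(1) squared-residual costs against fixed levels/lines."""

    def __init__(self, t: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.sn = np.concatenate([z, np.cumsum(np.ones_like(t))])
        self.st = np.concatenate([z, np.cumsum(t)])
        self.stt = np.concatenate([z, np.cumsum(t * t)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])
        self.sty = np.concatenate([z, np.cumsum(t * y)])

    def level_cost(self, a, b, lvl):
        n = self.sn[b] - self.sn[a]
        sy = self.sy[b] - self.sy[a]
        syy = self.syy[b] - self.syy[a]
        return syy - 2.0 * lvl * sy + lvl * lvl * n

    def line_cost(self, a, b, alpha, beta):
        n = self.sn[b] - self.sn[a]
        st = self.st[b] - self.st[a]
        stt = self.stt[b] - self.stt[a]
        sy = self.sy[b] - self.sy[a]
        syy = self.syy[b] - self.syy[a]
        sty = self.sty[b] - self.sty[a]
        return (
            syy - 2.0 * alpha * sy - 2.0 * beta * sty
            + alpha * alpha * n + 2.0 * alpha * beta * st + beta * beta * stt
        )


def _ols(t: np.ndarray, y: np.ndarray):
    """slope, intercept, r2, sd-about-mean for one window."""
    n = t.size
    mt, my = t.mean(), y.mean()
    vt = float(np.sum((t - mt) ** 2))
    vy = float(np.sum((y - my) ** 2))
    if n < 2 or vt == 0:
        return 0.0, my, float("nan"), 0.0
    cty = float(np.sum((t - mt) * (y - my)))
    slope = cty / vt
    r2 = cty**2 / (vt * vy) if vy > 0 else 1.0
    sd = math.sqrt(vy / (n - 1))
    return slope, my - slope * mt, r2, sd


# --------------------------------------------------------------------------
# segmentation proper


def segment_trace(
    trace: Trace,
    noise_profile: NoiseProfile,
    threshold_rate_bp_s: float,
    geometry: SubstrateGeometry,
) -> list[Segment]:
    """Segment one trace into baseline / event / pause / re-annealing.

    All reported deltas and rates are in the activity-positive convention
    (the geometry's direction sign is applied internally).  Segments tile the
    trace; ``threshold_rate_bp_s = 0`` disables both rate criteria (pass 1 of
    the two-pass procedure: exhaustive event collection).
    """
    if threshold_rate_bp_s < 0:
        raise ValidationError("threshold_rate_bp_s must be >= 0")
    if trace.position_bp is None:
        raise ValidationError(f"trace {trace.trace_id}: needs position_bp")
    y = geometry.direction_sign * np.asarray(trace.position_bp, float)
    t = trace.time_s
    n = y.size
    if n < MIN_PAUSE_SAMPLES:
        raise ValidationError("trace shorter than 6 samples")
    dt = 1.0 / trace.acquisition_hz
    sigma = noise_profile.noise_sd_bp
    scale = float(np.ptp(y)) or 1.0

    knots, fitted = fit_piecewise_linear(t, y, sigma)
    bounds = [0] + knots + [n]
    idx = list(zip(bounds[:-1], bounds[1:]))

    def make_segment(a: int, b: int) -> Segment:
        t0, t1 = a * dt, b * dt
        lvl0 = float(fitted[a])
        if b < n:
            lvl1 = float(fitted[b])
        else:  # extrapolate the final half-sample so deltas tile exactly
            lvl1 = float(fitted[n - 1])
            if n >= 2:
                lvl1 += float(fitted[n - 1] - fitted[n - 2])
        delta = lvl1 - lvl0
        dur = t1 - t0
        rate = delta / dur if dur > 0 else 0.0
        _, _, r2, sd = _ols(t[a:b], y[a:b])
        return Segment(
            kind="baseline",
            t_start_s=t0,
            t_end_s=t1,
            delta_bp=delta,
            rate_bp_s=rate,
            r2=r2,
            n_samples=b - a,
            sd_bp=sd,
        )

    segs = [make_segment(a, b) for a, b in idx]

    def window_delta(j: int) -> float:
        """Plateau-to-plateau level change of segment j from end-window means,
        rescaled to the full span.  Equals the fitted delta for a uniform
        ramp, but does not overshoot when the segment mixes flat stretches
        with a short advance (a straight line fitted across a centered step
        reads 1.5x the step height)."""
        a, b = idx[j]
        m = b - a
        w = max(1, min(20, m // 4))
        if m < 2 * w or m == w:
            return segs[j].delta_bp
        return (float(np.mean(y[b - w : b])) - float(np.mean(y[a : a + w]))) * (
            m / (m - w)
        )

    def persists(j: int) -> bool:
        """Short steep advances must carry the level past the next segment's
        end: a noise spike climbs and promptly falls back, a genuine fast
        burst steps the tether to a new plateau.  Long events are exempt (and
        may legitimately be followed by re-annealing)."""
        if segs[j].n_samples >= 80:
            return True
        if j == 0 or j == len(segs) - 1:
            # no reference plateau on one side: cannot certify a short burst
            return False
        a, _ = idx[j]
        b_next = idx[j + 1][1]
        lvl_end = float(fitted[min(b_next, n - 1)])
        return lvl_end - float(fitted[a]) >= noise_profile.resolution_bp

    def classify(j: int) -> str:
        seg = segs[j]
        flat = seg.sd_bp < _flat_limit(max(seg.n_samples, 2), sigma, scale)
        thr = threshold_rate_bp_s
        pause_slope_ok = thr == 0 or abs(seg.rate_bp_s) < thr
        if (
            seg.n_samples >= MIN_PAUSE_SAMPLES
            and seg.duration_s >= MIN_PAUSE_S
            and flat
            and pause_slope_ok
        ):
            return "pause"
        rate_ok = thr == 0 or abs(seg.rate_bp_s) >= thr
        delta = min(seg.delta_bp, window_delta(j))
        if delta >= noise_profile.resolution_bp and rate_ok:
            return "event"
        # sub-resolution flat wiggle: belongs to the surrounding pause as long
        # as its slope is far below the activity scale (5x threshold = half
        # the category mean rate); genuine sub-resolution bursts are faster
        # and stay baseline, keeping distinct pauses distinct
        wiggle_ok = thr == 0 or abs(seg.rate_bp_s) < 5.0 * thr
        if flat and wiggle_ok and abs(seg.delta_bp) < noise_profile.resolution_bp:
            return "pause"
        return "baseline"

    for j, seg in enumerate(segs):
        seg.kind = classify(j)
        if seg.kind == "event" and not persists(j):
            seg.kind = "baseline"

    def merge_same_kind() -> None:
        nonlocal segs, idx
        j = 0
        while j < len(segs) - 1:
            if segs[j].kind == segs[j + 1].kind:
                a, b = idx[j][0], idx[j + 1][1]
                merged = Segment(
                    kind=segs[j].kind,
                    t_start_s=segs[j].t_start_s,
                    t_end_s=segs[j + 1].t_end_s,
                    delta_bp=segs[j].delta_bp + segs[j + 1].delta_bp,
                    rate_bp_s=0.0,
                    n_samples=segs[j].n_samples + segs[j + 1].n_samples,
                )
                merged.rate_bp_s = merged.delta_bp / merged.duration_s
                _, _, merged.r2, merged.sd_bp = _ols(t[a:b], y[a:b])
                segs[j : j + 2] = [merged]
                idx[j : j + 2] = [(a, b)]
            else:
                j += 1

    merge_same_kind()

    # re-annealing: negative-progress intervals after the final event on a
    # shortening substrate
    ev = [j for j, s in enumerate(segs) if s.kind == "event"]
    if ev and geometry.direction_sign < 0:
        for j in range(ev[-1] + 1, len(segs)):
            s = segs[j]
            rate_ok = threshold_rate_bp_s == 0 or abs(s.rate_bp_s) >= threshold_rate_bp_s
            if s.delta_bp <= -noise_profile.resolution_bp and rate_ok:
                s.kind = "reanneal"
        merge_same_kind()

    # pauses must satisfy the minimum-duration rule even after merging, and
    # leading/trailing flat regions are baseline, not pauses
    ev = [j for j, s in enumerate(segs) if s.kind == "event"]
    for j, s in enumerate(segs):
        if s.kind != "pause":
            continue
        if (
            s.n_samples < MIN_PAUSE_SAMPLES
            or s.duration_s < MIN_PAUSE_S
            or not ev
            or j < ev[0]
            or j > ev[-1]
        ):
            s.kind = "baseline"
    merge_same_kind()

    # Final per-event rate/boundary estimation for events flanked by flats.
    # Any least-squares boundary estimate is biased outward at low SNR
    # (narrowing a fitted ramp costs steep corner mismatches, widening only a
    # shallow wedge), which dilutes delta/duration rates.  Instead:
    #   1. plateau levels from the flanking flats, measured away from the
    #      boundary region -> unbiased delta;
    #   2. the event's temporal midpoint from a two-level step fit with both
    #      levels fixed -> symmetric cost, unbiased and sharply localized;
    #   3. the rate from an OLS slope on a window around that midpoint small
    #      enough to sit inside the true ramp;
    #   4. boundaries re-placed as midpoint +/- (delta/rate)/2.
    sums = _Sums(t, y)
    demoted = False
    pad = 40  # samples next to the event excluded from the plateau level

    def plateau(a: int, b: int, near_start: bool) -> float:
        if b - a > pad + 10:
            sl = (a, b - pad) if near_start else (a + pad, b)
        else:
            sl = (a, b)
        return float(np.mean(y[sl[0] : sl[1]]))

    for j, s in enumerate(segs):
        if s.kind != "event":
            continue
        a, b = idx[j]
        prev_flat = j > 0 and segs[j - 1].kind in ("baseline", "pause")
        next_flat = j < len(segs) - 1 and segs[j + 1].kind in ("baseline", "pause")
        if j < len(segs) - 1 and segs[j + 1].kind == "reanneal":
            continue  # peak level is trustworthy; spline values stand
        # reference plateaus: from the flanking flat segments, or -- when a
        # flat flank was absorbed into the event -- from the event's own end
        # region, which then reads the absorbed plateau
        if prev_flat:
            pa = idx[j - 1][0]
            lvl1 = plateau(pa, a, near_start=False)
        else:
            pa = a
            lvl1 = float(np.mean(y[a : a + max(3, min(pad, (b - a) // 3))]))
        if next_flat:
            nb = idx[j + 1][1]
            lvl2 = plateau(b, nb, near_start=True)
        else:
            nb = b
            lvl2 = float(np.mean(y[b - max(3, min(pad, (b - a) // 3)) : b]))
        delta = lvl2 - lvl1
        if delta < noise_profile.resolution_bp:
            # the flanking plateaus give the sharpest delta estimate; a
            # candidate event they place below the resolution is noise
            s.kind = "baseline"
            demoted = True
            continue
        s.delta_bp = delta
        if threshold_rate_bp_s > 0:
            # the category mean rate is 10x the threshold by construction
            steep = 10.0 * threshold_rate_bp_s * dt >= 0.3 * sigma
        else:
            steep = s.rate_bp_s * dt >= 0.3 * sigma
        if sigma > 0 and steep:
            # steep (sampling-limited) burst: the trapezoid's corner misfit
            # dominates the noise, so a fixed-plateau trapezoid scan over
            # both kink positions localizes the ramp sharply
            pa2, nb2 = max(pa, a - 80), min(nb, b + 80)
            best = (np.inf, a, max(a + 1, b - 1))
            for ka in range(pa2 + 1, b):
                kb = np.arange(ka + 1, nb2)
                if kb.size == 0:
                    continue
                betas = (lvl2 - lvl1) / (t[kb] - t[ka])
                alphas = lvl1 - betas * t[ka]
                cost = (
                    float(sums.level_cost(pa2, ka, lvl1))
                    + sums.line_cost(ka, kb, alphas, betas)
                    + sums.level_cost(kb, nb2, lvl2)
                )
                i2 = int(np.argmin(cost))
                if cost[i2] < best[0]:
                    best = (float(cost[i2]), ka, int(kb[i2]))
            _, k1, k2 = best
            # grid correction: the fitted kinks snap outward to the sampling
            # grid, overstating the ramp by half a sample per side on average
            dur = max((k2 - k1 - 0.5) * dt, 0.5 * dt)
            s.rate_bp_s = delta / dur
            continue
        ks = np.arange(pa + 1, nb)
        cost = sums.level_cost(pa, ks, lvl1) + sums.level_cost(ks, nb, lvl2)
        k_mid = int(ks[int(np.argmin(cost))])
        # slope window sized to the ramp this delta implies at the category
        # mean rate (10x the threshold, as in the threshold rule), capped at
        # half the fitted extent; this keeps the window inside the true ramp
        # without trusting the outward-biased fitted boundaries
        if threshold_rate_bp_s > 0:
            h = int(0.4 * delta / (10.0 * threshold_rate_bp_s) / dt)
            h = max(6, min(h, (b - a) // 2))
        else:
            h = max(3, (b - a) // 4)
        w0 = max(pa + 1, k_mid - h)
        w1 = min(nb - 1, k_mid + h + 1)
        slope, _, _, _ = _ols(t[w0:w1], y[w0:w1])
        if slope > 0:
            s.rate_bp_s = slope
    if demoted:
        merge_same_kind()
        ev = [j for j, s in enumerate(segs) if s.kind == "event"]
        for j, s in enumerate(segs):
            if s.kind == "pause" and (not ev or j < ev[0] or j > ev[-1]):
                s.kind = "baseline"
        merge_same_kind()
    return segs


class TwoPassResult(NamedTuple):
    segments_by_trace: list[list[Segment]]
    threshold_bp_s: float
    pass1_rate_mean: float
    pass1_n_events: int


def two_pass_segment(
    traces: Sequence[Trace],
    noise_profile: NoiseProfile,
    geometry: SubstrateGeometry,
) -> TwoPassResult:
    """Two-pass procedure: collect event rates exhaustively (threshold 0),
    Gaussian-fit their distribution, set the category threshold to one tenth
    of the fitted mean (one significant figure), then re-segment."""
    from .kinetics import fit_rate_gaussian

    def fitted_mean(rates: list[float]) -> float:
        if len(rates) >= 10:
            try:
                return fit_rate_gaussian(rates).mean
            except (ValueError, RuntimeError):
                pass
        return float(np.mean(rates))

    pass1 = [segment_trace(tr, noise_profile, 0.0, geometry) for tr in traces]
    rates = [s.rate_bp_s for segs in pass1 for s in segs if s.kind == "event"]
    if not rates:
        raise DegenerateDataError("no activity detected")
    mean1 = fitted_mean(rates)
    n1 = len(rates)
    threshold = compute_threshold_rate(mean1)
    # iterate to the threshold's fixed point: the exhaustive pass slightly
    # underestimates rates (no category scale yet), which can round the
    # threshold one step low; re-segmenting with the settled threshold and
    # recomputing converges in one or two rounds
    result = pass1
    for _ in range(4):
        result = [segment_trace(tr, noise_profile, threshold, geometry) for tr in traces]
        rates2 = [s.rate_bp_s for segs in result for s in segs if s.kind == "event"]
        if not rates2:
            break
        new_threshold = compute_threshold_rate(fitted_mean(rates2))
        if new_threshold == threshold:
            break
        threshold = new_threshold
    return TwoPassResult(result, threshold, mean1, n1)


# --------------------------------------------------------------------------
# per-trace statistics


def trace_statistics(segments: Sequence[Segment]) -> TraceStats:
    """Single-step and multi-step bookkeeping for one segmented trace.

    Multi-step processivity is the total fitted DNA-length change of the
    trace up to any post-activity re-annealing: the tether length integrates
    every advance, including sub-resolution bursts before, between, and after
    the detected events, exactly as the experimental readout does.  The
    multi-step lifetime spans first event start to last event end, so interior
    pauses are included.
    """
    ev = [j for j, s in enumerate(segments) if s.kind == "event"]
    if not ev:
        return TraceStats()
    first, last = ev[0], ev[-1]
    steps = [
        SingleStep(s.delta_bp, s.duration_s, s.rate_bp_s)
        for s in segments
        if s.kind == "event"
    ]
    stop = len(segments)
    for j in range(last + 1, len(segments)):
        if segments[j].kind == "reanneal":
            stop = j
            break
    multi_proc = float(sum(s.delta_bp for s in segments[:stop]))
    multi_lt = segments[last].t_end_s - segments[first].t_start_s
    pauses = [
        s.duration_s
        for j, s in enumerate(segments)
        if s.kind == "pause" and first < j < last
    ]
    return TraceStats(
        single_steps=steps,
        multi_step_processivity_bp=multi_proc,
        multi_step_lifetime_s=multi_lt,
        restart_pauses_s=pauses,
        n_events=len(steps),
        restarted=len(steps) >= 2,
    )
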