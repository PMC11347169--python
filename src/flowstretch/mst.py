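"""Microscale-thermophoresis binding isotherm fitting.

The labeled target (20 nM polymerase) is comparable to the fitted dissociation
constant, so the hyperbolic approximation A/(Kd + A) is not valid and the
ligand-depletion (quadratic) isotherm is used: with titrant A, target T and
dissociation constant K the bound fraction of target is

    FB = [(K + A + T) - sqrt((K + A + T)^2 - 4 A T)] / (2 T),

the exact mass-action solution.  The measured thermophoresis signal is modeled
as unbound + (bound - unbound) * FB with the two plateau levels either fitted
(default) or fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError, ValidationError

__all__ = ["MSTCurve", "KdFit", "fraction_bound", "isotherm", "fit_kd"]


@dataclass
class MSTCurve:
    """One titration: descending titrant series and normalized signal."""

    titrant_nM: np.ndarray
    signal: np.ndarray
    target_nM: float = 20.0

    def __post_init__(self) -> None:
        self.titrant_nM = np.asarray(self.titrant_nM, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.titrant_nM.size != self.signal.size:
            raise ValidationError("titrant_nM and signal lengths differ")
        if np.any(self.titrant_nM <= 0):
            raise ValidationError("titrant_nM must be strictly positive")
        d = np.diff(self.titrant_nM)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValidationError("titrant_nM must be strictly monotone")
        if self.target_nM <= 0:
            raise ValidationError("target_nM must be positive")

    @property
    def n_points(self) -> int:
        return int(self.titrant_nM.size)


@dataclass(frozen=True)
class KdFit:
    kd_nM: float
    se_nM: float
    baseline_unbound: float
    amplitude_bound: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValidationError("kd_nM must be positive")


def fraction_bound(
    signal, unbound_level: float, bound_level: float
):
    """Normalize raw signal to bound fraction: (s - unbound)/(bound - unbound).

    Values outside [-0.05, 1.05] are reported as-is with a warning (they point
    at plateau misassignment rather than being clamped away).
    """
    if bound_level == unbound_level:
        raise ValidationError("bound_level must differ from unbound_level")
    fb = (np.asarray(signal, dtype=float) - unbound_level) / (bound_level - unbound_level)
    if np.any(fb < -0.05) or np.any(fb > 1.05):
        warnings.warn(
            "fraction bound outside [-0.05, 1.05]: check plateau levels",
            stacklevel=2,
        )
    return float(fb) if np.isscalar(signal) else fb


def isotherm(titrant_nM, target_nM: float, kd_nM: float):
    """Ligand-depletion (quadratic) isotherm: exact mass-action bound fraction.

    Evaluated in the cancellation-free form 2A / (K + A + T + sqrt(...)) so the
    K = 0 stoichiometric limit min(A, T)/T is exact.
    """
    a = np.asarray(titrant_nM, dtype=float)
    if target_nM <= 0:
        raise ValidationError("target_nM must be positive")
    if kd_nM < 0 or np.any(a < 0):
        raise ValidationError("concentrations must be non-negative")
    s = kd_nM + a + target_nM
    disc = np.sqrt(np.maximum(s * s - 4.0 * a * target_nM, 0.0))
    fb = 2.0 * a / (s + disc)
    return float(fb) if np.isscalar(titrant_nM) else fb


def fit_kd(
    curve: MSTCurve,
    unbound_level: float | None = None,
    bound_level: float | None = None,
) -> KdFit:
    """Nonlinear least-squares Kd fit of an MST titration.

    Plateaus are free by default; pass ``unbound_level`` / ``bound_level`` to
    fix either.  The Kd standard error comes from the fit covariance.
    """
    if curve.n_points < 6:
        raise ValidationError(
            f"need at least 6 titration points, got {curve.n_points}"
        )
    a, s = curve.titrant_nM, curve.signal
    span = float(np.ptp(s))
    if span == 0 or span < 1e-12 * max(1.0, float(np.abs(s).max())):
        raise DegenerateDataError("signal is flat: no binding transition to fit")
    order = np.argsort(a)
    u0 = float(s[order][0]) if unbound_level is None else unbound_level
    b0 = float(s[order][-1]) if bound_level is None else bound_level
    mid = 0.5 * (u0 + b0)
    k0 = float(np.interp(mid, s[order], a[order])) if b0 != u0 else float(np.median(a))
    k0 = min(max(k0, float(a.min())), float(a.max()))

    free: list[str] = ["kd"]
    if unbound_level is None:
        free.append("u")
    if bound_level is None:
        free.append("b")

    def model(aa, *params):
        p = dict(zip(free, params))
        u = p.get("u", unbound_level)
        b = p.get("b", bound_level)
        return u + (b - u) * isotherm(aa, curve.target_nM, p["kd"])

    p0 = [max(k0, 1e-3)] + ([u0] if unbound_level is None else []) + (
        [b0] if bound_level is None else []
    )
    lo = [1e-9] + [-np.inf] * (len(p0) - 1)
    hi = [1e9] + [np.inf] * (len(p0) - 1)
    try:
        popt, pcov = curve_fit(model, a, s, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Kd fit did not converge: {exc}") from exc
    p = dict(zip(free, popt))
    res = model(a, *popt) - s
    return KdFit(
        kd_nM=float(p["kd"]),
        se_nM=float(np.sqrt(pcov[0, 0])),
        baseline_unbound=float(p.get("u", unbound_level)),
        amplitude_bound=float(p.get("b", bound_level)),
        residual_norm=float(np.sqrt(np.sum(res**2))),
    )
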