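"""Force and length calibration for flow-stretching tethers.

Converts bead displacement (nm) to enzymatic progress (nt or bp) and back,
estimates the stretching force from transverse bead fluctuations via the
equipartition theorem, and fits force-extension data with the worm-like-chain
(WLC) interpolation formula of Marko & Siggia,

    F(x) = (kBT / P) * [ 1 / (4 (1 - x/L)^2) - 1/4 + x/L ],

where P is the persistence length and L the contour length.  At the working
force of a flow-stretching assay (~2.6 pN here) the difference in extension
per base between single- and double-stranded DNA gives a fixed conversion
factor (3.76 nt/nm for these substrates), which each substrate geometry
carries as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

from .errors import DegenerateDataError, FitError, ValidationError

#: Boltzmann constant times temperature in pN*nm at 25 degC.  Experiments run a
#: few degrees warmer (4.21 at 32 degC); the value is configurable everywhere.
KBT_PN_NM = 4.11

#: Conversion between ss- and dsDNA extension at the 2.6 pN working force.
NT_PER_NM_DEFAULT = 3.76

_GEOMETRY_NAMES = (
    "primer_extension",
    "unwinding_shortening",
    "unwinding_lengthening",
    "leading_ssb",
    "leading_rpa",
)


@dataclass(frozen=True)
class SubstrateGeometry:
    """How enzymatic activity maps to bead displacement for one DNA substrate.

    ``direction_sign`` is +1 when activity lengthens the tether (bead moves
    with the flow) and -1 when it shortens it (bead moves against the flow).
    """

    name: str
    direction_sign: int
    nt_per_nm: float = NT_PER_NM_DEFAULT
    force_pN: float = 2.6
    template_len: float = 7000.0

    def __post_init__(self) -> None:
        if self.name not in _GEOMETRY_NAMES:
            raise ValidationError(
                f"geometry name {self.name!r} not one of {_GEOMETRY_NAMES}"
            )
        if self.direction_sign not in (+1, -1):
            raise ValidationError("direction_sign must be +1 or -1")
        if self.nt_per_nm <= 0:
            raise ValidationError("nt_per_nm must be positive")
        if self.force_pN <= 0:
            raise ValidationError("force_pN must be positive")


#: Default geometry table: one entry per substrate configuration used in the
#: flow-stretching experiments.  Shortening geometries (bead against the flow)
#: carry direction_sign -1.
GEOMETRIES: dict[str, SubstrateGeometry] = {
    "primer_extension": SubstrateGeometry("primer_extension", +1, template_len=7200),
    "unwinding_shortening": SubstrateGeometry(
        "unwinding_shortening", -1, template_len=13500
    ),
    "unwinding_lengthening": SubstrateGeometry(
        "unwinding_lengthening", +1, template_len=7000
    ),
    "leading_ssb": SubstrateGeometry("leading_ssb", -1, template_len=7000),
    "leading_rpa": SubstrateGeometry("leading_rpa", +1, template_len=7000),
}


class EquipartitionForce(NamedTuple):
    force_pN: float
    se_pN: float


def equipartition_force(
    extension_nm: float,
    transverse_nm: Sequence[float],
    kBT_pN_nm: float = KBT_PN_NM,
    n_boot: int = 200,
    seed: int = 0,
) -> EquipartitionForce:
    """Estimate the drag force on a tethered bead from transverse fluctuations.

    F = kBT * extension / Var(transverse), with the variance computed about the
    sample mean.  The standard error comes from a seeded bootstrap over the
    transverse samples.
    """
    x = np.asarray(transverse_nm, dtype=float)
    if extension_nm <= 0:
        raise ValidationError("extension_nm must be positive")
    if x.size < 50:
        raise ValidationError(
            f"need at least 50 transverse samples, got {x.size}"
        )
    var = float(np.var(x - x.mean()))
    if var == 0.0:
        raise DegenerateDataError(
            "transverse series has zero variance (stuck bead?)"
        )
    force = kBT_pN_nm * extension_nm / var
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_var = np.var(x[idx] - x[idx].mean(axis=1, keepdims=True), axis=1)
    se = float(np.std(kBT_pN_nm * extension_nm / boot_var, ddof=1))
    return EquipartitionForce(force, se)


def wlc_force(
    x_over_L: float | np.ndarray,
    persistence_nm: float,
    kBT_pN_nm: float = KBT_PN_NM,
) -> float | np.ndarray:
    """Marko-Siggia WLC force at relative extension x/L in [0, 1)."""
    z = np.asarray(x_over_L, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValidationError("x_over_L must lie in [0, 1)")
    if persistence_nm <= 0:
        raise ValidationError("persistence_nm must be positive")
    f = (kBT_pN_nm / persistence_nm) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f) if np.isscalar(x_over_L) else f


def wlc_extension(
    force_pN: float,
    persistence_nm: float,
    contour_nm: float,
    kBT_pN_nm: float = KBT_PN_NM,
) -> float:
    """Invert the WLC force law numerically: extension (nm) at a given force."""
    if force_pN < 0:
        raise ValidationError("force_pN must be non-negative")
    if force_pN == 0:
        return 0.0
    fn = lambda z: wlc_force(z, persistence_nm, kBT_pN_nm) - force_pN
    z = brentq(fn, 0.0, 1.0 - 1e-12)
    return z * contour_nm


@dataclass(frozen=True)
class WLCFit:
    persistence_nm: float
    contour_nm: float
    kBT_pN_nm: float = KBT_PN_NM
    residual_norm: float = 0.0
    persistence_se: float = float("nan")
    contour_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.persistence_nm <= 0 or self.contour_nm <= 0:
            raise ValidationError("persistence_nm and contour_nm must be positive")


def fit_wlc(
    points: Sequence[tuple[float, float]] | np.ndarray,
    kBT_pN_nm: float = KBT_PN_NM,
) -> WLCFit:
    """Least-squares WLC fit of (extension_nm, force_pN) data.

    Estimates persistence length P and contour length L; standard errors come
    from the fit covariance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of (extension, force)")
    if pts.shape[0] < 5:
        raise ValidationError(
            f"need at least 5 force-extension points, got {pts.shape[0]}"
        )
    ext, force = pts[:, 0], pts[:, 1]

    def model(x, persistence, contour):
        z = np.clip(x / contour, 0.0, 1.0 - 1e-9)
        return (kBT_pN_nm / persistence) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)

    p0 = (50.0, max(ext.max() / 0.9, ext.max() + 1.0))
    try:
        popt, pcov = curve_fit(
            model, ext, force, p0=p0,
            bounds=([1e-3, ext.max() * 1.0000001], [1e4, 1e7]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy wording varies
        raise FitError(f"WLC fit did not converge: {exc}") from exc
    res = model(ext, *popt) - force
    ses = np.sqrt(np.diag(pcov))
    return WLCFit(
        persistence_nm=float(popt[0]),
        contour_nm=float(popt[1]),
        kBT_pN_nm=kBT_pN_nm,
        residual_norm=float(np.sqrt(np.sum(res**2))),
        persistence_se=float(ses[0]),
        contour_se=float(ses[1]),
    )


def displacement_to_nt(delta_nm: float | np.ndarray, geometry: SubstrateGeometry):
    """Signed bead displacement (nm) -> signed enzymatic progress (nt/bp).

    Positive output means net forward activity regardless of whether the
    substrate lengthens or shortens.
    """
    return geometry.direction_sign * np.asarray(delta_nm, dtype=float) * geometry.nt_per_nm


def nt_to_displacement(delta_nt: float | np.ndarray, geometry: SubstrateGeometry):
    """Exact inverse of :func:`displacement_to_nt`."""
    return geometry.direction_sign * np.asarray(delta_nt, dtype=float) / geometry.nt_per_nm


def conversion_factor_from_wlc(
    ss_fit: WLCFit, ds_fit: WLCFit, force_pN: float, nt_total: float
) -> float:
    """Derive an nt/nm factor from fitted ss and ds force-extension curves.

    The factor is the number of nucleotides converted per nm of length change
    at the working force: nt_total / |x_ds(F) - x_ss(F)|.  Optional alternative
    to the configured constant.
    """
    x_ss = wlc_extension(force_pN, ss_fit.persistence_nm, ss_fit.contour_nm, ss_fit.kBT_pN_nm)
    x_ds = wlc_extension(force_pN, ds_fit.persistence_nm, ds_fit.contour_nm, ds_fit.kBT_pN_nm)
    gap = abs(x_ds - x_ss)
    if gap == 0:
        raise DegenerateDataError("ss and ds curves coincide at the working force")
    return nt_total / gap
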