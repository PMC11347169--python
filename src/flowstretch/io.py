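"""Trace containers and plain-text tabular IO.

A :class:`Trace` is one molecule's bead position sampled on a strictly uniform
time grid (2 Hz by default).  Trace tables are long-format CSV with columns
``trace_id, time_s, position_nm, position_bp`` (at least one position column
must be present; its name declares the unit).  Readers validate rather than
repair: non-uniform grids and malformed rows are rejected with the offending
row named.  Gaps must be explicit NaN rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import SubstrateGeometry, GEOMETRIES
from .errors import ValidationError

DEFAULT_ACQUISITION_HZ = 2.0
_GRID_TOL = 1e-9


@dataclass
class Trace:
    """Bead position time series for one DNA molecule.

    ``position_nm`` is the raw displacement; ``position_bp`` the same series
    converted to base pairs / nucleotides (unsigned conversion |nm| * nt_per_nm;
    the geometry's direction sign is applied at segmentation time).
    """

    trace_id: str
    time_s: np.ndarray
    position_bp: np.ndarray | None = None
    position_nm: np.ndarray | None = None
    geometry_name: str | None = None
    force_pN: float = 2.6
    acquisition_hz: float = DEFAULT_ACQUISITION_HZ

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.position_bp is not None:
            self.position_bp = np.asarray(self.position_bp, dtype=float)
        if self.position_nm is not None:
            self.position_nm = np.asarray(self.position_nm, dtype=float)
        if self.position_bp is None and self.position_nm is None:
            raise ValidationError(
                f"trace {self.trace_id}: needs position_bp and/or position_nm"
            )
        n = self.time_s.size
        for name in ("position_bp", "position_nm"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValidationError(
                    f"trace {self.trace_id}: {name} length {arr.size} != time length {n}"
                )
        if n < 2:
            raise ValidationError(f"trace {self.trace_id}: needs at least 2 samples")
        dt = np.diff(self.time_s)
        step = 1.0 / self.acquisition_hz
        bad = np.nonzero(np.abs(dt - step) > _GRID_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"trace {self.trace_id}: non-uniform time grid at sample {bad[0] + 1} "
                f"(step {dt[bad[0]]:g} s, expected {step:g} s)"
            )

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def geometry(self) -> SubstrateGeometry | None:
        if self.geometry_name is None:
            return None
        return GEOMETRIES[self.geometry_name]


def attach_bp(trace: Trace, geometry: SubstrateGeometry) -> Trace:
    """Fill ``position_bp`` from ``position_nm`` using the geometry's factor.

    Uses the unsigned conversion (bp = nm * nt_per_nm) so the bp series keeps
    the displacement's sign convention; segmentation applies direction_sign.
    """
    if trace.position_nm is None:
        raise ValidationError(f"trace {trace.trace_id}: has no position_nm to convert")
    trace.position_bp = trace.position_nm * geometry.nt_per_nm
    trace.geometry_name = geometry.name
    return trace


def read_traces(path, geometry: SubstrateGeometry | None = None) -> list[Trace]:
    """Read a long-format trace table (CSV) into a list of traces.

    If only ``position_nm`` is present and a geometry is given, the bp series
    is attached via the geometry's conversion factor.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"trace_id", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    has_bp = "position_bp" in df.columns
    has_nm = "position_nm" in df.columns
    if not has_bp and not has_nm:
        raise ValidationError(
            f"{path}: needs a position_bp or position_nm column (unit declaration)"
        )
    if df.empty:
        raise ValidationError(f"{path}: no traces")
    for col in ("time_s", "position_bp", "position_nm"):
        if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise ValidationError(f"{path}: non-numeric value in {col} at line {row}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size >= 2:
            step = np.median(dt)
            bad = np.nonzero(np.abs(dt - step) > _GRID_TOL)[0]
            if bad.size:
                line = int(grp.index[bad[0] + 1]) + 2
                raise ValidationError(
                    f"{path}: trace {tid}: non-uniform time grid at line {line}"
                )
            hz = 1.0 / step
        else:
            hz = DEFAULT_ACQUISITION_HZ
        tr = Trace(
            trace_id=str(tid),
            time_s=t,
            position_bp=grp["position_bp"].to_numpy(float) if has_bp else None,
            position_nm=grp["position_nm"].to_numpy(float) if has_nm else None,
            acquisition_hz=hz,
        )
        if tr.position_bp is None and geometry is not None:
            attach_bp(tr, geometry)
        traces.append(tr)
    if not traces:
        raise ValidationError(f"{path}: no traces")
    return traces


def write_traces(path, traces: Iterable[Trace]) -> None:
    """Write traces as a long-format CSV (lossless full-precision roundtrip)."""
    frames = []
    for tr in traces:
        d = {"trace_id": tr.trace_id, "time_s": tr.time_s}
        if tr.position_nm is not None:
            d["position_nm"] = tr.position_nm
        if tr.position_bp is not None:
            d["position_bp"] = tr.position_bp
        frames.append(pd.DataFrame(d))
    if not frames:
        raise ValidationError("no traces to write")
    # default float formatting is shortest-roundtrip repr: lossless
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_segments(path, segments_by_trace: dict[str, Sequence]) -> None:
    """Write a segments table: trace_id, kind, t_start_s, t_end_s, delta_bp, rate_bp_s, r2."""
    rows = []
    for tid, segs in segments_by_trace.items():
        for s in segs:
            rows.append(
                {
                    "trace_id": tid,
                    "kind": s.kind,
                    "t_start_s": s.t_start_s,
                    "t_end_s": s.t_end_s,
                    "delta_bp": s.delta_bp,
                    "rate_bp_s": s.rate_bp_s,
                    "r2": s.r2,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_segments(path) -> dict[str, list]:
    """Read a segments table back into per-trace Segment lists."""
    from .segmentation import Segment

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.trace_id), []).append(
            Segment(
                kind=row.kind,
                t_start_s=float(row.t_start_s),
                t_end_s=float(row.t_end_s),
                delta_bp=float(row.delta_bp),
                rate_bp_s=float(row.rate_bp_s),
                r2=float(row.r2),
            )
        )
    return out


def write_summary(path, summary: dict) -> None:
    """Flat key=value text report (machine-readable)."""
    with open(path, "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}={val}\n")
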