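"""Waveform containers and geometric conversions.

The raw observable of a beating axoneme is its tracked centerline
``r(s, t)``; all downstream analysis runs on the tangent angle
``psi(s, t)`` — the angle of the centerline tangent with respect to the
horizontal lab axis at arc length ``s`` (μm, 0 at the base, increasing
tip-ward) and time ``t``.  Bending of the axoneme is produced by relative
sliding of the two filaments of the planar model, which is slaved to the
tangent angle:

    Delta(s, t) = Delta_b(t) + a * [psi(s, t) - psi(0, t)]

with ``a`` the filament spacing and ``Delta_b`` the sliding allowed at the
base.  The sign convention is such that a positive dynein force density
produces negative curvature.

File dialect
------------
Angle tables are UTF-8 delimited text with a header ``time_s, s_um_1..s_um_N``
and one row per frame; centerline tables use ``time_s, x1, y1, ..., xN, yN``
(μm).  A JSON sidecar next to the table (same stem, ``.json`` suffix) carries
``{"frame_rate", "length_L", "pixel_size"}`` plus any generator ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d

from .errors import FormatError, GeometryError

__all__ = [
    "TangentAngleSeries",
    "TrackedCenterline",
    "SlidingField",
    "load_waveform",
    "write_waveform",
    "centerline_to_angles",
    "angles_to_centerline",
    "sliding_from_angles",
]


@dataclass
class TangentAngleSeries:
    """Tangent angles ``psi[frame, arc_position]`` in radians.

    ``arc_positions`` are equally spaced in [0, L] (μm); ``frame_rate`` is in
    Hz.  Angles are stored unwrapped (no 2π jumps along either axis).
    """

    psi: np.ndarray
    arc_positions: np.ndarray
    frame_rate: float
    length_L: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        if self.psi.ndim != 2:
            raise FormatError("psi must be 2-D (frames x arc positions)")
        if self.arc_positions.size < 5:
            raise FormatError("need at least 5 arc positions")
        if self.psi.shape[1] != self.arc_positions.size:
            raise FormatError("psi columns must match arc_positions")
        if not np.all(np.isfinite(self.arc_positions)):
            raise FormatError("non-finite arc positions")
        d = np.diff(self.arc_positions)
        if np.any(d <= 0):
            raise FormatError("arc_positions must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise FormatError("arc_positions must be equally spaced")
        if not np.all(np.isfinite(self.psi)):
            i, j = np.argwhere(~np.isfinite(self.psi))[0]
            raise FormatError(
                f"non-finite tangent angle at frame {i}, arc position {j}"
            )
        if not (self.frame_rate > 0 and self.length_L > 0):
            raise FormatError("frame_rate and length_L must be positive")

    @property
    def n_frames(self) -> int:
        return self.psi.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class TrackedCenterline:
    """Per-frame xy point tracks (μm), ordered base → tip."""

    times: np.ndarray
    points: np.ndarray  # (frames, n_points, 2)
    pixel_size: float = np.nan
    basal_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 2:
            raise FormatError("points must have shape (frames, n_points, 2)")
        if self.points.shape[0] != self.times.size:
            raise FormatError("times must match the number of frames")
        if self.points.shape[1] < 5:
            raise FormatError("need at least 5 tracked points per frame")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("times must be strictly increasing")
        if not np.all(np.isfinite(self.points)):
            i = int(np.argwhere(~np.isfinite(self.points))[0][0])
            j = int(np.argwhere(~np.isfinite(self.points))[0][1])
            raise FormatError(f"non-finite coordinate at frame {i}, point {j}")
        seg = np.linalg.norm(np.diff(self.points, axis=1), axis=2)
        if np.any(seg <= 0):
            i, j = np.argwhere(seg <= 0)[0]
            raise GeometryError(
                f"zero-length segment at frame {int(i)}, segment {int(j)}"
            )


@dataclass
class SlidingField:
    """Inter-filament sliding ``Delta(s, t)`` (μm) and its basal part."""

    delta: np.ndarray  # (frames, arc positions)
    delta_b: np.ndarray  # (frames,)
    spacing_a: float

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.delta_b = np.asarray(self.delta_b, dtype=float)
        if not np.allclose(self.delta[:, 0], self.delta_b, atol=1e-12):
            raise ValueError("Delta(0, t) must equal Delta_b(t)")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_waveform(path, kind: str = "angles"):
    """Read a waveform table (see module docstring for the dialect).

    Parameters
    ----------
    path : path-like
        Delimited table; a JSON sidecar with the same stem must exist for the
        ``angles`` kind (it carries frame rate and total length).
    kind : {"angles", "centerline"}

    Returns
    -------
    TangentAngleSeries or TrackedCenterline
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform table not found: {path}")
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    if kind == "angles":
        cols = [c for c in df.columns if c.startswith("s_um_")]
        if "time_s" not in df.columns or not cols:
            raise FormatError(f"{path}: expected columns time_s, s_um_1..s_um_N")
        cols = sorted(cols, key=lambda c: int(c.split("_")[-1]))
        psi = df[cols].to_numpy(dtype=float)
        if np.isnan(psi).any():
            i, j = np.argwhere(np.isnan(psi))[0]
            raise FormatError(
                f"{path}: NaN angle at frame {int(i)}, arc position {int(j)}"
            )
        t = df["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: non-monotonic time column")
        if "frame_rate" in meta:
            frame_rate = float(meta["frame_rate"])
        else:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise FormatError(f"{path}: unequal frame spacing, no frame_rate")
            frame_rate = 1.0 / dt[0]
        if "length_L" not in meta:
            raise FormatError(f"{path}: sidecar {sidecar.name} must give length_L")
        L = float(meta["length_L"])
        s = np.linspace(0.0, L, len(cols))
        return TangentAngleSeries(psi, s, frame_rate, L, meta=meta)

    if kind == "centerline":
        if "time_s" not in df.columns:
            raise FormatError(f"{path}: missing time_s column")
        n = (len(df.columns) - 1) // 2
        want = [f"{ax}{i}" for i in range(1, n + 1) for ax in ("x", "y")]
        if any(c not in df.columns for c in want):
            raise FormatError(f"{path}: expected columns x1,y1..x{n},y{n}")
        xy = df[want].to_numpy(dtype=float)
        if np.isnan(xy).any():
            i, j = np.argwhere(np.isnan(xy))[0]
            raise FormatError(
                f"{path}: NaN coordinate at frame {int(i)}, point {int(j) // 2}"
            )
        pts = xy.reshape(len(df), n, 2)
        return TrackedCenterline(
            df["time_s"].to_numpy(dtype=float),
            pts,
            pixel_size=float(meta.get("pixel_size", np.nan)),
            meta=meta,
        )

    raise ValueError(f"unknown kind {kind!r}")


def write_waveform(obj, path) -> Path:
    """Write a series/track back to the dialect ``load_waveform`` reads.

    Returns the path of the JSON sidecar written next to the table.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, TangentAngleSeries):
        cols = {f"s_um_{j + 1}": obj.psi[:, j] for j in range(obj.psi.shape[1])}
        df = pd.DataFrame({"time_s": obj.times, **cols})
        meta = {
            **obj.meta,
            "frame_rate": obj.frame_rate,
            "length_L": obj.length_L,
        }
    elif isinstance(obj, TrackedCenterline):
        n = obj.points.shape[1]
        data = {"time_s": obj.times}
        for i in range(n):
            data[f"x{i + 1}"] = obj.points[:, i, 0]
            data[f"y{i + 1}"] = obj.points[:, i, 1]
        df = pd.DataFrame(data)
        meta = {**obj.meta, "pixel_size": obj.pixel_size}
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=1, default=float))
    return sidecar


def _frame_angles(pts: np.ndarray, n_points: int, oversample: int = 10):
    """Spline one frame and return (total arc length, tangent angles at
    n_points equally spaced arc lengths)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg <= 0):
        raise GeometryError("degenerate frame: zero-length segment")
    u = np.concatenate([[0.0], np.cumsum(seg)])
    # cubic interpolating spline; not-a-knot ends keep full cubic accuracy at
    # the tips (natural ends would force zero end curvature and bias the
    # basal tangent of a curved axoneme by ~0.1 rad)
    sx = CubicSpline(u, pts[:, 0], bc_type="not-a-knot")
    sy = CubicSpline(u, pts[:, 1], bc_type="not-a-knot")
    uu = np.linspace(0.0, u[-1], oversample * (len(pts) - 1) + 1)
    fine = np.column_stack([sx(uu), sy(uu)])
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(fine, axis=0), axis=1))]
    )
    total = arc[-1]
    u_of_s = interp1d(arc, uu, kind="linear", assume_sorted=True)
    targets = np.linspace(0.0, total, n_points)
    ut = u_of_s(targets)
    psi = np.unwrap(np.arctan2(sy(ut, 1), sx(ut, 1)))
    return total, psi


def centerline_to_angles(track: TrackedCenterline, n_points: int = 20) -> TangentAngleSeries:
    """Convert tracked xy points to an unwrapped tangent-angle series.

    Each frame is fitted with an interpolating cubic spline (natural end
    conditions), arc-length parameterized by cumulative chord length on a
    10x-oversampled curve, and resampled at ``n_points`` equally spaced arc
    lengths.  ``length_L`` is the mean total arc length over frames.  Angles
    are unwrapped first along ``s`` within each frame, then along ``t`` at
    fixed ``s`` (the beat is continuous in both variables).
    """
    lengths = np.empty(track.points.shape[0])
    psi = np.empty((track.points.shape[0], n_points))
    for i, pts in enumerate(track.points):
        lengths[i], psi[i] = _frame_angles(pts, n_points)
    psi = np.unwrap(psi, axis=0)
    L = float(lengths.mean())
    dt = np.diff(track.times)
    frame_rate = 1.0 / float(dt.mean()) if dt.size else 1.0
    return TangentAngleSeries(
        psi, np.linspace(0.0, L, n_points), frame_rate, L, meta=dict(track.meta)
    )


def angles_to_centerline(psi_of_s: np.ndarray, origin=(0.0, 0.0), L: float | None = None,
                         arc_positions: np.ndarray | None = None) -> np.ndarray:
    """Integrate an angle profile to xy positions.

    r(s) = origin + ∫₀ˢ (cos psi, sin psi) ds', evaluated by composite
    trapezoid on the given grid (grid-exact inverse of the resampling in
    :func:`centerline_to_angles`).
    """
    psi_of_s = np.asarray(psi_of_s, dtype=float)
    if arc_positions is None:
        if L is None:
            raise ValueError("give either arc_positions or L")
        arc_positions = np.linspace(0.0, L, psi_of_s.shape[-1])
    arc_positions = np.asarray(arc_positions, dtype=float)
    if np.any(np.diff(arc_positions) <= 0):
        raise ValueError("arc grid must be strictly increasing")
    tx, ty = np.cos(psi_of_s), np.sin(psi_of_s)
    ds = np.diff(arc_positions)
    x = np.concatenate([[0.0], np.cumsum(0.5 * ds * (tx[..., 1:] + tx[..., :-1]), -1)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * ds * (ty[..., 1:] + ty[..., :-1]), -1)])
    out = np.stack([x, y], axis=-1)
    return out + np.asarray(origin, dtype=float)


def sliding_from_angles(series: TangentAngleSeries, a: float,
                        delta_b: np.ndarray | float = 0.0) -> SlidingField:
    """Inter-filament sliding from the tangent angle.

    Applies Delta(s,t) = Delta_b(t) + a [psi(s,t) - psi(0,t)] per frame.
    Positive dynein force density corresponds to negative curvature under the
    fixed sign convention.
    """
    if not a > 0:
        raise ValueError("filament spacing a must be positive")
    db = np.broadcast_to(np.asarray(delta_b, dtype=float), (series.n_frames,))
    delta = db[:, None] + a * (series.psi - series.psi[:, :1])
    return SlidingField(delta, db.copy(), a)
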