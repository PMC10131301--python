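"""Multilateration of 3D source positions from TOADs, with residual-based
error assessment for overdetermined arrays, position filtering, track
construction and bat-pass counting.

A source at ``x`` predicts, for each non-reference microphone ``i``,

    toad_i(x) = (||x - m_i|| - ||x - m_ref||) / c

assuming isotropic spherical spreading at speed of sound ``c``.  The
position estimate minimises the sum of squared differences between observed
and predicted TOADs.  With more than four microphones the residuals carry
information about the localisation uncertainty, which is decomposed into a
radial component (along the line from the array centre to the position) and
a tangential component (in the plane perpendicular to that line), plus the
maximum per-microphone TOAD discrepancy expressed as a distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .acoustics import MicArray, ToadSet

__all__ = [
    "Position3D",
    "FlightTrack",
    "speed_of_sound",
    "theoretical_toads",
    "localise",
    "assess_errors",
    "filter_positions",
    "build_tracks",
    "count_bat_passes",
    "positions_to_frame",
    "save_positions_csv",
    "load_positions_csv",
]

DEFAULT_C = 343.0


def speed_of_sound(temperature_c: float | None = None) -> float:
    """Speed of sound in air (m/s); 343.0 by default, or from temperature."""
    if temperature_c is None:
        return DEFAULT_C
    return 331.3 * np.sqrt(1.0 + temperature_c / 273.15)


@dataclass
class Position3D:
    """A localised call position with its uncertainty estimates (metres)."""

    xyz: np.ndarray
    time: float
    radial_error: float = np.nan
    tangential_error: float = np.nan
    max_toad_error: float = np.nan
    residual_rms: float = np.nan
    n_mics_used: int = 0
    valid: bool = True
    guild_label: str | None = None
    frame: str = "array"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("xyz must be a 3-vector")

    @property
    def range_from_origin(self) -> float:
        return float(np.linalg.norm(self.xyz))


@dataclass
class FlightTrack:
    """A time-ordered chain of positions attributed to one continuous pass."""

    positions: list[Position3D]
    track_id: int

    def __post_init__(self) -> None:
        times = [p.time for p in self.positions]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


# ----------------------------------------------------------------------------
# Forward model


def theoretical_toads(xyz: np.ndarray, array: MicArray, c: float = DEFAULT_C) -> np.ndarray:
    """Predicted TOADs (s) of a source at ``xyz``, one per non-reference mic."""
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    xyz = np.asarray(xyz, dtype=float)
    d = np.linalg.norm(array.mic_positions - xyz, axis=1)
    return (d[array.non_reference_indices] - d[array.reference_index]) / c


def _toad_jacobian(xyz: np.ndarray, array: MicArray, c: float, rows: np.ndarray) -> np.ndarray:
    """d toad_i / d xyz for the selected non-reference rows (unit: s/m)."""
    diffs = xyz - array.mic_positions  # (8, 3)
    dists = np.linalg.norm(diffs, axis=1)
    dists = np.maximum(dists, 1e-12)
    units = diffs / dists[:, None]
    ref_u = units[array.reference_index]
    idx = array.non_reference_indices[rows]
    return (units[idx] - ref_u) / c


def _multistart_grid(array: MicArray, n_dirs: int = 26, radii=(2.0, 5.0, 10.0, 20.0, 40.0)):
    """Deterministic coarse grid: Fibonacci-spiral hemisphere directions × radii."""
    k = np.arange(n_dirs)
    # golden-angle spiral over the upper hemisphere (z >= 0)
    z = k / max(n_dirs - 1, 1)  # 0..1
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r_xy = np.sqrt(np.clip(1 - z**2, 0, 1))
    dirs = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    pts = (np.asarray(radii)[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
    return pts + array.centre


def localise(
    toads: ToadSet,
    array: MicArray,
    c: float = DEFAULT_C,
    max_residual_rms: float = 1e-4,
    n_polish: int = 4,
) -> Position3D:
    """Least-squares multilateration of one call.

    The observed-minus-predicted TOAD residual norm is evaluated on a coarse
    multi-start grid over the 2-40 m hemisphere; the best ``n_polish`` starts
    are refined with damped least squares and the lowest-residual solution
    wins.  Deterministic given its inputs.

    Raises ``ValueError`` with fewer than 4 valid microphones (including the
    reference); flags the result invalid if the residual RMS exceeds
    ``max_residual_rms`` seconds (non-physical TOAD sets, degenerate loci).
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    valid = toads.valid
    n_used = int(valid.sum()) + 1  # + reference
    if n_used < 4:
        raise ValueError(f"need >= 4 valid microphones, got {n_used}")
    obs = toads.toads[valid]
    rows = np.flatnonzero(valid)

    def residuals(x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(array.mic_positions - x, axis=1)
        pred = (d[array.non_reference_indices] - d[array.reference_index]) / c
        return pred[rows] - obs

    def jac(x: np.ndarray) -> np.ndarray:
        return _toad_jacobian(x, array, c, rows)

    starts = _multistart_grid(array)
    # vectorised residual norms over all starts
    d_all = np.linalg.norm(starts[:, None, :] - array.mic_positions[None, :, :], axis=2)
    pred_all = (
        d_all[:, array.non_reference_indices] - d_all[:, [array.reference_index]]
    ) / c
    costs = ((pred_all[:, rows] - obs) ** 2).sum(axis=1)
    order = np.argsort(costs)[:n_polish]

    best_x, best_cost = None, np.inf
    for i in order:
        sol = least_squares(
            residuals, starts[i], jac=jac, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=200
        )
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x
    res = residuals(best_x)
    rms = float(np.sqrt(np.mean(res**2)))
    pos = Position3D(
        xyz=best_x,
        time=toads.detection_time,
        residual_rms=rms,
        n_mics_used=n_used,
        valid=rms <= max_residual_rms and np.all(np.isfinite(best_x)),
    )
    return pos


# ----------------------------------------------------------------------------
# Error assessment


def assess_errors(
    pos: Position3D,
    toads: ToadSet,
    array: MicArray,
    c: float = DEFAULT_C,
) -> tuple[float, float, float]:
    """Radial, tangential and max-TOAD distance errors (metres) at a solution.

    Linearised error propagation: with Jacobian J of the predicted TOADs
    w.r.t. position and residual variance s² = SSR/(n-3), the position
    covariance is C = s² (JᵀJ)⁻¹.  The radial error is the 1-sigma extent of
    C along the unit vector r̂ from the array centre to the position; the
    tangential error is the root of the covariance trace projected onto the
    plane perpendicular to r̂.  The max-TOAD distance error is
    c·max_i |observed_i - predicted_i|.

    Requires redundancy: with exactly 4 microphones the residuals vanish by
    construction and the errors are undefined (position flagged
    unassessable).  Updates ``pos`` in place and returns the triple.
    """
    rows = np.flatnonzero(toads.valid)
    n_obs = len(rows)
    if pos.n_mics_used <= 4 or n_obs <= 3:
        pos.valid = False
        pos.radial_error = pos.tangential_error = pos.max_toad_error = np.nan
        return (np.nan, np.nan, np.nan)

    pred = theoretical_toads(pos.xyz, array, c)
    resid = toads.toads[rows] - pred[rows]
    s2 = float(resid @ resid) / (n_obs - 3)
    J = _toad_jacobian(pos.xyz, array, c, rows)
    jtj = J.T @ J
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        pos.valid = False
        return (np.nan, np.nan, np.nan)
    if np.linalg.cond(jtj) > 1e14:
        pos.valid = False
        return (np.nan, np.nan, np.nan)

    r = pos.xyz - array.centre
    rn = np.linalg.norm(r)
    r_hat = r / rn if rn > 0 else np.array([0.0, 0.0, 1.0])
    radial = float(np.sqrt(max(r_hat @ cov @ r_hat, 0.0)))
    proj = np.eye(3) - np.outer(r_hat, r_hat)
    tangential = float(np.sqrt(max(np.trace(proj @ cov @ proj), 0.0)))
    max_toad = float(c * np.abs(resid).max())

    pos.radial_error = radial
    pos.tangential_error = tangential
    pos.max_toad_error = max_toad
    return (radial, tangential, max_toad)


# ----------------------------------------------------------------------------
# Filtering, tracks, passes


def filter_positions(
    positions: list[Position3D],
    min_range: float = 2.0,
    max_error: float = 0.5,
    array_centre: np.ndarray | None = None,
) -> list[Position3D]:
    """Apply the range and error-cap rules.

    Keeps positions at least ``min_range`` metres from the array centre whose
    radial AND tangential errors are both at most ``max_error`` metres (a
    position is excluded as soon as either error exceeds the cap).  There is
    no upper range cut: distant positions from loud calls are retained.
    """
    centre = np.zeros(3) if array_centre is None else np.asarray(array_centre, float)
    kept = []
    for p in positions:
        if np.linalg.norm(p.xyz - centre) < min_range:
            continue
        if not (p.radial_error <= max_error and p.tangential_error <= max_error):
            continue
        kept.append(p)
    return kept


def build_tracks(
    positions: list[Position3D],
    max_gap: float = 1.0,
    max_speed: float = 20.0,
    min_positions: int = 3,
) -> list[FlightTrack]:
    """Greedy chaining of time-sorted positions into flight tracks.

    Each position joins the open track whose last point is spatially nearest,
    provided the time gap is at most ``max_gap`` seconds and the implied
    speed at most ``max_speed`` m/s; otherwise it opens a new track.  Tracks
    shorter than ``min_positions`` are discarded.  Track identity makes no
    claim about individual identity across gaps.
    """
    open_tracks: list[list[Position3D]] = []
    closed: list[list[Position3D]] = []
    for p in sorted(positions, key=lambda q: q.time):
        best_i, best_d = None, np.inf
        for i, tr in enumerate(open_tracks):
            last = tr[-1]
            dt = p.time - last.time
            if dt <= 0 or dt > max_gap:
                continue
            d = float(np.linalg.norm(p.xyz - last.xyz))
            if d / dt > max_speed:
                continue
            if d < best_d:
                best_i, best_d = i, d
        if best_i is None:
            open_tracks.append([p])
        else:
            open_tracks[best_i].append(p)
    closed.extend(open_tracks)
    tracks = [
        FlightTrack(positions=tr, track_id=i)
        for i, tr in enumerate(t for t in closed if len(t) >= min_positions)
    ]
    return tracks


def count_bat_passes(positions: list[Position3D], window: float = 10.0) -> int:
    """Number of ``window``-second bins (aligned to t=0) holding >= 1 position."""
    if not positions:
        return 0
    bins = {int(np.floor(p.time / window)) for p in positions}
    return len(bins)


# ----------------------------------------------------------------------------
# CSV I/O


_CSV_COLS = [
    "time",
    "x",
    "y",
    "z",
    "radial_error",
    "tangential_error",
    "max_toad_error",
    "residual_rms",
    "n_mics",
    "track_id",
    "guild_label",
]


def positions_to_frame(
    positions: list[Position3D], tracks: list[FlightTrack] | None = None
) -> pd.DataFrame:
    track_of = {}
    if tracks:
        for tr in tracks:
            for p in tr.positions:
                track_of[id(p)] = tr.track_id
    rows = []
    for p in positions:
        rows.append(
            {
                "time": p.time,
                "x": p.xyz[0],
                "y": p.xyz[1],
                "z": p.xyz[2],
                "radial_error": p.radial_error,
                "tangential_error": p.tangential_error,
                "max_toad_error": p.max_toad_error,
                "residual_rms": p.residual_rms,
                "n_mics": p.n_mics_used,
                "track_id": track_of.get(id(p), -1),
                "guild_label": p.guild_label or "",
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLS)


def save_positions_csv(
    path: str | Path,
    positions: list[Position3D],
    tracks: list[FlightTrack] | None = None,
    frame: str = "array",
) -> None:
    """Positions as CSV with a ``# frame:`` header comment recording the frame."""
    df = positions_to_frame(positions, tracks)
    with open(path, "w") as fh:
        fh.write(f"# frame: {frame}\n")
        df.to_csv(fh, index=False)


def load_positions_csv(path: str | Path) -> tuple[list[Position3D], str]:
    with open(path) as fh:
        first = fh.readline()
        frame = first.split("frame:")[1].strip() if first.startswith("#") else "array"
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh)
    positions = []
    for _, r in df.iterrows():
        positions.append(
            Position3D(
                xyz=np.array([r["x"], r["y"], r["z"]]),
                time=float(r["time"]),
                radial_error=float(r["radial_error"]),
                tangential_error=float(r["tangential_error"]),
                max_toad_error=float(r["max_toad_error"]),
                residual_rms=float(r.get("residual_rms", np.nan)),
                n_mics_used=int(r["n_mics"]),
                guild_label=(str(r["guild_label"]) or None)
                if pd.notna(r["guild_label"]) and str(r["guild_label"])
                else None,
                frame=frame,
            )
        )
    return positions, frame
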