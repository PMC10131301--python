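"""Distance-to-structure metrics and corridor / guild comparison statistics.

Each localised bat position gets its Euclidean distance to the nearest
vegetation voxel centre (a KD-tree query, identical to the brute-force
minimum) and its distance to the lamppost (horizontal distance to the
vertical lamppost axis by default, or 3D distance to the lamp head).
Groups of positions — e.g. narrow vs wide flight corridors, or bat guilds —
are compared with Welch's unequal-variance t-test and the two-sample
Kolmogorov–Smirnov statistic, both implemented from their defining formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import kstwobign
from scipy.stats import t as t_dist
from shapely.geometry import Point, Polygon

__all__ = [
    "DistanceRecord",
    "ComparisonResult",
    "distance_to_vegetation",
    "distance_to_lamppost",
    "welch_t",
    "ks_two_sample",
    "corridor_comparison",
    "assign_corridors",
    "distance_records",
]


@dataclass
class DistanceRecord:
    """Per-position structure distances (metres)."""

    time: float
    xyz: np.ndarray
    dist_vegetation: float
    dist_lamppost: float
    corridor_label: str | None = None
    guild_label: str | None = None


@dataclass
class ComparisonResult:
    """Two-group comparison of a distance metric."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    welch_t: float
    welch_df: float
    welch_p: float
    ks_d: float
    ks_p: float


def distance_to_vegetation(positions_xyz: np.ndarray, veg_centres: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance (m) from each position to a vegetation voxel
    centre; positions and voxels must share the LiDAR frame."""
    positions_xyz = np.asarray(positions_xyz, float).reshape(-1, 3)
    veg_centres = np.asarray(veg_centres, float).reshape(-1, 3)
    if len(veg_centres) == 0:
        raise ValueError("no vegetation voxels: distances are undefined")
    if len(positions_xyz) == 0:
        return np.empty(0)
    tree = cKDTree(veg_centres)
    d, _ = tree.query(positions_xyz, k=1)
    return np.asarray(d, float)


def distance_to_lamppost(
    positions_xyz: np.ndarray,
    lamppost_base: np.ndarray,
    mode: str = "horizontal",
    lamp_height: float = 4.0,
) -> np.ndarray:
    """Distance (m) from each position to the lamppost.

    ``horizontal`` (default): XY distance to the lamppost's vertical axis.
    ``head3d``: 3D distance to the lamp head at ``lamp_height`` above base.
    """
    positions_xyz = np.asarray(positions_xyz, float).reshape(-1, 3)
    base = np.asarray(lamppost_base, float).reshape(3)
    if mode == "horizontal":
        return np.linalg.norm(positions_xyz[:, :2] - base[:2], axis=1)
    if mode == "head3d":
        head = base + np.array([0.0, 0.0, lamp_height])
        return np.linalg.norm(positions_xyz - head, axis=1)
    raise ValueError(f"unknown lamppost distance mode: {mode!r}")


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic with Welch–Satterthwaite degrees
    of freedom and two-sided p-value.

        t  = (ā − b̄) / sqrt(s_a²/n_a + s_b²/n_b)
        df = (s_a²/n_a + s_b²/n_b)² / [ (s_a²/n_a)²/(n_a−1) + (s_b²/n_b)²/(n_b−1) ]
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate (zero-variance) samples")
    qa, qb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(qa + qb)
    df = (qa + qb) ** 2 / (qa**2 / (len(a) - 1) + qb**2 / (len(b) - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), p


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic D = sup|ECDF_a − ECDF_b|,
    evaluated at the pooled sample points, with the asymptotic p-value."""
    a = np.sort(np.asarray(a, float).ravel())
    b = np.sort(np.asarray(b, float).ravel())
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    cdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    d = float(np.abs(cdf_a - cdf_b).max())
    en = math.sqrt(len(a) * len(b) / (len(a) + len(b)))
    p = float(kstwobign.sf((en + 0.12 + 0.11 / en) * d))
    return d, min(max(p, 0.0), 1.0)


def assign_corridors(
    positions_xyz: np.ndarray, corridors: dict[str, list[tuple[float, float]]]
) -> list[str | None]:
    """Label each position by the corridor polygon (XY vertices) containing
    its horizontal projection; None when outside every polygon."""
    polys = {name: Polygon(verts) for name, verts in corridors.items()}
    labels: list[str | None] = []
    for p in np.asarray(positions_xyz, float).reshape(-1, 3):
        pt = Point(p[0], p[1])
        hit = None
        for name, poly in polys.items():
            if poly.covers(pt):
                hit = name
                break
        labels.append(hit)
    return labels


def distance_records(
    positions,
    veg_centres: np.ndarray,
    lamppost_base: np.ndarray,
    corridors: dict[str, list[tuple[float, float]]] | None = None,
    lamppost_mode: str = "horizontal",
    lamp_height: float = 4.0,
) -> pd.DataFrame:
    """Tidy per-position table of structure distances and corridor labels."""
    xyz = np.array([p.xyz for p in positions]).reshape(-1, 3)
    times = [p.time for p in positions]
    guilds = [p.guild_label for p in positions]
    dv = distance_to_vegetation(xyz, veg_centres) if len(xyz) else np.empty(0)
    dl = (
        distance_to_lamppost(xyz, lamppost_base, lamppost_mode, lamp_height)
        if len(xyz)
        else np.empty(0)
    )
    labels = assign_corridors(xyz, corridors) if corridors and len(xyz) else [None] * len(xyz)
    return pd.DataFrame(
        {
            "time": times,
            "x": xyz[:, 0] if len(xyz) else [],
            "y": xyz[:, 1] if len(xyz) else [],
            "z": xyz[:, 2] if len(xyz) else [],
            "dist_vegetation": dv,
            "dist_lamppost": dl,
            "corridor_label": labels,
            "guild_label": guilds,
        }
    )


def _summary(df: pd.DataFrame) -> dict:
    return {
        "n": int(len(df)),
        "mean_dist_vegetation": float(df["dist_vegetation"].mean()) if len(df) else np.nan,
        "median_dist_vegetation": float(df["dist_vegetation"].median()) if len(df) else np.nan,
        "mean_dist_lamppost": float(df["dist_lamppost"].mean()) if len(df) else np.nan,
        "median_dist_lamppost": float(df["dist_lamppost"].median()) if len(df) else np.nan,
    }


def corridor_comparison(records: pd.DataFrame) -> dict:
    """Per-corridor distance summaries plus pairwise Welch-t / KS comparisons.

    For every labelled corridor: n, mean and median distances to vegetation
    and lamppost, and the within-corridor vegetation-vs-lamppost contrast.
    For every corridor pair and each metric: Welch t (with df, p) and KS D
    (with p).  Groups with fewer than 2 positions are summarised but excluded
    from the tests with a warning.
    """
    labelled = records[records["corridor_label"].notna()]
    groups = {name: g for name, g in labelled.groupby("corridor_label")}
    if len(groups) == 0:
        raise ValueError("no labelled corridor groups")
    out: dict = {"groups": {}, "pairwise": [], "within_group": []}
    testable = {}
    for name, g in groups.items():
        out["groups"][name] = _summary(g)
        if len(g) >= 2:
            testable[name] = g
        else:
            warnings.warn(f"corridor {name!r} has n < 2; excluded from tests", stacklevel=2)
    for name, g in testable.items():
        try:
            t, df_, p = welch_t(g["dist_vegetation"], g["dist_lamppost"])
            d, kp = ks_two_sample(g["dist_vegetation"], g["dist_lamppost"])
            out["within_group"].append(
                {
                    "group": name,
                    "contrast": "vegetation_vs_lamppost",
                    "welch_t": t,
                    "welch_df": df_,
                    "welch_p": p,
                    "ks_d": d,
                    "ks_p": kp,
                }
            )
        except ValueError:
            pass
    names = sorted(testable)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            for metric in ("dist_vegetation", "dist_lamppost"):
                a = testable[na][metric].to_numpy()
                b = testable[nb][metric].to_numpy()
                t, df_, p = welch_t(a, b)
                d, kp = ks_two_sample(a, b)
                out["pairwise"].append(
                    ComparisonResult(
                        group_a=na,
                        group_b=nb,
                        n_a=len(a),
                        n_b=len(b),
                        mean_a=float(a.mean()),
                        mean_b=float(b.mean()),
                        welch_t=t,
                        welch_df=df_,
                        welch_p=p,
                        ks_d=d,
                        ks_p=kp,
                    ).__dict__
                    | {"metric": metric}
                )
    return out
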