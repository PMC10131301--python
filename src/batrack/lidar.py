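"""Terrestrial-LiDAR point-cloud handling: ingestion, pulse-deviation
filtering, voxelisation and vegetation-voxel extraction.

Pulse deviation is a per-return waveform-quality attribute; high values mark
semi-returns, soft targets or noise and are removed before analysis.  The
filtered cloud is binned into cubic voxels (default 20 cm edge) whose point
counts proxy local vegetation density; voxels reaching the occupancy
threshold (default 10 points) are "vegetation voxels".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PointCloud",
    "VoxelGrid",
    "load_point_cloud",
    "save_point_cloud",
    "filter_deviation",
    "voxelise",
    "vegetation_voxels",
    "save_voxel_grid",
    "load_voxel_grid",
]

DEFAULT_VOXEL_EDGE = 0.20
DEFAULT_MAX_DEVIATION = 15.0
DEFAULT_MIN_VEG_COUNT = 10


@dataclass
class PointCloud:
    points: np.ndarray  # (N, 3) metres
    deviation: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.deviation is not None:
            self.deviation = np.asarray(self.deviation, dtype=float).ravel()
            if len(self.deviation) != len(self.points):
                raise ValueError("deviation length must match point count")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VoxelGrid:
    """Sparse cubic-voxel occupancy grid: index triple -> point count."""

    origin: np.ndarray
    edge: float
    counts: dict[tuple[int, int, int], int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.edge <= 0:
            raise ValueError("voxel edge must be positive")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("sparse counts must be >= 1")

    @property
    def n_points(self) -> int:
        return sum(self.counts.values())

    def centres(self, indices=None) -> np.ndarray:
        """Voxel centre coordinates (metres) for the given (or all) indices."""
        if indices is None:
            indices = list(self.counts)
        if len(indices) == 0:
            return np.empty((0, 3))
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx + 0.5) * self.edge


def load_point_cloud(path: str | Path, fmt: str = "xyz") -> PointCloud:
    """Read an XYZ[,deviation] CSV into a point cloud (coordinates in metres).

    The file must have columns x, y, z and may have a ``deviation`` column
    (case-insensitive).  Malformed records raise an informative error.
    """
    path = Path(path)
    if fmt.lower() not in ("xyz", "csv"):
        raise ValueError(f"unknown point-cloud format: {fmt!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise IOError(f"cannot parse point cloud {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    for ax in "xyz":
        if ax not in cols:
            raise IOError(f"{path}: missing coordinate column {ax!r}")
    pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(pts), axis=1)
    if bad.any():
        raise IOError(f"{path}: non-finite coordinates at data row {int(np.flatnonzero(bad)[0])}")
    dev = df[cols["deviation"]].to_numpy(dtype=float) if "deviation" in cols else None
    return PointCloud(points=pts, deviation=dev, source_id=path.stem)


def save_point_cloud(path: str | Path, cloud: PointCloud) -> None:
    df = pd.DataFrame(cloud.points, columns=["x", "y", "z"])
    if cloud.deviation is not None:
        df["deviation"] = cloud.deviation
    df.to_csv(path, index=False, float_format="%.6f")


def filter_deviation(cloud: PointCloud, max_dev: float = DEFAULT_MAX_DEVIATION) -> PointCloud:
    """Remove returns with pulse deviation strictly greater than ``max_dev``."""
    if cloud.deviation is None:
        raise ValueError(
            "point cloud has no pulse-deviation attribute; cannot apply deviation filter"
        )
    keep = cloud.deviation <= max_dev
    return PointCloud(
        points=cloud.points[keep], deviation=cloud.deviation[keep], source_id=cloud.source_id
    )


def voxelise(
    cloud: PointCloud,
    edge: float = DEFAULT_VOXEL_EDGE,
    origin: np.ndarray | None = None,
) -> VoxelGrid:
    """Bin points into cubic voxels with half-open cells [lo, lo + edge).

    Voxel index = floor((p - origin)/edge) per axis; a point exactly on a cell
    boundary belongs to the higher-index cell.  The default origin is the
    cloud's minimum corner snapped down to edge multiples, so binning is
    deterministic for a given cloud.  Total counts equal the point count.
    """
    if edge <= 0:
        raise ValueError("voxel edge must be positive")
    if origin is None:
        if len(cloud) == 0:
            origin = np.zeros(3)
        else:
            origin = np.floor(cloud.points.min(axis=0) / edge) * edge
    origin = np.asarray(origin, dtype=float).reshape(3)
    if len(cloud) == 0:
        return VoxelGrid(origin=origin, edge=edge, counts={})
    idx = np.floor((cloud.points - origin) / edge).astype(np.int64)
    uniq, cnt = np.unique(idx, axis=0, return_counts=True)
    counts = {tuple(map(int, u)): int(c) for u, c in zip(uniq, cnt)}
    return VoxelGrid(origin=origin, edge=edge, counts=counts)


def vegetation_voxels(grid: VoxelGrid, min_count: int = DEFAULT_MIN_VEG_COUNT) -> np.ndarray:
    """Centres (metres) of voxels holding at least ``min_count`` points."""
    idx = [k for k, v in grid.counts.items() if v >= min_count]
    return grid.centres(idx)


def save_voxel_grid(path: str | Path, grid: VoxelGrid) -> None:
    rows = [(i, j, k, c) for (i, j, k), c in sorted(grid.counts.items())]
    df = pd.DataFrame(rows, columns=["i", "j", "k", "count"])
    with open(path, "w") as fh:
        fh.write(
            f"# origin: {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f} "
            f"edge: {grid.edge:.6f}\n"
        )
        df.to_csv(fh, index=False)


def load_voxel_grid(path: str | Path) -> VoxelGrid:
    with open(path) as fh:
        header = fh.readline()
        parts = header.replace("#", "").replace("origin:", "").replace("edge:", "").split()
        origin = np.array(parts[:3], dtype=float)
        edge = float(parts[3])
        df = pd.read_csv(fh)
    counts = {
        (int(r["i"]), int(r["j"]), int(r["k"])): int(r["count"]) for _, r in df.iterrows()
    }
    return VoxelGrid(origin=origin, edge=edge, counts=counts)
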