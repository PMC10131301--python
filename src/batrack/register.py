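"""Rigid-body co-registration of the acoustic (array-frame) coordinate
system with the LiDAR (scene-frame) coordinate system.

The array frame's reference points — the four ends and the centre of the
microphone frame — are surveyed in the LiDAR cloud; the least-squares
rotation + translation (no scaling, no reflection) mapping the array-frame
points onto their LiDAR counterparts is the classic orthogonal-Procrustes /
Kabsch solution.  The post-fit RMSD is surfaced as an alignment QC metric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .positions import Position3D

__all__ = [
    "RigidTransform",
    "CorrespondenceSet",
    "fit_rigid_transform",
    "apply_transform",
    "load_correspondences_csv",
    "save_correspondences_csv",
]

RMSD_WARN_THRESHOLD = 0.05  # m


@dataclass(frozen=True)
class RigidTransform:
    """x' = R x + t with R a proper rotation (det +1, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions of the scene")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation_row_major": self.rotation.ravel().tolist(),
                    "translation_m": self.translation.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["rotation_row_major"]).reshape(3, 3),
            np.array(d["translation_m"]),
        )


@dataclass
class CorrespondenceSet:
    """Paired reference points: source (array frame) and target (LiDAR frame)."""

    source_points: np.ndarray
    target_points: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.source_points = np.asarray(self.source_points, float).reshape(-1, 3)
        self.target_points = np.asarray(self.target_points, float).reshape(-1, 3)
        if len(self.source_points) != len(self.target_points):
            raise ValueError("source and target point counts differ")
        if len(self.source_points) < 3:
            raise ValueError("at least 3 reference-point correspondences are needed")

    def __len__(self) -> int:
        return len(self.source_points)


def _is_collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def fit_rigid_transform(corr: CorrespondenceSet) -> tuple[RigidTransform, float]:
    """Least-squares rotation + translation mapping source onto target.

    Kabsch/orthogonal-Procrustes with the reflection branch excluded (the
    smallest singular direction is sign-corrected so det(R) = +1: a mirror
    would invert the scene).  Returns the transform and the post-fit RMSD in
    metres; an RMSD above 5 cm triggers an alignment-quality warning.
    """
    src, dst = corr.source_points, corr.target_points
    if _is_collinear(src):
        raise ValueError("source reference points are collinear or duplicated")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    tf = RigidTransform(R, t)
    resid = tf.apply(src) - dst
    rmsd = float(np.sqrt((resid**2).sum(axis=1).mean()))
    if rmsd > RMSD_WARN_THRESHOLD:
        warnings.warn(
            f"registration RMSD {rmsd:.3f} m exceeds {RMSD_WARN_THRESHOLD} m; "
            "check the reference-point correspondences",
            stacklevel=2,
        )
    return tf, rmsd


def apply_transform(
    tf: RigidTransform, positions: list[Position3D], frame: str = "lidar"
) -> list[Position3D]:
    """Map positions into the target frame; rigid motion preserves the error
    fields (distances are unchanged), so they are copied through."""
    out = []
    for p in positions:
        out.append(
            Position3D(
                xyz=tf.apply(p.xyz),
                time=p.time,
                radial_error=p.radial_error,
                tangential_error=p.tangential_error,
                max_toad_error=p.max_toad_error,
                residual_rms=p.residual_rms,
                n_mics_used=p.n_mics_used,
                valid=p.valid,
                guild_label=p.guild_label,
                frame=frame,
            )
        )
    return out


def save_correspondences_csv(path: str | Path, corr: CorrespondenceSet) -> None:
    labels = corr.labels or tuple(f"p{i}" for i in range(len(corr)))
    df = pd.DataFrame(
        {
            "label": labels,
            "src_x": corr.source_points[:, 0],
            "src_y": corr.source_points[:, 1],
            "src_z": corr.source_points[:, 2],
            "dst_x": corr.target_points[:, 0],
            "dst_y": corr.target_points[:, 1],
            "dst_z": corr.target_points[:, 2],
        }
    )
    df.to_csv(path, index=False)


def load_correspondences_csv(path: str | Path) -> CorrespondenceSet:
    df = pd.read_csv(path)
    return CorrespondenceSet(
        source_points=df[["src_x", "src_y", "src_z"]].to_numpy(),
        target_points=df[["dst_x", "dst_y", "dst_z"]].to_numpy(),
        labels=tuple(df["label"].astype(str)),
    )
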