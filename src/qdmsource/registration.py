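"""Rigid alignment of duplicate acquisitions.

Duplicate field maps of the same field of view are collected after removing
and reinstalling sample and sensor, so the two sensor frames differ by an
in-plane rigid motion (rotation plus a translation of order 100 µm).
Landmarks visible in both reflected-light images (e.g. neuromelanin-bearing
neurons) provide matched point pairs from which the transform is estimated by
closed-form least squares (2-D orthogonal Procrustes with the reflection
branch rejected). Source matching downstream operates on fitted source
coordinates pushed through the point transform; map resampling exists for
visualization and difference imaging only, to keep interpolation bias out of
source positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .physics import FieldMap, SensorGeometry


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, clockwise-positive with y up) about ``center`` plus
    a translation, all in µm: p' = R (p - c) + c + t."""

    rotation: float
    translation: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)
    residual_rms: float | None = field(default=None, compare=False)

    def matrix(self) -> np.ndarray:
        th = np.radians(self.rotation)
        # clockwise-positive: +90 deg maps (1,0) -> (0,-1)
        return np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])

    def apply(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform2D":
        R = self.matrix()
        t = np.asarray(self.translation)
        c = np.asarray(self.center)
        # p = R^T (p' - c - t) + c  =>  rotation -rot about c, translation -R^T t
        return RigidTransform2D(
            rotation=-self.rotation,
            translation=tuple(-(R.T @ t)),
            center=tuple(c),
        )

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self after other: returns t with t(p) = self(other(p)), sharing
        self's center."""
        R1, R2 = other.matrix(), self.matrix()
        c1, t1 = np.asarray(other.center), np.asarray(other.translation)
        c2, t2 = np.asarray(self.center), np.asarray(self.translation)
        # self(other(p)) = R2 R1 p + R2 (b1 - c2) + c2 + t2, b1 = -R1 c1 + c1 + t1
        b1 = -R1 @ c1 + c1 + t1
        R = R2 @ R1
        offset = R2 @ (b1 - c2) + c2 + t2
        rot = float(np.degrees(np.arctan2(R[0, 1], R[0, 0])))
        trans = offset - (-R @ c2 + c2)
        return RigidTransform2D(rotation=rot, translation=tuple(trans), center=tuple(c2))

    @property
    def translation_magnitude(self) -> float:
        """Displacement at the pivot, µm (rotation contributes nothing there)."""
        return float(np.hypot(*self.translation))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation,
            "tx_um": self.translation[0],
            "ty_um": self.translation[1],
            "center_um": list(self.center),
            "residual_rms_um": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(
            rotation=d["rotation_deg"],
            translation=(d["tx_um"], d["ty_um"]),
            center=tuple(d.get("center_um", (0.0, 0.0))),
            residual_rms=d.get("residual_rms_um"),
        )


def estimate_transform(points_a, points_b, center=(0.0, 0.0)) -> RigidTransform2D:
    """Least-squares rigid transform mapping ``points_b`` onto ``points_a``.

    Points are matched by index (shared fiducial ids). Uses the closed-form
    cross-covariance (Kabsch/Procrustes) solution in 2-D, forcing the proper
    rotation branch (det = +1). Returns the transform with its per-point
    residual RMS in µm.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 matched point pairs of equal length")
    am, bm = a.mean(axis=0), b.mean(axis=0)
    H = (b - bm).T @ (a - am)
    if np.allclose(H, 0) and (np.allclose(a, a[0]) or np.allclose(b, b[0])):
        raise ValueError("degenerate fiducial configuration (coincident points)")
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    rot = float(np.degrees(np.arctan2(R[0, 1], R[0, 0])))
    c = np.asarray(center, dtype=float)
    # am = R (bm - c) + c + t
    t = am - (R @ (bm - c) + c)
    tf = RigidTransform2D(rotation=rot, translation=tuple(t), center=tuple(c))
    resid = tf.apply(b) - a
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform2D(
        rotation=tf.rotation,
        translation=tf.translation,
        center=tf.center,
        residual_rms=rms,
    )


def apply_transform_points(t: RigidTransform2D, pts) -> np.ndarray:
    """Exact rigid motion of µm coordinates; shape preserved."""
    pts_arr = np.asarray(pts, dtype=float)
    out = t.apply(pts_arr)
    return out[0] if pts_arr.ndim == 1 else out


def apply_transform_map(t: RigidTransform2D, fmap: FieldMap) -> FieldMap:
    """Resample a sensor-frame map into the reference (sample) frame.

    Output pixel at reference coordinate p takes the bilinearly interpolated
    value of the input at t^-1(p); pixels falling outside the input grid are
    flagged missing (NaN).
    """
    geom = SensorGeometry(
        pixel_size=fmap.pixel_size, n_cols=fmap.n_cols, n_rows=fmap.n_rows
    )
    xx, yy = geom.pixel_coords()
    inv = t.inverse()
    src_xy = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    row, col = geom.xy_to_rowcol(src_xy[:, 0], src_xy[:, 1])
    vals = ndimage.map_coordinates(
        fmap.values, [row, col], order=1, mode="constant", cval=np.nan
    ).reshape(fmap.values.shape)
    return fmap.copy_with(
        values=vals, frame="sample", metadata={"applied_transform": t.to_dict()}
    )


def match_fiducials(points_a, points_b, max_dist_um: float = 50.0):
    """Best-effort automatic correspondence between unlabeled fiducial sets.

    Greedy nearest-neighbor after removing the coarse translation given by
    the centroid offset; pairs farther than ``max_dist_um`` after that shift
    are dropped. Returns (matched_a, matched_b) index arrays. Intended as a
    convenience when shared ids are unavailable; curated correspondences are
    preferred.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    shift = a.mean(axis=0) - b.mean(axis=0)
    bs = b + shift
    d = np.linalg.norm(a[:, None, :] - bs[None, :, :], axis=2)
    ia, ib = [], []
    used_b: set[int] = set()
    for i in np.argsort(d.min(axis=1)):
        j = int(np.argmin(d[i]))
        if j in used_b or d[i, j] > max_dist_um:
            continue
        used_b.add(j)
        ia.append(int(i))
        ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)
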