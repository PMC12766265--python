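"""Synthetic duplicate-acquisition phantoms.

The study design images every field of view twice: between acquisitions the
diamond sensor and the sample are removed, cleaned and reinstalled, shifting
the sample frame by a rigid motion of order 100 µm. Three source populations
then behave differently:

* sample sources sit in the tissue, so their sensor-frame positions differ
  between the two maps by exactly the rigid motion;
* diamond artifacts (strain features in the NV layer) travel with the
  sensor and keep identical sensor-frame positions;
* surface contamination is removed by the cleaning step and appears in only
  one of the two maps.

The generator reproduces this structure on a configurable pixel grid,
together with fiducial marks (stand-ins for neuromelanin-bearing neurons
visible in reflected light), a connected tissue mask and i.i.d. Gaussian
pixel noise, and records complete ground truth for every source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .physics import (
    Direction,
    DipoleSource,
    FieldMap,
    MomentVector,
    SensorGeometry,
    dipole_field_at,
)
from .registration import RigidTransform2D
from .stats import sample_fisher_directions


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic acquisition pair.

    Defaults mirror the real acquisitions where stated (applied field along
    declination 0 / inclination 0, re-installation shift of order 100 µm with
    arbitrary bearing, source depths of a few µm, 1.17 µm pixels) and use a
    reduced 480 x 300 px field of view; the instrument's full 1920 x 1200 px
    grid is available by overriding ``n_cols``/``n_rows``.
    """

    n_sample_sources: int = 5
    n_artifacts: int = 5
    n_contaminants: int = 3
    moment_range: tuple[float, float] = (1e-17, 1e-14)  # A m^2, log-uniform
    depth_range: tuple[float, float] = (1.5, 6.0)  # µm below sample surface
    artifact_standoff_range: tuple[float, float] = (0.2, 1.0)  # µm
    contaminant_depth_max: float = 1.0  # µm
    direction_kappa: float = 30.0
    applied_field: Direction = field(default_factory=lambda: Direction(0.0, 0.0))
    transform_translation: float = 100.0  # µm, nominal magnitude
    transform_rotation: tuple[float, float] = (-3.0, 3.0)  # degrees, uniform
    noise_sigma: float = 5e-8  # tesla
    n_fiducials: int = 8
    fiducial_jitter: float = 0.3  # µm
    tissue_fraction: float = 0.5
    exclusion_radius: float = 15.0  # µm min source separation
    edge_buffer: float = 30.0  # µm keep-out from map edges
    pixel_size: float = 1.17  # µm
    n_cols: int = 480
    n_rows: int = 300
    nv_layer_correction: float = 1.0  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("moment_range", "depth_range", "artifact_standoff_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be ordered and positive")
        if min(self.n_sample_sources, self.n_artifacts, self.n_contaminants) < 0:
            raise ValueError("source counts must be >= 0")
        if self.direction_kappa <= 0:
            raise ValueError("direction_kappa must be > 0")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must be in (0, 1]")

    def geometry(self) -> SensorGeometry:
        return SensorGeometry(
            pixel_size=self.pixel_size,
            n_cols=self.n_cols,
            n_rows=self.n_rows,
            nv_layer_correction=self.nv_layer_correction,
        )


@dataclass(frozen=True)
class PhantomSource:
    """Ground-truth bookkeeping for one dipole in the phantom."""

    source: DipoleSource  # sample-frame (acquisition-1) coordinates
    role: str  # sample | artifact | contaminant
    host: str  # tissue | blank
    appears_in: tuple[int, ...]  # acquisition ids (1, 2) containing it
    sensor_xy_1: tuple[float, float] | None
    sensor_xy_2: tuple[float, float] | None


@dataclass
class AcquisitionPair:
    map1: FieldMap
    map2: FieldMap
    fiducials1: np.ndarray  # (n, 2) µm, sensor frame of acquisition 1
    fiducials2: np.ndarray
    true_transform: RigidTransform2D  # acquisition-2 sample frame -> 1
    truth: list[PhantomSource]
    tissue_mask: np.ndarray  # bool, acquisition-1 frame
    config: PhantomConfig


def make_tissue_mask(
    cfg: PhantomConfig, geom: SensorGeometry, rng: np.random.Generator | None = None
) -> np.ndarray:
    """A connected, blob-shaped tissue region covering ``tissue_fraction``
    of the field of view (within 1%).

    Built as a star-convex region around a random interior center whose
    radius varies smoothly with angle (a few random Fourier harmonics); the
    overall scale is bisected until the pixel-count fraction matches the
    request. A fraction of 1.0 returns the all-true mask.
    """
    frac = cfg.tissue_fraction
    if not 0 < frac <= 1:
        raise ValueError("tissue fraction must be in (0, 1]")
    if frac == 1.0:
        return np.ones((geom.n_rows, geom.n_cols), dtype=bool)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    xx, yy = geom.pixel_coords()
    w = geom.n_cols * geom.pixel_size
    h = geom.n_rows * geom.pixel_size
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(xx - cx, yy - cy)
    profile = np.ones_like(theta)
    for harmonic in (2, 3, 5):
        profile += 0.12 * rng.standard_normal() * np.cos(harmonic * theta) + (
            0.12 * rng.standard_normal() * np.sin(harmonic * theta)
        )
    profile = np.clip(profile, 0.3, None)
    n_pix = geom.n_rows * geom.n_cols
    target = frac * n_pix

    def count(scale: float) -> int:
        return int(np.count_nonzero(rr <= scale * profile))

    lo, hi = 0.0, 2.0 * np.hypot(w, h)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if count(mid) < target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    mask = rr <= scale * profile
    achieved = mask.mean()
    if abs(achieved - frac) > 0.01:
        raise RuntimeError(
            f"tissue mask fraction {achieved:.3f} missed target {frac:.3f}"
        )
    return mask


def _draw_position(
    rng: np.random.Generator,
    cfg: PhantomConfig,
    inv_transform: RigidTransform2D | None,
    occupied_1: list,
    occupied_2: list,
    in_map1: bool,
    in_map2: bool,
    max_attempts: int = 1000,
) -> tuple[float, float]:
    """Rejection-sample an acquisition-1-frame position whose image in every
    map it appears in stays ``edge_buffer`` from the borders and
    ``exclusion_radius`` from previously placed sources."""
    w = cfg.n_cols * cfg.pixel_size
    h = cfg.n_rows * cfg.pixel_size
    buf, excl = cfg.edge_buffer, cfg.exclusion_radius

    def inside(p) -> bool:
        return buf <= p[0] <= w - buf and buf <= p[1] <= h - buf

    def clear(p, occupied) -> bool:
        return all(np.hypot(p[0] - q[0], p[1] - q[1]) >= excl for q in occupied)

    for _ in range(max_attempts):
        p1 = (rng.uniform(buf, w - buf), rng.uniform(buf, h - buf))
        p2 = tuple(inv_transform.apply(p1)[0]) if inv_transform is not None else p1
        if in_map1 and not (inside(p1) and clear(p1, occupied_1)):
            continue
        if in_map2 and not (inside(p2) and clear(p2, occupied_2)):
            continue
        return p1
    raise RuntimeError("could not place source without overlap after 1000 attempts")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _uniform_sphere_direction(rng: np.random.Generator) -> Direction:
    v = rng.standard_normal(3)
    while np.linalg.norm(v) < 1e-12:
        v = rng.standard_normal(3)
    from .physics import vector_to_direction

    return vector_to_direction(v)


def make_phantom(cfg: PhantomConfig) -> AcquisitionPair:
    """Generate one duplicate-acquisition phantom with full ground truth.

    All randomness derives from ``cfg.seed``; the same config yields a
    bit-identical pair.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry()
    w = cfg.n_cols * cfg.pixel_size
    h = cfg.n_rows * cfg.pixel_size
    center = (w / 2.0, h / 2.0)

    # rigid motion between the acquisitions (acq-2 frame -> acq-1 frame)
    rot = rng.uniform(*cfg.transform_rotation)
    mag = cfg.transform_translation * rng.uniform(0.8, 1.2)
    bearing = rng.uniform(0.0, 2.0 * np.pi)
    transform = RigidTransform2D(
        rotation=rot,
        translation=(mag * np.sin(bearing), mag * np.cos(bearing)),
        center=center,
    )
    inv = transform.inverse()
    R_inv = inv.matrix()

    mask = make_tissue_mask(cfg, geom, rng)

    def host_of(p) -> str:
        row, col = geom.xy_to_rowcol(p[0], p[1])
        r, c = int(round(float(row))), int(round(float(col)))
        if 0 <= r < cfg.n_rows and 0 <= c < cfg.n_cols and mask[r, c]:
            return "tissue"
        return "blank"

    truth: list[PhantomSource] = []
    occupied_1: list[tuple[float, float]] = []
    occupied_2: list[tuple[float, float]] = []

    # sample sources: magnetized near the applied field, present in both maps
    sample_dirs = sample_fisher_directions(
        cfg.applied_field, cfg.direction_kappa, cfg.n_sample_sources, rng
    ) if cfg.n_sample_sources else []
    for d in sample_dirs:
        p1 = _draw_position(rng, cfg, inv, occupied_1, occupied_2, True, True)
        p2 = tuple(inv.apply(p1)[0])
        occupied_1.append(p1)
        occupied_2.append(p2)
        depth = rng.uniform(*cfg.depth_range)
        m = _log_uniform(rng, *cfg.moment_range)
        src = DipoleSource(
            x=p1[0], y=p1[1], standoff=depth + cfg.nv_layer_correction,
            moment=MomentVector.from_direction(d, m),
        )
        truth.append(
            PhantomSource(
                source=src, role="sample", host=host_of(p1),
                appears_in=(1, 2), sensor_xy_1=p1, sensor_xy_2=p2,
            )
        )

    # diamond artifacts: fixed in the sensor frame, random orientation
    for _ in range(cfg.n_artifacts):
        p = _draw_position(rng, cfg, None, occupied_1, occupied_2, True, True)
        occupied_1.append(p)
        occupied_2.append(p)
        standoff = rng.uniform(*cfg.artifact_standoff_range)
        m = _log_uniform(rng, *cfg.moment_range)
        src = DipoleSource(
            x=p[0], y=p[1], standoff=standoff,
            moment=MomentVector.from_direction(_uniform_sphere_direction(rng), m),
        )
        truth.append(
            PhantomSource(
                source=src, role="artifact", host=host_of(p),
                appears_in=(1, 2), sensor_xy_1=p, sensor_xy_2=p,
            )
        )

    # surface contaminants: removed by cleaning, so present in one map only
    for _ in range(cfg.n_contaminants):
        which = 1 if rng.random() < 0.5 else 2
        p1 = _draw_position(
            rng, cfg, inv, occupied_1, occupied_2, which == 1, which == 2
        )
        p2 = tuple(inv.apply(p1)[0])
        (occupied_1 if which == 1 else occupied_2).append(p1 if which == 1 else p2)
        # contamination sits on a surface within the first micron of standoff
        standoff = rng.uniform(0.2, max(cfg.contaminant_depth_max, 0.25))
        m = _log_uniform(rng, *cfg.moment_range)
        src = DipoleSource(
            x=p1[0], y=p1[1], standoff=standoff,
            moment=MomentVector.from_direction(_uniform_sphere_direction(rng), m),
        )
        truth.append(
            PhantomSource(
                source=src, role="contaminant", host=host_of(p1),
                appears_in=(which,),
                sensor_xy_1=p1 if which == 1 else None,
                sensor_xy_2=p2 if which == 2 else None,
            )
        )

    # fiducial marks, visible in both acquisitions, with localization jitter
    fid_sample_frame = []
    for _ in range(cfg.n_fiducials):
        fid_sample_frame.append(
            _draw_position(rng, cfg, inv, [], [], True, True)
        )
    fid1 = np.array(fid_sample_frame, dtype=float)
    fid2 = inv.apply(fid1) if len(fid1) else np.empty((0, 2))
    fid1 = fid1 + rng.normal(0.0, cfg.fiducial_jitter, fid1.shape)
    fid2 = fid2 + rng.normal(0.0, cfg.fiducial_jitter, fid2.shape)

    # superpose dipole fields, per acquisition
    xx, yy = geom.pixel_coords()
    vals1 = np.zeros((cfg.n_rows, cfg.n_cols))
    vals2 = np.zeros((cfg.n_rows, cfg.n_cols))
    for ps in truth:
        if 1 in ps.appears_in:
            s1 = replace(ps.source, x=ps.sensor_xy_1[0], y=ps.sensor_xy_1[1])
            vals1 += dipole_field_at(s1, xx, yy)[..., 2]
        if 2 in ps.appears_in:
            m = ps.source.moment.as_array()
            if ps.role == "sample" or (ps.role == "contaminant" and 2 in ps.appears_in):
                # the sample rotates with the sample frame: rotate the
                # in-plane moment components into acquisition-2 sensor axes
                mxy = R_inv @ m[:2]
                m2 = MomentVector(mxy[0], mxy[1], m[2])
            else:
                m2 = ps.source.moment
            s2 = replace(
                ps.source, x=ps.sensor_xy_2[0], y=ps.sensor_xy_2[1], moment=m2
            )
            vals2 += dipole_field_at(s2, xx, yy)[..., 2]
    if cfg.noise_sigma > 0:
        vals1 = vals1 + rng.normal(0.0, cfg.noise_sigma, vals1.shape)
        vals2 = vals2 + rng.normal(0.0, cfg.noise_sigma, vals2.shape)

    meta_common = {
        "applied_field": {
            "dec": cfg.applied_field.declination,
            "inc": cfg.applied_field.inclination,
        },
        "noise_sigma": cfg.noise_sigma,
        "seed": cfg.seed,
    }
    map1 = FieldMap(
        values=vals1, pixel_size=cfg.pixel_size, component="bz", frame="sensor",
        metadata={"acquisition_id": 1, **meta_common},
    )
    map2 = FieldMap(
        values=vals2, pixel_size=cfg.pixel_size, component="bz", frame="sensor",
        metadata={"acquisition_id": 2, **meta_common},
    )
    return AcquisitionPair(
        map1=map1, map2=map2, fiducials1=fid1, fiducials2=fid2,
        true_transform=transform, truth=truth, tissue_mask=mask, config=cfg,
    )
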