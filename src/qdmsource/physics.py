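"""Point-dipole physics for wide-field NV magnetometry maps.

Coordinate conventions (fixed for the whole package):

* ``x`` increases along columns (rightward), ``y`` increases toward the
  image's "12 o'clock" direction (i.e. toward row 0), ``z`` points from the
  sample toward the sensor. Array element ``values[i, j]`` sits at
  ``x = j * pixel_size``, ``y = (n_rows - 1 - i) * pixel_size``.
* Declination is measured clockwise from +y as seen from the sensor side;
  inclination is positive toward -z ("down" into the sample), following
  paleomagnetic convention. A magnetization with declination 0 and
  inclination 0 therefore points along +y, the direction of the in-plane
  magnetizing field applied to the samples.
* Positions and standoffs are expressed in micrometres at the interfaces,
  magnetic moments in A m^2, fields in tesla; conversions to SI metres
  happen inside the field evaluators.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A

#: saturation magnetization of magnetite, A/m
MAGNETITE_MS = 4.8e5


# ---------------------------------------------------------------------------
# directions


@dataclass(frozen=True)
class Direction:
    """A direction on the sphere in declination/inclination degrees.

    declination in [0, 360), clockwise from +y viewed from the sensor side;
    inclination in [-90, +90], positive pointing into the sample (-z).
    """

    declination: float
    inclination: float

    def __post_init__(self) -> None:
        if not -90.0 - 1e-9 <= self.inclination <= 90.0 + 1e-9:
            raise ValueError(f"inclination {self.inclination} outside [-90, 90]")
        object.__setattr__(self, "declination", float(self.declination) % 360.0)
        object.__setattr__(
            self, "inclination", float(np.clip(self.inclination, -90.0, 90.0))
        )

    def to_vector(self) -> np.ndarray:
        return direction_to_vector(self)

    def angle_to(self, other: "Direction") -> float:
        """Angular distance to ``other`` in degrees."""
        c = float(np.clip(np.dot(self.to_vector(), other.to_vector()), -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))


def direction_to_vector(d: Direction) -> np.ndarray:
    """Unit vector for a declination/inclination pair.

    (dec 0, inc 0) -> (0, 1, 0); (dec 90, inc 0) -> (1, 0, 0);
    (dec anything, inc 90) -> (0, 0, -1).
    """
    dec = np.radians(d.declination)
    inc = np.radians(d.inclination)
    return np.array(
        [np.sin(dec) * np.cos(inc), np.cos(dec) * np.cos(inc), -np.sin(inc)]
    )


def vector_to_direction(v: Iterable[float]) -> Direction:
    """Inverse of :func:`direction_to_vector`; ``v`` need not be unit length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    v = v / n
    inc = np.degrees(np.arcsin(np.clip(-v[2], -1.0, 1.0)))
    dec = np.degrees(np.arctan2(v[0], v[1])) % 360.0
    return Direction(dec, inc)


# ---------------------------------------------------------------------------
# moments and geometry


@dataclass(frozen=True)
class MomentVector:
    """Magnetic moment vector, components in A m^2 in the shared axes."""

    mx: float
    my: float
    mz: float

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(self.mx**2 + self.my**2 + self.mz**2))

    def direction(self) -> Direction:
        return vector_to_direction([self.mx, self.my, self.mz])

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)

    @classmethod
    def from_direction(cls, d: Direction, magnitude: float) -> "MomentVector":
        v = direction_to_vector(d) * magnitude
        return cls(*v)


@dataclass(frozen=True)
class SensorGeometry:
    """Pixel grid and sensing-layer metadata of the imager.

    Defaults reproduce the instrument's full field of view: 1920 x 1200
    pixels of 1.17 µm, i.e. 2.25 x 1.40 mm^2. ``nv_layer_correction`` is the
    depth subtracted from fitted map-to-source distances to account for the
    finite thickness of the NV sensing layer.
    """

    pixel_size: float = 1.17  # µm
    n_cols: int = 1920
    n_rows: int = 1200
    nv_layer_correction: float = 1.0  # µm
    measurement_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nv_layer_correction < 0:
            raise ValueError("nv_layer_correction must be >= 0")
        u = np.asarray(self.measurement_axis, dtype=float)
        if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
            raise ValueError("measurement_axis must be a unit vector")

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) µm coordinate grids of the pixel centers, shape (n_rows, n_cols)."""
        x = np.arange(self.n_cols) * self.pixel_size
        y = (self.n_rows - 1 - np.arange(self.n_rows)) * self.pixel_size
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) array indices for µm coordinates."""
        col = np.asarray(x_um, dtype=float) / self.pixel_size
        row = (self.n_rows - 1) - np.asarray(y_um, dtype=float) / self.pixel_size
        return row, col

    def rowcol_to_xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(col, dtype=float) * self.pixel_size
        y = (self.n_rows - 1 - np.asarray(row, dtype=float)) * self.pixel_size
        return x, y


@dataclass(frozen=True)
class DipoleSource:
    """A point source: in-plane position (µm), standoff below the sensing
    plane (µm, > 0) and moment vector."""

    x: float
    y: float
    standoff: float
    moment: MomentVector

    def __post_init__(self) -> None:
        if self.standoff <= 0:
            raise ValueError("standoff must be > 0 (source below the sensing plane)")


@dataclass
class FieldMap:
    """A gridded single-component magnetic field map.

    ``values`` holds tesla on the pixel grid of ``SensorGeometry``;
    ``component`` is ``"bz"`` (out-of-plane) or ``"b_axis"`` (projection on a
    single NV axis); ``frame`` tags whether coordinates are in the sensor
    frame of the acquisition or the realigned sample frame.
    """

    values: np.ndarray
    pixel_size: float
    component: str = "bz"
    frame: str = "sensor"
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FieldMap values must be 2-D")
        if self.component not in ("bz", "b_axis"):
            raise ValueError(f"unknown component {self.component!r}")
        if self.frame not in ("sensor", "sample"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def geometry(self, **kw) -> SensorGeometry:
        return SensorGeometry(
            pixel_size=self.pixel_size,
            n_cols=self.n_cols,
            n_rows=self.n_rows,
            **kw,
        )

    def copy_with(self, values: np.ndarray, **meta) -> "FieldMap":
        md = dict(self.metadata)
        md.update(meta.pop("metadata", {}))
        kw = dict(
            pixel_size=self.pixel_size,
            component=self.component,
            frame=self.frame,
        )
        kw.update(meta)
        return FieldMap(values=values, metadata=md, **kw)


# ---------------------------------------------------------------------------
# forward model


def dipole_field_at(
    src: DipoleSource, x_um: np.ndarray, y_um: np.ndarray
) -> np.ndarray:
    """Full vector dipole field B(r) (tesla) at points on the sensing plane.

    Returns an array of shape (..., 3). The source sits ``standoff`` µm below
    the plane, so the source-to-point vector has a +z component equal to the
    standoff and the field is finite everywhere.
    """
    if src.standoff <= 0:
        raise ValueError("standoff must be > 0")
    dx = (np.asarray(x_um, dtype=float) - src.x) * 1e-6
    dy = (np.asarray(y_um, dtype=float) - src.y) * 1e-6
    dz = np.full_like(dx, src.standoff * 1e-6)
    r2 = dx * dx + dy * dy + dz * dz
    r = np.sqrt(r2)
    m = src.moment.as_array()
    mdotr = m[0] * dx + m[1] * dy + m[2] * dz
    pref = MU0 / (4.0 * np.pi)
    inv_r5 = 1.0 / (r2 * r2 * r)
    inv_r3 = 1.0 / (r2 * r)
    bx = pref * (3.0 * dx * mdotr * inv_r5 - m[0] * inv_r3)
    by = pref * (3.0 * dy * mdotr * inv_r5 - m[1] * inv_r3)
    bz = pref * (3.0 * dz * mdotr * inv_r5 - m[2] * inv_r3)
    return np.stack([bx, by, bz], axis=-1)


def dipole_bz_map(src: DipoleSource, geom: SensorGeometry) -> FieldMap:
    """Out-of-plane field Bz of a point dipole sampled at pixel centers."""
    xx, yy = geom.pixel_coords()
    b = dipole_field_at(src, xx, yy)
    return FieldMap(values=b[..., 2], pixel_size=geom.pixel_size, component="bz")


def dipole_axis_map(src: DipoleSource, geom: SensorGeometry) -> FieldMap:
    """Projection of the dipole field onto the sensor's measurement axis."""
    u = np.asarray(geom.measurement_axis, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("measurement_axis must be nonzero")
    u = u / nu
    xx, yy = geom.pixel_coords()
    b = dipole_field_at(src, xx, yy)
    vals = b @ u
    return FieldMap(
        values=vals,
        pixel_size=geom.pixel_size,
        component="b_axis",
        metadata={"measurement_axis": tuple(u)},
    )


def superpose_maps(maps: Iterable[FieldMap]) -> FieldMap:
    """Sum of co-registered maps of the same component."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    out = maps[0].copy_with(values=sum(m.values for m in maps))
    return out


def on_axis_peak_bz(moment_z: float, standoff_um: float) -> float:
    """Closed-form Bz directly above a vertical dipole: mu0 m / (2 pi h^3)."""
    h = standoff_um * 1e-6
    return MU0 * moment_z / (2.0 * np.pi * h**3)


# ---------------------------------------------------------------------------
# magnetite sizing


def moment_to_diameter(m: float, ms: float = MAGNETITE_MS) -> float:
    """Diameter (nm) of a uniformly magnetized magnetite sphere of moment ``m``.

    Assumes a single, non-interacting sphere at saturation magnetization
    ``ms`` (default 480 kA/m): d = (6 m / (pi Ms))^(1/3).
    """
    if m < 0:
        raise ValueError("moment must be >= 0")
    if ms <= 0:
        raise ValueError("saturation magnetization must be > 0")
    d_m = (6.0 * m / (np.pi * ms)) ** (1.0 / 3.0)
    return float(d_m * 1e9)


def diameter_to_moment(d_nm: float, ms: float = MAGNETITE_MS) -> float:
    """Moment (A m^2) of a magnetite sphere of diameter ``d_nm`` nanometres."""
    if d_nm < 0:
        raise ValueError("diameter must be >= 0")
    if ms <= 0:
        raise ValueError("saturation magnetization must be > 0")
    return float(ms * (np.pi / 6.0) * (d_nm * 1e-9) ** 3)
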