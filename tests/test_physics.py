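"""Dipole forward model, direction conventions and magnetite sizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdmsource import (
    MU0,
    Direction,
    DipoleSource,
    MomentVector,
    SensorGeometry,
    diameter_to_moment,
    dipole_axis_map,
    dipole_bz_map,
    dipole_field_at,
    direction_to_vector,
    moment_to_diameter,
    on_axis_peak_bz,
    vector_to_direction,
)


@pytest.mark.parametrize(
    "dec,inc,expected",
    [
        (0.0, 0.0, (0.0, 1.0, 0.0)),  # convention-defining: 12 o'clock
        (90.0, 0.0, (1.0, 0.0, 0.0)),  # quarter turn clockwise from sensor side
        (0.0, 90.0, (0.0, 0.0, -1.0)),  # straight down into the sample
        (180.0, 0.0, (0.0, -1.0, 0.0)),
    ],
)
def test_direction_convention(dec, inc, expected):
    assert np.allclose(direction_to_vector(Direction(dec, inc)), expected, atol=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    dec=st.floats(0.0, 360.0, exclude_max=True),
    inc=st.floats(-89.999, 89.999),
)
def test_direction_roundtrip(dec, inc):
    d = Direction(dec, inc)
    d2 = vector_to_direction(direction_to_vector(d))
    assert abs(d2.inclination - d.inclination) < 1e-9
    ddec = (d2.declination - d.declination + 180.0) % 360.0 - 180.0
    assert abs(ddec) < 1e-9 / max(np.cos(np.radians(inc)), 1e-6)


def test_direction_poles_unconstrained_declination():
    d = vector_to_direction([0.0, 0.0, -1.0])
    assert d.inclination == pytest.approx(90.0)


def test_on_axis_peak_closed_form(small_geom):
    # mu0 m / (2 pi h^3): 3e-17 A m^2 at 1.5 µm -> ~1.78 µT
    assert on_axis_peak_bz(3e-17, 1.5) == pytest.approx(1.778e-6, rel=1e-3)
    # the sampled map reproduces it at the pixel directly above the source
    geom = SensorGeometry(pixel_size=1.0, n_cols=41, n_rows=41)
    src = DipoleSource(x=20.0, y=20.0, standoff=1.5, moment=MomentVector(0, 0, 3e-17))
    fmap = dipole_bz_map(src, geom)
    row, col = geom.xy_to_rowcol(20.0, 20.0)
    assert fmap.values[int(row), int(col)] == pytest.approx(
        on_axis_peak_bz(3e-17, 1.5), rel=1e-12
    )


def test_zero_moment_gives_zero_map(small_geom):
    src = DipoleSource(x=10.0, y=10.0, standoff=2.0, moment=MomentVector(0, 0, 0))
    assert np.all(dipole_bz_map(src, small_geom).values == 0.0)


def test_vertical_dipole_rotational_symmetry():
    geom = SensorGeometry(pixel_size=1.0, n_cols=81, n_rows=81)
    src = DipoleSource(x=40.0, y=40.0, standoff=2.0, moment=MomentVector(0, 0, 1e-16))
    vals = dipole_bz_map(src, geom).values
    assert np.max(np.abs(vals - np.rot90(vals))) <= 1e-12 * np.max(np.abs(vals))


def test_negative_standoff_rejected():
    with pytest.raises(ValueError):
        DipoleSource(x=0, y=0, standoff=-1.0, moment=MomentVector(0, 0, 1e-17))


def test_superposition_moment_additivity(small_geom):
    """The field of a source with moment m1+m2 equals the sum of the fields
    of co-located sources with moments m1 and m2 (linearity in m)."""
    at = dict(x=40.0, y=50.0, standoff=2.0)
    m1 = MomentVector(1e-16, 0.0, 5e-17)
    m2 = MomentVector(-3e-17, 2e-16, -1e-16)
    msum = MomentVector(m1.mx + m2.mx, m1.my + m2.my, m1.mz + m2.mz)
    vsum = dipole_bz_map(DipoleSource(moment=msum, **at), small_geom).values
    v12 = (
        dipole_bz_map(DipoleSource(moment=m1, **at), small_geom).values
        + dipole_bz_map(DipoleSource(moment=m2, **at), small_geom).values
    )
    assert np.allclose(vsum, v12, rtol=1e-12)


def test_distance_scaling_inverse_cube():
    # doubling every length at fixed moment divides each pixel value by 8
    g1 = SensorGeometry(pixel_size=1.0, n_cols=33, n_rows=33)
    g2 = SensorGeometry(pixel_size=2.0, n_cols=33, n_rows=33)
    m = MomentVector(3e-17, -1e-17, 2e-17)
    v1 = dipole_bz_map(DipoleSource(x=16.0, y=16.0, standoff=2.0, moment=m), g1).values
    v2 = dipole_bz_map(DipoleSource(x=32.0, y=32.0, standoff=4.0, moment=m), g2).values
    assert np.allclose(v1, 8.0 * v2, rtol=1e-9)


def test_axis_map_equals_bz_for_z_axis(small_geom, center_source):
    geom = SensorGeometry(
        pixel_size=small_geom.pixel_size,
        n_cols=small_geom.n_cols,
        n_rows=small_geom.n_rows,
        measurement_axis=(0.0, 0.0, 1.0),
    )
    assert np.array_equal(
        dipole_axis_map(center_source, geom).values,
        dipole_bz_map(center_source, geom).values,
    )


def test_axis_map_linearity(small_geom, center_source):
    geom = SensorGeometry(
        pixel_size=1.17, n_cols=60, n_rows=60,
        measurement_axis=tuple(np.array([0.5, 0.5, np.sqrt(0.5)])),
    )
    doubled = DipoleSource(
        x=center_source.x, y=center_source.y, standoff=center_source.standoff,
        moment=MomentVector(
            2 * center_source.moment.mx,
            2 * center_source.moment.my,
            2 * center_source.moment.mz,
        ),
    )
    assert np.allclose(
        dipole_axis_map(doubled, geom).values,
        2.0 * dipole_axis_map(center_source, geom).values,
        rtol=1e-12,
    )


def test_axis_map_matches_brute_force_vector_field():
    """Tilted-axis projection vs an independent pixel-by-pixel evaluation of
    the textbook dipole formula, for a vertical dipole under a 54.7deg axis."""
    th = np.radians(54.7)
    u = np.array([np.sin(th), 0.0, np.cos(th)])
    geom = SensorGeometry(
        pixel_size=1.0, n_cols=21, n_rows=21, measurement_axis=tuple(u)
    )
    m = np.array([0.0, 0.0, 2e-17])
    src = DipoleSource(x=10.0, y=10.0, standoff=2.5, moment=MomentVector(*m))
    got = dipole_axis_map(src, geom).values
    expected = np.empty_like(got)
    for i in range(21):
        for j in range(21):
            x = j * 1.0
            y = (21 - 1 - i) * 1.0
            r = np.array([x - 10.0, y - 10.0, 2.5]) * 1e-6
            rn = np.linalg.norm(r)
            b = MU0 / (4 * np.pi) * (3 * r * (m @ r) / rn**5 - m / rn**3)
            expected[i, j] = b @ u
    assert np.allclose(got, expected, rtol=1e-12)


# --- magnetite sizing ------------------------------------------------------


@pytest.mark.parametrize(
    "moment,expected_nm,tol_nm",
    [
        (3e-17, 49.2, 0.5),   # detection threshold, "approximately 50 nm"
        (6.2e-17, 63.0, 0.5),  # smallest bona fide moment in human tissue
        (6.6e-16, 138.0, 0.5),  # largest
        (0.0, 0.0, 1e-12),
    ],
)
def test_moment_to_diameter_reference_points(moment, expected_nm, tol_nm):
    assert abs(moment_to_diameter(moment) - expected_nm) <= tol_nm


def test_diameter_to_moment_closed_form():
    assert diameter_to_moment(50.0) == pytest.approx(3.14159e-17, rel=1e-4)
    assert diameter_to_moment(0.0) == 0.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(d=st.floats(0.1, 1e4))
def test_sizing_roundtrip(d):
    assert moment_to_diameter(diameter_to_moment(d)) == pytest.approx(d, rel=1e-9)


def test_sizing_monotone():
    ms = np.logspace(-18, -13, 40)
    diams = [moment_to_diameter(m) for m in ms]
    assert np.all(np.diff(diams) > 0)


def test_sizing_rejects_negative():
    with pytest.raises(ValueError):
        moment_to_diameter(-1e-18)
    with pytest.raises(ValueError):
        diameter_to_moment(-5.0)
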