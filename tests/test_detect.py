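"""Candidate detection, dipole inversion and the noise-floor survey."""

import numpy as np
import pytest

from qdmsource import (
    Direction,
    DipoleSource,
    FieldMap,
    MomentVector,
    SensorGeometry,
    detect_candidates,
    dipole_bz_map,
    fit_dipole,
    noise_floor_survey,
)
from conftest import noisy_single_source_map


def test_flat_maps_yield_no_candidates():
    for values in (np.zeros((50, 50)), np.full((50, 50), 2.5e-7)):
        fmap = FieldMap(values=values, pixel_size=1.17)
        assert detect_candidates(fmap) == []


def test_single_dipole_detected_within_two_pixels(small_geom):
    rng_sigma = 5e-8
    src = DipoleSource(
        x=70.0, y=80.0, standoff=2.0,
        moment=MomentVector.from_direction(Direction(0.0, 0.0), 4e-16),
    )
    fmap = noisy_single_source_map(small_geom, src, rng_sigma, seed=1)
    peak = np.max(np.abs(dipole_bz_map(src, small_geom).values))
    assert peak >= 20 * rng_sigma  # the premise of the check
    cands = detect_candidates(fmap)
    assert len(cands) == 1
    # the in-plane dipole's |Bz| peak sits ~h/2 off the epicenter, so allow
    # the lobe offset plus the stated 2 px localization slack
    lobe_offset = src.standoff / 2.0
    err = np.hypot(cands[0].x - src.x, cands[0].y - src.y)
    assert err <= lobe_offset + 2 * small_geom.pixel_size


def test_many_dipoles_no_false_positives_over_seeds():
    """10 well-separated sources at >=10x noise: exactly 10 candidates and
    no spurious ones, across 20 noise seeds."""
    geom = SensorGeometry(pixel_size=1.17, n_cols=350, n_rows=280)
    rng = np.random.default_rng(99)
    positions = [
        (50.0 + 90.0 * (i % 4), 60.0 + 90.0 * (i // 4)) for i in range(10)
    ]
    base = np.zeros((geom.n_rows, geom.n_cols))
    from qdmsource import dipole_field_at

    xx, yy = geom.pixel_coords()
    sigma = 5e-8
    for (x, y) in positions:
        src = DipoleSource(
            x=x, y=y, standoff=rng.uniform(2.0, 4.0),
            moment=MomentVector.from_direction(
                Direction(rng.uniform(0, 360), rng.uniform(-20, 20)), 2e-15
            ),
        )
        contrib = dipole_field_at(src, xx, yy)[..., 2]
        assert np.max(np.abs(contrib)) >= 10 * sigma  # premise: each >=10x noise
        base += contrib
    for seed in range(20):
        noisy = base + np.random.default_rng(seed).normal(0, sigma, base.shape)
        cands = detect_candidates(FieldMap(values=noisy, pixel_size=1.17), min_sep_px=15)
        assert len(cands) == 10
        for c in cands:
            d = min(np.hypot(c.x - x, c.y - y) for x, y in positions)
            assert d <= 5.0  # every candidate belongs to a true source


@pytest.mark.parametrize(
    "dec,inc",
    [(0.0, 0.0), (120.0, 10.0), (300.0, -35.0), (45.0, 80.0)],
)
def test_noiseless_fit_recovers_all_six_parameters(small_geom, dec, inc):
    src = DipoleSource(
        x=69.0, y=72.5, standoff=3.2,
        moment=MomentVector.from_direction(Direction(dec, inc), 5e-16),
    )
    fmap = dipole_bz_map(src, small_geom)
    cands = detect_candidates(fmap)
    fit = fit_dipole(fmap, cands[0], small_geom)
    assert np.hypot(fit.x - src.x, fit.y - src.y) <= 0.05 * small_geom.pixel_size
    assert fit.fitted_distance == pytest.approx(src.standoff, rel=0.01)
    assert fit.moment_magnitude == pytest.approx(src.moment.magnitude, rel=0.01)
    assert fit.direction.angle_to(src.moment.direction()) <= 0.5
    assert fit.converged
    assert fit.r_squared > 0.999


def test_depth_is_distance_minus_layer_correction(small_geom, center_source):
    fmap = dipole_bz_map(center_source, small_geom)
    fit = fit_dipole(fmap, detect_candidates(fmap)[0], small_geom)
    assert fit.depth == pytest.approx(fit.fitted_distance - 1.0, abs=1e-12)
    geom2 = SensorGeometry(
        pixel_size=1.17, n_cols=120, n_rows=120, nv_layer_correction=0.5
    )
    fit2 = fit_dipole(fmap, detect_candidates(fmap)[0], geom2)
    assert fit2.depth == pytest.approx(fit2.fitted_distance - 0.5, abs=1e-12)


def test_fit_self_consistency_fixed_point(small_geom, center_source):
    """Fitting the forward map of a previous fit reproduces that fit."""
    fmap = dipole_bz_map(center_source, small_geom)
    fit = fit_dipole(fmap, detect_candidates(fmap)[0], small_geom)
    refit_src = DipoleSource(
        x=fit.x, y=fit.y, standoff=fit.fitted_distance, moment=fit.moment
    )
    fmap2 = dipole_bz_map(refit_src, small_geom)
    fit2 = fit_dipole(fmap2, detect_candidates(fmap2)[0], small_geom)
    assert np.hypot(fit2.x - fit.x, fit2.y - fit.y) <= 0.05 * small_geom.pixel_size
    assert fit2.fitted_distance == pytest.approx(fit.fitted_distance, rel=0.01)
    assert fit2.moment_magnitude == pytest.approx(fit.moment_magnitude, rel=0.01)


def test_repeatability_under_independent_noise(small_geom, center_source):
    """Two fits of the same source under independent noise draws agree
    within 3x the Monte-Carlo spread of the moment estimate."""
    sigma = 5e-8
    moments = []
    for seed in range(50):
        fmap = noisy_single_source_map(small_geom, center_source, sigma, seed)
        cands = detect_candidates(fmap)
        moments.append(fit_dipole(fmap, cands[0], small_geom).moment_magnitude)
    moments = np.array(moments)
    spread = moments.std(ddof=1)
    assert abs(moments[0] - moments[1]) <= 3.0 * np.sqrt(2.0) * spread


def test_noise_degradation_is_monotone(small_geom, center_source):
    """Median moment error never decreases as pixel noise grows."""
    sigmas = [2e-8, 8e-8, 3.2e-7]
    medians = []
    for sigma in sigmas:
        errs = []
        for seed in range(15):
            fmap = noisy_single_source_map(small_geom, center_source, sigma, 100 + seed)
            cands = detect_candidates(fmap)
            if not cands:
                errs.append(np.inf)
                continue
            fit = fit_dipole(fmap, cands[0], small_geom)
            errs.append(
                abs(fit.moment_magnitude - center_source.moment.magnitude)
                / center_source.moment.magnitude
            )
        medians.append(np.median(errs))
    slack = 1.2  # Monte-Carlo error bar on a 15-sample median
    assert medians[0] <= medians[1] * slack
    assert medians[1] <= medians[2] * slack


# --- noise-floor survey ----------------------------------------------------


def _fake_fit(m):
    from qdmsource import DipoleFit

    return DipoleFit(
        x=0.0, y=0.0, fitted_distance=2.0, depth=1.0,
        moment=MomentVector(m, 0.0, 0.0), residual_rms=0.0,
        r_squared=1.0, converged=True,
    )


def test_survey_all_equal_moments():
    fits = [_fake_fit(4e-17) for _ in range(10)]
    s = noise_floor_survey(fits, n_smallest=10)
    assert s["median"] == pytest.approx(4e-17)
    assert s["min"] == pytest.approx(4e-17)
    assert s["mode_bin"] == pytest.approx(4e-17, rel=0.05)


def test_survey_matches_sort_and_slice_oracle():
    rng = np.random.default_rng(31)
    moments = np.exp(rng.uniform(np.log(1e-17), np.log(1e-14), 100))
    fits = [_fake_fit(m) for m in moments]
    s = noise_floor_survey(fits, n_smallest=10)
    smallest = np.sort(moments)[:10]
    assert s["median"] == pytest.approx(np.median(smallest))
    assert s["min"] == pytest.approx(smallest.min())
    assert s["n"] == 10


def test_survey_boundary_and_errors():
    with pytest.raises(ValueError):
        noise_floor_survey([])
    fits = [_fake_fit(m) for m in (1e-17, 2e-17, 3e-17)]
    with pytest.warns(RuntimeWarning):
        s = noise_floor_survey(fits, n_smallest=147)
    assert s["n"] == 3
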