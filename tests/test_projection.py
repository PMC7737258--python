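"""Film projection, ellipse recovery and Woo-Morrey measurement."""

import numpy as np
import pytest

from cupsim import (
    BeamConfig,
    CupOrientation,
    PelvisPose,
    ProjectedRim,
    apply_pelvic_tilt,
    fit_ellipse,
    make_rim,
    measure_va,
    project,
    run_sweep,
    simulate_cl_measurement,
)
from cupsim.errors import DegenerateMeasurementError, ParameterError

import oracles


def chain(anteversion, inclination, pelvic_tilt, beam=None, n_points=256):
    cup = CupOrientation(anteversion, inclination)
    rim = apply_pelvic_tilt(make_rim(cup, n_points=n_points), PelvisPose(pelvic_tilt))
    return project(rim, beam or BeamConfig())


def test_projection_matches_explicit_matrix_operator(rng):
    op = oracles.film_operator(45.0)
    rim = make_rim(CupOrientation(23.0, 52.0, radius_mm=31.0), n_points=64)
    proj = project(rim, BeamConfig())
    np.testing.assert_allclose(proj.points, rim.points @ op.T, atol=1e-12)


def test_edge_on_rim_projects_to_a_line():
    """With the 45-degree beam and 45-degree inclination at natural tilt the
    rim plane contains the beam, so the film shows a pure line."""
    proj = chain(15.0, 45.0, 60.0)
    ell = fit_ellipse(proj)
    assert ell.semi_minor < 1e-9 * ell.semi_major


def test_true_lateral_projection_drops_transverse_coordinate():
    rim = make_rim(CupOrientation(25.0, 45.0))
    proj = project(rim, BeamConfig(beam_to_long_axis_deg=90.0))
    # film basis at beam 90: u = -y, v = z
    np.testing.assert_allclose(
        proj.points, np.column_stack([-rim.points[:, 1], rim.points[:, 2]]),
        atol=1e-12,
    )


def test_fit_ellipse_recovers_constructed_ellipse():
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    pts = np.column_stack([2.0 * np.cos(t), 1.0 * np.sin(t)])
    ell = fit_ellipse(ProjectedRim(points=pts, beam=BeamConfig()))
    assert abs(ell.semi_major - 2.0) < 1e-9
    assert abs(ell.semi_minor - 1.0) < 1e-9
    assert abs(abs(ell.major_axis @ np.array([1.0, 0.0])) - 1.0) < 1e-9


def test_fit_ellipse_rotated_30_degrees():
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    base = np.column_stack([2.0 * np.cos(t), 1.0 * np.sin(t)])
    ang = np.radians(30.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    ell = fit_ellipse(ProjectedRim(points=base @ rot.T, beam=BeamConfig()))
    got = np.degrees(np.arctan2(ell.major_axis[1], ell.major_axis[0]))
    assert abs(got - 30.0) < 1e-9


def test_fit_ellipse_axes_match_svd_oracle():
    cup = CupOrientation(25.0, 50.0, radius_mm=24.0)
    rim = apply_pelvic_tilt(make_rim(cup), PelvisPose(45.0))
    ell = fit_ellipse(project(rim, BeamConfig()))
    sv = oracles.plane_to_film_singular_values(rim.plane_normal())
    np.testing.assert_allclose(
        [ell.semi_major, ell.semi_minor], 24.0 * sv, atol=1e-9
    )


def test_fit_ellipse_agrees_with_algebraic_conic_fit():
    proj = chain(25.0, 50.0, 45.0, n_points=64)
    ell = fit_ellipse(proj)
    a, b, ang = oracles.fit_conic_ellipse(proj.points)
    assert abs(a - ell.semi_major) < 1e-6
    assert abs(b - ell.semi_minor) < 1e-6
    got = np.degrees(np.arctan2(ell.major_axis[0], ell.major_axis[1]))
    assert abs(got - ang) < 1e-6


def test_fit_ellipse_collinear_is_degenerate_valid():
    t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    pts = np.column_stack([np.cos(t), np.zeros_like(t)])
    ell = fit_ellipse(ProjectedRim(points=pts, beam=BeamConfig()))
    assert ell.semi_minor == 0.0
    assert abs(abs(ell.major_axis[0]) - 1.0) < 1e-12


def test_measure_va_identity_at_natural_tilt():
    """At natural tilt with the standard beam the measurement equals the set
    anteversion exactly — the geometric reason the published 60-degree row
    is nearly the identity."""
    for va in (0.0, 5.0, 15.0, 25.0, 40.0, -10.0):
        assert abs(simulate_cl_measurement(
            CupOrientation(va, 45.0), PelvisPose(60.0)
        ) - va) < 1e-9


def test_measure_va_known_distorted_cell():
    got = simulate_cl_measurement(CupOrientation(25.0, 45.0), PelvisPose(40.0))
    assert got == pytest.approx(40.44, abs=2.5)


def test_measure_va_vertical_edge_on_is_zero():
    t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    pts = np.column_stack([np.zeros_like(t), np.cos(t)])
    assert measure_va(ProjectedRim(points=pts, beam=BeamConfig())) == 0.0


def test_measure_va_circular_projection_raises():
    t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    pts = np.column_stack([np.cos(t), np.sin(t)])
    with pytest.raises(DegenerateMeasurementError):
        measure_va(ProjectedRim(points=pts, beam=BeamConfig()))


def test_pipeline_matches_closed_form_oracle():
    """Point-sampling pipeline vs the analytic projected-normal angle on a
    5 x 5 x 3 grid of anteversion, inclination and tilt."""
    for a in (0.0, 10.0, 20.0, 30.0, 40.0):
        for i in (30.0, 40.0, 45.0, 50.0, 60.0):
            for pt in (30.0, 55.0, 75.0):
                got = simulate_cl_measurement(CupOrientation(a, i), PelvisPose(pt))
                want = oracles.measured_va_closed_form(a, i, pt)
                assert got == pytest.approx(want, abs=1e-6), (a, i, pt)


def test_true_lateral_tilt_sensitivity_is_exactly_one():
    """At beam 90 the tilt axis coincides with the beam, the image rotates
    rigidly, and each degree of tilt changes the measurement by exactly one
    degree."""
    beam = BeamConfig(beam_to_long_axis_deg=90.0)
    base = simulate_cl_measurement(CupOrientation(15.0, 45.0), PelvisPose(60.0), beam)
    for pt in (50.0, 55.0, 61.0, 70.0):
        got = simulate_cl_measurement(CupOrientation(15.0, 45.0), PelvisPose(pt), beam)
        assert got - base == pytest.approx(-(pt - 60.0), abs=1e-9)


def test_measured_va_strictly_decreasing_in_tilt():
    pts = np.arange(20.0, 85.0, 5.0)
    for va in np.arange(0.0, 45.0, 5.0):
        vals = [
            simulate_cl_measurement(CupOrientation(va, 45.0), PelvisPose(pt))
            for pt in pts
        ]
        assert np.all(np.diff(vals) < 0), va


def test_measured_va_approximately_linear_in_tilt():
    pts = np.arange(20.0, 85.0, 5.0)
    for va in (0.0, 15.0, 40.0):
        vals = np.array([
            simulate_cl_measurement(CupOrientation(va, 45.0), PelvisPose(pt))
            for pt in pts
        ])
        r = np.corrcoef(pts, vals)[0, 1]
        assert r**2 >= 0.99


def test_radius_does_not_affect_measured_angles():
    grid = dict(pt_values=np.arange(20, 85, 10), va_values=np.arange(0, 45, 10))
    small = run_sweep(**grid, radius_mm=10.0)
    large = run_sweep(**grid, radius_mm=50.0)
    np.testing.assert_allclose(
        small.data["measured_va_deg"], large.data["measured_va_deg"], atol=1e-9
    )


def test_left_right_mirror_measurements_equal():
    for va in (0.0, 10.0, 20.0, 30.0, 40.0):
        for pt in (30.0, 45.0, 60.0, 70.0, 80.0):
            right = simulate_cl_measurement(
                CupOrientation(va, 45.0, side="right"), PelvisPose(pt)
            )
            left = simulate_cl_measurement(
                CupOrientation(va, 45.0, side="left"), PelvisPose(pt)
            )
            assert left == pytest.approx(right, abs=1e-9)


def test_angle_stable_in_point_count():
    for n in (128, 512):
        got = simulate_cl_measurement(
            CupOrientation(25.0, 45.0), PelvisPose(40.0), n_points=n
        )
        ref = simulate_cl_measurement(
            CupOrientation(25.0, 45.0), PelvisPose(40.0), n_points=256
        )
        assert got == pytest.approx(ref, abs=1e-6)


def test_translation_of_rim_does_not_change_angle():
    """Orthographic projection: the rotation centre / rim position along any
    axis is irrelevant to the measured angle."""
    cup = CupOrientation(25.0, 45.0)
    rim = apply_pelvic_tilt(make_rim(cup), PelvisPose(40.0))
    shifted = type(rim)(
        points=rim.points + np.array([13.0, -7.0, 42.0]),
        center=rim.center + np.array([13.0, -7.0, 42.0]),
        radius_mm=rim.radius_mm,
        side=rim.side,
    )
    assert measure_va(project(shifted, BeamConfig())) == pytest.approx(
        measure_va(project(rim, BeamConfig())), abs=1e-12
    )


def test_simulate_noiseless_is_deterministic():
    vals = {
        simulate_cl_measurement(CupOrientation(17.0, 43.0), PelvisPose(52.0))
        for _ in range(5)
    }
    assert len(vals) == 1


def test_simulate_seeded_noise_reproducible():
    a = simulate_cl_measurement(
        CupOrientation(15.0, 45.0), PelvisPose(50.0), noise_sd=1.0, rng=7
    )
    b = simulate_cl_measurement(
        CupOrientation(15.0, 45.0), PelvisPose(50.0), noise_sd=1.0, rng=7
    )
    assert a == b


def test_observer_noise_sd_contract(rng):
    base = simulate_cl_measurement(CupOrientation(15.0, 45.0), PelvisPose(50.0))
    draws = np.array([
        simulate_cl_measurement(
            CupOrientation(15.0, 45.0), PelvisPose(50.0), noise_sd=1.0, rng=rng
        )
        for _ in range(4000)
    ])
    assert draws.std(ddof=1) == pytest.approx(1.0, abs=0.05)
    assert draws.mean() == pytest.approx(base, abs=0.06)


def test_negative_noise_sd_rejected():
    with pytest.raises(ParameterError):
        simulate_cl_measurement(
            CupOrientation(15.0, 45.0), PelvisPose(50.0), noise_sd=-1.0
        )


def test_invalid_beam_rejected():
    with pytest.raises(ParameterError):
        BeamConfig(beam_to_long_axis_deg=0.0)
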