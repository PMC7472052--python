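"""Ray-transfer-matrix model: closed forms, imaging condition, depth-to-column map."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from stripescope import optics
from stripescope.optics import (
    DegenerateConfigurationError,
    NoSolutionError,
    OpticalConfig,
    image_distance,
    magnification,
    measurement_range,
    sensitivity,
    specimen_from_column,
    stripe_column,
    system_matrix,
    sweep,
)


def closed_form_elements(cfg, x1, x2):
    """Independent expansion of the system-matrix elements (textbook algebra)."""
    f1, f2, d = cfg.f1, cfg.f2, cfg.d
    a = 1 - x2 / f2 - d / f1 + d * x2 / (f1 * f2) - x2 / f1
    b = (
        x1 + x2 + d - x1 * d / f1 - x1 * x2 / f2 - x2 * d / f2
        - x1 * x2 / f1 + x1 * x2 * d / (f1 * f2)
    )
    c = -1 / f1 - 1 / f2 + d / (f1 * f2)
    dd = 1 - x1 / f1 - x1 / f2 - d / f2 + x1 * d / (f1 * f2)
    return a, b, c, dd


@pytest.mark.parametrize(
    "cfg,x1,x2",
    [
        (OpticalConfig(), 45.0, 18.0),
        (OpticalConfig(), 43.1, 20.0),
        (OpticalConfig(d=100.0), 45.0, 30.0),
        (OpticalConfig(f1=30.0, f2=25.0, d=70.0), 28.0, 40.0),
    ],
)
def test_system_matrix_matches_closed_forms(cfg, x1, x2):
    m = system_matrix(cfg, x1, x2)
    a, b, c, d = closed_form_elements(cfg, x1, x2)
    for got, want in zip((m.a, m.b, m.c, m.d), (a, b, c, d)):
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


@given(
    f1=st.floats(5.0, 200.0),
    f2=st.floats(5.0, 200.0),
    d=st.floats(1.0, 400.0),
    x1=st.floats(-100.0, 100.0),
    x2=st.floats(-100.0, 100.0),
)
def test_system_matrix_is_unimodular(f1, f2, d, x1, x2):
    cfg = OpticalConfig(f1=f1, f2=f2, d=d)
    m = system_matrix(cfg, x1, x2)
    assert m.determinant == pytest.approx(1.0, rel=1e-12, abs=1e-10)


@pytest.mark.parametrize("x1", [41.8, 45.0, 48.2])
@pytest.mark.parametrize("d", [63.0, 100.0, 150.0])
def test_image_distance_satisfies_imaging_condition(proto, d, x1):
    """The returned x2 zeroes the B element (imaging condition)."""
    cfg = dataclasses.replace(proto, d=d)
    x2 = image_distance(cfg, x1)
    m = system_matrix(cfg, x1, x2)
    scale = max(abs(x1), abs(x2), cfg.d)
    assert abs(m.b) < 1e-9 * scale


@pytest.mark.parametrize("d,x1", [(63.0, 45.0), (100.0, 45.0), (150.0, 44.0)])
def test_image_distance_agrees_with_root_finding_oracle(proto, d, x1):
    """Independent route: solve B(x2) = 0 numerically and compare."""
    cfg = dataclasses.replace(proto, d=d)
    b_of_x2 = lambda x2: system_matrix(cfg, x1, x2).b
    x2_oracle = brentq(b_of_x2, -500.0, 500.0, xtol=1e-12)
    assert image_distance(cfg, x1) == pytest.approx(x2_oracle, abs=1e-8)


def test_telecentric_image_distance_is_affine(proto):
    """At d = f1 + f2 the map reduces to x2 = f2 + f2^2/f1 - (f2/f1)^2 x1."""
    f1, f2 = proto.f1, proto.f2
    for x1 in np.linspace(41.8, 48.2, 17):
        expected = f2 + f2**2 / f1 - (f2 / f1) ** 2 * x1
        assert image_distance(proto, x1) == pytest.approx(expected, rel=1e-12)
    assert image_distance(proto, 45.0) == pytest.approx(18.0)
    assert image_distance(proto, 41.8) == pytest.approx(18.512, abs=1e-3)


def test_degenerate_specimen_position_raises():
    cfg = OpticalConfig(d=100.0)
    # pole of the rational map: f1 f2 - x1 (f1 + f2 - d) - d f1 = 0
    x1_pole = (cfg.f1 * cfg.f2 - cfg.d * cfg.f1) / (cfg.f1 + cfg.f2 - cfg.d)
    with pytest.raises(DegenerateConfigurationError):
        image_distance(cfg, x1_pole)


def test_magnification_telecentric_is_constant(proto):
    for x1 in (42.0, 45.0, 48.0):
        assert magnification(proto, x1) == pytest.approx(-proto.f2 / proto.f1, rel=1e-12)


def test_magnification_varies_off_telecentric(proto):
    cfg = dataclasses.replace(proto, d=150.0)
    assert magnification(cfg, 45.0) != pytest.approx(magnification(cfg, 46.0), rel=1e-6)


def test_stripe_column_center_and_endpoints(proto):
    assert stripe_column(proto, 45.0) == pytest.approx(proto.n_columns / 2, abs=1e-9)
    assert stripe_column(proto, 41.8) == pytest.approx(1280, abs=4)
    assert stripe_column(proto, 48.2) == pytest.approx(0, abs=4)
    lo, hi, span = measurement_range(proto)
    assert round(lo, 1) == 41.8
    assert round(hi, 1) == 48.2
    assert round(span, 1) == 6.4


def test_stripe_column_affine_and_monotone_at_telecentric(proto):
    grid = np.linspace(41.818, 48.182, 1000)
    c = np.array([stripe_column(proto, x) for x in grid])
    assert np.all(np.diff(c) < 0)  # strictly decreasing
    slope, intercept = np.polyfit(grid, c, 1)
    residual = np.abs(c - (slope * grid + intercept))
    assert residual.max() < 1e-6 * np.abs(c).max()
    m = np.array([magnification(proto, x) for x in grid])
    s = np.array([sensitivity(proto, x) for x in grid])
    assert np.ptp(m) < 1e-12
    assert np.ptp(s) < 1e-9 * abs(s[0])


@pytest.mark.parametrize("d", [63.0, 100.0, 150.0, 200.0])
def test_sensitivity_matches_central_difference(proto, d):
    cfg = dataclasses.replace(proto, d=d)
    h = 1e-4
    for x1 in (43.0, 45.0, 47.0):
        fd = (stripe_column(cfg, x1 + h) - stripe_column(cfg, x1 - h)) / (2 * h)
        assert sensitivity(cfg, x1) == pytest.approx(fd, rel=1e-3)


def test_prototype_sensitivity_value(proto):
    """Ideal-case slope of the depth-to-column map: about -201 columns per mm."""
    s = sensitivity(proto, 45.0)
    expected = -(proto.f2 / proto.f1) ** 2 * proto.n_columns / (
        proto.sensor_width * proto.cos_tilt
    )
    assert s == pytest.approx(expected, rel=1e-12)
    assert round(s) == -201


def test_sensitivity_scales_inversely_with_sensor_width(proto):
    wide = dataclasses.replace(proto, sensor_width=2 * proto.sensor_width)
    assert sensitivity(wide, 45.0) == pytest.approx(sensitivity(proto, 45.0) / 2, rel=1e-12)


def test_off_telecentric_sensitivity_is_not_constant(proto):
    cfg = dataclasses.replace(proto, d=100.0)
    s = [sensitivity(cfg, x) for x in (43.0, 45.0, 47.0)]
    assert np.ptp(s) > 1e-3 * abs(s[1])


def test_specimen_from_column_inverts_center(proto):
    assert specimen_from_column(proto, 640.0) == pytest.approx(45.0, abs=1e-9)
    assert specimen_from_column(proto, 1280.0) == pytest.approx(41.818, abs=1e-3)
    assert specimen_from_column(proto, 0.0) == pytest.approx(48.182, abs=1e-3)


@given(x1=st.floats(41.9, 48.1), d=st.sampled_from([63.0, 100.0, 150.0]))
def test_specimen_column_round_trip(x1, d):
    cfg = OpticalConfig(d=d)
    c = stripe_column(cfg, x1)
    x1_back = specimen_from_column(cfg, c)
    # round-trip within 1e-6 px through the forward map
    assert abs(stripe_column(cfg, x1_back) - c) < 1e-6
    assert x1_back == pytest.approx(x1, abs=1e-8)


def test_specimen_from_column_rejects_unreachable(proto):
    # inverse-map pole: x2 = f2 (d - f1) / (d - f1 - f2)
    cfg = dataclasses.replace(proto, d=100.0)
    x2_pole = cfg.f2 * (cfg.d - cfg.f1) / (cfg.d - cfg.f1 - cfg.f2)
    c_pole = (x2_pole - cfg.f2 + cfg.sensor_width * cfg.cos_tilt / 2) / cfg.cos_tilt * (
        cfg.n_columns / cfg.sensor_width
    )
    with pytest.raises(NoSolutionError):
        specimen_from_column(cfg, c_pole)


def test_sweep_prototype_range_and_resolution(proto):
    lo, hi, span = measurement_range(proto)
    table = sweep(proto, np.linspace(lo, hi, 1281))
    assert table["column_px"].max() - table["column_px"].min() == pytest.approx(1280, abs=1e-6)
    assert round(span, 1) == 6.4
    assert round(span / proto.n_columns, 3) == 0.005
    assert not table["off_sensor"].any()


def test_sweep_single_point_matches_scalar_ops(proto):
    t = sweep(proto, [45.0])
    assert len(t) == 1
    assert t.loc[0, "x2_mm"] == pytest.approx(image_distance(proto, 45.0))
    assert t.loc[0, "magnification"] == pytest.approx(magnification(proto, 45.0))
    assert t.loc[0, "column_px"] == pytest.approx(stripe_column(proto, 45.0))
    assert t.loc[0, "sensitivity_per_mm"] == pytest.approx(sensitivity(proto, 45.0))


def test_sweep_flags_degenerate_points_without_aborting():
    cfg = OpticalConfig(d=100.0)
    x1_pole = (cfg.f1 * cfg.f2 - cfg.d * cfg.f1) / (cfg.f1 + cfg.f2 - cfg.d)
    t = sweep(cfg, [45.0, x1_pole, 46.0])
    assert len(t) == 3
    assert math.isnan(t.loc[1, "column_px"]) and t.loc[1, "off_sensor"]
    assert math.isfinite(t.loc[0, "column_px"]) and math.isfinite(t.loc[2, "column_px"])


@pytest.mark.parametrize(
    "kwargs",
    [
        {"f1": -1.0},
        {"d": 0.0},
        {"n_columns": 1},
        {"tilt_deg": 0.0},
        {"tilt_deg": 95.0},
        {"sensor_width": -0.5},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ValueError):
        OpticalConfig(**kwargs)
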