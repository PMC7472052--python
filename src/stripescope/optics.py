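"""Paraxial (ABCD ray-transfer-matrix) model of the tilted-sensor depth encoder.

The instrument is a two-lens wide-field imaging train (objective lens I of
focal length ``f1``, tube lens II of focal length ``f2``, separated by ``d``)
with the image sensor tilted 45 degrees to the optical axis.  A specimen plane
at axial distance ``x1`` in front of lens I is imaged to a plane at distance
``x2`` behind lens II; because the sensor is tilted, only the narrow band of
pixel columns where the sensor crosses that image plane is in focus.  The
column of that in-focus *stripe* therefore encodes specimen depth, and axial
(Z) motion of the specimen reads out as lateral motion of the stripe.

Everything here is closed-form thin-lens paraxial optics.  All lengths are in
millimetres; columns are continuous sensor coordinates with ``c = 0`` at the
left edge and ``c = n_columns`` at the right edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OpticalConfig",
    "RayTransferMatrix",
    "AxialState",
    "DegenerateConfigurationError",
    "NoSolutionError",
    "system_matrix",
    "image_distance",
    "magnification",
    "stripe_column",
    "sensitivity",
    "specimen_from_column",
    "sweep",
]


class DegenerateConfigurationError(ValueError):
    """No finite image exists for this specimen position (imaging condition unsolvable)."""


class NoSolutionError(ValueError):
    """The requested stripe column is unreachable for this optical configuration."""


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the two-lens train and the tilted sensor.

    Parameters
    ----------
    f1, f2 : float
        Effective focal lengths of lens I (objective) and lens II (tube lens), mm.
    d : float
        Separation between the two lenses, mm.  ``d = f1 + f2`` is the
        telecentric (4f) condition giving constant magnification and a
        linear depth-to-column map.
    sensor_width : float
        Width of the sensor image area along the tilted direction, mm.
    n_columns : int
        Number of pixel columns across ``sensor_width``.
    tilt_deg : float
        Sensor tilt relative to the optical axis, degrees.  Only the 45-degree
        prototype geometry is experimentally validated; other angles use the
        same geometric projection with ``cos(tilt)`` substituted.
    """

    f1: float = 45.0
    f2: float = 18.0
    d: float = 63.0
    sensor_width: float = 1.44
    n_columns: int = 1280
    tilt_deg: float = 45.0

    def __post_init__(self) -> None:
        if not (self.f1 > 0 and self.f2 > 0 and self.d > 0 and self.sensor_width > 0):
            raise ValueError("f1, f2, d and sensor_width must all be positive")
        if self.n_columns < 2:
            raise ValueError("n_columns must be at least 2")
        if not 0.0 < self.tilt_deg < 90.0:
            raise ValueError("tilt_deg must lie strictly between 0 and 90 degrees")

    @property
    def cos_tilt(self) -> float:
        return math.cos(math.radians(self.tilt_deg))

    @property
    def is_telecentric(self) -> bool:
        return math.isclose(self.d, self.f1 + self.f2, rel_tol=0.0, abs_tol=1e-12)


#: The laboratory prototype: 45 mm / 18 mm objectives at the 4f separation,
#: a 1.44 mm-wide 1280-column sensor tilted 45 degrees.
PROTOTYPE = OpticalConfig()


@dataclass(frozen=True)
class RayTransferMatrix:
    """2x2 paraxial system matrix.  ``b == 0`` is the imaging condition; ``a`` is then the magnification."""

    a: float
    b: float
    c: float
    d: float

    @property
    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AxialState:
    """Per-specimen-position summary: image distance, magnification, stripe column, sensitivity."""

    x1: float
    x2: float
    magnification: float
    column: float
    sensitivity: float
    off_sensor: bool = field(default=False)


def _translation(t: float) -> np.ndarray:
    return np.array([[1.0, t], [0.0, 1.0]])


def _thin_lens(f: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [-1.0 / f, 1.0]])


def system_matrix(cfg: OpticalConfig, x1: float, x2: float) -> RayTransferMatrix:
    """Ray-transfer matrix from the specimen plane to a candidate image plane.

    Computed as the literal product
    ``T(x2) · L(f2) · T(d) · L(f1) · T(x1)`` of translation and thin-lens
    factors, so the unit-determinant invariant holds by construction.
    """
    if not (math.isfinite(x1) and math.isfinite(x2)):
        raise ValueError("x1 and x2 must be finite")
    m = (
        _translation(x2)
        @ _thin_lens(cfg.f2)
        @ _translation(cfg.d)
        @ _thin_lens(cfg.f1)
        @ _translation(x1)
    )
    return RayTransferMatrix(a=m[0, 0], b=m[0, 1], c=m[1, 0], d=m[1, 1])


def _image_distance_fraction(cfg: OpticalConfig, x1: float) -> tuple[float, float]:
    """Numerator and denominator of the rational-linear map x1 -> x2."""
    f1, f2, d = cfg.f1, cfg.f2, cfg.d
    num = d * x1 * f2 - d * f1 * f2 - x1 * f1 * f2
    den = f1 * f2 - x1 * f2 - x1 * f1 - d * f1 + d * x1
    return num, den


def image_distance(cfg: OpticalConfig, x1: float) -> float:
    """Image-plane distance ``x2`` behind lens II for a specimen at ``x1``.

    Solves the imaging condition (B element of the system matrix equal to
    zero).  Raises :class:`DegenerateConfigurationError` when no finite image
    exists (the rational map has a pole at this ``x1``).
    """
    num, den = _image_distance_fraction(cfg, x1)
    scale = max(abs(num), abs(cfg.f1 * cfg.f2), 1.0)
    if abs(den) < 1e-12 * scale:
        raise DegenerateConfigurationError(
            f"no finite image plane for x1={x1} mm with d={cfg.d} mm"
        )
    return num / den


def magnification(cfg: OpticalConfig, x1: float) -> float:
    """Transverse magnification: the A element evaluated at the imaging condition.

    Negative values denote image inversion.  At the telecentric separation
    ``d = f1 + f2`` this is the constant ``-f2/f1`` independent of ``x1``.
    """
    x2 = image_distance(cfg, x1)
    f1, f2, d = cfg.f1, cfg.f2, cfg.d
    return 1.0 - x2 / f2 - d / f1 + d * x2 / (f1 * f2) - x2 / f1


def _column_from_image_distance(cfg: OpticalConfig, x2: float) -> float:
    ct = cfg.cos_tilt
    w = cfg.sensor_width
    return (x2 - cfg.f2 + w * ct / 2.0) / ct * cfg.n_columns / w


def _image_distance_from_column(cfg: OpticalConfig, c: float) -> float:
    ct = cfg.cos_tilt
    w = cfg.sensor_width
    return cfg.f2 - w * ct / 2.0 + ct * c * w / cfg.n_columns


def stripe_column(cfg: OpticalConfig, x1: float) -> float:
    """Continuous stripe column for a specimen at ``x1``.

    The sensor centre column ``n_columns / 2`` corresponds to an image plane
    at the rear focus of lens II (``x2 = f2``).  Values outside
    ``[0, n_columns]`` mean the stripe falls off the sensor; they are
    returned unchanged (use :func:`sweep` or the caller to flag them) because
    clamping would silently corrupt downstream calibration.
    """
    return _column_from_image_distance(cfg, image_distance(cfg, x1))


def sensitivity(cfg: OpticalConfig, x1: float) -> float:
    """Analytic derivative dc/dx1 of the stripe column, per mm.

    Negative for the prototype: moving the specimen away from lens I moves
    the stripe toward lower columns.
    """
    num, den = _image_distance_fraction(cfg, x1)
    scale = max(abs(num), abs(cfg.f1 * cfg.f2), 1.0)
    if abs(den) < 1e-12 * scale:
        raise DegenerateConfigurationError(
            f"sensitivity undefined at x1={x1} mm with d={cfg.d} mm"
        )
    f1, f2, d = cfg.f1, cfg.f2, cfg.d
    dnum = d * f2 - f1 * f2
    dden = d - f1 - f2
    dx2_dx1 = (dnum * den - num * dden) / den**2
    return dx2_dx1 * cfg.n_columns / (cfg.sensor_width * cfg.cos_tilt)


def specimen_from_column(cfg: OpticalConfig, c: float) -> float:
    """Specimen position ``x1`` whose stripe falls at column ``c`` (inverse map).

    The depth-to-column map is a Mobius (rational-linear) function of ``x1``,
    so its inverse is closed-form for any lens separation; no iteration is
    needed.  Raises :class:`NoSolutionError` when ``c`` is unreachable.
    """
    x2 = _image_distance_from_column(cfg, c)
    f1, f2, d = cfg.f1, cfg.f2, cfg.d
    num = x2 * f1 * (d - f2) - d * f1 * f2
    den = x2 * (d - f1 - f2) + f2 * (f1 - d)
    if abs(den) < 1e-12 * max(abs(num), f1 * f2, 1.0):
        raise NoSolutionError(
            f"column {c} is unreachable for this configuration (inverse map pole)"
        )
    x1 = num / den
    if not math.isfinite(x1) or x1 <= 0:
        raise NoSolutionError(
            f"column {c} maps to non-physical specimen position x1={x1} mm"
        )
    return x1


def sweep(cfg: OpticalConfig, x1_grid: Sequence[float]) -> pd.DataFrame:
    """Evaluate the model over a grid of specimen positions.

    Returns a DataFrame with columns ``x1_mm, x2_mm, magnification,
    column_px, sensitivity_per_mm, off_sensor``.  Degenerate grid points
    (no finite image) are kept as NaN rows rather than aborting the sweep.
    """
    grid = np.asarray(list(x1_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("x1_grid must be nonempty")
    rows = []
    for x1 in grid:
        try:
            x2 = image_distance(cfg, x1)
            m = magnification(cfg, x1)
            c = _column_from_image_distance(cfg, x2)
            s = sensitivity(cfg, x1)
            rows.append((x1, x2, m, c, s, not 0.0 <= c <= cfg.n_columns))
        except DegenerateConfigurationError:
            rows.append((x1, np.nan, np.nan, np.nan, np.nan, True))
    return pd.DataFrame(
        rows,
        columns=[
            "x1_mm",
            "x2_mm",
            "magnification",
            "column_px",
            "sensitivity_per_mm",
            "off_sensor",
        ],
    )


def measurement_range(cfg: OpticalConfig) -> tuple[float, float, float]:
    """Specimen-position endpoints mapped to the sensor edges and their span.

    Returns ``(x1_at_right_edge, x1_at_left_edge, span_mm)`` where the right
    edge is column ``n_columns`` and the left edge is column 0.  For the
    prototype the span is the theoretical maximum measurement range.
    """
    x1_hi_col = specimen_from_column(cfg, float(cfg.n_columns))
    x1_lo_col = specimen_from_column(cfg, 0.0)
    return x1_hi_col, x1_lo_col, abs(x1_lo_col - x1_hi_col)
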