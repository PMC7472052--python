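"""Linear calibration of stripe column against stage displacement.

The instrument is calibrated by stepping the specimen axially in known
increments on a translation stage and recording the stripe column at each
step.  Column ``y`` is regressed on displacement ``x`` with the linear model
``y = a x + b``; displacement is then recovered from a measured column as
``(y - b) / a``.  The worst-case *indication error* — the largest
discrepancy between stage displacement and the displacement the fitted
sensor indicates — summarises calibration accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .optics import OpticalConfig, specimen_from_column, stripe_column
from .synth import SceneConfig

__all__ = [
    "CalibrationTable",
    "CalibrationFit",
    "fit_calibration",
    "column_to_displacement",
    "displacement_to_column",
    "simulate_calibration_run",
]


@dataclass(frozen=True)
class CalibrationTable:
    """Paired stage displacements (mm) and measured stripe columns (px)."""

    displacements: np.ndarray
    columns: np.ndarray
    column_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        c = np.asarray(self.columns, dtype=float)
        if d.ndim != 1 or d.shape != c.shape:
            raise ValueError("displacements and columns must be 1-D and the same length")
        if d.size < 2:
            raise ValueError("need at least 2 calibration points")
        diffs = np.diff(d)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("displacements must be strictly monotone")
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "columns", c)
        if self.column_sd is not None:
            s = np.asarray(self.column_sd, dtype=float)
            if s.shape != d.shape:
                raise ValueError("column_sd must match the table length")
            object.__setattr__(self, "column_sd", s)

    def __len__(self) -> int:
        return self.displacements.size


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line column = a * displacement + b with 1-sigma standard errors."""

    a: float                      # slope, px per mm
    b: float                      # intercept, px
    se_a: float
    se_b: float
    pearson_r: float
    max_indication_error_mm: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "a_per_mm": self.a,
            "b_px": self.b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "pearson_r": self.pearson_r,
            "max_indication_error_mm": self.max_indication_error_mm,
            "n_points": self.n_points,
        }


def fit_calibration(table: CalibrationTable) -> CalibrationFit:
    """Ordinary least squares of column on displacement.

    Standard errors come from the residual variance (undefined at two
    points: reported as 0 with a warning).  ``max_indication_error_mm`` is
    the largest |inverse-predicted − true| displacement over the table
    itself, matching how the instrument's indication error is quoted.
    """
    x, y = table.displacements, table.columns
    res = stats.linregress(x, y)
    a, b = float(res.slope), float(res.intercept)
    if a == 0.0:
        raise ValueError("degenerate calibration: fitted slope is zero")
    se_a, se_b = float(res.stderr), float(res.intercept_stderr)
    if len(table) == 2:
        warnings.warn(
            "two-point calibration: exact interpolating line, standard errors undefined "
            "(reported as 0)",
            stacklevel=2,
        )
        se_a = se_b = 0.0
    max_err = float(np.max(np.abs((y - b) / a - x)))
    return CalibrationFit(
        a=a,
        b=b,
        se_a=se_a,
        se_b=se_b,
        pearson_r=float(res.rvalue),
        max_indication_error_mm=max_err,
        n_points=len(table),
    )


def column_to_displacement(fit: CalibrationFit, column: float | np.ndarray):
    """Invert the calibration line: displacement = (column - b) / a."""
    if fit.a == 0:
        raise ZeroDivisionError("calibration slope is zero")
    return (np.asarray(column, dtype=float) - fit.b) / fit.a


def displacement_to_column(fit: CalibrationFit, displacement: float | np.ndarray):
    """Forward calibration line: column = a * displacement + b."""
    return fit.a * np.asarray(displacement, dtype=float) + fit.b


def simulate_calibration_run(
    optics_cfg: OpticalConfig,
    scene: SceneConfig,
    n_steps: int = 13,
    step_mm: float = 0.5,
    seed: int | None = None,
    mask=None,
    quality=None,
) -> CalibrationTable:
    """Emulate the stage-stepping calibration protocol end to end.

    Starts with the stripe at the right sensor edge (highest column), steps
    the specimen away from the objective in increments of ``step_mm``,
    renders a frame at each step and localizes the stripe.  Steps whose true
    stripe column leaves the sensor truncate the run with a warning, as the
    physical protocol stops when the stripe reaches the left edge.
    """
    from .filtering import BandpassSpec, build_mask
    from .stripe import QualitySpec, estimate_stripe
    from .synth import render_frame

    if mask is None:
        mask = build_mask((scene.rows, optics_cfg.n_columns), BandpassSpec())
    if quality is None:
        quality = QualitySpec()
    if seed is None:
        seed = scene.seed
    rng = np.random.default_rng(seed)
    # place the first step half a step inside the right edge so every
    # rendered stripe is fully on-sensor
    x1_start = specimen_from_column(optics_cfg, optics_cfg.n_columns - 1.0)
    displacements, columns = [], []
    for k in range(n_steps):
        x1 = x1_start + k * step_mm
        c_true = stripe_column(optics_cfg, x1)
        if not 0.0 <= c_true <= optics_cfg.n_columns:
            warnings.warn(
                f"calibration run truncated at step {k}: stripe column {c_true:.1f} "
                "is off the sensor",
                stacklevel=2,
            )
            break
        frame = render_frame(optics_cfg, scene, x1, rng=rng)
        est = estimate_stripe(frame, mask, quality)
        if not est.valid:
            warnings.warn(f"invalid stripe estimate at step {k}; skipping", stacklevel=2)
            continue
        displacements.append(k * step_mm)
        columns.append(est.column_mean)
    return CalibrationTable(
        displacements=np.asarray(displacements), columns=np.asarray(columns)
    )
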