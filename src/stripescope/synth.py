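"""Seeded synthetic renderer for tilted-sensor frames and motion sequences.

Real recordings from the instrument show three superimposed components: a
high-spatial-frequency texture band (the in-focus stripe) whose column
position encodes specimen depth, a smooth illumination baseline that drifts
across the field, and sensor noise.  This module renders frames with exactly
those three components so the whole pipeline — filtering, stripe
localization, calibration, motion analysis — can be exercised against known
ground truth.

The specimen texture is a sine grating along columns whose phase advances
slightly from row to row (a skewed grating).  Only the grating's spatial
frequency matters to the estimator; the skew makes per-row peak positions
sample different grating phases so that the row-averaged stripe position
gains sub-pixel precision, as the pixel mosaic of a real specimen does.
Defocus away from the in-focus column is modelled by the exact amplitude
attenuation a Gaussian blur applies to a sinusoid:
``exp(-2 pi^2 sigma^2 / period^2)`` with blur width ``sigma`` growing
linearly with column distance from the stripe centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import OpticalConfig, stripe_column

__all__ = [
    "BaselineModel",
    "SceneConfig",
    "MotionWaveform",
    "OffSensorWarning",
    "AliasingWarning",
    "render_frame",
    "render_sequence",
    "make_waveform",
]


class OffSensorWarning(UserWarning):
    """The stripe column for the requested specimen position falls off the sensor."""


class AliasingWarning(UserWarning):
    """A waveform component frequency is at or above the Nyquist limit of the frame rate."""


@dataclass(frozen=True)
class BaselineModel:
    """Smooth illumination field: 2-D polynomial (degree <= 2) plus an optional broad Gaussian blob.

    ``poly`` holds coefficients of ``u^i * v^j`` on coordinates normalised to
    [-1, 1] across the frame, keyed ``(i, j)`` with ``i + j <= 2``; units are
    grey levels.  The blob emulates vignetting / uneven epi-illumination.
    """

    poly: dict = field(default_factory=lambda: {(0, 0): 90.0, (1, 0): 4.0, (0, 1): 2.0})
    blob_amplitude: float = 6.0
    blob_center: tuple[float, float] = (0.2, -0.1)  # (u, v) in normalised coords
    blob_sigma: float = 0.7

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        u = np.linspace(-1.0, 1.0, cols)[np.newaxis, :]
        v = np.linspace(-1.0, 1.0, rows)[:, np.newaxis]
        out = np.zeros((rows, cols))
        for (i, j), coef in self.poly.items():
            if i + j > 2:
                raise ValueError("baseline polynomial degree must be <= 2")
            out = out + coef * u**i * v**j
        if self.blob_amplitude:
            r2 = (u - self.blob_center[0]) ** 2 + (v - self.blob_center[1]) ** 2
            out = out + self.blob_amplitude * np.exp(-r2 / (2.0 * self.blob_sigma**2))
        return out


@dataclass(frozen=True)
class SceneConfig:
    """Rendering parameters for one synthetic specimen/illumination condition.

    Defaults emulate the prototype's functional-test scene: a fine periodic
    specimen texture whose spectral energy sits mid-way through the 20-300
    frequency-pixel annulus the bandpass filter passes, modest baseline
    drift, and a low sensor noise floor.
    """

    rows: int = 720
    texture_period: float = 8.0       # px per cycle; spectral radius = n_cols / period
    texture_contrast: float = 80.0    # grey levels, peak amplitude of the grating
    row_phase_skew: float = 0.05      # grating cycles of phase advance per row
    stripe_core_px: float = 4.0       # half-width of the fully in-focus band
    blur_scale: float = 0.08          # blur sigma px per px of distance from the stripe
    baseline: BaselineModel = field(default_factory=BaselineModel)
    noise_sigma: float = 2.0          # grey levels, additive Gaussian
    poisson_noise: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if self.texture_period < 2:
            raise ValueError("texture_period must be >= 2 px to be representable")
        if self.texture_contrast <= 0:
            raise ValueError("texture_contrast must be positive")
        if self.noise_sigma < 0 or self.blur_scale < 0:
            raise ValueError("noise_sigma and blur_scale must be non-negative")


@dataclass(frozen=True)
class MotionWaveform:
    """Sampled specimen trajectory: times (s) and axial positions x1 (mm)."""

    times: np.ndarray
    x1_values: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x1_values, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("times and x1_values must be 1-D and the same length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x1_values", x)

    def __len__(self) -> int:
        return self.times.size


def stripe_envelope(columns: np.ndarray, center: float, scene: SceneConfig) -> np.ndarray:
    """Texture-contrast attenuation profile across columns.

    1 inside the in-focus core, then the Gaussian-blur attenuation of a
    sinusoid of the scene's period with blur sigma growing linearly in the
    distance from the stripe centre.
    """
    dist = np.abs(np.asarray(columns, dtype=float) - center)
    sigma = scene.blur_scale * dist
    env = np.exp(-2.0 * np.pi**2 * sigma**2 / scene.texture_period**2)
    env[dist <= scene.stripe_core_px] = 1.0
    return env


def render_frame(
    optics_cfg: OpticalConfig,
    scene: SceneConfig,
    x1: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame (float64 grid, rows x n_columns) for a specimen at ``x1``.

    Deterministic given the scene seed (or an explicit ``rng``).  If the
    stripe column falls off the sensor an :class:`OffSensorWarning` is
    emitted and the frame contains only strongly defocused texture,
    baseline and noise.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    cols = optics_cfg.n_columns
    c = stripe_column(optics_cfg, x1)
    if not 0.0 <= c <= cols:
        warnings.warn(
            f"stripe column {c:.1f} for x1={x1} mm is off the sensor [0, {cols}]",
            OffSensorWarning,
            stacklevel=2,
        )
    col_idx = np.arange(cols, dtype=float)
    row_idx = np.arange(scene.rows, dtype=float)
    envelope = stripe_envelope(col_idx, c, scene)
    phase = 2.0 * np.pi * (
        col_idx[np.newaxis, :] / scene.texture_period
        + scene.row_phase_skew * row_idx[:, np.newaxis]
    )
    texture = scene.texture_contrast * envelope[np.newaxis, :] * np.sin(phase)
    frame = scene.baseline.evaluate((scene.rows, cols)) + texture
    if scene.poisson_noise:
        frame = rng.poisson(np.clip(frame, 0.0, None)).astype(float)
    if scene.noise_sigma > 0:
        frame = frame + rng.normal(0.0, scene.noise_sigma, size=frame.shape)
    return frame


def render_sequence(
    optics_cfg: OpticalConfig,
    scene: SceneConfig,
    waveform: MotionWaveform,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one frame per waveform sample plus a ground-truth table.

    Returns ``(stack, truth)`` where ``stack`` is ``(n, rows, cols)`` float64
    and ``truth`` has columns ``frame_index, time_s, x1_mm, column_px,
    off_sensor``.  A single RNG seeded from the scene seed drives the whole
    sequence, so identical inputs give bit-identical stacks.
    """
    rng = np.random.default_rng(scene.seed)
    n = len(waveform)
    stack = np.empty((n, scene.rows, optics_cfg.n_columns), dtype=np.float32)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OffSensorWarning)
        for i, (t, x1) in enumerate(zip(waveform.times, waveform.x1_values)):
            stack[i] = render_frame(optics_cfg, scene, x1, rng=rng)
            c = stripe_column(optics_cfg, x1)
            records.append((i, t, x1, c, not 0.0 <= c <= optics_cfg.n_columns))
    truth = pd.DataFrame(
        records, columns=["frame_index", "time_s", "x1_mm", "column_px", "off_sensor"]
    )
    return stack, truth


def make_waveform(
    kind: str,
    duration_s: float = 10.0,
    frame_rate: float = 30.0,
    center_mm: float = 45.0,
    amplitude_mm: float = 0.5,
    frequency_hz: float = 1.0,
    cardiac_frequency_hz: float = 7.0,
    cardiac_ratio: float = 0.01,
) -> MotionWaveform:
    """Build a sampled specimen trajectory.

    kind
        ``constant`` — fixed position at ``center_mm``;
        ``sine`` — ``center + amplitude * sin(2 pi f t)``, emulating
        respiration-dominated organ motion;
        ``resp_plus_cardiac`` — the respiratory sine plus a cardiac
        component at ``cardiac_frequency_hz`` with amplitude
        ``cardiac_ratio`` times the respiratory one (heartbeat-induced
        motion is roughly 100x smaller than respiratory motion outside the
        heart itself).

    ``amplitude_mm`` is the half-amplitude of the respiratory sine.  An
    :class:`AliasingWarning` is emitted when any component frequency reaches
    the Nyquist limit ``frame_rate / 2``.
    """
    n = int(round(duration_s * frame_rate))
    if n < 1:
        raise ValueError("duration too short for the frame rate")
    t = np.arange(n) / frame_rate
    if kind == "constant":
        x1 = np.full(n, center_mm)
    elif kind in ("sine", "resp_plus_cardiac"):
        freqs = [frequency_hz] if kind == "sine" else [frequency_hz, cardiac_frequency_hz]
        for f in freqs:
            if f >= frame_rate / 2.0:
                warnings.warn(
                    f"component at {f} Hz is at or above Nyquist ({frame_rate / 2} Hz); "
                    "the sampled waveform will alias",
                    AliasingWarning,
                    stacklevel=2,
                )
        x1 = center_mm + amplitude_mm * np.sin(2.0 * np.pi * frequency_hz * t)
        if kind == "resp_plus_cardiac":
            x1 = x1 + cardiac_ratio * amplitude_mm * np.sin(
                2.0 * np.pi * cardiac_frequency_hz * t
            )
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    return MotionWaveform(times=t, x1_values=x1, frame_rate=frame_rate)


def amplitude_for_column_span(optics_cfg: OpticalConfig, span_px: float, center_mm: float = 45.0) -> float:
    """Half-amplitude in mm that makes a sine waveform's stripe sweep ``span_px`` peak-to-peak.

    Uses the local model sensitivity at the trajectory centre; exact for a
    telecentric configuration where the depth-to-column map is affine.
    """
    from .optics import sensitivity

    return span_px / (2.0 * abs(sensitivity(optics_cfg, center_mm)))
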