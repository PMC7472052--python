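"""Readers and writers: frame stacks, traces, tables, fits, reports, config.

File conventions
----------------
* Frame stacks: multi-page grayscale TIFF, or a directory of equally-shaped
  PNG/TIFF frames read in lexicographic order.  Color frames are collapsed
  to luminance with the Rec. 601 weights (0.299 R + 0.587 G + 0.114 B).
* Traces / calibration tables / model sweeps: CSV with headers, floats at 6
  significant digits, empty cells (not zeros) for missing values.
* Calibration fits and motion reports: JSON.
* Run configuration: YAML with ``optics``, ``scene``, ``bandpass``,
  ``quality`` and ``seed`` sections; absent keys fall back to the prototype
  defaults.

Indexing is 0-based everywhere; column 0 is the leftmost sensor column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationFit, CalibrationTable
from .filtering import BandpassSpec, FrequencyMask
from .motion import MotionTrace
from .optics import OpticalConfig
from .stripe import QualitySpec
from .synth import SceneConfig

logger = logging.getLogger("stripescope")

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "read_table",
    "write_table",
    "read_fit",
    "write_fit",
    "write_report",
    "write_sweep",
    "read_mask",
    "write_mask",
    "load_config",
]

_FLOAT_FMT = "%.6g"
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_luminance(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        if frame.shape[-1] == 4:
            frame = frame[..., :3]
        if frame.shape[-1] != 3:
            raise ValueError(f"cannot interpret frame of shape {frame.shape}")
        frame = frame @ _LUMA
    elif frame.ndim != 2:
        raise ValueError(f"cannot interpret frame of shape {frame.shape}")
    return frame.astype(np.float64)


def read_stack(path: str | Path) -> np.ndarray:
    """Load a frame stack as ``(n, rows, cols)`` float64 luminance.

    ``path`` is either a multi-page TIFF or a directory of PNG/TIFF frames
    (lexicographic order).  Mixed frame shapes are an error naming the
    offending file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in directory {path}")
        frames = []
        shape = None
        for f in files:
            try:
                frame = _to_luminance(iio.imread(f))
            except Exception as exc:  # noqa: BLE001 - reraise with the file name
                raise OSError(f"unreadable frame file {f}") from exc
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise ValueError(f"frame {f} has shape {frame.shape}, expected {shape}")
            frames.append(frame)
        stack = np.stack(frames)
    else:
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable TIFF stack {path}") from exc
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim == 4:  # pages x rows x cols x channels
            data = np.stack([_to_luminance(f) for f in data])
        stack = data.astype(np.float64)
    logger.info("read stack %s: %d frames of %s", path, stack.shape[0], stack.shape[1:])
    return stack


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a stack as 8-bit multi-page TIFF (values clipped to [0, 255])."""
    data = np.clip(np.asarray(stack), 0, 255).round().astype(np.uint8)
    if data.ndim == 2:
        data = data[np.newaxis]
    tifffile.imwrite(Path(path), data, photometric="minisblack")
    logger.info("wrote stack %s: %d frames", path, data.shape[0])


def write_trace(path: str | Path, trace: MotionTrace) -> None:
    n = len(trace)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "time_s": trace.times,
            "column_px": trace.columns,
            "column_sd_px": trace.column_sd if trace.column_sd is not None else np.full(n, np.nan),
            "n_rows_used": trace.n_rows_used if trace.n_rows_used is not None else np.zeros(n, int),
            "valid": (
                trace.valid
                if trace.valid is not None
                else np.isfinite(trace.columns)
            ).astype(int),
        }
    )
    if trace.displacements is not None:
        df["displacement_mm"] = trace.displacements
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_trace(path: str | Path, frame_rate: float | None = None) -> MotionTrace:
    df = pd.read_csv(Path(path))
    times = df["time_s"].to_numpy(float)
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(times))) if len(df) > 1 else 30.0
    return MotionTrace(
        times=times,
        columns=df["column_px"].to_numpy(float),
        frame_rate=frame_rate,
        displacements=(
            df["displacement_mm"].to_numpy(float) if "displacement_mm" in df else None
        ),
        column_sd=df["column_sd_px"].to_numpy(float) if "column_sd_px" in df else None,
        valid=df["valid"].to_numpy(bool) if "valid" in df else None,
    )


def write_table(path: str | Path, table: CalibrationTable) -> None:
    df = pd.DataFrame(
        {"displacement_mm": table.displacements, "column_px": table.columns}
    )
    if table.column_sd is not None:
        df["column_sd_px"] = table.column_sd
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> CalibrationTable:
    df = pd.read_csv(Path(path))
    return CalibrationTable(
        displacements=df["displacement_mm"].to_numpy(float),
        columns=df["column_px"].to_numpy(float),
        column_sd=df["column_sd_px"].to_numpy(float) if "column_sd_px" in df else None,
    )


def write_fit(path: str | Path, fit: CalibrationFit) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit(path: str | Path) -> CalibrationFit:
    d = json.loads(Path(path).read_text())
    return CalibrationFit(
        a=d["a_per_mm"],
        b=d["b_px"],
        se_a=d["se_a"],
        se_b=d["se_b"],
        pearson_r=d["pearson_r"],
        max_indication_error_mm=d["max_indication_error_mm"],
        n_points=d["n_points"],
    )


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, allow_nan=False) + "\n")


def write_sweep(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_mask(path: str | Path, mask: FrequencyMask) -> None:
    """Export a frequency mask as 32-bit float TIFF for visual inspection."""
    tifffile.imwrite(Path(path), mask.values.astype(np.float32))


def read_mask(path: str | Path) -> FrequencyMask:
    return FrequencyMask(values=tifffile.imread(Path(path)).astype(np.float64))


def _section(raw: dict, key: str) -> dict:
    value = raw.get(key) or {}
    if not isinstance(value, dict):
        raise ValueError(f"config section {key!r} must be a mapping")
    return value


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML run configuration, filling prototype defaults.

    Returns a dict with instantiated ``optics`` (:class:`OpticalConfig`),
    ``scene`` (:class:`SceneConfig`), ``bandpass`` (:class:`BandpassSpec`),
    ``quality`` (:class:`QualitySpec`) and ``seed``.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    optics_raw = _section(raw, "optics")
    key_map = {
        "f1_mm": "f1",
        "f2_mm": "f2",
        "d_mm": "d",
        "sensor_width_mm": "sensor_width",
        "n_columns": "n_columns",
        "tilt_deg": "tilt_deg",
    }
    optics_kwargs = {key_map[k]: v for k, v in optics_raw.items() if k in key_map}
    unknown = set(optics_raw) - set(key_map)
    if unknown:
        raise ValueError(f"unknown optics config keys: {sorted(unknown)}")
    scene_raw = _section(raw, "scene")
    if "baseline" in scene_raw:
        from .synth import BaselineModel

        b = scene_raw.pop("baseline")
        scene_raw["baseline"] = BaselineModel(
            poly={tuple(int(x) for x in k.split(",")): v for k, v in b.get("poly", {}).items()}
            if "poly" in b
            else BaselineModel().poly,
            blob_amplitude=b.get("blob_amplitude", BaselineModel().blob_amplitude),
        )
    return {
        "optics": OpticalConfig(**optics_kwargs),
        "scene": SceneConfig(**scene_raw),
        "bandpass": BandpassSpec(**_section(raw, "bandpass")),
        "quality": QualitySpec(**_section(raw, "quality")),
        "seed": int(raw.get("seed", 7)),
    }
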