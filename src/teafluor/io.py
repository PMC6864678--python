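"""Spectral CSV dialect and dataset manifests.

One CSV file per measurement: first column the wavelength in nm printed with
5 decimals, then eight intensity columns headed LED1..LED7, BACKGROUND.  A
JSON manifest in the dataset directory lists the files, their class labels,
the generator seed and parameters.  Processed matrices use a transposed
layout (7 rows x 837 columns, wavelength header) matching how the
classifiers consume them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .grid import WavelengthGrid
from .preprocess import ProcessedMatrix
from .synthetic import RawMeasurement

__all__ = [
    "write_measurement_csv",
    "read_measurement_csv",
    "write_dataset",
    "read_dataset",
    "write_processed_csv",
    "read_processed_csv",
]

_ROW_HEADERS = [f"LED{i}" for i in range(1, 8)] + ["BACKGROUND"]
MANIFEST_NAME = "manifest.json"


def write_measurement_csv(raw: RawMeasurement, path) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": raw.grid.wavelengths}
        | {h: raw.rows[i] for i, h in enumerate(_ROW_HEADERS)}
    )
    df.to_csv(path, index=False, float_format="%.5f")


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    steps = np.diff(wl)
    if len(wl) < 2 or not np.allclose(steps, steps[0], atol=1e-4):
        raise FormatError("wavelength column is not uniformly spaced")
    # recover the exact step from the full span (single-step differences are
    # quantized by the 5-decimal print format)
    step = (wl[-1] - wl[0]) / (len(wl) - 1)
    return WavelengthGrid(start_nm=float(wl[0]), end_nm=float(wl[-1]), step_nm=float(step))


def read_measurement_csv(path, label: str) -> RawMeasurement:
    df = pd.read_csv(path)
    missing = [h for h in ["wavelength_nm", *_ROW_HEADERS] if h not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    rows = np.stack([df[h].to_numpy(float) for h in _ROW_HEADERS])
    return RawMeasurement(grid=grid, rows=rows, label=label)


def write_dataset(directory, measurements: list[RawMeasurement], seed: int, params: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, raw in enumerate(measurements):
        name = f"measurement_{i:05d}.csv"
        write_measurement_csv(raw, directory / name)
        entries.append({"file": name, "label": raw.label})
    manifest = {"seed": seed, "parameters": params or {}, "measurements": entries}
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def read_dataset(directory) -> tuple[list[RawMeasurement], dict]:
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    measurements = [
        read_measurement_csv(directory / e["file"], e["label"])
        for e in manifest["measurements"]
    ]
    return measurements, manifest


def write_processed_csv(matrix: ProcessedMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=[f"LED{i}" for i in range(1, 8)],
                      columns=np.round(matrix.wavelengths, 5))
    df.to_csv(path, index_label="row")


def read_processed_csv(path, label: str) -> ProcessedMatrix:
    df = pd.read_csv(path, index_col="row")
    wavelengths = df.columns.to_numpy(float)
    return ProcessedMatrix(values=df.to_numpy(float), wavelengths=wavelengths, label=label)
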