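"""Spectral pre-processing: background subtraction, Savitzky-Golay smoothing,
chlorophyll-peak normalization, truncation to the 500-900 nm window.

The steps are applied in exactly this order; normalization must follow
smoothing because the smoother changes the 650-700 nm maximum that the
normalization divides by.  Each eight-row acquisition becomes a 7 x 837
matrix: the background row is consumed by the subtraction, and each LED row
is independently rescaled so its maximum over 650-700 nm (the red
chlorophyll peak) equals 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, FormatError, ParameterError
from .grid import WINDOW_POINTS, WavelengthGrid
from .synthetic import RawMeasurement

__all__ = [
    "CHL_PEAK_LO_NM",
    "CHL_PEAK_HI_NM",
    "ProcessedMatrix",
    "subtract_background",
    "smooth_sg",
    "normalize_to_chl_peak",
    "truncate_to_window",
    "preprocess_measurement",
    "split_dataset",
]

# reference region holding the first (red) chlorophyll peak
CHL_PEAK_LO_NM = 650.0
CHL_PEAK_HI_NM = 700.0

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 2


@dataclass(frozen=True)
class ProcessedMatrix:
    """Normalized 7 x 837 excitation-emission matrix of one measurement."""

    values: np.ndarray  # (7, 837)
    wavelengths: np.ndarray  # (837,), 500..900 nm
    label: str

    def __post_init__(self) -> None:
        if self.values.shape != (7, WINDOW_POINTS):
            raise FormatError(f"processed matrix shape {self.values.shape} != (7, {WINDOW_POINTS})")


def subtract_background(raw: RawMeasurement) -> np.ndarray:
    """Subtract the dark row (row 8) from each of the seven LED rows.

    Negative values are permitted; smoothing and normalization follow.
    """
    if raw.rows.shape[0] != 8:
        raise FormatError(f"expected 8 rows, got {raw.rows.shape[0]}")
    return raw.rows[:7] - raw.rows[7]


def smooth_sg(
    spectrum: np.ndarray,
    window_length: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLYORDER,
) -> np.ndarray:
    """Savitzky-Golay smoothing: sliding least-squares polynomial fit.

    Edges are handled by fitting the polynomial over the last full window and
    evaluating it at the edge points (scipy's ``mode='interp'``), i.e. a
    one-sided polynomial extrapolation rather than signal padding.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window_length % 2 == 0:
        raise ParameterError(f"window_length must be odd, got {window_length}")
    if window_length <= poly_order:
        raise ParameterError("window_length must exceed poly_order")
    if spectrum.shape[-1] < window_length:
        raise ParameterError("spectrum shorter than the smoothing window")
    return savgol_filter(spectrum, window_length, poly_order, axis=-1, mode="interp")


def normalize_to_chl_peak(
    spectrum: np.ndarray,
    grid: WavelengthGrid,
    measurement_id: str | None = None,
) -> np.ndarray:
    """Divide by the maximum over the 650-700 nm red-chlorophyll region."""
    idx = grid.window_indices(CHL_PEAK_LO_NM, CHL_PEAK_HI_NM)
    peak = float(np.max(np.asarray(spectrum, float)[..., idx]))
    if peak <= 0:
        raise DegenerateSpectrumError(
            f"non-positive maximum ({peak:g}) in the {CHL_PEAK_LO_NM:g}-{CHL_PEAK_HI_NM:g} nm "
            f"normalization region (measurement {measurement_id or 'unknown'})",
            measurement_id=measurement_id,
        )
    return spectrum / peak


def truncate_to_window(spectrum: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Keep the 837 samples with wavelength in [500, 900] nm."""
    grid.validate_window()
    idx = grid.window_indices()
    return np.asarray(spectrum)[..., idx]


def preprocess_measurement(
    raw: RawMeasurement,
    window_length: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLYORDER,
    measurement_id: str | None = None,
) -> ProcessedMatrix:
    """Full pipeline: subtract -> smooth -> normalize (per LED row) -> truncate."""
    corrected = subtract_background(raw)
    smoothed = smooth_sg(corrected, window_length, poly_order)
    normalized = np.stack(
        [
            normalize_to_chl_peak(row, raw.grid, measurement_id=measurement_id)
            for row in smoothed
        ]
    )
    truncated = truncate_to_window(normalized, raw.grid)
    wavelengths = raw.grid.wavelengths[raw.grid.window_indices()]
    return ProcessedMatrix(values=truncated, wavelengths=wavelengths, label=raw.label)


def split_dataset(
    matrices: list[ProcessedMatrix],
    fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[ProcessedMatrix], list[ProcessedMatrix]]:
    """Stratified random train/test split, deterministic given ``seed``.

    ``fraction`` is the training share per class (default the 50/50 split).
    """
    if not 0 < fraction < 1:
        raise ParameterError("fraction must lie strictly between 0 and 1")
    by_class: dict[str, list[int]] = defaultdict(list)
    for i, m in enumerate(matrices):
        by_class[m.label].append(i)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.asarray(by_class[label])
        if len(idx) < 2:
            raise ParameterError(f"class {label} has {len(idx)} samples; need >= 2 to split")
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train = [matrices[i] for i in sorted(train_idx)]
    test = [matrices[i] for i in sorted(test_idx)]
    return train, test
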