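"""Wavelength axis of the simulated spectrometer.

The instrument records from the near-UV to the NIR on a uniform grid.  Only
the emission window 500-900 nm is analysed downstream; the grid is aligned so
that this closed window contains exactly ``WINDOW_POINTS`` samples, which
fixes the step to 400/836 nm.  With a 200 nm start, both 500 nm and 900 nm
then fall exactly on grid points (300 and 400 are integer multiples of the
step times 627 and 836 respectively).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import ConfigurationError

WINDOW_LO_NM = 500.0
WINDOW_HI_NM = 900.0
WINDOW_POINTS = 837
DEFAULT_STEP_NM = (WINDOW_HI_NM - WINDOW_LO_NM) / (WINDOW_POINTS - 1)

# half a picometre: forgiving of float round-off, far below the grid step
_TOL_NM = 5e-4


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling axis, in nanometres."""

    start_nm: float = 200.0
    end_nm: float = 1100.0
    step_nm: float = DEFAULT_STEP_NM

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ConfigurationError("grid step must be positive")
        if self.start_nm > WINDOW_LO_NM or self.end_nm < WINDOW_HI_NM:
            raise ConfigurationError(
                f"grid [{self.start_nm}, {self.end_nm}] nm must cover the "
                f"[{WINDOW_LO_NM}, {WINDOW_HI_NM}] nm analysis window"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @cached_property
    def wavelengths(self) -> np.ndarray:
        wl = self.start_nm + self.step_nm * np.arange(self.n_points)
        wl.setflags(write=False)
        return wl

    def window_indices(self, lo_nm: float = WINDOW_LO_NM, hi_nm: float = WINDOW_HI_NM) -> np.ndarray:
        """Indices of grid points inside the closed interval [lo, hi] nm."""
        wl = self.wavelengths
        return np.nonzero((wl >= lo_nm - _TOL_NM) & (wl <= hi_nm + _TOL_NM))[0]

    def index_nearest(self, wavelength_nm: float) -> int:
        i = int(round((wavelength_nm - self.start_nm) / self.step_nm))
        return min(max(i, 0), self.n_points - 1)

    def validate_window(self) -> None:
        """Raise unless the closed [500, 900] nm window holds exactly 837 points."""
        n = len(self.window_indices())
        if n != WINDOW_POINTS:
            raise ConfigurationError(
                f"[{WINDOW_LO_NM:g}, {WINDOW_HI_NM:g}] nm window contains {n} "
                f"grid points, expected {WINDOW_POINTS}"
            )


def default_grid() -> WavelengthGrid:
    """Spectrometer-range grid (200-1100 nm) aligned to the 837-point window."""
    grid = WavelengthGrid()
    grid.validate_window()
    return grid
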