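"""Forward model of the multi-channel LED-induced fluorescence measurement.

One acquisition lights seven near-UV/blue LEDs in sequence, recording a full
emission spectrum for each, and finishes with a background row taken with all
LEDs off.  Leaf fluorescence is modelled as three Gaussian emission bands:

* a broad *green-orange* band between 500 and 600 nm, excited efficiently
  only by the most ultraviolet LED (371 nm);
* the *red* chlorophyll-a band near 680 nm;
* the *far-red* chlorophyll-a band near 740 nm.

Each tea class is a :class:`TeaClassProfile`: per-band mean amplitudes
(relative to the red chlorophyll peak), per-band coefficients of variation,
band centres, and an excitation-efficiency map over the seven LEDs derived
from a class-specific Soret-absorption optimum.  The far-red/red amplitude
ratio encodes fermentation grade: above 0.6 for the green and white classes,
below 0.6 for the two black classes, with G-HM and B-L placed close to that
boundary so the two fermentation grades can overlap measurement-to-
measurement.

Measurement-to-measurement variation has four components, all scaled by a
single ``overlap`` dial: lognormal band-amplitude draws (one draw per band
per acquisition, shared by all seven LED rows), a shared wavelength jitter of
every band centre, a shared lognormal band-width scale, and additive Gaussian
detector noise.  ``overlap=0`` gives essentially noiseless, well separated
classes; ``overlap=1`` is the calibrated regime in which linear baselines
make errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError
from .grid import WavelengthGrid, default_grid

__all__ = [
    "LED_CENTERS_NM",
    "CLASS_LABELS",
    "GREEN_CLASSES",
    "BLACK_CLASSES",
    "WHITE_CLASSES",
    "BAND_GREEN_ORANGE",
    "BAND_CHL_RED",
    "BAND_CHL_FAR_RED",
    "LEDProfile",
    "FluorophoreBand",
    "TeaClassProfile",
    "NoiseModel",
    "RawMeasurement",
    "default_led_profiles",
    "default_class_profiles",
    "simulate_measurement",
    "generate_dataset",
]

LED_CENTERS_NM = (371.0, 381.0, 394.0, 404.0, 412.0, 423.0, 431.0)

CLASS_LABELS = ("G-LJ1", "G-LJ2", "G-LJ3", "W-MC", "G-V", "G-HM", "B-KM", "B-L", "G-WNZ")
GREEN_CLASSES = tuple(c for c in CLASS_LABELS if c.startswith("G-"))
BLACK_CLASSES = ("B-KM", "B-L")
WHITE_CLASSES = ("W-MC",)

BAND_GREEN_ORANGE = "green_orange"
BAND_CHL_RED = "chl_red"
BAND_CHL_FAR_RED = "chl_far_red"

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


@dataclass(frozen=True)
class LEDProfile:
    """Normalized Gaussian emission line of one excitation LED."""

    center_nm: float
    fwhm_nm: float = 15.0
    peak_intensity: float = 1.0

    def intensity(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_nm * _FWHM_TO_SIGMA
        return self.peak_intensity * _gaussian(np.asarray(wavelengths_nm, float), self.center_nm, sigma)


@dataclass(frozen=True)
class FluorophoreBand:
    """One Gaussian emission band; ``width_nm`` is the Gaussian standard deviation."""

    name: str
    center_nm: float
    width_nm: float


@dataclass(frozen=True)
class TeaClassProfile:
    """Generator parameters of one tea class.

    ``band_mean_amplitude`` is expressed relative to the red chlorophyll peak
    (the red band therefore has amplitude 1.0 by convention), so that after
    per-row normalization to the 650-700 nm maximum the far-red amplitude is,
    in expectation, the configured far-red/red ratio.
    """

    label: str
    bands: tuple[FluorophoreBand, ...]
    band_mean_amplitude: dict[str, float]
    band_cv: dict[str, float]
    excitation_efficiency: dict[str, tuple[float, ...]]
    peak_jitter_sd_nm: float = 0.0
    width_cv: float = 0.0

    def band(self, name: str) -> FluorophoreBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def far_red_ratio_mean(self) -> float:
        return self.band_mean_amplitude[BAND_CHL_FAR_RED] / self.band_mean_amplitude[BAND_CHL_RED]


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise and dark background shared by all eight rows.

    ``additive_sd`` and ``background_level`` are in the same relative counts
    as the band amplitudes (red chlorophyll peak = 1).  The background is a
    slowly varying quadratic in wavelength, identical in distribution for the
    seven LED rows and the dark row.  ``led_reflection`` scales the residual
    excitation light that reaches the detector below 500 nm.
    """

    additive_sd: float = 0.01
    background_level: float = 0.05
    background_coeffs: tuple[float, ...] = (1.0, 0.15, -0.10)
    led_reflection: float = 3.0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ConfigurationError("additive_sd must be >= 0")

    def background(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        u = (np.asarray(wavelengths_nm, float) - 650.0) / 450.0
        shape = np.polynomial.polynomial.polyval(u, np.asarray(self.background_coeffs))
        return self.background_level * np.clip(shape, 0.0, None)


@dataclass(frozen=True)
class RawMeasurement:
    """One acquisition: rows 0-6 are LED1-LED7 excitation spectra, row 7 the background."""

    grid: WavelengthGrid
    rows: np.ndarray  # (8, n_points), counts
    label: str

    def __post_init__(self) -> None:
        if self.rows.shape != (8, self.grid.n_points):
            raise ConfigurationError(
                f"rows shape {self.rows.shape} != (8, {self.grid.n_points})"
            )


def default_led_profiles(fwhm_nm: float = 15.0) -> list[LEDProfile]:
    """The seven excitation LEDs (centres 371-431 nm).

    With the default 15 nm FWHM every profile's Gaussian wings are far below
    1% of peak at 500 nm, so the excitation light never contaminates the
    fluorescence analysis window.
    """
    return [LEDProfile(center_nm=c, fwhm_nm=fwhm_nm) for c in LED_CENTERS_NM]


# Per-class generator calibration.  Columns: far-red/red ratio mean,
# green-orange mean amplitude, green-orange centre, red centre, far-red
# centre, Soret absorption optimum (drives the chlorophyll excitation-
# efficiency pattern over the 7 LEDs), and the far-red excitation tilt
# (fractional change of the far-red/red ratio from LED1 to LED7, a
# reabsorption effect: excitation depth varies with LED wavelength, and the
# far-red band is less reabsorbed than the red one).  Ratios: all green
# classes and the white tea above 0.6, both black teas below; G-HM and B-L
# sit near the boundary so their measured ratios overlap.  Green-orange:
# G-LJ2 strongly elevated, then G-LJ1, G-LJ3 and B-KM, the rest weak.
_CLASS_TABLE: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "G-LJ1": (0.78, 0.38, 548.0, 679.0, 737.5, 425.0, +0.10),
    "G-LJ2": (0.82, 0.55, 552.0, 680.5, 742.0, 428.0, -0.06),
    "G-LJ3": (0.75, 0.35, 545.0, 678.5, 738.5, 431.0, +0.04),
    "W-MC":  (0.68, 0.15, 556.0, 680.0, 735.0, 434.0, -0.12),
    "G-V":   (0.70, 0.16, 560.0, 682.0, 739.5, 422.0, +0.15),
    "G-HM":  (0.66, 0.18, 550.0, 679.5, 742.5, 437.0, -0.15),
    "B-KM":  (0.42, 0.32, 558.0, 681.0, 745.5, 433.0, +0.07),
    "B-L":   (0.55, 0.12, 554.0, 677.5, 745.0, 427.0, 0.00),
    "G-WNZ": (0.72, 0.13, 546.0, 681.5, 735.0, 430.0, -0.03),
}

_GO_WIDTH_NM = 35.0
_RED_WIDTH_NM = 10.0
_FAR_RED_WIDTH_NM = 16.0

# Excitation-efficiency shape parameters: the green-orange fluorophore is a
# narrow UV-A absorber (optimum at the 371 nm LED), chlorophyll a broad
# Soret-band absorber excited by all seven LEDs.
_GO_ABS_OPTIMUM_NM = 371.0
_GO_ABS_WIDTH_NM = 5.0
_CHL_ABS_WIDTH_NM = 45.0

_BASE_BAND_CV = 0.15
_BASE_JITTER_SD_NM = 2.0
_BASE_WIDTH_CV = 0.05


def _efficiency(optimum_nm: float, width_nm: float, tilt: float = 0.0) -> tuple[float, ...]:
    """Gaussian absorption efficiency over the 7 LEDs, optionally tilted.

    ``tilt`` is the fractional efficiency change from the first LED (371 nm)
    to the last (431 nm); LED1 is the tilt's fixed point.
    """
    eff = []
    span = LED_CENTERS_NM[-1] - LED_CENTERS_NM[0]
    for c in LED_CENTERS_NM:
        base = np.exp(-0.5 * ((c - optimum_nm) / width_nm) ** 2)
        factor = 1.0 + tilt * (c - LED_CENTERS_NM[0]) / span
        eff.append(float(np.clip(base * factor, 0.0, 1.0)))
    return tuple(eff)


def default_class_profiles(overlap: float = 1.0) -> list[TeaClassProfile]:
    """Calibrated profiles of the nine tea classes.

    ``overlap`` scales every source of measurement-to-measurement variation
    (band CVs, peak jitter, width jitter).  At 0 the classes are essentially
    deterministic and trivially separable; the default 1.0 is the calibrated
    regime mirroring real within-class fluctuation.
    """
    if overlap < 0:
        raise ConfigurationError("overlap must be >= 0")
    profiles = []
    for label, (ratio, go_amp, go_c, red_c, fr_c, chl_opt, fr_tilt) in _CLASS_TABLE.items():
        bands = (
            FluorophoreBand(BAND_GREEN_ORANGE, go_c, _GO_WIDTH_NM),
            FluorophoreBand(BAND_CHL_RED, red_c, _RED_WIDTH_NM),
            FluorophoreBand(BAND_CHL_FAR_RED, fr_c, _FAR_RED_WIDTH_NM),
        )
        cv = _BASE_BAND_CV * overlap
        profiles.append(
            TeaClassProfile(
                label=label,
                bands=bands,
                band_mean_amplitude={
                    BAND_GREEN_ORANGE: go_amp,
                    BAND_CHL_RED: 1.0,
                    BAND_CHL_FAR_RED: ratio,
                },
                band_cv={BAND_GREEN_ORANGE: cv, BAND_CHL_RED: cv, BAND_CHL_FAR_RED: cv},
                excitation_efficiency={
                    BAND_GREEN_ORANGE: _efficiency(_GO_ABS_OPTIMUM_NM, _GO_ABS_WIDTH_NM),
                    BAND_CHL_RED: _efficiency(chl_opt, _CHL_ABS_WIDTH_NM),
                    BAND_CHL_FAR_RED: _efficiency(chl_opt, _CHL_ABS_WIDTH_NM, tilt=fr_tilt),
                },
                peak_jitter_sd_nm=_BASE_JITTER_SD_NM * overlap,
                width_cv=_BASE_WIDTH_CV * overlap,
            )
        )
    return profiles


def _lognormal_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One lognormal draw with the given mean and coefficient of variation."""
    if mean == 0.0:
        return 0.0
    if cv == 0.0:
        return mean
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(mean * np.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma))


def simulate_measurement(
    profile: TeaClassProfile,
    leds: list[LEDProfile],
    grid: WavelengthGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> RawMeasurement:
    """Simulate one eight-row acquisition of the given tea class.

    Band amplitudes, peak jitter and width scales are drawn once per
    measurement and shared across the seven LED rows, as the leaf does not
    change between the sequential LED exposures; detector noise is drawn
    independently per row.
    """
    if len(leds) != 7:
        raise ConfigurationError(f"expected 7 LED profiles, got {len(leds)}")
    wl = grid.wavelengths
    background = noise.background(wl)

    amplitudes = {
        b.name: _lognormal_draw(rng, profile.band_mean_amplitude[b.name], profile.band_cv[b.name])
        for b in profile.bands
    }
    jitter = rng.normal(0.0, profile.peak_jitter_sd_nm) if profile.peak_jitter_sd_nm > 0 else 0.0
    width_scales = {
        b.name: _lognormal_draw(rng, 1.0, profile.width_cv) for b in profile.bands
    }

    rows = np.empty((8, grid.n_points))
    for r, led in enumerate(leds):
        spectrum = background.copy()
        spectrum += noise.led_reflection * led.intensity(wl)
        for b in profile.bands:
            eff = profile.excitation_efficiency[b.name][r]
            amp = amplitudes[b.name] * eff
            if amp > 0:
                spectrum += amp * _gaussian(wl, b.center_nm + jitter, b.width_nm * width_scales[b.name])
        rows[r] = spectrum
    rows[7] = background
    if noise.additive_sd > 0:
        rows = rows + rng.normal(0.0, noise.additive_sd, size=rows.shape)
    rows = np.clip(rows, 0.0, None)
    return RawMeasurement(grid=grid, rows=rows, label=profile.label)


def generate_dataset(
    n_per_class: int,
    seed: int,
    overlap: float = 1.0,
    profiles: list[TeaClassProfile] | None = None,
    leds: list[LEDProfile] | None = None,
    grid: WavelengthGrid | None = None,
    noise: NoiseModel | None = None,
) -> list[RawMeasurement]:
    """Simulate ``n_per_class`` acquisitions for each of the nine classes.

    Deterministic given ``seed``.  Measurements are ordered class-major in
    the canonical label order.
    """
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2 (a 50/50 split needs at least 2)")
    profiles = profiles if profiles is not None else default_class_profiles(overlap)
    leds = leds if leds is not None else default_led_profiles()
    grid = grid if grid is not None else default_grid()
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    measurements = []
    for profile in profiles:
        for _ in range(n_per_class):
            measurements.append(simulate_measurement(profile, leds, grid, noise, rng))
    return measurements
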