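"""Seeded virtual spectrometer.

Forward model: a warm-white LED source, Beer-Lambert transmission through a
1 cm cuvette, Gaussian slit-function blur (FWHM = spectral resolution),
pixel sampling on the calibration grid, additive Gaussian dark/read noise,
10-bit quantization and clipping.  Every stochastic operation takes an
explicit ``numpy.random.Generator`` or integer seed — no silent entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import (
    AccumulatedSpectrum,
    RawSpectrum,
    WavelengthCalibration,
    accumulate,
    default_calibration,
)

__all__ = [
    "GaussianBand",
    "SourceModel",
    "AnalyteSpectrum",
    "SampleModel",
    "DetectorModel",
    "InstrumentModel",
    "sample_transmission",
    "expected_counts",
    "acquire_frame",
    "acquire_frames",
    "make_rgb_fixture",
    "make_calibration_series",
    "default_instrument",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    fwhm_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_nm * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(-0.5 * ((np.asarray(lam, float) - self.center_nm) / sigma) ** 2)


@dataclass(frozen=True)
class SourceModel:
    """Emission model: a sum of Gaussian bands.

    ``peak_counts`` is the expected dark-subtracted count at the brightest
    working-range pixel for a baseline acquisition at the reference exposure.
    """

    components: tuple[GaussianBand, ...]
    peak_counts: float = 950.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("source needs at least one emission band")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        object.__setattr__(self, "components", tuple(self.components))

    def relative_intensity(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = np.zeros_like(lam)
        for band in self.components:
            out += band(lam)
        return out


def warm_white_led(peak_counts: float = 950.0) -> SourceModel:
    """Default source: narrow blue band plus a broad phosphor band.

    Amplitudes are chosen so the blurred intensity near 550 nm sits at
    roughly half the working-range maximum.
    """
    return SourceModel(
        components=(
            GaussianBand(450.0, 20.0, 1.0),
            GaussianBand(560.0, 120.0, 0.45),
        ),
        peak_counts=peak_counts,
    )


@dataclass(frozen=True)
class AnalyteSpectrum:
    """Molar absorptivity profile epsilon(lambda), L mmol^-1 cm^-1.

    Parameterized as Gaussian bands plus optional flat (top-hat) bands.
    """

    name: str
    bands: tuple[GaussianBand, ...] = ()
    flat_bands: tuple[tuple[float, float, float], ...] = ()  # (lo, hi, eps)

    def __post_init__(self) -> None:
        for lo, hi, eps in self.flat_bands:
            if hi <= lo:
                raise ValueError("flat band must have hi > lo")
            if eps < 0:
                raise ValueError("epsilon must be nonnegative")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "flat_bands", tuple(tuple(b) for b in self.flat_bands))

    def epsilon(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        out = np.zeros_like(lam)
        for band in self.bands:
            out += band(lam)
        for lo, hi, eps in self.flat_bands:
            out += np.where((lam >= lo) & (lam <= hi), eps, 0.0)
        return out


@dataclass(frozen=True)
class SampleModel:
    """Cuvette contents: (analyte, concentration) pairs and the path length."""

    constituents: tuple[tuple[AnalyteSpectrum, float], ...] = ()
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be positive")
        for _, conc in self.constituents:
            if conc < 0:
                raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "constituents", tuple(self.constituents))

    def absorbance(self, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        total = np.zeros_like(lam)
        for analyte, conc in self.constituents:
            total += analyte.epsilon(lam) * conc * self.path_length_cm
        return total


def sample_transmission(sample: SampleModel, lam) -> np.ndarray | float:
    """Beer-Lambert transmittance T = 10**(-sum eps_i c_i l) at ``lam``."""
    t = 10.0 ** (-sample.absorbance(lam))
    return float(t) if np.isscalar(lam) else t


@dataclass(frozen=True)
class DetectorModel:
    n_pixels: int = 288
    bits: int = 10
    dark_mean: float = 30.0
    dark_rms: float = 11.5
    slit_fwhm_nm: float = 15.0
    exposure_ref_us: float = 200.0
    shot_noise: bool = False  # optional Poisson toggle, off by default

    def __post_init__(self) -> None:
        if self.dark_rms <= 0:
            raise ValueError("dark_rms must be positive")
        if self.slit_fwhm_nm <= 0:
            raise ValueError("slit_fwhm_nm must be positive")
        if self.n_pixels <= 0 or self.bits <= 0:
            raise ValueError("n_pixels and bits must be positive")

    @property
    def full_scale(self) -> int:
        return (1 << self.bits) - 1


@dataclass(frozen=True)
class InstrumentModel:
    source: SourceModel
    detector: DetectorModel = field(default_factory=DetectorModel)
    calibration: WavelengthCalibration = field(default_factory=default_calibration)

    def __post_init__(self) -> None:
        if self.calibration.n_pixels != self.detector.n_pixels:
            raise ValueError(
                "calibration pixel range must cover the detector pixel count"
            )

    # -- noiseless forward model -------------------------------------------

    def _dense_grid(self) -> np.ndarray:
        lam = self.calibration.wavelengths()
        pad = 4.0 * self.detector.slit_fwhm_nm
        return np.arange(lam[0] - pad, lam[-1] + pad, 0.25)

    def _blur(
        self, dense_lam: np.ndarray, dense_signal: np.ndarray, out_lam: np.ndarray
    ) -> np.ndarray:
        """Gaussian slit blur of a continuous spectrum, sampled at ``out_lam``.

        The kernel is normalized per output point so a flat spectrum stays
        flat (signal conservation away from range edges).
        """
        sigma = self.detector.slit_fwhm_nm * _FWHM_TO_SIGMA
        diff = np.atleast_1d(out_lam)[:, None] - dense_lam[None, :]
        kernel = np.exp(-0.5 * (diff / sigma) ** 2)
        kernel /= kernel.sum(axis=1, keepdims=True)
        return kernel @ dense_signal

    def _blur_to_pixels(self, dense_lam: np.ndarray, dense_signal: np.ndarray) -> np.ndarray:
        return self._blur(dense_lam, dense_signal, self.calibration.wavelengths())

    def _source_scale(self) -> float:
        dense = self._dense_grid()
        blurred = self._blur_to_pixels(dense, self.source.relative_intensity(dense))
        peak = blurred[self.calibration.working_pixels()].max()
        return self.source.peak_counts / peak

    def expected_signal(self, sample: SampleModel | None, exposure_us: float) -> np.ndarray:
        """Expected dark-subtracted counts per pixel (real-valued, unclipped)."""
        dense = self._dense_grid()
        spectrum = self.source.relative_intensity(dense)
        if sample is not None:
            spectrum = spectrum * sample_transmission(sample, dense)
        blurred = self._blur_to_pixels(dense, spectrum)
        return self._source_scale() * (exposure_us / self.detector.exposure_ref_us) * blurred

    def expected_signal_at(
        self, sample: SampleModel | None, exposure_us: float, lam_query
    ) -> np.ndarray | float:
        """Expected dark-subtracted signal at arbitrary wavelengths (dense oracle)."""
        dense = self._dense_grid()
        spectrum = self.source.relative_intensity(dense)
        if sample is not None:
            spectrum = spectrum * sample_transmission(sample, dense)
        out = self._blur(dense, spectrum, np.asarray(lam_query, dtype=float))
        out = self._source_scale() * (exposure_us / self.detector.exposure_ref_us) * out
        return float(out[0]) if np.isscalar(lam_query) else out


def default_instrument(**detector_overrides) -> InstrumentModel:
    return InstrumentModel(
        source=warm_white_led(), detector=DetectorModel(**detector_overrides)
    )


def expected_counts(
    model: InstrumentModel, sample: SampleModel | None, role: str, exposure_us: float
) -> np.ndarray:
    """Noiseless, unquantized expected counts (the oracle for tests)."""
    det = model.detector
    if role == "dark":
        return np.full(det.n_pixels, det.dark_mean)
    return det.dark_mean + model.expected_signal(sample, exposure_us)


def acquire_frame(
    model: InstrumentModel,
    sample: SampleModel | None = None,
    role: str = "sample",
    exposure_us: float | None = None,
    rng=0,
    frame_id: str = "",
) -> RawSpectrum:
    """Acquire one noisy, quantized frame.  Identical seeds give identical frames."""
    return acquire_frames(
        model, n=1, sample=sample, role=role, exposure_us=exposure_us, rng=rng,
        frame_prefix=frame_id,
    )[0]


def acquire_frames(
    model: InstrumentModel,
    n: int,
    sample: SampleModel | None = None,
    role: str = "sample",
    exposure_us: float | None = None,
    rng=0,
    frame_prefix: str = "",
) -> list[RawSpectrum]:
    """Acquire ``n`` frames sharing one noiseless expectation (fast path)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    det = model.detector
    if exposure_us is None:
        exposure_us = det.exposure_ref_us
    if exposure_us < 0:
        raise ValueError("exposure must be nonnegative")
    rng = _as_rng(rng)
    expected = expected_counts(model, sample, role, exposure_us)
    frames = []
    for i in range(n):
        counts = expected.copy()
        if det.shot_noise and role != "dark":
            signal = np.clip(expected - det.dark_mean, 0, None)
            counts = det.dark_mean + rng.poisson(signal).astype(float)
        counts = counts + rng.normal(0.0, det.dark_rms, size=det.n_pixels)
        counts = np.clip(np.rint(counts), 0, det.full_scale).astype(np.int64)
        frames.append(
            RawSpectrum(
                counts=counts,
                exposure_us=float(exposure_us),
                role=role,
                bits=det.bits,
                frame_id=f"{frame_prefix}{role}-{i:04d}",
            )
        )
    return frames


def acquire_accumulated(
    model: InstrumentModel,
    n: int,
    sample: SampleModel | None = None,
    role: str = "sample",
    exposure_us: float | None = None,
    rng=0,
) -> AccumulatedSpectrum:
    return accumulate(
        acquire_frames(model, n, sample=sample, role=role, exposure_us=exposure_us, rng=rng)
    )


def make_rgb_fixture(
    seed=0,
    centers_nm: Sequence[float] = (470.0, 530.0, 630.0),
    fwhm_nm: float = 20.0,
    n_frames: int = 50,
    detector: DetectorModel | None = None,
    noiseless: bool = False,
):
    """Narrow-band R/G/B emission frames plus ground-truth peak centers.

    Returns ``(frame_sets, true_centers)`` where ``frame_sets`` maps each
    center to a list of frames.  The Gaussian band blurred by the Gaussian
    slit stays centered, so the band center is the true blurred peak.
    """
    rng = _as_rng(seed)
    det = detector or DetectorModel()
    if noiseless:
        det = DetectorModel(
            n_pixels=det.n_pixels, bits=det.bits, dark_mean=det.dark_mean,
            dark_rms=1e-12, slit_fwhm_nm=det.slit_fwhm_nm,
            exposure_ref_us=det.exposure_ref_us,
        )
    frame_sets: dict[float, list[RawSpectrum]] = {}
    for center in centers_nm:
        source = SourceModel(components=(GaussianBand(center, fwhm_nm, 1.0),), peak_counts=900.0)
        model = InstrumentModel(source=source, detector=det)
        frame_sets[float(center)] = acquire_frames(
            model, n_frames, sample=None, role="baseline", rng=rng,
            frame_prefix=f"rgb{center:.0f}-",
        )
    return frame_sets, tuple(float(c) for c in centers_nm)


def make_calibration_series(
    slope: float,
    intercept: float,
    levels: Sequence[float],
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed=0,
    n_days: int = 1,
    day_sd: float = 0.0,
    unit: str = "ppm",
) -> pd.DataFrame:
    """Synthetic (concentration, response) table: response = a + b*c + noise.

    With ``n_days > 1`` a shared Gaussian day offset of sd ``day_sd`` is added
    to every response of a day, giving inter-day structure for precision
    statistics.
    """
    if not len(levels):
        raise ValueError("levels must be nonempty")
    if noise_sd < 0 or day_sd < 0:
        raise ValueError("noise sds must be nonnegative")
    rng = _as_rng(seed)
    rows = []
    for day in range(1, n_days + 1):
        day_offset = rng.normal(0.0, day_sd) if day_sd > 0 else 0.0
        for level in levels:
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "concentration": float(level),
                        "response": intercept + slope * float(level) + day_offset + noise,
                        "day": day,
                        "replicate": rep,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["unit"] = unit
    return df
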