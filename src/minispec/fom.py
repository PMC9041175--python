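"""Instrument figures of merit: dark noise, dynamic range, SNR, wavelength accuracy.

Conventions: standard deviations use the n-1 denominator; decibel values use
10*log10 of the raw ratio.  The raw ratio is always reported alongside the
dB form because vendor datasheets label the bare full-scale/noise ratio
itself as "dB".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import Frame, RawSpectrum, WavelengthCalibration, default_calibration

__all__ = [
    "DynamicRange",
    "SnrResult",
    "WavelengthAccuracy",
    "FomReport",
    "rms_dark_noise",
    "dynamic_range",
    "snr",
    "snr_spectrum",
    "peak_wavelength",
    "wavelength_accuracy",
    "characterize",
]


def _stack(frames: Sequence[Frame]) -> np.ndarray:
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    n = frames[0].n_pixels
    for f in frames[1:]:
        if f.n_pixels != n:
            raise ValueError("frames have unequal pixel counts")
    return np.stack([np.asarray(f.counts, dtype=float) for f in frames])


def rms_dark_noise(dark_frames: Sequence[RawSpectrum]) -> float:
    """Mean over pixels of the per-pixel sample standard deviation (ddof=1)."""
    stack = _stack(dark_frames)
    return float(stack.std(axis=0, ddof=1).mean())


@dataclass(frozen=True)
class DynamicRange:
    ratio: float
    db: float
    bits: int
    rms_dark: float


def dynamic_range(rms_dark: float, bits: int = 10) -> DynamicRange:
    """(2**bits - 1) / rms_dark, with the 10*log10 dB form alongside."""
    if rms_dark <= 0:
        raise ValueError("rms_dark must be positive")
    ratio = ((1 << bits) - 1) / rms_dark
    return DynamicRange(ratio=ratio, db=10.0 * math.log10(ratio), bits=bits, rms_dark=rms_dark)


@dataclass(frozen=True)
class SnrResult:
    ratio: float
    db: float
    wavelength_nm: float | None
    pixel: int | None
    mean: float
    sd: float
    infinite: bool = False


def _ratio_to_snr(mean: float, sd: float, wavelength_nm=None, pixel=None) -> SnrResult:
    if sd == 0.0:
        return SnrResult(
            ratio=math.inf, db=math.inf, wavelength_nm=wavelength_nm,
            pixel=pixel, mean=mean, sd=sd, infinite=True,
        )
    ratio = mean / sd
    return SnrResult(
        ratio=ratio, db=10.0 * math.log10(ratio) if ratio > 0 else math.nan,
        wavelength_nm=wavelength_nm, pixel=pixel, mean=mean, sd=sd,
    )


def snr(
    frames: Sequence[Frame],
    cal: WavelengthCalibration | None = None,
    wavelength_nm: float | None = None,
) -> SnrResult:
    """Mean/sd over repeated frames at the pixel nearest ``wavelength_nm``.

    Zero sd is reported as an infinite-SNR flag, not an exception.
    """
    cal = cal or default_calibration()
    if wavelength_nm is None:
        raise ValueError("wavelength_nm is required")
    if not cal.in_working_range(wavelength_nm):
        raise ValueError(f"{wavelength_nm} nm outside working range {cal.working_range}")
    stack = _stack(frames)
    pixel = cal.pixel_nearest(wavelength_nm)
    col = stack[:, pixel]
    return _ratio_to_snr(
        float(col.mean()), float(col.std(ddof=1)),
        wavelength_nm=float(cal(pixel)), pixel=pixel,
    )


def snr_from_stats(mean: float, sd: float) -> SnrResult:
    """SNR directly from a reported (mean, sd) operating point."""
    return _ratio_to_snr(float(mean), float(sd))


def snr_spectrum(
    frames: Sequence[Frame], normalized: bool = False
) -> np.ndarray:
    """Per-pixel mean/sd ratio across frames; optionally peak-normalized."""
    stack = _stack(frames)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, mean / sd, np.inf)
    if normalized:
        finite = ratio[np.isfinite(ratio)]
        if finite.size:
            ratio = ratio / finite.max()
    return ratio


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the parabola through three (x, y) points.

    Handles unequal spacing (the pixel->wavelength map is nonlinear).
    """
    x0, x1, x2 = x
    y0, y1, y2 = y
    d0 = (y1 - y0) / (x1 - x0)
    d1 = (y2 - y1) / (x2 - x1)
    a = (d1 - d0) / (x2 - x0)
    if a == 0:
        return float(x1)
    b = d0 - a * (x0 + x1)
    return float(-b / (2 * a))


def peak_wavelength(
    spectrum: Frame | np.ndarray,
    cal: WavelengthCalibration | None = None,
    method: str = "argmax",
) -> tuple[float, str]:
    """Wavelength of the emission maximum.

    ``method='argmax'`` returns the maximal pixel's wavelength;
    ``method='parabolic'`` refines it with the vertex of the parabola through
    the maximal pixel and its two neighbours in wavelength space.  Returns
    ``(wavelength_nm, method_used)`` — parabolic falls back to argmax when
    the maximum sits on a boundary pixel.
    """
    cal = cal or default_calibration()
    counts = np.asarray(
        spectrum if isinstance(spectrum, np.ndarray) else spectrum.counts, dtype=float
    )
    lam = cal.wavelengths()
    if counts.size != lam.size:
        raise ValueError("spectrum length does not match the calibration pixel range")
    imax = int(np.argmax(counts))
    if method == "argmax":
        return float(lam[imax]), "argmax"
    if method != "parabolic":
        raise ValueError(f"unknown method {method!r}")
    if imax == 0 or imax == counts.size - 1:
        return float(lam[imax]), "argmax_boundary_fallback"
    vertex = _parabolic_vertex(lam[imax - 1 : imax + 2], counts[imax - 1 : imax + 2])
    if not lam[imax - 1] <= vertex <= lam[imax + 1]:
        return float(lam[imax]), "argmax_boundary_fallback"
    return vertex, "parabolic"


@dataclass(frozen=True)
class WavelengthAccuracy:
    mean_abs_delta_nm: float
    deltas_nm: tuple[float, ...]
    measured_nm: tuple[float, ...]
    reference_nm: tuple[float, ...]


def wavelength_accuracy(
    measured_nm: Sequence[float], reference_nm: Sequence[float]
) -> WavelengthAccuracy:
    """Per-peak |measured - reference| and their arithmetic mean, in nm."""
    if len(measured_nm) != len(reference_nm):
        raise ValueError("measured and reference peak lists must have equal length")
    deltas = tuple(abs(m - r) for m, r in zip(measured_nm, reference_nm))
    return WavelengthAccuracy(
        mean_abs_delta_nm=float(np.mean(deltas)),
        deltas_nm=deltas,
        measured_nm=tuple(float(m) for m in measured_nm),
        reference_nm=tuple(float(r) for r in reference_nm),
    )


@dataclass(frozen=True)
class FomReport:
    rms_dark: float
    dynamic_range: DynamicRange
    snr_at_query: SnrResult | None = None
    snr_by_pixel: np.ndarray | None = None
    wavelength_accuracy: WavelengthAccuracy | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "rms_dark_counts": self.rms_dark,
            "dynamic_range": {
                "ratio": self.dynamic_range.ratio,
                "db_10log10": self.dynamic_range.db,
                "bits": self.dynamic_range.bits,
            },
        }
        if self.snr_at_query is not None:
            s = self.snr_at_query
            out["snr"] = {
                "wavelength_nm": s.wavelength_nm,
                "pixel": s.pixel,
                "mean": s.mean,
                "sd": s.sd,
                "ratio": None if s.infinite else s.ratio,
                "db_10log10": None if s.infinite else s.db,
                "infinite": s.infinite,
            }
        if self.snr_by_pixel is not None:
            clean = np.where(np.isfinite(self.snr_by_pixel), self.snr_by_pixel, -1.0)
            out["snr_by_pixel"] = [round(float(v), 4) for v in clean]
        if self.wavelength_accuracy is not None:
            w = self.wavelength_accuracy
            out["wavelength_accuracy"] = {
                "mean_abs_delta_nm": w.mean_abs_delta_nm,
                "peaks": [
                    {"measured_nm": m, "reference_nm": r, "abs_delta_nm": d}
                    for m, r, d in zip(w.measured_nm, w.reference_nm, w.deltas_nm)
                ],
            }
        return out


def characterize(
    dark_frames: Sequence[RawSpectrum],
    lit_frames: Sequence[Frame] | None = None,
    cal: WavelengthCalibration | None = None,
    snr_wavelength_nm: float = 540.0,
    bits: int | None = None,
) -> FomReport:
    """Full characterization run from a set of dark and illuminated frames."""
    cal = cal or default_calibration()
    rms = rms_dark_noise(dark_frames)
    bits = bits if bits is not None else dark_frames[0].bits
    report_snr = None
    spectrum = None
    if lit_frames:
        report_snr = snr(lit_frames, cal, snr_wavelength_nm)
        spectrum = snr_spectrum(lit_frames)
    return FomReport(
        rms_dark=rms,
        dynamic_range=dynamic_range(rms, bits),
        snr_at_query=report_snr,
        snr_by_pixel=spectrum,
    )
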