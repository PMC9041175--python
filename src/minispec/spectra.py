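"""Core data model for detector frames, wavelength calibration and absorbance.

The processing chain is the standard single-beam transmission one: a *dark*
frame captures the detector offset, a *baseline* frame the light source
through the empty optical path, and a *sample* frame the source attenuated
by the cuvette contents.  Absorbance is then

    A(p) = log10( (B(p) - D(p)) / (S(p) - D(p)) )

per pixel ``p``, mapped onto the wavelength grid of the pixel->wavelength
calibration polynomial and restricted to the instrument's working range.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "FLAG_OK",
    "FLAG_SATURATED",
    "FLAG_NONPOSITIVE",
    "RawSpectrum",
    "AccumulatedSpectrum",
    "WavelengthCalibration",
    "AbsorbanceSpectrum",
    "UnusableBaselineError",
    "default_calibration",
    "dark_correct",
    "accumulate",
    "compute_absorbance",
    "absorbance_at",
    "pixel_to_wavelength",
]

ROLES = ("dark", "baseline", "sample")

# Per-point quality flags on an absorbance spectrum.
FLAG_OK = "ok"
FLAG_SATURATED = "saturated"
FLAG_NONPOSITIVE = "nonpositive_signal"


class UnusableBaselineError(ValueError):
    """Raised when the baseline carries no signal above the dark level."""


@dataclass(frozen=True)
class RawSpectrum:
    """One detector readout: integer ADC counts per pixel plus metadata."""

    counts: np.ndarray
    exposure_us: float
    role: str
    bits: int = 10
    frame_id: str = ""
    timestamp: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("counts must be integers")
            counts = as_int
        else:
            counts = counts.astype(np.int64)
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.bits <= 0:
            raise ValueError("bits must be positive")
        if self.exposure_us < 0:
            raise ValueError("exposure_us must be nonnegative")
        full = self.full_scale
        if counts.min() < 0 or counts.max() > full:
            bad = int(np.argmax((counts < 0) | (counts > full)))
            raise ValueError(
                f"count {counts[bad]} at pixel {bad} outside ADC range [0, {full}]"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def full_scale(self) -> int:
        return (1 << self.bits) - 1

    @property
    def n_pixels(self) -> int:
        return int(self.counts.size)

    @property
    def saturated(self) -> np.ndarray:
        """Boolean mask of pixels at the ADC ceiling."""
        return self.counts == self.full_scale


@dataclass(frozen=True)
class AccumulatedSpectrum:
    """Per-pixel arithmetic mean of several frames of the same role."""

    counts: np.ndarray  # real-valued means
    exposure_us: float
    role: str
    bits: int
    n_frames: int
    frame_ids: tuple[str, ...] = ()
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        sat = self.saturated
        if sat is None:
            sat = np.zeros(counts.size, dtype=bool)
        sat = np.asarray(sat, dtype=bool)
        sat.setflags(write=False)
        object.__setattr__(self, "saturated", sat)

    @property
    def full_scale(self) -> int:
        return (1 << self.bits) - 1

    @property
    def n_pixels(self) -> int:
        return int(self.counts.size)


Frame = RawSpectrum | AccumulatedSpectrum


# Default pixel->wavelength map.  Real units are factory-calibrated per chip;
# these repository-default cubic coefficients (in a 5th-order container) span
# 340 nm at pixel 0 to 850 nm at pixel 287 with the dispersion peaking
# mid-range, so that the adjacent-pixel step across the 450-750 nm working
# range averages ~2.1 nm.
DEFAULT_COEFFICIENTS = (340.0, 0.8, 1.0212584e-2, -2.3722601e-5, 0.0, 0.0)


@dataclass(frozen=True)
class WavelengthCalibration:
    """Monotone polynomial pixel-index -> wavelength (nm) map.

    ``coefficients`` are ordered lowest power first.  The map must be
    strictly increasing over ``pixel_range`` and its image must contain
    ``working_range``.
    """

    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    pixel_range: tuple[int, int] = (0, 287)
    working_range: tuple[float, float] = (450.0, 750.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        lo, hi = self.pixel_range
        if lo > hi:
            raise ValueError("pixel_range must be (low, high) with low <= high")
        wlo, whi = self.working_range
        if wlo >= whi:
            raise ValueError("working_range must be increasing")
        lam = self.wavelengths()
        if not np.all(np.diff(lam) > 0):
            raise ValueError("pixel->wavelength map must be strictly increasing")
        if wlo < lam[0] or whi > lam[-1]:
            raise ValueError("working_range not contained in the map's image")

    @property
    def n_pixels(self) -> int:
        return self.pixel_range[1] - self.pixel_range[0] + 1

    def __call__(self, pixel) -> np.ndarray | float:
        p = np.asarray(pixel, dtype=float)
        lam = np.polynomial.polynomial.polyval(p, self.coefficients)
        return float(lam) if np.isscalar(pixel) or p.ndim == 0 else lam

    def wavelengths(self, pixels: Sequence[int] | None = None) -> np.ndarray:
        """Wavelengths for ``pixels`` (default: the full pixel range)."""
        if pixels is None:
            pixels = np.arange(self.pixel_range[0], self.pixel_range[1] + 1)
        return np.atleast_1d(self(np.asarray(pixels)))

    def in_working_range(self, wavelength_nm: float) -> bool:
        lo, hi = self.working_range
        return lo <= wavelength_nm <= hi

    def working_pixels(self) -> np.ndarray:
        """Pixel indices whose wavelength falls inside the working range."""
        pix = np.arange(self.pixel_range[0], self.pixel_range[1] + 1)
        lam = self.wavelengths(pix)
        lo, hi = self.working_range
        return pix[(lam >= lo) & (lam <= hi)]

    def pixel_nearest(self, wavelength_nm: float) -> int:
        """Pixel whose calibrated wavelength is closest to ``wavelength_nm``."""
        pix = np.arange(self.pixel_range[0], self.pixel_range[1] + 1)
        lam = self.wavelengths(pix)
        return int(pix[np.argmin(np.abs(lam - wavelength_nm))])


def default_calibration() -> WavelengthCalibration:
    return WavelengthCalibration()


def pixel_to_wavelength(cal: WavelengthCalibration, pixel: int) -> float:
    """Evaluate the calibration polynomial at one pixel index."""
    lo, hi = cal.pixel_range
    if not lo <= pixel <= hi:
        raise ValueError(f"pixel {pixel} outside pixel_range [{lo}, {hi}]")
    return float(cal(pixel))


def _check_compatible(a: Frame, b: Frame, *, what: str) -> None:
    if a.n_pixels != b.n_pixels:
        raise ValueError(
            f"{what}: pixel count mismatch ({a.n_pixels} vs {b.n_pixels})"
        )
    if not math.isclose(a.exposure_us, b.exposure_us, rel_tol=1e-9):
        raise ValueError(
            f"{what}: exposure mismatch ({a.exposure_us} vs {b.exposure_us} us); "
            "frames of unequal exposure are never combined implicitly"
        )


def dark_correct(frame: Frame, dark: Frame) -> np.ndarray:
    """Elementwise ``frame - dark``.

    Negative results are preserved (flagged downstream, never clipped).
    """
    _check_compatible(frame, dark, what="dark_correct")
    return np.asarray(frame.counts, dtype=float) - np.asarray(dark.counts, dtype=float)


def accumulate(frames: Sequence[RawSpectrum]) -> AccumulatedSpectrum:
    """Per-pixel arithmetic mean of ``frames`` (all same role/length/exposure)."""
    frames = list(frames)
    if not frames:
        raise ValueError("accumulate requires at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if f.role != first.role:
            raise ValueError(f"mixed roles: {first.role!r} and {f.role!r}")
        _check_compatible(first, f, what="accumulate")
        if f.bits != first.bits:
            raise ValueError("mixed ADC bit depths")
    stack = np.stack([np.asarray(f.counts, dtype=float) for f in frames])
    sat = np.zeros(first.n_pixels, dtype=bool)
    for f in frames:
        sat |= f.saturated if isinstance(f, RawSpectrum) else np.zeros_like(sat)
    return AccumulatedSpectrum(
        counts=stack.mean(axis=0),
        exposure_us=first.exposure_us,
        role=first.role,
        bits=first.bits,
        n_frames=len(frames),
        frame_ids=tuple(f.frame_id for f in frames),
        saturated=sat,
    )


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Wavelength-indexed absorbance with per-point quality flags.

    Points flagged ``nonpositive_signal`` hold NaN, never a finite number.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    flags: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if lam.shape != ab.shape or lam.ndim != 1:
            raise ValueError("wavelengths and absorbance must be matching 1-D arrays")
        if len(self.flags) != lam.size:
            raise ValueError("one flag per grid point required")
        if lam.size > 1 and not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        for i, fl in enumerate(self.flags):
            if fl == FLAG_NONPOSITIVE and np.isfinite(ab[i]):
                raise ValueError("nonpositive_signal points must be NaN")
        lam.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "flags", tuple(self.flags))

    def __len__(self) -> int:
        return int(self.wavelengths.size)


def _frame_label(frame: Frame | None) -> str | tuple[str, ...]:
    if frame is None:
        return "none"
    if isinstance(frame, AccumulatedSpectrum):
        return frame.frame_ids or f"accumulated(n={frame.n_frames})"
    return frame.frame_id


def compute_absorbance(
    sample: Frame,
    baseline: Frame,
    dark: Frame | None = None,
    cal: WavelengthCalibration | None = None,
) -> AbsorbanceSpectrum:
    """Single-beam absorbance from sample, baseline and optional dark frames.

    With no dark frame the dark level is taken as zero (the device has no
    shutter; documented limitation).  Pixels where either corrected signal
    is <= 0 are flagged ``nonpositive_signal`` and set to NaN; saturated
    input pixels are flagged ``saturated`` but still evaluated.
    """
    cal = cal or default_calibration()
    _check_compatible(sample, baseline, what="compute_absorbance")
    if dark is not None:
        b = dark_correct(baseline, dark)
        s = dark_correct(sample, dark)
    else:
        b = np.asarray(baseline.counts, dtype=float)
        s = np.asarray(sample.counts, dtype=float)
    if np.all(b <= 0):
        raise UnusableBaselineError(
            "baseline is entirely at or below the dark level"
        )

    pix = cal.working_pixels()
    lam = cal.wavelengths(pix)
    bw, sw = b[pix], s[pix]
    sat = np.zeros(len(pix), dtype=bool)
    for fr in (sample, baseline):
        sat |= np.asarray(fr.saturated)[pix]

    absorbance = np.full(len(pix), np.nan)
    flags: list[str] = []
    ok = (bw > 0) & (sw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        absorbance[ok] = np.log10(bw[ok] / sw[ok])
    for i in range(len(pix)):
        if not ok[i]:
            flags.append(FLAG_NONPOSITIVE)
        elif sat[i]:
            flags.append(FLAG_SATURATED)
        else:
            flags.append(FLAG_OK)

    provenance = {
        "sample": _frame_label(sample),
        "baseline": _frame_label(baseline),
        "dark": _frame_label(dark),
        "working_range": list(cal.working_range),
    }
    return AbsorbanceSpectrum(lam, absorbance, tuple(flags), provenance)


def absorbance_at(spec: AbsorbanceSpectrum, wavelength_nm: float) -> tuple[float, str]:
    """Absorbance at one wavelength by linear interpolation on the grid.

    Returns ``(value, flag)``.  An exact grid hit returns the stored value;
    if either bracketing point is undefined the result is NaN with the
    ``nonpositive_signal`` flag.
    """
    lam = spec.wavelengths
    if not lam[0] <= wavelength_nm <= lam[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside the spectrum grid "
            f"[{lam[0]:.2f}, {lam[-1]:.2f}]"
        )
    j = int(np.searchsorted(lam, wavelength_nm))
    if lam[j] == wavelength_nm:
        return float(spec.absorbance[j]), spec.flags[j]
    i = j - 1
    a0, a1 = spec.absorbance[i], spec.absorbance[j]
    if not (np.isfinite(a0) and np.isfinite(a1)):
        return float("nan"), FLAG_NONPOSITIVE
    t = (wavelength_nm - lam[i]) / (lam[j] - lam[i])
    value = float(a0 + t * (a1 - a0))
    flag = FLAG_OK
    if FLAG_SATURATED in (spec.flags[i], spec.flags[j]):
        flag = FLAG_SATURATED
    return value, flag
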