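"""File formats: frame CSV, absorbance CSV, calibration-series CSV,
calibration-map JSON and instrument configuration.

CSV dialect: comma-separated, UTF-8, LF endings, ``#``-prefixed
``key=value`` header metadata.  Reals are written with 6 significant
digits; counts round-trip losslessly as integers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calstats import CalibrationSeries
from .simulate import (
    AnalyteSpectrum,
    DetectorModel,
    GaussianBand,
    InstrumentModel,
    SampleModel,
    SourceModel,
    warm_white_led,
)
from .spectra import (
    AbsorbanceSpectrum,
    RawSpectrum,
    WavelengthCalibration,
)

__all__ = [
    "FrameFormatError",
    "read_frame_csv",
    "write_frame_csv",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_series_csv",
    "write_series_csv",
    "read_calibration_json",
    "write_calibration_json",
    "load_instrument_config",
    "config_hash",
]

_REQUIRED_FRAME_KEYS = ("bits", "exposure_us", "role", "n_pixels")


class FrameFormatError(ValueError):
    """Malformed frame CSV (missing keys, bad counts, truncation)."""


def _format_real(x: float) -> str:
    if not np.isfinite(x):
        return "nan"
    return f"{x:.6g}"


def write_frame_csv(frame: RawSpectrum, path) -> None:
    lines = [
        f"# bits={frame.bits}",
        f"# exposure_us={_format_real(frame.exposure_us)}",
        f"# role={frame.role}",
        f"# n_pixels={frame.n_pixels}",
        f"# frame_id={frame.frame_id}",
        "pixel,count",
    ]
    lines += [f"{p},{c}" for p, c in enumerate(frame.counts)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _parse_headers(lines: list[str]) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta, i


def read_frame_csv(path) -> RawSpectrum:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, start = _parse_headers(lines)
    for key in _REQUIRED_FRAME_KEYS:
        if key not in meta:
            raise FrameFormatError(f"{path}: missing required header key {key!r}")
    bits = int(meta["bits"])
    n_pixels = int(meta["n_pixels"])
    full = (1 << bits) - 1

    body = lines[start:]
    if body and body[0].strip() == "pixel,count":
        body = body[1:]
        start += 1
    counts = np.zeros(n_pixels, dtype=np.int64)
    seen = 0
    for offset, line in enumerate(body):
        if not line.strip():
            continue
        lineno = start + offset + 1
        parts = line.split(",")
        if len(parts) != 2:
            raise FrameFormatError(f"{path}: parse error at line {lineno}: {line!r}")
        try:
            pixel, count = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise FrameFormatError(f"{path}: parse error at line {lineno}: {exc}") from exc
        if not 0 <= pixel < n_pixels:
            raise FrameFormatError(f"{path}: pixel index {pixel} out of range at line {lineno}")
        if not 0 <= count <= full:
            raise FrameFormatError(
                f"{path}: count {count} at pixel {pixel} outside ADC range [0, {full}]"
            )
        counts[pixel] = count
        seen += 1
    if seen != n_pixels:
        raise FrameFormatError(
            f"{path}: expected {n_pixels} pixel rows, found {seen} (file truncated?)"
        )
    return RawSpectrum(
        counts=counts,
        exposure_us=float(meta["exposure_us"]),
        role=meta["role"],
        bits=bits,
        frame_id=meta.get("frame_id", ""),
    )


def write_absorbance_csv(spec: AbsorbanceSpectrum, path, extra_meta: dict | None = None) -> None:
    lines = []
    meta = dict(extra_meta or {})
    meta.setdefault("provenance", json.dumps(spec.provenance, sort_keys=True))
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    lines.append("wavelength_nm,absorbance,flag")
    for lam, ab, fl in zip(spec.wavelengths, spec.absorbance, spec.flags):
        lines.append(f"{_format_real(lam)},{_format_real(ab)},{fl}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_absorbance_csv(path) -> AbsorbanceSpectrum:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, start = _parse_headers(lines)
    body = [l for l in lines[start:] if l.strip()]
    if not body or body[0].strip() != "wavelength_nm,absorbance,flag":
        raise FrameFormatError(f"{path}: missing absorbance CSV column header")
    lam, ab, flags = [], [], []
    for line in body[1:]:
        w, a, fl = line.split(",")
        lam.append(float(w))
        ab.append(float(a))
        flags.append(fl.strip())
    provenance = {}
    if "provenance" in meta:
        try:
            provenance = json.loads(meta["provenance"])
        except json.JSONDecodeError:
            provenance = {"raw": meta["provenance"]}
    return AbsorbanceSpectrum(
        np.asarray(lam), np.asarray(ab), tuple(flags), provenance
    )


def write_series_csv(df: pd.DataFrame, path, unit: str = "") -> None:
    """Calibration series CSV: concentration,response[,day,replicate]."""
    cols = [c for c in ("concentration", "response", "day", "replicate") if c in df]
    lines = [f"# unit={unit or df.attrs.get('unit', '')}", ",".join(cols)]
    for _, row in df.iterrows():
        vals = []
        for c in cols:
            v = row[c]
            vals.append(str(int(v)) if c in ("day", "replicate") else _format_real(float(v)))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_series_csv(path) -> CalibrationSeries:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta, start = _parse_headers(lines)
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(lines[start:])))
    if "concentration" not in df or "response" not in df:
        raise FrameFormatError(f"{path}: need concentration and response columns")
    return CalibrationSeries.from_frame(df, unit=meta.get("unit", ""))


def write_calibration_json(cal: WavelengthCalibration, path) -> None:
    payload = {
        "coefficients_lowest_first": list(cal.coefficients),
        "pixel_range": list(cal.pixel_range),
        "working_range_nm": list(cal.working_range),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_calibration_json(path) -> WavelengthCalibration:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return WavelengthCalibration(
        coefficients=tuple(payload["coefficients_lowest_first"]),
        pixel_range=tuple(payload["pixel_range"]),
        working_range=tuple(payload["working_range_nm"]),
    )


# -- instrument / sample configuration -------------------------------------


def _bands_from_config(entries) -> tuple[GaussianBand, ...]:
    return tuple(
        GaussianBand(e["center_nm"], e["fwhm_nm"], e.get("amplitude", 1.0))
        for e in entries
    )


def load_instrument_config(path) -> tuple[InstrumentModel, SampleModel | None]:
    """Build an instrument (and optional sample) from a YAML/JSON config."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    src_cfg = cfg.get("source")
    if src_cfg is None:
        source = warm_white_led()
    else:
        source = SourceModel(
            components=_bands_from_config(src_cfg.get("bands", [])),
            peak_counts=src_cfg.get("peak_counts", 950.0),
        )
    det = DetectorModel(**cfg.get("detector", {}))
    cal_cfg = cfg.get("calibration")
    if cal_cfg is None:
        cal = WavelengthCalibration()
    else:
        cal = WavelengthCalibration(
            coefficients=tuple(cal_cfg["coefficients_lowest_first"]),
            pixel_range=tuple(cal_cfg.get("pixel_range", (0, det.n_pixels - 1))),
            working_range=tuple(cal_cfg.get("working_range_nm", (450.0, 750.0))),
        )
    model = InstrumentModel(source=source, detector=det, calibration=cal)
    sample = None
    if "sample" in cfg:
        scfg = cfg["sample"]
        constituents = []
        for entry in scfg.get("constituents", []):
            analyte = AnalyteSpectrum(
                name=entry.get("name", "analyte"),
                bands=_bands_from_config(entry.get("bands", [])),
                flat_bands=tuple(
                    (b["lo_nm"], b["hi_nm"], b["epsilon"])
                    for b in entry.get("flat_bands", [])
                ),
            )
            constituents.append((analyte, entry["concentration"]))
        sample = SampleModel(
            constituents=tuple(constituents),
            path_length_cm=scfg.get("path_length_cm", 1.0),
        )
    return model, sample


def config_hash(path) -> str:
    """Stable sha256 of a config file, for run provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
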