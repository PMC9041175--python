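"""Packaged worked-example calibration series."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .calstats import CalibrationSeries
from .io import read_series_csv

__all__ = ["available", "load_series", "fixture_path"]

_FIXTURES = {
    "vitamin_b12": "vitamin_b12_osms.csv",
    "phosphate": "phosphate_osms.csv",
    "h2o2": "h2o2_osms.csv",
}


def available() -> tuple[str, ...]:
    return tuple(_FIXTURES)


def fixture_path(name: str) -> Path:
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return Path(resources.files("minispec.data") / _FIXTURES[name])


def load_series(name: str) -> CalibrationSeries:
    """Load one of the packaged concentration-response series by name."""
    return read_series_csv(fixture_path(name))
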