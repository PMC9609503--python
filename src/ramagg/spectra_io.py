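"""Spectrum container and text I/O.

Canonical on-disk format: two whitespace-separated columns (wavenumber,
intensity), metadata as ``# key=value`` header lines.  A CSV dialect with a
``wavenumber,intensity`` header row is also supported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import TextIO

import numpy as np

from .exceptions import AxisOrderError, InsufficientDataError, SpectrumParseError

MIN_POINTS = 10

_META_FIELDS = ("sample_id", "ph", "time_h", "normalized", "baseline_removed")


@dataclass
class SpectrumMeta:
    sample_id: str | None = None
    ph: float | None = None
    time_h: float | None = None
    normalized: bool = False
    baseline_removed: bool = False

    def to_header_items(self) -> list[tuple[str, str]]:
        items: list[tuple[str, str]] = []
        if self.sample_id is not None:
            items.append(("sample_id", str(self.sample_id)))
        if self.ph is not None:
            items.append(("ph", repr(float(self.ph))))
        if self.time_h is not None:
            items.append(("time_h", repr(float(self.time_h))))
        if self.normalized:
            items.append(("normalized", "true"))
        if self.baseline_removed:
            items.append(("baseline_removed", "true"))
        return items


@dataclass
class Spectrum:
    """A Raman spectrum: strictly ascending wavenumber axis with intensities."""

    wavenumbers: np.ndarray  # cm^-1
    intensities: np.ndarray  # arbitrary units
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise AxisOrderError("wavenumber axis must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum on [lo, hi] cm^-1 (inclusive), metadata preserved."""
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return Spectrum(self.wavenumbers[m], self.intensities[m], replace(self.meta))

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(),
            np.asarray(intensities, dtype=float),
            replace(self.meta, **meta_updates),
        )


def _parse_meta_value(key: str, raw: str):
    raw = raw.strip()
    if key in ("normalized", "baseline_removed"):
        return raw.lower() in ("1", "true", "yes")
    if key in ("ph", "time_h"):
        return float(raw)
    return raw


def read_spectrum(source: TextIO | str, dialect: str = "two-column") -> Spectrum:
    """Read a spectrum from a text stream or string.

    ``dialect='two-column'``: whitespace-separated pairs with '#' comments.
    ``dialect='csv-with-header'``: a header row then comma-separated pairs.
    Descending axes are sorted ascending (intensities co-sorted).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    meta = SpectrumMeta()
    wn: list[float] = []
    it: list[float] = []
    header_seen = False
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _META_FIELDS:
                    try:
                        setattr(meta, key, _parse_meta_value(key, val))
                    except ValueError:
                        raise SpectrumParseError(f"bad metadata value for {key!r}", lineno)
            continue
        if dialect == "csv-with-header":
            if not header_seen:
                header_seen = True
                # tolerate a numeric first row (headerless CSV)
                first = stripped.split(",")[0]
                try:
                    float(first)
                except ValueError:
                    continue
            parts = stripped.split(",")
        elif dialect == "two-column":
            parts = stripped.split()
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        if len(parts) != 2:
            raise SpectrumParseError(f"expected 2 columns, got {len(parts)}", lineno)
        try:
            wn.append(float(parts[0]))
            it.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(f"non-numeric row: {stripped!r}", lineno)
    if len(wn) < MIN_POINTS:
        raise InsufficientDataError(
            f"spectrum has {len(wn)} points; at least {MIN_POINTS} required"
        )
    w = np.asarray(wn)
    i = np.asarray(it)
    order = np.argsort(w)
    return Spectrum(w[order], i[order], meta)


def write_spectrum(spectrum: Spectrum, sink: TextIO, dialect: str = "two-column") -> None:
    """Write a spectrum with >=9 significant digits; metadata as '#' header."""
    for key, val in spectrum.meta.to_header_items():
        sink.write(f"# {key}={val}\n")
    if dialect == "csv-with-header":
        sink.write("wavenumber,intensity\n")
        sep = ","
    elif dialect == "two-column":
        sep = " "
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
        sink.write(f"{w:.12g}{sep}{i:.12g}\n")
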