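"""Marker-band observables and their time series.

Each marker is read off a regional Lorentzian fit: the S-S stretch height at
505 cm^-1 (disulphide integrity), the Trp indole FWHM at 759 cm^-1 and the
I1341/I1363 Fermi-doublet ratio (Trp environment/hydrophobicity), the Tyr
doublet position near 830 cm^-1 (phenolic H-bonding), the skeletal markers
at 900/932 cm^-1, the Amide III height at 1280 cm^-1, and the CH-deformation
FWHM at 1446 cm^-1.  "Intensity" of a marker is the fitted Lorentzian height
throughout (config-switchable to area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import (
    DeconvolutionError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .peakfit import FitResult, fit_lorentzians
from .spectra_io import Spectrum


class PeakMetrics(NamedTuple):
    position: float  # cm^-1
    fwhm: float  # cm^-1
    height: float  # intensity (anchor units)
    area: float  # intensity * cm^-1


def peak_metrics(fit: FitResult, target_center: float) -> PeakMetrics:
    """Metrics of the component labelled by its initialization center."""
    if not fit.converged:
        raise DeconvolutionError("metrics requested from a non-converged fit", fit)
    p = fit.peak_by_label(target_center)
    return PeakMetrics(position=p.center, fwhm=p.fwhm, height=p.height, area=p.area)


def ss_band_intensity(fit: FitResult) -> float:
    """Fitted height of the 505 cm^-1 S-S stretching component."""
    return peak_metrics(fit, 505.0).height


def hydrophobicity_ratio(fit: FitResult) -> float:
    """The Trp Fermi-doublet intensity ratio I(1341)/I(1363)."""
    h_num = peak_metrics(fit, 1341.0).height
    h_den = peak_metrics(fit, 1363.0).height
    if h_den <= 0:
        raise UndefinedRatioError("1363 cm^-1 component has non-positive height")
    return h_num / h_den


@dataclass(frozen=True)
class MarkerSpec:
    """How to extract one marker: fit region, component centers, metric.

    ``metric`` is one of height/position/fwhm/area (read off the component at
    ``target``) or ratio (height of centers[0] over height of centers[1]).
    """

    name: str
    region: tuple[float, float]
    centers: tuple[float, ...]
    metric: str
    target: float | None = None
    center_drift: float = 5.0
    fwhm_bounds: tuple[float, float] = (4.0, 40.0)

    @property
    def target_center(self) -> float:
        return self.target if self.target is not None else self.centers[0]


def default_marker_specs() -> list[MarkerSpec]:
    """The standard HEWL marker set."""
    return [
        MarkerSpec("I505", (475.0, 535.0), (505.0,), "height"),
        MarkerSpec("FWHM759", (735.0, 785.0), (759.0,), "fwhm"),
        MarkerSpec("pos830", (806.0, 868.0), (830.0, 850.0), "position", target=830.0),
        MarkerSpec("pos876", (862.0, 892.0), (876.0,), "position"),
        MarkerSpec("pos900", (884.0, 956.0), (900.0, 932.0), "position", target=900.0),
        MarkerSpec("I932", (884.0, 956.0), (900.0, 932.0), "height", target=932.0),
        MarkerSpec("I1004", (985.0, 1025.0), (1004.0,), "height"),
        MarkerSpec("I1280", (1200.0, 1310.0), (1240.0, 1280.0), "height", target=1280.0),
        MarkerSpec("ratio1341_1363", (1320.0, 1385.0), (1341.0, 1363.0), "ratio",
                   center_drift=4.0),
        MarkerSpec("FWHM1446", (1415.0, 1480.0), (1446.0,), "fwhm"),
    ]


# default initial FWHM guesses per component center
_INIT_FWHM = {505.0: 12.0, 759.0: 9.0, 830.0: 10.0, 850.0: 10.0, 876.0: 10.0,
              900.0: 12.0, 932.0: 12.0, 1004.0: 8.0, 1240.0: 18.0, 1280.0: 18.0,
              1341.0: 10.0, 1363.0: 10.0, 1446.0: 16.0}


def fit_marker_region(spectrum: Spectrum, spec: MarkerSpec) -> FitResult:
    """Fit the marker's region jointly with its overlapping companions."""
    sub = spectrum.crop(*spec.region)
    floor = float(np.min(sub.intensities))
    init = []
    for c in spec.centers:
        idx = int(np.argmin(np.abs(sub.wavenumbers - c)))
        h = max(float(sub.intensities[idx]) - floor, 1e-6)
        init.append((c, _INIT_FWHM.get(c, 12.0), h))
    return fit_lorentzians(
        spectrum,
        spec.region,
        init,
        center_drift=spec.center_drift,
        fwhm_bounds=spec.fwhm_bounds,
        background="constant",
    )


def _metric_value(fit: FitResult, spec: MarkerSpec) -> tuple[float, float]:
    """(value, sigma) for one spec from one converged fit."""
    if spec.metric == "ratio":
        num = fit.peak_by_label(spec.centers[0])
        den = fit.peak_by_label(spec.centers[1])
        if den.height <= 0:
            raise UndefinedRatioError("denominator component has non-positive height")
        value = num.height / den.height
        rel = 0.0
        for p in (num, den):
            if np.isfinite(p.area_se) and p.area > 0:
                rel += (p.area_se / p.area) ** 2
        sigma = value * np.sqrt(rel) if rel > 0 else float("nan")
        return value, sigma
    m = peak_metrics(fit, spec.target_center)
    p = fit.peak_by_label(spec.target_center)
    if spec.metric == "height":
        sigma = p.area_se / (np.pi * p.gamma) if np.isfinite(p.area_se) else float("nan")
        return m.height, sigma
    if spec.metric == "position":
        return m.position, p.center_se
    if spec.metric == "fwhm":
        return m.fwhm, 2.0 * p.gamma_se
    if spec.metric == "area":
        return m.area, p.area_se
    raise ValueError(f"unknown metric {spec.metric!r}")


@dataclass
class MarkerSeries:
    """One marker versus time; missing values are NaN."""

    name: str
    times: np.ndarray  # hours
    values: np.ndarray
    uncertainties: np.ndarray
    usable: bool = True  # False when <3 valid points (unfit for kinetics)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if not (self.times.shape == self.values.shape == self.uncertainties.shape):
            raise ValueError("times/values/uncertainties must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly ascending")

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.values)))


def build_marker_series(
    spectra: list[Spectrum],
    marker_specs: list[MarkerSpec] | None = None,
) -> list[MarkerSeries]:
    """Assemble per-marker time series from time-ordered preprocessed spectra.

    A failed or non-converged regional fit contributes a missing value (NaN)
    at that time point only; other time points are unaffected.  Series with
    fewer than 3 valid points are flagged unusable for kinetics.
    """
    if len(spectra) < 3:
        raise InsufficientDataError("marker series need at least 3 time points")
    specs = marker_specs if marker_specs is not None else default_marker_specs()
    times = np.array(
        [s.meta.time_h if s.meta.time_h is not None else float(i) for i, s in enumerate(spectra)]
    )
    series = []
    for spec in specs:
        values = np.full(len(spectra), np.nan)
        sigmas = np.full(len(spectra), np.nan)
        for i, spectrum in enumerate(spectra):
            try:
                sub = spectrum.crop(*spec.region)
                if sub.wavenumbers.size == 0 or np.max(np.abs(sub.intensities)) == 0:
                    continue  # dead spectrum: record as missing
                fit = fit_marker_region(spectrum, spec)
                if not fit.converged:
                    continue
                values[i], sigmas[i] = _metric_value(fit, spec)
            except Exception:
                continue  # missing value, never fabricated
        usable = int(np.sum(np.isfinite(values))) >= 3
        if not usable:
            warnings.warn(
                f"marker {spec.name!r} has <3 valid points; unusable for kinetics",
                stacklevel=2,
            )
        series.append(MarkerSeries(spec.name, times, values, sigmas, usable=usable))
    return series
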