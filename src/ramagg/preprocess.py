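"""Spectral preprocessing: cosmic-ray spike removal, baseline subtraction and
normalization to the conformation-insensitive phenylalanine band at 1004 cm^-1.

The fixed pipeline order is spike removal -> baseline -> normalization; the
order is recorded in each Spectrum's metadata flags so downstream fits can
verify their preconditions.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .exceptions import DomainError, InsufficientDataError, NormalizationError
from .peakfit import fit_lorentzians
from .spectra_io import Spectrum

DEFAULT_SPIKE_Z = 8.0
# fraction of the global intensity maximum a single-point excursion must reach
# before it can be called a spike; keeps genuine sharp bands (FWHM >= 8 cm^-1
# on a 1 cm^-1 grid) untouched even on noiseless data
SPIKE_REL_FLOOR = 0.1
DEFAULT_NORM_REFERENCE = 1004.0
DEFAULT_NORM_WINDOW = 8.0

# flat inter-band regions of the HEWL Raman spectrum, used as baseline anchors
DEFAULT_ANCHORS = (
    305.0, 360.0, 420.0, 560.0, 620.0, 680.0, 720.0, 800.0, 960.0,
    1060.0, 1120.0, 1170.0, 1315.0, 1410.0, 1530.0, 1580.0, 1745.0, 1795.0,
)


def remove_spikes(spectrum: Spectrum, z_threshold: float = DEFAULT_SPIKE_Z) -> Spectrum:
    """Replace single-point cosmic-ray spikes by linear interpolation.

    A point is a spike when its positive excursion above the mean of its two
    neighbours exceeds ``z_threshold`` robust standard deviations of that
    second-difference statistic *and* a fixed fraction of the global maximum.
    Both gates must fire: the z-score rejects noise, the relative floor keeps
    genuine narrow bands intact on noiseless spectra.
    """
    if z_threshold <= 0:
        raise DomainError("z_threshold must be positive")
    y = spectrum.intensities
    n = y.size
    if n < 5:
        raise InsufficientDataError("need at least 5 points for spike detection")
    # excursion of each interior point above its neighbour midpoint
    e = np.zeros(n)
    e[1:-1] = y[1:-1] - 0.5 * (y[:-2] + y[2:])
    mad = np.median(np.abs(e[1:-1] - np.median(e[1:-1])))
    sigma = max(1.4826 * mad, 1e-300)
    floor = SPIKE_REL_FLOOR * float(np.max(np.abs(y))) if n else 0.0
    flagged = (e > z_threshold * sigma) & (e > floor)
    flagged[0] = flagged[-1] = False
    if not np.any(flagged):
        return spectrum.with_intensities(y.copy())
    good = ~flagged
    x = spectrum.wavenumbers
    cleaned = y.copy()
    cleaned[flagged] = np.interp(x[flagged], x[good], y[good])
    return spectrum.with_intensities(cleaned)


def _als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10) -> np.ndarray:
    """Asymmetric least squares baseline (Eilers-Boelens smoother)."""
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        w_mat = sparse.diags(w)
        z = spsolve((w_mat + dtd).tocsc(), w * y)
        w = p * (y > z) + (1.0 - p) * (y <= z)
    return np.asarray(z)


def subtract_baseline(
    spectrum: Spectrum,
    method: str = "anchor_points",
    anchors: tuple[float, ...] = DEFAULT_ANCHORS,
    anchor_half_window: float = 3.0,
    lam: float = 1e5,
    p: float = 0.01,
) -> Spectrum:
    """Subtract a baseline and set the ``baseline_removed`` flag.

    ``anchor_points`` interpolates linearly between the spectrum's intensity
    at the anchor wavenumbers (the scripted analogue of a user-drawn
    baseline).  Each node value is the mean over ``anchor_half_window`` cm^-1
    on either side of the anchor, which suppresses single-pixel noise;
    set it to 0 to use the bare grid point.  On locally linear data the
    output intensity at every anchor is exactly zero.  ``als`` fits an
    asymmetric-least-squares smooth baseline instead.
    """
    x, y = spectrum.wavenumbers, spectrum.intensities
    if method == "anchor_points":
        inside = [a for a in anchors if x[0] <= a <= x[-1]]
        if len(inside) != len(anchors):
            raise DomainError("baseline anchors must lie inside the wavenumber axis")
        if len(inside) < 2:
            raise DomainError("anchor_points baseline needs at least 2 anchors")
        nodes_x, nodes_y = [], []
        for a in inside:
            # keep the averaging window symmetric inside the axis so that a
            # locally linear signal yields exactly its on-anchor value
            half = min(anchor_half_window, a - x[0], x[-1] - a)
            mask = np.abs(x - a) <= half + 1e-9
            if not np.any(mask):
                mask = np.zeros_like(x, dtype=bool)
                mask[int(np.argmin(np.abs(x - a)))] = True
            nodes_x.append(a)
            nodes_y.append(float(np.mean(y[mask])))
        baseline = np.interp(x, nodes_x, nodes_y)
    elif method == "als":
        baseline = _als_baseline(y, lam=lam, p=p)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return spectrum.with_intensities(y - baseline, baseline_removed=True)


def normalize_to_phe(
    spectrum: Spectrum,
    reference: float = DEFAULT_NORM_REFERENCE,
    window: float = DEFAULT_NORM_WINDOW,
    mode: str = "fit",
) -> Spectrum:
    """Divide the spectrum by the fitted height of the 1004 cm^-1 band.

    ``mode='fit'`` (default) fits one Lorentzian plus a constant offset inside
    ``reference +/- window`` and uses its height; ``mode='max'`` uses the raw
    maximum.  Already-normalized spectra are returned unchanged, which makes
    normalization exactly idempotent.
    """
    x = spectrum.wavenumbers
    if reference - window < x[0] or reference + window > x[-1]:
        raise DomainError("normalization window must lie inside the wavenumber axis")
    if spectrum.meta.normalized:
        return spectrum.with_intensities(spectrum.intensities.copy())
    if not spectrum.meta.baseline_removed:
        warnings.warn(
            "normalizing a spectrum whose baseline_removed flag is not set",
            stacklevel=2,
        )
    region = (reference - window, reference + window)
    if mode == "max":
        height = float(np.max(spectrum.crop(*region).intensities))
    elif mode == "fit":
        sub = spectrum.crop(*region)
        guess_h = float(np.max(sub.intensities) - np.min(sub.intensities))
        try:
            fit = fit_lorentzians(
                spectrum,
                region,
                [(reference, 8.0, max(guess_h, 1e-6))],
                center_drift=4.0,
                fwhm_bounds=(4.0, 24.0),
                background="constant",
            )
        except InsufficientDataError:
            raise
        except Exception as exc:  # optimizer failure
            raise NormalizationError(f"reference-band fit failed: {exc}") from exc
        if not fit.converged:
            raise NormalizationError("reference-band fit did not converge")
        height = fit.peaks[0].height
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    min_height = 1e-3 * float(np.max(np.abs(spectrum.intensities)))
    if not np.isfinite(height) or height <= min_height:
        raise NormalizationError(
            f"no detectable band at {reference} cm^-1 (fitted height {height!r})"
        )
    return spectrum.with_intensities(spectrum.intensities / height, normalized=True)


def preprocess(
    spectrum: Spectrum,
    spike_z: float = DEFAULT_SPIKE_Z,
    baseline_method: str = "anchor_points",
    anchors: tuple[float, ...] = DEFAULT_ANCHORS,
    norm_reference: float = DEFAULT_NORM_REFERENCE,
    norm_window: float = DEFAULT_NORM_WINDOW,
    norm_mode: str = "fit",
) -> Spectrum:
    """Full preprocessing chain: spikes -> baseline -> 1004 cm^-1 normalization."""
    s = remove_spikes(spectrum, z_threshold=spike_z)
    s = subtract_baseline(s, method=baseline_method, anchors=anchors)
    return normalize_to_phe(s, reference=norm_reference, window=norm_window, mode=norm_mode)
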