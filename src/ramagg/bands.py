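"""Raman band library for hen egg-white lysozyme (HEWL).

Band positions follow the standard protein Raman assignments: the Amide I
components near 1647/1657/1671/1688 cm^-1 report random coil, alpha-helix,
beta-sheet and beta-turn content respectively; the phenylalanine ring-breathing
band at 1004 cm^-1 is conformation-insensitive and serves as the intensity
normalization anchor; the remaining markers (S-S stretch at 505, tryptophan
indole at 759/876/1341/1363, tyrosine Fermi doublet near 830/850, backbone
skeletal modes at 900/932, CH deformation at 1446, Amide III near 1240/1280)
track unfolding and aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError

AMIDE1_CATEGORIES = ("amide1_coil", "amide1_alpha", "amide1_beta", "amide1_turn")


@dataclass(frozen=True)
class Band:
    """One library entry: a Lorentzian band with nominal parameters.

    ``default_height`` is in normalization-anchor units (the 1004 cm^-1
    phenylalanine band has height 1.0 by convention).
    """

    center: float  # cm^-1
    default_fwhm: float  # cm^-1
    assignment: str
    category: str  # amide1_* | marker | other
    default_height: float = 0.0

    @property
    def gamma(self) -> float:
        """Half-width at half-maximum, cm^-1."""
        return self.default_fwhm / 2.0


@dataclass
class BandLibrary:
    """A validated collection of bands used by the spectrum generator and fitters."""

    entries: list[Band] = field(default_factory=list)

    def __post_init__(self) -> None:
        centers = [b.center for b in self.entries]
        if any(c <= 0 for c in centers):
            raise ConfigError("band centers must be strictly positive")
        if len(set(centers)) != len(centers):
            raise ConfigError("band centers must be unique")
        for cat in AMIDE1_CATEGORIES:
            n = sum(1 for b in self.entries if b.category == cat)
            if n != 1:
                raise ConfigError(f"band library must contain exactly one {cat} band, found {n}")

    def by_center(self, center: float, tol: float = 0.5) -> Band:
        for b in self.entries:
            if abs(b.center - center) <= tol:
                return b
        raise KeyError(f"no band within {tol} cm^-1 of {center}")

    def by_category(self, category: str) -> list[Band]:
        return [b for b in self.entries if b.category == category]

    @property
    def amide1_centers(self) -> dict[str, float]:
        return {cat: self.by_category(cat)[0].center for cat in AMIDE1_CATEGORIES}


def default_band_library() -> BandLibrary:
    """The default HEWL band set (positions in cm^-1, heights in anchor units)."""
    return BandLibrary(
        entries=[
            Band(505.0, 12.0, "S-S stretch", "marker", 0.45),
            Band(759.0, 9.0, "Trp indole breathing", "marker", 0.90),
            Band(830.0, 10.0, "Tyr Fermi doublet (low)", "marker", 0.55),
            Band(850.0, 10.0, "Tyr Fermi doublet (high)", "other", 0.50),
            Band(876.0, 10.0, "Trp indole N-H", "marker", 0.35),
            Band(900.0, 12.0, "N-Calpha-C stretch", "marker", 0.20),
            Band(932.0, 12.0, "N-Calpha-C stretch (helical)", "marker", 0.40),
            Band(1004.0, 8.0, "Phe ring breathing", "marker", 1.00),
            Band(1240.0, 18.0, "Amide III (extended)", "other", 0.50),
            Band(1280.0, 18.0, "Amide III (helical)", "marker", 0.80),
            Band(1341.0, 10.0, "Trp doublet (low)", "marker", 1.10),
            Band(1363.0, 10.0, "Trp doublet (high)", "marker", 0.85),
            Band(1446.0, 16.0, "CH2/CH3 deformation", "marker", 0.95),
            Band(1647.0, 20.0, "Amide I random coil", "amide1_coil"),
            Band(1657.0, 20.0, "Amide I alpha-helix", "amide1_alpha"),
            Band(1671.0, 20.0, "Amide I beta-sheet", "amide1_beta"),
            Band(1688.0, 20.0, "Amide I beta-turn", "amide1_turn"),
        ]
    )
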