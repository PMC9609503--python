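"""Synthetic data with known ground truth: Raman spectra, aggregation time
courses, and toy two-chain structures/trajectories.

The generators emulate the study system — hen egg-white lysozyme (HEWL)
incubated at pH 7.0 (folded control) or pH 12.2 (aggregating): spectra are
sums of Lorentzian bands at the standard HEWL positions on a polynomial
baseline with additive Gaussian noise; Amide I component areas are set
proportional to the ground-truth secondary-structure percentages, so
deconvolution has an exact target.  Time courses interpolate markers between
a folded start state (alpha ~50%, beta ~23%) and an aggregated end state
(alpha ~20%, beta ~45%) either without a lag phase (isodesmic regime), with
a logistic lag (nucleated regime), or not at all (static regime).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .bands import AMIDE1_CATEGORIES, BandLibrary, default_band_library
from .exceptions import AxisOrderError, ConfigError, DomainError
from .peakfit import lorentzian
from .peptides import build_chain
from .spectra_io import Spectrum, SpectrumMeta
from .structure import Atom, Chain, StructureModel, Trajectory

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0, 240.0)
DEFAULT_TOTAL_AMIDE1_AREA = 50.0  # anchor-band units x cm^-1
REGIMES = ("static", "isodesmic", "nucleated")

# folded state (pH 7.0 control; also t=0 at pH 12.2) and aggregated end state
SS_FOLDED = {"alpha": 50.0, "beta_sheet": 23.0, "beta_turn": 17.0, "coil": 10.0}
SS_AGGREGATED = {"alpha": 20.0, "beta_sheet": 45.0, "beta_turn": 20.0, "coil": 15.0}


@dataclass(frozen=True)
class MarkerState:
    """Instantaneous Lorentzian parameters of one marker band."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    height: float  # anchor units


# marker band states in the folded protein and the 240 h aggregate at pH 12.2
MARKERS_FOLDED = {
    505: MarkerState(505.0, 12.0, 0.45),
    759: MarkerState(759.0, 9.0, 0.90),
    830: MarkerState(834.5, 10.0, 0.55),
    876: MarkerState(876.0, 10.0, 0.35),
    900: MarkerState(900.0, 12.0, 0.20),
    932: MarkerState(932.0, 12.0, 0.40),
    1280: MarkerState(1280.0, 18.0, 0.80),
    1341: MarkerState(1341.0, 10.0, 1.10),
    1363: MarkerState(1363.0, 10.0, 0.85),
    1446: MarkerState(1446.0, 16.0, 0.95),
}
MARKERS_AGGREGATED = {
    505: MarkerState(505.0, 12.0, 0.0225),  # S-S band almost fully lost by 240 h
    759: MarkerState(759.0, 12.0, 0.90),  # indole FWHM 9 -> 12
    830: MarkerState(829.7, 10.0, 0.55),  # Tyr doublet position 834.5 -> 829.7
    876: MarkerState(878.0, 12.0, 0.35),
    900: MarkerState(903.0, 16.0, 0.20),
    932: MarkerState(932.0, 12.0, 0.18),  # helical skeletal intensity falls
    1280: MarkerState(1280.0, 18.0, 0.40),  # Amide III alpha component falls
    1341: MarkerState(1341.0, 10.0, 0.64),  # I1341/I1363 ratio decays
    1363: MarkerState(1363.0, 10.0, 0.85),
    1446: MarkerState(1446.0, 22.0, 0.95),  # CH deformation broadens
}


@dataclass
class GroundTruthSlice:
    """State of the sample at one time point: SS percentages + marker bands."""

    time_h: float
    ss: dict[str, float]
    markers: dict[int, MarkerState] = field(default_factory=lambda: dict(MARKERS_FOLDED))
    regime: str = "static"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown kinetic regime {self.regime!r}")
        total = sum(self.ss.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"secondary-structure percentages sum to {total}, not 100")

    def to_dict(self) -> dict:
        return {
            "time_h": self.time_h,
            "ss": dict(self.ss),
            "markers": {
                str(k): {"center": m.center, "fwhm": m.fwhm, "height": m.height}
                for k, m in self.markers.items()
            },
            "regime": self.regime,
        }


def ground_truth_json(slices: list[GroundTruthSlice]) -> str:
    return json.dumps([s.to_dict() for s in slices], indent=1)


@dataclass
class KineticParams:
    """Kinetic description of a time course.

    ``rate`` is the exponential rate (h^-1) of the isodesmic regime or the
    logistic steepness of the nucleated regime; ``t50`` is the logistic
    midpoint (hours, nucleated only).
    """

    t50: float = 48.0
    rate: float = 0.5
    ss_start: dict[str, float] = field(default_factory=lambda: dict(SS_FOLDED))
    ss_end: dict[str, float] = field(default_factory=lambda: dict(SS_AGGREGATED))
    marker_start: dict[int, MarkerState] = field(default_factory=lambda: dict(MARKERS_FOLDED))
    marker_end: dict[int, MarkerState] = field(default_factory=lambda: dict(MARKERS_AGGREGATED))


def default_axis() -> np.ndarray:
    """The default wavenumber grid: 300-1800 cm^-1 at 1 cm^-1 spacing."""
    return np.arange(300.0, 1801.0, 1.0)


def generate_spectrum(
    ground_truth: GroundTruthSlice,
    band_library: BandLibrary | None = None,
    axis: np.ndarray | None = None,
    baseline_coeffs: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    spike_count: int = 0,
    seed: int = 0,
    total_amide1_area: float = DEFAULT_TOTAL_AMIDE1_AREA,
    ph: float | None = None,
    sample_id: str | None = None,
) -> Spectrum:
    """Synthesize one Raman spectrum from a ground-truth slice.

    Intensity = sum of Lorentzians (Amide I component areas proportional to
    the SS percentages; marker bands at their ground-truth states; all other
    library bands at defaults; the 1004 cm^-1 normalization anchor is always
    present) + polynomial baseline (coefficients over u=(x-300)/1500, highest
    power first) + Gaussian noise + optional single-point positive spikes.
    Identical seeds give bit-identical spectra.
    """
    lib = band_library or default_band_library()
    x = default_axis() if axis is None else np.asarray(axis, dtype=float)
    if x.size >= 2 and not np.all(np.diff(x) > 0):
        raise AxisOrderError("wavenumber axis must be strictly ascending")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if spike_count < 0:
        raise DomainError("spike_count must be non-negative")

    y = np.zeros_like(x)
    for band in lib.entries:
        if band.category in AMIDE1_CATEGORIES:
            key = band.category.removeprefix("amide1_")
            key = {"alpha": "alpha", "beta": "beta_sheet", "turn": "beta_turn", "coil": "coil"}[key]
            area = ground_truth.ss[key] / 100.0 * total_amide1_area
            y += lorentzian(x, band.center, band.gamma, area)
        else:
            state = ground_truth.markers.get(int(round(band.center)))
            if state is None:
                state = MarkerState(band.center, band.default_fwhm, band.default_height)
            gamma = state.fwhm / 2.0
            y += lorentzian(x, state.center, gamma, state.height * np.pi * gamma)

    clean_max = float(np.max(y)) if y.size else 0.0
    if baseline_coeffs:
        u = (x - 300.0) / 1500.0
        y = y + np.polyval(baseline_coeffs, u)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    if spike_count > 0:
        idx = rng.choice(x.size, size=min(spike_count, x.size), replace=False)
        amplitude = 25.0 * noise_sd + 0.75 * clean_max
        y[idx] += amplitude

    meta = SpectrumMeta(
        sample_id=sample_id or f"synthetic-{ground_truth.regime}",
        ph=ph,
        time_h=ground_truth.time_h,
    )
    return Spectrum(x, y, meta)


def _progress(regime: str, t: np.ndarray, params: KineticParams) -> np.ndarray:
    if regime == "static":
        return np.zeros_like(t)
    if regime == "isodesmic":
        return 1.0 - np.exp(-params.rate * t)
    if regime == "nucleated":
        return 1.0 / (1.0 + np.exp(-params.rate * (t - params.t50)))
    raise ConfigError(f"unknown kinetic regime {regime!r}")


def ground_truth_timecourse(
    regime: str,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    kinetic_params: KineticParams | None = None,
) -> list[GroundTruthSlice]:
    """Ground-truth slices along a time course, without spectra."""
    if regime not in REGIMES:
        raise ConfigError(f"unknown kinetic regime {regime!r}")
    t = np.asarray(timepoints, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise DomainError("timepoints must be non-negative and strictly ascending")
    if kinetic_params is None:
        kinetic_params = KineticParams(rate=0.02 if regime == "isodesmic" else 0.5)
    p = _progress(regime, t, kinetic_params)
    slices = []
    for ti, pi in zip(t, p):
        ss = {
            k: kinetic_params.ss_start[k] + pi * (kinetic_params.ss_end[k] - kinetic_params.ss_start[k])
            for k in kinetic_params.ss_start
        }
        markers = {}
        for key, m0 in kinetic_params.marker_start.items():
            m1 = kinetic_params.marker_end.get(key, m0)
            markers[key] = MarkerState(
                center=m0.center + pi * (m1.center - m0.center),
                fwhm=m0.fwhm + pi * (m1.fwhm - m0.fwhm),
                height=m0.height + pi * (m1.height - m0.height),
            )
        slices.append(GroundTruthSlice(time_h=float(ti), ss=ss, markers=markers, regime=regime))
    return slices


def generate_timecourse(
    regime: str,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    kinetic_params: KineticParams | None = None,
    noise_sd: float = 0.0,
    spike_count: int = 0,
    seed: int = 0,
    band_library: BandLibrary | None = None,
) -> list[tuple[Spectrum, GroundTruthSlice]]:
    """Generate (spectrum, ground truth) pairs along a kinetic time course.

    static: SS percentages constant (the pH 7.0 control).  isodesmic:
    exponential saturation, changing from t=0 with no lag (the pH 12.2
    aggregation).  nucleated: logistic change with a lag phase (amyloid-like
    kinetics, for contrast).
    """
    slices = ground_truth_timecourse(regime, timepoints, kinetic_params)
    ph = 7.0 if regime == "static" else 12.2
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(slices))
    out = []
    for child, sl in zip(child_seeds, slices):
        spec = generate_spectrum(
            sl,
            band_library=band_library,
            noise_sd=noise_sd,
            spike_count=spike_count,
            seed=int(child),
            ph=ph,
            sample_id=f"synthetic-{regime}-t{sl.time_h:g}h",
        )
        out.append((spec, sl))
    return out


# ---------------------------------------------------------------------------
# Toy structures and trajectories

HEWL_CYS_POSITIONS = (6, 30, 64, 76, 80, 94, 115, 127)
HEWL_DISULPHIDES = ((6, 127), (30, 115), (64, 80), (76, 94))
HEWL_N_RESIDUES = 129


@dataclass
class ChainTemplate:
    """Residue-level description of one toy chain (extended conformation)."""

    n_residues: int = 24
    cys_positions: tuple[int, ...] = ()
    residue_names: dict[int, str] = field(default_factory=dict)  # overrides, 1-based
    phi: float = -120.0
    psi: float = 130.0

    def sequence(self) -> list[str]:
        seq = ["ALA"] * self.n_residues
        for pos in self.cys_positions:
            seq[pos - 1] = "CYS"
        for pos, name in self.residue_names.items():
            seq[pos - 1] = name
        return seq


@dataclass(frozen=True)
class ContactSpec:
    """A contact to plant between chain A and chain B (1-based residues)."""

    kind: str  # hydrogen_bond | salt_bridge | pi_cation | pi_pi
    res_a: int
    res_b: int
    distance: float | None = None


_CONTACT_DEFAULTS = {
    # (chain A residue, chain B residue, default geometry distance in Angstrom)
    "hydrogen_bond": ("SER", "SER", 2.9),
    "salt_bridge": ("LYS", "ASP", 3.8),
    "pi_cation": ("LYS", "PHE", 4.5),
    "pi_pi": ("PHE", "PHE", 4.5),
}


def _model_com(chains: list[Chain]) -> np.ndarray:
    pts, masses = [], []
    for c in chains:
        for r in c.residues:
            for a in r.atoms:
                pts.append(a.pos)
                masses.append(a.mass)
    pts = np.asarray(pts)
    m = np.asarray(masses)
    return (pts * m[:, None]).sum(axis=0) / m.sum()


def _translate_chain(chain: Chain, shift: np.ndarray) -> Chain:
    return Chain(
        chain.chain_id,
        [
            # fresh Atom objects so templates stay immutable
            type(r)(r.index, r.name, [Atom(a.name, a.element, a.pos + shift, a.mass) for a in r.atoms])
            for r in chain.residues
        ],
    )


_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
# chains are separated along z; contacts approach along this axis
_APPROACH = np.array([0.0, 0.0, 1.0])
_STALK = 2.0  # Angstrom the B-side functional group hangs below the B backbone


def _prepare_interface(chain_b: Chain, contacts: list[ContactSpec]) -> None:
    """Reposition chain B's contact-partner functional atoms onto short stalks
    pointing toward chain A, clear of the B backbone (toy geometry)."""
    if not contacts:
        return
    z_min = min(a.pos[2] for r in chain_b.residues for a in r.atoms)
    z0 = z_min - _STALK
    for spec in contacts:
        res_b = next(r for r in chain_b.residues if r.index == spec.res_b)
        ca = res_b.atom("CA").pos
        if spec.kind == "hydrogen_bond":
            res_b.atom("OG").pos = np.array([ca[0], ca[1], z0])
        elif spec.kind == "salt_bridge":
            res_b.atom("OD1").pos = np.array([ca[0], ca[1], z0])
            res_b.atom("OD2").pos = np.array([ca[0] + 2.2, ca[1], z0])
            res_b.atom("CG").pos = np.array([ca[0] + 1.1, ca[1], z0 + 1.0])
        elif spec.kind in ("pi_cation", "pi_pi"):
            center = np.array([ca[0], ca[1], z0])
            for k, name in enumerate(_RING_NAMES):
                theta = k * np.pi / 3.0
                res_b.atom(name).pos = center + 1.39 * np.array(
                    [np.cos(theta), np.sin(theta), 0.0]
                )
            res_b.atom("CB").pos = center + np.array([0.0, 0.0, 1.5])
        else:
            raise ConfigError(f"unknown contact kind {spec.kind!r}")


def _plant_contacts(
    chain_a: Chain, chain_b: Chain, contacts: list[ContactSpec]
) -> Chain:
    """Move chain A functional atoms so each contact holds exactly vs chain B.

    Chain A's partner atom is placed at the required distance straight below
    (toward A) the chain B target group, so planted pairs sit isolated in the
    inter-chain gap and cannot create accidental extra contacts.
    """
    new_a = _translate_chain(chain_a, np.zeros(3))
    for spec in contacts:
        res_a = next(r for r in new_a.residues if r.index == spec.res_a)
        res_b = next(r for r in chain_b.residues if r.index == spec.res_b)
        dist = spec.distance or _CONTACT_DEFAULTS[spec.kind][2]
        if spec.kind == "hydrogen_bond":
            mover, target = res_a.atom("OG"), res_b.atom("OG").pos
        elif spec.kind == "salt_bridge":
            mover, target = res_a.atom("NZ"), res_b.atom("OD1").pos
        elif spec.kind == "pi_cation":
            ring = [res_b.atom(n).pos for n in _RING_NAMES]
            mover, target = res_a.atom("NZ"), np.mean(ring, axis=0)
        elif spec.kind == "pi_pi":
            ring_b = [res_b.atom(n).pos for n in _RING_NAMES]
            centroid_b = np.mean(ring_b, axis=0)
            ring_a = [res_a.atom(n) for n in _RING_NAMES]
            centroid_a = np.mean([a.pos for a in ring_a], axis=0)
            shift = (centroid_b - dist * _APPROACH) - centroid_a
            for a in ring_a:
                a.pos = a.pos + shift
            continue
        else:
            raise ConfigError(f"unknown contact kind {spec.kind!r}")
        if mover is None:
            raise ConfigError(
                f"chain A residue {spec.res_a} lacks the functional atom for {spec.kind}"
            )
        mover.pos = target - dist * _APPROACH
    return new_a


def generate_dimer_trajectory(
    chain_template: ChainTemplate | None = None,
    n_frames: int = 50,
    com_start: float = 27.19,
    com_end: float = 23.0,
    planted_contacts: list[ContactSpec] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
    total_time_ns: float = 200.0,
) -> Trajectory:
    """A two-chain approach trajectory with exactly known COM distances.

    The inter-chain center-of-mass distance interpolates linearly (hence
    monotonically) from ``com_start`` to ``com_end`` across frames; planted
    contacts satisfy the structure module's geometric criteria in the final
    frame.  Optional Gaussian ``jitter`` (Angstrom) is added after the exact
    construction.  Defaults mirror the aggregating dimer: approach from
    27.19 A to ~23 A.
    """
    if n_frames < 2:
        raise DomainError("n_frames must be >= 2")
    if com_end <= 0:
        raise DomainError("com_end must be positive")
    if com_start <= com_end:
        raise DomainError("com_start must exceed com_end")
    template = chain_template or ChainTemplate(cys_positions=(4, 12))
    contacts = planted_contacts or []

    names = dict(template.residue_names)
    for spec in contacts:
        name_a, name_b, _ = _CONTACT_DEFAULTS[spec.kind]
        names.setdefault(spec.res_a, name_a)
    template_a = replace(template, residue_names=names)
    names_b = dict(template.residue_names)
    for spec in contacts:
        _, name_b, _ = _CONTACT_DEFAULTS[spec.kind]
        names_b.setdefault(spec.res_b, name_b)
    template_b = replace(template, residue_names=names_b)

    chain_a = build_chain(template_a.sequence(), template.phi, template.psi, "A")
    chain_b0 = build_chain(template_b.sequence(), template.phi, template.psi, "B")
    _prepare_interface(chain_b0, contacts)

    def place_b(com_a: np.ndarray, d: float) -> Chain:
        # chains grow along x; separate them along z so they lie side by side
        com_b_local = _model_com([chain_b0])
        return _translate_chain(chain_b0, com_a + np.array([0.0, 0.0, d]) - com_b_local)

    # fixed-point: planting moves chain A atoms, which moves its COM, which
    # moves the final-frame placement of chain B the contacts refer to
    for _ in range(60):
        com_a = _model_com([chain_a])
        b_final = place_b(com_a, com_end)
        planted = _plant_contacts(chain_a, b_final, contacts)
        delta = float(
            np.max(np.abs(np.concatenate([
                (a.pos - b.pos)
                for ra, rb in zip(chain_a.residues, planted.residues)
                for a, b in zip(ra.atoms, rb.atoms)
            ]))) if contacts else 0.0
        )
        chain_a = planted
        if delta < 1e-12:
            break

    com_a = _model_com([chain_a])
    distances = np.linspace(com_start, com_end, n_frames)
    frames = []
    for d in distances:
        b = place_b(com_a, float(d))
        model = StructureModel([chain_a, b])
        frames.append(model.coords())
    frames = np.stack(frames)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, jitter, size=frames.shape)
    topology = StructureModel([chain_a, place_b(com_a, float(distances[0]))])
    times = np.linspace(0.0, total_time_ns, n_frames)
    return Trajectory(topology=topology, frames=frames, frame_times=times)


def hewl_like_chain(chain_id: str = "A") -> Chain:
    """A synthetic 129-residue HEWL-like chain: ALA backbone with CYS at the
    eight disulphide positions (6, 30, 64, 76, 80, 94, 115, 127).

    This is a *synthetic* stand-in for the 1HEW crystal structure — ideal
    extended geometry, not experimental coordinates.
    """
    template = ChainTemplate(n_residues=HEWL_N_RESIDUES, cys_positions=HEWL_CYS_POSITIONS)
    return build_chain(template.sequence(), template.phi, template.psi, chain_id)


def hewl_like_monomer(bonded_disulphides: bool = True) -> StructureModel:
    """Synthetic HEWL-like monomer; optionally with the four native disulphide
    pairs' SG atoms placed within bonding distance (2.04 A)."""
    chain = hewl_like_chain("A")
    if bonded_disulphides:
        for i, j in HEWL_DISULPHIDES:
            res_i = next(r for r in chain.residues if r.index == i)
            res_j = next(r for r in chain.residues if r.index == j)
            sg_i, sg_j = res_i.atom("SG"), res_j.atom("SG")
            mid = 0.5 * (sg_i.pos + sg_j.pos)
            direction = sg_i.pos - sg_j.pos
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            sg_i.pos = mid + 1.02 * direction
            sg_j.pos = mid - 1.02 * direction
    return StructureModel([chain])


def hewl_like_dimer(separation: float = 30.0) -> StructureModel:
    """Two synthetic HEWL-like chains lying side by side (8 Cys per chain)."""
    a = hewl_like_chain("A")
    b = _translate_chain(hewl_like_chain("B"), np.array([0.0, 0.0, separation]))
    return StructureModel([a, b])
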