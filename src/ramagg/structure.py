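"""Geometric analysis of protein structures and trajectories.

Covers the quantities needed to follow monomer unfolding and dimer contact
formation: backbone RMSD after optimal (Kabsch) superposition, inter-chain
center-of-mass distance, Cys-Cys distance maps (disulphide-forming SG atoms),
Ramachandran-window secondary-structure content, and geometric detection of
non-bonded contacts (hydrogen bonds, salt bridges, pi-cation, pi-pi).

PDB text is parsed with gemmi; multi-MODEL files become trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    CongruenceError,
    DomainError,
    EmptyAssignmentError,
    EmptyStructureError,
    LookupError_,
    StructureParseError,
)

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Ramachandran windows (degrees) used for secondary-structure assignment
ALPHA_PHI = (-100.0, -30.0)
ALPHA_PSI = (-67.0, -7.0)
BETA_PHI = (-180.0, -70.0)
BETA_PSI_1 = (80.0, 180.0)
BETA_PSI_2 = (-180.0, -170.0)
MIN_RUN = 3  # shorter alpha/beta runs are demoted to 'other'


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name when the element column is absent."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in ("SE", "FE", "ZN", "CL", "BR", "MG", "NA"):
        return stripped[:2].upper()
    return stripped[0].upper()


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # Angstrom, shape (3,)
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.mass == 0.0:
            self.mass = ATOMIC_MASS.get(self.element.upper(), 12.011)


@dataclass
class Residue:
    index: int  # PDB residue sequence number (1-based)
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate residue indices in chain {self.chain_id}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class StructureModel:
    """Chains -> residues -> atoms, with coordinates in Angstrom."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError("structure has no chains")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise LookupError_(f"no chain {chain_id!r} in structure")

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    def iter_atoms(self) -> Iterable[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def coords(self) -> np.ndarray:
        return np.array([a.pos for _, _, a in self.iter_atoms()], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise CongruenceError(
                f"coordinate array shape {coords.shape} does not match {self.n_atoms} atoms"
            )
        k = 0
        new_chains = []
        for c in self.chains:
            new_res = []
            for r in c.residues:
                new_atoms = []
                for a in r.atoms:
                    new_atoms.append(Atom(a.name, a.element, coords[k].copy(), a.mass))
                    k += 1
                new_res.append(Residue(r.index, r.name, new_atoms))
            new_chains.append(Chain(c.chain_id, new_res))
        return StructureModel(new_chains)


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over one topology."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise CongruenceError("every frame needs one coordinate triple per topology atom")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # hydrogen_bond | salt_bridge | pi_cation | pi_pi
    partner_a: tuple[str, int, str]  # (chain, residue index, residue name)
    partner_b: tuple[str, int, str]
    distance: float  # Angstrom
    angle: float = float("nan")  # degrees, where applicable


@dataclass
class InteractionCriteria:
    """Geometric cutoffs for non-bonded contact detection (Angstrom/degrees)."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    salt_bridge_distance: float = 4.0
    pi_cation_distance: float = 6.0
    pi_pi_distance: float = 5.5
    his_charged: bool = False  # His+ counts as cationic (pH ~7 context)


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise StructureParseError("ATOM record shorter than coordinate fields", lineno)
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise StructureParseError("malformed coordinate columns", lineno)


def _convert_model(model: gemmi.Model, include_hetero: bool) -> StructureModel:
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            if res.name == "HOH":
                continue
            if not include_hetero and res.het_flag == "H":
                continue
            atoms = []
            for at in res:
                el = at.element.name.upper() if at.element and at.element.name else ""
                if el in ("", "X"):
                    el = element_from_name(at.name)
                atoms.append(Atom(at.name, el, np.array([at.pos.x, at.pos.y, at.pos.z])))
            if atoms:
                residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise EmptyStructureError("no ATOM records after filtering")
    return StructureModel(chains)


def read_structure(pdb_text: str, include_hetero: bool = False) -> StructureModel | Trajectory:
    """Parse PDB text; multi-MODEL files yield a Trajectory.

    Waters and (by default) hetero groups are excluded.  Elements are taken
    from columns 77-78 when present, otherwise inferred from the atom name.
    """
    _validate_pdb_lines(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"gemmi could not parse PDB text: {exc}")
    if len(st) == 0:
        raise EmptyStructureError("PDB text contains no models")
    models = [_convert_model(m, include_hetero) for m in st]
    if len(models) == 1:
        return models[0]
    topo = models[0]
    frames = np.stack([m.coords() for m in models])
    return Trajectory(topology=topo, frames=frames)


def read_structure_file(path, include_hetero: bool = False) -> StructureModel | Trajectory:
    with open(path) as fh:
        return read_structure(fh.read(), include_hetero=include_hetero)


def _atom_line(serial: int, a: Atom, r: Residue, chain_id: str) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {r.name:<3s} {chain_id:1s}{r.index:4d}    "
        f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(obj: StructureModel | Trajectory, sink: TextIO) -> None:
    """Write a structure (or multi-MODEL trajectory) as fixed-column PDB text."""

    def write_model(model: StructureModel) -> None:
        serial = 0
        for c in model.chains:
            for r in c.residues:
                for a in r.atoms:
                    serial += 1
                    sink.write(_atom_line(serial, a, r, c.chain_id) + "\n")
            sink.write("TER\n")

    if isinstance(obj, Trajectory):
        for i in range(obj.n_frames):
            sink.write(f"MODEL     {i + 1:4d}\n")
            write_model(obj.frame(i))
            sink.write("ENDMDL\n")
    else:
        write_model(obj)
    sink.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and distances


def _backbone_coords(model: StructureModel, selection: tuple[str, ...]) -> np.ndarray:
    pts = []
    for _, r, a in model.iter_atoms():
        if a.name in selection:
            pts.append(a.pos)
    return np.asarray(pts, dtype=float)


def backbone_rmsd(
    frame: StructureModel,
    reference: StructureModel,
    selection: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """RMSD (Angstrom) of the backbone selection after optimal superposition.

    Both structures are centered and the least-squares (Kabsch) rotation is
    applied before computing the root-mean-square deviation, so the result is
    invariant to any rigid transform of either argument.
    """
    a = _backbone_coords(frame, selection)
    b = _backbone_coords(reference, selection)
    if a.shape != b.shape:
        raise CongruenceError(
            f"selection mismatch: {a.shape[0]} vs {b.shape[0]} atoms"
        )
    if a.shape[0] < 3:
        raise DomainError("need at least 3 atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))


def _chain_com(chain: Chain, mass_weighted: bool) -> np.ndarray:
    pts = np.array([a.pos for r in chain.residues for a in r.atoms])
    if pts.size == 0:
        raise LookupError_(f"chain {chain.chain_id!r} has no atoms")
    if mass_weighted:
        m = np.array([a.mass for r in chain.residues for a in r.atoms])
        return (pts * m[:, None]).sum(axis=0) / m.sum()
    return pts.mean(axis=0)


def com_distance(
    frame: StructureModel, chain_a: str, chain_b: str, mass_weighted: bool = True
) -> float:
    """Euclidean distance between the (mass-weighted) centroids of two chains."""
    ca = _chain_com(frame.chain(chain_a), mass_weighted)
    cb = _chain_com(frame.chain(chain_b), mass_weighted)
    return float(np.linalg.norm(ca - cb))


def com_distance_series(
    traj: Trajectory, chain_a: str, chain_b: str, mass_weighted: bool = True
) -> np.ndarray:
    return np.array(
        [com_distance(traj.frame(i), chain_a, chain_b, mass_weighted) for i in range(traj.n_frames)]
    )


def _cys_atoms(chain: Chain, atom_priority: tuple[str, ...]) -> list[tuple[int, Atom]]:
    out = []
    for r in chain.residues:
        if r.name != "CYS":
            continue
        for name in atom_priority:
            a = r.atom(name)
            if a is not None:
                out.append((r.index, a))
                break
    return out


def cys_pair_distances(
    frame: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    atom_priority: tuple[str, ...] = ("SG", "CB"),
) -> tuple[list[int], list[int], np.ndarray]:
    """Inter-chain Cys-Cys distance matrix over disulphide-forming SG atoms.

    Returns (residue indices in chain A, residue indices in chain B, matrix
    of distances in Angstrom).  CB is used for cysteines missing SG.  A chain
    without cysteines yields an empty matrix (with a warning), not an error.
    """
    if chain_a is None or chain_b is None:
        ids = [c.chain_id for c in frame.chains]
        if len(ids) < 2:
            raise LookupError_("inter-chain Cys map needs two chains")
        chain_a, chain_b = ids[0], ids[1]
    cys_a = _cys_atoms(frame.chain(chain_a), atom_priority)
    cys_b = _cys_atoms(frame.chain(chain_b), atom_priority)
    if not cys_a or not cys_b:
        import warnings

        warnings.warn("a chain has no cysteines; Cys-Cys map is empty", stacklevel=2)
        return ([i for i, _ in cys_a], [i for i, _ in cys_b], np.zeros((len(cys_a), len(cys_b))))
    pa = np.array([a.pos for _, a in cys_a])
    pb = np.array([a.pos for _, a in cys_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return ([i for i, _ in cys_a], [i for i, _ in cys_b], d)


def min_cys_pair(
    frame: StructureModel, chain_a: str | None = None, chain_b: str | None = None
) -> tuple[int, int, float]:
    """The closest inter-chain cysteine pair: (res index A, res index B, distance)."""
    ia, ib, d = cys_pair_distances(frame, chain_a, chain_b)
    if d.size == 0:
        raise LookupError_("no cysteine pairs available")
    k = np.unravel_index(np.argmin(d), d.shape)
    return ia[k[0]], ib[k[1]], float(d[k])


def find_disulphides(model: StructureModel, cutoff: float = 2.5) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Cys pairs whose SG atoms lie within ``cutoff`` Angstrom (bonded S-S)."""
    sgs = []
    for c in model.chains:
        for r in c.residues:
            if r.name == "CYS":
                a = r.atom("SG")
                if a is not None:
                    sgs.append((c.chain_id, r.index, a.pos))
    pairs = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if np.linalg.norm(sgs[i][2] - sgs[j][2]) <= cutoff:
                pairs.append(((sgs[i][0], sgs[i][1]), (sgs[j][0], sgs[j][1])))
    return pairs


# ---------------------------------------------------------------------------
# Secondary structure by backbone dihedrals


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _in_window(v: float, lo: float, hi: float) -> bool:
    return lo <= v <= hi


def assign_secondary_structure(
    frame: StructureModel,
) -> tuple[list[tuple[str, int, str]], dict[str, float]]:
    """Per-residue alpha/beta/other labels from phi/psi windows, plus content %.

    A residue is assignable when both phi and psi are computable (complete
    backbone for itself and its neighbours).  Alpha: phi in [-100,-30] and
    psi in [-67,-7]; beta: phi in [-180,-70] and psi in [80,180] or
    [-180,-170].  Runs shorter than 3 residues are demoted to 'other'.
    Percentages are over assignable residues and sum to 100.
    """
    labels: list[tuple[str, int, str]] = []
    for chain in frame.chains:
        res = chain.residues
        chain_labels: list[str | None] = []
        for i, r in enumerate(res):
            phi = psi = None
            n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
            if n is not None and ca is not None and c is not None:
                if i > 0 and res[i - 1].index == r.index - 1:
                    c_prev = res[i - 1].atom("C")
                    if c_prev is not None:
                        phi = dihedral(c_prev.pos, n.pos, ca.pos, c.pos)
                if i + 1 < len(res) and res[i + 1].index == r.index + 1:
                    n_next = res[i + 1].atom("N")
                    if n_next is not None:
                        psi = dihedral(n.pos, ca.pos, c.pos, n_next.pos)
            if phi is None or psi is None:
                chain_labels.append(None)
                continue
            if _in_window(phi, *ALPHA_PHI) and _in_window(psi, *ALPHA_PSI):
                chain_labels.append("alpha")
            elif _in_window(phi, *BETA_PHI) and (
                _in_window(psi, *BETA_PSI_1) or _in_window(psi, *BETA_PSI_2)
            ):
                chain_labels.append("beta")
            else:
                chain_labels.append("other")
        # demote alpha/beta runs shorter than MIN_RUN
        i = 0
        while i < len(chain_labels):
            lab = chain_labels[i]
            j = i
            while j < len(chain_labels) and chain_labels[j] == lab:
                j += 1
            if lab in ("alpha", "beta") and (j - i) < MIN_RUN:
                for k in range(i, j):
                    chain_labels[k] = "other"
            i = j
        for r, lab in zip(res, chain_labels):
            if lab is not None:
                labels.append((chain.chain_id, r.index, lab))
    if not labels:
        raise EmptyAssignmentError("no residues with computable phi/psi")
    n_tot = len(labels)
    content = {
        key: 100.0 * sum(1 for _, _, lab in labels if lab == key) / n_tot
        for key in ("alpha", "beta", "other")
    }
    return labels, content


# ---------------------------------------------------------------------------
# Non-bonded interactions

_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "ASN": ("ND2",),
    "GLN": ("NE2",), "TRP": ("NE1",), "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
_CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _collect(frame: StructureModel):
    """Index donors/acceptors/cations/anions/rings once per frame."""
    import warnings

    donors, acceptors, cations, anions, rings, hydrogens = [], [], [], [], [], []
    for c in frame.chains:
        for r in c.residues:
            tag = (c.chain_id, r.index, r.name)
            if r.name not in _STANDARD_RESIDUES:
                warnings.warn(f"unknown residue {r.name}; skipped", stacklevel=3)
                continue
            for a in r.atoms:
                if a.element == "H":
                    hydrogens.append((tag, a))
            n = r.atom("N")
            if n is not None and r.name != "PRO":
                donors.append((tag, n))
            o = r.atom("O")
            if o is not None:
                acceptors.append((tag, o))
            oxt = r.atom("OXT")
            if oxt is not None:
                acceptors.append((tag, oxt))
                anions.append((tag, oxt))
            for name in _SIDECHAIN_DONORS.get(r.name, ()):
                a = r.atom(name)
                if a is not None:
                    donors.append((tag, a))
            for name in _SIDECHAIN_ACCEPTORS.get(r.name, ()):
                a = r.atom(name)
                if a is not None:
                    acceptors.append((tag, a))
            for name in _CATION_ATOMS.get(r.name, ()):
                a = r.atom(name)
                if a is not None:
                    cations.append((tag, a))
            for name in _ANION_ATOMS.get(r.name, ()):
                a = r.atom(name)
                if a is not None:
                    anions.append((tag, a))
            ring_names = _RING_ATOMS.get(r.name)
            if ring_names:
                pts = [r.atom(nm) for nm in ring_names]
                if all(p is not None for p in pts):
                    rings.append((tag, np.mean([p.pos for p in pts], axis=0)))
    return donors, acceptors, cations, anions, rings, hydrogens


def _cross_chain(tag_a, tag_b, mode: str) -> bool:
    if tag_a[:2] == tag_b[:2]:
        return False  # same residue never interacts with itself
    if mode == "inter_chain":
        return tag_a[0] != tag_b[0]
    # intra mode: skip sequence-adjacent residues on the same chain
    if tag_a[0] == tag_b[0] and abs(tag_a[1] - tag_b[1]) <= 1:
        return False
    return True


def detect_interactions(
    frame: StructureModel,
    mode: str = "inter_chain",
    criteria: InteractionCriteria | None = None,
) -> tuple[list[InteractionRecord], dict[str, int]]:
    """Detect hydrogen bonds, salt bridges, pi-cation and pi-pi contacts.

    Purely geometric: hydrogen bonds by donor-acceptor heavy-atom distance
    (plus D-H...A angle when hydrogens are present), salt bridges by cationic
    N to carboxylate O distance, pi interactions by ring-centroid distances.
    A pair satisfying the salt-bridge criterion is recorded as salt_bridge
    only (kind precedence), so counts are disjoint by construction.
    """
    if mode not in ("inter_chain", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    crit = criteria or InteractionCriteria()
    donors, acceptors, cations, anions, rings, hydrogens = _collect(frame)
    if crit.his_charged:
        for c in frame.chains:
            for r in c.residues:
                if r.name == "HIS":
                    for name in ("ND1", "NE2"):
                        a = r.atom(name)
                        if a is not None:
                            cations.append(((c.chain_id, r.index, r.name), a))

    records: list[InteractionRecord] = []
    salt_pairs: set[tuple] = set()

    for tag_c, cat in cations:
        for tag_an, an in anions:
            if not _cross_chain(tag_c, tag_an, mode):
                continue
            d = float(np.linalg.norm(cat.pos - an.pos))
            if d <= crit.salt_bridge_distance:
                key = (tag_c[:2], tag_an[:2])
                if key in salt_pairs or (key[1], key[0]) in salt_pairs:
                    continue
                salt_pairs.add(key)
                records.append(InteractionRecord("salt_bridge", tag_c, tag_an, d))

    hbond_pairs: set[tuple] = set()
    for tag_d, don in donors:
        don_h = [a for tag, a in hydrogens if tag[:2] == tag_d[:2]
                 and np.linalg.norm(a.pos - don.pos) < 1.3]
        for tag_a, acc in acceptors:
            if not _cross_chain(tag_d, tag_a, mode):
                continue
            if (tag_d[:2], tag_a[:2]) in salt_pairs or (tag_a[:2], tag_d[:2]) in salt_pairs:
                continue
            d = float(np.linalg.norm(don.pos - acc.pos))
            if d > crit.hbond_distance:
                continue
            angle = float("nan")
            if don_h:
                angles = []
                for h in don_h:
                    v1 = don.pos - h.pos
                    v2 = acc.pos - h.pos
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                angle = max(angles)
                if angle < crit.hbond_angle:
                    continue
            key = frozenset((tag_d[:2] + (don.name,), tag_a[:2] + (acc.name,)))
            if key in hbond_pairs:
                continue
            hbond_pairs.add(key)
            records.append(InteractionRecord("hydrogen_bond", tag_d, tag_a, d, angle))

    for tag_c, cat in cations:
        for tag_r, centroid in rings:
            if not _cross_chain(tag_c, tag_r, mode):
                continue
            d = float(np.linalg.norm(cat.pos - centroid))
            if d <= crit.pi_cation_distance:
                records.append(InteractionRecord("pi_cation", tag_c, tag_r, d))

    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            tag_i, ci = rings[i]
            tag_j, cj = rings[j]
            if not _cross_chain(tag_i, tag_j, mode):
                continue
            d = float(np.linalg.norm(ci - cj))
            if d <= crit.pi_pi_distance:
                records.append(InteractionRecord("pi_pi", tag_i, tag_j, d))

    counts = {k: 0 for k in ("hydrogen_bond", "salt_bridge", "pi_cation", "pi_pi")}
    for rec in records:
        counts[rec.kind] += 1
    return records, counts


def average_interaction_counts(
    traj: Trajectory,
    frame_indices: Iterable[int] | None = None,
    mode: str = "inter_chain",
    criteria: InteractionCriteria | None = None,
) -> dict[str, float]:
    """Mean per-kind interaction counts over a window of trajectory frames."""
    idx = list(frame_indices) if frame_indices is not None else list(range(traj.n_frames))
    if not idx:
        raise DomainError("empty frame window")
    totals = {k: 0.0 for k in ("hydrogen_bond", "salt_bridge", "pi_cation", "pi_pi")}
    for i in idx:
        _, counts = detect_interactions(traj.frame(i), mode=mode, criteria=criteria)
        for k, v in counts.items():
            totals[k] += v
    return {k: v / len(idx) for k, v in totals.items()}
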