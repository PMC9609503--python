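"""Construction of idealized peptide backbones from internal coordinates.

Backbones are grown atom-by-atom with the standard NeRF (natural extension
reference frame) placement from ideal bond lengths and angles, at caller-
specified (phi, psi) dihedrals.  Side chains carry only the functional atoms
the geometric analyses need (CB, OG, SG, NZ, carboxylate O's, aromatic ring);
their conformation is a plausible extended rotamer, not an energy minimum.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Chain, Residue, StructureModel

# ideal backbone geometry (Angstrom / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.5
OMEGA = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral_angle: float) -> np.ndarray:
    """Position atom d with |c-d|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=dihedral."""
    ang = np.radians(angle)
    dih = np.radians(dihedral_angle)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(dih), bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _side_chain_atoms(resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> list[Atom]:
    """CB plus the functional atoms relevant to contact detection."""
    if resname == "GLY":
        return []
    cb = place_atom(n, c, ca, 1.53, 110.1, 122.6)
    out = [Atom("CB", "C", cb)]
    u = _unit(cb - ca)  # radial growth direction for the extended rotamer
    if resname == "SER":
        out.append(Atom("OG", "O", cb + 1.41 * u))
    elif resname == "CYS":
        out.append(Atom("SG", "S", cb + 1.81 * u))
    elif resname == "LYS":
        out.append(Atom("NZ", "N", cb + 3.9 * u))
    elif resname == "ASP":
        cg = cb + 1.52 * u
        perp = _unit(np.cross(u, c - ca))
        out.append(Atom("CG", "C", cg))
        out.append(Atom("OD1", "O", cg + 1.25 * _unit(u + 0.7 * perp)))
        out.append(Atom("OD2", "O", cg + 1.25 * _unit(u - 0.7 * perp)))
    elif resname == "GLU":
        cd = cb + 2.8 * u
        perp = _unit(np.cross(u, c - ca))
        out.append(Atom("OE1", "O", cd + 1.25 * _unit(u + 0.7 * perp)))
        out.append(Atom("OE2", "O", cd + 1.25 * _unit(u - 0.7 * perp)))
    elif resname in ("PHE", "TYR"):
        cg = cb + 1.51 * u
        perp = _unit(np.cross(u, c - ca))
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        center = cg + 1.39 * u
        ring = []
        for k, name in enumerate(ring_names):
            theta = np.pi + k * np.pi / 3.0  # CG sits opposite the growth direction
            pos = center + 1.39 * (np.cos(theta) * u + np.sin(theta) * perp)
            ring.append(Atom(name, "C", pos))
        out.extend(ring)
        if resname == "TYR":
            out.append(Atom("OH", "O", center + 2.75 * u))
    return out


def build_chain(
    sequence: list[str],
    phi: float | list[float],
    psi: float | list[float],
    chain_id: str = "A",
    start_index: int = 1,
) -> Chain:
    """Build an ideal-geometry chain at the given backbone dihedrals.

    ``phi``/``psi`` may be scalars (uniform conformation) or per-residue
    lists.  phi of the first residue and psi of the last only affect CB/O
    placement.
    """
    n_res = len(sequence)
    phis = [float(phi)] * n_res if np.isscalar(phi) else [float(v) for v in phi]
    psis = [float(psi)] * n_res if np.isscalar(psi) else [float(v) for v in psi]
    if len(phis) != n_res or len(psis) != n_res:
        raise ValueError("phi/psi lists must match the sequence length")

    bb: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([B_N_CA, 0.0, 0.0])
            ang = np.radians(180.0 - A_N_CA_C)
            c = ca + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            n_prev, ca_prev, c_prev = bb[i - 1]
            n = place_atom(n_prev, ca_prev, c_prev, B_C_N, A_CA_C_N, psis[i - 1])
            ca = place_atom(ca_prev, c_prev, n, B_N_CA, A_C_N_CA, OMEGA)
            c = place_atom(c_prev, n, ca, B_CA_C, A_N_CA_C, phis[i])
        bb.append((n, ca, c))

    residues = []
    for i, resname in enumerate(sequence):
        n, ca, c = bb[i]
        atoms = [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c)]
        o = place_atom(n, ca, c, B_C_O, A_CA_C_O, psis[i] + 180.0)
        atoms.append(Atom("O", "O", o))
        atoms.extend(_side_chain_atoms(resname, n, ca, c))
        residues.append(Residue(start_index + i, resname, atoms))
    return Chain(chain_id, residues)


def build_model(sequence: list[str], phi: float | list[float], psi: float | list[float],
                chain_id: str = "A") -> StructureModel:
    return StructureModel([build_chain(sequence, phi, psi, chain_id)])
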