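"""Backbone structure handling: PDB reading, proton reconstruction, and an
ideal alpha-helix builder.

The GAF stage needs, per residue, the backbone atoms N, H, CA, HA, C, O in a
common coordinate frame.  Experimental structures often lack protons; amide H
and HA are rebuilt from standard geometry and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .datamodel import FormatError

# standard backbone geometry (Angstrom, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
BOND_N_H = 1.02
BOND_CA_HA = 1.10
BOND_CA_CB = 1.53
ANG_C_N_CA = 121.7
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_CA_C_O = 120.5
ANG_C_N_H = 119.0

ALPHA_PHI = -57.0
ALPHA_PSI = -47.0


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates indexed by residue number."""

    residues: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    residue_names: dict[int, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def residue_numbers(self) -> list[int]:
        return sorted(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom D from internal coordinates relative to chain A-B-C.

    ``bond`` = |C-D|, ``angle_deg`` = angle B-C-D, ``torsion_deg`` = dihedral
    A-B-C-D (standard NeRF construction).
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _reconstruct_amide_h(prev_c: np.ndarray, n: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Amide proton on the C(i-1)/N/CA bisector, trans to both heavy neighbours."""
    u1 = (prev_c - n) / np.linalg.norm(prev_c - n)
    u2 = (ca - n) / np.linalg.norm(ca - n)
    d = -(u1 + u2)
    return n + BOND_N_H * d / np.linalg.norm(d)


def _tetrahedral_pair(ca: np.ndarray, n: np.ndarray, c: np.ndarray):
    """Unit directions from CA for (HA, CB) completing an L-configured tetrahedron."""
    u_n = (n - ca) / np.linalg.norm(n - ca)
    u_c = (c - ca) / np.linalg.norm(c - ca)
    n1 = u_n + u_c
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(u_n, u_c)
    n2 /= np.linalg.norm(n2)
    # choose in-plane/out-of-plane mix for ~109.5 deg to both N and C
    cos_t = -np.cos(np.deg2rad(109.5)) / max(abs(np.dot(u_n, n1)), 1e-9)
    cos_t = min(cos_t, 1.0)
    sin_t = np.sqrt(1 - cos_t**2)
    ha_dir = -n1 * cos_t - n2 * sin_t  # det[uN,uC,uHA] < 0 for L-residues
    cb_dir = -n1 * cos_t + n2 * sin_t
    return ha_dir, cb_dir


def _reconstruct_ha(ca: np.ndarray, n: np.ndarray, c: np.ndarray,
                    cb: np.ndarray | None) -> np.ndarray:
    if cb is not None:
        u = [(x - ca) / np.linalg.norm(x - ca) for x in (n, c, cb)]
        d = -sum(u)
        return ca + BOND_CA_HA * d / np.linalg.norm(d)
    ha_dir, _ = _tetrahedral_pair(ca, n, c)
    return ca + BOND_CA_HA * ha_dir


def read_structure(path) -> BackboneStructure:
    """Read a single-model PDB into per-residue backbone coordinates.

    Residues missing any of N/CA/C are excluded with a warning; missing
    amide H or HA are reconstructed geometrically and flagged.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}")
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no models/atoms found")
    model = models[0]
    out = BackboneStructure()
    raw: dict[int, dict[str, np.ndarray]] = {}
    for chain in model:
        for res in chain:
            het, num, _ = res.id
            if het.strip():
                continue
            atoms = {a.get_name(): a.get_coord().astype(float) for a in res}
            raw[num] = atoms
            out.residue_names[num] = res.get_resname()
    if not raw:
        raise FormatError(f"{path}: no protein residues found")
    for num in sorted(raw):
        atoms = raw[num]
        if not all(k in atoms for k in ("N", "CA", "C")):
            warnings.warn(f"residue {num}: missing backbone atom, excluded", stacklevel=2)
            out.residue_names.pop(num, None)
            continue
        keep = {k: atoms[k] for k in ("N", "CA", "C", "O", "CB", "H", "HA") if k in atoms}
        if "H" not in keep and "HN" in atoms:
            keep["H"] = atoms["HN"]
        if "HA" not in keep and num != min(raw):
            pass
        out.residues[num] = keep
    nums = sorted(out.residues)
    for num in nums:
        atoms = out.residues[num]
        if "H" not in atoms and (num - 1) in out.residues:
            prev = out.residues[num - 1]
            if "C" in prev:
                atoms["H"] = _reconstruct_amide_h(prev["C"], atoms["N"], atoms["CA"])
                out.flags.append(f"H rebuilt for residue {num}")
        if "HA" not in atoms:
            atoms["HA"] = _reconstruct_ha(
                atoms["CA"], atoms["N"], atoms["C"], atoms.get("CB")
            )
            out.flags.append(f"HA rebuilt for residue {num}")
    return out


def build_ideal_helix(
    n_res: int,
    phi: float = ALPHA_PHI,
    psi: float = ALPHA_PSI,
    omega: float = 180.0,
    residue_name: str = "ALA",
    with_protons: bool = True,
    with_cb: bool = True,
) -> BackboneStructure:
    """Build an ideal alpha-helix (phi=-57, psi=-47, standard geometry).

    Residues are numbered from 1.  Protons (H, HA) and CB are placed from
    standard internal coordinates; the first residue has no amide H partner
    geometry issue since its H uses the generic bisector once residue 0's C
    does not exist, so it is placed trans to CA-C instead.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    st = BackboneStructure()
    # seed first three atoms
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANG_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords = {1: {"N": n0, "CA": ca0, "C": c0}}
    for i in range(2, n_res + 1):
        prev = coords[i - 1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANG_CA_C_N, psi)
        ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANG_C_N_CA, omega)
        c = place_atom(prev["C"], n, ca, BOND_CA_C, ANG_N_CA_C, phi)
        coords[i] = {"N": n, "CA": ca, "C": c}
    for i in range(1, n_res + 1):
        atoms = coords[i]
        if i < n_res:
            nxt = coords[i + 1]["N"]
            atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                    BOND_C_O, ANG_CA_C_O, psi - 180.0)
        else:
            atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                    BOND_C_O, ANG_CA_C_O, psi - 180.0)
        if with_protons:
            if i > 1:
                atoms["H"] = _reconstruct_amide_h(coords[i - 1]["C"], atoms["N"], atoms["CA"])
            else:
                u = (atoms["CA"] - atoms["N"]) / np.linalg.norm(atoms["CA"] - atoms["N"])
                atoms["H"] = atoms["N"] - BOND_N_H * u  # placeholder for chain start
            ha_dir, cb_dir = _tetrahedral_pair(atoms["CA"], atoms["N"], atoms["C"])
            atoms["HA"] = atoms["CA"] + BOND_CA_HA * ha_dir
            if with_cb:
                atoms["CB"] = atoms["CA"] + BOND_CA_CB * cb_dir
        st.residues[i] = atoms
        st.residue_names[i] = residue_name
    return st


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{resseq:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)

_ATOM_ORDER = ["N", "H", "CA", "HA", "CB", "C", "O"]


def write_pdb(structure: BackboneStructure, path, chain: str = "A") -> None:
    """Write backbone coordinates as a single-model PDB file."""
    serial = 1
    with open(path, "w") as fh:
        for num in structure.residue_numbers():
            atoms = structure.residues[num]
            resname = structure.residue_names.get(num, "ALA")
            for name in _ATOM_ORDER + sorted(set(atoms) - set(_ATOM_ORDER)):
                if name not in atoms:
                    continue
                x, y, z = atoms[name]
                fh.write(_PDB_ATOM.format(
                    serial=serial, name=name, alt=" ", res=resname, chain=chain,
                    resseq=num, icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0,
                    elem=name[0],
                ))
                serial += 1
        fh.write("END\n")


def helix_axis(structure: BackboneStructure, residues=None) -> np.ndarray:
    """Principal axis of the CA trace (unit vector, oriented N->C terminus)."""
    nums = residues if residues is not None else structure.residue_numbers()
    ca = np.array([structure.residues[n]["CA"] for n in nums])
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)
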