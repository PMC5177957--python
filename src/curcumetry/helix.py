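"""Peptide helices, heptad-repeat scanning, and ligand superimposition.

The Abeta(25-35) fragment (GSNKGAIIGLM, residues 25-35) in its helical form
presents an i, i+4, i+7 face (Asn27, Ile31, Leu34) analogous to the "a"/"d"
positions of a coiled-coil heptad repeat.  This module builds ideal
alpha-helices (phi = -57, psi = -47 deg) from sequence, locates heptad
triples, computes side-chain centroids, and rigidly superimposes a ligand's
three pharmacophore centroids (aryl ring X, central bridge moiety, aryl ring
Y) onto a triple to produce the starting pose for docking.

PDB input/output goes through biotite; ideal side-chain geometry comes from
the Chemical Component Dictionary shipped with biotite (the CCD idealized
coordinates serve as the default rotamer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bsinfo
import biotite.structure.io.pdb as bpdb

from .conformers import Conformer
from .ligand import LigandTopology

__all__ = [
    "Residue",
    "PeptideStructure",
    "HeptadMatch",
    "read_pdb",
    "write_pdb",
    "build_ideal_helix",
    "sidechain_centroid",
    "heptad_scan",
    "superimpose_ligand",
    "kabsch",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

HYDROPHOBIC = set("AVLIMFWY")

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Residue:
    name: str                       # three-letter code
    number: int                     # author residue number (1-based)
    chain: str
    atoms: dict[str, np.ndarray]    # atom name -> xyz (A)
    elements: dict[str, str] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def heavy_sidechain_atoms(self) -> list[np.ndarray]:
        return [xyz for name, xyz in self.atoms.items()
                if name not in _BACKBONE
                and not self.elements.get(name, name[0]).startswith("H")]


@dataclass
class PeptideStructure:
    residues: list[Residue]
    source: str                     # "pdb_file" or "ideal_helix"

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def backbone_complete(self) -> bool:
        return all({"N", "CA", "C", "O"} <= set(r.atoms)
                   for r in self.residues)

    def all_coordinates(self) -> np.ndarray:
        return np.vstack([xyz for r in self.residues
                          for xyz in r.atoms.values()])

    def heavy_coordinates(self) -> np.ndarray:
        out = []
        for r in self.residues:
            for name, xyz in r.atoms.items():
                if not r.elements.get(name, name[0]).startswith("H"):
                    out.append(xyz)
        return np.vstack(out)

    def to_atom_array(self) -> bst.AtomArray:
        n = sum(len(r.atoms) for r in self.residues)
        arr = bst.AtomArray(n)
        k = 0
        for r in self.residues:
            for name, xyz in r.atoms.items():
                arr.coord[k] = xyz
                arr.atom_name[k] = name
                arr.res_name[k] = r.name
                arr.res_id[k] = r.number
                arr.chain_id[k] = r.chain
                arr.element[k] = r.elements.get(name, name[0])
                arr.hetero[k] = False
                k += 1
        return arr


@dataclass
class HeptadMatch:
    """An (i, i+4, i+7) triple with side-chain centroid geometry."""

    residue_numbers: tuple[int, int, int]
    residue_names: tuple[str, str, str]
    centroids: np.ndarray                 # (3, 3): rows i, i+4, i+7
    distances: dict[str, float]           # pairwise centroid distances, A
    fit_rmsd: float | None = None

    def __post_init__(self) -> None:
        i, j, k = self.residue_numbers
        if (j - i, k - i) != (4, 7):
            raise ValueError("heptad spacing must be (0, +4, +7)")


def _structure_from_atom_array(arr: bst.AtomArray,
                               source: str) -> PeptideStructure:
    residues: list[Residue] = []
    for start in bst.get_residue_starts(arr):
        mask = (arr.res_id == arr.res_id[start]) \
            & (arr.chain_id == arr.chain_id[start])
        sub = arr[mask]
        atoms = {str(n): np.array(c, dtype=float)
                 for n, c in zip(sub.atom_name, sub.coord)}
        elements = {str(n): str(e) for n, e in zip(sub.atom_name,
                                                   sub.element)}
        residues.append(Residue(name=str(arr.res_name[start]),
                                number=int(arr.res_id[start]),
                                chain=str(arr.chain_id[start]),
                                atoms=atoms, elements=elements))
    return PeptideStructure(residues=residues, source=source)


def read_pdb(path: str, chain: str | None = None,
             res_range: tuple[int, int] | None = None) -> PeptideStructure:
    """Load a peptide from PDB, keeping highest-occupancy altlocs.

    Author (1-based) residue numbering is preserved.  Requesting an absent
    chain or an empty residue range raises ``ValueError``.
    """
    pdb_file = bpdb.PDBFile.read(path)
    arr = pdb_file.get_structure(model=1, altloc="occupancy")
    arr = arr[bst.filter_amino_acids(arr)]
    if chain is not None:
        if chain not in set(arr.chain_id):
            raise ValueError(f"chain {chain!r} not present "
                             f"(have {sorted(set(arr.chain_id))})")
        arr = arr[arr.chain_id == chain]
    if res_range is not None:
        lo, hi = res_range
        arr = arr[(arr.res_id >= lo) & (arr.res_id <= hi)]
        if arr.array_length() == 0:
            raise ValueError(f"no residues in range {lo}-{hi}")
    if arr.array_length() == 0:
        raise ValueError("no amino-acid atoms found")
    return _structure_from_atom_array(arr, source="pdb_file")


def write_pdb(peptide: PeptideStructure, path: str) -> None:
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(peptide.to_atom_array())
    pdb_file.write(path)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d.

    Returns d with |c-d| = bond, angle(b,c,d) = angle_deg and dihedral
    (a,b,c,d) = torsion_deg.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal backbone geometry (Engh-Huber-like)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}


def build_ideal_helix(sequence: str, phi: float = -57.0, psi: float = -47.0,
                      start_resnum: int = 1,
                      chain: str = "A") -> PeptideStructure:
    """Ideal alpha-helix with CCD idealized side chains as default rotamers.

    Interior residues of the construction satisfy the helical backbone
    hydrogen bond O(i)...N(i+4) < 3.5 A.
    """
    sequence = sequence.strip().upper()
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
    n_res = len(sequence)
    omega = 180.0

    bb_n = [np.array([0.0, 0.0, 0.0])]
    bb_ca = [np.array([_B["N-CA"], 0.0, 0.0])]
    c0 = bb_ca[0] + _B["CA-C"] * np.array([
        -math.cos(math.radians(_A["N-CA-C"])),
        math.sin(math.radians(_A["N-CA-C"])), 0.0])
    bb_c = [c0]
    for _ in range(1, n_res):
        n_next = place_atom(bb_n[-1], bb_ca[-1], bb_c[-1],
                            _B["C-N"], _A["CA-C-N"], psi)
        ca_next = place_atom(bb_ca[-1], bb_c[-1], n_next,
                             _B["N-CA"], _A["C-N-CA"], omega)
        c_next = place_atom(bb_c[-1], n_next, ca_next,
                            _B["CA-C"], _A["N-CA-C"], phi)
        bb_n.append(n_next)
        bb_ca.append(ca_next)
        bb_c.append(c_next)

    residues: list[Residue] = []
    for i, letter in enumerate(sequence):
        res3 = ONE_TO_THREE[letter]
        if i + 1 < n_res:  # carbonyl O in the peptide plane
            o = place_atom(bb_n[i + 1], bb_ca[i], bb_c[i],
                           _B["C-O"], _A["CA-C-O"], 180.0)
        else:
            o = place_atom(bb_n[i], bb_ca[i], bb_c[i],
                           _B["C-O"], _A["CA-C-O"], psi - 180.0)
        atoms = {"N": bb_n[i], "CA": bb_ca[i], "C": bb_c[i], "O": o}
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        if i > 0 and res3 != "PRO":  # amide H trans to the carbonyl O
            prev_o = residues[i - 1].atoms["O"]
            atoms["H"] = place_atom(prev_o, bb_c[i - 1], bb_n[i],
                                    1.01, 119.0, 180.0)
            elements["H"] = "H"

        template = bsinfo.residue(res3)
        keep = [k for k in range(template.array_length())
                if template.atom_name[k] not in
                ("N", "CA", "C", "O", "OXT", "HXT", "H", "H2", "H3")]
        if keep:
            src = np.vstack([template.coord[template.atom_name == nm][0]
                             for nm in ("N", "CA", "C")])
            dst = np.vstack([bb_n[i], bb_ca[i], bb_c[i]])
            rot, trans = kabsch(src, dst)
            for k in keep:
                name = str(template.atom_name[k])
                atoms[name] = template.coord[k] @ rot.T + trans
                elements[name] = str(template.element[k])
        residues.append(Residue(name=res3, number=start_resnum + i,
                                chain=chain, atoms=atoms, elements=elements))
    return PeptideStructure(residues=residues, source="ideal_helix")


def sidechain_centroid(residue: Residue) -> np.ndarray:
    """Unweighted mean of the side-chain heavy atoms (Cbeta outward)."""
    heavy = residue.heavy_sidechain_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.name}{residue.number} has no "
                         "side-chain heavy atoms")
    return np.mean(heavy, axis=0)


def heptad_scan(peptide: PeptideStructure) -> list[HeptadMatch]:
    """All (i, i+4, i+7) triples compatible with the heptad consensus.

    Each of the three "a"/"d"-type positions must be hydrophobic
    (A, V, L, I, M, F, W, Y), except that one may be an asparagine.  Returns
    an empty list when nothing matches (fewer than 8 residues included).
    """
    matches: list[HeptadMatch] = []
    res = peptide.residues
    for i in range(len(res) - 7):
        triple = (res[i], res[i + 4], res[i + 7])
        letters = [r.one_letter for r in triple]
        n_asn = sum(1 for x in letters if x == "N")
        if n_asn > 1:
            continue
        if any(x not in HYDROPHOBIC and x != "N" for x in letters):
            continue
        try:
            cents = np.vstack([sidechain_centroid(r) for r in triple])
        except ValueError:
            continue
        dist = {
            "i_i4": float(np.linalg.norm(cents[0] - cents[1])),
            "i_i7": float(np.linalg.norm(cents[0] - cents[2])),
            "i4_i7": float(np.linalg.norm(cents[1] - cents[2])),
        }
        matches.append(HeptadMatch(
            residue_numbers=tuple(r.number for r in triple),
            residue_names=tuple(r.name for r in triple),
            centroids=cents, distances=dist))
    return matches


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (proper rotation only): src -> dst.

    Returns (R, t) with ``x @ R.T + t`` mapping src onto dst.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cd - cs @ rot.T
    return rot, trans


def _ligand_pharmacophore_points(conformer: Conformer,
                                 top: LigandTopology) -> np.ndarray:
    coords = conformer.coordinates

    def heavy_centroid(idx):
        idx = [a for a in idx if top.mol.GetAtomWithIdx(a).GetAtomicNum() > 1]
        return coords[idx].mean(axis=0)

    return np.vstack([
        heavy_centroid(top.ring_atoms("X")),
        heavy_centroid(top.bridge_atoms()),
        heavy_centroid(top.ring_atoms("Y")),
    ])


def superimpose_ligand(conformer: Conformer, top: LigandTopology,
                       match: HeptadMatch) -> tuple[Conformer, float]:
    """Rigid fit of ligand centroids (X, bridge, Y) onto (i, i+4, i+7).

    Proper rotations only (no reflection); all intra-ligand distances are
    preserved.  Returns the posed conformer and the three-point fit RMSD;
    the RMSD is also stored on the match.  Degenerate (collinear) target
    triples raise ``ValueError``.
    """
    targets = match.centroids
    v1, v2 = targets[1] - targets[0], targets[2] - targets[0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
        raise ValueError("collinear heptad centroids; cannot superimpose")
    pts = _ligand_pharmacophore_points(conformer, top)
    rot, trans = kabsch(pts, targets)
    new_coords = conformer.coordinates @ rot.T + trans
    fitted = pts @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - targets) ** 2, axis=1))))
    posed = Conformer(
        coordinates=new_coords, energy=conformer.energy,
        torsions=dict(conformer.torsions), rel_energy=conformer.rel_energy,
        d1=conformer.d1, family=conformer.family,
        subfamily=conformer.subfamily, converged=conformer.converged,
        cycle_index=conformer.cycle_index)
    match.fit_rmsd = rmsd
    return posed, rmsd
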