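"""Curcuminoid ligand topologies and the molecular-mechanics energy model.

A :class:`LigandTopology` wraps an RDKit molecule (explicit hydrogens, one 3D
conformer) together with the torsional bookkeeping the conformational search
and the docking stage need:

* rotatable torsions (labelled ``tau1``, ``tau2``, ... from aryl ring X toward
  ring Y along the bridge),
* acyclic C=C double-bond torsions, restrained to 180 deg (k = 100 kcal/mol)
  during sampling so that high-temperature annealing cannot isomerize them,
* conjugated acyclic sp2-sp2 C-C single bonds of the enone bridge, held
  planar by a twofold restraint (see :class:`EnergyModel`).

Intramolecular energies are MMFF94 energies (RDKit implementation) with a
distance-dependent dielectric: the ``polar`` mode uses eps = 80*r (aqueous
screening), ``apolar`` uses a constant eps = 1 (membrane-like interior),
``docking`` uses eps = 30*r and ``scoring`` eps = 2*r.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

__all__ = [
    "TEMPLATES",
    "AtomRecord",
    "LigandTopology",
    "IonizationInput",
    "EnergyModel",
    "DIELECTRIC_MODES",
    "build_ligand",
    "ionized_fraction",
    "assign_energy_model",
]


# Shipped curcuminoid templates.  SMILES encode the tautomer explicitly;
# E-geometry of the bridge double bonds is part of the template.
TEMPLATES: dict[tuple[str, str], str] = {
    ("curcumin", "diketone"):
        r"COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O",
    ("curcumin", "keto-enol"):
        r"COc1cc(/C=C/C(=O)/C=C(O)/C=C/c2ccc(O)c(OC)c2)ccc1O",
    ("demethoxycurcumin", "diketone"):
        r"COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)cc2)ccc1O",
    ("demethoxycurcumin", "keto-enol"):
        r"COc1cc(/C=C/C(=O)/C=C(O)/C=C/c2ccc(O)cc2)ccc1O",
    ("bisdemethoxycurcumin", "diketone"):
        r"Oc1ccc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)cc2)cc1",
    ("bisdemethoxycurcumin", "keto-enol"):
        r"Oc1ccc(/C=C/C(=O)/C=C(O)/C=C/c2ccc(O)cc2)cc1",
    ("cyclocurcumin", "cyclic"):
        r"COc1cc(/C=C/C2=CC(=O)C[C@@H](c3ccc(O)c(OC)c3)O2)ccc1O",
    ("tetrahydrocurcumin", "diketone"):
        r"COc1cc(CCC(=O)CC(=O)CCc2ccc(O)c(OC)c2)ccc1O",
    ("tetrahydrocurcumin", "keto-enol"):
        r"COc1cc(CCC(=O)/C=C(O)/CCc2ccc(O)c(OC)c2)ccc1O",
}

_ROTATABLE_SMARTS = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")

# UFF nonbonded parameters (x_ii: vdW minimum distance, Angstrom;
# D_ii: well depth, kcal/mol).  Used for the topology record and for the
# intermolecular terms in docking; MMFF94 supplies the intramolecular terms.
UFF_VDW: dict[str, tuple[float, float]] = {
    "H": (2.886, 0.044),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "S": (4.035, 0.274),
    "P": (4.147, 0.305),
    "F": (3.364, 0.050),
    "Cl": (3.947, 0.227),
    "Br": (4.189, 0.251),
}

DIELECTRIC_MODES: dict[str, tuple[float, bool]] = {
    # mode -> (dielectric constant/slope, distance_dependent)
    "polar": (80.0, True),
    "apolar": (1.0, False),
    "docking": (30.0, True),
    "scoring": (2.0, True),
}

_EMBED_SEED = 20230517  # fixed so identical inputs give identical topologies


@dataclass(frozen=True)
class AtomRecord:
    element: str
    partial_charge: float          # e, Gasteiger
    vdw_radius: float              # Angstrom, UFF x_ii
    vdw_well_depth: float          # kcal/mol, UFF D_ii


@dataclass
class LigandTopology:
    """Parameterized single-tautomer curcuminoid (or user) ligand."""

    name: str
    tautomer: str
    mol: Chem.Mol                                   # explicit H, 1 conformer
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, float]]
    rotatable_torsions: dict[str, tuple[int, int, int, int]]
    constrained_torsions: list[tuple[tuple[int, int, int, int], float, float]]
    conjugated_torsions: list[tuple[int, int, int, int]]
    aromatic_rings: list[tuple[int, ...]]
    ring_x: int                                     # index into aromatic_rings
    ring_y: int
    has_intramolecular_hbond_motif: bool = False

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol)

    def coordinates(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def ring_atoms(self, which: str) -> tuple[int, ...]:
        """Atom indices of terminal aryl ring ``"X"`` or ``"Y"``."""
        idx = {"X": self.ring_x, "Y": self.ring_y}[which]
        return self.aromatic_rings[idx]

    def bridge_atoms(self) -> tuple[int, ...]:
        """Heavy atoms of the central moiety linking rings X and Y.

        For cyclocurcumin this is the dihydropyran-4-one ring; for the open
        curcuminoids it is the heavy atoms on the shortest bond path between
        the two aryl rings (the bridge), exclusive of the rings themselves.
        """
        ri = self.mol.GetRingInfo()
        aromatic = set(self.aromatic_rings[self.ring_x]) | set(
            self.aromatic_rings[self.ring_y])
        for ring in ri.AtomRings():
            if not any(a in aromatic for a in ring) and len(ring) == 6:
                if not all(self.mol.GetAtomWithIdx(a).GetIsAromatic()
                           for a in ring):
                    return tuple(ring)
        path = Chem.GetShortestPath(
            self.mol, self.aromatic_rings[self.ring_x][0],
            self.aromatic_rings[self.ring_y][0])
        bridge = tuple(a for a in path if a not in aromatic)
        if not bridge:
            raise ValueError("ligand has no bridge between rings X and Y")
        return bridge

    def validate(self) -> None:
        frags = Chem.GetMolFrags(self.mol)
        if len(frags) != 1:
            raise ValueError("bond graph is not connected")
        if self.ring_x == self.ring_y:
            raise ValueError("rings X and Y must differ")
        for r in (self.ring_atoms("X"), self.ring_atoms("Y")):
            if len(r) < 5:
                raise ValueError("terminal aryl ring with <5 atoms")
        total = sum(a.partial_charge for a in self.atoms)
        if abs(total - self.formal_charge) > 1e-6:
            raise ValueError(
                f"partial charges sum to {total:.8f}, expected "
                f"{self.formal_charge}")
        for label, (a, i, j, d) in self.rotatable_torsions.items():
            bond = self.mol.GetBondBetweenAtoms(i, j)
            if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
                raise ValueError(f"torsion {label} central bond not single "
                                 "acyclic")

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "tautomer": self.tautomer,
            "smiles": Chem.MolToSmiles(Chem.RemoveHs(self.mol)),
            "molblock": Chem.MolToMolBlock(self.mol),
            "atoms": [[a.element, a.partial_charge, a.vdw_radius,
                       a.vdw_well_depth] for a in self.atoms],
            "bonds": self.bonds,
            "rotatable_torsions": self.rotatable_torsions,
            "constrained_torsions": self.constrained_torsions,
            "conjugated_torsions": self.conjugated_torsions,
            "aromatic_rings": self.aromatic_rings,
            "ring_x": self.ring_x,
            "ring_y": self.ring_y,
            "has_intramolecular_hbond_motif":
                self.has_intramolecular_hbond_motif,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LigandTopology":
        d = json.loads(text)
        mol = Chem.MolFromMolBlock(d["molblock"], removeHs=False)
        return cls(
            name=d["name"], tautomer=d["tautomer"], mol=mol,
            atoms=[AtomRecord(*a) for a in d["atoms"]],
            bonds=[tuple(b) for b in d["bonds"]],
            rotatable_torsions={k: tuple(v) for k, v in
                                d["rotatable_torsions"].items()},
            constrained_torsions=[(tuple(q), t, k) for q, t, k in
                                  d["constrained_torsions"]],
            conjugated_torsions=[tuple(q) for q in d["conjugated_torsions"]],
            aromatic_rings=[tuple(r) for r in d["aromatic_rings"]],
            ring_x=d["ring_x"], ring_y=d["ring_y"],
            has_intramolecular_hbond_motif=
                d["has_intramolecular_hbond_motif"],
        )


@dataclass
class IonizationInput:
    pKa: float
    pH: float = 7.2
    acid_or_base: str = "acid"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pKa) and math.isfinite(self.pH)):
            raise ValueError("pKa and pH must be finite")
        if self.acid_or_base not in ("acid", "base"):
            raise ValueError("acid_or_base must be 'acid' or 'base'")
        if not (0.0 < self.pKa < 14.0):
            import warnings
            warnings.warn(f"pKa {self.pKa} outside the usual 0-14 range")


def ionized_fraction(ion: IonizationInput) -> float:
    """Percent ionized at the given pH (Henderson-Hasselbalch).

    Acids: 100 / (1 + 10**(pKa - pH)); bases: 100 / (1 + 10**(pH - pKa)).
    At pH == pKa both branches give exactly 50%.
    """
    if ion.acid_or_base == "acid":
        return 100.0 / (1.0 + 10.0 ** (ion.pKa - ion.pH))
    return 100.0 / (1.0 + 10.0 ** (ion.pH - ion.pKa))


def _heavy_neighbor(mol: Chem.Mol, i: int, exclude: int,
                    prefer: set[int] | None = None) -> int:
    cands = [n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()
             if n.GetIdx() != exclude and n.GetAtomicNum() > 1]
    if not cands:
        raise ValueError(f"atom {i} has no heavy neighbor for a torsion")
    if prefer:
        on_path = [c for c in cands if c in prefer]
        if on_path:
            return min(on_path)
    return min(cands)


def _torsion_quad(mol: Chem.Mol, i: int, j: int,
                  prefer: set[int] | None = None) -> tuple[int, int, int,
                                                           int]:
    """Reference neighbors follow the inter-ring bridge when possible, so a
    180 deg target means chain-trans (substituents like the enol OH stay
    cis to the chain, as the chelate requires)."""
    return (_heavy_neighbor(mol, i, j, prefer), i, j,
            _heavy_neighbor(mol, j, i, prefer))


def _select_terminal_rings(mol: Chem.Mol) -> tuple[list[tuple[int, ...]], int, int]:
    ri = mol.GetRingInfo()
    rings = [tuple(r) for r in ri.AtomRings()
             if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in r)]
    if len(rings) < 2:
        raise ValueError("ligand must contain at least two aromatic rings")
    if len(rings) == 2:
        ix, iy = 0, 1
    else:
        # the two terminal aryl rings are the pair with maximal topological
        # separation
        best, pair = -1, (0, 1)
        for a in range(len(rings)):
            for b in range(a + 1, len(rings)):
                d = len(Chem.GetShortestPath(mol, rings[a][0], rings[b][0]))
                if d > best:
                    best, pair = d, (a, b)
        ix, iy = pair
    # ring X = the one containing the lower atom index (deterministic)
    if min(rings[iy]) < min(rings[ix]):
        ix, iy = iy, ix
    return rings, ix, iy


def _bridge_path_atoms(mol: Chem.Mol, rings, ix, iy) -> set[int]:
    return set(Chem.GetShortestPath(mol, rings[ix][0], rings[iy][0]))


def ordered_all(conjugated, flexible, rank) -> list[tuple[int, int]]:
    return sorted(conjugated, key=rank) + sorted(flexible, key=rank)


def build_ligand(template_or_smiles: str, tautomer: str | None = None,
                 name: str | None = None) -> LigandTopology:
    """Build a parameterized topology from a shipped template or SMILES/SDF.

    Parameters
    ----------
    template_or_smiles:
        A template name (``curcumin``, ``cyclocurcumin``, ...), a SMILES
        string, or a path to an SDF/MOL file.
    tautomer:
        Required for templates with several tautomers (``diketone``,
        ``keto-enol``, ``cyclic``).
    """
    key = (template_or_smiles.lower(), (tautomer or "").lower())
    if template_or_smiles.lower() in {k[0] for k in TEMPLATES}:
        if key not in TEMPLATES:
            valid = sorted(t for n, t in TEMPLATES if n == key[0])
            raise ValueError(
                f"unknown tautomer {tautomer!r} for {template_or_smiles!r}; "
                f"valid: {valid}")
        smiles = TEMPLATES[key]
        mol0 = Chem.MolFromSmiles(smiles)
        name = name or template_or_smiles.lower()
    else:
        if template_or_smiles.endswith((".sdf", ".mol")):
            mol0 = Chem.MolFromMolFile(template_or_smiles)
        else:
            mol0 = Chem.MolFromSmiles(template_or_smiles)
        if mol0 is None:
            raise ValueError(f"unparseable input {template_or_smiles!r}")
        mol0 = Chem.RemoveHs(mol0)
        name = name or "ligand"
        tautomer = tautomer or "custom"

    # torsion typing on the heavy-atom graph (atom indices are preserved by
    # AddHs, which appends hydrogens)
    rot_bonds = [b for b in mol0.GetSubstructMatches(_ROTATABLE_SMARTS)]
    double_bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol0.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() == 6
        and b.GetEndAtom().GetAtomicNum() == 6]
    # beta-ketoenol chelate: the C(=O)-C(enol) bond sits inside the
    # resonance-assisted intramolecular H-bond ring (O=C-C=C-O-H) and is
    # configurationally locked s-Z; treat it like a double bond
    chelate_quads: list[tuple[int, int, int, int]] = []
    chelate_bonds: set[tuple[int, int]] = set()
    for o_k, c_a, c_b, c_c, o_h in mol0.GetSubstructMatches(
            Chem.MolFromSmarts("[OX1]=[CX3]-[CX3H1]=[CX3]-[OX2H]")):
        chelate_quads.append((o_k, c_a, c_b, c_c))  # 0 deg = chelated s-Z
        chelate_bonds.add(tuple(sorted((c_a, c_b))))

    mol = Chem.AddHs(mol0)
    if AllChem.EmbedMolecule(mol, randomSeed=_EMBED_SEED) != 0:
        raise ValueError("3D embedding failed")

    rings, ix, iy = _select_terminal_rings(mol)
    bridge_path = _bridge_path_atoms(mol, rings, ix, iy)

    def is_conjugated_single(i: int, j: int) -> bool:
        ai, aj = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)
        sp2 = Chem.HybridizationType.SP2
        return (ai.GetAtomicNum() == 6 and aj.GetAtomicNum() == 6
                and ai.GetHybridization() == sp2
                and aj.GetHybridization() == sp2
                and i in bridge_path and j in bridge_path)

    conjugated, flexible = [], []
    for i, j in rot_bonds:
        if tuple(sorted((i, j))) in chelate_bonds:
            continue  # locked, not sampled
        (conjugated if is_conjugated_single(i, j) else flexible).append((i, j))

    # tau labels ordered by distance from ring X along the molecule
    def bond_rank(ij: tuple[int, int]) -> int:
        ref = rings[ix][0]
        return min(0 if a == ref else len(Chem.GetShortestPath(mol, ref, a))
                   for a in ij)

    # bridge torsions (central bond on the X..Y path) get "tau" labels in the
    # paper's sense and define subfamilies; peripheral torsions (methoxy,
    # aryl-O) get "chi" labels — sampled and deduplicated, but not
    # subfamily-defining
    bridge_bonds = [ij for ij in ordered_all(conjugated, flexible, bond_rank)
                    if ij[0] in bridge_path and ij[1] in bridge_path]
    periph_bonds = [ij for ij in ordered_all(conjugated, flexible, bond_rank)
                    if ij not in bridge_bonds]
    rotatable = {f"tau{k + 1}": _torsion_quad(mol, i, j, bridge_path)
                 for k, (i, j) in enumerate(bridge_bonds)}
    rotatable.update({f"chi{k + 1}": _torsion_quad(mol, i, j)
                      for k, (i, j) in enumerate(periph_bonds)})
    conj_quads = [_torsion_quad(mol, i, j, bridge_path)
                  for i, j in conjugated]
    constrained = [(_torsion_quad(mol, i, j, bridge_path), 180.0, 100.0)
                   for i, j in double_bonds]
    constrained += [(quad, 0.0, 100.0) for quad in chelate_quads]

    conf = mol.GetConformer()
    for quad, target, _k in constrained:
        rdMolTransforms.SetDihedralDeg(conf, *quad, target)
    # orient the enol hydroxyl proton into the chelate (syn to the ketone O)
    for _o_k, _c_a, c_b, c_c, o_h in mol0.GetSubstructMatches(
            Chem.MolFromSmarts("[OX1]=[CX3]-[CX3H1]=[CX3]-[OX2H]")):
        h_idx = next(n.GetIdx() for n in mol.GetAtomWithIdx(o_h)
                     .GetNeighbors() if n.GetAtomicNum() == 1)
        rdMolTransforms.SetDihedralDeg(conf, c_b, c_c, o_h, h_idx, 0.0)
    for quad in conj_quads:
        cur = rdMolTransforms.GetDihedralDeg(conf, *quad)
        rdMolTransforms.SetDihedralDeg(
            conf, *quad, 180.0 if abs(abs(cur) - 180.0) <= 90.0 else 0.0)

    AllChem.ComputeGasteigerCharges(mol)
    atoms = []
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        if el not in UFF_VDW:
            raise ValueError(f"no vdW parameters for atom {a.GetIdx()} "
                             f"({el})")
        q = float(a.GetDoubleProp("_GasteigerCharge"))
        atoms.append(AtomRecord(el, q, *UFF_VDW[el]))
    # Gasteiger charges carry rounding; rescale so the sum matches the formal
    # charge exactly (spread uniformly, < 1e-3 e per atom in practice)
    total, formal = sum(a.partial_charge for a in atoms), Chem.GetFormalCharge(mol)
    shift = (formal - total) / len(atoms)
    atoms = [AtomRecord(a.element, a.partial_charge + shift, a.vdw_radius,
                        a.vdw_well_depth) for a in atoms]

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
              float(b.GetBondTypeAsDouble())) for b in mol.GetBonds()]

    # keto-enol forms carry the enol O-H donor / ketone O acceptor motif
    hbond_motif = mol0.HasSubstructMatch(
        Chem.MolFromSmarts("[OX1]=C-C=C-[OX2H]")) or mol0.HasSubstructMatch(
        Chem.MolFromSmarts("[OX1]=C-C-C-[OX2H]"))

    top = LigandTopology(
        name=name, tautomer=tautomer or "default", mol=mol, atoms=atoms,
        bonds=bonds, rotatable_torsions=rotatable,
        constrained_torsions=constrained, conjugated_torsions=conj_quads,
        aromatic_rings=rings, ring_x=ix, ring_y=iy,
        has_intramolecular_hbond_motif=bool(hbond_motif))
    top.validate()
    return top


class EnergyModel:
    """MMFF94 intramolecular energy with mode-dependent dielectric.

    The planarity of the conjugated enone bridge is maintained by a twofold
    torsional restraint ``k_planar * sin^2(tau)`` on conjugated acyclic
    sp2-sp2 single bonds (minima at 0 and 180 deg).  MMFF94's intrinsic
    barriers for these bonds are too shallow to prevent unphysical stacked
    conformers that the fully delocalized pi system rules out.  Acyclic C=C
    double bonds are restrained to 180 deg with the protocol's k = 100.
    """

    K_PLANAR = 10.0  # kcal/mol barrier at 90 deg twist

    def __init__(self, top: LigandTopology, mode: str = "polar"):
        if mode not in DIELECTRIC_MODES:
            raise ValueError(f"unknown dielectric mode {mode!r}")
        self.top = top
        self.mode = mode
        eps, ddd = DIELECTRIC_MODES[mode]
        self.dielectric = eps
        self.distance_dependent = ddd
        self._props = AllChem.MMFFGetMoleculeProperties(top.mol)
        if self._props is None:
            bad = [a.GetIdx() for a in top.mol.GetAtoms()]
            raise ValueError(
                f"MMFF94 cannot parameterize this molecule (atoms {bad})")
        self._props.SetMMFFDielectricModel(2 if ddd else 1)
        self._props.SetMMFFDielectricConstant(eps)

    def forcefield(self, mol: Chem.Mol | None = None, conf_id: int = -1,
                   restrain_planarity: bool = True):
        """RDKit force field bound to *mol*'s conformer, with restraints.

        Double bonds get the single-well 180 deg restraint.  Conjugated
        single bonds get a single-well restraint toward their nearest planar
        target (0 or 180, judged from the current geometry) which realizes
        the twofold potential piecewise; the torsion-space sampler uses the
        analytic twofold form directly via :meth:`planarity_penalty`.
        """
        mol = mol or self.top.mol
        ff = AllChem.MMFFGetMoleculeForceField(mol, self._props,
                                               confId=conf_id)
        conf = mol.GetConformer(conf_id)
        for quad, target, k in self.top.constrained_torsions:
            ff.MMFFAddTorsionConstraint(*quad, False, target - 0.05,
                                        target + 0.05, k)
        if restrain_planarity:
            for quad in self.top.conjugated_torsions:
                cur = rdMolTransforms.GetDihedralDeg(conf, *quad)
                tgt = 180.0 if abs(abs(cur) - 180.0) <= 90.0 else 0.0
                if tgt == 180.0:
                    ff.MMFFAddTorsionConstraint(*quad, False, 175.0, 185.0,
                                                self.K_PLANAR)
                else:
                    ff.MMFFAddTorsionConstraint(*quad, False, -5.0, 5.0,
                                                self.K_PLANAR)
        return ff

    def planarity_penalty(self, mol: Chem.Mol | None = None,
                          conf_id: int = -1) -> float:
        """Twofold restraint energy k * sin^2(tau) over conjugated bonds."""
        mol = mol or self.top.mol
        conf = mol.GetConformer(conf_id)
        e = 0.0
        for quad in self.top.conjugated_torsions:
            tau = math.radians(rdMolTransforms.GetDihedralDeg(conf, *quad))
            e += self.K_PLANAR * math.sin(tau) ** 2
        return e

    def energy(self, mol: Chem.Mol | None = None, conf_id: int = -1,
               include_planarity: bool = True) -> float:
        """MMFF energy (+ planarity restraint) of the current geometry."""
        mol = mol or self.top.mol
        ff = AllChem.MMFFGetMoleculeForceField(mol, self._props,
                                               confId=conf_id)
        e = ff.CalcEnergy()
        if include_planarity:
            e += self.planarity_penalty(mol, conf_id)
        return e


def assign_energy_model(top: LigandTopology,
                        dielectric_mode: str = "polar") -> EnergyModel:
    """Attach MMFF94 parameters and a dielectric mode to a topology.

    Deterministic: two calls on the same topology give identical parameters.
    Raises if any atom lacks parameters (element listed in the message).
    """
    return EnergyModel(top, dielectric_mode)
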