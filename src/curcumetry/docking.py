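"""Monte-Carlo / simulated-annealing docking of a curcuminoid to a peptide helix.

The protocol mirrors the dynamic-docking scheme used for the
cyclocurcumin:Abeta(25-35) complex:

1. The starting complex comes from heptad superimposition
   (:func:`curcumetry.helix.superimpose_ligand`).
2. ``mc_generate`` produces up to 20 acceptable complexes.  Each attempt
   moves the ligand from the last accepted structure by a random combination
   of translation (<= 3 A), rotation (<= 180 deg) and torsional changes,
   pre-screens with a huge energy tolerance (10^6 kcal/mol, i.e. wide input
   variance) under 0.1-scaled nonbonded terms, minimizes (eps = 30*r), and
   applies the 50 kcal/mol energy-window test versus the best structure plus
   a 0.3 A rms dissimilarity test versus all previously accepted poses.
3. ``sa_refine`` anneals each complex from 500 K to 300 K over 50 stages
   (100 fs each) while the nonbonded scaling ramps from 0.1 to 1.0,
   finishing with an unrestrained minimization.  A complex is ``bound`` if
   any ligand-peptide heavy-atom contact is within 4.5 A and ``stable`` if
   in addition the ligand pose RMSD to the pre-annealing pose stays below
   2 A (same binding mode).
4. ``rank_complexes`` orders by conformational energy and picks the
   representative that is simultaneously lowest in conformational and
   interaction energy when one exists.

Energies: ligand intramolecular terms are MMFF94 (eps = 30*r during docking);
ligand-peptide terms are Lennard-Jones (UFF parameters, geometric combining)
plus Coulomb with Gasteiger ligand charges and a compact polar-atom charge
set for the peptide, eps = 30*r while docking and eps = 2*r for the reported
interaction energy (group-based 100 A cutoff).  The peptide is held rigid;
the helix backbone hydrogen-bond distances of the Asn27-Leu34 stretch (the
restrained "structurally conserved region") are monitored and reported on
every complex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from .conformers import Conformer, _set_coordinates
from .helix import PeptideStructure
from .ligand import LigandTopology, UFF_VDW, assign_energy_model

__all__ = [
    "DockingConfig",
    "SARefineConfig",
    "DockedComplex",
    "PeptideField",
    "DockingEngine",
    "mc_generate",
    "sa_refine",
    "rank_complexes",
    "interaction_energy",
]

logger = logging.getLogger(__name__)

_COULOMB = 332.0637   # kcal*A/(mol*e^2)
_R_KCAL = 1.987204259e-3

# Compact polar-atom charge set for peptide atoms (e).  Apolar carbons and
# their hydrogens are neutral; each residue is neutralized onto CA so that
# the total charge matches the formal charge of the residue.
_BACKBONE_Q = {"N": -0.42, "H": 0.27, "C": 0.60, "O": -0.57}
_SIDECHAIN_Q: dict[str, dict[str, float]] = {
    "SER": {"OG": -0.65, "HG": 0.45, "CB": 0.20},
    "THR": {"OG1": -0.65, "HG1": 0.45, "CB": 0.20},
    "ASN": {"CG": 0.60, "OD1": -0.57, "ND2": -0.60,
            "HD21": 0.30, "HD22": 0.30},
    "GLN": {"CD": 0.60, "OE1": -0.57, "NE2": -0.60,
            "HE21": 0.30, "HE22": 0.30},
    "LYS": {"CE": 0.31, "NZ": -0.30, "HZ1": 0.33, "HZ2": 0.33, "HZ3": 0.33},
    "MET": {"CG": 0.10, "SD": -0.20, "CE": 0.10},
    "TYR": {"OH": -0.55, "HH": 0.40, "CZ": 0.15},
}
_FORMAL_RES_CHARGE = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}


@dataclass
class DockingConfig:
    max_complexes: int = 20
    energy_tolerance: float = 1e6        # kcal/mol, pre-minimization screen
    energy_window: float = 50.0          # kcal/mol vs best structure
    similarity_rms: float = 0.3          # A, ligand heavy-atom RMS
    max_translation: float = 3.0         # A   (MxRChange)
    max_rotation_deg: float = 180.0      # deg (MxAngChange)
    min_iterations: int = 10_000         # minimizer evaluation cap
    initial_nb_scale: float = 0.1
    restraint_distance: float = 2.5      # A, backbone H-bond donor-acceptor
    restraint_k: float = 10.0            # kcal/mol/A^2
    attempts_per_complex: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.initial_nb_scale <= 1.0):
            raise ValueError("initial_nb_scale must be in (0, 1]")
        for name in ("max_complexes", "energy_window", "similarity_rms",
                     "max_translation", "min_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SARefineConfig:
    t_start: float = 500.0
    t_end: float = 300.0
    n_stages: int = 50
    stage_fs: float = 100.0
    timestep_fs: float = 1.0
    temp_window: float = 10.0
    final_min_steps: int = 100_000
    nb_scale_start: float = 0.1
    nb_scale_end: float = 1.0
    stability_rmsd: float = 2.0          # A, same-binding-mode threshold
    contact_cutoff: float = 4.5          # A, bound criterion

    def __post_init__(self) -> None:
        if self.t_start <= self.t_end:
            raise ValueError("t_start must exceed t_end")
        if self.n_stages < 1 or self.stage_fs <= 0 or self.timestep_fs <= 0:
            raise ValueError("invalid stage setup")

    @property
    def total_ps(self) -> float:
        return self.n_stages * self.stage_fs / 1000.0

    def stage_temperatures(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_stages)

    def stage_nb_scales(self) -> np.ndarray:
        return np.linspace(self.nb_scale_start, self.nb_scale_end,
                           self.n_stages)

    @property
    def steps_per_stage(self) -> int:
        return max(1, round(self.stage_fs / self.timestep_fs))


@dataclass
class DockedComplex:
    ligand_coordinates: np.ndarray
    torsions: dict[str, float]
    conformational_energy: float         # ligand internal + interaction
    interaction_energy: float            # vdW + Coulomb, eps = 2*r
    stable: bool = False
    bound: bool = True
    restraint_distances: dict[str, float] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if self.stable and not self.bound:
            raise ValueError("stable implies bound")
        if not (math.isfinite(self.conformational_energy)
                and math.isfinite(self.interaction_energy)):
            raise ValueError("energies must be finite")


class PeptideField:
    """Rigid-peptide nonbonded field: coordinates, charges, vdW parameters."""

    def __init__(self, peptide: PeptideStructure):
        self.peptide = peptide
        coords, charges, x_ii, d_ii, res_index, heavy = [], [], [], [], [], []
        for ri, res in enumerate(peptide.residues):
            raw = {}
            for name, xyz in res.atoms.items():
                el = res.elements.get(name, name[0])
                q = _BACKBONE_Q.get(name, 0.0)
                q = _SIDECHAIN_Q.get(res.name, {}).get(name, q)
                raw[name] = (xyz, q, el)
            formal = _FORMAL_RES_CHARGE.get(res.name, 0.0)
            resid_q = formal - sum(q for _, q, _ in raw.values())
            for name, (xyz, q, el) in raw.items():
                if name == "CA":
                    q += resid_q
                el_key = el if el in UFF_VDW else el[0]
                if el_key not in UFF_VDW:
                    raise ValueError(f"no vdW parameters for peptide atom "
                                     f"{res.name}{res.number}:{name}")
                coords.append(xyz)
                charges.append(q)
                x_ii.append(UFF_VDW[el_key][0])
                d_ii.append(UFF_VDW[el_key][1])
                res_index.append(ri)
                heavy.append(not el_key.startswith("H"))
        self.coords = np.asarray(coords, float)
        self.charges = np.asarray(charges, float)
        self.x_ii = np.asarray(x_ii, float)
        self.d_ii = np.asarray(d_ii, float)
        self.res_index = np.asarray(res_index, int)
        self.heavy_mask = np.asarray(heavy, bool)
        self.res_centers = np.vstack([
            self.coords[self.res_index == ri].mean(axis=0)
            for ri in range(len(peptide.residues))])

    def backbone_hbond_pairs(self, first_resnum: int = 27,
                             last_resnum: int = 34) -> dict[str, float]:
        """Backbone H-bond donor-acceptor distances, restrained stretch.

        Uses the amide H(i+4)...O(i) distance when the hydrogen is present,
        falling back to N(i+4)...O(i) otherwise (tagged in the key).
        """
        out = {}
        bynum = {r.number: r for r in self.peptide.residues}
        for num in range(first_resnum, last_resnum - 3):
            a, b = bynum.get(num), bynum.get(num + 4)
            if a is None or b is None or "O" not in a.atoms:
                continue
            if "H" in b.atoms:
                out[f"O{num}..H{num + 4}"] = float(
                    np.linalg.norm(a.atoms["O"] - b.atoms["H"]))
            elif "N" in b.atoms:
                out[f"O{num}..N{num + 4}"] = float(
                    np.linalg.norm(a.atoms["O"] - b.atoms["N"]))
        return out


def _pair_energy(lig_coords: np.ndarray, lig_q: np.ndarray,
                 lig_x: np.ndarray, lig_d: np.ndarray,
                 field: PeptideField, eps_scale: float,
                 cutoff: float = 100.0, nb_scale: float = 1.0) -> float:
    """LJ + distance-dependent-dielectric Coulomb over ligand-peptide pairs.

    Group-based cutoff: a peptide residue enters if its centroid lies within
    ``cutoff`` of the ligand centroid.
    """
    lig_center = lig_coords.mean(axis=0)
    groups = np.linalg.norm(field.res_centers - lig_center, axis=1) <= cutoff
    mask = groups[field.res_index]
    if not mask.any():
        return 0.0
    pc = field.coords[mask]
    diff = lig_coords[:, None, :] - pc[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    r2 = np.maximum(r2, 0.4)  # soft core floor, avoids singularities
    x_ij = np.sqrt(lig_x[:, None] * field.x_ii[None, mask])
    d_ij = np.sqrt(lig_d[:, None] * field.d_ii[None, mask])
    s6 = (x_ij * x_ij / r2) ** 3
    vdw = float(np.sum(d_ij * (s6 * s6 - 2.0 * s6)))
    # eps = eps_scale * r  =>  q_i q_j / (eps_scale * r^2)
    coul = float(_COULOMB / eps_scale
                 * np.sum(lig_q[:, None] * field.charges[None, mask] / r2))
    return nb_scale * (vdw + coul)


class DockingEngine:
    """Working state for one ligand against a rigid peptide field."""

    def __init__(self, top: LigandTopology, field: PeptideField,
                 start_pose: Conformer, cfg: DockingConfig | None = None):
        self.top = top
        self.field = field
        self.cfg = cfg or DockingConfig()
        self.model = assign_energy_model(top, "docking")
        self.mol = Chem.Mol(top.mol)
        _set_coordinates(self.mol, start_pose.coordinates)
        self._ff = AllChem.MMFFGetMoleculeForceField(
            self.mol, self.model._props)
        self.lig_q = np.array([a.partial_charge for a in top.atoms])
        self.lig_x = np.array([a.vdw_radius for a in top.atoms])
        self.lig_d = np.array([a.vdw_well_depth for a in top.atoms])
        self.lig_heavy = np.array(
            [a.GetAtomicNum() > 1 for a in top.mol.GetAtoms()])
        self.quads = list(top.rotatable_torsions.values())
        self.labels = list(top.rotatable_torsions.keys())

    # -- geometry helpers -------------------------------------------------
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), float)

    def set_coords(self, coords: np.ndarray) -> None:
        _set_coordinates(self.mol, coords)

    def torsions(self) -> dict[str, float]:
        conf = self.mol.GetConformer()
        return {lab: float(rdMolTransforms.GetDihedralDeg(conf, *q))
                for lab, q in zip(self.labels, self.quads)}

    # -- energies ---------------------------------------------------------
    def ligand_internal(self) -> float:
        return self._ff.CalcEnergy() + self.model.planarity_penalty(self.mol)

    def intermolecular(self, eps_scale: float = 30.0,
                       nb_scale: float = 1.0) -> float:
        return _pair_energy(self.coords(), self.lig_q, self.lig_x,
                            self.lig_d, self.field, eps_scale,
                            nb_scale=nb_scale)

    def total_energy(self, nb_scale: float = 1.0) -> float:
        return self.ligand_internal() + self.intermolecular(30.0, nb_scale)

    def interaction_energy(self) -> float:
        return self.intermolecular(eps_scale=2.0, nb_scale=1.0)

    # -- moves ------------------------------------------------------------
    def random_move(self, rng: np.random.Generator,
                    trans_scale: float | None = None,
                    rot_scale: float | None = None,
                    torsion_scale: float = 180.0) -> None:
        cfg = self.cfg
        trans_scale = cfg.max_translation if trans_scale is None \
            else trans_scale
        rot_scale = cfg.max_rotation_deg if rot_scale is None else rot_scale
        conf = self.mol.GetConformer()
        for quad in self.quads:
            if rng.random() < 0.5:
                cur = rdMolTransforms.GetDihedralDeg(conf, *quad)
                rdMolTransforms.SetDihedralDeg(
                    conf, *quad,
                    cur + float(rng.uniform(-torsion_scale, torsion_scale)))
        xyz = self.coords()
        center = xyz.mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(float(rng.uniform(-rot_scale, rot_scale)))
        rot = Rotation.from_rotvec(axis * angle).as_matrix()
        vec = rng.normal(size=3)
        vec /= np.linalg.norm(vec)
        shift = vec * float(rng.uniform(0.0, trans_scale))
        self.set_coords((xyz - center) @ rot.T + center + shift)

    # -- minimization over rigid-body + torsion coordinates ---------------
    def minimize_pose(self, max_evals: int | None = None) -> float:
        base = self.coords()
        n_t = len(self.quads)
        base_tors = np.array([rdMolTransforms.GetDihedralDeg(
            self.mol.GetConformer(), *q) for q in self.quads])
        center = base.mean(axis=0)
        evals = 0
        cap = max_evals or self.cfg.min_iterations

        def build(x: np.ndarray) -> np.ndarray:
            conf = self.mol.GetConformer()
            _set_coordinates(self.mol, base)
            for q, t0, dt in zip(self.quads, base_tors, x[6:]):
                rdMolTransforms.SetDihedralDeg(conf, *q, float(t0 + dt))
            xyz = self.coords()
            rot = Rotation.from_rotvec(x[3:6]).as_matrix()
            return (xyz - center) @ rot.T + center + x[:3]

        def objective(x: np.ndarray) -> float:
            nonlocal evals
            evals += 1
            self.set_coords(build(x))
            return self.total_energy()

        x0 = np.zeros(6 + n_t)
        # local refinement: translations bounded by the move scheme's
        # MxRChange so a clashed start relaxes in place instead of being
        # ejected down the separation coordinate
        bounds = ([(-self.cfg.max_translation, self.cfg.max_translation)] * 3
                  + [(-math.pi, math.pi)] * 3 + [(-180.0, 180.0)] * n_t)
        res = scipy_minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": cap, "eps": 1e-4, "ftol": 1e-8})
        self.set_coords(build(res.x))
        return float(self.total_energy())

    def snapshot(self) -> DockedComplex:
        return DockedComplex(
            ligand_coordinates=self.coords(), torsions=self.torsions(),
            conformational_energy=self.total_energy(),
            interaction_energy=self.interaction_energy(),
            bound=self.is_bound(),
            restraint_distances=self.field.backbone_hbond_pairs())

    def is_bound(self, cutoff: float = 4.5) -> bool:
        lig = self.coords()[self.lig_heavy]
        pep = self.field.coords[self.field.heavy_mask]
        d2 = np.min(np.sum((lig[:, None, :] - pep[None, :, :]) ** 2,
                           axis=-1))
        return bool(d2 <= cutoff * cutoff)

    def ligand_rmsd(self, other_coords: np.ndarray) -> float:
        a = self.coords()[self.lig_heavy]
        b = np.asarray(other_coords, float)[self.lig_heavy]
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def mc_generate(engine: DockingEngine,
                cfg: DockingConfig | None = None) -> list[DockedComplex]:
    """Monte-Carlo/minimization generation of up to ``max_complexes`` poses.

    The minimized starting complex counts as the first accepted structure;
    each subsequent attempt starts from the last accepted structure.  Raises
    ``RuntimeError`` if nothing is accepted within the attempt cap.
    """
    cfg = cfg or engine.cfg
    rng = np.random.default_rng(cfg.seed)
    accepted: list[DockedComplex] = []

    engine.minimize_pose()
    first = engine.snapshot()
    accepted.append(first)
    best_e = first.conformational_energy
    last_coords = first.ligand_coordinates
    last_screen_e = engine.total_energy(nb_scale=cfg.initial_nb_scale)

    attempts = 0
    cap = cfg.attempts_per_complex * cfg.max_complexes
    while len(accepted) < cfg.max_complexes and attempts < cap:
        attempts += 1
        engine.set_coords(last_coords)
        engine.random_move(rng)
        screen_e = engine.total_energy(nb_scale=cfg.initial_nb_scale)
        if not math.isfinite(screen_e) \
                or screen_e > last_screen_e + cfg.energy_tolerance:
            continue  # outside the (intentionally huge) input tolerance
        e = engine.minimize_pose()
        if not math.isfinite(e):
            continue
        if e > min(best_e, e) + cfg.energy_window:
            continue
        if any(engine.ligand_rmsd(c.ligand_coordinates) < cfg.similarity_rms
               for c in accepted):
            continue
        snap = engine.snapshot()
        accepted.append(snap)
        best_e = min(best_e, e)
        last_coords = snap.ligand_coordinates
        last_screen_e = engine.total_energy(nb_scale=cfg.initial_nb_scale)
    if not accepted:
        raise RuntimeError(f"no acceptable complex within {cap} attempts")
    # drop structures that fell out of the final 50 kcal/mol window
    accepted = [c for c in accepted
                if c.conformational_energy <= best_e + cfg.energy_window]
    return accepted


def sa_refine(engine: DockingEngine, complex_: DockedComplex,
              sa_cfg: SARefineConfig | None = None,
              seed: int = 0) -> DockedComplex:
    """Staged-temperature annealing of one docked complex (500 -> 300 K).

    Metropolis Monte Carlo in torsion + rigid-body space with per-stage
    move-size annealing and the nonbonded 0.1 -> 1.0 ramp, followed by a
    final minimization.  Sets the ``stable`` (same binding mode) and
    ``bound`` (any contact <= 4.5 A) flags.
    """
    sa_cfg = sa_cfg or SARefineConfig()
    rng = np.random.default_rng(seed)
    engine.set_coords(complex_.ligand_coordinates)
    temps = sa_cfg.stage_temperatures()
    scales = sa_cfg.stage_nb_scales()
    e = engine.total_energy(nb_scale=scales[0])
    for temp, nb in zip(temps, scales):
        frac = temp / sa_cfg.t_start
        e = engine.total_energy(nb_scale=nb)
        for _ in range(sa_cfg.steps_per_stage):
            before = engine.coords()
            # move sizes mirror the per-femtosecond mobility of the
            # dynamics this stands in for; larger steps make the weakly
            # coupled (0.1-scaled) early stages unphysically diffusive
            engine.random_move(rng, trans_scale=0.08 * frac,
                               rot_scale=4.0 * frac,
                               torsion_scale=10.0 * frac)
            e_new = engine.total_energy(nb_scale=nb)
            if not math.isfinite(e_new):
                engine.set_coords(before)
                continue
            if e_new <= e or rng.random() < math.exp(
                    -(e_new - e) / (_R_KCAL * temp)):
                e = e_new
            else:
                engine.set_coords(before)
    e = engine.minimize_pose(max_evals=min(sa_cfg.final_min_steps, 20_000))
    if not math.isfinite(e):
        raise RuntimeError("non-finite energy after annealing")
    refined = engine.snapshot()
    refined.bound = engine.is_bound(sa_cfg.contact_cutoff)
    pose_shift = engine.ligand_rmsd(complex_.ligand_coordinates)
    refined.stable = bool(refined.bound
                          and pose_shift < sa_cfg.stability_rmsd)
    refined.note = f"pose_rmsd_vs_input={pose_shift:.2f}A"
    return refined


def rank_complexes(complexes: list[DockedComplex],
                   engine: DockingEngine | None = None,
                   ) -> tuple[list[DockedComplex], DockedComplex]:
    """Sort by conformational energy and select the representative complex.

    The representative is the complex that is simultaneously lowest in
    conformational energy and most favorable in interaction energy; if no
    complex holds both records, the lowest-conformational-energy one is
    returned with a logged note (ties broken by interaction energy).  When
    an engine is supplied, the representative is re-minimized without
    tethering restraints before being returned.
    """
    if not complexes:
        raise ValueError("no complexes to rank")
    ordered = sorted(complexes,
                     key=lambda c: (c.conformational_energy,
                                    c.interaction_energy))
    best_conf = ordered[0]
    best_inter = min(complexes, key=lambda c: c.interaction_energy)
    rep = best_conf
    if best_inter is not best_conf:
        logger.info("lowest-energy and best-interaction complexes differ "
                    "(%.2f vs %.2f kcal/mol interaction); using lowest "
                    "conformational energy",
                    best_conf.interaction_energy,
                    best_inter.interaction_energy)
    if engine is not None:
        engine.set_coords(rep.ligand_coordinates)
        engine.minimize_pose()
        final = engine.snapshot()
        final.stable, final.bound = rep.stable, engine.is_bound()
        final.note = (rep.note + "; re-minimized unrestrained").lstrip("; ")
        rep = final
        ordered[0] = final
    return ordered, rep


def interaction_energy(engine: DockingEngine,
                       complex_: DockedComplex | None = None,
                       cutoff: float = 100.0) -> float:
    """Ligand-peptide vdW + Coulomb (eps = 2*r, group-based cutoff), kcal/mol.

    Symmetric in the two molecules by construction and -> 0 as the
    separation grows beyond the cutoff.
    """
    if complex_ is not None:
        engine.set_coords(complex_.ligand_coordinates)
    return _pair_energy(engine.coords(), engine.lig_q, engine.lig_x,
                        engine.lig_d, engine.field, eps_scale=2.0,
                        cutoff=cutoff)
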