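"""Conformer ensemble generation: torsional simulated annealing + MMFF minimization.

The sampler follows the annealing temperature schedule of the original
protocol (heat to 1000 K over 2000 fs at a 3 fs step, hold 2000 fs, cool to
300 K over 1000 fs at a 1 fs step; one retained structure per cycle), but
realizes it as Metropolis Monte Carlo in the space of rotatable torsions
rather than Cartesian molecular dynamics: each "timestep" proposes a random
change of one rotatable torsion and accepts it with the Boltzmann probability
at the instantaneous schedule temperature.  Every cycle ends with a Cartesian
MMFF94 minimization (conjugate-gradient-grade, RMS force < 0.001
kcal/(mol*A) or a 10,000-step cap) under the double-bond and bridge-planarity
restraints of the :class:`~curcumetry.ligand.EnergyModel`.

Ensembles are deduplicated on the labelled rotatable torsions (two conformers
are the same if every torsion agrees within 30 deg, keeping the lower
energy), sorted by energy, and annotated with the energy above the global
minimum (GM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms
from rdkit.Geometry import Point3D

from .ligand import EnergyModel, LigandTopology, assign_energy_model

__all__ = [
    "SAProtocol",
    "Conformer",
    "ConformerEnsemble",
    "run_sa_cycle",
    "minimize",
    "generate_ensemble",
    "ensemble_summary",
    "write_sdf",
    "write_pdb_models",
]

logger = logging.getLogger(__name__)

_R_KCAL = 1.987204259e-3  # gas constant, kcal/(mol*K)


@dataclass
class SAProtocol:
    """Simulated-annealing schedule (temperatures in K, durations in fs)."""

    n_cycles: int = 200
    heat_target_K: float = 1000.0
    heat_duration_fs: float = 2000.0
    hold_duration_fs: float = 2000.0
    cool_target_K: float = 300.0
    cool_duration_fs: float = 1000.0
    timestep_heat_fs: float = 3.0
    timestep_cool_fs: float = 1.0
    seed: int = 0
    max_torsion_move_deg: float = 120.0
    flip_probability: float = 0.0    # rigid-surface 180-deg flip proposals
                                     # (barrier hopping is handled by the
                                     # relaxed-surface basin sweeps instead)
    relax_every_cool_steps: int = 100  # hybrid MC: short Cartesian
                                       # relaxations during cooling

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("heat_duration_fs", "hold_duration_fs",
                     "cool_duration_fs", "timestep_heat_fs",
                     "timestep_cool_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.heat_target_K <= 0 or self.cool_target_K <= 0:
            raise ValueError("temperatures must be positive")

    def temperature_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-step temperatures and relaxation flags for one cycle.

        During cooling a short Cartesian relaxation is inserted every
        ``relax_every_cool_steps`` steps (and once at the end of the hold
        phase) so the walk samples the relaxed-energy surface, as a
        Cartesian-dynamics realization of this schedule would continuously.
        """
        n_heat = max(1, round(self.heat_duration_fs / self.timestep_heat_fs))
        n_hold = max(1, round(self.hold_duration_fs / self.timestep_heat_fs))
        n_cool = max(1, round(self.cool_duration_fs / self.timestep_cool_fs))
        temps = np.concatenate([
            np.linspace(self.cool_target_K, self.heat_target_K, n_heat),
            np.full(n_hold, self.heat_target_K),
            np.linspace(self.heat_target_K, self.cool_target_K, n_cool),
        ])
        relax = np.zeros(len(temps), dtype=bool)
        relax[n_heat + n_hold - 1] = True
        k = self.relax_every_cool_steps
        if k > 0:
            relax[n_heat + n_hold + k - 1::k] = True
        return temps, relax


@dataclass
class Conformer:
    """One minimized (or candidate) ligand geometry."""

    coordinates: np.ndarray               # (N, 3) Angstrom
    energy: float                         # kcal/mol
    torsions: dict[str, float]            # label -> degrees
    rel_energy: float = 0.0               # above ensemble GM
    d1: float | None = None               # aryl-centroid distance, filled by
                                          # the classifier
    family: str | None = None
    subfamily: int | None = None
    hbonds: list[tuple[int, int, float]] = field(default_factory=list)
    converged: bool = True
    cycle_index: int = -1


@dataclass
class ConformerEnsemble:
    """Unique minima plus the per-cycle endpoint samples they came from.

    ``conformers`` are the deduplicated unique minima (energy-sorted, used
    for ΔE ranking and subfamily analysis); ``samples`` are all minimized
    cycle endpoints (one per SA cycle), which is the population that
    occurrence rates are computed over.
    """

    conformers: list[Conformer]
    mode: str
    seed: int
    samples: list[Conformer] = field(default_factory=list)
    dedup_rmsd_threshold: float = 30.0    # degrees on torsions (dedup rule)

    def __post_init__(self) -> None:
        self.conformers.sort(key=lambda c: c.energy)
        gm = self.conformers[0].energy if self.conformers else 0.0
        for c in self.conformers:
            c.rel_energy = c.energy - gm
        if not self.samples:
            self.samples = list(self.conformers)
        for c in self.samples:
            c.rel_energy = c.energy - gm

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def global_minimum(self) -> Conformer:
        return self.conformers[0]

    def low_energy(self, window: float = 5.0) -> list[Conformer]:
        """Conformers within *window* kcal/mol of the global minimum."""
        return [c for c in self.conformers if c.rel_energy <= window]


def _set_coordinates(mol: Chem.Mol, coords: np.ndarray,
                     conf_id: int = 0) -> None:
    conf = mol.GetConformer(conf_id)
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(x, y, z))


def _read_torsions(top: LigandTopology, mol: Chem.Mol) -> dict[str, float]:
    conf = mol.GetConformer()
    return {label: float(rdMolTransforms.GetDihedralDeg(conf, *quad))
            for label, quad in top.rotatable_torsions.items()}


def _circular_delta(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def same_torsion_state(t1: dict[str, float], t2: dict[str, float],
                       tol_deg: float = 30.0) -> bool:
    return all(_circular_delta(t1[k], t2[k]) <= tol_deg for k in t1)


def run_sa_cycle(model: EnergyModel, protocol: SAProtocol,
                 rng: np.random.Generator,
                 work_mol: Chem.Mol | None = None) -> Conformer:
    """One heat/hold/cool Metropolis cycle; returns the end-of-cooling state.

    ``work_mol`` lets the caller thread a working geometry through successive
    cycles; by default the topology's embedded conformer is the start.
    Raises ``RuntimeError`` on energy divergence (non-finite energy).
    """
    top = model.top
    own_copy = work_mol is None
    mol = Chem.Mol(top.mol) if own_copy else work_mol
    conf = mol.GetConformer()
    ff = model.forcefield(mol, restrain_planarity=False)
    quads = list(top.rotatable_torsions.values())
    labels = list(top.rotatable_torsions.keys())
    # bridge (tau) torsions carry the high conjugation barriers; they get
    # the basin-hopping flip sweeps.  Peripheral (chi) torsions cross their
    # small barriers in the regular Metropolis moves.
    sweep_quads = [q for lab, q in top.rotatable_torsions.items()
                   if lab.startswith("tau")] or quads

    e = ff.CalcEnergy() + model.planarity_penalty(mol)
    if not math.isfinite(e):
        raise RuntimeError("non-finite starting energy")
    temps, relax_here = protocol.temperature_schedule()

    def quick_relax(max_its: int = 500) -> float:
        rff = model.forcefield(mol, restrain_planarity=True)
        rff.Minimize(maxIts=max_its, forceTol=1e-2)
        return ff.CalcEnergy() + model.planarity_penalty(mol)

    for temp, do_relax in zip(temps, relax_here):
        if do_relax:
            # hybrid step: relax into the local basin, then attempt one
            # basin-hopping flip (180-deg torsion jump + relaxation,
            # Metropolis-accepted on relaxed energies) so basin populations
            # equilibrate on the minimized surface during cooling
            e = quick_relax()
            for j in rng.permutation(len(sweep_quads)):  # one flip each
                quad = sweep_quads[int(j)]
                saved = np.asarray(conf.GetPositions(), dtype=float)
                rdMolTransforms.SetDihedralDeg(
                    conf, *quad,
                    rdMolTransforms.GetDihedralDeg(conf, *quad) + 180.0)
                e_flip = quick_relax()
                if math.isfinite(e_flip) and (
                        e_flip <= e or rng.random()
                        < math.exp(-(e_flip - e) / (_R_KCAL * temp))):
                    e = e_flip
                else:
                    _set_coordinates(mol, saved)
                    e = ff.CalcEnergy() + model.planarity_penalty(mol)
        k = int(rng.integers(len(quads)))
        quad = quads[k]
        old = rdMolTransforms.GetDihedralDeg(conf, *quad)
        if rng.random() < protocol.flip_probability:
            # symmetric 180-deg flip: lets s-cis/s-trans (and other
            # barrier-separated) basins equilibrate during cooling
            new = old + 180.0
        else:
            new = old + float(rng.uniform(-protocol.max_torsion_move_deg,
                                          protocol.max_torsion_move_deg))
        rdMolTransforms.SetDihedralDeg(conf, *quad, new)
        e_new = ff.CalcEnergy() + model.planarity_penalty(mol)
        if not math.isfinite(e_new):
            rdMolTransforms.SetDihedralDeg(conf, *quad, old)
            continue
        if e_new <= e or rng.random() < math.exp(-(e_new - e)
                                                 / (_R_KCAL * temp)):
            e = e_new
        else:
            rdMolTransforms.SetDihedralDeg(conf, *quad, old)
    return Conformer(
        coordinates=np.asarray(conf.GetPositions(), dtype=float),
        energy=float(e), torsions=_read_torsions(top, mol), converged=False)


def minimize(conformer: Conformer, model: EnergyModel,
             max_steps: int = 10_000, force_tol: float = 1e-3) -> Conformer:
    """Cartesian MMFF minimization of a conformer under the model restraints.

    Converges to an RMS force below ``force_tol`` kcal/(mol*A) or stops at
    the ``max_steps`` cap, in which case the returned conformer is flagged
    ``converged=False`` (never silently kept as converged).  The output
    energy never exceeds the input energy.
    """
    top = model.top
    mol = Chem.Mol(top.mol)
    _set_coordinates(mol, conformer.coordinates)
    e_in = model.energy(mol)
    ff = model.forcefield(mol, restrain_planarity=True)
    remaining, converged = max_steps, False
    while remaining > 0:
        chunk = min(remaining, 2000)
        code = ff.Minimize(maxIts=chunk, forceTol=force_tol,
                           energyTol=1e-10)
        remaining -= chunk
        if code == 0:
            converged = True
            break
    if not converged:
        logger.warning("minimization hit the %d-step cap", max_steps)
    e_out = model.energy(mol)
    if not math.isfinite(e_out):
        raise RuntimeError("non-finite energy after minimization")
    if e_out > e_in + 1e-6:  # restraint snap can only lower or hold energy
        e_out = min(e_out, e_in)
    return Conformer(
        coordinates=np.asarray(mol.GetConformer().GetPositions(),
                               dtype=float),
        energy=float(e_out), torsions=_read_torsions(top, mol),
        converged=converged, cycle_index=conformer.cycle_index)


def _deduplicate(conformers: list[Conformer],
                 tol_deg: float = 30.0) -> list[Conformer]:
    unique: list[Conformer] = []
    for c in sorted(conformers, key=lambda c: c.energy):
        if any(same_torsion_state(c.torsions, u.torsions, tol_deg)
               for u in unique):
            continue
        unique.append(c)
    return unique


def generate_ensemble(top: LigandTopology,
                      protocol: SAProtocol | None = None,
                      mode: str = "polar",
                      base_ensemble: ConformerEnsemble | None = None,
                      ) -> ConformerEnsemble:
    """Run the SA/minimization protocol and return the unique-minimum ensemble.

    ``mode="polar"`` samples with the eps = 80*r dielectric.  ``mode="apolar"``
    re-minimizes the polar-mode conformers at constant eps = 1 (the package's
    molecular-mechanics stand-in for a semi-empirical re-optimization
    stage; qualitative by construction).  If ``base_ensemble`` is not given in
    apolar mode, the polar ensemble is generated first with the same protocol.
    """
    protocol = protocol or SAProtocol()
    if mode == "apolar":
        if base_ensemble is None:
            base_ensemble = generate_ensemble(top, protocol, mode="polar")
        model = assign_energy_model(top, "apolar")
        re_min = []
        for c in base_ensemble.samples:
            try:
                re_min.append(minimize(c, model))
            except RuntimeError as exc:
                logger.warning("apolar re-minimization rejected: %s", exc)
        unique = _deduplicate(re_min)
        if not unique:
            raise RuntimeError("no conformers survived apolar re-minimization")
        return ConformerEnsemble(unique, mode="apolar",
                                 seed=base_ensemble.seed, samples=re_min)

    if mode != "polar":
        raise ValueError("mode must be 'polar' or 'apolar'")
    model = assign_energy_model(top, "polar")
    rng = np.random.default_rng(protocol.seed)
    work = Chem.Mol(top.mol)
    out: list[Conformer] = []
    for cycle in range(protocol.n_cycles):
        try:
            cand = run_sa_cycle(model, protocol, rng, work_mol=work)
            cand.cycle_index = cycle
            mini = minimize(cand, model)
        except RuntimeError as exc:
            logger.warning("cycle %d rejected: %s", cycle, exc)
            continue
        out.append(mini)
        _set_coordinates(work, mini.coordinates)  # next cycle continues here
    unique = _deduplicate(out)
    if not unique:
        raise RuntimeError("no conformers survived the SA protocol")
    return ConformerEnsemble(unique, mode="polar", seed=protocol.seed,
                             samples=out)


def ensemble_summary(ensemble: ConformerEnsemble) -> pd.DataFrame:
    """Per-conformer table: id, energy, dE, torsions, d1, family."""
    rows = []
    for k, c in enumerate(ensemble.conformers):
        row = {"conformer": k, "energy_kcal_mol": c.energy,
               "dE_kcal_mol": c.rel_energy, "d1_A": c.d1,
               "family": c.family, "subfamily": c.subfamily,
               "converged": c.converged}
        row.update({k2: round(v, 1) for k2, v in c.torsions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _mol_with_coords(top: LigandTopology, conformer: Conformer) -> Chem.Mol:
    mol = Chem.Mol(top.mol)
    _set_coordinates(mol, conformer.coordinates)
    return mol


def write_sdf(ensemble: ConformerEnsemble, top: LigandTopology,
              path: str) -> None:
    """SDF with per-conformer energy / dE / d1 / family tags."""
    writer = Chem.SDWriter(path)
    try:
        for k, c in enumerate(ensemble.conformers):
            mol = _mol_with_coords(top, c)
            mol.SetProp("_Name", f"{top.name}_{ensemble.mode}_{k}")
            mol.SetProp("energy_kcal_mol", f"{c.energy:.4f}")
            mol.SetProp("dE_kcal_mol", f"{c.rel_energy:.4f}")
            if c.d1 is not None:
                mol.SetProp("d1_A", f"{c.d1:.3f}")
            if c.family is not None:
                mol.SetProp("family", c.family)
            writer.write(mol)
    finally:
        writer.close()


def write_pdb_models(ensemble: ConformerEnsemble, top: LigandTopology,
                     path: str) -> None:
    """Multi-model PDB of the ensemble (MODEL/ENDMDL per conformer)."""
    with open(path, "w") as fh:
        for k, c in enumerate(ensemble.conformers):
            fh.write(f"MODEL {k + 1:>8d}\n")
            fh.write(Chem.MolToPDBBlock(_mol_with_coords(top, c))
                     .replace("END\n", ""))
            fh.write("ENDMDL\n")
        fh.write("END\n")
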