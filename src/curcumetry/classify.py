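"""Conformer family classification by aryl-centroid distance d1.

d1 is the Euclidean distance between the unweighted heavy-atom centroids of
the two terminal aryl rings (X and Y).  Families:

* folded:       d1 <= 5 A
* semi-folded:  5 A < d1 < 9 A
* extended:     d1 >= 9 A

Subfamilies (conf I, II, ...) are defined purely by rotamer binning of the
labelled torsions: each torsion is rounded to the nearest of
{0, +-60, +-120, 180} deg (ties toward the lower absolute angle).

Intramolecular hydrogen bonds use a geometric criterion: donor-acceptor
heavy-atom distance <= 3.5 A and D-H...A angle >= 120 deg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .conformers import Conformer, ConformerEnsemble
from .ligand import LigandTopology

__all__ = [
    "FAMILIES",
    "FamilyLabel",
    "OccurrenceTable",
    "compute_d1",
    "classify",
    "detect_hbonds",
    "subfamily_bins",
    "classify_ensemble",
    "occurrence_rates",
]

logger = logging.getLogger(__name__)

FAMILIES = ("folded", "semi-folded", "extended")

_ROTAMER_GRID = (0.0, 60.0, -60.0, 120.0, -120.0, 180.0)

_HBOND_DA_MAX = 3.5     # Angstrom, donor-acceptor heavy atoms
_HBOND_DHA_MIN = 120.0  # degrees


@dataclass(frozen=True)
class FamilyLabel:
    family: str
    subfamily: int


@dataclass
class OccurrenceTable:
    """Occurrence rates (%) of each family, per dielectric mode."""

    counts: dict[tuple[str, str], int]       # (mode, family) -> n
    percentages: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        modes = sorted({m for m, _ in self.counts})
        rows = []
        for m in modes:
            row = {"mode": m}
            for fam in FAMILIES:
                row[fam] = self.percentages.get((m, fam), 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def compute_d1(conformer: Conformer | np.ndarray,
               top: LigandTopology) -> float:
    """Distance between heavy-atom centroids of aryl rings X and Y (A)."""
    coords = (conformer.coordinates if isinstance(conformer, Conformer)
              else np.asarray(conformer, dtype=float))
    cents = []
    for which in ("X", "Y"):
        idx = [a for a in top.ring_atoms(which)
               if top.mol.GetAtomWithIdx(a).GetAtomicNum() > 1]
        if not idx:
            raise ValueError(f"ring {which} has no heavy atoms flagged")
        cents.append(coords[idx].mean(axis=0))
    return float(np.linalg.norm(cents[0] - cents[1]))


def classify(d1: float) -> str:
    """Family from d1: <=5 folded; >5 and <9 semi-folded; >=9 extended."""
    if not math.isfinite(d1) or d1 < 0:
        raise ValueError(f"invalid d1 {d1!r}")
    if d1 <= 5.0:
        return "folded"
    if d1 < 9.0:
        return "semi-folded"
    return "extended"


def detect_hbonds(conformer: Conformer,
                  top: LigandTopology) -> list[tuple[int, int, float]]:
    """Intramolecular H-bonds as (donor_heavy, acceptor, distance) triples.

    Requires explicit hydrogens in the topology (curcumetry topologies always
    carry them).  Donors are O/N with an attached H; acceptors are O/N.  A
    donor-acceptor pair separated by fewer than 3 bonds is skipped (covalent
    neighbourhood, not a hydrogen bond).
    """
    mol = top.mol
    coords = conformer.coordinates
    donors = []  # (heavy, hydrogen)
    acceptors = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            acceptors.append(atom.GetIdx())
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    donors.append((atom.GetIdx(), nb.GetIdx()))
    out = []
    for d_heavy, d_h in donors:
        for acc in acceptors:
            if acc == d_heavy:
                continue
            n_bonds = len(Chem.GetShortestPath(mol, d_heavy, acc)) - 1
            if n_bonds < 3:
                continue
            r_da = float(np.linalg.norm(coords[d_heavy] - coords[acc]))
            if r_da > _HBOND_DA_MAX:
                continue
            v1 = coords[d_heavy] - coords[d_h]
            v2 = coords[acc] - coords[d_h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                       * np.linalg.norm(v2))
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if ang >= _HBOND_DHA_MIN:
                out.append((d_heavy, acc, r_da))
    return out


def _bin_torsion(value: float) -> float:
    best = None
    for g in _ROTAMER_GRID:
        delta = abs((value - g + 180.0) % 360.0 - 180.0)
        # tie at a bin edge goes to the lower absolute angle; grid order
        # already lists lower |angle| first, so strict '<' implements it
        if best is None or delta < best[0] - 1e-9:
            best = (delta, g)
    return best[1]


def subfamily_bins(ensemble: ConformerEnsemble) -> list[int]:
    """Assign subfamily ids (conf I, II, ... as 0, 1, ...) by rotamer binning.

    Conformers sharing every binned torsion belong to the same subfamily
    (+-180 deg are the same rotamer).  Ids are ordered by the energy of each
    subfamily's best conformer; assignments are also written to
    ``conformer.subfamily``.
    """
    def key_of(c: Conformer) -> tuple:
        return tuple(
            abs(_bin_torsion(v)) if abs(_bin_torsion(v)) == 180.0
            else _bin_torsion(v)
            for label, v in c.torsions.items() if label.startswith("tau"))

    keys = [key_of(c) for c in ensemble.conformers]
    order: dict[tuple, int] = {}
    for k in keys:  # ensemble is energy-sorted, so first-seen = lowest E
        if k not in order:
            order[k] = len(order)
    ids = [order[k] for k in keys]
    for c, sid in zip(ensemble.conformers, ids):
        c.subfamily = sid
    for c in ensemble.samples:  # endpoint samples inherit subfamily ids
        k = key_of(c)
        if k in order:
            c.subfamily = order[k]
    return ids


def classify_ensemble(ensemble: ConformerEnsemble, top: LigandTopology,
                      low_energy_window: float | None = None,
                      family_override_by_subfamily: bool = False,
                      ) -> ConformerEnsemble:
    """Fill d1, family, subfamily and H-bond annotations in place.

    ``low_energy_window`` restricts the ensemble to conformers within that
    many kcal/mol of the GM before classification (the conventional window is
    5 kcal/mol).  With ``family_override_by_subfamily`` set, conformers whose
    strict-threshold family disagrees with the majority family of their
    torsional subfamily are reassigned to that majority; every reassignment
    is logged.  This matches the common reporting convention in which a
    torsionally homogeneous subfamily carries a single family label even
    when individual members cross a d1 boundary.
    """
    if low_energy_window is not None:
        kept = ensemble.low_energy(low_energy_window)
        ensemble = ConformerEnsemble(kept, mode=ensemble.mode,
                                     seed=ensemble.seed)
    seen: set[int] = set()
    for c in ensemble.conformers + ensemble.samples:
        if id(c) in seen:
            continue
        seen.add(id(c))
        c.d1 = compute_d1(c, top)
        c.family = classify(c.d1)
        c.hbonds = detect_hbonds(c, top)
    subfamily_bins(ensemble)
    if family_override_by_subfamily:
        by_sub: dict[int, list[Conformer]] = {}
        for c in ensemble.conformers:
            by_sub.setdefault(c.subfamily, []).append(c)
        majority_of = {
            sid: max(set(f := [m.family for m in members]), key=f.count)
            for sid, members in by_sub.items()}
        for c in ensemble.conformers + ensemble.samples:
            maj = majority_of.get(c.subfamily)
            if maj is not None and c.family != maj:
                logger.info("subfamily %s: conformer d1=%.2f reassigned "
                            "%s -> %s", c.subfamily, c.d1, c.family, maj)
                c.family = maj
    return ensemble


def occurrence_rates(*ensembles: ConformerEnsemble,
                     count: str = "samples") -> OccurrenceTable:
    """Percentage of conformers per family, per dielectric mode.

    ``count="samples"`` (default) counts every minimized SA-cycle endpoint,
    the population whose family frequencies the occurrence-rate table
    reports (percentages then come in 1/n_cycles steps);
    ``count="unique"`` counts deduplicated minima instead.  Every conformer
    must already be classified; percentages per mode sum to 100.
    """
    if count not in ("samples", "unique"):
        raise ValueError("count must be 'samples' or 'unique'")
    counts: dict[tuple[str, str], int] = {}
    for ens in ensembles:
        pop = ens.samples if count == "samples" else ens.conformers
        if not pop:
            raise ValueError("empty ensemble")
        for c in pop:
            if c.family is None:
                raise ValueError("ensemble not classified; run "
                                 "classify_ensemble first")
            key = (ens.mode, c.family)
            counts[key] = counts.get(key, 0) + 1
    percentages = {}
    for mode in {m for m, _ in counts}:
        total = sum(n for (m, _), n in counts.items() if m == mode)
        for fam in FAMILIES:
            percentages[(mode, fam)] = 100.0 * counts.get((mode, fam), 0) \
                / total
    return OccurrenceTable(counts=counts, percentages=percentages)
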