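"""Synthetic inputs with known ground truth for every pipeline stage.

Generators return ``(object, truth)`` pairs: the generated artifact plus a
sidecar dictionary holding the exact programmed quantities, so round-trip
tests read the truth only from the sidecar.

The EPR generator models just what the extractor measures — three
first-derivative lines whose outer extrema are programmed at
``B0 +- splitting/2`` — not the underlying spin physics.  The CD generator
emits noisy linear combinations of the shipped basis curves.  Toy molecules
(biphenyl-like chains with 1-3 rotatable bonds and two terminal rings) make
the torsional landscape exhaustively enumerable, and the ideal
Abeta(25-35) helix replaces the experimental NMR structure so no download
is needed.
"""

from __future__ import annotations

import numpy as np

from .cd import CDSpectrum, reference_basis, DEFAULT_WAVELENGTHS
from .epr import EPRSpectrum
from .helix import PeptideStructure, build_ideal_helix
from .ligand import LigandTopology, build_ligand

__all__ = [
    "EPRGenParams",
    "CDGenParams",
    "gen_epr",
    "gen_cd",
    "gen_toy_molecule",
    "gen_abeta_helix",
]

from dataclasses import dataclass

_MAX_SPLITTING = 55.0   # G, fully ordered 5-PCSL-like limit


@dataclass
class EPRGenParams:
    center_field: float = 3350.0   # G (9 GHz band)
    isotropic_A: float = 16.0      # G; order_parameter=0 -> splitting 2A
    order_parameter: float = 0.0   # in [0, 1], monotone -> splitting
    linewidth: float = 3.0         # G, derivative peak-to-peak half-scale
    snr: float = 50.0
    label: str = "5-PCSL"
    composition: str = ""
    sweep_width: float = 100.0
    n_points: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.order_parameter <= 1.0):
            raise ValueError("order_parameter must be in [0, 1]")
        if self.linewidth <= 0 or self.snr <= 0:
            raise ValueError("linewidth and snr must be positive")

    @property
    def outer_splitting(self) -> float:
        base = 2.0 * self.isotropic_A
        return base + self.order_parameter * (_MAX_SPLITTING - base)


@dataclass
class CDGenParams:
    helix: float = 1 / 3
    sheet: float = 1 / 3
    coil: float = 1 - 2 / 3
    noise_sigma: float = 0.0       # fraction of the max |ellipticity|
    sample: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.helix, self.sheet, self.coil)
        if any(f < -1e-9 for f in fr) or abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError("fractions must lie on the simplex")


def _derivative_line(field: np.ndarray, center: float,
                     width: float, amp: float) -> np.ndarray:
    """First derivative of a Gaussian absorption line.

    Extrema sit at ``center +- width``; amplitude normalized so the
    extremum magnitude equals ``amp``.
    """
    z = (field - center) / width
    return -amp * z * np.exp(0.5 * (1.0 - z * z))


def gen_epr(params: EPRGenParams) -> tuple[EPRSpectrum, dict]:
    """Three-line first-derivative nitroxide-like spectrum.

    The outer lines are placed so their outer derivative extrema fall at
    ``center_field +- outer_splitting/2`` — exactly what
    :func:`curcumetry.epr.extract_2amax` measures.
    """
    rng = np.random.default_rng(params.seed)
    b0, w = params.center_field, params.linewidth
    s = params.outer_splitting
    field = np.linspace(b0 - params.sweep_width / 2.0,
                        b0 + params.sweep_width / 2.0, params.n_points)
    # outer extremum of the low-field line at b0 - s/2 => center + w offset
    lo_amp, hi_amp = 0.65, 0.55
    clean = (_derivative_line(field, b0 - s / 2.0 + w, w, lo_amp)
             + _derivative_line(field, b0, w, 1.0)
             + _derivative_line(field, b0 + s / 2.0 - w, w, hi_amp))
    # SNR is referenced to the smallest analyzed feature (the high-field
    # outer extremum): resolvability of the outer lines, not the dominant
    # central line, is what limits the 2A_max measurement
    noise_sigma = min(lo_amp, hi_amp) / params.snr
    intensity = clean + rng.normal(0.0, noise_sigma, size=field.shape)
    spec = EPRSpectrum(field=field, intensity=intensity, label=params.label,
                       composition=params.composition,
                       sweep_width=params.sweep_width,
                       n_points=params.n_points)
    truth = {"outer_splitting_G": s,
             "low_field_max_G": b0 - s / 2.0,
             "high_field_min_G": b0 + s / 2.0,
             "noise_sigma": noise_sigma,
             "order_parameter": params.order_parameter}
    return spec, truth


def gen_cd(params: CDGenParams) -> tuple[CDSpectrum, dict]:
    """Noisy linear combination of the helix/sheet/coil basis curves."""
    rng = np.random.default_rng(params.seed)
    basis = reference_basis(DEFAULT_WAVELENGTHS)
    clean = (params.helix * basis["helix"].to_numpy()
             + params.sheet * basis["sheet"].to_numpy()
             + params.coil * basis["coil"].to_numpy())
    sigma = params.noise_sigma * float(np.max(np.abs(clean)))
    ell = clean + rng.normal(0.0, sigma, size=clean.shape)
    spec = CDSpectrum(wavelength=DEFAULT_WAVELENGTHS.copy(),
                      ellipticity=ell, sample=params.sample)
    truth = {"helix": params.helix, "sheet": params.sheet,
             "coil": params.coil, "noise_sigma": sigma}
    return spec, truth


_TOY_SMILES = {
    1: "c1ccc(-c2ccccc2)cc1",      # biphenyl: one inter-ring torsion
    2: "c1ccc(Cc2ccccc2)cc1",      # diphenylmethane: two torsions
    3: "c1ccc(CCc2ccccc2)cc1",     # bibenzyl: three torsions
}


def gen_toy_molecule(n_torsions: int) -> tuple[LigandTopology, dict]:
    """Two-ring chain molecule with an exhaustively enumerable torsion space.

    ``n_torsions`` rotatable bonds (1-3); a 10-degree grid over them has at
    most 36**3 points, so grid enumeration + minimization provides an exact
    well-set oracle for the annealing sampler.
    """
    if n_torsions not in _TOY_SMILES:
        raise ValueError("n_torsions must be 1, 2 or 3")
    top = build_ligand(_TOY_SMILES[n_torsions], tautomer="toy",
                       name=f"toy{n_torsions}")
    if len(top.rotatable_torsions) != n_torsions:
        raise AssertionError("unexpected torsion count in toy template")
    truth = {"n_torsions": n_torsions,
             "grid_points": 36 ** n_torsions}
    return top, truth


def gen_abeta_helix() -> PeptideStructure:
    """Ideal helical Abeta(25-35) (GSNKGAIIGLM), residues numbered 25-35."""
    return build_ideal_helix("GSNKGAIIGLM", start_resnum=25)
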