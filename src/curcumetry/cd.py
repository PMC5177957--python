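"""Far-UV CD secondary-structure quantification by constrained least squares.

A measured spectrum is modelled as a non-negative linear combination of
three reference basis curves (alpha-helix, beta-sheet, random coil) on a
common wavelength grid; the coefficients, renormalized to sum to one, are
the secondary-structure fractions.  This is a deliberately simple,
fully-documented stand-in for server-based deconvolution suites — it is not
a reimplementation of CONTIN, SELCON or K2D.

The shipped basis is synthetic, with the canonical textbook band shapes:
helix with minima at 208 and 222 nm and a maximum near 192 nm; sheet with a
minimum at 218 nm and maximum near 196 nm; coil with a minimum near 198 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CDSpectrum",
    "SecondaryStructureFractions",
    "reference_basis",
    "deconvolve",
    "compare_conditions",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

DEFAULT_WAVELENGTHS = np.arange(190.0, 260.5, 0.5)


@dataclass
class CDSpectrum:
    wavelength: np.ndarray      # nm, increasing
    ellipticity: np.ndarray     # mean-residue ellipticity, arbitrary scale
    sample: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, float)
        self.ellipticity = np.asarray(self.ellipticity, float)
        if self.wavelength.shape != self.ellipticity.shape:
            raise ValueError("wavelength/ellipticity length mismatch")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelengths must be increasing")
        if self.wavelength[0] > 200.0 or self.wavelength[-1] < 250.0:
            raise ValueError("spectrum must cover at least 200-250 nm")


@dataclass
class SecondaryStructureFractions:
    helix: float
    sheet: float
    coil: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("helix", "sheet", "coil"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name} fraction {v} outside [0, 1]")
        total = self.helix + self.sheet + self.coil
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, expected 1")

    def as_dict(self) -> dict[str, float]:
        return {"helix": self.helix, "sheet": self.sheet, "coil": self.coil}


def _gauss(x: np.ndarray, center: float, width: float,
           amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2)


def reference_basis(wavelength: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic helix/sheet/coil reference curves on the given grid.

    Band positions and signs follow the canonical far-UV shapes; amplitudes
    are in arbitrary mean-residue-ellipticity-like units (scale cancels in
    the sum-to-one normalization).
    """
    wl = DEFAULT_WAVELENGTHS if wavelength is None else np.asarray(
        wavelength, float)
    helix = (_gauss(wl, 192.0, 5.5, 65.0) + _gauss(wl, 208.0, 6.0, -36.0)
             + _gauss(wl, 222.0, 7.5, -33.0))
    sheet = _gauss(wl, 196.0, 5.5, 35.0) + _gauss(wl, 218.0, 8.0, -18.0)
    coil = _gauss(wl, 198.0, 6.5, -42.0) + _gauss(wl, 222.0, 12.0, 3.0)
    return pd.DataFrame({"wavelength_nm": wl, "helix": helix,
                         "sheet": sheet, "coil": coil})


def deconvolve(spec: CDSpectrum,
               basis: pd.DataFrame | None = None
               ) -> SecondaryStructureFractions:
    """Non-negative least squares fit with sum-to-one renormalization.

    The basis must share the spectrum's wavelength grid.  Raises on grid
    mismatch or a singular (all-zero-coefficient) solution.
    """
    basis = reference_basis(spec.wavelength) if basis is None else basis
    grid = basis["wavelength_nm"].to_numpy(float)
    if grid.shape != spec.wavelength.shape or not np.allclose(
            grid, spec.wavelength):
        raise ValueError("basis and spectrum wavelength grids differ")
    a = basis[["helix", "sheet", "coil"]].to_numpy(float)
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("singular basis")
    coefs, rnorm = nnls(a, spec.ellipticity)
    total = float(coefs.sum())
    if total <= 0:
        raise ValueError("degenerate fit: all coefficients zero")
    frac = coefs / total
    return SecondaryStructureFractions(
        helix=float(frac[0]), sheet=float(frac[1]), coil=float(frac[2]),
        residual=float(rnorm))


def compare_conditions(spec_without: CDSpectrum, spec_with: CDSpectrum,
                       basis: pd.DataFrame | None = None,
                       helix_threshold: float = 0.05
                       ) -> tuple[dict[str, float], bool]:
    """Per-class fraction changes upon ligand addition.

    Returns the signed deltas and the helix-stabilizing verdict
    (``True`` iff the helix fraction increases by more than
    ``helix_threshold``, regardless of the other classes).
    """
    f0 = deconvolve(spec_without, basis)
    f1 = deconvolve(spec_with, basis)
    deltas = {k: f1.as_dict()[k] - f0.as_dict()[k] for k in
              ("helix", "sheet", "coil")}
    return deltas, bool(deltas["helix"] > helix_threshold)


def read_spectrum_csv(path: str, sample: str = "") -> CDSpectrum:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return CDSpectrum(wavelength=df.iloc[:, 0].to_numpy(float),
                      ellipticity=df.iloc[:, 1].to_numpy(float),
                      sample=sample)


def write_spectrum_csv(spec: CDSpectrum, path: str) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelength,
                  "ellipticity": spec.ellipticity}).to_csv(path, index=False)
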