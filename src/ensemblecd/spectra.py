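"""Gaussian convolution of stick spectra into molar absorption curves.

Each electronic excitation 0 -> k contributes a Gaussian centred at its
energy E_0k (eV).  With sigma = HWHM / sqrt(ln 2):

    eps(E)  = 2.870e4 * (1 / (sigma sqrt(pi))) * Sum_k f_0k exp(-((E - E_0k)/sigma)^2)

    Deps(E) = [1 / 2.297e-39] * (1 / (sigma sqrt(pi)))
              * Sum_k R_0k E_0k exp(-((E - E_0k)/sigma)^2)

in M^-1 cm^-1, with f_0k the (dimensionless) oscillator strength and R_0k
the rotatory strength in raw cgs units.  TDDFT codes print R in 1e-40 cgs,
which is the package's file convention; values are rescaled internally
before the 2.297e-39 prefactor is applied.

The weighted ensemble spectrum is the pointwise weighted sum over
conformations/clusters, renormalized by default because the basin weights
P(i) (or p(j,i)) sum to less than 1 when frames fall outside all basins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, NumericalError, StructuralError

logger = logging.getLogger(__name__)

#: photoabsorption prefactor (M^-1 cm^-1 eV)
EPSILON_PREFACTOR = 2.870e4
#: circular-dichroism prefactor denominator (cgs)
CD_PREFACTOR_DENOM = 2.297e-39
#: nm <-> eV conversion (CODATA-consistent)
EV_NM = 1239.84193

#: default broadening (eV); 0.4 reproduces the tripeptide resolution,
#: 0.3 the decapeptide one
DEFAULT_HWHM_EV = 0.4

STICK_COLUMNS = ("E_eV", "f", "R_1e-40cgs")


@dataclass(frozen=True)
class Stick:
    """One excitation: energy (eV), oscillator strength, rotatory strength
    (in 1e-40 cgs by file convention)."""

    energy: float
    oscillator: float
    rotatory: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise DataError(f"excitation energy must be positive, got {self.energy}")
        if self.oscillator < 0:
            raise DataError(f"oscillator strength must be >= 0, got {self.oscillator}")


@dataclass
class StickSpectrum:
    """Sticks of one conformation/cluster, sorted by energy, with its weight."""

    label: str
    sticks: list[Stick]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise DataError(f"weight must be >= 0, got {self.weight}")
        self.sticks = sorted(self.sticks, key=lambda s: s.energy)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.sticks])

    @property
    def oscillators(self) -> np.ndarray:
        return np.array([s.oscillator for s in self.sticks])

    @property
    def rotatories(self) -> np.ndarray:
        return np.array([s.rotatory for s in self.sticks])


def sigma_from_hwhm(hwhm: float) -> float:
    """Gaussian width sigma = HWHM / sqrt(ln 2) (eV)."""
    if hwhm <= 0:
        raise ValueError(f"HWHM must be positive, got {hwhm}")
    return hwhm / np.sqrt(np.log(2.0))


def hwhm_from_sigma(sigma: float) -> float:
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * np.sqrt(np.log(2.0))


@dataclass(frozen=True)
class Lineshape:
    """Gaussian lineshape parameterized by its half width at half maximum."""

    hwhm: float

    @property
    def sigma(self) -> float:
        return sigma_from_hwhm(self.hwhm)


@dataclass
class ConvolvedSpectrum:
    """eps/Deps curves on a uniform, strictly increasing energy grid (eV)."""

    energies: np.ndarray
    epsilon: np.ndarray
    delta_epsilon: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.energies) <= 0):
            raise StructuralError("energy grid must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        return EV_NM / self.energies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"E_eV": self.energies, "lambda_nm": self.wavelengths,
             "epsilon": self.epsilon, "delta_epsilon": self.delta_epsilon}
        )


def default_grid(lambda_min_nm: float = 170.0, lambda_max_nm: float = 260.0,
                 n_points: int = 2000) -> np.ndarray:
    """Uniform energy grid (eV) spanning the given wavelength window."""
    if not 0 < lambda_min_nm < lambda_max_nm:
        raise ValueError("need 0 < lambda_min < lambda_max")
    return np.linspace(EV_NM / lambda_max_nm, EV_NM / lambda_min_nm, n_points)


def _check_coverage(grid: np.ndarray, energies: np.ndarray, sigma: float) -> None:
    if energies.size == 0:
        return
    if grid[0] > energies.min() - 5 * sigma or grid[-1] < energies.max() + 5 * sigma:
        warnings.warn(
            "energy grid does not cover all sticks +/- 5 sigma; "
            "band tails will be truncated",
            stacklevel=3,
        )


def _gaussian_sum(grid: np.ndarray, energies: np.ndarray,
                  amplitudes: np.ndarray, sigma: float) -> np.ndarray:
    if energies.size == 0:
        return np.zeros_like(grid)
    arg = (grid[:, None] - energies[None, :]) / sigma
    return (np.exp(-arg * arg) @ amplitudes) / (sigma * np.sqrt(np.pi))


def convolve_absorption(sticks: StickSpectrum, shape: Lineshape,
                        grid: np.ndarray) -> np.ndarray:
    """Molar absorptivity eps(E) (M^-1 cm^-1) from oscillator strengths."""
    grid = np.asarray(grid, dtype=float)
    _check_coverage(grid, sticks.energies, shape.sigma)
    return EPSILON_PREFACTOR * _gaussian_sum(
        grid, sticks.energies, sticks.oscillators, shape.sigma
    )


def convolve_cd(sticks: StickSpectrum, shape: Lineshape, grid: np.ndarray,
                rotatory_units: str = "1e-40cgs") -> np.ndarray:
    """Circular dichroism Deps(E) (M^-1 cm^-1) from rotatory strengths.

    ``rotatory_units`` declares the unit the stick table carries:
    ``"1e-40cgs"`` (the TDDFT-output convention, default) or ``"raw_cgs"``.
    """
    grid = np.asarray(grid, dtype=float)
    _check_coverage(grid, sticks.energies, shape.sigma)
    if rotatory_units == "1e-40cgs":
        R_cgs = sticks.rotatories * 1e-40
    elif rotatory_units == "raw_cgs":
        R_cgs = sticks.rotatories
    else:
        raise ValueError(f"unknown rotatory_units {rotatory_units!r}")
    amplitudes = R_cgs * sticks.energies
    return _gaussian_sum(grid, sticks.energies, amplitudes, shape.sigma) / CD_PREFACTOR_DENOM


def convolve(sticks: StickSpectrum, shape: Lineshape, grid: np.ndarray,
             rotatory_units: str = "1e-40cgs") -> ConvolvedSpectrum:
    """Both eps and Deps of one stick spectrum on a common grid."""
    return ConvolvedSpectrum(
        energies=np.asarray(grid, dtype=float),
        epsilon=convolve_absorption(sticks, shape, grid),
        delta_epsilon=convolve_cd(sticks, shape, grid, rotatory_units),
        label=sticks.label,
    )


def combine_weighted(spectra: list[ConvolvedSpectrum], weights,
                     renormalize: bool = True) -> ConvolvedSpectrum:
    """Pointwise weighted sum of spectra sharing one grid.

    With ``renormalize`` (default) the result is divided by the weight sum,
    turning basin weights that sum below 1 into a proper ensemble average.
    """
    if not spectra:
        raise DataError("no spectra to combine")
    w = np.asarray(weights, dtype=float)
    if w.size != len(spectra):
        raise DataError(f"{len(spectra)} spectra but {w.size} weights")
    if np.any(w < 0) or not np.any(w > 0):
        raise DataError("weights must be non-negative with a positive sum")
    grid = spectra[0].energies
    for s in spectra[1:]:
        if s.energies.shape != grid.shape or not np.array_equal(s.energies, grid):
            raise StructuralError(
                "spectra are on different energy grids; no silent resampling"
            )
    eps = sum(wi * s.epsilon for wi, s in zip(w, spectra))
    deps = sum(wi * s.delta_epsilon for wi, s in zip(w, spectra))
    if renormalize:
        eps = eps / w.sum()
        deps = deps / w.sum()
    return ConvolvedSpectrum(energies=grid.copy(), epsilon=eps,
                             delta_epsilon=deps, label="ensemble")


def half_width_check(spectrum: ConvolvedSpectrum, channel: str = "epsilon") -> float:
    """Realized half width at half maximum of a single-band spectrum (eV).

    Bisects along the grid for the offset |E - E_peak| at which the
    intensity first drops to half the peak, on the high-energy side.
    """
    y = np.abs(getattr(spectrum, channel))
    E = spectrum.energies
    i_peak = int(np.argmax(y))
    half = y[i_peak] / 2.0
    tail = y[i_peak:]
    below = np.flatnonzero(tail <= half)
    if below.size == 0 or y[i_peak] == 0:
        raise NumericalError("grid too coarse/short to bracket the half maximum")
    j = i_peak + below[0]
    # linear interpolation between the bracketing grid points
    if j == i_peak:
        return 0.0
    E_half = np.interp(half, [y[j], y[j - 1]], [E[j], E[j - 1]])
    return float(E_half - E[i_peak])


# ---------------------------------------------------------------------------
# stick-table I/O: CSV with header E_eV,f,R_1e-40cgs
# ---------------------------------------------------------------------------

def read_sticks(path: str | Path, label: str | None = None,
                weight: float = 1.0) -> StickSpectrum:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not read stick table {path}: {exc}") from exc
    missing = [c for c in STICK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} lacks column(s) {missing}; expected "
                          f"header {','.join(STICK_COLUMNS)}")
    sticks = [
        Stick(energy=float(e), oscillator=float(f), rotatory=float(r))
        for e, f, r in zip(df["E_eV"], df["f"], df["R_1e-40cgs"])
    ]
    return StickSpectrum(label=label or path.stem, sticks=sticks, weight=weight)


def write_sticks(spectrum: StickSpectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "E_eV": spectrum.energies,
            "f": spectrum.oscillators,
            "R_1e-40cgs": spectrum.rotatories,
        }
    )
    df.to_csv(path, index=False)
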