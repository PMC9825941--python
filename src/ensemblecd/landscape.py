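"""Free-energy landscape on the essential plane and basin statistics.

The 2-D density of the principal components is histogrammed, converted to
a relative free energy

    F(cell) = -RT ln( n(cell) / n(max cell) )   [kJ/mol, min cell at 0]

and the conformational basins are taken as the 4-connected components of
cells at or below a free-energy cutoff (default 3 kJ/mol, the window from
which representative structures are drawn).  The statistical weight of
basin i is P(i) = member frames / total frames, and its free energy
relative to the most populated basin follows

    P(i) = P_ref * exp(-dG_i / RT)   <=>   dG_i = -RT ln(P(i)/P_ref).

Note Sum_i P(i) <= 1: frames whose cells lie above the cutoff stay
unassigned; weights are renormalized only at the spectra stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InsufficientDataError, NumericalError
from .essential_dynamics import Projection

logger = logging.getLogger(__name__)

#: gas constant in kJ/(mol K)
GAS_CONSTANT_KJ = 8.31446e-3

DEFAULT_BINS = (100, 100)
DEFAULT_CUTOFF_KJ = 3.0

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic state: absolute temperature (K) and R (kJ/(mol K))."""

    temperature: float
    gas_constant: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature} K")

    @classmethod
    def from_celsius(cls, celsius: float) -> "Thermo":
        return cls(temperature=celsius + 273.15)

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class LandscapeGrid:
    """Histogram of the essential plane with per-cell free energies.

    ``free_energy`` is in kJ/mol relative to the most populated cell; empty
    cells carry +inf.  ``frame_cells`` maps every frame to its (i, j) cell.
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    frame_cells: np.ndarray
    thermo: Thermo

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        return cx, cy

    def to_frame(self) -> pd.DataFrame:
        """Free-energy matrix as a DataFrame (rows = proj-1 bins)."""
        return pd.DataFrame(self.free_energy)


@dataclass
class Basin:
    """A connected low-free-energy region of the landscape."""

    id: str
    cells: list[tuple[int, int]]
    frame_indices: np.ndarray
    population: float
    delta_G: float
    representatives: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return int(self.frame_indices.size)


def free_energy(P_i: float, P_ref: float, thermo: Thermo) -> float:
    """Relative free energy (kJ/mol) of a basin with weight ``P_i`` against a
    reference with weight ``P_ref``: dG = -RT ln(P_i / P_ref)."""
    if P_i <= 0 or P_ref <= 0:
        raise ValueError(f"probabilities must be positive (got {P_i}, {P_ref})")
    return float(-thermo.RT * np.log(P_i / P_ref))


def build_grid(proj: Projection, bins=DEFAULT_BINS, thermo: Thermo | None = None) -> LandscapeGrid:
    """Histogram the first two projection components and attach free energies.

    Bins are half-open over [min, max] per axis with the last bin closed
    (numpy convention), so every frame lands in exactly one cell.
    """
    if thermo is None:
        thermo = Thermo.from_celsius(30.0)
    comps = proj.components
    if comps.shape[0] < 2:
        raise InsufficientDataError("landscape needs at least 2 frames")
    if comps.shape[1] < 2:
        raise NumericalError("landscape needs 2 projection components")
    bx, by = (bins, bins) if np.isscalar(bins) else bins
    if bx < 2 or by < 2:
        raise ValueError(f"need >= 2 bins per axis, got {bins}")
    x, y = comps[:, 0], comps[:, 1]
    counts, ex, ey = np.histogram2d(x, y, bins=(bx, by))
    counts = counts.astype(int)

    n_max = counts.max()
    if counts[counts > 0].size == 1 or (counts == counts.sum()).any():
        logger.warning("degenerate landscape: all frames fall in a single cell")
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -thermo.RT * np.log(counts / n_max), np.inf)
    F = np.where(counts > 0, np.maximum(F, 0.0), np.inf)

    # per-frame cell assignment consistent with histogram2d's binning
    ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, bx - 1)
    iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, by - 1)
    frame_cells = np.column_stack([ix, iy])
    return LandscapeGrid(edges_x=ex, edges_y=ey, counts=counts, free_energy=F,
                         frame_cells=frame_cells, thermo=thermo)


def detect_basins(grid: LandscapeGrid, cutoff: float = DEFAULT_CUTOFF_KJ) -> list[Basin]:
    """Basins = 4-connected components of populated cells with F <= cutoff.

    Basins are labelled B1, B2, ... in order of decreasing population; the
    most populated one is the free-energy reference (dG = 0).  Frames in
    cells above the cutoff are left unassigned, so Sum P(i) <= 1.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    mask = (grid.counts > 0) & (grid.free_energy <= cutoff)
    labels, n_basins = ndimage.label(mask, structure=_FOUR_CONNECTED)
    if n_basins == 0:  # cannot happen: the max-count cell always has F = 0
        raise NumericalError("no cell below the basin cutoff")

    frame_labels = labels[grid.frame_cells[:, 0], grid.frame_cells[:, 1]]
    total = grid.frame_cells.shape[0]

    raw = []
    for lab in range(1, n_basins + 1):
        frames = np.flatnonzero(frame_labels == lab)
        cells = [tuple(c) for c in np.argwhere(labels == lab)]
        raw.append((frames, cells))
    # order by population, ties by lowest first frame index for determinism
    raw.sort(key=lambda t: (-t[0].size, t[0][0] if t[0].size else np.inf))

    P_ref = raw[0][0].size / total
    basins = []
    for rank, (frames, cells) in enumerate(raw, start=1):
        P_i = frames.size / total
        dG = free_energy(P_i, P_ref, grid.thermo) if P_i > 0 else np.inf
        basins.append(Basin(id=f"B{rank}", cells=cells, frame_indices=frames,
                            population=P_i, delta_G=dG))
    assigned = sum(b.population for b in basins)
    logger.info("detected %d basin(s); assigned weight %.4f (unassigned %.4f)",
                len(basins), assigned, 1.0 - assigned)
    return basins


def select_representatives(basin: Basin, proj: Projection, k: int = 1,
                           seed: int = 0) -> list[int]:
    """Representative frame indices for a basin.

    ``k`` = 1: the member frame whose projection is closest to the basin
    centroid in the essential plane.  ``k`` > 1: k-means over the member
    projections with a fixed seed, returning the medoid of each cluster
    (member minimizing the summed in-cluster distance).  All ties break to
    the lowest frame index.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    members = basin.frame_indices
    if members.size == 0:
        raise InsufficientDataError(f"basin {basin.id} has no member frames")
    if k > members.size:
        logger.warning("basin %s has %d frames < k=%d; reducing k",
                       basin.id, members.size, k)
        k = int(members.size)
    pts = proj.components[members, :2]

    if k == 1:
        centroid = pts.mean(axis=0)
        d2 = np.sum((pts - centroid) ** 2, axis=1)
        return [int(members[int(np.argmin(d2))])]  # argmin takes first on ties

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    cluster_of = km.fit_predict(pts)
    reps = []
    for c in range(k):
        in_c = np.flatnonzero(cluster_of == c)
        sub = pts[in_c]
        if sub.shape[0] > 5000:
            # medoid cost is quadratic; chunk the distance accumulation
            cost = np.zeros(sub.shape[0])
            for start in range(0, sub.shape[0], 1000):
                block = sub[start:start + 1000]
                cost += np.linalg.norm(sub[:, None, :] - block[None, :, :],
                                       axis=2).sum(axis=1)
        else:
            cost = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2).sum(axis=1)
        reps.append(int(members[in_c[int(np.argmin(cost))]]))
    return sorted(reps)


def basin_report(basins: list[Basin]) -> pd.DataFrame:
    """Per-basin summary table (CSV-ready)."""
    return pd.DataFrame(
        {
            "id": [b.id for b in basins],
            "n_frames": [b.n_frames for b in basins],
            "P": [b.population for b in basins],
            "delta_G_kJmol": [b.delta_G for b in basins],
            "representatives": [
                ";".join(str(i + 1) for i in b.representatives) for b in basins
            ],  # 1-based frame numbers in reports
        }
    )
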