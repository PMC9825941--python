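"""Seed-deterministic synthetic fixtures with known ground truth.

Three generators mirror the three kinds of input the pipeline consumes:

* a multi-conformer bead-chain trajectory sampled from a Markov chain with
  prescribed stationary populations (ground truth for basin weights and
  Boltzmann-relation free energies),
* a constrained solvated trajectory: frozen solute at the centre of a
  periodic cubic box, water-like 3-site solvent whose inner shell switches
  between two arrangements with known occupancies (ground truth for the
  hierarchical cluster weights p(j,i)),
* per-conformer stick spectra (reproducible stand-ins for excited-state
  calculations).

Every generator returns its true labels so recovery tests can compare
pipeline output against the generating parameters.  The dynamics are not
physical: conformers are rigid templates plus isotropic Gaussian noise,
and solvent has no interactions beyond a minimum-distance constraint.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DataError
from .spectra import Stick, StickSpectrum
from .trajectory_io import AtomRecord, Frame, Trajectory

logger = logging.getLogger(__name__)

MIN_SOLVENT_DIST_NM = 0.15
OH_BOND_NM = 0.0957
HOH_ANGLE_DEG = 104.5

_BACKBONE_NAMES = ("N", "CA", "C")
_TRIPEPTIDE_RESNAMES = ("GLY", "ALA", "GLY")


# ---------------------------------------------------------------------------
# toy solute: a 9-bead tripeptide backbone in two reference conformations
# ---------------------------------------------------------------------------

def tripeptide_topology() -> list[AtomRecord]:
    """N/CA/C beads of a 3-residue chain (one molecule)."""
    records = []
    for res, resname in enumerate(_TRIPEPTIDE_RESNAMES, start=1):
        for name in _BACKBONE_NAMES:
            records.append(
                AtomRecord(index=len(records), name=name, residue_name=resname,
                           residue_index=res, molecule_id=0,
                           element="N" if name == "N" else "C")
            )
    return records


def _extended_chain(n_beads: int = 9, spacing: float = 0.13) -> np.ndarray:
    """Zig-zag chain along x, emulating an extended (beta-strand-like) shape."""
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = np.arange(n_beads) * spacing
    coords[:, 1] = 0.05 * (-1.0) ** np.arange(n_beads)
    return coords - coords.mean(axis=0)


def _folded_chain(n_beads: int = 9, radius: float = 0.25) -> np.ndarray:
    """Beads on a 3/4 circular arc, emulating a compact (pPII-like) shape."""
    theta = np.linspace(0.0, 1.5 * np.pi, n_beads)
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), 0.03 * np.arange(n_beads)]
    )
    return coords - coords.mean(axis=0)


@dataclass
class ConformerSpec:
    """Markov-chain conformer generator parameters.

    ``transition`` defaults to i.i.d. sampling (every row equal to the
    stationary vector); when given it must be row-stochastic and admit
    ``stationary`` as its stationary distribution.
    """

    references: np.ndarray = field(
        default_factory=lambda: np.stack([_folded_chain(), _extended_chain()])
    )
    stationary: np.ndarray = field(default_factory=lambda: np.array([0.7, 0.3]))
    transition: np.ndarray | None = None
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.references = np.asarray(self.references, dtype=float)
        self.stationary = np.asarray(self.stationary, dtype=float)
        k = self.references.shape[0]
        if self.stationary.shape != (k,):
            raise ConfigError(
                f"{k} conformers but stationary vector of shape {self.stationary.shape}"
            )
        if not np.isclose(self.stationary.sum(), 1.0, atol=1e-10):
            raise ConfigError("stationary probabilities must sum to 1")
        if self.transition is None:
            self.transition = np.tile(self.stationary, (k, 1))
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (k, k) or np.any(self.transition < 0):
            raise ConfigError("transition matrix must be a non-negative k x k matrix")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-10):
            raise ConfigError("transition matrix rows must sum to 1")
        if not np.allclose(self.stationary @ self.transition, self.stationary,
                           atol=1e-10):
            raise ConfigError(
                "transition matrix does not admit the stated stationary vector"
            )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def gen_conformer_trajectory(spec: ConformerSpec, n_frames: int
                             ) -> tuple[Trajectory, np.ndarray]:
    """Sample a trajectory from the conformer Markov chain.

    Each frame is its conformer's reference structure plus isotropic
    Gaussian noise, under a uniformly random rigid motion (which the
    superposition stage must remove).  Returns the trajectory and the true
    per-frame conformer labels.
    """
    if n_frames < 100:
        raise ConfigError(f"need n_frames >= 100, got {n_frames}")
    rng = np.random.default_rng(spec.seed)
    k = spec.references.shape[0]

    labels = np.empty(n_frames, dtype=int)
    cum = np.cumsum(spec.transition, axis=1)
    labels[0] = np.searchsorted(np.cumsum(spec.stationary), rng.random())
    u = rng.random(n_frames)
    for f in range(1, n_frames):
        labels[f] = np.searchsorted(cum[labels[f - 1]], u[f])
    labels = np.clip(labels, 0, k - 1)

    n_beads = spec.references.shape[1]
    frames = []
    for f in range(n_frames):
        coords = spec.references[labels[f]] + spec.noise_sigma * rng.standard_normal(
            (n_beads, 3)
        )
        R = _random_rotation(rng)
        t = rng.uniform(-0.5, 0.5, 3)
        frames.append(Frame(coordinates=coords @ R.T + t, box=None, time=float(f)))
    topology = tripeptide_topology()
    if n_beads != len(topology):
        topology = [
            AtomRecord(index=i, name="CA", residue_name="GLY", residue_index=i + 1,
                       molecule_id=0, element="C")
            for i in range(n_beads)
        ]
    traj = Trajectory(topology=topology, frames=frames)
    return traj, labels


# ---------------------------------------------------------------------------
# constrained solvated trajectory
# ---------------------------------------------------------------------------

@dataclass
class SolventSpec:
    """Two-state solvation-shell generator parameters.

    ``n_shell`` molecules sit on a spherical shell whose radius switches
    between ``shell_radii[0]`` and ``shell_radii[1]`` according to a
    frame-level state drawn i.i.d. with probabilities ``occupancies``; the
    remaining molecules are bulk, fixed up to jitter.  The density default
    (600 molecules in a 2.7 nm box) is liquid-like.
    """

    n_molecules: int = 600
    box: float = 2.7
    shell_radii: tuple[float, float] = (0.55, 0.85)
    occupancies: tuple[float, float] = (1.0, 0.0)
    n_shell: int = 8
    jitter: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        if np.any(occ < 0) or np.any(occ > 1) or not np.isclose(occ.sum(), 1.0):
            raise ConfigError("occupancies must lie in [0,1] and sum to 1")
        r0, r1 = self.shell_radii
        if r0 <= 0 or r1 <= 0 or abs(r1 - r0) < 4 * self.jitter + MIN_SOLVENT_DIST_NM / 2:
            raise ConfigError("shell radii must be positive and non-overlapping")
        if self.n_shell > self.n_molecules:
            raise ConfigError("n_shell exceeds n_molecules")


def _water_sites(o_positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rigid 3-site waters (O, H, H) with fixed random orientations, (M, 3, 3)."""
    m = o_positions.shape[0]
    out = np.empty((m, 3, 3))
    half = np.deg2rad(HOH_ANGLE_DEG) / 2
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [OH_BOND_NM * np.sin(half), OH_BOND_NM * np.cos(half), 0.0],
            [-OH_BOND_NM * np.sin(half), OH_BOND_NM * np.cos(half), 0.0],
        ]
    )
    for i in range(m):
        R = _random_rotation(rng)
        out[i] = o_positions[i] + local @ R.T
    return out


def _place_bulk(rng, n, box, forbidden, min_dist):
    """Random O sites in the box keeping min_dist (periodic) from each other
    and from ``forbidden`` points; rejection sampling with a retry budget."""
    forbidden = np.asarray(forbidden, dtype=float).reshape(-1, 3)
    pool = np.empty((forbidden.shape[0] + n, 3))
    pool[: forbidden.shape[0]] = forbidden
    count = forbidden.shape[0]
    target = forbidden.shape[0] + n
    budget = 300 * n + 1000
    while count < target and budget > 0:
        budget -= 1
        p = rng.uniform(0.0, box, 3)
        d = pool[:count] - p
        d -= box * np.round(d / box)
        if np.min(np.einsum("ij,ij->i", d, d)) >= min_dist**2:
            pool[count] = p
            count += 1
    if count < target:
        raise DataError(
            f"could not place {n} solvent molecules at density "
            f"{n / box**3:.1f} nm^-3 without overlaps"
        )
    return pool[forbidden.shape[0]:]


def gen_solvated_constrained(spec: SolventSpec, solute: np.ndarray,
                             n_frames: int) -> tuple[Trajectory, np.ndarray]:
    """Frozen solute at the box centre surrounded by switching-shell waters.

    Returns the trajectory (solute first, then ``n_molecules`` SOL
    residues) and the true per-frame shell state (0 or 1).
    """
    solute = np.asarray(solute, dtype=float)
    center = np.full(3, spec.box / 2.0)
    solute = solute - solute.mean(axis=0) + center
    if np.any(solute < 0) or np.any(solute > spec.box):
        raise DataError("solute does not fit in the box")
    rng = np.random.default_rng(spec.seed)

    # fixed angular positions for the switchable shell (same directions in
    # both states, radius switches) => two well-separated solvent basins;
    # directions are kept mutually separated so shell waters never overlap
    min_chord = MIN_SOLVENT_DIST_NM / min(spec.shell_radii)
    for _ in range(1000):
        dirs = rng.standard_normal((spec.n_shell, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pairwise = np.linalg.norm(dirs[:, None, :] - dirs[None, :, :], axis=2)
        np.fill_diagonal(pairwise, np.inf)
        if pairwise.min() >= min_chord:
            break
    else:
        raise DataError("could not place shell molecules without overlaps")
    shell_sites = {
        s: center + r * dirs for s, r in enumerate(spec.shell_radii)
    }
    forbidden = np.concatenate(
        [solute, shell_sites[0], shell_sites[1]]
    )
    n_bulk = spec.n_molecules - spec.n_shell
    bulk = _place_bulk(rng, n_bulk, spec.box, forbidden, MIN_SOLVENT_DIST_NM)

    states = (rng.random(n_frames) >= spec.occupancies[0]).astype(int)

    # fixed orientations per molecule (rigid waters)
    base_sites = np.concatenate([shell_sites[0], bulk])
    orientations_seed = rng.integers(0, 2**31 - 1)

    topology = []
    for a in tripeptide_topology() if solute.shape[0] == 9 else [
        AtomRecord(index=i, name="CA", residue_name="GLY", residue_index=i + 1,
                   molecule_id=0, element="C") for i in range(solute.shape[0])
    ]:
        topology.append(a)
    n_res0 = max(a.residue_index for a in topology)
    for m in range(spec.n_molecules):
        for name, element in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            topology.append(
                AtomRecord(index=len(topology), name=name, residue_name="SOL",
                           residue_index=n_res0 + m + 1, molecule_id=m + 1,
                           element=element)
            )

    frames = []
    for f in range(n_frames):
        sites = np.concatenate([shell_sites[states[f]], bulk])
        waters = _water_sites(sites, np.random.default_rng([orientations_seed]))
        waters = waters + spec.jitter * rng.standard_normal(waters.shape)
        coords = np.concatenate([solute, waters.reshape(-1, 3)])
        frames.append(Frame(coordinates=coords, box=spec.box, time=float(f)))
    traj = Trajectory(topology=topology, frames=frames)
    return traj, states


# ---------------------------------------------------------------------------
# stick spectra
# ---------------------------------------------------------------------------

def gen_stick_spectrum(label: str, n_sticks: int = 70,
                       energy_range: tuple[float, float] = (4.8, 7.3),
                       seed: int = 0) -> StickSpectrum:
    """Reproducible random stick spectrum; distinct labels give distinct
    spectra at the same seed (label hashed into the stream)."""
    if n_sticks < 1:
        raise ConfigError(f"need n_sticks >= 1, got {n_sticks}")
    lo, hi = energy_range
    if not 0 < lo < hi:
        raise ConfigError(f"bad energy range {energy_range}")
    rng = np.random.default_rng([seed, zlib.crc32(label.encode())])
    energies = np.sort(rng.uniform(lo, hi, n_sticks))
    oscillators = rng.uniform(0.0, 0.3, n_sticks)
    rotatories = rng.normal(0.0, 10.0, n_sticks)
    sticks = [Stick(energy=float(e), oscillator=float(f), rotatory=float(r))
              for e, f, r in zip(energies, oscillators, rotatories)]
    return StickSpectrum(label=label, sticks=sticks)
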