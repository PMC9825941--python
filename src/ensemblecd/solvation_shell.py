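"""Chromophore-solvent cluster extraction and hierarchical weighting.

A constrained trajectory (solute frozen at the box centre) samples solvent
arrangements around one solute conformation i of free-MD weight P(i).  Per
frame the N solvent molecules with the smallest squared distance in the
metric of the solute-shaped ellipsoid,

    m(x) = Sum_k ( (x - c) . u_k / a_k )^2 ,

are extracted (c: solute geometric centre, u_k: principal directions of
the solute's single-structure positional covariance, a_k: max projection
of the solute onto u_k plus an optional padding).  Essential dynamics on
the slot-ordered solvent site coordinates of the resulting cluster
trajectory yields solvent-shell basins j with weights

    p(j, i) = (basin-j frame fraction within constrained MD) * P(i) ,

so that Sum_j p(j, i) = P(i) when every frame is basin-assigned.

Slot ordering (ascending metric per frame) resolves the relabelling
ambiguity of identical solvent molecules; identity swaps between
equal-metric shells blur the cluster covariance and are accepted as an
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, StructuralError
from .essential_dynamics import EDModel, ed_from_matrix, project_matrix
from .landscape import (
    DEFAULT_BINS,
    DEFAULT_CUTOFF_KJ,
    Basin,
    Thermo,
    build_grid,
    detect_basins,
    free_energy,
)
from .trajectory_io import (
    SOLVENT_RESNAMES,
    Selection,
    Trajectory,
    minimum_image,
)

logger = logging.getLogger(__name__)

FROZEN_TOL_NM = 1e-6


@dataclass(frozen=True)
class Ellipsoid:
    """Solute-shaped ellipsoid: centre (nm), orthonormal axes (rows of
    ``axes_units``), semi-axes sorted descending (nm)."""

    center: np.ndarray
    axes_units: np.ndarray
    semi_axes: np.ndarray


def build_ellipsoid(solute_coords: np.ndarray, padding: float = 0.0) -> Ellipsoid:
    """Ellipsoid best describing the solute shape.

    Axes are the eigenvectors of the single-structure positional covariance
    (gyration tensor); semi-axis k is the maximum |projection| of any solute
    atom onto axis k, plus ``padding``.  A planar/linear solute gets its
    vanishing semi-axes floored at ``padding`` (warned).
    """
    coords = np.asarray(solute_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise StructuralError("ellipsoid needs >= 3 solute atoms")
    center = coords.mean(axis=0)
    centered = coords - center
    gyration = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(gyration)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows are unit axes, largest variance first

    semi = np.abs(centered @ axes.T).max(axis=0) + padding
    floor = max(padding, 1e-9)
    if np.any(semi < floor):
        logger.warning("degenerate solute shape: flooring semi-axes at %.3g nm", floor)
        semi = np.maximum(semi, floor)
    order2 = np.argsort(semi)[::-1]
    return Ellipsoid(center=center, axes_units=axes[order2], semi_axes=semi[order2])


def ellipsoid_metric(e: Ellipsoid, point: np.ndarray, box: float) -> float | np.ndarray:
    """Dimensionless squared distance of ``point`` (or (..., 3) points) from
    the ellipsoid centre, minimum-imaged in the cubic box; 1 on the surface."""
    delta = minimum_image(np.asarray(point, dtype=float) - e.center, box)
    proj = delta @ e.axes_units.T
    m = np.sum((proj / e.semi_axes) ** 2, axis=-1)
    return float(m) if np.ndim(m) == 0 else m


@dataclass
class ClusterFrame:
    """Frozen solute plus the N nearest solvent molecules of one frame.

    Solvent molecules are slot-ordered by ascending ellipsoid metric;
    coordinates are minimum-image shifted as rigid units into the
    solute-centred cell.
    """

    solute_coordinates: np.ndarray
    molecule_ids: np.ndarray
    solvent_coordinates: np.ndarray  # (N, atoms_per_molecule, 3) nm
    site_coordinates: np.ndarray     # (N, 3) nm, the ranked site per molecule
    metrics: np.ndarray              # (N,) ascending

    @property
    def n_solvent(self) -> int:
        return int(self.molecule_ids.size)


class WeightTree:
    """Hierarchical weights p(j, i) of solvent basin j around conformation i.

    Rows accumulate across conformations; ``delta_G`` is evaluated against
    the globally most probable cluster basin.
    """

    def __init__(self) -> None:
        self._rows: list[dict] = []

    def add(self, conformation_id: str, basin_id: str, P_i: float, p_ji: float) -> None:
        self._rows.append(
            {"conformation_id": conformation_id, "basin_id": basin_id,
             "P_i": P_i, "p_ji": p_ji}
        )

    def to_frame(self, thermo: Thermo | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self._rows,
                          columns=["conformation_id", "basin_id", "P_i", "p_ji"])
        if thermo is not None and len(df):
            p_ref = df["p_ji"].max()
            df["delta_G_kJmol"] = [
                free_energy(p, p_ref, thermo) if p > 0 else np.inf
                for p in df["p_ji"]
            ]
        return df

    def labels(self) -> list[str]:
        return [f"{r['conformation_id']}/{r['basin_id']}" for r in self._rows]

    def weights(self) -> np.ndarray:
        return np.array([r["p_ji"] for r in self._rows], dtype=float)

    def conservation_deficit(self, conformation_id: str, P_i: float) -> float:
        s = sum(r["p_ji"] for r in self._rows
                if r["conformation_id"] == conformation_id)
        return P_i - s


def _solvent_molecules(traj: Trajectory, solvent_resnames=SOLVENT_RESNAMES):
    """Molecule ids (sorted) recognized as solvent, with their atom indices."""
    by_mol: dict[int, list[int]] = {}
    for atom in traj.topology:
        if atom.residue_name in solvent_resnames:
            by_mol.setdefault(atom.molecule_id, []).append(atom.index)
    if not by_mol:
        raise DataError("no solvent molecules found (residue names "
                        f"{sorted(solvent_resnames)})")
    mol_ids = sorted(by_mol)
    sizes = {len(v) for v in by_mol.values()}
    if len(sizes) != 1:
        raise StructuralError(f"solvent molecules differ in size: {sorted(sizes)}")
    atom_idx = np.array([by_mol[m] for m in mol_ids], dtype=int)  # (M, s)
    return np.array(mol_ids), atom_idx


def _site_positions(coords_mol: np.ndarray, names: list[str], policy: str) -> np.ndarray:
    """Ranking site per molecule: water oxygen or centre of geometry.

    ``coords_mol`` is (M, s, 3); ``names`` the per-molecule atom names.
    """
    if policy == "oxygen":
        for k, nm in enumerate(names):
            if nm.upper().startswith("O"):
                return coords_mol[:, k, :]
        logger.warning("no oxygen site found; falling back to centre of geometry")
    elif policy != "cog":
        raise ValueError(f"unknown solvent site policy {policy!r}")
    return coords_mol.mean(axis=1)


def verify_frozen_solute(traj: Trajectory, solute: Selection,
                         tol: float = FROZEN_TOL_NM) -> float:
    """Maximum solute atom displacement across frames; error if above tol."""
    coords = traj.coordinate_array()[:, solute.indices, :]
    disp = float(np.abs(coords - coords[0]).max())
    if disp > tol:
        raise DataError(
            f"solute is not frozen: max displacement {disp:.3e} nm exceeds "
            f"{tol:.0e} nm — this trajectory is not a constrained run"
        )
    return disp


def extract_clusters(traj: Trajectory, solute: Selection, n_solvent: int,
                     solvent_site: str = "oxygen", padding: float = 0.0,
                     solvent_resnames=SOLVENT_RESNAMES) -> list[ClusterFrame]:
    """Per frame, keep the ``n_solvent`` molecules nearest in the ellipsoid
    metric, slot-ordered ascending, shifted minimum-image to the solute."""
    verify_frozen_solute(traj, solute)
    box = traj.frames[0].box
    if box is None:
        raise DataError("cluster extraction needs a periodic (cubic) box")

    solute_coords = traj.frames[0].coordinates[solute.indices]
    ellipsoid = build_ellipsoid(solute_coords, padding=padding)

    mol_ids, atom_idx = _solvent_molecules(traj, solvent_resnames)
    if n_solvent > mol_ids.size:
        raise DataError(
            f"requested {n_solvent} solvent molecules but only {mol_ids.size} present"
        )
    names = [traj.topology[i].name for i in atom_idx[0]]

    clusters = []
    for frame in traj.frames:
        mol_coords = frame.coordinates[atom_idx]          # (M, s, 3)
        sites = _site_positions(mol_coords, names, solvent_site)
        metrics = ellipsoid_metric(ellipsoid, sites, box)
        # ties at the N-th rank resolve to the lower molecule id
        order = np.lexsort((mol_ids, metrics))[:n_solvent]

        sel_sites = sites[order]
        # shift each molecule rigidly by the image offset of its site
        delta = minimum_image(sel_sites - ellipsoid.center, box)
        shift = (ellipsoid.center + delta) - sel_sites     # multiple of box
        sel_coords = mol_coords[order] + shift[:, None, :]
        clusters.append(
            ClusterFrame(
                solute_coordinates=solute_coords,
                molecule_ids=mol_ids[order],
                solvent_coordinates=sel_coords,
                site_coordinates=sel_sites + shift,
                metrics=metrics[order],
            )
        )
    return clusters


def cluster_site_matrix(clusters: list[ClusterFrame]) -> np.ndarray:
    """Slot-ordered solvent site coordinates as an (n_frames, 3N) matrix."""
    if not clusters:
        raise DataError("no cluster frames")
    n = {c.n_solvent for c in clusters}
    if len(n) != 1:
        raise StructuralError(f"cluster frames differ in solvent count: {sorted(n)}")
    return np.stack([c.site_coordinates.reshape(-1) for c in clusters])


def cluster_ed_and_weights(
    clusters: list[ClusterFrame],
    thermo: Thermo,
    P_i: float,
    conformation_id: str = "i",
    bins=DEFAULT_BINS,
    cutoff: float = DEFAULT_CUTOFF_KJ,
    tree: WeightTree | None = None,
) -> tuple[EDModel, list[Basin], WeightTree]:
    """ED + landscape machinery on the cluster trajectory; hierarchical weights.

    The covariance is built over slot-ordered solvent site coordinates (the
    frozen solute would only add exact zero rows).  Basin fractions within
    the constrained trajectory are multiplied by the conformation weight
    ``P_i`` to give p(j, i).
    """
    X = cluster_site_matrix(clusters)
    model = ed_from_matrix(X)
    # fluctuations below 1e-12 nm RMS are numerically frozen solvent
    if model.trace <= 1e-24 * X.shape[1]:
        # fully frozen solvent: one basin holding everything
        logger.warning("cluster covariance has zero trace; single degenerate basin")
        tree = tree if tree is not None else WeightTree()
        tree.add(conformation_id, "B1", P_i, P_i)
        basin = Basin(id="B1", cells=[(0, 0)],
                      frame_indices=np.arange(X.shape[0]),
                      population=1.0, delta_G=0.0)
        return model, [basin], tree
    proj = project_matrix(X, model, n_vectors=2)
    grid = build_grid(proj, bins=bins, thermo=thermo)
    basins = detect_basins(grid, cutoff=cutoff)

    tree = tree if tree is not None else WeightTree()
    for basin in basins:
        p_ji = basin.population * P_i
        tree.add(conformation_id, basin.id, P_i, p_ji)
    deficit = tree.conservation_deficit(conformation_id, P_i)
    if deficit > 1e-12:
        logger.info("conformation %s: weight deficit %.4g (frames above cutoff)",
                    conformation_id, deficit)
    return model, basins, tree


def clusters_to_trajectory(clusters: list[ClusterFrame],
                           traj: Trajectory, solute: Selection) -> Trajectory:
    """Cluster frames as a writable trajectory: solute atoms first, then the
    slot-ordered solvent molecules (topology from slot ranks, not identities)."""
    from .trajectory_io import AtomRecord, Frame

    mol_ids, atom_idx = _solvent_molecules(traj)
    template = [traj.topology[i] for i in atom_idx[0]]

    topology = []
    for a in (traj.topology[i] for i in solute.indices):
        topology.append(AtomRecord(index=len(topology), name=a.name,
                                   residue_name=a.residue_name,
                                   residue_index=a.residue_index,
                                   molecule_id=0, element=a.element))
    n_res0 = max(a.residue_index for a in topology) if topology else 0
    for slot in range(clusters[0].n_solvent):
        for a in template:
            topology.append(AtomRecord(index=len(topology), name=a.name,
                                       residue_name=a.residue_name,
                                       residue_index=n_res0 + slot + 1,
                                       molecule_id=slot + 1, element=a.element))
    frames = []
    for c in clusters:
        coords = np.concatenate([c.solute_coordinates,
                                 c.solvent_coordinates.reshape(-1, 3)])
        frames.append(Frame(coordinates=coords, box=None))
    return Trajectory(topology=topology, frames=frames)
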