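"""Least-squares removal of rigid-body motion prior to covariance analysis.

Essential-dynamics eigenvectors must describe *internal* fluctuations, so
every frame is superposed onto a common reference by a mass-unweighted
Kabsch fit (the covariance analysed downstream is positional, not
mass-weighted).  The reference is the iteratively refined mean structure:
fit all frames to a starting reference, recompute the mean, refit, until
the mean stops moving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NumericalError
from .trajectory_io import Frame, Selection, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_TOL_NM = 1e-6
DEFAULT_MAX_ITER = 50


@dataclass(frozen=True)
class FitResult:
    """Rigid transform x' = rotation @ x + translation and the fitted RMSD (nm)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_rank(centered: np.ndarray, what: str) -> None:
    if centered.shape[0] < 3 or np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise NumericalError(
            f"{what} selection is degenerate (needs >= 3 non-collinear atoms)"
        )


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               fit_selection: Selection | None = None) -> FitResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimize the mass-unweighted RMSD over the fit
    selection (all atoms when ``fit_selection`` is None).  The proper-rotation
    branch is always taken: a reflection is never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise NumericalError(
            f"mobile {mobile.shape} and reference {reference.shape} shapes differ"
        )
    idx = fit_selection.indices if fit_selection is not None else np.arange(len(mobile))
    mob = mobile[idx]
    ref = reference[idx]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    _check_rank(mob - mob_c, "mobile")

    # align_vectors solves the orthogonal Procrustes problem with the
    # proper-rotation (Kabsch) sign correction built in
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return FitResult(rotation=R, translation=t, rmsd=rmsd)


def apply_fit(frame_coords: np.ndarray, fit: FitResult) -> np.ndarray:
    return fit.apply(np.asarray(frame_coords, dtype=float))


def iterative_fit(traj: Trajectory, fit_selection: Selection,
                  tol: float = DEFAULT_TOL_NM,
                  max_iter: int = DEFAULT_MAX_ITER) -> Trajectory:
    """Superpose every frame onto the converged mean structure.

    Iterates fit -> mean -> refit until the mean structure (restricted to the
    fit selection) moves less than ``tol`` nm RMS between successive
    iterations, or ``max_iter`` is reached (logged).  Returns a new
    trajectory flagged ``superposed``.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    coords = traj.coordinate_array().copy()
    idx = fit_selection.indices
    # mean-structure start: makes the procedure a no-op on an already
    # superposed trajectory (idempotence); one iteration then fixes the blur
    # a raw unfitted mean carries
    reference = coords[:, idx].mean(axis=0)

    for iteration in range(1, max_iter + 1):
        for f in range(coords.shape[0]):
            mob = coords[f, idx]
            mob_c = mob.mean(axis=0)
            ref_c = reference.mean(axis=0)
            _check_rank(mob - mob_c, "fit")
            rot, _ = Rotation.align_vectors(reference - ref_c, mob - mob_c)
            R = rot.as_matrix()
            t = ref_c - R @ mob_c
            coords[f] = coords[f] @ R.T + t
        new_reference = coords[:, idx].mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_reference - reference) ** 2, axis=1))))
        reference = new_reference
        if shift < tol:
            logger.info("iterative fit converged in %d iteration(s) (shift %.2e nm)",
                        iteration, shift)
            break
    else:
        logger.warning("iterative fit hit max_iter=%d (last shift %.2e nm)",
                       max_iter, shift)

    frames = [
        Frame(coordinates=coords[f], box=traj.frames[f].box, time=traj.frames[f].time)
        for f in range(coords.shape[0])
    ]
    return Trajectory(topology=traj.topology, frames=frames, superposed=True)
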