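"""Essential dynamics: positional covariance matrix and principal components.

The 3n x 3n covariance of the superposed coordinates of the analysis
selection is diagonalized; eigenvectors with the largest eigenvalues (the
"essential eigenvectors") span the directions of largest-amplitude
internal fluctuation, and projecting the trajectory onto the top two gives
the essential plane on which the conformational landscape is built.

Conventions (stated because the method itself does not fix them):

* population divisor 1/N, so eigenvalues are mean-square fluctuations;
* no mass weighting anywhere;
* each eigenvector's largest-magnitude component is made positive so
  projections are stable across runs;
* eigenvalues sorted descending, tiny negative round-off clamped to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NumericalError, StructuralError
from .trajectory_io import Selection, Trajectory

logger = logging.getLogger(__name__)

EIGENVALUE_CLAMP = -1e-12  # nm^2; anything above this is round-off


@dataclass
class EDModel:
    """Mean structure, covariance and eigenpairs of an analysis selection.

    ``eigenvectors`` holds one orthonormal 3n-vector per column, matching
    the descending order of ``eigenvalues`` (nm^2).
    """

    mean: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    selection: Selection | None = None

    @property
    def trace(self) -> float:
        return float(np.trace(self.covariance))

    @property
    def n_dof(self) -> int:
        return int(self.mean.size)

    def spectrum_frame(self) -> pd.DataFrame:
        """Eigenvalue spectrum as a table (rank, eigenvalue, cumulative fraction)."""
        cum = np.cumsum(self.eigenvalues)
        total = self.trace
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.eigenvalues.size + 1),
                "eigenvalue_nm2": self.eigenvalues,
                "cumulative_fraction": cum / total if total > 0 else np.nan,
            }
        )


@dataclass
class Projection:
    """Per-frame coordinates along the chosen eigenvectors, (n_frames, k) nm."""

    components: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.components.shape[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {f"proj{k + 1}": self.components[:, k]
                for k in range(self.components.shape[1])}
        return pd.DataFrame({"frame": np.arange(self.n_frames), **cols})


def _fix_eigen_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude component is positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def ed_from_matrix(X: np.ndarray) -> EDModel:
    """Essential-dynamics model from a raw (n_frames, n_dof) coordinate matrix.

    This is the engine shared by the solute analysis and the
    chromophore-solvent cluster analysis (where the matrix holds slot-ordered
    solvent site coordinates).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise StructuralError(f"coordinate matrix must be 2-D, got shape {X.shape}")
    n_frames = X.shape[0]
    if n_frames < 2:
        raise InsufficientDataError(
            f"covariance needs at least 2 frames, got {n_frames}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / n_frames  # population divisor: mean-square fluctuations
    cov = 0.5 * (cov + cov.T)

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]  # descending, ties keep index order
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.size and evals.min() < EIGENVALUE_CLAMP * max(1.0, float(evals.max())):
        raise NumericalError(
            f"covariance eigenvalue {evals.min():.3e} below round-off tolerance"
        )
    evals = np.clip(evals, 0.0, None)
    evecs = _fix_eigen_signs(evecs)

    near_degenerate = np.abs(np.diff(evals)) < 1e-12 * max(evals[0], 1e-30)
    if near_degenerate.any():
        logger.info("degenerate eigenvalue pair(s) at rank(s) %s; tie order by index",
                    list(np.flatnonzero(near_degenerate) + 1))
    return EDModel(mean=mean, covariance=cov, eigenvalues=evals, eigenvectors=evecs)


def build_covariance(traj: Trajectory, selection: Selection) -> EDModel:
    """Positional covariance of the selection over all frames, diagonalized."""
    if not traj.superposed:
        warnings.warn(
            "building a covariance from a trajectory that was not superposed; "
            "roto-translations will contaminate the eigenvectors",
            stacklevel=2,
        )
    X = traj.coordinate_array()[:, selection.indices, :].reshape(traj.n_frames, -1)
    model = ed_from_matrix(X)
    model.selection = selection
    return model


def project_matrix(X: np.ndarray, model: EDModel, n_vectors: int) -> Projection:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_dof:
        raise StructuralError(
            f"coordinate matrix has {X.shape[1]} dof, model expects {model.n_dof}"
        )
    if not 1 <= n_vectors <= model.n_dof:
        raise ValueError(f"n_vectors must be in [1, {model.n_dof}], got {n_vectors}")
    comps = (X - model.mean) @ model.eigenvectors[:, :n_vectors]
    return Projection(components=comps)


def project(traj: Trajectory, model: EDModel, n_vectors: int = 2) -> Projection:
    """Project each frame onto the first ``n_vectors`` essential eigenvectors."""
    if model.selection is None:
        raise StructuralError("model carries no selection; use project_matrix")
    idx = model.selection.indices
    if idx.max() >= traj.n_atoms:
        raise StructuralError("model selection indices exceed trajectory atom count")
    X = traj.coordinate_array()[:, idx, :].reshape(traj.n_frames, -1)
    return project_matrix(X, model, n_vectors)


def fluctuation_fraction(model: EDModel, n_vectors: int) -> float:
    """Fraction of the total fluctuation (covariance trace) captured by the
    first ``n_vectors`` eigenvalues."""
    if not 1 <= n_vectors <= model.n_dof:
        raise ValueError(f"n_vectors must be in [1, {model.n_dof}], got {n_vectors}")
    total = model.trace
    if total <= 0:
        raise NumericalError("covariance trace is zero; fluctuation fraction undefined")
    return float(model.eigenvalues[:n_vectors].sum() / total)
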