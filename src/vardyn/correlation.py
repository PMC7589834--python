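"""Residue-level dynamic cross-correlation and essential dynamics PCA.

The dynamic cross-correlation map (DCCM) is the normalised covariance
of residue displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with ``dr`` the deviation from the time-averaged position after
superposition on the mean structure.  Entries lie in [-1, 1]: +1 for
perfectly correlated motion, -1 for antiphase motion, 0 for
uncorrelated motion.  Residues with zero variance give an undefined
(NaN) entry, flagged rather than silently zeroed.

PCA (essential dynamics) diagonalises the 3N x 3N positional covariance
of the superposed Calpha coordinates; leading eigenvectors are the
dominant collective motions, eigenvalues their variance in A^2.
Eigenvector signs are fixed by forcing the largest-magnitude component
positive so projections are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientFramesError
from .geometry import superpose_frames, _mean_structure
from .structure import Trajectory, select_atoms

__all__ = ["CorrelationMap", "PCAResult", "compute_dccm", "compute_pca",
           "cumulative_variance"]


@dataclass
class CorrelationMap:
    """N x N residue cross-correlation matrix with residue labels."""

    matrix: np.ndarray
    residue_indices: np.ndarray
    undefined: np.ndarray  # boolean mask of zero-variance residues

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residue_indices,
                            columns=self.residue_indices)


@dataclass
class PCAResult:
    """Eigendecomposition of the positional fluctuation covariance."""

    eigenvalues: np.ndarray        # descending, A^2
    eigenvectors: np.ndarray       # (3N, 3N) columns, orthonormal
    variance_fractions: np.ndarray
    projections: np.ndarray        # (n_frames, 3N), A
    pc1_residue_mobility: pd.Series
    residue_indices: np.ndarray


def _windowed_deviations(
    traj: Trajectory, selection: str, window, superpose: bool
):
    sub = select_atoms(traj, selection)
    coords = sub.coords if window is None else sub.coords[list(window)]
    if coords.shape[0] < 2:
        raise InsufficientFramesError("need >= 2 frames in the window")
    if superpose:
        mean = _mean_structure(coords)
        coords = superpose_frames(coords, mean)
    mean = coords.mean(axis=0)
    return coords - mean, sub.topology.residue_index_labels, sub


def compute_dccm(
    traj: Trajectory,
    selection: str = "CA",
    window=None,
    superpose: bool = True,
) -> CorrelationMap:
    """Dynamic cross-correlation map over the analysis window.

    ``superpose=False`` keeps rigid-body motion in the signal (used by
    the rigid-translation sanity cases; the default removes it).
    For multi-atom selections the residue displacement is the mean of
    the residue's atom displacements.
    """
    dev, labels, sub = _windowed_deviations(traj, selection, window, superpose)
    n_res = sub.topology.n_residues
    res_dev = np.empty((dev.shape[0], n_res, 3))
    for g, (_, _, _, slots) in enumerate(sub.topology.residues):
        res_dev[:, g] = dev[:, slots].mean(axis=1)
    inner = np.einsum("fia,fja->ij", res_dev, res_dev) / dev.shape[0]
    var = np.diag(inner).copy()
    undefined = var <= 1e-15
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = inner / denom
    matrix[undefined, :] = np.nan
    matrix[:, undefined] = np.nan
    return CorrelationMap(matrix, labels, undefined)


def compute_pca(
    traj: Trajectory,
    selection: str = "CA",
    window=None,
    superpose: bool = True,
) -> PCAResult:
    """Essential-dynamics PCA of the superposed coordinates."""
    dev, labels, sub = _windowed_deviations(traj, selection, window, superpose)
    flat = dev.reshape(dev.shape[0], -1)  # (F, 3N)
    cov = flat.T @ flat / flat.shape[0]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    # reproducible sign: largest-magnitude component positive
    for k in range(v.shape[1]):
        imax = np.argmax(np.abs(v[:, k]))
        if v[imax, k] < 0:
            v[:, k] = -v[:, k]
    fractions = w / w.sum() if w.sum() > 0 else np.zeros_like(w)
    projections = flat @ v
    pc1 = v[:, 0].reshape(-1, 3)
    if sub.topology.n_residues == pc1.shape[0]:
        mobility_vals = np.sqrt(w[0]) * np.linalg.norm(pc1, axis=1)
    else:  # multi-atom selection: RMS over the residue's atoms
        mobility_vals = []
        for _, _, _, slots in sub.topology.residues:
            mobility_vals.append(
                np.sqrt(w[0]) * np.sqrt(
                    np.mean(np.linalg.norm(pc1[slots], axis=1) ** 2)
                )
            )
        mobility_vals = np.asarray(mobility_vals)
    mobility = pd.Series(
        mobility_vals, index=pd.Index(labels, name="residue_index"),
        name="pc1_mobility",
    )
    return PCAResult(w, v, fractions, projections, mobility, labels)


def cumulative_variance(pca: PCAResult, k: int) -> float:
    """Fraction of total fluctuation variance captured by the first k PCs."""
    if not 1 <= k <= len(pca.variance_fractions):
        raise IndexError(f"k must lie in [1, {len(pca.variance_fractions)}]")
    return float(pca.variance_fractions[:k].sum())
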