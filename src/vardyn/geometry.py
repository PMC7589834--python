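"""Superposition and scalar conformational descriptors.

RMSD series answer "how far has the structure drifted from a reference
after removing rigid-body motion"; RMSF profiles answer "how much does
each residue fluctuate about its mean position"; the radius of gyration
tracks overall compactness.  All three are the standard first-pass
descriptors of a comparative MD analysis, and the equilibration window
(discard the first fraction of frames, analyse the rest) defines the
portion of the trajectory every later stage consumes.

Superposition is the mass-unweighted least-squares (Kabsch) fit; the
RMSF reference is the mean structure after superposition, recomputed
once after an initial fit (two-pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, InsufficientFramesError, SelectionError, StructureError
from .structure import Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "ScalarSeries",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "rmsf_per_residue",
    "bfactor_from_rmsf",
    "rg_series",
    "equilibration_window",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (u) for the elements that occur in protein
#: heavy-atom models (plus hydrogen).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "Se": 78.971,
}

BFACTOR_PER_RMSF2 = 8.0 * np.pi**2 / 3.0  # B = (8 pi^2 / 3) RMSF^2


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit of a mobile conformation onto a reference."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ScalarSeries:
    """One number per frame (RMSD, Rg, SASA, H-bond count, ...)."""

    values: np.ndarray
    label: str
    frame_interval: float = 25.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Frame times in picoseconds."""
        return self.frame_interval * np.arange(len(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, self.label: self.values})


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Minimises the mass-unweighted sum of squared deviations over proper
    rotations and translations; ``rmsd`` is the minimised value.
    Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise StructureError(
            f"atom-count mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise DegenerateInputError("superposition needs >= 3 points of shape (n, 3)")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    if np.linalg.matrix_rank(x, tol=1e-8) < 2:
        raise DegenerateInputError("mobile coordinates are collinear")
    u, s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rotation = (u @ corr @ vt).T
    translation = rc - rotation @ mc
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd)


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray, fit_indices=None
) -> np.ndarray:
    """Superpose every frame of ``coords`` onto ``reference``.

    The fit is computed on ``fit_indices`` (default: all atoms) and the
    resulting transform applied to the whole frame.
    """
    coords = np.asarray(coords, dtype=float)
    out = np.empty_like(coords)
    idx = slice(None) if fit_indices is None else fit_indices
    for f in range(coords.shape[0]):
        res = kabsch_superpose(coords[f, idx], reference[idx])
        out[f] = res.apply(coords[f])
    return out


def _mean_structure(coords: np.ndarray) -> np.ndarray:
    """Two-pass mean: fit to the first frame, average, refit, average."""
    aligned = superpose_frames(coords, coords[0])
    mean = aligned.mean(axis=0)
    aligned = superpose_frames(coords, mean)
    return aligned.mean(axis=0)


def rmsd_series(
    traj: Trajectory,
    reference: str = "first_frame",
    selection: str = "backbone",
) -> ScalarSeries:
    """Per-frame RMSD to a reference after optimal superposition.

    ``reference`` is ``"first_frame"`` or ``"mean_structure"`` (two-pass
    mean of the superposed frames).
    """
    sub = select_atoms(traj, selection)
    if sub.n_atoms == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms")
    coords = sub.coords
    if reference == "first_frame":
        ref = coords[0]
    elif reference == "mean_structure":
        ref = _mean_structure(coords)
    else:
        raise ConfigError(
            f"reference must be 'first_frame' or 'mean_structure', got {reference!r}"
        )
    values = np.array(
        [kabsch_superpose(coords[f], ref).rmsd for f in range(coords.shape[0])]
    )
    return ScalarSeries(values, f"rmsd_{selection}", traj.frame_interval)


def rmsf_per_residue(traj: Trajectory, selection: str = "CA") -> pd.Series:
    """Root-mean-square fluctuation of each residue about the mean structure.

    Frames are superposed on the two-pass mean structure first;
    ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)``.  With a multi-atom selection the
    per-residue value is the RMS over the residue's selected atoms.
    """
    sub = select_atoms(traj, selection)
    if sub.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    mean = _mean_structure(sub.coords)
    aligned = superpose_frames(sub.coords, mean)
    mean = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # per atom
    labels = []
    values = []
    for chain, resi, _, slots in sub.topology.residues:
        labels.append(resi)
        values.append(np.sqrt(np.mean(msf_atom[slots])))
    return pd.Series(values, index=pd.Index(labels, name="residue_index"),
                     name="rmsf")


def bfactor_from_rmsf(profile: pd.Series) -> pd.Series:
    """Crystallographic-style B-factor, ``B = (8 pi^2 / 3) RMSF^2`` (A^2)."""
    if (np.asarray(profile) < 0).any():
        raise ConfigError("RMSF values must be >= 0")
    out = BFACTOR_PER_RMSF2 * profile.astype(float) ** 2
    out.name = "bfactor"
    return out


def rg_series(
    traj: Trajectory, selection: str = "heavy", mass_weighted: bool = True
) -> ScalarSeries:
    """Radius of gyration per frame.

    ``Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i)``; with
    ``mass_weighted=False`` all masses are 1.
    """
    sub = select_atoms(traj, selection)
    if mass_weighted:
        try:
            masses = np.array(
                [ATOMIC_MASSES[e] for e in sub.topology.elements]
            )
        except KeyError as exc:
            raise ConfigError(f"no atomic mass for element {exc}") from None
    else:
        masses = np.ones(sub.n_atoms)
    total = masses.sum()
    if total <= 0:
        raise ConfigError("total mass is zero")
    com = np.einsum("fij,i->fj", sub.coords, masses) / total
    dev = sub.coords - com[:, None, :]
    rg = np.sqrt(np.einsum("fij,fij,i->f", dev, dev, masses) / total)
    return ScalarSeries(rg, f"rg_{selection}", traj.frame_interval)


def equilibration_window(series, cutoff_fraction: float) -> range:
    """Frame range ``[ceil(f * n), n)`` retained for analysis.

    ``series`` may be a :class:`ScalarSeries`, a sequence, or an integer
    frame count.  A fraction of 0.4 mirrors discarding the first 120 ns
    of a 300 ns run.  A window of a single frame triggers a warning.
    """
    if not 0.0 <= cutoff_fraction < 1.0:
        raise ConfigError("cutoff_fraction must lie in [0, 1)")
    n = series if isinstance(series, int) else len(series)
    start = int(np.ceil(cutoff_fraction * n))
    if start >= n:
        start = n - 1
    if n - start < 1:
        raise ConfigError("equilibration window is empty")
    if n - start == 1:
        warnings.warn("equilibration window contains a single frame",
                      stacklevel=2)
    return range(start, n)
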