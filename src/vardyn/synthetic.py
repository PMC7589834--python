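"""Synthetic trajectories and score tables with known ground truth.

Real MD ensembles for the systems this package targets are not publicly
deposited, so every analysis stage is validated against generators whose
ground truth is prescribed exactly:

* near-harmonic fluctuation ensembles with a planted residue-residue
  displacement covariance (what DCCM/PCA/RMSF assume);
* two-state conformational ensembles with prescribed occupancies (what a
  two-basin free-energy landscape encodes);
* ideal polypeptide backbones (alpha-helix, extended chain, antiparallel
  sheet) built from internal coordinates, for secondary-structure,
  H-bond and contact-network fixtures;
* predictor score tables with planted deleterious variants and missing
  entries, for the consensus screen.

All generators are deterministic for a fixed ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import SpecError
from .structure import Topology, Trajectory

__all__ = [
    "HarmonicEnsembleSpec",
    "TwoStateSpec",
    "ScoreTableSpec",
    "sample_harmonic_ensemble",
    "sample_two_state",
    "build_ideal_helix",
    "build_extended_chain",
    "build_antiparallel_sheet",
    "build_ca_chain",
    "generate_score_table",
    "SCORE_COLUMNS",
]

# ---------------------------------------------------------------------------
# ensemble generators
# ---------------------------------------------------------------------------


@dataclass
class HarmonicEnsembleSpec:
    """Gaussian fluctuation ensemble around a reference conformation.

    ``residue_covariance`` (Angstrom^2) is the per-axis displacement
    covariance between residues; the same residue-level displacement is
    applied to every atom of a residue and independently to each axis,
    so the planted residue-residue correlation structure is exactly what
    DCCM should recover.
    """

    reference: Trajectory
    residue_covariance: np.ndarray
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.residue_covariance, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise SpecError("residue_covariance must be a square matrix")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise SpecError("residue_covariance must be symmetric")
        if cov.shape[0] != self.reference.n_residues:
            raise SpecError(
                f"covariance is {cov.shape[0]}x{cov.shape[0]} but the "
                f"reference has {self.reference.n_residues} residues"
            )
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-10:
            raise SpecError(
                f"residue_covariance is not positive semi-definite "
                f"(min eigenvalue {w.min():.3e})"
            )
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        self.residue_covariance = cov


def sample_harmonic_ensemble(spec: HarmonicEnsembleSpec) -> Trajectory:
    """Draw frames ``reference + per-residue Gaussian displacements``."""
    ref = spec.reference
    cov = spec.residue_covariance
    n_res = ref.n_residues
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # cov = factor @ factor.T
    rng = np.random.default_rng(spec.seed)
    # independent residue-level displacement per frame and axis
    z = rng.standard_normal((spec.n_frames, 3, n_res))
    disp = z @ factor.T  # (F, 3, N) with residue covariance = cov per axis
    coords = np.repeat(ref.coords[:1], spec.n_frames, axis=0)
    for g, (_, _, _, slots) in enumerate(ref.topology.residues):
        coords[:, slots, :] += disp[:, :, g][:, None, :]
    return Trajectory(ref.topology, coords, ref.frame_interval)


@dataclass
class TwoStateSpec:
    """Ensemble hopping between two conformations with fixed occupancy."""

    state_a: Trajectory
    state_b: Trajectory
    occupancy_a: float
    jitter_sd: float = 0.1
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_a <= 1.0:
            raise SpecError("occupancy_a must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")
        ta, tb = self.state_a.topology, self.state_b.topology
        if ta.n_atoms != tb.n_atoms or not np.array_equal(
            ta.residue_indices, tb.residue_indices
        ):
            raise SpecError("state_a and state_b must share one topology")


def sample_two_state(spec: TwoStateSpec) -> Trajectory:
    """Each frame is state A with probability ``occupancy_a``, else B,
    plus isotropic Gaussian jitter of standard deviation ``jitter_sd``."""
    rng = np.random.default_rng(spec.seed)
    in_a = rng.random(spec.n_frames) < spec.occupancy_a
    base = np.where(
        in_a[:, None, None], spec.state_a.coords[0], spec.state_b.coords[0]
    )
    if spec.jitter_sd > 0:
        base = base + spec.jitter_sd * rng.standard_normal(base.shape)
    return Trajectory(spec.state_a.topology, base, spec.state_a.frame_interval)


# ---------------------------------------------------------------------------
# ideal backbone construction (internal-coordinate build-up)
# ---------------------------------------------------------------------------

# ideal peptide geometry (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = (
    111.0, 116.6, 121.7, 120.8, 110.5,
)


def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom d with |cd| = r, angle(b,c,d) = theta, dihedral(a,b,c,d) = chi."""
    theta, chi = np.deg2rad(theta_deg), np.deg2rad(chi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(chi),
         r * np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_residues: int, phi: float, psi: float, omega: float = 180.0):
    """N/CA/C/O/CB positions for a uniform (phi, psi) polypeptide."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    C = [_nerf(np.array([0.0, -1.0, 0.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C, 0.0)]
    for i in range(1, n_residues):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O, CB = [], []
    for i in range(n_residues):
        O.append(_nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi - 180.0))
        CB.append(_nerf(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, 122.6))
    return np.array(N), np.array(CA), np.array(C), np.array(O), np.array(CB)


def _assemble(
    coords_per_res, residue_names, chain_id="A", first_residue=1
):
    names, elements, resi, resn, chains, rows = [], [], [], [], [], []
    for k, (res_atoms, rname) in enumerate(zip(coords_per_res, residue_names)):
        for aname, pos in res_atoms:
            names.append(aname)
            elements.append(aname[0])
            resi.append(first_residue + k)
            resn.append(rname)
            chains.append(chain_id)
            rows.append(pos)
    top = Topology(
        np.array(names), np.array(elements), np.array(resi), np.array(resn),
        np.array(chains),
    )
    return Trajectory(top, np.array(rows)[None, :, :])


def _chain_trajectory(n_residues, phi, psi, residue_names, chain_id="A",
                      first_residue=1):
    if n_residues < 2:
        raise SpecError("need at least 2 residues")
    if residue_names is None:
        residue_names = ["ALA"] * n_residues
    if len(residue_names) != n_residues:
        raise SpecError("residue_names length must equal n_residues")
    N, CA, C, O, CB = _build_backbone(n_residues, phi, psi)
    per_res = []
    for i in range(n_residues):
        atoms = [("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])]
        if residue_names[i] != "GLY":
            atoms.append(("CB", CB[i]))
        per_res.append(atoms)
    return _assemble(per_res, residue_names, chain_id, first_residue)


def build_ideal_helix(n_residues: int, residue_names=None) -> Trajectory:
    """One-frame ideal alpha-helix (phi = -57, psi = -47).

    Backbone N/CA/C/O plus CB (omitted for glycine); consecutive CA-CA
    distance is ~3.8 A and the O(i)...N(i+4) register is ~3.1 A.
    """
    if n_residues < 4:
        raise SpecError("an ideal helix needs at least 4 residues")
    return _chain_trajectory(n_residues, -57.0, -47.0, residue_names)


def build_extended_chain(n_residues: int, residue_names=None) -> Trajectory:
    """Fully extended chain (phi = psi = 180); no H-bond partners."""
    return _chain_trajectory(n_residues, 180.0, 180.0, residue_names)


def build_ca_chain(n_residues: int, spacing: float = 3.8) -> Trajectory:
    """Calpha-only pseudo-chain along x; reference for residue-level
    fluctuation ensembles where only per-residue motion matters."""
    if n_residues < 1:
        raise SpecError("need at least 1 residue")
    coords = np.zeros((n_residues, 3))
    coords[:, 0] = spacing * np.arange(n_residues)
    per_res = [[("CA", coords[i])] for i in range(n_residues)]
    # glycine, so the CB-or-CA network selection resolves to the CA
    return _assemble(per_res, ["GLY"] * n_residues)


def build_antiparallel_sheet(n_per_strand: int = 8) -> Trajectory:
    """Two-strand antiparallel beta-sheet.

    Strand A (chain A, residues 1..n) is built with beta dihedrals
    (phi = -139, psi = 135); strand B (chain B, residues n+1..2n) is the
    same strand placed by a two-fold rotation and a rigid shift tuned so
    that the canonical two-way N-H...O=C pairs of the antiparallel
    register sit at ~2.9 A.  The placement is a deterministic
    least-squares fit, so the fixture is reproducible bit-for-bit.
    """
    if n_per_strand < 4:
        raise SpecError("need at least 4 residues per strand")
    n = n_per_strand
    N, CA, C, O, CB = _build_backbone(n, -139.0, 135.0)

    def transform(params, pts):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return pts @ rot.T + params[3:]

    # bridge partners j = n-1-i; two-way H-bonded pairs at alternating i
    hb_pairs = [(i, n - 1 - i) for i in range(1, n - 1, 2)]
    all_pairs = [(i, n - 1 - i) for i in range(n)]

    def objective(p):
        NB, OB, CAB = (transform(p, x) for x in (N, O, CA))
        s = 0.0
        for i, j in hb_pairs:
            s += (np.linalg.norm(N[i] - OB[j]) - 2.9) ** 2
            s += (np.linalg.norm(O[i] - NB[j]) - 2.9) ** 2
        for i, j in all_pairs:  # keep inter-strand CA spacing near 4.9 A
            s += 0.02 * (np.linalg.norm(CA[i] - CAB[j]) - 4.9) ** 2
        return s

    x0 = np.array([0.0, 0.0, np.pi, 0.0, 4.8, 0.0])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options=dict(maxiter=20000, xatol=1e-10, fatol=1e-12))
    p = res.x
    NB, CAB, CBk, OB, CBB = (transform(p, x) for x in (N, CA, C, O, CB))

    per_res = []
    for i in range(n):
        per_res.append([("N", N[i]), ("CA", CA[i]), ("C", C[i]),
                        ("O", O[i]), ("CB", CB[i])])
    traj_a = _assemble(per_res, ["ALA"] * n, "A", 1)
    per_res_b = []
    for i in range(n):
        per_res_b.append([("N", NB[i]), ("CA", CAB[i]), ("C", CBk[i]),
                          ("O", OB[i]), ("CB", CBB[i])])
    traj_b = _assemble(per_res_b, ["ALA"] * n, "B", n + 1)

    top = Topology(
        np.concatenate([traj_a.topology.names, traj_b.topology.names]),
        np.concatenate([traj_a.topology.elements, traj_b.topology.elements]),
        np.concatenate([traj_a.topology.residue_indices,
                        traj_b.topology.residue_indices]),
        np.concatenate([traj_a.topology.residue_names,
                        traj_b.topology.residue_names]),
        np.concatenate([traj_a.topology.chain_ids, traj_b.topology.chain_ids]),
    )
    coords = np.concatenate([traj_a.coords[0], traj_b.coords[0]])
    return Trajectory(top, coords[None])


# ---------------------------------------------------------------------------
# predictor score tables
# ---------------------------------------------------------------------------

#: Column order of a generated/parsed score table (PolyPhen-2 contributes
#: two sub-scores but counts as a single tool in the consensus).
SCORE_COLUMNS = [
    "SIFT", "PolyPhen2_HumDiv", "PolyPhen2_HumVar", "MAPP", "PANTHER",
    "SNP_GO", "PhD_SNP", "PredictSNP", "PROVEAN", "I_Mutant3",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScoreTableSpec:
    """Planted-truth predictor score table.

    Deleterious rows draw a score past each tool's cutoff with
    probability ``pass_probability`` (neutral rows with
    ``neutral_pass_probability``); each score cell is independently
    blanked with probability ``missing_rate``.
    """

    n_variants: int
    planted_deleterious: frozenset = field(default_factory=frozenset)
    missing_rate: float = 0.05
    pass_probability: float = 0.95
    neutral_pass_probability: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_deleterious = frozenset(self.planted_deleterious)
        if self.n_variants < 1:
            raise SpecError("n_variants must be >= 1")
        if any(i < 0 or i >= self.n_variants for i in self.planted_deleterious):
            raise SpecError("planted indices must be < n_variants")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must lie in [0, 1)")
        for p in (self.pass_probability, self.neutral_pass_probability):
            if not 0.0 <= p <= 1.0:
                raise SpecError("pass probabilities must lie in [0, 1]")


def _draw_score(rng, tool: str, passing: bool):
    """One score on the deleterious or neutral side of ``tool``'s cutoff."""
    u = rng.random()
    if tool == "SIFT":
        return round(0.05 * u, 3) if passing else round(0.06 + 0.94 * u, 3)
    if tool in ("PolyPhen2_HumDiv", "PolyPhen2_HumVar"):
        return round(0.901 + 0.099 * u, 3) if passing else round(0.9 * u, 3)
    if tool == "PROVEAN":
        return round(-2.5 - 7.5 * u, 3) if passing else round(-2.4 + 4.4 * u, 3)
    if tool == "I_Mutant3":
        return round(-0.51 - 2.49 * u, 2) if passing else round(-0.5 + 1.5 * u, 2)
    if tool in ("PhD_SNP", "SNP_GO", "MAPP"):
        return round(0.501 + 0.499 * u, 3) if passing else round(0.5 * u, 3)
    if tool == "PANTHER":
        return round(0.5 + 0.5 * u, 3) if passing else round(0.499 * u, 3)
    if tool == "PredictSNP":
        return "D" if passing else "N"
    raise SpecError(f"unknown tool {tool!r}")


def generate_score_table(spec: ScoreTableSpec) -> pd.DataFrame:
    """Generate a variant score table with planted deleterious rows.

    Returns a DataFrame with ``rs_id``, ``substitution`` and one column
    per predictor sub-score; missing entries are ``NaN`` (written as
    ``-`` by :func:`pandas.DataFrame.to_csv` with ``na_rep='-'``).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_variants):
        planted = i in spec.planted_deleterious
        p_pass = spec.pass_probability if planted else spec.neutral_pass_probability
        wild = _AA[rng.integers(len(_AA))]
        mutant = _AA[rng.integers(len(_AA))]
        while mutant == wild:
            mutant = _AA[rng.integers(len(_AA))]
        position = int(rng.integers(903, 1148))  # NBD1 author numbering
        row = {
            "rs_id": f"rs{900000000 + i}",
            "substitution": f"{wild}{position}{mutant}",
        }
        # PolyPhen-2 is one tool: both sub-scores pass or fail together
        tool_pass = {}
        for tool in ("SIFT", "PolyPhen2", "MAPP", "PANTHER", "SNP_GO",
                     "PhD_SNP", "PredictSNP", "PROVEAN", "I_Mutant3"):
            tool_pass[tool] = rng.random() < p_pass
        for col in SCORE_COLUMNS:
            tool = "PolyPhen2" if col.startswith("PolyPhen2") else col
            row[col] = _draw_score(rng, col, tool_pass[tool])
        rows.append(row)
    df = pd.DataFrame(rows)
    if spec.missing_rate > 0:
        mask = rng.random((spec.n_variants, len(SCORE_COLUMNS))) < spec.missing_rate
        for j, col in enumerate(SCORE_COLUMNS):
            df.loc[mask[:, j], col] = np.nan
    return df
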