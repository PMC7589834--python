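"""Solvent-accessible surface area and intramolecular hydrogen bonds.

SASA follows the Shrake-Rupley construction: each atom is inflated by
the probe radius (1.4 A water probe) and the accessible fraction of a
quasi-uniform point shell on that sphere is converted to area.  The
numerical work is delegated to :func:`biotite.structure.sasa` with the
radius table defined here, so the quadrature is auditable against the
closed-form sphere area of an isolated atom.

Hydrogen bonds are counted per frame from geometry.  Structures built
by this package carry no hydrogens, so the default criteria operate in
``heavy_only`` mode: donor nitrogen/oxygen to acceptor oxygen within a
distance cutoff, with an acceptor-antecedent angle requirement
(C=O...N) that separates true H-bond registers from mere packing
contacts; backbone amide nitrogen is treated as donor-only, since its
lone pair is delocalised into the peptide bond.  When hydrogens are
present an explicit D-H...A angle criterion is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial import cKDTree

from .errors import ConfigError, RadiusTableError
from .geometry import ScalarSeries
from .structure import Trajectory

__all__ = [
    "RadiusTable",
    "HBondCriteria",
    "shrake_rupley_sasa",
    "sasa_series",
    "hbond_count_series",
]


@dataclass
class RadiusTable:
    """Van der Waals radii (A) plus the solvent probe radius."""

    radii: dict = field(default_factory=lambda: {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    })
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.probe_radius < 0:
            raise RadiusTableError("radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise RadiusTableError(
                f"element {element!r} has no van der Waals radius"
            ) from None


@dataclass
class HBondCriteria:
    """Geometric definition of a hydrogen bond.

    ``heavy_only`` mode (the default; fixtures carry no hydrogens) uses
    the donor-acceptor distance plus the acceptor-antecedent angle;
    ``with_hydrogens`` mode uses the D-H...A angle at the hydrogen.
    """

    donor_acceptor_max: float = 3.5
    angle_min_deg: float = 120.0           # D-H...A, with hydrogens
    acceptor_angle_min_deg: float = 120.0  # antecedent-A...D, heavy-only
    mode: str = "heavy_only"

    def __post_init__(self) -> None:
        if self.donor_acceptor_max <= 0:
            raise ConfigError("donor_acceptor_max must be > 0")
        for a in (self.angle_min_deg, self.acceptor_angle_min_deg):
            if not 0.0 < a <= 180.0:
                raise ConfigError("angle thresholds must lie in (0, 180]")
        if self.mode not in ("heavy_only", "with_hydrogens"):
            raise ConfigError("mode must be 'heavy_only' or 'with_hydrogens'")


def _to_atom_array(traj: Trajectory, frame: int) -> struc.AtomArray:
    top = traj.topology
    arr = struc.AtomArray(top.n_atoms)
    arr.coord = np.asarray(traj.coords[frame], dtype=np.float32)
    arr.chain_id = top.chain_ids.astype("U4")
    arr.res_id = top.residue_indices
    arr.res_name = top.residue_names.astype("U5")
    arr.atom_name = top.names.astype("U6")
    arr.element = top.elements.astype("U2")
    arr.hetero = np.zeros(top.n_atoms, dtype=bool)
    return arr


def shrake_rupley_sasa(
    traj: Trajectory,
    frame: int = 0,
    radii: RadiusTable | None = None,
    n_sphere_points: int = 960,
):
    """Shrake-Rupley SASA of one frame.

    Returns ``(total, per_residue)`` in A^2, where ``per_residue`` is a
    :class:`pandas.Series` keyed by residue index (sum over the
    residue's atoms).
    """
    if n_sphere_points < 24:
        raise ConfigError("n_sphere_points must be >= 24")
    radii = radii or RadiusTable()
    per_atom_radius = np.array(
        [radii.radius(e) for e in traj.topology.elements]
    )
    arr = _to_atom_array(traj, frame)
    per_atom = struc.sasa(
        arr,
        probe_radius=radii.probe_radius,
        point_number=n_sphere_points,
        vdw_radii=per_atom_radius,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(np.asarray(per_atom, dtype=float))
    labels, values = [], []
    for _, resi, _, slots in traj.topology.residues:
        labels.append(resi)
        values.append(per_atom[slots].sum())
    per_residue = pd.Series(
        values, index=pd.Index(labels, name="residue_index"), name="sasa"
    )
    return float(per_atom.sum()), per_residue


def sasa_series(
    traj: Trajectory,
    radii: RadiusTable | None = None,
    n_sphere_points: int = 960,
    stride: int = 1,
) -> ScalarSeries:
    """Total SASA per frame (optionally strided for long trajectories)."""
    frames = range(0, traj.n_frames, stride)
    totals = [shrake_rupley_sasa(traj, f, radii, n_sphere_points)[0]
              for f in frames]
    return ScalarSeries(np.asarray(totals), "sasa_total",
                        traj.frame_interval * stride)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v, w = a - b, c - b
    cosang = np.dot(v, w) / (np.linalg.norm(v) * np.linalg.norm(w))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_candidates(traj: Trajectory, criteria: HBondCriteria):
    """Static donor/acceptor bookkeeping shared by all frames."""
    top = traj.topology
    is_n = top.elements == "N"
    is_o = top.elements == "O"
    is_h = top.elements == "H"
    has_h = bool(is_h.any())
    if criteria.mode == "with_hydrogens" and not has_h:
        raise ConfigError(
            "criteria require hydrogens but the structure has none; "
            "use mode='heavy_only'"
        )
    backbone_o = is_o & np.isin(top.names, ("O", "OXT"))
    backbone_n = is_n & (top.names == "N")
    # donors: amide/amine N and hydroxyl-type O (not carbonyl O)
    donors = np.flatnonzero(is_n | (is_o & ~backbone_o))
    # acceptors: any O plus non-amide N; amide N is donor-only
    acceptors = np.flatnonzero(is_o | (is_n & ~backbone_n))
    # antecedent of each acceptor: the nearest heavy atom of the same
    # residue in the first frame (the carbonyl C for a backbone O)
    coords0 = traj.coords[0]
    antecedent = {}
    for a in acceptors:
        same = [
            i for i in range(top.n_atoms)
            if i != a
            and top.residue_indices[i] == top.residue_indices[a]
            and top.chain_ids[i] == top.chain_ids[a]
            and top.elements[i] != "H"
        ]
        if same:
            d = [np.linalg.norm(coords0[i] - coords0[a]) for i in same]
            antecedent[a] = same[int(np.argmin(d))]
    hydrogens = {}
    if has_h:
        h_idx = np.flatnonzero(is_h)
        for d_ in donors:
            near = [
                h for h in h_idx
                if top.residue_indices[h] == top.residue_indices[d_]
                and np.linalg.norm(coords0[h] - coords0[d_]) < 1.3
            ]
            hydrogens[d_] = near
    return donors, acceptors, antecedent, hydrogens, backbone_n, backbone_o


def hbond_count_series(
    traj: Trajectory, criteria: HBondCriteria | None = None
) -> ScalarSeries:
    """Count unique intramolecular donor-acceptor pairs per frame.

    Pairs within one residue are excluded, as is the backbone N(i+1)-O(i)
    pair across each peptide bond (those two atoms are covalently tied
    through the amide plane, not hydrogen-bonded).
    """
    criteria = criteria or HBondCriteria()
    top = traj.topology
    donors, acceptors, antecedent, hydrogens, _, _ = _hbond_candidates(
        traj, criteria
    )
    counts = np.zeros(traj.n_frames)
    resi = top.residue_indices
    chain = top.chain_ids
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        tree = cKDTree(coords[acceptors])
        n_bonds = 0
        for d_ in donors:
            for ja in tree.query_ball_point(
                coords[d_], criteria.donor_acceptor_max
            ):
                a = acceptors[ja]
                if a == d_:
                    continue
                if resi[a] == resi[d_] and chain[a] == chain[d_]:
                    continue
                # peptide-bond exclusion: amide N against the carbonyl O
                # of the preceding residue (same chain)
                if (
                    top.names[d_] == "N"
                    and top.names[a] in ("O", "OXT")
                    and chain[a] == chain[d_]
                    and resi[d_] - resi[a] == 1
                ):
                    continue
                if criteria.mode == "with_hydrogens":
                    ok = any(
                        _angle_deg(coords[d_], coords[h], coords[a])
                        >= criteria.angle_min_deg
                        for h in hydrogens.get(d_, [])
                    )
                else:
                    ant = antecedent.get(a)
                    ok = ant is None or (
                        _angle_deg(coords[ant], coords[a], coords[d_])
                        >= criteria.acceptor_angle_min_deg
                    )
                if ok:
                    n_bonds += 1
        counts[f] = n_bonds
    return ScalarSeries(counts, "hbond_count", traj.frame_interval)
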