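"""Simplified Kabsch-Sander secondary-structure assignment.

A self-contained re-implementation of the core of the DSSP algorithm,
small enough to audit: backbone H-bonds are scored with the
Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

and assigned when E < -0.5 kcal/mol.  Amide hydrogens are
reconstructed geometrically (N-H 1.01 A, anti to the previous
carbonyl) because the structures this package handles are
hydrogen-free.  From the H-bond matrix, n-turns at offsets 3/4/5 yield
3-10/alpha helices, two-way or flanking nonlocal bond patterns yield
beta bridges and ladders (E), remaining turn residues are T, strong
backbone curvature is a bend (S), everything else coil (C).  The
pi-helix class, chirality flags and chain-break bookkeeping of full
DSSP are deliberately omitted.

Class priority when assignments overlap: H > E > G > T > S > C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SelectionError
from .structure import Trajectory

__all__ = ["SSETimeline", "backbone_hbond_energy", "assign_sse",
           "sse_fractions", "HBOND_ENERGY_CUTOFF"]

HBOND_ENERGY_CUTOFF = -0.5          # kcal/mol
_KS_FACTOR = 0.084 * 332.0          # partial charges * electrostatic constant
_NH_LENGTH = 1.01                   # A
_PEPTIDE_BOND_MAX = 2.0             # A, C(i)-N(i+1) distance for a real bond
_BEND_ANGLE = 70.0                  # degrees
_CLASSES = ("H", "G", "E", "T", "S", "C")


@dataclass
class SSETimeline:
    """frames x residues matrix of single-letter secondary-structure codes."""

    classes: np.ndarray            # dtype U1, shape (n_frames, n_residues)
    residue_indices: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.classes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.classes, columns=self.residue_indices)


def _backbone_slots(traj: Trajectory):
    """Per-residue slots of N/CA/C/O plus bonded-predecessor links."""
    top = traj.topology
    slots = []
    for g, (chain, resi, resname, _) in enumerate(top.residues):
        entry = {}
        for name in ("N", "CA", "C", "O"):
            s = top.atom_slot(g, name)
            if s is None:
                raise SelectionError(
                    f"residue {chain}:{resi} ({resname}) lacks backbone "
                    f"atom {name}"
                )
            entry[name] = s
        entry["chain"] = chain
        entry["resi"] = resi
        slots.append(entry)
    return slots


def _predecessors(slots, coords0):
    """prev[i] = i-1 when residue i-1's C is peptide-bonded to i's N."""
    prev = [None] * len(slots)
    for i in range(1, len(slots)):
        if slots[i]["chain"] != slots[i - 1]["chain"]:
            continue
        d = np.linalg.norm(
            coords0[slots[i]["N"]] - coords0[slots[i - 1]["C"]]
        )
        if d <= _PEPTIDE_BOND_MAX:
            prev[i] = i - 1
    return prev


def _amide_h(coords, slots, prev, i):
    """Reconstructed amide H of residue i, or None for a chain start."""
    p = prev[i]
    if p is None:
        return None
    v = coords[slots[p]["C"]] - coords[slots[p]["O"]]
    v = v / np.linalg.norm(v)
    return coords[slots[i]["N"]] + _NH_LENGTH * v


def _ks_energy(n_pos, h_pos, c_pos, o_pos) -> float:
    r_on = np.linalg.norm(o_pos - n_pos)
    r_ch = np.linalg.norm(c_pos - h_pos)
    r_oh = np.linalg.norm(o_pos - h_pos)
    r_cn = np.linalg.norm(c_pos - n_pos)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atom clash, treat as no bond
        return 0.0
    return _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def backbone_hbond_energy(
    traj: Trajectory, donor_res: int, acceptor_res: int, frame: int = 0
) -> float:
    """Kabsch-Sander energy of donor N-H(i) against acceptor C=O(j).

    ``donor_res``/``acceptor_res`` are author residue indices.  Adjacent
    or identical residues (|i - j| < 2 in chain order) are not
    evaluated; a donor at a chain start (no amide H) gives 0.
    """
    slots = _backbone_slots(traj)
    coords = traj.coords[frame]
    prev = _predecessors(slots, traj.coords[0])
    by_resi = {(e["chain"], e["resi"]): k for k, e in enumerate(slots)}
    try:
        i = next(k for (c, r), k in by_resi.items() if r == donor_res)
        j = next(k for (c, r), k in by_resi.items() if r == acceptor_res)
    except StopIteration:
        raise ConfigError(
            f"residue {donor_res} or {acceptor_res} not in topology"
        ) from None
    if abs(i - j) < 2:
        raise ConfigError(
            "Kabsch-Sander energy is not evaluated for adjacent residues"
        )
    h = _amide_h(coords, slots, prev, i)
    if h is None:
        return 0.0
    return _ks_energy(
        coords[slots[i]["N"]], h, coords[slots[j]["C"]], coords[slots[j]["O"]]
    )


def _hbond_matrix(coords, slots, prev) -> np.ndarray:
    """hb[i, j] = residue i's N-H donates to residue j's C=O."""
    n = len(slots)
    hb = np.zeros((n, n), dtype=bool)
    h_pos = [_amide_h(coords, slots, prev, i) for i in range(n)]
    for i in range(n):
        if h_pos[i] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            e = _ks_energy(
                coords[slots[i]["N"]], h_pos[i],
                coords[slots[j]["C"]], coords[slots[j]["O"]],
            )
            if e < HBOND_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb


def _assign_frame(coords, slots, prev) -> np.ndarray:
    n = len(slots)
    hb = _hbond_matrix(coords, slots, prev)

    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in turn:
        for i in range(n - k):
            if hb[i + k, i]:
                turn[k][i] = True

    is_h = np.zeros(n, dtype=bool)
    is_g = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            is_h[i:i + 4] = True
    for i in range(1, n - 3):
        if turn[3][i - 1] and turn[3][i]:
            is_g[i:i + 3] = True

    # beta bridges: nonlocal two-way or flanking H-bond patterns
    is_e = np.zeros(n, dtype=bool)

    def hbond(a, b):  # CO(a) ... HN(b), i.e. donor b -> acceptor a
        return 0 <= a < n and 0 <= b < n and hb[b, a]

    for i in range(n):
        for j in range(i + 3, n):
            parallel = (
                (hbond(i - 1, j) and hbond(j, i + 1))
                or (hbond(j - 1, i) and hbond(i, j + 1))
            )
            antiparallel = (
                (hbond(i, j) and hbond(j, i))
                or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            )
            if parallel or antiparallel:
                is_e[i] = is_e[j] = True

    is_t = np.zeros(n, dtype=bool)
    for k, flags in turn.items():
        for i in np.flatnonzero(flags):
            is_t[i + 1:i + k] = True

    is_s = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if prev[i] is None or prev[i - 1] is None:
            continue
        if i + 2 >= n or prev[i + 1] is None or prev[i + 2] is None:
            continue
        v = coords[slots[i]["CA"]] - coords[slots[i - 2]["CA"]]
        w = coords[slots[i + 2]["CA"]] - coords[slots[i]["CA"]]
        cosang = np.dot(v, w) / (np.linalg.norm(v) * np.linalg.norm(w))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > _BEND_ANGLE:
            is_s[i] = True

    out = np.full(n, "C", dtype="U1")
    out[is_s] = "S"
    out[is_t] = "T"
    out[is_g] = "G"
    out[is_e] = "E"
    out[is_h] = "H"
    return out


def assign_sse(traj: Trajectory, window=None) -> SSETimeline:
    """Secondary-structure class of every residue in every window frame."""
    slots = _backbone_slots(traj)
    prev = _predecessors(slots, traj.coords[0])
    frames = range(traj.n_frames) if window is None else list(window)
    rows = [ _assign_frame(traj.coords[f], slots, prev) for f in frames ]
    labels = np.array([e["resi"] for e in slots])
    return SSETimeline(np.array(rows), labels)


def sse_fractions(timeline: SSETimeline) -> pd.DataFrame:
    """Per-residue fraction of frames spent in each class (rows sum to 1)."""
    if timeline.n_frames < 1:
        raise ConfigError("timeline has no frames")
    data = {
        cls: (timeline.classes == cls).mean(axis=0) for cls in _CLASSES
    }
    df = pd.DataFrame(data, index=pd.Index(timeline.residue_indices,
                                           name="residue_index"))
    return df
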