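"""Multi-model coordinate I/O and the shared topology/trajectory model.

Every analysis stage consumes the :class:`Trajectory` defined here: an
ordered set of conformations (frames) sharing one :class:`Topology`.
Coordinates are in Angstrom and residue numbering is the author numbering
of the input file (never renumbered), so motif positions quoted in the
literature (e.g. Walker A 933-940 of the ABCA1 NBD1 domain) can be used
directly as residue labels.

Reading and writing of the wwPDB fixed-width format is delegated to
biotite; alternate locations are resolved to the highest-occupancy
conformer, because all downstream stages assume single-conformer frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import PDBParseError, SelectionError, StructureError

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "SELECTORS",
]

#: Selection names accepted by :func:`select_atoms`.
SELECTORS = ("CA", "CB_or_CA_for_GLY", "backbone", "heavy")

_BACKBONE_NAMES = ("N", "CA", "C", "O")

# Two-letter element symbols that can appear in protein/ligand atom names.
_TWO_LETTER = {"CL", "BR", "FE", "MG", "ZN", "NA", "SE", "MN", "CU", "NI"}


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Names starting with a digit (``1HB``) are hydrogens; recognised
    two-letter symbols are kept; otherwise the first letter is used.
    """
    name = atom_name.strip().upper()
    if not name:
        raise PDBParseError("empty atom name")
    if name[0].isdigit():
        return "H"
    if name[:2] in _TWO_LETTER:
        return name[:2].capitalize()
    return name[0]


@dataclass(frozen=True)
class Atom:
    """One atom of one frame; a convenience view, not the storage format."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial}: non-finite position")


class Topology:
    """Per-atom annotations plus the residue grouping derived from them.

    Residues are identified by ``(chain_id, residue_index)`` in order of
    first appearance; ``residue_index`` is strictly increasing within a
    chain, and every atom belongs to exactly one residue.
    """

    def __init__(
        self,
        names: np.ndarray,
        elements: np.ndarray,
        residue_indices: np.ndarray,
        residue_names: np.ndarray,
        chain_ids: np.ndarray,
        serials: np.ndarray | None = None,
    ) -> None:
        n = len(names)
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.serials = (
            np.arange(1, n + 1) if serials is None else np.asarray(serials, dtype=int)
        )
        for arr in (self.elements, self.residue_indices, self.residue_names,
                    self.chain_ids, self.serials):
            if len(arr) != n:
                raise StructureError("topology annotation arrays differ in length")
        self._validate()
        self._groups = self._build_groups()

    def _validate(self) -> None:
        if self.n_atoms == 0:
            raise StructureError("topology has no atoms")
        if any(not n for n in self.names):
            raise StructureError("atom names must be non-empty")
        # author numbering must be strictly increasing within a chain
        for chain in dict.fromkeys(self.chain_ids.tolist()):
            mask = self.chain_ids == chain
            resi = self.residue_indices[mask]
            # consecutive distinct residue ids must increase
            changes = resi[np.r_[True, resi[1:] != resi[:-1]]]
            if np.any(np.diff(changes) <= 0):
                raise StructureError(
                    f"residue indices not strictly increasing in chain {chain!r}"
                )

    def _build_groups(self) -> list[tuple[str, int, str, np.ndarray]]:
        groups: list[tuple[str, int, str, np.ndarray]] = []
        keys = list(zip(self.chain_ids.tolist(), self.residue_indices.tolist()))
        order: dict[tuple[str, int], list[int]] = {}
        for i, key in enumerate(keys):
            order.setdefault(key, []).append(i)
        for (chain, resi), idx in order.items():
            groups.append(
                (chain, resi, str(self.residue_names[idx[0]]), np.asarray(idx))
            )
        return groups

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(self._groups)

    @property
    def residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """``(chain_id, residue_index, residue_name, atom_slots)`` per residue."""
        return self._groups

    @property
    def residue_index_labels(self) -> np.ndarray:
        return np.array([resi for _, resi, _, _ in self._groups])

    def atom_slot(self, group: int, atom_name: str) -> int | None:
        """Slot of ``atom_name`` within residue ``group``, or ``None``."""
        _, _, _, idx = self._groups[group]
        hits = idx[self.names[idx] == atom_name]
        return int(hits[0]) if len(hits) else None

    def subset(self, indices: np.ndarray) -> "Topology":
        indices = np.asarray(indices, dtype=int)
        return Topology(
            self.names[indices],
            self.elements[indices],
            self.residue_indices[indices],
            self.residue_names[indices],
            self.chain_ids[indices],
            self.serials[indices],
        )


@dataclass
class Trajectory:
    """Ordered conformations sharing one topology.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom;
    ``frame_interval`` is the sampling interval in picoseconds.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval: float = 25.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frames carry {self.coords.shape[1]} atoms but the topology "
                f"defines {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def atom(self, frame: int, slot: int) -> Atom:
        top = self.topology
        return Atom(
            serial=int(top.serials[slot]),
            name=str(top.names[slot]),
            element=str(top.elements[slot]),
            residue_index=int(top.residue_indices[slot]),
            residue_name=str(top.residue_names[slot]),
            chain_id=str(top.chain_ids[slot]),
            position=self.coords[frame, slot],
        )

    def with_frames(self, frame_indices) -> "Trajectory":
        return Trajectory(self.topology, self.coords[frame_indices],
                          self.frame_interval)


def _prescan(lines: list[str]) -> None:
    """Validate ATOM/HETATM records and per-model atom counts.

    Raises :class:`PDBParseError` naming the offending line, or
    :class:`StructureError` when models disagree in atom count.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: unparseable coordinates in {rec} record"
                ) from None
            current += 1
    if saw_model and in_model:  # MODEL without ENDMDL: tolerate, close it
        counts.append(current)
    if not saw_model:
        counts = [current]
    if not counts or counts[0] == 0:
        raise PDBParseError("file contains no ATOM/HETATM records")
    if len(set(counts)) > 1:
        raise StructureError(
            f"inconsistent atom count across models: {sorted(set(counts))}"
        )


def read_multimodel_pdb(path, frame_interval: float = 25.0) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    Frames are ordered by MODEL number; the topology is taken from the
    first model.  A file without MODEL/ENDMDL keywords yields a one-frame
    trajectory.  Highest-occupancy altLoc conformers are kept.
    """
    with open(path) as fh:
        lines = fh.readlines()
    _prescan(lines)
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(f"{path}: {exc}") from exc
    elements = np.array(
        [e if e else infer_element(n)
         for e, n in zip(stack.element, stack.atom_name)],
        dtype="U2",
    )
    top = Topology(
        names=stack.atom_name,
        elements=elements,
        residue_indices=stack.res_id,
        residue_names=stack.res_name,
        chain_ids=stack.chain_id,
    )
    return Trajectory(top, np.asarray(stack.coord, dtype=float), frame_interval)


def write_multimodel_pdb(traj: Trajectory, path, frames=None) -> None:
    """Write a trajectory (or a subset of frames) as a multi-model PDB."""
    coords = traj.coords if frames is None else traj.coords[frames]
    if coords.ndim == 2:
        coords = coords[None]
    top = traj.topology
    stack = struc.AtomArrayStack(coords.shape[0], top.n_atoms)
    stack.coord = np.asarray(coords, dtype=np.float32)
    stack.chain_id = top.chain_ids.astype("U4")
    stack.res_id = top.residue_indices
    stack.res_name = top.residue_names.astype("U5")
    stack.atom_name = top.names.astype("U6")
    stack.element = top.elements.astype("U2")
    stack.hetero = np.zeros(top.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def select_atoms(traj: Trajectory, selector: str) -> Trajectory:
    """Reduce a trajectory to a named atom selection, preserving order.

    ``CB_or_CA_for_GLY`` yields exactly one atom per residue (the Cbeta,
    or the Calpha for glycine), the convention used for residue
    interaction networks.
    """
    if selector not in SELECTORS:
        raise SelectionError(
            f"unknown selector {selector!r}; expected one of {SELECTORS}"
        )
    top = traj.topology
    if selector == "heavy":
        indices = np.flatnonzero(top.elements != "H")
        if len(indices) == 0:
            raise SelectionError("selection 'heavy' matched no atoms")
        return Trajectory(top.subset(indices), traj.coords[:, indices],
                          traj.frame_interval)

    indices: list[int] = []
    missing: list[tuple[str, int]] = []
    for g, (chain, resi, resname, _) in enumerate(top.residues):
        if selector == "CA":
            slot = top.atom_slot(g, "CA")
            if slot is None:
                missing.append((chain, resi))
            else:
                indices.append(slot)
        elif selector == "CB_or_CA_for_GLY":
            name = "CA" if resname == "GLY" else "CB"
            slot = top.atom_slot(g, name)
            if slot is None:
                missing.append((chain, resi))
            else:
                indices.append(slot)
        elif selector == "backbone":
            slots = [top.atom_slot(g, n) for n in _BACKBONE_NAMES]
            if any(s is None for s in slots):
                missing.append((chain, resi))
            else:
                indices.extend(slots)
    if missing:
        raise SelectionError(
            f"selector {selector!r}: residues lacking required atoms: "
            + ", ".join(f"{c}:{r}" for c, r in missing)
        )
    idx = np.asarray(indices, dtype=int)
    return Trajectory(top.subset(idx), traj.coords[:, idx], traj.frame_interval)
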