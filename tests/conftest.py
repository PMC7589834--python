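import numpy as np
import pytest

from vardyn.structure import Topology, Trajectory


def make_trajectory(positions, names=None, elements=None, residue_indices=None,
                    residue_names=None, chain_ids=None):
    """Small hand-built trajectory for unit tests.

    ``positions`` is (n_frames, n_atoms, 3) or (n_atoms, 3).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    n = positions.shape[1]
    names = np.array(names if names is not None else ["CA"] * n)
    elements = np.array(
        elements if elements is not None else [nm[0] for nm in names]
    )
    residue_indices = np.array(
        residue_indices if residue_indices is not None else range(1, n + 1)
    )
    residue_names = np.array(
        residue_names if residue_names is not None else ["GLY"] * n
    )
    chain_ids = np.array(chain_ids if chain_ids is not None else ["A"] * n)
    top = Topology(names, elements, residue_indices, residue_names, chain_ids)
    return Trajectory(top, positions)


@pytest.fixture
def helix12():
    from vardyn.synthetic import build_ideal_helix

    return build_ideal_helix(12)


@pytest.fixture
def pdb_2model(tmp_path):
    """A 2-model, 5-atom PDB file written by hand (fixed-width)."""
    coords = [
        ("N", "N", 1.0, 2.0, 3.0),
        ("CA", "C", 2.5, 2.0, 3.0),
        ("C", "C", 3.5, 3.0, 3.0),
        ("O", "O", 3.5, 4.2, 3.0),
        ("CB", "C", 2.5, 0.6, 3.5),
    ]
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL     {model:4d}")
        for k, (name, elem, x, y, z) in enumerate(coords, start=1):
            shift = 0.0 if model == 1 else 1.5
            lines.append(
                f"ATOM  {k:5d}  {name:<3s}ALA A   1    "
                f"{x + shift:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
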