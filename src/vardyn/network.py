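"""Dynamic residue interaction networks.

A frame's residue interaction network (RIN) has one node per residue
and an edge wherever the Cbeta-Cbeta distance (Calpha for glycine) is
within a cutoff, 6.7 A by default.  Two per-residue summaries are
computed over the analysis window and averaged across frames:

* betweenness centrality (BC) - the fraction of all shortest node-pair
  paths passing through a residue, normalised by (N-1)(N-2)/2 so
  profiles are comparable across window lengths;
* average shortest path length (L) - the mean hop distance from a
  residue to every *reachable* residue; unreachable pairs are excluded
  from both numerator and denominator and flagged, never given a
  penalty distance.

Delta profiles contrast a system against its first analysis frame
("vs_first_frame", the per-system convention of dynamic-network plots)
or against another system ("vs_other_system"); residue usage is the
wild-minus-variant difference of delta-BC profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ComparisonError
from .structure import Trajectory, select_atoms

__all__ = [
    "ResidueGraph",
    "CentralityProfile",
    "PathLengthProfile",
    "DeltaProfile",
    "build_rin",
    "betweenness_profile",
    "shortest_path_profile",
    "delta_profile",
    "residue_usage",
]

DEFAULT_CUTOFF = 6.7  # A, Cbeta-Cbeta contact distance


@dataclass
class ResidueGraph:
    """Undirected residue contact graph of one frame."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return list(self.graph.edges)


@dataclass
class CentralityProfile:
    """Mean normalised betweenness centrality per residue."""

    values: pd.Series
    n_frames: int


@dataclass
class PathLengthProfile:
    """Mean average-shortest-path length per residue (hops).

    ``had_unreachable`` flags residues that had unreachable partners in
    at least one frame (those pairs were excluded from the average).
    """

    values: pd.Series
    n_frames: int
    had_unreachable: pd.Series


@dataclass
class DeltaProfile:
    """Per-residue difference of two profiles; ``convention`` records
    the baseline ("vs_first_frame", "vs_other_system" or "usage")."""

    values: pd.Series
    convention: str


def _one_atom_per_residue(traj: Trajectory,
                          selection: str = "CB_or_CA_for_GLY") -> Trajectory:
    sub = select_atoms(traj, selection)
    if sub.n_atoms != sub.n_residues:
        raise ComparisonError(
            f"selection {selection!r} is not one atom per residue"
        )
    return sub


def build_rin(
    traj: Trajectory,
    frame: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    selection: str = "CB_or_CA_for_GLY",
) -> ResidueGraph:
    """Residue interaction network of one frame.

    Edge iff the Euclidean distance between the residues' selected
    atoms is <= ``cutoff`` (boundary inclusive); no self-edges.
    """
    sub = _one_atom_per_residue(traj, selection)
    labels = sub.topology.residue_index_labels
    dist = squareform(pdist(sub.coords[frame]))
    g = nx.Graph()
    g.add_nodes_from(labels.tolist())
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                g.add_edge(int(labels[i]), int(labels[j]))
    return ResidueGraph(g, cutoff)


def betweenness_profile(
    traj: Trajectory,
    window=None,
    cutoff: float = DEFAULT_CUTOFF,
    selection: str = "CB_or_CA_for_GLY",
) -> CentralityProfile:
    """Per-residue betweenness centrality averaged over frames.

    Per frame, node BC is the sum over source-target pairs of the
    fraction of shortest paths passing through the node, normalised by
    (N-1)(N-2)/2.  Disconnected graphs are allowed: unreachable pairs
    contribute zero.
    """
    frames = range(traj.n_frames) if window is None else window
    frames = list(frames)
    acc: pd.Series | None = None
    for f in frames:
        rin = build_rin(traj, f, cutoff, selection)
        bc = nx.betweenness_centrality(rin.graph, normalized=True)
        s = pd.Series(bc, dtype=float)
        acc = s if acc is None else acc + s
    values = acc / len(frames)
    values.index.name = "residue_index"
    values.name = "betweenness"
    return CentralityProfile(values.sort_index(), len(frames))


def shortest_path_profile(
    traj: Trajectory,
    window=None,
    cutoff: float = DEFAULT_CUTOFF,
    selection: str = "CB_or_CA_for_GLY",
) -> PathLengthProfile:
    """Per-residue average shortest path length, averaged over frames.

    ``L_i = sum_j d(i, j) / n_reachable(i)`` per frame; a residue with
    no reachable partner in a frame contributes NaN for that frame (and
    NaN overall if that holds in every frame).
    """
    frames = range(traj.n_frames) if window is None else window
    frames = list(frames)
    per_frame: list[pd.Series] = []
    flags: pd.Series | None = None
    for f in frames:
        rin = build_rin(traj, f, cutoff, selection)
        g = rin.graph
        n = g.number_of_nodes()
        vals, flag = {}, {}
        for node in g.nodes:
            lengths = nx.single_source_shortest_path_length(g, node)
            reachable = len(lengths) - 1  # exclude the node itself
            vals[node] = (
                sum(lengths.values()) / reachable if reachable else np.nan
            )
            flag[node] = reachable < n - 1
        per_frame.append(pd.Series(vals, dtype=float))
        fl = pd.Series(flag)
        flags = fl if flags is None else (flags | fl)
    stacked = pd.concat(per_frame, axis=1)
    values = stacked.mean(axis=1, skipna=True)
    values.index.name = "residue_index"
    values.name = "avg_shortest_path"
    flags.index.name = "residue_index"
    return PathLengthProfile(values.sort_index(), len(frames),
                             flags.sort_index())


def delta_profile(profile_a, profile_b, convention: str = "vs_other_system") -> DeltaProfile:
    """``a - b`` on the shared residue set.

    ``profile_a``/``profile_b`` may be pandas Series or the profile
    dataclasses above (their ``.values`` Series are used).
    """
    a = profile_a.values if hasattr(profile_a, "values") and not isinstance(
        profile_a, pd.Series) else profile_a
    b = profile_b.values if hasattr(profile_b, "values") and not isinstance(
        profile_b, pd.Series) else profile_b
    a, b = pd.Series(a), pd.Series(b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ComparisonError("profiles share no residues")
    values = (a.loc[shared] - b.loc[shared]).astype(float)
    values.index.name = "residue_index"
    return DeltaProfile(values, convention)


def residue_usage(delta_wild: DeltaProfile,
                  delta_variant: DeltaProfile) -> DeltaProfile:
    """Residue usage = delta-BC(wild) - delta-BC(variant).

    Positive values mark residues whose communication role the variant
    has weakened relative to the wild-type.
    """
    diff = delta_profile(delta_wild.values, delta_variant.values,
                         convention="usage")
    return diff
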