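"""Orchestration: wild-type vs variant comparison and the SNP screen.

``run_compare`` executes the full dynamics characterisation for a
wild-type trajectory and any number of variant trajectories, writes
every per-stage result as plain TSV under the output directory, and
logs a JSON manifest with every parameter so a run can be reproduced
bit-for-bit.  ``run_screen`` runs the consensus classifier on a score
table.  Both are thin compositions of the analysis modules; invoking a
module directly with the same window gives identical numbers.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ComparisonError, ConfigError
from .structure import Trajectory, read_multimodel_pdb, write_multimodel_pdb
from .geometry import (
    equilibration_window, rg_series, rmsd_series, rmsf_per_residue,
    bfactor_from_rmsf,
)
from .surface import HBondCriteria, RadiusTable, hbond_count_series, sasa_series
from .correlation import compute_dccm, compute_pca, cumulative_variance
from .network import (
    betweenness_profile, shortest_path_profile, delta_profile, residue_usage,
)
from .secondary import assign_sse, sse_fractions
from .landscape import compute_fel, extract_basins
from .screen import consensus, read_score_table, tool_agreement_matrix

__all__ = ["RunConfig", "run_compare", "run_screen"]


@dataclass
class RunConfig:
    """Every knob of a comparison run, serialised into the manifest."""

    wild_path: str = ""
    variant_paths: dict = field(default_factory=dict)  # name -> path
    score_table_path: str = ""
    output_dir: str = "vardyn_out"
    rmsd_selection: str = "backbone"
    rmsf_selection: str = "CA"
    rmsd_reference: str = "first_frame"
    equilibration_fraction: float = 0.4
    rin_cutoff: float = 6.7
    fel_bins: tuple = (50, 50)
    temperature: float = 300.0
    hbond_max_distance: float = 3.5
    sasa_points: int = 960
    sasa_stride: int = 1
    min_tools: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ConfigError("equilibration_fraction must lie in [0, 1)")
        for path in [self.wild_path, *self.variant_paths.values()]:
            if path and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")


def _log(msg: str) -> None:
    print(f"[vardyn] {msg}", file=sys.stderr)


def _write_series(series, path: Path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)


def _write_profile(profile: pd.Series, path: Path) -> None:
    profile.rename_axis("residue_index").to_csv(path, sep="\t")


def _analyse_system(name: str, traj: Trajectory, cfg: RunConfig,
                    outdir: Path) -> dict:
    t0 = time.time()
    sysdir = outdir / name
    sysdir.mkdir(parents=True, exist_ok=True)

    rmsd = rmsd_series(traj, cfg.rmsd_reference, cfg.rmsd_selection)
    window = equilibration_window(rmsd, cfg.equilibration_fraction)
    win_traj = traj.with_frames(list(window))

    rg = rg_series(win_traj)
    sasa = sasa_series(win_traj, RadiusTable(), cfg.sasa_points,
                       cfg.sasa_stride)
    hbonds = hbond_count_series(
        win_traj, HBondCriteria(donor_acceptor_max=cfg.hbond_max_distance)
    )
    rmsf = rmsf_per_residue(win_traj, cfg.rmsf_selection)
    bfac = bfactor_from_rmsf(rmsf)
    dccm = compute_dccm(win_traj, cfg.rmsf_selection)
    pca = compute_pca(win_traj, cfg.rmsf_selection)
    bc = betweenness_profile(win_traj, cutoff=cfg.rin_cutoff)
    pathlen = shortest_path_profile(win_traj, cutoff=cfg.rin_cutoff)
    timeline = assign_sse(win_traj)
    fractions = sse_fractions(timeline)
    rmsd_win = rmsd_series(win_traj, cfg.rmsd_reference, cfg.rmsd_selection)
    fel = compute_fel(rmsd_win, rg, cfg.fel_bins, cfg.temperature)
    basins = extract_basins(fel, rmsd_win, rg)

    _write_series(rmsd, sysdir / "rmsd.tsv")
    _write_series(rg, sysdir / "rg.tsv")
    _write_series(sasa, sysdir / "sasa.tsv")
    _write_series(hbonds, sysdir / "hbonds.tsv")
    _write_profile(rmsf, sysdir / "rmsf.tsv")
    _write_profile(bfac, sysdir / "bfactor.tsv")
    dccm.to_frame().to_csv(sysdir / "dccm.tsv", sep="\t")
    pd.DataFrame(pca.projections[:, :3],
                 columns=["PC1", "PC2", "PC3"]).to_csv(
        sysdir / "pca_projections.tsv", sep="\t", index=False)
    _write_profile(pca.pc1_residue_mobility, sysdir / "pc1_mobility.tsv")
    _write_profile(bc.values, sysdir / "betweenness.tsv")
    _write_profile(pathlen.values, sysdir / "avg_shortest_path.tsv")
    timeline.to_frame().to_csv(sysdir / "sse_timeline.tsv", sep="\t",
                               index=False)
    fractions.to_csv(sysdir / "sse_fractions.tsv", sep="\t")
    fel.to_long_format().to_csv(sysdir / "fel.tsv", sep="\t", index=False)
    for k, basin in enumerate(basins):
        frame = window[0] + basin.representative_frame
        write_multimodel_pdb(traj, sysdir / f"basin{k}_representative.pdb",
                             frames=[frame])

    _log(f"{name}: analysed {len(window)} frames in "
         f"{time.time() - t0:.1f} s")
    return {
        "window_start": window[0],
        "window_stop": window[-1] + 1,
        "rmsf": rmsf,
        "bc": bc,
        "pathlen": pathlen,
        "pca_top3": cumulative_variance(pca, 3),
        "basins": [
            {"bin": b.bin_index, "n_members": int(len(b.member_frames)),
             "G": b.G, "representative_frame": int(b.representative_frame)}
            for b in basins
        ],
    }


def run_compare(config: RunConfig) -> dict:
    """Full wild-vs-variant comparison; returns the manifest dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    systems = {"wild": read_multimodel_pdb(config.wild_path)}
    for name, path in config.variant_paths.items():
        systems[name] = read_multimodel_pdb(path)

    wild_res = set(systems["wild"].topology.residue_index_labels.tolist())
    for name, traj in systems.items():
        res = set(traj.topology.residue_index_labels.tolist())
        if res != wild_res:
            offending = sorted(res.symmetric_difference(wild_res))
            raise ComparisonError(
                f"system {name!r} numbering differs from wild-type at "
                f"residues {offending}"
            )

    results = {}
    for name, traj in systems.items():
        results[name] = _analyse_system(name, traj, config, outdir)

    # wild-vs-variant contrasts
    for name in config.variant_paths:
        contrast = outdir / f"delta_wild_vs_{name}"
        contrast.mkdir(exist_ok=True)
        d_rmsf = delta_profile(results["wild"]["rmsf"],
                               results[name]["rmsf"])
        d_bc = delta_profile(results["wild"]["bc"], results[name]["bc"])
        d_l = delta_profile(results["wild"]["pathlen"],
                            results[name]["pathlen"])
        _write_profile(d_rmsf.values.rename("delta_rmsf"),
                       contrast / "delta_rmsf.tsv")
        _write_profile(d_bc.values.rename("delta_bc"),
                       contrast / "delta_bc.tsv")
        _write_profile(d_l.values.rename("delta_l"),
                       contrast / "delta_l.tsv")

    manifest = {
        "tool": "vardyn",
        "version": __version__,
        "command": "compare",
        "config": {**asdict(config),
                   "fel_bins": list(config.fel_bins)},
        "systems": {
            name: {k: v for k, v in res.items()
                   if k in ("window_start", "window_stop", "pca_top3",
                            "basins")}
            for name, res in results.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_screen(config: RunConfig) -> pd.DataFrame:
    """Consensus screen on the configured score table.

    Writes ``consensus.tsv`` and ``tool_agreement.tsv`` under the
    output directory and returns the consensus table.  An empty table
    produces an empty report with a warning (not an error).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(config.score_table_path, sep=None, engine="python",
                     dtype=str)
    if df.empty:
        _log("score table is empty; writing empty report")
        empty = pd.DataFrame(columns=["rs_id", "substitution",
                                      "n_deleterious",
                                      "is_consensus_deleterious"])
        empty.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        return empty
    records = read_score_table(df)
    table = consensus(records, min_tools=config.min_tools)
    table.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    if len(records) >= 2:
        phi, undefined = tool_agreement_matrix(records)
        phi.to_csv(outdir / "tool_agreement.tsv", sep="\t")
    n_hits = int(table["is_consensus_deleterious"].sum())
    _log(f"screen: {n_hits} of {len(table)} variants flagged at "
         f">= {config.min_tools} tools")
    return table
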