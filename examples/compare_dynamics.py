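"""Wild-type vs rigidified-variant trajectory comparison, end to end.

Builds two synthetic ensembles around the same helical reference - the
"variant" has half the wild-type's per-residue displacement variance,
mimicking a rigidifying substitution - and runs the full comparison
pipeline: RMSD/Rg/SASA/H-bond series, RMSF and B-factor profiles,
DCCM, PCA, residue-network centralities, secondary-structure timeline
and the free-energy landscape, plus wild-minus-variant delta tables.
"""

import json
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from vardyn import (
    HarmonicEnsembleSpec, RunConfig, build_ideal_helix, run_compare,
    sample_harmonic_ensemble, write_multimodel_pdb,
)

workdir = Path(tempfile.mkdtemp(prefix="vardyn_demo_"))
n_res, n_frames = 12, 80
reference = build_ideal_helix(n_res)
cov = 0.6 * np.eye(n_res)

wild = sample_harmonic_ensemble(
    HarmonicEnsembleSpec(reference, cov, n_frames, seed=1))
variant = sample_harmonic_ensemble(
    HarmonicEnsembleSpec(reference, 0.25 * cov, n_frames, seed=2))
write_multimodel_pdb(wild, workdir / "wild.pdb")
write_multimodel_pdb(variant, workdir / "variant.pdb")

config = RunConfig(
    wild_path=str(workdir / "wild.pdb"),
    variant_paths={"rigid": str(workdir / "variant.pdb")},
    output_dir=str(workdir / "out"),
    sasa_stride=8,
    fel_bins=(5, 5),
)
manifest = run_compare(config)

print("analysis windows and PCA variance captured by the top 3 PCs:")
print(json.dumps(manifest["systems"], indent=2, sort_keys=True))

delta = pd.read_csv(workdir / "out" / "delta_wild_vs_rigid" /
                    "delta_rmsf.tsv", sep="\t", index_col=0)
print("\nwild-minus-variant RMSF per residue (A):")
print(delta.round(3).to_string())
print("\nEvery delta is positive: the variant fluctuates less at every")
print("residue, the signature of a rigidifying substitution. All stage")
print(f"outputs are plain TSV under {workdir / 'out'}.")
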