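# vardyn

Consensus missense-variant screening and comparative molecular-dynamics
trajectory analysis, built for studies that ask two linked questions
about a protein domain — here modelled on the first nucleotide-binding
domain (NBD1, residues 903–1147) of the human ABCA1 cholesterol
exporter:

1. **Which missense variants (nsSNPs) are worth simulating?**
   A consensus screen consumes a table of scores from nine established
   predictors (SIFT, PolyPhen-2 HumDiv/HumVar, PROVEAN, I-Mutant 3.0,
   PhD-SNP, SNP&GO, PANTHER, PredictSNP, MAPP — consumed as scores, never
   re-run) and flags a variant as deleterious when at least seven of the
   nine tools pass their published cutoffs.
2. **How does a flagged variant change the domain's dynamics?**
   A trajectory-characterisation suite compares wild-type and variant
   ensembles frame by frame: RMSD/Rg/SASA/H-bond series, per-residue
   RMSF and B-factors, dynamic cross-correlation maps, essential-dynamics
   PCA, dynamic residue interaction networks, secondary-structure
   timelines and (RMSD, Rg) free-energy landscapes.

The library is the primary interface; `examples/` holds one short
narrative script per capability, and a thin CLI (`vardyn
compare/screen/simulate`) wraps the pipeline for shell use.

## The statistics at the core

* **RMSF / B-factor** — after least-squares (Kabsch) superposition on the
  mean structure, `RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` and
  `B_i = (8π²/3)·RMSF_i²`.
* **DCCM** — normalised displacement covariance
  `C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^½ ∈ [−1, 1]`; +1 is
  correlated, −1 antiphase motion.
* **PCA (essential dynamics)** — eigendecomposition of the 3N×3N Cα
  positional covariance; eigenvalues are mode variances (Å²), the
  leading eigenvectors the dominant collective motions.
* **Residue networks** — nodes are residues, edges are Cβ–Cβ contacts
  (Cα for Gly) within 6.7 Å; per-residue betweenness centrality (BC,
  normalised by (N−1)(N−2)/2) and average shortest path length L over
  the trajectory, with wild-minus-variant Δ profiles and residue usage
  `ΔBC_wild − ΔBC_variant`.
* **Free-energy landscape** — Boltzmann inversion of the (RMSD, Rg)
  occupancy histogram, `G_i = −k_B T ln(N_i/N_max)` at 300 K with
  `k_B = 0.0083145 kJ/mol/K`; basins are local minima with
  representative frames.
* **Secondary structure** — a simplified Kabsch–Sander assignment
  (H/G/E/T/S/C) from the electrostatic H-bond model
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with
  geometrically reconstructed amide hydrogens.

Because the original trajectories of such studies are rarely deposited,
the package ships a synthetic-data module that generates ensembles with
*known* ground truth — planted residue–residue correlations, two-state
occupancies, ideal helix/strand backbones, and score tables with planted
deleterious variants — so every stage is validated quantitatively.

## Worked example

```sh
python examples/consensus_screen.py
```

prints

```
       rs_id substitution  n_deleterious  is_consensus_deleterious
 rs762112742        S741C              8                      True
rs1394779021       S1067C              7                      True
rs1461682152        Y793C              7                      True
 rs985622413       G1050V              7                      True
```

Each row is one candidate ABCA1 nsSNP from the packaged score table;
`n_deleterious` counts supporting tools (missing scores are no-calls and
never count either way), and all four variants reach the seven-tool
consensus — S741C with eight supporting tools. The other examples follow
the same pattern: `compare_dynamics.py` runs the full wild-vs-variant
pipeline on a synthetic rigidified variant and shows every per-residue
ΔRMSF positive; `correlation_maps.py` recovers a planted 0.9 correlation
block to three decimals; `free_energy_landscape.py` recovers the
k_BT·ln 2 ≈ 1.73 kJ/mol basin gap of a 2:1 two-state ensemble.

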