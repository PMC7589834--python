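# Methods

This note documents the models, parameter choices and numerical
conventions behind each analysis stage, what the synthetic generators
do and do not emulate, and the known limitations.

## Structure model and I/O

All stages share one in-memory model: a `Topology` (per-atom names,
elements, residue indices, chains) plus a `Trajectory` of frames
(n_frames × n_atoms × 3, Å). Residue numbering is the author numbering
of the input file and is never rewritten, so motif positions quoted in
the literature (Walker A 933–940, Walker B 1053–1057, LSGGQ 1033–1037,
H-loop 1088–1090 of ABCA1 NBD1) remain valid labels. Multi-model PDB is
the only trajectory format: frames are MODEL blocks ordered by model
number, the topology comes from the first model, and models with a
different atom count are rejected. Alternate locations collapse to the
highest-occupancy conformer because every downstream stage assumes
single-conformer frames. Parsing and writing are delegated to biotite;
a pre-scan of the raw lines produces parse errors that name the
offending line. Elements missing from the element column are inferred
from the atom name (leading digit ⇒ hydrogen, known two-letter symbols
kept, else first letter).

Selections are named, not expression-based: `CA`, `backbone`
(N/CA/C/O), `heavy` (element ≠ H) and `CB_or_CA_for_GLY` (exactly one
atom per residue, the convention of residue-interaction networks). A
residue that cannot satisfy a selection is an error listing the
residue, never silently dropped.

## Synthetic ensembles (what the tests mean)

The generators define ensembles whose ground truth is known exactly;
they are first-class, tested code, not ad-hoc fixtures.

* **Harmonic ensemble** — frames are `reference + displacement`, where
  the per-residue displacement is Gaussian with a prescribed N×N
  residue covariance (Å², per axis), drawn independently for x, y, z
  and applied identically to all atoms of a residue. This is the
  fluctuation structure DCCM, PCA and RMSF assume. Because the three
  axes are sampled independently with the same covariance, each
  residue-space eigenvalue appears as a near-degenerate triplet in the
  3N eigen-spectrum; recovery tests therefore compare *residue-mode*
  fractions (sums over each PC triplet).
* **Two-state ensemble** — each frame is conformation A with a fixed
  occupancy, else B, plus isotropic Gaussian jitter. This is the
  minimal model of a two-basin free-energy landscape.
* **Ideal backbones** — helix (φ = −57°, ψ = −47°), extended chain
  (φ = ψ = 180°) and a two-strand antiparallel sheet (φ = −139°,
  ψ = 135°) are built from ideal internal coordinates (N–CA 1.458,
  CA–C 1.525, C–N 1.329, C=O 1.231 Å; ω = 180°) by natural-extension
  (NeRF) build-up. The sheet's second strand is placed by a two-fold
  rotation plus a rigid shift fitted deterministically so the two-way
  N–H···O=C pairs of the antiparallel register sit at 2.9 Å. Measured
  on the helix: CA(i)–CA(i+1) 3.81 Å, O(i)···N(i+4) 3.09 Å,
  O(i)···N(i+3) 3.20 Å.
* **Score tables** — planted deleterious rows draw each tool's score
  past its cutoff with probability 0.95 (neutral rows 0.05), cells are
  blanked at a configurable missing rate (default 0.05), and the
  PolyPhen-2 sub-scores pass or fail jointly since they form one tool.

All generators are bit-reproducible for a fixed seed. What passing
tests on these ensembles do **not** show: real force-field ensembles
are anharmonic, solvated and autocorrelated in time; the generators
have none of that, so agreement here validates the estimators, not any
claim about a specific protein's dynamics.

## Scalar descriptors

Superposition is the mass-unweighted Kabsch fit (SVD with a
determinant correction, so the rotation is always proper);
mass-weighting is irrelevant for the Cα-level selections these
analyses use. RMSD series use the first frame as reference by default
(`mean_structure` optional). RMSF uses a two-pass reference: fit to
the first frame, average, refit to that mean, average again — the
standard mean-structure convention behind B-factor tubes
(`B = 8π²/3 · RMSF²`). Rg is mass-weighted with standard atomic masses
(internal table; unknown elements are an error, not a guess).

The equilibration window is a configuration fraction, not a detector:
`window = [⌈f·n⌉, n)` with f = 0.4 by default, mirroring the common
practice of discarding the first 40% of a production run (e.g. 120 of
300 ns) after visual RMSD inspection. A one-frame window warns.

## SASA and hydrogen bonds

SASA follows Shrake–Rupley: each atom inflated by the 1.4 Å probe, the
accessible fraction of a quasi-uniform point shell (960 points by
default) converted to area; the quadrature is delegated to
`biotite.structure.sasa` with this package's radius table (C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20 Å). A doubling of the point count moves
an isolated atom's area by < 1%, and the isolated-atom value is
checked against 4π(r + 1.4)².

Hydrogen-bond counting defaults to `heavy_only` because the structures
handled here carry no hydrogens. A pair counts when: donor is N, or a
non-carbonyl O; acceptor is O, or a non-amide N (the backbone amide N
is donor-only — its lone pair is delocalised into the peptide bond);
D···A ≤ 3.5 Å; and the acceptor-antecedent angle (e.g. C=O···N) is
≥ 120°. The angular term is essential: in a true α-helix the
i→i+3 (3.20 Å) and i→i+2 (3.36 Å) O···N separations also fall inside
3.5 Å, but at acceptor angles of 111° and 75° versus 161° for the
canonical i→i+4 register — a plain distance cutoff would triple-count
helix bonds. Same-residue pairs and the covalent N(i+1)–O(i) pair
across each peptide bond are excluded. With explicit hydrogens the
criterion switches to D–H···A ≥ 120°. Absolute counts are therefore a
self-consistent geometric definition, comparable between systems
analysed by this package but not directly against engines with their
own (often energy-based) definitions.

## DCCM and PCA

Frames are superposed on the window's mean structure (disabling
superposition is exposed for rigid-motion sanity checks), deviations
taken per residue, and

    C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)^½ .

This is the only normalisation with C_ii = 1 and range [−1, 1].
Zero-variance residues yield NaN entries plus an explicit flag — never
a silent 0, which would masquerade as "uncorrelated". DCCM is
symmetric by construction and invariant to time reversal.

PCA diagonalises the 3N×3N covariance of the superposed coordinates
(ddof 0, so the eigenvalue sum equals Σ RMSF² exactly on the same
selection and window). Eigenvector signs are fixed by forcing the
largest-magnitude component positive, making projections reproducible.
PC1 residue mobility is √λ₁ times the per-residue norm of the first
eigenvector. No mass-weighting, matching the residue-level (Cα)
convention of the rest of the package.

## Residue interaction networks

Edges connect residues whose Cβ (Cα for Gly) atoms lie within 6.7 Å,
boundary inclusive. Graphs are unweighted (hop counts). Betweenness is
averaged over frames and normalised by (N−1)(N−2)/2 so profiles are
comparable across window lengths; computation is delegated to
networkx, and both BC and L are verified against hand-written
exhaustive path-enumeration oracles on random small graphs. Average
shortest path excludes unreachable pairs from numerator and
denominator (keeping L finite on disconnected graphs) and flags the
affected residues; a fully isolated residue is NaN. Δ profiles support
two baselines, recorded in the result: `vs_first_frame` (per-system
change, the convention of dynamic-network difference plots) and
`vs_other_system` (direct wild-variant contrast); residue usage is
ΔBC_wild − ΔBC_variant.

## Secondary structure

A deliberately small Kabsch–Sander core: backbone H-bonds scored with
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond if
E < −0.5, amide H rebuilt at 1.01 Å anti to the previous carbonyl,
pairs closer than two residues in chain order never evaluated, peptide
connectivity decided by the C(i)–N(i+1) distance (≤ 2.0 Å), so chain
breaks and multi-chain sheets are handled without bookkeeping. Two
consecutive (i, i+4) turns make an α-helix (H) over the spanned
residues; (i, i+3) analogously 3₁₀ (G); nonlocal two-way or flanking
bond patterns make β bridges (E); leftover turn residues are T; Cα
curvature above 70° is a bend (S); priority H > E > G > T > S > C,
terminal residues defaulting to C. Omitted relative to full DSSP:
π-helices, chirality flags, bridge-partner bookkeeping beyond the
class label. On the fixtures this yields `CHHHHHHHHHHC` for the
12-residue helix, all-coil for the extended chain and dipeptide, and
strand labels on both sheets' bridge partners.

## Free-energy landscape

`G_i = −k_B T ln(N_i/N_max)` with k_B = 0.0083145 kJ/mol/K and T =
300 K by default, over a 50×50 histogram of the observed (RMSD, Rg)
range (numpy's convention: last bin closed above). Empty bins receive
an artificial barrier of max(G) + 2 k_B T so the grid is finite — the
barrier marks "unvisited", not a physical estimate. Basin minima are
populated bins with no strictly lower 4-connected populated neighbour
(4- rather than 8-connectivity so two diagonal-adjacent coarse basins
both survive), ranked by G then population; members are the frames in
the minimum bin and the representative frame is the member nearest the
bin centre in bin-width units. ΔG between two basins converges to
−k_B T ln(p₁/p₂) as sampling grows; at 10⁴ frames the binomial noise
is ≈ 0.05 kJ/mol.

## Consensus screen

Cutoffs, with boundaries exactly as published: SIFT ≤ 0.05; PolyPhen-2
HumDiv > 0.9 **and** HumVar > 0.9 (one tool; either sub-score missing
⇒ no-call); PROVEAN ≤ −2.5; I-Mutant < −0.5 (strict); PhD-SNP > 0.5;
SNP&GO > 0.5; PANTHER ≥ 0.5; PredictSNP and MAPP: categorical "D" or
score > 0.5 (their numeric thresholds are not published, so the value
is exposed in `CutoffTable`). Missing cells are no-calls: they count
neither for nor against, which is what lets a variant with two silent
tools still reach a seven-of-nine consensus. The packaged table
reproduces the published four-variant outcome (8, 7, 7, 7 supporting
tools). Tool agreement is the phi coefficient of binary calls over
co-called variants; pairs where a tool's calls are constant (e.g. a
categorical tool that called everything "D") are flagged undefined
rather than reported as 0. The per-variant significance sometimes
printed alongside such screens is not computed here — no published
definition exists to implement.

## Pipeline

`run_compare` applies the stages in a fixed order per system (RMSD →
window → Rg/SASA/H-bonds → RMSF/B-factor → DCCM/PCA → networks → SSE →
FEL/basins), writes every result as TSV, representative basin frames
as single-model PDB, and a JSON manifest holding every parameter — the
manifest is sufficient to re-run bit-identically, and each stage's
file equals a direct module call with the same window (no hidden
state). SASA supports a frame stride for long trajectories; all other
stages use every window frame. Demonstration and test problem sizes
(10–60 residues, 60–10⁴ frames) were chosen so each stage's
statistical target (e.g. ±0.05 on a correlation, ±0.3 kJ/mol on a
basin gap) is comfortably inside the generator's sampling noise.

## Known limitations

* Only multi-model PDB input; no DCD/XTC/mmCIF, no bond perception,
  no hydrogen placement.
* Heavy-only H-bond counts are a geometric surrogate, not an energy
  model; compare within this package only.
* The DSSP re-implementation targets class-level agreement, not
  per-residue fidelity to any particular DSSP build.
* The screen consumes predictor scores; it cannot re-derive them, and
  rows whose tools all abstain are simply unflagged.
* Landscape energies are relative occupancy measures; absolute depths
  depend on bin geometry and sampling.
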