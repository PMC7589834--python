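"""Secondary-structure assignment on reference backbones.

Runs the simplified Kabsch-Sander assignment on three constructed
fixtures - an ideal alpha-helix, a fully extended chain and a two-strand
antiparallel beta-sheet - and prints the per-residue class strings.
"""

from vardyn import (
    assign_sse, build_antiparallel_sheet, build_extended_chain,
    build_ideal_helix, sse_fractions,
)

for label, traj in [
    ("ideal alpha-helix (12 aa)", build_ideal_helix(12)),
    ("extended chain   (10 aa)", build_extended_chain(10)),
    ("antiparallel sheet (2 x 8 aa)", build_antiparallel_sheet(8)),
]:
    timeline = assign_sse(traj)
    print(f"{label:32s} {''.join(timeline.classes[0])}")

print()
print("Codes: H alpha-helix, G 3-10 helix, E strand, T turn, S bend,")
print("C coil. The helix core is H (the canonical i -> i+4 hydrogen-bond")
print("ladder), the extended chain has no bonded partner so stays coil,")
print("and the sheet's bridge partners are assigned E on both strands.")

frac = sse_fractions(assign_sse(build_ideal_helix(12)))
print()
print("Per-residue class fractions over frames (helix, single frame):")
print(frac.round(2).to_string())
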