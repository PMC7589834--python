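"""Consensus deleteriousness screen on the packaged ABCA1 score table.

Loads the packaged table of candidate ABCA1 missense variants (one row
per nsSNP, one column per predictor score), applies each tool's
published cutoff, and flags variants called deleterious by at least
seven of the nine tools.
"""

from vardyn import consensus, load_packaged_table, read_score_table, tool_agreement_matrix

records = read_score_table(load_packaged_table())
table = consensus(records, min_tools=7)

print(table[["rs_id", "substitution", "n_deleterious",
             "is_consensus_deleterious"]].to_string(index=False))
print()
print("n_deleterious counts how many of the nine tools called the variant")
print("deleterious; missing scores are no-calls and never count. All four")
print("variants reach the seven-tool consensus; S741C is supported by 8.")

phi, undefined = tool_agreement_matrix(records)
print()
print("Pairwise tool agreement (phi) over co-called variants:")
print(phi.round(2).to_string())
print("(NaN marks pairs with too few informative co-calls to correlate.)")
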