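"""Cross-signature enrichment statistics on published count tables.

The 2x2 machinery shared by every comparison stage: mouse-model
signature overlap (Fisher), transcription-factor enrichment
(chi-squared), homolog mapping, and gene-set over-representation.
"""

from astrotraj.enrichment import (
    ContingencyTable,
    HomologyMap,
    SignatureSet,
    chi_squared_2x2,
    fisher_exact_2x2,
    map_homologs,
    ora_gene_sets,
)

# 5xFAD disease-associated astrocytes vs the human reactive signature:
# 29 shared genes of 224 mapped mouse genes and 196 human genes within
# a 17,012-gene universe.
res = fisher_exact_2x2(ContingencyTable(29, 195, 167, 16621))
print(f"5xFAD overlap: p = {res.p_value:.3e}, odds ratio = {res.odds_ratio:.2f}")

# Transcription factors among downregulated genes: 17 of 144 are TFs
# against 1129 TFs among 17,012 genes.
tf = chi_squared_2x2(ContingencyTable(17, 127, 1112, 15756))
print(f"TF enrichment (down): chi2 = {tf.statistic:.2f}, p = {tf.p_value:.4f}, "
      f"OR = {tf.table.odds_ratio:.2f}")

# Mouse -> human homolog mapping restricted to the analysis universe.
mapping = HomologyMap({"Gfap": "GFAP", "Vim": "VIM", "Fake1": "NOPE"})
mouse = SignatureSet("mouse", ["Gfap", "Vim", "Fake1"], {"Gfap": "up", "Vim": "up"})
mapped, unmapped = map_homologs(mouse, mapping, {"GFAP", "VIM", "NRXN1"})
print(f"homologs: {mapped.genes} mapped, {unmapped} dropped")

# Over-representation of a signature against a small gene-set collection.
universe = {f"G{i}" for i in range(300)}
signature = SignatureSet("sig", [f"G{i}" for i in range(25)])
collection = {"reactive": [f"G{i}" for i in range(20)], "unrelated": [f"G{i}" for i in range(200, 230)]}
print(ora_gene_sets(signature, collection, universe).round(4).to_string(index=False))

# Small p with OR >> 1 marks sets concentrated inside the signature.
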