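"""Graft species missing from a phylogeny at their congeneric MRCA.

Field inventories routinely record species absent from published
mega-phylogenies. Each missing species is attached at the most recent common
ancestor of its congeners (or by bisecting the terminal branch of a single
congener); distances among original tips are untouched and an ultrametric
tree stays ultrametric.
"""

import phylograd as pg

tree = pg.phylo.parse_newick(
    "(((Quercus_alba:10,Quercus_rubra:10):25,Fagus_grandifolia:35):15,"
    "Acer_rubrum:50);")

missing = ["Quercus_velutina", "Fagus_sylvatica", "Betula_nigra"]
grafted, report = pg.graft_missing(tree, missing)

print(report.to_frame().to_string(index=False))
print()

D = pg.cophenetic_matrix(grafted)
print("patristic distance Quercus_velutina - Quercus_alba:",
      D.loc["Quercus_velutina", "Quercus_alba"], "Myr  (= 2 x MRCA height)")
print("patristic distance Fagus_sylvatica - Fagus_grandifolia:",
      D.loc["Fagus_sylvatica", "Fagus_grandifolia"],
      "Myr  (= terminal branch, bisected)")
print("Betula_nigra has no congener in the tree ->",
      report.excluded, "excluded and reported")
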