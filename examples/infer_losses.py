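"""Map family losses on a species tree under Dollo parsimony.

Uses a toy land-plant cladogram where liverworts, early-diverging mosses
and vascular plants carry the family but hornworts and the moss crown
do not: the reconstruction places a single gain at the common ancestor
and finds the minimal set of independent losses.
"""

from rgfmine.phylo import dollo_map, enumerate_loss_oracle
from rgfmine.seqio import read_newick

newick = ("(((horn1,horn2),((liv1,liv2),(mossE1,(mossE2,(mossB,mossA))))),"
          "(lyco,(fern,(gymno,angio))));")
tree = read_newick(newick)

presence = {"horn1": False, "horn2": False, "liv1": True, "liv2": True,
            "mossE1": True, "mossE2": True, "mossB": False, "mossA": False,
            "lyco": True, "fern": True, "gymno": True, "angio": True}

result = dollo_map(tree, presence, character="family")
labels = {n.label: sorted(l.taxon.label for l in n.leaf_iter())
          for n in tree.preorder_node_iter() if n.is_internal()}

print(f"gain placed at: {result.gain_node}")
print(f"independent losses: {result.n_independent_losses}")
for edge in result.loss_edges:
    tips = labels.get(edge, [edge])
    print(f"  loss on the edge to {{{', '.join(tips)}}}")
print(f"brute-force minimal loss count: {enumerate_loss_oracle(tree, presence)}")
print("\nEach loss is a maximal clade in which the family was not detected; "
      "under a single-origin assumption this is the minimal reconstruction.")
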