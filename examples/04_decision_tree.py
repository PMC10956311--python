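"""CART classifier with cost-complexity pruning and variable importance.

The tree is grown greedily on Gini impurity, its weakest-link pruning
sequence is tabulated with 10-fold cross-validated errors (the printcp
layout), and it is pruned at CP = 0.03.  Importance is the percent share
of realised impurity reduction at primary splits.
"""

from pdxms import CohortGenSpec, fit_cart, generate_cohort, prune_tree

cohort = generate_cohort(CohortGenSpec(n=320, seed=3)).table
tree = fit_cart(cohort, "engrafted",
                variables=["age", "ki67", "subtype", "hg", "nac", "size_cm",
                           "NP", "SP", "ICP", "TILP"],
                seed=1)
print("pruning table (CP / splits / training and CV error, relative to "
      "the root risk):")
print(tree.cp_table.round(4).to_string(index=False))

pruned = prune_tree(tree, cp=0.03)
print(f"\npruned at CP=0.03: {pruned.n_splits()} split(s) "
      f"(full tree had {tree.n_splits()})")
print("variable importance (% of impurity reduction):")
for var, pct in sorted(pruned.variable_importance.items(),
                       key=lambda kv: -kv[1]):
    print(f"  {var:>8}: {pct:5.1f}")
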