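"""Median-joining network of simulated R-macro haplotypes.

Builds binary haplotypes for a small cohort, keeps haplotypes seen more than
once, applies star contraction (radius 5, as used for large clades), builds
the median-joining network (epsilon 10) and prunes it with the maximum
parsimony step. The node and edge counts summarize the haplotype diversity;
median (inferred) nodes are unobserved intermediates the method adds to
shorten connections.
"""

from mitocline import (
    HaplotypeSet,
    build_mj,
    bundled_tree,
    default_panel,
    denmark_model,
    frequency_filter,
    mp_postprocess,
    simulate_cohort,
    simulate_genotypes,
    star_contraction,
)

tree = bundled_tree()
panel = default_panel(tree)
tree.attach_panel(panel)

cohort = simulate_cohort(denmark_model(), tree, n=800, seed=11)
r_macro = cohort[cohort["true_hg"].map(
    lambda h: tree.ancestor_at_level(h, "macro") == "R"
)].reset_index(drop=True)
geno = simulate_genotypes(r_macro, tree, panel, private_mut_rate=0.004, seed=12)

h = HaplotypeSet.from_matrix(geno.calls, labels=list(r_macro["true_hg"]))
print(f"distinct haplotypes among {len(r_macro)} R-macro samples: {len(h)}")

h = frequency_filter(h, min_count=2)
print(f"after the frequency > 1 filter: {len(h)}")

h, log = star_contraction(h, max_radius=5)
print(f"after star contraction (radius 5): {len(h)}  ({len(log)} stars merged)")

net = mp_postprocess(build_mj(h, epsilon=10))
n_median = len(net.median_nodes)
print(
    f"\nMJ network: {net.graph.number_of_nodes()} nodes "
    f"({n_median} inferred medians), {net.graph.number_of_edges()} edges, "
    f"MP mode = {net.params['mp_mode']}"
)
print("Observed haplotypes always survive pruning; the network stays connected.")
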