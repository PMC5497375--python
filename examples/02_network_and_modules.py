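"""Build a co-expression network step by step and cluster it with MCL.

Generates a stage-wise expression matrix with two planted 20-gene modules,
overlays Pearson correlation on a simulated interaction scaffold, keeps the
significantly co-expressed edges (BH q <= 0.01) and reads the functional
modules off the MCL partition.
"""

import pivotnet as pn

expr, truth = pn.generate_stage_expression(
    n_genes=400, modules=[(20, 0.9), (20, 0.9)], n_pivots=0,
    de_spec={}, seed=7)
ppi_table = pn.generate_ppi(truth, seed=8)
go_table = pn.generate_go_annotations(truth, seed=9)

tpm = pn.compute_tpm(expr)
expressed = pn.filter_expressed(tpm)            # TPM > 1 in > 50% replicates
tpm = tpm.subset_genes(expressed)
print(f"{len(expressed)} of {len(truth.genes)} genes pass the expressed filter")

scaffold = pn.load_ppi(ppi_table)
network = pn.edge_correlation(scaffold, pn.log2_transform(tpm), q_cutoff=0.01)
print(f"{network.number_of_edges()} of {network.graph['n_tested']} scaffold "
      f"edges are significantly co-expressed "
      f"({network.number_of_nodes()} genes connected)")

clusters = pn.mcl_cluster(network)
modules = pn.select_functional_modules(clusters, go_table, set(network.nodes))
print(f"MCL found {len(clusters)} clusters; "
      f"{len(modules.functional_indices)} are functional modules "
      f"(>= 10 genes, GO-enriched at q <= 0.05)")
for i in modules.functional_indices:
    best = min(modules.enrichment[i], key=lambda r: r.q)
    members = modules.clusters[i]
    planted = {truth.module_assignments.get(g) for g in members} - {None}
    print(f"  module {i}: {len(members)} genes, top term {best.term} "
          f"(k={best.k}/{best.K}, q={best.q:.2e}); planted module(s) {planted}")
print()
print("With strong planted co-expression the two MCL modules coincide with "
      "the planted gene sets and each is enriched for its planted term.")
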