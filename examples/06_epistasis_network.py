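"""Build an epistasis network from pairwise logistic interaction tests.

Two independent interacting pairs drive disease in separate halves of the
sample; all SNP pairs among the top NPDR hits are tested with
y ~ g1 + g2 + g1*g2 and significant product terms become weighted edges.
"""

import npdr

G, y, truth = npdr.simulate_design("interact-4", seed=2)
print(f"planted interacting pairs: ({truth.functional_snps[0]}, "
      f"{truth.functional_snps[1]}) and ({truth.functional_snps[2]}, "
      f"{truth.functional_snps[3]})")

res = npdr.run_npdr(G, y)
top = res.top(8)["snp"].tolist()
G_top = G.subset_snps([G.snps.index(s) for s in top])
net = npdr.build_network(G_top, y, alpha=1e-3)

print(f"\n{len(net.edges)} edge(s) from {net.n_tests} tested pairs "
      f"(edge weight = -log10 adjusted p):")
print(net.edges.to_string(index=False))
hub = net.hub()
if hub:
    print(f"hub: {hub[0]} with degree {hub[1]}")
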