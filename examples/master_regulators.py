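"""Find the planted master regulator in a synthetic signalling network.

A ~300-node random digraph contains a hidden regulator wired to reach all 12
NF-κB-like input nodes within two steps.  Every node is scored by the
weighted ratio (reached inputs + 2x reached context proteins) / (all
reachable nodes within radius 10), and significance comes from 8000
permutations of pseudo-input sets.  Controlling nodes are kept at
FDR <= 0.05 and Z >= 1.
"""

from nfkbrepo.keynodes import empirical_significance, select_controlling_nodes
from nfkbrepo.simulate import FixtureSpec, make_network

nf = make_network(FixtureSpec(seed=5))
print(f"network: {nf.network.n_nodes} nodes, {nf.network.n_edges} edges; "
      f"planted regulator: {nf.regulator}")

table = empirical_significance(nf.network, nf.inputs, n_random=8000, seed=5)
print(table.head(5).to_string(index=False))

controlling = select_controlling_nodes(table, fdr_max=0.05, z_min=1.0)
print(f"controlling nodes at FDR<=0.05, Z>=1.0: {controlling}")
print("The planted regulator should top the Z ranking: it reaches the whole "
      "input set while reaching little else, which random pseudo-inputs "
      "almost never reproduce.")
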