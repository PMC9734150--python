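"""Dynamical flexibility index: where does regulator binding rigidify the
catalytic subunit?

Computes DFI profiles for the free and interface-stiffened toy dimer and
locates the largest flexibility change relative to the perturbed
interface nodes.
"""

import networkx as nx
import numpy as np

import allonet as al

net, info = al.build_toy_dimer()
stiff = al.perturb_network(net, info["interface"], factor=5.0)

cov_free = al.network_covariance(net, mode="scalar")
cov_bound = al.network_covariance(stiff, mode="scalar")
dfi_free = al.dfi_profile(al.perturbation_response_matrix(cov_free),
                          labels=net.labels)
dfi_bound = al.dfi_profile(al.perturbation_response_matrix(cov_bound),
                           labels=net.labels)

delta = dfi_bound.dfi - dfi_free.dfi
order = np.argsort(-np.abs(delta))
g = nx.Graph(list(net.springs.keys()))
iface = [net.labels.index(lb) for lb in info["interface"]]

print("residue   DFI(free)  DFI(bound)   ΔDFI    dist-to-interface")
for idx in order[:5]:
    d = min(nx.shortest_path_length(g, int(idx), i) for i in iface)
    print(f"{net.labels[idx]:8s}  {dfi_free.dfi[idx]:.4f}     "
          f"{dfi_bound.dfi[idx]:.4f}    {delta[idx]:+.4f}   {d}")
print("\nThe largest flexibility changes cluster at and next to the "
      "stiffened interface: binding constrains dynamics locally and "
      "redistributes flexibility elsewhere.")
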