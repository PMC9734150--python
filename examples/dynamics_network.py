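"""Ensemble → DCCM → residue network: how regulator binding rewires
cross-subunit communication.

Builds a toy two-subunit elastic-network dimer, samples Gaussian ensembles
for the free (nonactivated) and interface-stiffened (regulator-bound)
states, and compares their correlation structure and shortest-path maps.
"""

import numpy as np

import allonet as al

net, info = al.build_toy_dimer()
stiff = al.perturb_network(net, info["interface"], factor=5.0)

dccms = {}
spms = {}
for name, network in [("nonactivated", net), ("activated", stiff)]:
    cov = al.network_covariance(network, mode="scalar")
    traj = al.sample_ensemble(cov, n_frames=5000, seed=0)
    dccm = al.compute_dccm(traj, superpose=False)
    graph = al.build_residue_graph(traj, dccm)
    spm = al.compute_spm(graph)
    cpl = al.characteristic_path_length(graph)
    inter = sum(1 for (u, v) in spm.spm_edges
                if u.partition(":")[0] != v.partition(":")[0])
    dccms[name], spms[name] = dccm, spm
    print(f"{name:13s}: {graph.graph.number_of_edges()} edges, "
          f"CPL {cpl.cpl:.2f}, SPM edges {len(spm.spm_edges)} "
          f"({inter} inter-subunit)")

comp = al.compare_dccm_spearman(dccms["nonactivated"], dccms["activated"])
print(f"Spearman rho between the two DCCMs: {comp.rho:.2f} "
      f"(n = {comp.n} upper-triangle entries)")
print("Stiffening the interface adds inter-subunit SPM edges: the "
      "regulator opens communication pathways across the dimer.")

# which residues does communication depend on most?
table = al.node_weakening(al.build_residue_graph(
    al.sample_ensemble(al.network_covariance(stiff, mode="scalar"), 5000, 0),
    dccms["activated"]))
print("\nTop node-weakening candidates (largest |ΔCPL| on removal):")
print(table.table.head(3).to_string(index=False))
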