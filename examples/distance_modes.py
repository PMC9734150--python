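"""Side-chain rotamer analysis from a distance distribution.

An active-site arginine exchanges between a catalytic salt-bridge
conformation (~4.4 Å between its guanidinium carbon and the substrate
pyrophosphate phosphorus) and a non-catalytic rotamer (~7.8 Å).  The KDE
mode detector recovers both conformations from a sampled distance series.
"""

from allonet import distance_distribution, simulate_distance_series

series = simulate_distance_series(modes=[4.4, 7.8], weights=[0.5, 0.5],
                                  sigma=0.3, n=10_000, seed=0,
                                  label_a="R56:CZ", label_b="PRPP:PA")
dist = distance_distribution(series)

print(f"{len(series.values)} frames, KDE bandwidth {dist.bandwidth:.2f} A")
for mode, dens in zip(dist.modes, dist.mode_densities):
    kind = "salt-bridge (catalytic)" if mode < 6 else "open rotamer"
    print(f"  mode at {mode:.2f} A  (density {dens:.2f})  — {kind}")
print("A population shift toward the lower mode is the structural "
      "signature of allosteric activation.")
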