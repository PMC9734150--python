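# allonet

Allosteric-communication network analysis and activation kinetics for
two-subunit enzymes.

`allonet` is aimed at structural biologists and enzymologists studying
allosteric activation in hetero-oligomeric enzymes — the motivating system
is ATP phosphoribosyltransferase (ATPPRT), whose catalytic subunit
(HisG<sub>S</sub>) is activated by a regulatory protein (HisZ) that binds
far from the active site.  The package answers two complementary
questions:

1. **Dynamics** — how does regulator binding change the catalytic
   subunit's correlated motions, communication pathways and flexibility?
2. **Kinetics** — how strong is the activation, and how tight is the
   regulator–subunit interaction?

## What it computes

**Ensemble analysis.**  From a conformational ensemble (multi-model PDB or
frame CSV; a seedable elastic-network generator supplies synthetic
ensembles) the package computes, after Kabsch superposition:

- the dynamic cross-correlation matrix (DCCM)
  `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, and two-sided Spearman
  rank comparisons between DCCMs;
- a correlation-weighted residue-contact network with edge length
  `−log|C_ij|`, its **shortest path map** (SPM: per-edge usage by
  all-pairs Dijkstra shortest paths, normalized to the busiest edge), the
  **characteristic path length** (CPL, mean shortest-path length over
  reachable pairs), and **node weakening** (ΔCPL ranking of node
  removals);
- the **dynamical flexibility index**,
  `DFI_i = Σ_j R_ij / Σ_kj R_kj` with `R_ij` the root-mean-square linear
  response of residue *i* to isotropic unit forces at residue *j*;
- Cartesian PCA, and KDE mode detection on side-chain–ligand distance
  series (e.g. the bimodal salt-bridge / open-rotamer signature of an
  active-site arginine).

**Kinetics.**  Evaluators and nonlinear least-squares fits
(asymptotic standard errors) for

- Michaelis–Menten saturation `v/E_T = k_cat·S/(K_M+S)`;
- Boltzmann melting curves `F_U = LL + (UL−LL)/(1+e^{(T_m−T)/c})` (DSF);
- the tight-binding activation quadratic
  `v = V_max·(G+Z+K_D^app − √((G+Z+K_D^app)² − 4GZ))/(2G)` for regulator
  titrations where free-regulator depletion matters, plus the derived
  holoenzyme concentration;
- the Hill equation `v = V_max·Z^h/(K_0.5^h + Z^h)` for cooperative
  activation (an as-printed variant with un-exponentiated `K_0.5` is kept
  behind a flag);
- fold-change arithmetic for activation/impairment ratios.

## Worked example

```bash
python examples/kinetics_fits.py
```

prints

```
Michaelis fit: k_cat = 1.720 s^-1, K_M = 0.440 mM
Tight-binding fit: K_D(app) = 9.00 uM (complex at Z = 19.7 uM: 0.130 uM of 0.19 uM subunit)
Hill fit: K_0.5 = 8.10 uM, h = 1.68 (h > 1: positive cooperativity; descriptive fit)
Activation of the wild type by the regulator: 29.4 -> 29-fold
Catalytic impairment of C115S: 117.2 -> 117-fold
```

The Michaelis fit recovers the turnover number and Michaelis constant of
the activated holoenzyme; the tight-binding fit recovers the apparent
dissociation constant of a regulator titrated at concentrations
comparable to the catalytic subunit's; the Hill coefficient above 1
indicates positive cooperativity of the rescue of an impaired mutant; the
fold ratios quantify how strongly the regulator activates (29-fold for
the wild type) and how much a mutation impairs the free subunit
(117-fold for C115S).

The dynamics side:

```bash
python examples/dynamics_network.py
```

```
nonactivated : 85 edges, CPL 4.82, SPM edges 3 (1 inter-subunit)
activated    : 89 edges, CPL 4.28, SPM edges 19 (5 inter-subunit)
Spearman rho between the two DCCMs: 0.82 (n = 276 upper-triangle entries)
```

Stiffening the subunit interface (the elastic-network surrogate for
regulator binding) shortens the characteristic path length and adds
inter-subunit edges to the shortest path map — communication across the
dimer opens up.  `examples/distance_modes.py` and
`examples/flexibility_dfi.py` cover rotamer-distance modes and DFI.

A thin CLI mirrors the library:
`allonet {simulate,dccm,compare,pca,distances,spm,cpl,weaken,dfi,fit,fold,run}`.

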