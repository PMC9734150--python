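# Methods

This note documents the models behind `allonet`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions.

## Surrogate ensembles: the elastic-network generator

The analysis stages (DCCM, residue networks, DFI) are defined on
conformational ensembles.  Production studies obtain these from long
molecular-dynamics simulations; `allonet.synthetic` substitutes a
Gaussian elastic-network model, which preserves exactly the statistical
structure the downstream stages consume — correlated Gaussian
fluctuations about a mean structure — while having closed-form oracles.

Nodes within a contact cutoff are joined by harmonic springs.  Two
fluctuation models are derived:

- **scalar mode** (default for tests): one fluctuation coordinate per
  node; covariance = `scale × pinv(Kirchhoff)`, the stiffness-weighted
  graph Laplacian, with its single uniform zero mode removed.  This is
  the Gaussian-network-model convention, and every covariance,
  correlation and response quantity has a closed form.
- **three_d mode**: the anisotropic 3N×3N Hessian built from spring
  geometry; covariance = `scale × pinv(Hessian)` with the six rigid-body
  zero modes removed.

Zero modes are classified at a relative eigenvalue tolerance of 1e-8 of
the largest eigenvalue (standard elastic-network practice); finding more
zero modes than expected raises an error rather than silently inverting a
floppy or disconnected network.  Note that 3-D rigidity requires enough
springs (≥ 3N−6): sparse chains and planar geometries are mechanically
floppy in three_d mode and are rejected by this check.

`scale` plays the role of kT over spring stiffness; it is arbitrary and
every downstream quantity used for inference (correlations, SPM ranking,
DFI) is invariant to it.

**The toy dimer.**  `build_toy_dimer()` is the standing test system: two
12-node orthorhombic lattices (3.8 Å spacing, the Cα virtual-bond length)
facing across a 4.6 Å gap, so only the facing layers form inter-subunit
contacts at the default 6 Å cutoff.  "Regulator binding" is emulated by
multiplying the stiffness of all springs incident on the interface layers
by a factor (default 5 in examples/tests), which provably cannot increase
any node variance and empirically increases cross-interface correlation —
the minimal mechanical caricature of an activator that rigidifies the
interface.

**What the surrogate does not emulate:** anharmonicity, conformational
substates and barrier crossing, solvent effects, side-chain packing, and
sequence specificity.  Tests passing on these ensembles certify the
*analysis machinery* (estimators converge to the generating truth;
graph/DFI algorithms match oracles; qualitative activation signatures
follow from interface stiffening), not any claim about a particular
protein's dynamics.

Default frame count is 5,000 per ensemble: large enough that DCCM entries
converge to within ±0.05 of the generating correlation (sampling error of
a correlation coefficient is ≈ n^(−1/2)), small enough to keep any
analysis interactive.

**Distance series** are drawn from a Gaussian mixture (default modes
4.4 / 7.8 Å, σ 0.3 Å — a salt-bridged versus open side-chain rotamer).
Negative draws are redrawn rather than truncated, preserving the mixture
shape near its modes; redraw rates above 1% are reported.

## Superposition and DCCM

Frames are rigid-body aligned by the Kabsch algorithm (SVD with proper
rotation enforced; degenerate/collinear frames rejected).  The default
reference is the iterated ensemble mean (re-align, recompute mean, stop
when the mean shifts < 1e-6 Å RMS or after 20 rounds); a frame index or
external structure may be supplied instead.  Superposition before the
DCCM is the default because rigid-body motion otherwise contaminates the
correlations; it can be disabled for ensembles generated without
rigid-body motion (the scalar-mode generator), where it would be
degenerate.

The DCCM uses unweighted displacement vectors from the per-point mean and
the full 3-D dot product; entries are clipped to [−1, 1] and the diagonal
set to exactly 1.  Spearman comparisons between matrices use the strict
upper triangle by default — the diagonal is identically 1 and carries no
information — with an upper-plus-diagonal option; the test is two-sided.

## The residue network

Edges require both persistent contact (pairwise distance ≤ 6 Å in ≥ 50%
of frames) and correlation (|C_ij| ≥ 0.05); all three thresholds are
exposed and echoed into run manifests.  Edge length is `−log|C_ij|`:
monotone decreasing in correlation strength and additive along paths, so
a shortest path is a maximum-likelihood-style chain of pairwise
correlations.  Perfectly correlated pairs would give length 0; the length
is clamped at 1e-6 and the clamp logged.  Signed correlations are kept in
the matrix; the network takes absolute values.

**SPM.**  Shortest paths use Dijkstra with a deterministic tie-break
(among exactly equal-length paths the lexicographically smallest node
sequence wins), so edge-usage scores are reproducible.  Usage accumulates
over shortest paths between *all* ordered node pairs and is normalized by
the busiest edge; the display threshold (default 0.3) selects the SPM.  A
single endpoint-pair accumulation variant (`pairs="ends"`) is retained
because path-map constructions differ on this point in the literature.
On disconnected graphs the SPM is computed per component and flagged.

**CPL and node weakening.**  CPL is the mean shortest-path length over
reachable unordered pairs; on disconnected graphs the reachable fraction
is reported rather than letting the mean diverge — this keeps ΔCPL finite
and rankable.  Node weakening removes one candidate node at a time,
recomputes CPL over the remaining reachable pairs, and ranks candidates
by |ΔCPL|; removals that disconnect the remainder are flagged (a removal
that isolates everything yields NaN and sorts last).

## DFI

Linear response on the fluctuation covariance: the displacement of
residue *i* under a force **f** at residue *j* is `u_i = C_ij f` (3×3
covariance block).  Averaging |u|² over isotropic unit force directions
has the closed form `tr(C_ijᵀC_ij)/3`, so the response magnitude is
`R_ij = ‖C_ij‖_F/√3` (root mean square over directions; in scalar mode
this collapses to |cov_ij|).  A Monte-Carlo direction-sampling estimator
is retained purely as a test oracle.  `DFI_i` is row-normalized response,
summing to 1; it is invariant to uniform covariance scaling
(temperature).  The covariance may be the analytic network model or a
trajectory estimate; the source is recorded in the profile.

## Distance distributions

Gaussian KDE (Silverman bandwidth by default, overridable) evaluated on a
2,000-point grid over [0, max + 3σ]; modes are local maxima above 10% of
the global maximum, sorted ascending.  Components closer than the
bandwidth merge into one mode — documented behaviour, tested.  A
zero-variance series short-circuits to a single degenerate mode.

## Kinetic fits

All fits are unweighted nonlinear least squares (lmfit/MINPACK,
ftol = xtol = 1e-12) with data-driven initial guesses (amplitude from the
rate maximum; half-saturation abscissa for K_M/K_D/K_0.5; mid-signal
temperature for T_m) and positivity bounds; the Hill coefficient is
bounded to (0, 10].  Uncertainties are asymptotic standard errors from
the Jacobian, i.e. the "mean ± fitting error" convention of
nonlinear-regression software.  Negative or out-of-range estimates
(T_m outside the scanned temperatures, inverted melting baselines) are
rejected as fit failures rather than returned.

The tight-binding quadratic's discriminant is clamped at zero against
rounding; a discriminant negative beyond 1e-9 of scale is an input error.
The derived complex concentration is symmetric in G and Z and bounded by
min(G, Z).

The Hill equation defaults to the dimensionally consistent standard form
(`K_0.5` raised to *h*); the variant with un-exponentiated `K_0.5` is
kept verbatim behind `form="as_printed"` because published formulations
differ.  Hill fits are flagged descriptive-only: when regulator and
subunit concentrations are comparable, the pseudo-first-order assumption
fails, and K_0.5/h characterise curve shape, not microscopic constants.

Fold changes are exact ratios plus a round-half-away-from-zero integer
("N-fold").  Integer folds quoted from rounded rate constants can differ
by one unit from folds computed on unrounded raw data; tests therefore
compare recomputed folds to quoted ones at the printed precision (±1).

## Reproducibility

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from one root seed by hashing, so stages are independent
but the whole run is reproducible.  Run manifests record input hashes,
effective parameters and output hashes; identical configurations produce
byte-identical numeric outputs.

## Known limitations

- The elastic-network surrogate cannot reproduce system-specific numbers
  (published Spearman coefficients, SPM topologies or DFI profiles of a
  real enzyme); those require the original trajectories.
- Scalar mode embeds fluctuations along one axis; its ensembles are for
  estimator validation, not for geometry-sensitive analyses.
- The contact definition uses point (Cα-like) distances only; no
  heavy-atom or side-chain contact criterion is available.
- No weighted fitting or global multi-dataset fitting; no
  inhibition-mechanism models.
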