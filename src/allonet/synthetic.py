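"""Synthetic-data generators: elastic networks, Gaussian ensembles,
bimodal distance series and kinetic datasets.

The analysis stages in this package (DCCM, correlation-weighted residue
networks, DFI) operate on conformational ensembles.  Real studies obtain
those from molecular-dynamics trajectories; here an elastic-network model
provides a statistically faithful surrogate: nodes connected by harmonic
springs fluctuate as a zero-mean multivariate Gaussian whose covariance is
a scaled pseudo-inverse of the connectivity (Kirchhoff) matrix in scalar
mode, or of the anisotropic Hessian in full 3-D mode.  A "regulator-bound"
variant stiffens the springs at a subunit interface, emulating the
constrained dynamics of the activated holoenzyme.

Everything is seed-deterministic so downstream tests are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleTrajectory
from . import kinetics as kin
from .trajstats import DistanceSeries

__all__ = [
    "SyntheticDataError",
    "ToyElasticNetwork",
    "CovarianceModel",
    "build_toy_network",
    "build_toy_dimer",
    "network_covariance",
    "perturb_network",
    "sample_ensemble",
    "simulate_distance_series",
    "simulate_rate_data",
    "write_network_tsv",
]

# relative eigenvalue tolerance for classifying zero modes of the
# connectivity / Hessian spectrum
ZERO_MODE_RTOL = 1e-8


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class ToyElasticNetwork:
    """Harmonic-spring network over labelled 3-D nodes.

    ``springs`` maps node-index pairs (i < j) to stiffness (energy/Å²,
    arbitrary units); the network must be connected.
    """

    coords: np.ndarray                       # (N, 3) Å
    labels: tuple[str, ...]
    springs: dict[tuple[int, int], float]
    cutoff: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = coords.shape[0]
        for (i, j), k in self.springs.items():
            if i == j:
                raise SyntheticDataError(f"self-spring on node {i}")
            if not (0 <= i < j < n):
                raise SyntheticDataError(f"bad spring pair ({i}, {j})")
            if not k > 0:
                raise SyntheticDataError(f"non-positive stiffness on ({i}, {j})")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def kirchhoff(self) -> np.ndarray:
        """Stiffness-weighted graph Laplacian (scalar-mode connectivity)."""
        n = self.n_nodes
        K = np.zeros((n, n))
        for (i, j), k in self.springs.items():
            K[i, j] -= k
            K[j, i] -= k
            K[i, i] += k
            K[j, j] += k
        return K

    def hessian(self) -> np.ndarray:
        """Anisotropic-network 3N×3N Hessian built from spring geometry."""
        n = self.n_nodes
        H = np.zeros((3 * n, 3 * n))
        for (i, j), k in self.springs.items():
            d = self.coords[j] - self.coords[i]
            r2 = float(d @ d)
            if r2 == 0:
                raise SyntheticDataError(f"coincident nodes {i}, {j}")
            block = k * np.outer(d, d) / r2
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            H[si, sj] -= block
            H[sj, si] -= block
            H[si, si] += block
            H[sj, sj] += block
        return H


@dataclass(frozen=True)
class CovarianceModel:
    """Gaussian fluctuation model: mean structure plus PSD covariance.

    ``mode`` is ``"scalar"`` (one fluctuation coordinate per node, N×N
    covariance) or ``"three_d"`` (3N×3N).  ``dropped_modes`` records how
    many zero eigenvalues were removed before pseudo-inversion: 1 for the
    scalar uniform mode, 6 for the 3-D rigid-body modes.
    """

    mean_coords: np.ndarray
    labels: tuple[str, ...]
    covariance: np.ndarray
    mode: str
    dropped_modes: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise SyntheticDataError("covariance must be symmetric")
        evals = np.linalg.eigvalsh(cov)
        tol = ZERO_MODE_RTOL * max(evals.max(), 1e-300)
        if evals.min() < -tol:
            raise SyntheticDataError("covariance is not positive semi-definite")
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def node_variance(self) -> np.ndarray:
        """Per-node fluctuation variance (trace of the 3×3 block in 3-D mode)."""
        if self.mode == "scalar":
            return np.diag(self.covariance).copy()
        d = np.diag(self.covariance)
        return d.reshape(-1, 3).sum(axis=1)

    def correlation(self) -> np.ndarray:
        """Analytic node–node correlation implied by the covariance.

        In scalar mode this is the plain normalized covariance; in 3-D mode
        the inner-product correlation tr(C_ij)/√(tr C_ii · tr C_jj) — the
        quantity a DCCM estimates from sampled frames.
        """
        if self.mode == "scalar":
            d = np.sqrt(np.diag(self.covariance))
            return self.covariance / np.outer(d, d)
        n = self.n_nodes
        blocks = self.covariance.reshape(n, 3, n, 3)
        inner = np.einsum("iaja->ij", blocks)
        d = np.sqrt(np.diag(inner))
        return inner / np.outer(d, d)


def build_toy_network(
    coords,
    cutoff: float,
    stiffness: float = 1.0,
    labels: tuple[str, ...] | None = None,
) -> ToyElasticNetwork:
    """Place springs between every node pair within ``cutoff`` Å.

    Raises if the resulting network is disconnected, naming the nodes that
    are cut off from the largest connected component.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import squareform, pdist

    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise SyntheticDataError("coords must be (N, 3)")
    n = coords.shape[0]
    if n < 3:
        raise SyntheticDataError("need at least 3 nodes")
    if not cutoff > 0:
        raise SyntheticDataError("cutoff must be > 0")
    if labels is None:
        labels = tuple(f"A:{i + 1}" for i in range(n))

    dist = squareform(pdist(coords))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    springs = {(i, j): float(stiffness)
               for i in range(n) for j in range(i + 1, n) if adj[i, j]}

    n_comp, comp = connected_components(adj, directed=False)
    if n_comp != 1:
        sizes = np.bincount(comp)
        main = int(np.argmax(sizes))
        isolated = [labels[i] for i in range(n) if comp[i] != main]
        raise SyntheticDataError(
            f"network disconnected at cutoff {cutoff} Å; "
            f"nodes outside the main component: {', '.join(isolated)}")
    return ToyElasticNetwork(coords=coords, labels=labels,
                             springs=springs, cutoff=float(cutoff))


def build_toy_dimer(
    cutoff: float = 6.0,
    stiffness: float = 1.0,
    spacing: float = 3.8,
    gap: float = 4.6,
) -> tuple[ToyElasticNetwork, dict]:
    """Two-subunit toy dimer: a pair of 3×2×2 lattices facing across a gap.

    Each subunit is a 12-node orthorhombic block with Cα-like spacing;
    the blocks are separated along x by ``gap`` Å so that only the facing
    layers form inter-subunit contacts at the default cutoff.  Returns the
    network and an info dict with per-subunit label sets and the interface
    node labels (the facing layers) — the nodes whose springs are stiffened
    to emulate regulator binding.
    """
    base = np.array([(x, y, z)
                     for x in range(3) for y in range(2) for z in range(2)],
                    dtype=float) * spacing
    shift = np.array([2 * spacing + gap, 0.0, 0.0])
    coords = np.vstack([base, base + shift])
    labels = tuple(f"A:{i + 1}" for i in range(12)) + tuple(
        f"B:{i + 1}" for i in range(12))
    net = build_toy_network(coords, cutoff=cutoff, stiffness=stiffness,
                            labels=labels)
    iface_a = [labels[i] for i in range(12) if base[i, 0] == 2 * spacing]
    iface_b = [labels[12 + i] for i in range(12) if base[i, 0] == 0.0]
    info = {
        "subunits": {"A": labels[:12], "B": labels[12:]},
        "interface": tuple(iface_a + iface_b),
    }
    return net, info


def _pseudo_inverse_psd(mat: np.ndarray, expected_zero: int) -> np.ndarray:
    evals, evecs = np.linalg.eigh(mat)
    tol = ZERO_MODE_RTOL * evals.max()
    n_zero = int(np.sum(np.abs(evals) <= tol))
    if n_zero != expected_zero:
        raise SyntheticDataError(
            f"expected {expected_zero} zero mode(s), found {n_zero}: "
            "network disconnected or geometry degenerate")
    inv = np.where(np.abs(evals) <= tol, 0.0, 1.0 / np.where(evals == 0, 1.0, evals))
    return (evecs * inv) @ evecs.T


def network_covariance(
    net: ToyElasticNetwork, mode: str = "scalar", scale: float = 1.0
) -> CovarianceModel:
    """Fluctuation covariance of an elastic network.

    Scalar mode: ``scale × pinv(Kirchhoff)`` (one zero mode, the uniform
    translation).  3-D mode: ``scale × pinv(Hessian)`` (six rigid-body
    zero modes).  ``scale`` plays the role of kT/γ.
    """
    if mode == "scalar":
        cov = scale * _pseudo_inverse_psd(net.kirchhoff(), expected_zero=1)
        dropped = 1
    elif mode == "three_d":
        cov = scale * _pseudo_inverse_psd(net.hessian(), expected_zero=6)
        dropped = 6
    else:
        raise SyntheticDataError(f"unknown mode {mode!r}")
    return CovarianceModel(mean_coords=net.coords.copy(), labels=net.labels,
                           covariance=cov, mode=mode, dropped_modes=dropped,
                           scale=float(scale))


def perturb_network(
    net: ToyElasticNetwork, node_set, factor: float
) -> ToyElasticNetwork:
    """Multiply the stiffness of every spring touching ``node_set`` by ``factor``.

    ``node_set`` may contain labels or integer node indices.  With
    ``factor > 1`` this stiffens the neighbourhood of the given nodes
    (e.g. a subunit interface upon regulator binding), which can only
    reduce fluctuation variances.
    """
    if not len(node_set):
        raise SyntheticDataError("node_set must be non-empty")
    if not factor > 0:
        raise SyntheticDataError("factor must be > 0")
    idx = set()
    for node in node_set:
        if isinstance(node, str):
            if node not in net.labels:
                raise SyntheticDataError(f"unknown node label {node!r}")
            idx.add(net.labels.index(node))
        else:
            if not 0 <= int(node) < net.n_nodes:
                raise SyntheticDataError(f"node index {node} out of range")
            idx.add(int(node))
    springs = {
        pair: (k * factor if (pair[0] in idx or pair[1] in idx) else k)
        for pair, k in net.springs.items()
    }
    return ToyElasticNetwork(coords=net.coords.copy(), labels=net.labels,
                             springs=springs, cutoff=net.cutoff)


def sample_ensemble(
    cov: CovarianceModel, n_frames: int, seed: int
) -> EnsembleTrajectory:
    """Draw independent Gaussian frames from a covariance model.

    Scalar-mode fluctuations are embedded along the x axis (one coordinate
    per node) on top of the mean structure; 3-D mode draws full
    displacement vectors.  Reproducible for a fixed seed.
    """
    if n_frames < 2:
        raise SyntheticDataError("need n_frames ≥ 2")
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh(cov.covariance)
    tol = ZERO_MODE_RTOL * max(evals.max(), 1e-300)
    if evals.min() < -tol:
        raise SyntheticDataError("covariance not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    factor = evecs * np.sqrt(evals)           # cov = factor @ factor.T
    z = rng.standard_normal((n_frames, factor.shape[1]))
    disp = z @ factor.T
    frames = np.repeat(cov.mean_coords[None], n_frames, axis=0)
    if cov.mode == "scalar":
        frames[:, :, 0] += disp
    else:
        frames += disp.reshape(n_frames, cov.n_nodes, 3)
    if n_frames < 10:
        warnings.warn(
            f"ensemble of only {n_frames} frames: downstream statistics are "
            "low-confidence", stacklevel=2)
    return EnsembleTrajectory(coords=frames, labels=cov.labels, seed=seed)


def simulate_distance_series(
    modes, weights, sigma: float, n: int, seed: int,
    label_a: str = "a", label_b: str = "b",
) -> DistanceSeries:
    """Draw a distance series from a Gaussian mixture (Å).

    Emulates e.g. the bimodal side-chain–ligand distance of an arginine
    that exchanges between a salt-bridge conformation (~4.4 Å) and a
    non-catalytic rotamer (~7.8 Å).  Negative draws are redrawn (distances
    are non-negative); a warning is issued if more than 1% required it.
    """
    modes = np.asarray(modes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if modes.shape != weights.shape or modes.ndim != 1:
        raise SyntheticDataError("modes and weights must be 1-D of equal length")
    if not np.isclose(weights.sum(), 1.0):
        raise SyntheticDataError("weights must sum to 1")
    if not sigma >= 0:
        raise SyntheticDataError("sigma must be ≥ 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(modes), size=n, p=weights)
    draws = rng.normal(modes[comp], sigma)
    n_redrawn = 0
    neg = draws < 0
    while neg.any():
        n_redrawn += int(neg.sum())
        draws[neg] = rng.normal(modes[comp[neg]], sigma)
        neg = draws < 0
    if n_redrawn > 0.01 * n:
        warnings.warn(
            f"{n_redrawn} of {n} draws were negative and redrawn "
            "(mixture mass near zero)", stacklevel=2)
    return DistanceSeries(values=draws, label_a=label_a, label_b=label_b)


_RATE_MODELS = {
    "michaelis": (("k_cat", "K_M"),
                  lambda x, p: kin.michaelis_rate(x, p["k_cat"], p["K_M"])),
    "melting": (("LL", "UL", "T_m", "c"),
                lambda x, p: kin.melting_fraction(x, p["LL"], p["UL"],
                                                  p["T_m"], p["c"])),
    "binding": (("G", "V_max", "K_D_app"),
                lambda x, p: kin.binding_rate(x, p["G"], p["V_max"],
                                              p["K_D_app"])),
    "hill": (("V_max", "K_half", "h"),
             lambda x, p: kin.hill_rate(x, p["V_max"], p["K_half"], p["h"],
                                        form=p.get("form", "standard"))),
}


def simulate_rate_data(
    model: str, params: dict, grid, noise_sd: float = 0.0, seed: int = 0
) -> kin.RateMeasurementSet:
    """Generate a rate/signal dataset from a named kinetic model.

    ``model`` is one of ``michaelis``, ``melting``, ``binding``, ``hill``;
    ``params`` must contain all parameters of that model (missing ones are
    reported by name).  Gaussian noise of standard deviation ``noise_sd``
    is added; ``noise_sd=0`` gives the exact curve.
    """
    if model not in _RATE_MODELS:
        raise SyntheticDataError(
            f"unknown model {model!r}; choose from {sorted(_RATE_MODELS)}")
    required, evaluate = _RATE_MODELS[model]
    missing = [p for p in required if p not in params]
    if missing:
        raise SyntheticDataError(
            f"model {model!r} missing parameter(s): {', '.join(missing)}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise SyntheticDataError("grid must be non-empty")
    v = np.asarray(evaluate(grid, params), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    fixed = {k: params[k] for k in ("G", "E_T") if k in params}
    return kin.RateMeasurementSet(x=grid, v=v, fixed=fixed,
                                  noise_sd=float(noise_sd), seed=seed)


def write_network_tsv(net: ToyElasticNetwork, path) -> None:
    """Edge-list TSV (label_i, label_j, stiffness)."""
    import pandas as pd

    rows = [(net.labels[i], net.labels[j], k)
            for (i, j), k in sorted(net.springs.items())]
    pd.DataFrame(rows, columns=["node_i", "node_j", "stiffness"]).to_csv(
        path, sep="\t", index=False)
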