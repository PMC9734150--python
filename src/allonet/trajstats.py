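"""Ensemble statistics: superposition, DCCM, PCA and distance distributions.

The central object is the dynamic cross-correlation matrix (DCCM),

    C_ij = ⟨Δr_i · Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

with Δr_i the displacement of point i from its ensemble-mean position.
Rigid-body motion contaminates these correlations, so frames are
least-squares superposed (Kabsch, proper rotations only) onto a reference
— the iterated ensemble mean by default — before the matrix is formed.

Distance series between two labelled points (e.g. an arginine side-chain
Cζ and the Pα of a bound PRPP pyrophosphate moiety) are summarised by a
Gaussian-KDE distribution whose local maxima are reported as modes; a
bimodal series with one mode near the salt-bridge distance and another at
a non-catalytic rotamer is the signature analysed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.spatial.transform import Rotation

from .ensemble import EnsembleTrajectory

__all__ = [
    "CorrelationMatrix",
    "DccmComparison",
    "DistanceSeries",
    "DistanceDistribution",
    "superpose_ensemble",
    "compute_dccm",
    "compare_dccm_spearman",
    "principal_components",
    "extract_distance_series",
    "distance_distribution",
]


class TrajectoryStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper-rotation + translation of ``mobile`` onto ``reference``.

    Returns the aligned coordinates and the post-fit RMSD (Å).
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    aligned = rot.apply(mob_c) + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return aligned, rmsd


def _check_nondegenerate(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if len(sv) < 2 or sv[1] / scale < 1e-10:
        raise TrajectoryStatsError(
            "degenerate (collinear or coincident) coordinates: rotation is ill-defined")


def superpose_ensemble(
    traj: EnsembleTrajectory,
    reference: str | int | np.ndarray = "mean",
    max_iter: int = 20,
    tol: float = 1e-6,
) -> tuple[EnsembleTrajectory, np.ndarray]:
    """Rigid-body align every frame to a reference; returns per-frame RMSD.

    ``reference`` may be ``"mean"`` (iterate alignment to the ensemble mean
    until the mean shifts < ``tol`` Å RMS, at most ``max_iter`` rounds), a
    frame index, or an external (n_points, 3) structure.
    """
    if traj.n_points < 3:
        raise TrajectoryStatsError("need ≥ 3 points per frame for superposition")
    coords = traj.coords
    for frame in coords:
        _check_nondegenerate(frame)

    if isinstance(reference, str) and reference == "mean":
        ref = coords[0]
        aligned = coords
        for _ in range(max_iter):
            aligned = np.stack([_kabsch_align(f, ref)[0] for f in aligned])
            new_ref = aligned.mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1))))
            ref = new_ref
            if shift < tol:
                break
    else:
        if isinstance(reference, (int, np.integer)):
            ref = coords[int(reference)]
        else:
            ref = np.asarray(reference, dtype=float)
            if ref.shape != (traj.n_points, 3):
                raise TrajectoryStatsError(
                    f"external reference must have shape {(traj.n_points, 3)}")
        _check_nondegenerate(ref)
        aligned = coords

    out = np.empty_like(coords)
    rmsd = np.empty(traj.n_frames)
    for k, frame in enumerate(aligned):
        out[k], rmsd[k] = _kabsch_align(frame, ref)
    return (
        EnsembleTrajectory(coords=out, labels=traj.labels, seed=traj.seed),
        rmsd,
    )


# ---------------------------------------------------------------------------
# DCCM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric normalized cross-correlation matrix over labelled points."""

    values: np.ndarray
    labels: tuple[str, ...]
    n_frames: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TrajectoryStatsError("correlation matrix must be square")
        if v.shape[0] != len(self.labels):
            raise TrajectoryStatsError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise TrajectoryStatsError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise TrajectoryStatsError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, n_frames: int = 0) -> "CorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), labels=tuple(map(str, df.index)),
                   n_frames=n_frames)


def compute_dccm(
    traj: EnsembleTrajectory,
    selection: list[str] | None = None,
    superpose: bool = True,
    reference: str | int | np.ndarray = "mean",
) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of the selected points.

    Frames are superposed (unless ``superpose=False``, e.g. for ensembles
    generated without rigid-body motion); displacements are taken from the
    per-point ensemble mean; correlations use the full 3-D dot product.
    """
    if traj.n_frames < 2:
        raise TrajectoryStatsError("need ≥ 2 frames for a correlation matrix")
    work = traj if selection is None else traj.select(selection)
    if superpose:
        work, _ = superpose_ensemble(work, reference=reference)
    disp = work.coords - work.coords.mean(axis=0)
    # inner[i, j] = mean over frames of Δr_i · Δr_j
    inner = np.einsum("fid,fjd->ij", disp, disp) / work.n_frames
    var = np.diag(inner)
    zero = np.where(var <= 0)[0]
    if zero.size:
        bad = ", ".join(work.labels[i] for i in zero)
        raise TrajectoryStatsError(f"zero-variance point(s): {bad}")
    corr = inner / np.sqrt(np.outer(var, var))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(values=corr, labels=work.labels, n_frames=work.n_frames)


@dataclass(frozen=True)
class DccmComparison:
    rho: float
    pvalue: float
    n: int
    region: str


def _region_indices(n: int, region: str) -> tuple[np.ndarray, np.ndarray]:
    if region == "upper":
        return np.triu_indices(n, k=1)
    if region == "upper_with_diagonal":
        return np.triu_indices(n, k=0)
    raise TrajectoryStatsError(f"unknown region {region!r}")


def compare_dccm_spearman(
    a: CorrelationMatrix, b: CorrelationMatrix, region: str = "upper"
) -> DccmComparison:
    """Two-sided Spearman rank correlation between two DCCMs.

    By default compares the strict upper triangles (the diagonal is 1 by
    construction and carries no information).
    """
    if a.labels != b.labels:
        raise TrajectoryStatsError("matrices have different labels/shape")
    idx = _region_indices(len(a.labels), region)
    x, y = a.values[idx], b.values[idx]
    rho, p = stats.spearmanr(x, y, alternative="two-sided")
    return DccmComparison(rho=float(rho), pvalue=float(p), n=len(x), region=region)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def principal_components(
    traj: EnsembleTrajectory, selection: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian-space PCA of the (superposed) ensemble.

    Returns eigenvalues (non-increasing, Å²) and orthonormal eigenvectors
    (columns, length 3·n_points) of the coordinate covariance matrix.
    """
    if traj.n_frames < 2:
        raise TrajectoryStatsError("need ≥ 2 frames for PCA")
    work = traj if selection is None else traj.select(selection)
    flat = work.coords.reshape(work.n_frames, -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / work.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return np.clip(evals[order], 0.0, None), evecs[:, order]


# ---------------------------------------------------------------------------
# distance series and distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame Euclidean distance (Å) between two named points."""

    values: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise TrajectoryStatsError("distance series must be a non-empty 1-D array")
        if np.any(v < 0) or not np.isfinite(v).all():
            raise TrajectoryStatsError("distances must be finite and ≥ 0")
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        pd.DataFrame({"frame": np.arange(len(self.values)),
                      "distance_A": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label_a: str = "a", label_b: str = "b") -> "DistanceSeries":
        df = pd.read_csv(path)
        return cls(values=df["distance_A"].to_numpy(), label_a=label_a, label_b=label_b)


@dataclass(frozen=True)
class DistanceDistribution:
    grid: np.ndarray
    density: np.ndarray
    modes: np.ndarray          # Å, ascending
    mode_densities: np.ndarray
    bandwidth: float


def extract_distance_series(
    traj: EnsembleTrajectory, point_a: str, point_b: str
) -> DistanceSeries:
    """Per-frame distance between two labelled points (superposition-free)."""
    ia, ib = traj.index_of(point_a), traj.index_of(point_b)
    d = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return DistanceSeries(values=d, label_a=point_a, label_b=point_b)


def distance_distribution(
    series: DistanceSeries,
    bandwidth: float | str = "silverman",
    rel_height: float = 0.1,
    n_grid: int = 2000,
) -> DistanceDistribution:
    """Gaussian-KDE distribution of a distance series with mode detection.

    Modes are the local maxima of the KDE, evaluated on a dense grid over
    [0, max + 3σ], that rise above ``rel_height`` of the global maximum;
    they are returned sorted ascending.  Components separated by less than
    the bandwidth merge into a single mode.
    """
    x = series.values
    sd = float(np.std(x))
    if sd == 0:
        # constant series: degenerate single mode at the shared value
        val = float(x[0])
        return DistanceDistribution(
            grid=np.array([val]), density=np.array([np.inf]),
            modes=np.array([val]), mode_densities=np.array([np.inf]),
            bandwidth=0.0)
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(0.0, float(x.max()) + 3.0 * sd, n_grid)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, height=rel_height * dens.max())
    if peaks.size == 0:  # monotone density: take the global maximum
        peaks = np.array([int(np.argmax(dens))])
    order = np.argsort(grid[peaks])
    return DistanceDistribution(
        grid=grid, density=dens,
        modes=grid[peaks][order], mode_densities=dens[peaks][order],
        bandwidth=bw)
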