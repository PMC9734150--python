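"""Dynamical flexibility index (DFI) via linear perturbation response.

Within linear response theory the displacement of residue i caused by a
force f applied at residue j is u_i = C_ij f, with C_ij the 3×3 covariance
block coupling the two residues.  Averaging the squared response magnitude
over isotropically distributed unit force directions gives the closed form

    ⟨|u_i|²⟩_f = tr(C_ijᵀ C_ij) / 3,

so the response magnitude used here is R_ij = ‖C_ij‖_F / √3 (root-mean-
square over force directions).  In scalar mode the block is a scalar and
R_ij = |cov_ij| exactly.  The DFI of residue i is its share of the total
response,

    DFI_i = Σ_j R_ij / Σ_kj R_kj,

a per-residue flexibility profile summing to 1: high-DFI residues move
strongly no matter where the protein is poked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CovarianceModel

__all__ = ["DFIProfile", "perturbation_response_matrix", "dfi_profile",
           "monte_carlo_response_matrix"]


class DfiError(ValueError):
    pass


@dataclass(frozen=True)
class DFIProfile:
    dfi: np.ndarray
    labels: tuple[str, ...]
    normalized: bool
    source: str

    def __post_init__(self) -> None:
        dfi = np.asarray(self.dfi, dtype=float)
        if np.any(dfi < 0):
            raise DfiError("DFI values must be ≥ 0")
        if self.normalized and not np.isclose(dfi.sum(), 1.0, atol=1e-9):
            raise DfiError("normalized DFI must sum to 1")
        object.__setattr__(self, "dfi", dfi)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_csv(self, path) -> None:
        pd.DataFrame({"residue": self.labels, "dfi": self.dfi}).to_csv(
            path, index=False)


def perturbation_response_matrix(model: CovarianceModel) -> np.ndarray:
    """N×N response magnitudes R_ij under isotropic unit forces at j.

    The force-direction average is analytic (RMS over the unit sphere);
    see the module docstring.  Scalar mode collapses to |cov_ij|.
    """
    if model.mode == "scalar":
        return np.abs(model.covariance)
    n = model.n_nodes
    blocks = model.covariance.reshape(n, 3, n, 3)
    # ||C_ij||_F^2 summed over the two 3-D axes
    frob2 = np.einsum("iajb,iajb->ij", blocks, blocks)
    return np.sqrt(frob2 / 3.0)


def monte_carlo_response_matrix(
    model: CovarianceModel, n_forces: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo estimate of the response matrix (test oracle).

    Samples unit force directions uniformly on the sphere, applies each at
    every node and averages the squared displacement magnitudes; kept as an
    independent check of the analytic direction average.
    """
    rng = np.random.default_rng(seed)
    if model.mode == "scalar":
        return np.abs(model.covariance)
    n = model.n_nodes
    f = rng.standard_normal((n_forces, 3))
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    blocks = model.covariance.reshape(n, 3, n, 3)
    # u[i, k, a] = C_ij f_k for force k applied at j, accumulated per (i, j)
    resp2 = np.zeros((n, n))
    for j in range(n):
        u = np.einsum("iab,kb->kia", blocks[:, :, j, :], f)
        resp2[:, j] = np.mean(np.sum(u**2, axis=2), axis=0)
    return np.sqrt(resp2)


def dfi_profile(response: np.ndarray, labels=None,
                source: str = "covariance") -> DFIProfile:
    """Normalize row sums of a response matrix into a DFI profile."""
    response = np.asarray(response, dtype=float)
    if response.ndim != 2 or response.shape[0] != response.shape[1]:
        raise DfiError("response matrix must be square")
    if np.any(response < 0):
        raise DfiError("response magnitudes must be ≥ 0")
    total = response.sum()
    if total == 0:
        raise DfiError("all-zero response matrix")
    if labels is None:
        labels = tuple(str(i + 1) for i in range(response.shape[0]))
    dfi = response.sum(axis=1) / total
    return DFIProfile(dfi=dfi, labels=tuple(labels), normalized=True,
                      source=source)
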