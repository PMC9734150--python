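"""Conformational-ensemble container and file I/O.

An :class:`EnsembleTrajectory` holds an ordered set of frames of labelled
3-D points (coarse-grained residue positions, typically one point per Cα,
plus optional ligand atoms).  Labels are chain-qualified strings of the
form ``"A:12"`` so that cross-subunit contacts in a dimer are explicit.

Ensembles round-trip through two plain-text formats: a frame table CSV
(exact to float precision) and multi-model PDB (one MODEL per frame,
3-decimal coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class EnsembleError(ValueError):
    """Raised for malformed or inconsistent ensemble input."""


@dataclass(frozen=True)
class EnsembleTrajectory:
    """Frames × labelled points × 3 Cartesian coordinates (Å).

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_points, 3)
        Coordinates in Å; must be finite.
    labels : tuple of str
        Point identifiers, identical across frames, e.g. ``("A:1", "A:2")``.
    seed : int or None
        Seed used to generate the ensemble; ``None`` for loaded data.
    """

    coords: np.ndarray
    labels: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise EnsembleError(
                f"coords must have shape (frames, points, 3), got {coords.shape}"
            )
        if coords.shape[1] != len(self.labels):
            raise EnsembleError(
                f"{coords.shape[1]} points per frame but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise EnsembleError("duplicate labels in ensemble")
        if not np.isfinite(coords).all():
            raise EnsembleError("non-finite coordinates in ensemble")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in ensemble") from None

    def select(self, labels: list[str] | tuple[str, ...]) -> "EnsembleTrajectory":
        """Sub-ensemble restricted to the given labels (kept in given order)."""
        idx = [self.index_of(lb) for lb in labels]
        return replace(self, coords=self.coords[:, idx, :], labels=tuple(labels))

    def mean_structure(self) -> np.ndarray:
        """Per-point mean coordinates over frames, shape (n_points, 3)."""
        return self.coords.mean(axis=0)


def _split_label(label: str) -> tuple[str, int]:
    """Map a ``"chain:resid"`` label onto PDB chain id and residue number."""
    if ":" in label:
        chain, _, res = label.partition(":")
        try:
            return chain[:1] or "X", int(res)
        except ValueError:
            pass
    return "X", 0


def write_frame_csv(traj: EnsembleTrajectory, path) -> None:
    """Write the ensemble as a long-format CSV (frame, label, x, y, z)."""
    n_f, n_p = traj.n_frames, traj.n_points
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_f), n_p),
            "label": list(traj.labels) * n_f,
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
            "z": traj.coords[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def load_frame_csv(path) -> EnsembleTrajectory:
    """Load an ensemble from the long-format CSV written by :func:`write_frame_csv`."""
    df = pd.read_csv(path)
    required = {"frame", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise EnsembleError(f"frame CSV must have columns {sorted(required)}")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    labels = tuple(first["label"].astype(str))
    coords = np.empty((len(frames), len(labels), 3))
    for k, fr in enumerate(frames):
        sub = df[df["frame"] == fr]
        if tuple(sub["label"].astype(str)) != labels:
            raise EnsembleError(f"frame {fr}: label set differs from frame {frames[0]}")
        coords[k] = sub[["x", "y", "z"]].to_numpy()
    return EnsembleTrajectory(coords=coords, labels=labels)


def write_pdb(traj: EnsembleTrajectory, path) -> None:
    """Write the ensemble as a multi-model PDB, one MODEL per frame.

    Points are emitted as Cα pseudo-atoms of glycine residues; chain and
    residue number come from the ``chain:resid`` label convention.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_f, n_p = traj.n_frames, traj.n_points
    stack = struc.AtomArrayStack(n_f, n_p)
    stack.coord = traj.coords.copy()
    chains, resids = zip(*(_split_label(lb) for lb in traj.labels))
    stack.chain_id = np.array(chains, dtype="U4")
    stack.res_id = np.array(resids, dtype=int)
    stack.res_name = np.full(n_p, "GLY", dtype="U5")
    stack.atom_name = np.full(n_p, "CA", dtype="U6")
    stack.element = np.full(n_p, "C", dtype="U2")
    stack.hetero = np.zeros(n_p, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def load_pdb(path) -> EnsembleTrajectory:
    """Load a multi-model PDB into an ensemble (labels rebuilt as chain:resid)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure()
    except Exception as exc:  # inconsistent atom counts across MODELs
        raise EnsembleError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:
        coords = coords[None]
    labels = tuple(
        f"{ch}:{ri}" for ch, ri in zip(stack.chain_id, stack.res_id)
    )
    return EnsembleTrajectory(coords=np.asarray(coords, dtype=float), labels=labels)
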