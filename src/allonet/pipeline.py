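"""Pipeline orchestration: validated configuration, standard-format I/O
and run manifests for the two workflows.

The *dynamics* workflow goes ensemble → DCCM → residue network →
SPM / CPL / node weakening → DFI → distance distributions; the *kinetics*
workflow goes simulated or loaded rate data → nonlinear fits → fold-change
reports.  Every run writes a manifest recording input hashes, seeds and
the parameter values actually used, so identical configurations reproduce
identical numeric outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import kinetics as kin
from . import synthetic
from .dfi import dfi_profile, perturbation_response_matrix
from .ensemble import EnsembleTrajectory, load_frame_csv, load_pdb, write_frame_csv, write_pdb
from .network import build_residue_graph, characteristic_path_length, compute_spm, node_weakening
from .trajstats import compute_dccm, distance_distribution, extract_distance_series

__all__ = ["PipelineConfig", "DynamicsConfig", "KineticsConfig",
           "RunManifest", "load_ensemble", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


def load_ensemble(path, fmt: str | None = None) -> EnsembleTrajectory:
    """Load an ensemble from multi-model PDB or long-format frame CSV.

    The format is inferred from the suffix unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"ensemble file not found: {path}")
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() == ".pdb" else "csv"
    if fmt == "pdb":
        return load_pdb(path)
    if fmt == "csv":
        return load_frame_csv(path)
    raise PipelineError(f"unknown ensemble format {fmt!r}")


class DynamicsConfig(BaseModel):
    """Parameters of the ensemble-analysis workflow.

    Without ``ensemble_path`` a synthetic two-subunit elastic-network
    ensemble is generated (optionally with the interface stiffened to
    emulate regulator binding).
    """

    model_config = ConfigDict(extra="forbid")

    ensemble_path: str | None = None
    n_frames: int = 5000
    mode: str = "scalar"
    covariance_scale: float = 1.0
    interface_factor: float | None = None
    contact_cutoff: float = 6.0
    occupancy_min: float = 0.5
    corr_min: float = 0.05
    spm_threshold: float = 0.3
    spm_pairs: str = "all"
    kde_bandwidth: str | float = "silverman"
    distance_pairs: list[tuple[str, str]] = Field(default_factory=list)
    weaken_nodes: list[str] | None = None


class RateDataset(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    model: str                       # michaelis | melting | binding | hill
    params: dict[str, float | str]
    grid: list[float]
    noise_sd: float = 0.0


class FoldSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    numerator: float
    denominator: float
    numerator_label: str = "numerator"
    denominator_label: str = "denominator"


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    datasets: list[RateDataset] = Field(default_factory=list)
    folds: list[FoldSpec] = Field(default_factory=list)


class PipelineConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    workflow: str                    # "dynamics" | "kinetics"
    seed: int = 0
    outdir: str = "allonet_out"
    dynamics: DynamicsConfig | None = None
    kinetics: KineticsConfig | None = None
    version: str = "1"


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    workflow: str
    seed: int
    parameters: dict
    input_hashes: dict[str, str]
    outputs: dict[str, str]
    output_hashes: dict[str, str]
    timestamp: str

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _derive_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _run_dynamics(cfg: PipelineConfig, outdir: Path) -> tuple[dict, dict]:
    dyn = cfg.dynamics or DynamicsConfig()
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    if dyn.ensemble_path is not None:
        inputs[dyn.ensemble_path] = _sha256(dyn.ensemble_path)
        traj = load_ensemble(dyn.ensemble_path)
        superpose = True
    else:
        net, info = synthetic.build_toy_dimer(cutoff=dyn.contact_cutoff)
        if dyn.interface_factor is not None:
            net = synthetic.perturb_network(net, info["interface"],
                                            dyn.interface_factor)
        cov = synthetic.network_covariance(net, mode=dyn.mode,
                                           scale=dyn.covariance_scale)
        traj = synthetic.sample_ensemble(cov, dyn.n_frames,
                                         seed=_derive_seed(cfg.seed, "ensemble"))
        ens_path = outdir / "ensemble.csv"
        write_frame_csv(traj, ens_path)
        outputs["ensemble"] = str(ens_path)
        pdb_path = outdir / "ensemble.pdb"
        write_pdb(traj, pdb_path)
        outputs["ensemble_pdb"] = str(pdb_path)

    # scalar synthetic ensembles carry no rigid-body motion; superposing a
    # 1-D embedded ensemble is degenerate, so skip it there
    superpose = dyn.mode != "scalar" or dyn.ensemble_path is not None
    dccm = compute_dccm(traj, superpose=superpose)
    dccm_path = outdir / "dccm.tsv"
    dccm.to_tsv(dccm_path)
    outputs["dccm"] = str(dccm_path)

    rg = build_residue_graph(traj, dccm, contact_cutoff=dyn.contact_cutoff,
                             occupancy_min=dyn.occupancy_min,
                             corr_min=dyn.corr_min)
    graphml_path = outdir / "network.graphml"
    rg.to_graphml(graphml_path)
    outputs["network_graphml"] = str(graphml_path)

    spm = compute_spm(rg, threshold=dyn.spm_threshold, pairs=dyn.spm_pairs)
    spm_path = outdir / "spm.csv"
    spm.to_csv(spm_path)
    outputs["spm"] = str(spm_path)

    edges_path = outdir / "network_edges.tsv"
    rg.to_edge_tsv(edges_path, spm=spm)
    outputs["network_edges"] = str(edges_path)

    cpl = characteristic_path_length(rg)
    weaken = node_weakening(rg, dyn.weaken_nodes)
    weaken_path = outdir / "node_weakening.csv"
    weaken.to_csv(weaken_path)
    outputs["node_weakening"] = str(weaken_path)
    (outdir / "cpl.json").write_text(json.dumps(
        {"cpl": cpl.cpl, "n_pairs": cpl.n_pairs,
         "reachable_fraction": cpl.reachable_fraction}, indent=2))
    outputs["cpl"] = str(outdir / "cpl.json")

    cov_est = _trajectory_covariance_model(traj, dyn.mode)
    dfi = dfi_profile(perturbation_response_matrix(cov_est),
                      labels=traj.labels, source="trajectory covariance")
    dfi_path = outdir / "dfi.csv"
    dfi.to_csv(dfi_path)
    outputs["dfi"] = str(dfi_path)

    for a, b in dyn.distance_pairs:
        series = extract_distance_series(traj, a, b)
        name = f"distance_{a}_{b}".replace(":", "")
        p = outdir / f"{name}.csv"
        series.to_csv(p)
        outputs[name] = str(p)
        dist = distance_distribution(series, bandwidth=dyn.kde_bandwidth)
        (outdir / f"{name}_modes.json").write_text(json.dumps(
            {"modes_A": dist.modes.tolist(),
             "bandwidth_A": dist.bandwidth}, indent=2))
        outputs[f"{name}_modes"] = str(outdir / f"{name}_modes.json")

    params = dyn.model_dump()
    params["superpose"] = superpose
    return inputs | {}, outputs | {"__params__": json.dumps(params)}


def _trajectory_covariance_model(traj: EnsembleTrajectory, mode: str):
    """Covariance model estimated from sampled frames (for DFI)."""
    if mode == "scalar":
        x = traj.coords[:, :, 0]
        cov = np.cov(x, rowvar=False, bias=True)
        dropped = 0
    else:
        flat = traj.coords.reshape(traj.n_frames, -1)
        cov = np.cov(flat, rowvar=False, bias=True)
        dropped = 0
    return synthetic.CovarianceModel(
        mean_coords=traj.mean_structure(), labels=traj.labels,
        covariance=cov, mode=mode, dropped_modes=dropped)


_FITTERS = {
    "michaelis": kin.fit_michaelis,
    "melting": kin.fit_melting,
    "binding": kin.fit_binding,
    "hill": kin.fit_hill,
}


def _run_kinetics(cfg: PipelineConfig, outdir: Path) -> tuple[dict, dict]:
    kcfg = cfg.kinetics or KineticsConfig()
    outputs: dict[str, str] = {}
    for ds in kcfg.datasets:
        data = synthetic.simulate_rate_data(
            ds.model, dict(ds.params), ds.grid, noise_sd=ds.noise_sd,
            seed=_derive_seed(cfg.seed, f"rates:{ds.name}"))
        csv_path = outdir / f"{ds.name}_data.csv"
        import pandas as pd

        pd.DataFrame({"x": data.x, "v": data.v}).to_csv(csv_path, index=False)
        outputs[f"{ds.name}_data"] = str(csv_path)
        fit = _FITTERS[ds.model](data)
        report = fit.as_dict()
        report["dataset"] = ds.name
        fit_path = outdir / f"{ds.name}_fit.json"
        fit_path.write_text(json.dumps(report, indent=2))
        outputs[f"{ds.name}_fit"] = str(fit_path)
    folds = []
    for spec in kcfg.folds:
        rep = kin.fold_change(spec.numerator, spec.denominator,
                              numerator_label=spec.numerator_label,
                              denominator_label=spec.denominator_label)
        folds.append({"name": spec.name, "fold": rep.fold,
                      "fold_rounded": rep.fold_rounded})
    if folds:
        fold_path = outdir / "fold_changes.json"
        fold_path.write_text(json.dumps(folds, indent=2))
        outputs["fold_changes"] = str(fold_path)
    return {}, outputs


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute a configured workflow and return its manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.workflow == "dynamics":
        inputs, outputs = _run_dynamics(config, outdir)
    elif config.workflow == "kinetics":
        inputs, outputs = _run_kinetics(config, outdir)
    else:
        raise PipelineError(f"unknown workflow {config.workflow!r}")
    params = outputs.pop("__params__", None)
    manifest = RunManifest(
        workflow=config.workflow,
        seed=config.seed,
        parameters=config.model_dump() | (
            {"effective_dynamics": json.loads(params)} if params else {}),
        input_hashes=inputs,
        outputs=outputs,
        output_hashes={k: _sha256(v) for k, v in outputs.items()},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
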